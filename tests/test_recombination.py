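import itertools
import math

import numpy as np
import pytest

from wtfkit.family_sim import inject_single_crossover
from wtfkit.recombination import (
    AlignmentMatrix, PhiResult, compare_regions, max_descent_p_value,
    phi_test, refined_incompatibility, rmin, triplet_scan,
)
from .conftest import mutate_dna, random_dna

# ---------------------------------------------------------------------------
# independent oracles


def all_unrooted_trees(n_leaves: int):
    """All leaf-labelled unrooted binary topologies as adjacency dicts;
    leaves are 0..n-1, internal nodes negative."""
    base = {0: [-1], 1: [-1], 2: [-1], -1: [0, 1, 2]}
    trees = [base]
    next_internal = -2
    for leaf in range(3, n_leaves):
        new_trees = []
        for t in trees:
            edges = {tuple(sorted((a, b), reverse=True))
                     for a, nbrs in t.items() for b in nbrs}
            for (a, b) in edges:
                t2 = {k: list(v) for k, v in t.items()}
                mid = next_internal
                t2[a].remove(b)
                t2[b].remove(a)
                t2[a].append(mid)
                t2[b].append(mid)
                t2[mid] = [a, b, leaf]
                t2[leaf] = [mid]
                new_trees.append(t2)
        trees = new_trees
        next_internal -= 1
    return trees


def fitch_steps(tree: dict, char: dict[int, int]) -> int:
    """Minimal substitutions for one multistate character (Fitch)."""
    root = min(k for k in tree if k < 0)
    steps = 0

    def down(node, parent):
        nonlocal steps
        kids = [x for x in tree[node] if x != parent]
        if not kids:
            return {char[node]}
        sets = [down(k, node) for k in kids]
        inter = set.intersection(*sets)
        if len(sets) == 1:
            return sets[0]
        if inter:
            acc = sets[0]
            for s in sets[1:]:
                if acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    steps += 1
            return acc
        acc = sets[0]
        for s in sets[1:]:
            if acc & s:
                acc = acc & s
            else:
                acc = acc | s
                steps += 1
        return acc

    down(root, None)
    return steps


def oracle_pair_incompatibility(site_a, site_b) -> int:
    """Minimum homoplasies over every tree, by exhaustive topology search."""
    taxa = [t for t in range(len(site_a)) if site_a[t] >= 0 and site_b[t] >= 0]
    relabel = {t: i for i, t in enumerate(taxa)}
    ca = {relabel[t]: int(site_a[t]) for t in taxa}
    cb = {relabel[t]: int(site_b[t]) for t in taxa}
    ka = len(set(ca.values()))
    kb = len(set(cb.values()))
    best = math.inf
    for tree in all_unrooted_trees(len(taxa)):
        best = min(best, fitch_steps(tree, ca) + fitch_steps(tree, cb))
    return int(best - (ka - 1) - (kb - 1))


def oracle_max_disjoint_intervals(intervals) -> int:
    """Max number of pairwise disjoint open intervals, by DP over the sorted
    list (independent of the greedy in rmin)."""
    ivs = sorted(intervals)
    n = len(ivs)
    memo = {}

    def best(i):
        if i >= n:
            return 0
        if i in memo:
            return memo[i]
        skip = best(i + 1)
        l, r = ivs[i]
        j = i + 1
        while j < n and ivs[j][0] < r:
            j += 1
        memo[i] = max(skip, 1 + best(j))
        return memo[i]

    return best(0)


def oracle_rmin(matrix: np.ndarray) -> int:
    """Four-gamete incompatible pairs + exact disjoint-interval count,
    re-derived from scratch on a 0/1 site matrix (taxa x sites)."""
    n_sites = matrix.shape[1]
    intervals = []
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if len(np.unique(matrix[:, i])) < 2 or len(np.unique(matrix[:, j])) < 2:
                continue
            gametes = {(int(a), int(b)) for a, b in zip(matrix[:, i], matrix[:, j])}
            if len(gametes) == 4:
                intervals.append((i, j))
    return oracle_max_disjoint_intervals(intervals)


# ---------------------------------------------------------------------------


class TestRefinedIncompatibility:
    def test_three_gametes_compatible(self):
        a = np.array([0, 0, 1, 1, 0])
        b = np.array([0, 1, 1, 1, 0])  # gametes 00, 01, 11 only
        assert refined_incompatibility(a, b) == 0

    def test_four_gametes_score_one(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert refined_incompatibility(a, b) == 1

    def test_too_few_complete_taxa_scores_zero(self):
        a = np.array([0, 1, -1, -1])
        b = np.array([0, -1, 1, 0])
        assert refined_incompatibility(a, b) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_multistate_pair_matches_exhaustive_tree_search(self, seed):
        # 3-state x 2-state characters over 6 taxa vs brute force over all
        # 105 unrooted topologies scored by Fitch parsimony
        rng = np.random.default_rng(seed)
        while True:
            a = rng.integers(0, 3, 6)
            b = rng.integers(0, 2, 6)
            if len(set(a)) == 3 and len(set(b)) == 2:
                break
        assert refined_incompatibility(a, b) == oracle_pair_incompatibility(a, b)


class TestPhi:
    def test_alignment_validation(self):
        with pytest.raises(ValueError):
            AlignmentMatrix(["a"], ["ACGT"])
        with pytest.raises(ValueError):
            AlignmentMatrix(["a", "b"], ["ACGT", "ACG"])

    def test_duplicated_identical_rows_not_testable(self):
        aln = AlignmentMatrix(list("abcd"), ["ACGTACGT"] * 4)
        res = phi_test(aln, permutations=100, seed=0)
        assert not res.testable and res.p_perm == 1.0

    def test_statistic_zero_on_tree_like_alignment_gives_p_one(self):
        # two clades, nested infinite-sites mutations: fully compatible
        rows = ["AAAAAA", "AAAAAG", "CCAAAA", "CCAATA", "CCGATA", "CCGATA"]
        aln = AlignmentMatrix([f"t{i}" for i in range(6)], rows)
        res = phi_test(aln, permutations=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_perm == 1.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        rows = ["".join(r) for r in
                np.array(list("ACGT"))[rng.integers(0, 4, (8, 120))]]
        aln = AlignmentMatrix([f"t{i}" for i in range(8)], rows)
        r1 = phi_test(aln, permutations=200, seed=3)
        r2 = phi_test(aln, permutations=200, seed=3)
        assert (r1.statistic, r1.p_perm) == (r2.statistic, r2.p_perm)

    def test_mosaic_alignment_detected(self):
        # 12 taxa, two diverged haplotype blocks recombined at the midpoint
        rng = np.random.default_rng(8)
        a = random_dna(rng, 400)
        b = mutate_dna(rng, a, 0.25)
        rows = []
        for i in range(12):
            left = a if i % 2 else b
            right = a if i % 4 < 2 else b
            row = left[:200] + right[200:]
            rows.append(mutate_dna(rng, row, 0.01))
        aln = AlignmentMatrix([f"t{i}" for i in range(12)], rows)
        res = phi_test(aln, permutations=500, seed=0)
        assert res.p_perm < 0.05


class TestTripletScan:
    def test_child_identical_to_parent_p(self):
        aln = AlignmentMatrix(
            ["P", "Q", "C"],
            ["AAAACCCC", "GGGGTTTT", "AAAACCCC"])
        res = triplet_scan(aln, candidate_triplets=[("P", "Q", "C")])
        r = res[0]
        assert r.n == 0 and r.max_descent == 0 and r.p_exact == 1.0

    def test_uuuddd_descent_equals_enumeration(self):
        # m=3 up then n=3 down: k=3; p = #arrangements with descent>=3 / 20
        count = 0
        for pos in itertools.combinations(range(6), 3):
            steps = [1 if i in pos else -1 for i in range(6)]
            run_max = cur = drop = 0
            for s in steps:
                cur += s
                run_max = max(run_max, cur)
                drop = max(drop, run_max - cur)
            if drop >= 3:
                count += 1
        assert max_descent_p_value(3, 3, 3) == pytest.approx(count / 20)

    @pytest.mark.parametrize("m,n", [(2, 2), (3, 4), (4, 3), (4, 4)])
    def test_dp_matches_enumeration_small(self, m, n):
        for k in range(0, n + 1):
            count = 0
            total = 0
            for pos in itertools.combinations(range(m + n), m):
                steps = [1 if i in pos else -1 for i in range(m + n)]
                run_max = cur = drop = 0
                for s in steps:
                    cur += s
                    run_max = max(run_max, cur)
                    drop = max(drop, run_max - cur)
                total += 1
                count += drop >= k
            assert max_descent_p_value(m, n, k) == pytest.approx(count / total)

    def test_chimera_breakpoint_recovered(self):
        rng = np.random.default_rng(3)
        p = random_dna(rng, 600)
        q = mutate_dna(rng, p, 0.15)
        bp = 300
        chim, _ = inject_single_crossover(p, q, bp)
        out = mutate_dna(rng, p, 0.3)
        aln = AlignmentMatrix(["P", "Q", "C", "O"], [p, q, chim, out])
        res = triplet_scan(aln, candidate_triplets=[("P", "Q", "C")])[0]
        assert res.max_descent > 0 and res.p_exact < 0.01
        lo, hi = res.breakpoint_interval
        assert lo <= bp + 1 and hi >= bp

    def test_sidak_correction_bounded(self):
        rng = np.random.default_rng(4)
        rows = [random_dna(rng, 100) for _ in range(4)]
        aln = AlignmentMatrix(list("abcd"), rows)
        for r in triplet_scan(aln):
            assert 0.0 <= r.p_corrected <= 1.0
            assert r.p_corrected >= r.p_exact - 1e-12


class TestRmin:
    def test_single_four_gamete_pair(self):
        aln = AlignmentMatrix(list("abcd"), ["AA", "AT", "CA", "CT"])
        res = rmin(aln)
        assert res.rmin == 1
        assert res.incompatible_intervals == [(1, 2)]

    def test_compatible_alignment_is_zero(self):
        aln = AlignmentMatrix(list("abcd"), ["AAAA", "AAAT", "CCAA", "CCTA"])
        assert rmin(aln).rmin == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, (8, 20))
        rows = ["".join("AC"[v] for v in row) for row in mat]
        aln = AlignmentMatrix([f"t{i}" for i in range(8)], rows)
        assert rmin(aln).rmin == oracle_rmin(mat)


class TestCompareRegions:
    def _aln_with_hotspot(self):
        # incompatibility confined to the first 40 columns ("exon 1")
        rows = []
        for i in range(8):
            row = list("A" * 100)
            row[4] = "C" if i in (2, 3, 6, 7) else "A"
            row[30] = "T" if i in (1, 3, 5, 7) else "A"
            rows.append("".join(row))
        return AlignmentMatrix([f"t{i}" for i in range(8)], rows)

    def test_hotspot_partition_ranks_highest(self):
        df = compare_regions({"g1": self._aln_with_hotspot()}, {"g1": 40})
        assert df.loc["g1", "exon1"] > df.loc["g1", "rest"]

    def test_compatible_groups_are_all_zero(self):
        aln = AlignmentMatrix(list("abcd"), ["AAAA", "AAAT", "CCAA", "CCTA"])
        df = compare_regions({"g": aln}, {"g": 2})
        assert (df[["full", "exon1", "rest"]].fillna(0) == 0).all().all()

    def test_group_ranking_orders_by_full_rate(self):
        hot = self._aln_with_hotspot()
        cold = AlignmentMatrix(list("abcd"), ["AAAA", "AAAT", "CCAA", "CCTA"])
        df = compare_regions({"hot": hot, "cold": cold}, {"hot": 40, "cold": 2})
        assert df.index[0] == "hot"
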