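"""Recombination-signal statistics on multiple sequence alignments.

Three complementary detectors:

* a pairwise homoplasy (PHI-style) test — mean refined incompatibility over
  nearby informative-site pairs, with a column-permutation null;
* a triplet breakpoint scan — for each (parent P, parent Q, child C) triple,
  a +/-1 random walk over sites where C matches exactly one parent, scored by
  the maximum descent from a running maximum, with an exact combinatorial
  p-value and a breakpoint interval;
* the four-gamete minimum recombination count Rmin with Hudson-Kaplan
  interval thinning, reported per ungapped bp for between-region and
  between-group comparisons.

Gap ('-') and ambiguous ('N') characters are handled by pairwise deletion:
each site pair or triplet drops the taxa undefined at the sites involved.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SeqRecordSet

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": -1, "N": -1}


class AlignmentMatrix:
    """Aligned sequences as a taxa x columns character matrix over {A,C,G,T,-,N}."""

    def __init__(self, taxa: Sequence[str], rows: Sequence[str]):
        if len(taxa) != len(rows):
            raise ValueError("taxa and rows differ in length")
        if len(taxa) < 2:
            raise ValueError("an alignment needs at least 2 taxa")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        self.taxa = list(taxa)
        self.matrix = np.array([list(r.upper()) for r in rows], dtype="U1")

    @classmethod
    def from_seqrecords(cls, records: SeqRecordSet) -> "AlignmentMatrix":
        return cls(records.ids(), [e.seq for e in records])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        from .io_formats import read_fasta
        return cls.from_seqrecords(read_fasta(path))

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sub_columns(self, cols: Sequence[int] | slice) -> "AlignmentMatrix":
        sub = self.matrix[:, cols]
        return AlignmentMatrix(self.taxa, ["".join(r) for r in sub])

    def sub_taxa(self, names: Sequence[str]) -> "AlignmentMatrix":
        idx = [self.taxa.index(n) for n in names]
        return AlignmentMatrix(list(names), ["".join(self.matrix[i]) for i in idx])

    def encoded(self) -> np.ndarray:
        """Integer encoding: A,C,G,T -> 0..3; gap and N -> -1."""
        enc = np.full(self.matrix.shape, -1, dtype=np.int8)
        for ch, code in _CODE.items():
            if code >= 0:
                enc[self.matrix == ch] = code
        return enc

    def ungapped_length(self) -> int:
        """Columns whose majority character is not a gap (physical consensus length)."""
        return int(np.sum(~self._consensus_gap()))

    def _consensus_gap(self) -> np.ndarray:
        return np.mean(self.matrix == "-", axis=0) > 0.5

    def consensus_coordinates(self) -> np.ndarray:
        """Physical (ungapped-consensus) coordinate of every alignment column."""
        return np.cumsum(~self._consensus_gap())


# ---------------------------------------------------------------------------
# Refined incompatibility


def _components(edges: list[tuple[int, int]], nodes: set[int]) -> int:
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(v) for v in nodes})


def refined_incompatibility(site_i: np.ndarray, site_j: np.ndarray) -> int:
    """Minimum number of extra (homoplasious) steps any tree needs for a site pair.

    After pairwise deletion of taxa undefined at either site, build the
    state-intersection (partition) graph: one node per observed state at each
    site, one edge per observed joint state.  The minimum extra steps over all
    trees equals the graph's cycle rank  E - V + C; it is 0 exactly when the
    two characters are compatible.  Sites may carry -1 for gap/N (dropped).
    """
    mask = (site_i >= 0) & (site_j >= 0)
    if int(mask.sum()) < 4:
        return 0  # too few complete taxa to witness incompatibility
    a, b = site_i[mask], site_j[mask]
    joint = np.unique(a.astype(np.int64) * 8 + b)
    states_a = {int(s >> 3) for s in joint}
    states_b = {int(s & 7) + 8 for s in joint}
    if len(states_a) < 2 or len(states_b) < 2:
        return 0
    edges = [(int(s >> 3), int(s & 7) + 8) for s in joint]
    nodes = states_a | states_b
    c = _components(edges, nodes)
    return len(edges) - len(nodes) + c


def _informative_columns(enc: np.ndarray) -> np.ndarray:
    """Parsimony-informative columns: >=2 states each carried by >=2 taxa."""
    cols = []
    for j in range(enc.shape[1]):
        col = enc[:, j]
        vals, counts = np.unique(col[col >= 0], return_counts=True)
        if np.sum(counts >= 2) >= 2:
            cols.append(j)
    return np.array(cols, dtype=int)


def _pair_score_matrix(sites: list[np.ndarray]) -> np.ndarray:
    """All-pairs refined incompatibility; complete biallelic pairs take a
    bitmask four-gamete fast path, everything else the general scorer."""
    k = len(sites)
    full = (1 << len(sites[0])) - 1
    masks: list[tuple[int, int] | None] = []
    def bitmask(cond: np.ndarray) -> int:
        m = 0
        for b in np.flatnonzero(cond):
            m |= 1 << int(b)
        return m

    for s in sites:
        valid = bitmask(s >= 0)
        vals = np.unique(s[s >= 0])
        if len(vals) == 2:
            masks.append((valid, bitmask(s == vals[1])))
        else:
            masks.append(None)
    scores = np.zeros((k, k))
    for i in range(k):
        mi = masks[i]
        for j in range(i + 1, k):
            mj = masks[j]
            if mi is not None and mj is not None and mi[0] == mj[0] == full:
                a, b = mi[1], mj[1]
                s = int(bool(a & b) and bool(a & ~b & full)
                        and bool(~a & b & full) and bool(~a & ~b & full))
            else:
                s = refined_incompatibility(sites[i], sites[j])
            if s:
                scores[i, j] = scores[j, i] = s
    return scores


@dataclasses.dataclass
class PhiResult:
    statistic: float
    window_w: int
    p_perm: float
    n_informative: int
    permutations_used: int
    testable: bool = True


def phi_test(aln: AlignmentMatrix, w: int = 100, permutations: int = 1000,
             seed: int | None = None) -> PhiResult:
    """Homoplasy-based recombination test with a permutation null.

    The statistic is the mean refined incompatibility over all pairs of
    parsimony-informative sites lying within ``w`` bp of each other, distance
    measured on the ungapped consensus.  Under clonal evolution homoplasy is
    independent of inter-site distance, while recombination leaves nearby
    sites more compatible than distant ones — so the test rejects when the
    observed statistic is LOW against the null that permutes the assignment
    of informative-site contents to physical positions.  The p-value is the
    add-one-corrected lower tail  (1 + #{perm <= obs}) / (1 + permutations).
    """
    if aln.n_taxa < 4:
        return PhiResult(0.0, w, 1.0, 0, 0, testable=False)
    enc = aln.encoded()
    inf_cols = _informative_columns(enc)
    k = len(inf_cols)
    if k < 2:
        return PhiResult(0.0, w, 1.0, k, 0, testable=False)
    coords = aln.consensus_coordinates()[inf_cols]
    # index pairs of informative sites within the physical window
    ia, ib = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if coords[j] - coords[i] > w:
                break
            ia.append(i)
            ib.append(j)
    if not ia:
        return PhiResult(0.0, w, 1.0, k, 0, testable=False)
    ia = np.array(ia)
    ib = np.array(ib)
    # score matrix over informative-site pairs (contents only; position-free)
    sites = [enc[:, c] for c in inf_cols]
    scores = _pair_score_matrix(sites)
    observed = float(scores[ia, ib].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(k)
        if scores[perm[ia], perm[ib]].mean() <= observed + 1e-12:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PhiResult(observed, w, p, k, permutations)


# ---------------------------------------------------------------------------
# Triplet breakpoint scan


def max_descent_p_value(m: int, n: int, k: int) -> float:
    """Exact P(max descent >= k) for a uniformly random arrangement of
    ``m`` up-steps and ``n`` down-steps.

    Dynamic programme over (ups used, downs used, deficit below the running
    maximum); a walk is absorbed when the deficit reaches ``k``, and absorbed
    prefixes are completed freely.  Exact integer arithmetic.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    total = math.comb(m + n, m)
    # f[(u, d)] = number of unabsorbed prefixes with u ups, current deficit d
    f = {(0, 0): 1}
    hits = 0
    for step in range(m + n):
        nxt: dict[tuple[int, int], int] = {}
        for (u, d), cnt in f.items():
            t = step  # steps taken so far
            downs = t - u
            if u < m:  # place an up-step
                key = (u + 1, max(d - 1, 0))
                nxt[key] = nxt.get(key, 0) + cnt
            if downs < n:  # place a down-step
                if d + 1 >= k:
                    # absorbed: remaining steps arranged freely
                    rem_u, rem_d = m - u, n - downs - 1
                    hits += cnt * math.comb(rem_u + rem_d, rem_u)
                else:
                    key = (u, d + 1)
                    nxt[key] = nxt.get(key, 0) + cnt
        f = nxt
    return hits / total


@dataclasses.dataclass
class TripletResult:
    child: str
    parent_p: str
    parent_q: str
    m: int
    n: int
    max_descent: int
    p_exact: float
    breakpoint_interval: tuple[int, int]  # 1-based inclusive alignment columns
    p_corrected: float = float("nan")


def _triplet_walk(aln: AlignmentMatrix, p: str, q: str, c: str
                  ) -> tuple[list[int], list[int]]:
    """Informative columns (1-based) and +1/-1 steps for child C against P, Q."""
    ep, eq, ec = (aln.row(t) for t in (p, q, c))
    cols, steps = [], []
    for j in range(aln.length):
        a, b, x = ep[j], eq[j], ec[j]
        if "-" in (a, b, x) or "N" in (a, b, x) or a == b:
            continue
        if x == a:
            cols.append(j + 1)
            steps.append(1)
        elif x == b:
            cols.append(j + 1)
            steps.append(-1)
    return cols, steps


def _max_descent(steps: Sequence[int]) -> tuple[int, int, int]:
    """(k, peak_index, trough_index) of the maximal drop from a running maximum."""
    best, cur, runmax = 0, 0, 0
    peak = trough = peak_at_runmax = -1
    for i, s in enumerate(steps):
        cur += s
        if cur >= runmax:
            runmax = cur
            peak_at_runmax = i
        drop = runmax - cur
        if drop > best:
            best = drop
            peak = peak_at_runmax
            trough = i
    return best, peak, trough


def triplet_scan(aln: AlignmentMatrix,
                 candidate_triplets: Iterable[tuple[str, str, str]] | None = None,
                 correction: str = "dunn-sidak") -> list[TripletResult]:
    """Scan ordered (P, Q, C) triplets for mosaic ancestry in C.

    Informative sites are columns where C matches exactly one of P and Q;
    the walk takes +1 on a P match and -1 on a Q match.  The statistic is the
    maximum descent; its exact p-value treats the arrangement of up and down
    steps as exchangeable.  ``correction`` in {"dunn-sidak", "bonferroni"}
    adjusts for the number of triplets actually tested.
    """
    if aln.n_taxa < 3:
        raise ValueError("triplet_scan needs at least 3 taxa")
    if candidate_triplets is None:
        candidate_triplets = [
            (p, q, c)
            for c in aln.taxa
            for p, q in itertools.combinations([t for t in aln.taxa if t != c], 2)
        ]
    results: list[TripletResult] = []
    for p, q, c in candidate_triplets:
        cols, steps = _triplet_walk(aln, p, q, c)
        if not steps:
            continue
        m = steps.count(1)
        n = steps.count(-1)
        k, peak, trough = _max_descent(steps)
        p_exact = max_descent_p_value(m, n, k)
        if k == 0:
            interval = (1, aln.length)
        else:
            start = 1 if peak < 0 else cols[peak] + 1
            interval = (start, cols[trough])
        results.append(TripletResult(c, p, q, m, n, k, p_exact, interval))
    t = len(results)
    for r in results:
        if correction == "bonferroni":
            r.p_corrected = min(1.0, r.p_exact * t)
        else:
            r.p_corrected = 1.0 - (1.0 - r.p_exact) ** t
    return results


# ---------------------------------------------------------------------------
# Minimum recombination (four-gamete) count


@dataclasses.dataclass
class RminResult:
    rmin: int
    incompatible_intervals: list[tuple[int, int]]  # 1-based column pairs
    per_bp: float


def _biallelic_sites(aln: AlignmentMatrix) -> tuple[list[int], list[np.ndarray]]:
    enc = aln.encoded()
    cols, binary = [], []
    for j in range(enc.shape[1]):
        col = enc[:, j]
        vals = np.unique(col[col >= 0])
        if len(vals) != 2:
            continue  # monomorphic or >2 states excluded
        b = np.where(col < 0, -1, (col == vals[1]).astype(np.int8))
        cols.append(j)
        binary.append(b)
    return cols, binary


def _four_gamete(a: np.ndarray, b: np.ndarray) -> bool:
    mask = (a >= 0) & (b >= 0)
    if mask.sum() < 4:
        return False
    pairs = {(int(x), int(y)) for x, y in zip(a[mask], b[mask])}
    return len(pairs) == 4


def rmin(aln: AlignmentMatrix) -> RminResult:
    """Hudson-Kaplan minimum number of recombination events.

    Biallelic sites only; every four-gamete-incompatible site pair defines an
    open interval that must contain a recombination event.  Intervals that
    contain another interval are redundant; the thinned maximal set of
    mutually disjoint intervals has size Rmin.
    """
    if aln.n_taxa < 4:
        raise ValueError("rmin needs at least 4 taxa")
    cols, binary = _biallelic_sites(aln)
    intervals: list[tuple[int, int]] = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if _four_gamete(binary[i], binary[j]):
                intervals.append((cols[i] + 1, cols[j] + 1))
    # greedy disjoint-interval selection by right endpoint == Hudson-Kaplan count
    chosen: list[tuple[int, int]] = []
    last_right = -1
    for left, right in sorted(intervals, key=lambda iv: iv[1]):
        if left >= last_right:  # open intervals (left, right): disjoint if no shared gap
            chosen.append((left, right))
            last_right = right
    ung = aln.ungapped_length()
    return RminResult(len(chosen), chosen, len(chosen) / ung if ung else 0.0)


def compare_regions(alignments_by_group: Mapping[str, AlignmentMatrix],
                    exon1_end_by_group: Mapping[str, int]) -> pd.DataFrame:
    """Per-bp Rmin for {full, exon1, rest} partitions of each group's alignment.

    ``exon1_end_by_group`` gives the 1-based alignment column where exon 1
    ends.  Groups are ranked by the full-length per-bp rate; empty partitions
    are reported as NA.
    """
    rows = []
    for group, aln in alignments_by_group.items():
        cut = exon1_end_by_group.get(group)
        entry = {"group": group}
        entry["full"] = rmin(aln).per_bp
        if cut is None or not 0 < cut < aln.length:
            entry["exon1"] = float("nan")
            entry["rest"] = float("nan")
        else:
            entry["exon1"] = rmin(aln.sub_columns(slice(0, cut))).per_bp
            entry["rest"] = rmin(aln.sub_columns(slice(cut, aln.length))).per_bp
        rows.append(entry)
    df = pd.DataFrame(rows).set_index("group")
    df["rank_full"] = df["full"].rank(ascending=False, method="min").astype(int)
    return df.sort_values("rank_full")
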