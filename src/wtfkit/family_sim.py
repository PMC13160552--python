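"""Forward-time simulator of a multi-locus poison-antidote-like gene family.

Strains evolve along a random coalescent-shaped genealogy.  Each generation,
every family member independently draws point mutations, duplication to a
brand-new locus, gene conversion (a tract copied in from a random co-resident
family member), and pseudogenization (a stop-gain at a random in-frame
codon).  Genes are gap-free, so every copy lives on the shared ancestral
coordinate system and the simulator can emit exact ("true") alignments with
no aligner.  Every event is written to a ground-truth log, and each locus
carries unique flanking sequence inherited down the strain tree, which makes
flank-based locus assignment testable.

All randomness flows from a single seed; identical parameters and seed give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import Feature, FeatureTable, SeqEntry, SeqRecordSet
from .recombination import AlignmentMatrix

_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

SPACER_LEN = 100


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


@dataclasses.dataclass(frozen=True)
class AncestorModel:
    """Exon/intron template of the founding gene (lengths in bp).

    The default mirrors a six-exon driver-type family member: ~1.7 kb of
    coding sequence split over six exons with five short introns, 2 kb of
    unspliced gene in total.
    """
    exon_lengths: tuple[int, ...] = (300, 240, 240, 240, 240, 420)
    intron_lengths: tuple[int, ...] = (64, 64, 64, 64, 64)

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if sum(self.exon_lengths) % 3 != 0:
            raise ValueError("spliced length must be a multiple of 3")

    @property
    def gene_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def exon_intervals(self) -> list[tuple[int, int]]:
        """1-based inclusive exon coordinates in gene space."""
        out, pos = [], 1
        for i, el in enumerate(self.exon_lengths):
            out.append((pos, pos + el - 1))
            pos += el
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return out

    def spliced_positions(self) -> np.ndarray:
        """0-based gene-space indices of spliced (exonic) sites, 5'->3'."""
        idx = []
        for s, e in self.exon_intervals():
            idx.extend(range(s - 1, e))
        return np.array(idx, dtype=int)


@dataclasses.dataclass
class FamilySimParams:
    n_strains: int = 5
    n_loci: int = 8
    generations: int = 400
    mu: float = 2e-5              # per-site per-generation substitution prob
    dup_rate: float = 1e-4        # per-gene per-generation duplication prob
    conv_rate: float = 2e-4       # per-gene per-generation conversion prob
    tract_len_mean: float = 300.0  # mean conversion tract length (geometric)
    pseudo_rate: float = 1e-4     # per-gene per-generation stop-gain prob
    ancestor_model: AncestorModel = dataclasses.field(default_factory=AncestorModel)
    flank_len: int = 1000
    infinite_sites: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("mu", "dup_rate", "conv_rate", "pseudo_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_strains < 1 or self.n_loci < 1 or self.generations < 1:
            raise ValueError("counts must be >= 1")
        if self.tract_len_mean < 1:
            raise ValueError("tract_len_mean must be >= 1")
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")


@dataclasses.dataclass
class SimEvent:
    kind: str            # mutation | duplication | conversion | pseudogenization
    time: int            # generation (depth from root)
    lineage: str         # tree-node label where the event happened
    gene: int            # internal gene uid
    details: dict


@dataclasses.dataclass
class TruthLog:
    events: list[SimEvent]
    genealogy_newick: str
    registry: pd.DataFrame  # one row per final gene copy
    n_loci_final: int

    def events_of(self, kind: str) -> list[SimEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_tsv(self, path) -> None:
        rows = [
            {"kind": e.kind, "time": e.time, "lineage": e.lineage,
             "gene_uid": e.gene, **{f"detail_{k}": v for k, v in e.details.items()}}
            for e in self.events
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class SimOutput:
    genomes: dict[str, SeqRecordSet]
    models: dict[str, FeatureTable]
    true_alignments: dict[str, AlignmentMatrix]
    truth: TruthLog
    params: FamilySimParams

    def family_alignment(self, loci: Sequence[str] | None = None) -> AlignmentMatrix:
        """Pool gene copies from the chosen loci (default: all) into one
        alignment; valid because all copies share the ancestral coordinates."""
        taxa, rows = [], []
        for locus, aln in sorted(self.true_alignments.items()):
            if loci is not None and locus not in loci:
                continue
            for t, r in zip(aln.taxa, aln.matrix):
                taxa.append(t)
                rows.append("".join(r))
        if len(taxa) < 2:
            raise ValueError("fewer than 2 gene copies in the requested loci")
        return AlignmentMatrix(taxa, rows)


# ---------------------------------------------------------------------------
# internal sim state

class _Gene:
    __slots__ = ("uid", "locus", "seq", "pseudo")

    def __init__(self, uid: int, locus: str, seq: np.ndarray, pseudo: bool = False):
        self.uid = uid
        self.locus = locus
        self.seq = seq
        self.pseudo = pseudo

    def copy(self, uid: int | None = None, locus: str | None = None) -> "_Gene":
        return _Gene(uid if uid is not None else self.uid,
                     locus if locus is not None else self.locus,
                     self.seq.copy(), self.pseudo)


class _Node:
    def __init__(self, label: str, time: int):
        self.label = label
        self.time = time  # depth from root, in generations
        self.children: list[_Node] = []

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}"
        inner = ",".join(
            f"{c.newick()}:{c.time - self.time}" for c in self.children)
        return f"({inner}){self.label}"


def _coalescent_tree(n: int, generations: int, rng: np.random.Generator) -> _Node:
    """Random bifurcating ultrametric genealogy with leaf depth = generations."""
    leaves = [_Node(f"S{i + 1:02d}", 0) for i in range(n)]
    if n == 1:
        root = _Node("N1", 0)
        root.children = [leaves[0]]
        leaves[0].time = generations
        # single lineage: root->leaf branch carries all generations
        return _relabel_depths(root, generations)
    nodes = list(leaves)
    times = {id(nd): 0.0 for nd in nodes}
    t = 0.0
    counter = 0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        counter += 1
        parent = _Node(f"N{counter}", 0)
        parent.children = [nodes[i], nodes[j]]
        times[id(parent)] = t
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)] + [parent]
    root = nodes[0]
    depth = times[id(root)]

    def set_time(node: _Node):
        # node.time = generations from root down to the node
        node.time = int(round(generations * (1.0 - times[id(node)] / depth)))
        for c in node.children:
            set_time(c)

    set_time(root)
    return root


def _relabel_depths(root: _Node, generations: int) -> _Node:
    root.time = 0
    for c in root.children:
        c.time = generations
    return root


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        cod = "".join(_BASES[rng.integers(0, 4, size=3)])
        if cod not in _STOP_CODONS:
            codons.append(cod)
    codons.append("TAA")
    return "".join(codons)


def _ancestral_gene(model: AncestorModel, rng: np.random.Generator) -> np.ndarray:
    cds = _random_cds(sum(model.exon_lengths) // 3, rng)
    gene = np.empty(model.gene_length, dtype=np.int8)
    gene[:] = rng.integers(0, 4, size=model.gene_length)  # introns random
    spliced_pos = model.spliced_positions()
    gene[spliced_pos] = _encode(cds)
    return gene


class _SimState:
    def __init__(self, params: FamilySimParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.model = params.ancestor_model
        self.L = self.model.gene_length
        self.events: list[SimEvent] = []
        self.used_sites: set[int] = set()  # infinite-sites bookkeeping
        self.next_uid = 0
        self.next_locus = 0
        self.exonic = set(int(i) for i in self.model.spliced_positions())
        self.spliced_pos = self.model.spliced_positions()
        n_codons = len(self.spliced_pos) // 3
        # stop-gains land before the final 10% of codons, after the start codon
        self.pseudo_codon_max = max(2, int(math.floor(n_codons * 0.9)) - 1)

    def new_uid(self) -> int:
        self.next_uid += 1
        return self.next_uid

    def new_locus(self) -> str:
        self.next_locus += 1
        return f"L{self.next_locus:02d}"

    def mutate_site(self, seq: np.ndarray, site: int) -> None:
        old = seq[site]
        seq[site] = (old + 1 + self.rng.integers(0, 3)) % 4

    def draw_mutation_sites(self, count: int) -> list[int]:
        if count == 0:
            return []
        if not self.params.infinite_sites:
            return list(self.rng.integers(0, self.L, size=count))
        sites = []
        free = self.L - len(self.used_sites)
        if count > free:
            raise RuntimeError(
                "infinite-sites model exhausted: use a longer ancestral gene")
        while len(sites) < count:
            s = int(self.rng.integers(0, self.L))
            if s not in self.used_sites:
                self.used_sites.add(s)
                sites.append(s)
        return sites


def _evolve_branch(state: _SimState, node: _Node, genes: list[_Gene],
                   flanks: dict[str, tuple[np.ndarray, np.ndarray]],
                   start_gen: int, n_gens: int) -> None:
    p = state.params
    rng = state.rng
    L = state.L
    for g in range(n_gens):
        now = start_gen + g
        for gene in list(genes):
            nmut = int(rng.binomial(L, p.mu))
            if nmut:
                for site in state.draw_mutation_sites(nmut):
                    state.mutate_site(gene.seq, site)
                    state.events.append(SimEvent(
                        "mutation", now, node.label, gene.uid, {"site": site + 1}))
            if p.dup_rate and rng.random() < p.dup_rate:
                locus = state.new_locus()
                newg = gene.copy(uid=state.new_uid(), locus=locus)
                genes.append(newg)
                flanks[locus] = (rng.integers(0, 4, size=p.flank_len).astype(np.int8),
                                 rng.integers(0, 4, size=p.flank_len).astype(np.int8))
                state.events.append(SimEvent(
                    "duplication", now, node.label, gene.uid,
                    {"new_gene": newg.uid, "new_locus": locus}))
            if p.conv_rate and len(genes) > 1 and rng.random() < p.conv_rate:
                partners = [x for x in genes if x.uid != gene.uid]
                donor = partners[int(rng.integers(0, len(partners)))]
                start = int(rng.integers(0, L))
                tract = int(rng.geometric(1.0 / p.tract_len_mean))
                end = min(L, start + tract)
                gene.seq[start:end] = donor.seq[start:end]
                state.events.append(SimEvent(
                    "conversion", now, node.label, gene.uid,
                    {"donor": donor.uid, "acceptor": gene.uid,
                     "start": start + 1, "end": end}))
            if p.pseudo_rate and not gene.pseudo and rng.random() < p.pseudo_rate:
                codon = int(rng.integers(1, state.pseudo_codon_max))
                pos = state.spliced_pos[3 * codon: 3 * codon + 3]
                gene.seq[pos] = _encode("TAA")
                gene.pseudo = True
                state.events.append(SimEvent(
                    "pseudogenization", now, node.label, gene.uid,
                    {"codon": codon + 1, "gene_positions":
                     ",".join(str(int(x) + 1) for x in pos)}))
        if p.mu and p.flank_len:
            for locus, (fl, fr) in flanks.items():
                for arr in (fl, fr):
                    nm = int(rng.binomial(p.flank_len, p.mu))
                    for s in rng.integers(0, p.flank_len, size=nm):
                        arr[s] = (arr[s] + 1 + rng.integers(0, 3)) % 4


def simulate_family(params: FamilySimParams) -> SimOutput:
    """Run the forward simulation and return genomes, models, true alignments
    and the ground-truth event log."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    state = _SimState(params, rng)
    tree = _coalescent_tree(params.n_strains, params.generations, rng)

    if params.infinite_sites:
        total_branch_gens = _total_branch_generations(tree)
        expected = params.mu * state.L * total_branch_gens * params.n_loci
        if expected > state.L:
            raise ValueError(
                f"infinite-sites model infeasible: ~{expected:.0f} expected "
                f"mutations exceed the {state.L} bp gene; use a longer "
                "ancestral gene or lower mu")

    # founder: one gene per locus, identical sequence, locus-specific flanks
    anc_seq = _ancestral_gene(params.ancestor_model, rng)
    founder_genes = []
    founder_flanks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for _ in range(params.n_loci):
        locus = state.new_locus()
        founder_genes.append(_Gene(state.new_uid(), locus, anc_seq.copy()))
        founder_flanks[locus] = (
            rng.integers(0, 4, size=params.flank_len).astype(np.int8),
            rng.integers(0, 4, size=params.flank_len).astype(np.int8))

    leaf_state: dict[str, tuple[list[_Gene], dict]] = {}

    def descend(node: _Node, genes: list[_Gene], flanks: dict) -> None:
        if not node.children:
            leaf_state[node.label] = (genes, flanks)
            return
        for child in node.children:
            cg = [g.copy() for g in genes]
            cf = {k: (l.copy(), r.copy()) for k, (l, r) in flanks.items()}
            _evolve_branch(state, child, cg, cf, node.time,
                           child.time - node.time)
            descend(child, cg, cf)

    descend(tree, founder_genes, founder_flanks)

    genomes, models, registry_rows = {}, {}, []
    locus_rows: dict[str, list[tuple[str, np.ndarray]]] = {}
    exon_ivs = params.ancestor_model.exon_intervals()
    for strain in sorted(leaf_state):
        genes, flanks = leaf_state[strain]
        contig = f"{strain}_contig"
        chunks: list[np.ndarray] = []
        feats: list[Feature] = []
        pos = 0
        for gene in sorted(genes, key=lambda g: g.locus):
            gid = f"{strain}.{gene.locus}"
            # sequence-level coding status: the pseudogenization channel is
            # not the only source of disruptions — drifting point mutations
            # can also hit a stop into frame
            disrupted = gene.pseudo or _coding_disrupted(
                gene.seq, state.spliced_pos)
            fl, fr = flanks[gene.locus]
            spacer = rng.integers(0, 4, size=SPACER_LEN).astype(np.int8)
            chunks.extend([spacer, fl])
            gstart = pos + SPACER_LEN + params.flank_len + 1  # 1-based
            gend = gstart + state.L - 1
            chunks.extend([gene.seq, fr])
            pos = gend + params.flank_len
            status = "pseudogene" if disrupted else "intact"
            feats.append(Feature(contig, "wtfkit_sim", "gene", gstart, gend, "+",
                                 {"ID": gid, "locus": gene.locus, "status": status}))
            feats.append(Feature(contig, "wtfkit_sim", "mRNA", gstart, gend, "+",
                                 {"ID": gid + ".m1", "Parent": gid}))
            for k, (es, ee) in enumerate(exon_ivs, start=1):
                feats.append(Feature(contig, "wtfkit_sim", "exon",
                                     gstart + es - 1, gstart + ee - 1, "+",
                                     {"ID": f"{gid}.e{k}", "Parent": gid + ".m1"}))
            registry_rows.append({
                "strain": strain, "gene_id": gid, "locus_id": gene.locus,
                "contig": contig, "start": gstart, "end": gend, "strand": "+",
                "status": status, "pseudo_event": gene.pseudo,
                "uid": gene.uid})
            locus_rows.setdefault(gene.locus, []).append((gid, gene.seq))
        genomes[strain] = SeqRecordSet(
            [SeqEntry(contig, _decode(np.concatenate(chunks)))])
        models[strain] = FeatureTable(feats)

    true_alignments = {
        locus: AlignmentMatrix([gid for gid, _ in rows],
                               [_decode(seq) for _, seq in rows])
        for locus, rows in sorted(locus_rows.items()) if len(rows) >= 2
    }
    registry = pd.DataFrame(registry_rows)
    truth = TruthLog(state.events, tree.newick() + ";", registry,
                     n_loci_final=registry["locus_id"].nunique())
    return SimOutput(genomes, models, true_alignments, truth, params)


def _coding_disrupted(seq: np.ndarray, spliced_pos: np.ndarray) -> bool:
    """Start codon lost, or a premature stop before the final 10% of codons."""
    cds = _decode(seq[spliced_pos])
    if not cds.startswith("ATG"):
        return True
    n_codons = len(cds) // 3
    cutoff = int(math.ceil(n_codons * 0.9))
    for i in range(n_codons - 1):
        if cds[3 * i:3 * i + 3] in _STOP_CODONS and (i + 1) < cutoff:
            return True
    return False


def _total_branch_generations(root: _Node) -> int:
    total = 0
    stack = [root]
    while stack:
        nd = stack.pop()
        for c in nd.children:
            total += c.time - nd.time
            stack.append(c)
    return total


def make_clonal_null(params: FamilySimParams) -> SimOutput:
    """Matched no-recombination control: conversion off, infinite sites on.

    Every alignment column then maps onto the strain genealogy with a single
    mutation, so four-gamete tests find zero incompatible site pairs.
    """
    q = dataclasses.replace(params, conv_rate=0.0, infinite_sites=True)
    return simulate_family(q)


@dataclasses.dataclass
class CrossoverRecord:
    parent_a: str
    parent_b: str
    breakpoint: int  # last column taken from A (0 = none)


def inject_single_crossover(gene_a: str, gene_b: str, breakpoint: int,
                            names: tuple[str, str] = ("A", "B")
                            ) -> tuple[str, CrossoverRecord]:
    """Chimera = columns [1, breakpoint] of A followed by (breakpoint, end] of B.

    Both parents must live on the same alignment coordinate system (equal
    length).  breakpoint = 0 returns B; breakpoint = length returns A.
    """
    if len(gene_a) != len(gene_b):
        raise ValueError("parents are not on the same coordinate system")
    if not 0 <= breakpoint <= len(gene_a):
        raise ValueError(f"breakpoint {breakpoint} outside [0, {len(gene_a)}]")
    chimera = gene_a[:breakpoint] + gene_b[breakpoint:]
    return chimera, CrossoverRecord(names[0], names[1], breakpoint)
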