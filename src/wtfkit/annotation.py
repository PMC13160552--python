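"""Family-member identification and annotation in genome assemblies.

The homology search is a seeded local-alignment scan (exact k-mer seeding on
both strands, banded gapped extension, Karlin-Altschul-style E-values with
lambda solved from the score scheme and K calibrated on shuffled sequence).
Candidate intervals inherit exon structure from the closest reference model,
get screened for coding disruptions (pseudogene calls), poison-isoform start
codons (exon-2-ATG / intron-1-ATG), and solo-LTR flanks, and are grouped
into syntenic loci by flanking-sequence identity.
"""

from __future__ import annotations

import dataclasses
import functools
import math
import re
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy.optimize import brentq

from .exon_network import pairwise_identity
from .io_formats import FeatureTable, SeqRecordSet

START_CODON = "ATG"
STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Gene model


@dataclasses.dataclass
class GeneModel:
    """One family member: genomic placement plus gene-space structure.

    ``seq`` is the unspliced gene sequence 5'->3' (already reverse-
    complemented for - strand genes); ``exons`` are 1-based inclusive
    intervals in gene space, ordered 5'->3'.
    """
    gene_id: str
    strain: str
    contig: str
    span: tuple[int, int]  # 1-based inclusive genomic coordinates
    strand: str
    exons: list[tuple[int, int]]
    seq: str
    status: str = "intact"
    disruptions: list[str] = dataclasses.field(default_factory=list)
    poison_starts: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {"exon2_atg": False, "intron1_atg": False})
    solo_ltr_flank: bool = False
    locus_id: str | None = None
    notes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        last_end = 0
        for s, e in self.exons:
            if s <= last_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unordered")
            if e < s or e > len(self.seq):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene")
            last_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_sequences(self) -> list[str]:
        return [self.seq[s - 1:e] for s, e in self.exons]

    def intron_sequences(self) -> list[str]:
        return [self.seq[self.exons[i][1]:self.exons[i + 1][0] - 1]
                for i in range(len(self.exons) - 1)]

    def spliced(self) -> str:
        return "".join(self.exon_sequences())


def gene_models_from_tables(genomes: Mapping[str, SeqRecordSet],
                            tables: Mapping[str, FeatureTable]) -> list[GeneModel]:
    """Build GeneModels from per-strain GFF3 feature tables and genomes."""
    models = []
    for strain in sorted(tables):
        table = tables[strain]
        genome = genomes[strain]
        for gene in table.of_type("gene"):
            gid = gene.id
            exon_feats = []
            for mrna in table.children_of(gid):
                exon_feats.extend(f for f in table.children_of(mrna.id)
                                  if f.type == "exon")
            if not exon_feats:
                exon_feats = [f for f in table.children_of(gid) if f.type == "exon"]
            exon_feats.sort(key=lambda f: f.start)
            contig_seq = genome[gene.seq_id].seq
            raw = contig_seq[gene.start - 1:gene.end]
            if gene.strand == "-":
                raw = str(Seq(raw).reverse_complement())
                exons = sorted(
                    (gene.end - f.end + 1, gene.end - f.start + 1)
                    for f in exon_feats)
            else:
                exons = [(f.start - gene.start + 1, f.end - gene.start + 1)
                         for f in exon_feats]
            models.append(GeneModel(
                gene_id=gid, strain=strain, contig=gene.seq_id,
                span=(gene.start, gene.end), strand=gene.strand,
                exons=exons, seq=raw,
                status=gene.attributes.get("status", "intact")))
    return models


# ---------------------------------------------------------------------------
# Seeded homology search

MATCH, MISMATCH = 1, -2
GAP_OPEN, GAP_EXTEND = -5, -2


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_LOCAL = _local_aligner()


@functools.lru_cache(maxsize=None)
def _karlin_lambda() -> float:
    """Solve sum_ij p_i p_j exp(lambda s_ij) = 1 for the ungapped scheme at
    uniform base composition."""
    f = lambda lam: 0.25 * math.exp(lam * MATCH) + 0.75 * math.exp(lam * MISMATCH) - 1
    return brentq(f, 1e-6, 5.0)


@functools.lru_cache(maxsize=None)
def _karlin_k(n_reps: int = 30, seed: int = 20260924) -> float:
    """Calibrate K on shuffled-sequence best local scores.

    For Gumbel-tailed local scores, P(S >= s) = 1 - exp(-K m n e^(-lambda s));
    solving at the empirical median gives K = ln 2 / (m n e^(-lambda s_med)).
    """
    lam = _karlin_lambda()
    rng = np.random.default_rng(seed)
    m, n = 200, 2000
    bases = np.array(list("ACGT"))
    scores = []
    for _ in range(n_reps):
        q = "".join(bases[rng.integers(0, 4, m)])
        t = "".join(bases[rng.integers(0, 4, n)])
        scores.append(_LOCAL.score(q, t))
    s_med = float(np.median(scores))
    return math.log(2.0) / (m * n * math.exp(-lam * s_med))


@dataclasses.dataclass
class CandidateHit:
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    query_id: str
    score: float
    evalue: float
    identity: float


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _seed_positions(genome_index: dict[str, dict[str, list[int]]],
                    query: str, k: int) -> dict[tuple[str, int], list[int]]:
    """Cluster query k-mer hits by (contig, diagonal)."""
    hits: dict[tuple[str, int], list[int]] = {}
    for qpos in range(len(query) - k + 1):
        word = query[qpos:qpos + k]
        if "N" in word:
            continue
        for contig, positions in genome_index.items():
            for gpos in positions.get(word, ()):
                hits.setdefault((contig, gpos - qpos), []).append(gpos)
    return hits


def _index_genome(genome: SeqRecordSet, k: int) -> dict[str, dict[str, list[int]]]:
    index: dict[str, dict[str, list[int]]] = {}
    for entry in genome:
        d: dict[str, list[int]] = {}
        s = entry.seq
        for i in range(len(s) - k + 1):
            word = s[i:i + k]
            if "N" not in word:
                d.setdefault(word, []).append(i)
        index[entry.id] = d
    return index


def find_family_members(genome: SeqRecordSet, queries: SeqRecordSet,
                        e_max: float = 1e-5, seed_length: int = 11,
                        band: int = 32) -> list[CandidateHit]:
    """Seeded local-alignment search of every query against both strands.

    Exact k-mer seeds are grouped by diagonal, merged into candidate regions,
    re-aligned locally (match +1 / mismatch -2 / gap open -5 / extend -2),
    scored with a calibrated extreme-value E-value, filtered at ``e_max``,
    and overlapping candidates from different queries are merged (>=50% of
    the shorter interval).
    """
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    for q in queries:
        if len(q.seq) < seed_length:
            raise ValueError(
                f"query {q.id!r} shorter than the seed length {seed_length}")
    lam = _karlin_lambda()
    kcal = _karlin_k()
    index = _index_genome(genome, seed_length)
    genome_len = sum(len(e.seq) for e in genome)
    raw: list[CandidateHit] = []
    for q in queries:
        for strand in "+-":
            qseq = q.seq if strand == "+" else _revcomp(q.seq)
            diag_hits = _seed_positions(index, qseq, seed_length)
            # merge diagonals within the band into candidate regions per contig
            regions: dict[str, list[list[int]]] = {}
            for (contig, diag), gpositions in sorted(diag_hits.items()):
                lo = min(gpositions)
                hi = max(gpositions) + seed_length
                merged = False
                for reg in regions.setdefault(contig, []):
                    if lo <= reg[1] + band and hi >= reg[0] - band:
                        reg[0], reg[1] = min(reg[0], lo), max(reg[1], hi)
                        merged = True
                        break
                if not merged:
                    regions[contig].append([lo, hi])
            for contig, regs in regions.items():
                cseq = genome[contig].seq
                for lo, hi in regs:
                    pad = len(qseq)
                    wlo, whi = max(0, lo - pad), min(len(cseq), hi + pad)
                    hit = _extend_candidate(qseq, cseq[wlo:whi])
                    if hit is None:
                        continue
                    score, tstart, tend, matches, cols = hit
                    if score <= 0:
                        continue
                    evalue = kcal * len(qseq) * genome_len * math.exp(-lam * score)
                    if evalue > e_max:
                        continue
                    raw.append(CandidateHit(
                        contig, wlo + tstart + 1, wlo + tend, strand, q.id,
                        float(score), float(evalue),
                        matches / cols if cols else 0.0))
    return _merge_hits(raw)


def _extend_candidate(qseq: str, window: str
                      ) -> tuple[float, int, int, int, int] | None:
    """Align the full query into the candidate window (edlib infix mode) and
    score the returned alignment path with the declared match/mismatch/gap
    scheme.  Returns (score, target_start, target_end, matches, columns)."""
    res = edlib.align(qseq, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    tstart, tend = res["locations"][0]
    score = 0.0
    matches = cols = 0
    qpos, tpos = 0, tstart
    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        count = int(count)
        cols += count
        if op in "=XM":
            for _ in range(count):
                if qseq[qpos] == window[tpos]:
                    score += MATCH
                    matches += 1
                else:
                    score += MISMATCH
                qpos += 1
                tpos += 1
        else:  # insertion/deletion: affine gap cost
            score += GAP_OPEN + (count - 1) * GAP_EXTEND
            if op == "I":
                qpos += count
            else:
                tpos += count
    return score, tstart, tend + 1, matches, cols


def _merge_hits(hits: list[CandidateHit]) -> list[CandidateHit]:
    """Merge candidates overlapping >=50% of the shorter interval; the
    highest-scoring hit represents the merged candidate."""
    hits = sorted(hits, key=lambda h: (h.contig, h.start, -h.score))
    out: list[CandidateHit] = []
    for h in hits:
        merged = False
        for o in out:
            if o.contig != h.contig:
                continue
            ov = min(o.end, h.end) - max(o.start, h.start) + 1
            shorter = min(o.end - o.start, h.end - h.start) + 1
            if ov >= 0.5 * shorter:
                if h.score > o.score:
                    o.query_id, o.score = h.query_id, h.score
                    o.evalue, o.identity, o.strand = h.evalue, h.identity, h.strand
                o.start, o.end = min(o.start, h.start), max(o.end, h.end)
                merged = True
                break
        if not merged:
            out.append(dataclasses.replace(h))
    return out


# ---------------------------------------------------------------------------
# Structure transfer


def _global_free_end_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    a.end_gap_score = 0
    return a


_GLOBAL = _global_free_end_aligner()


def transfer_exon_structure(candidate: CandidateHit, genome: SeqRecordSet,
                            reference_models: Sequence[GeneModel],
                            strain: str = "query",
                            identity_floor: float = 0.5) -> GeneModel:
    """Annotate a candidate interval with the exon structure of the closest
    reference model (ties broken by reference order, tie logged).

    Exon boundaries are mapped through the pairwise alignment of the
    candidate sequence and the chosen reference's unspliced sequence;
    boundaries landing in alignment gaps map to the nearest candidate
    position and are flagged.  Raises ValueError when no reference reaches
    ``identity_floor``.
    """
    cseq = genome[candidate.contig].seq[candidate.start - 1:candidate.end]
    if candidate.strand == "-":
        cseq = _revcomp(cseq)
    idents = [pairwise_identity(cseq, ref.seq) for ref in reference_models]
    best = max(idents)
    if best < identity_floor:
        raise ValueError(
            f"candidate {candidate.contig}:{candidate.start}-{candidate.end} "
            f"rejected: best reference identity {best:.3f} < {identity_floor}")
    best_idx = idents.index(best)
    notes = []
    if idents.count(best) > 1:
        notes.append(f"reference tie broken by order (identity {best:.3f})")
    ref = reference_models[best_idx]
    aln = _GLOBAL.align(ref.seq, cseq)[0]
    rmap = _position_map(str(aln[0]), str(aln[1]))
    exons = []
    for (es, ee) in ref.exons:
        ms, flag_s = rmap[es - 1]
        me, flag_e = rmap[ee - 1]
        if flag_s or flag_e:
            notes.append(f"exon boundary ({es},{ee}) fell in an alignment gap")
        exons.append((ms + 1, me + 1))
    exons = _sanitize_intervals(exons, len(cseq))
    gid = f"{strain}:{candidate.contig}:{candidate.start}-{candidate.end}"
    model = GeneModel(
        gene_id=gid, strain=strain, contig=candidate.contig,
        span=(candidate.start, candidate.end), strand=candidate.strand,
        exons=exons, seq=cseq, notes=notes)
    model.notes.append(f"structure from {ref.gene_id} (identity {best:.3f})")
    return model


def _position_map(ref_row: str, cand_row: str) -> list[tuple[int, bool]]:
    """For each ungapped reference position, the candidate position it aligns
    to (nearest preceding position when in a gap; flagged)."""
    out = []
    cpos = -1
    for rch, cch in zip(ref_row, cand_row):
        if cch != "-":
            cpos += 1
        if rch != "-":
            out.append((max(cpos, 0), cch == "-"))
    return out


def _sanitize_intervals(exons: list[tuple[int, int]], length: int
                        ) -> list[tuple[int, int]]:
    fixed = []
    prev_end = 0
    for s, e in exons:
        s = max(s, prev_end + 1)
        e = min(max(e, s), length)
        if s > length:
            break
        fixed.append((s, e))
        prev_end = e
    return fixed


# ---------------------------------------------------------------------------
# Coding status and poison starts


def call_pseudogene(model: GeneModel, tail_fraction: float = 0.1
                    ) -> tuple[str, list[str]]:
    """Classify the spliced CDS: intact, or pseudogene with itemized
    disruptions (premature stop before the final ``tail_fraction`` of codons,
    frameshifting spliced length, missing start codon)."""
    cds = model.spliced()
    disruptions = []
    if len(cds) % 3 != 0:
        disruptions.append(f"frameshift: spliced length {len(cds)} not divisible by 3")
    if not cds.upper().startswith(START_CODON):
        disruptions.append("missing start codon")
    n_codons = len(cds) // 3
    cutoff = int(math.ceil(n_codons * (1 - tail_fraction)))
    for i in range(n_codons - 1):
        codon = cds[3 * i:3 * i + 3].upper()
        if codon in STOP_CODONS and (i + 1) < cutoff:
            disruptions.append(f"premature stop {codon} at codon {i + 1}/{n_codons}")
            break
    status = "pseudogene" if disruptions else "intact"
    model.status = status
    model.disruptions = disruptions
    return status, disruptions


def detect_poison_starts(model: GeneModel, window: int = 30) -> dict[str, bool]:
    """Flags for the short-isoform start codons.

    exon2_atg: an in-frame ATG within the first ``window`` nt of exon 2
    (frame of the exon-1 start).  intron1_atg: an ATG within the last
    ``window`` nt of intron 1 whose reading frame runs continuously into
    exon 2's frame when the intron tail is retained.
    """
    flags = {"exon2_atg": False, "intron1_atg": False}
    if model.n_exons < 2:
        model.notes.append("single-exon model: poison starts undetectable")
        model.poison_starts = flags
        return flags
    exon_seqs = model.exon_sequences()
    off2 = len(exon_seqs[0])  # spliced offset of exon 2
    e2 = exon_seqs[1]
    for i in range(0, min(window, len(e2) - 2)):
        if e2[i:i + 3].upper() == START_CODON and (off2 + i) % 3 == 0:
            flags["exon2_atg"] = True
            break
    intron1 = model.intron_sequences()[0]
    tail = intron1[-window:] if len(intron1) > window else intron1
    base = len(intron1) - len(tail)
    for i in range(len(tail) - 2):
        if tail[i:i + 3].upper() == START_CODON:
            t = len(intron1) - (base + i)  # nt from the ATG to the intron end
            if t % 3 == off2 % 3:
                flags["intron1_atg"] = True
                break
    model.poison_starts = flags
    return flags


# ---------------------------------------------------------------------------
# Locus assignment and presence matrix


@dataclasses.dataclass
class PresenceMatrix:
    intact: pd.DataFrame      # loci x strains copy counts
    pseudogene: pd.DataFrame  # loci x strains copy counts
    locus_of: dict[str, str]  # gene_id -> locus label

    @property
    def n_loci(self) -> int:
        return len(self.intact.index)

    def per_strain_totals(self) -> pd.Series:
        return (self.intact + self.pseudogene).sum(axis=0)

    def to_tsv(self, path) -> None:
        rows = self.intact.astype(str) + "i+" + self.pseudogene.astype(str) + "p"
        rows[(self.intact == 0) & (self.pseudogene == 0)] = "absent"
        rows.to_csv(path, sep="\t")


def _kmer_set(seq: str, k: int = 13) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _flanks(model: GeneModel, genome: SeqRecordSet, flank_len: int
            ) -> tuple[str | None, str | None, bool]:
    contig = genome[model.contig].seq
    s, e = model.span
    left = contig[max(0, s - 1 - flank_len):s - 1]
    right = contig[e:e + flank_len]
    truncated = len(left) < flank_len or len(right) < flank_len
    if model.strand == "-":
        left, right = _revcomp(right), _revcomp(left)
    return (left or None, right or None, truncated)


def assign_loci(models: Sequence[GeneModel], genomes: Mapping[str, SeqRecordSet],
                flank_len: int = 1000, flank_identity_min: float = 0.8
                ) -> PresenceMatrix:
    """Group genes from different strains into syntenic loci by flank identity.

    Genes are nodes; an edge joins two genes from different strains when
    every flank available on both sides aligns at identity >=
    ``flank_identity_min``.  Connected components are loci; the matrix
    reports per-locus per-strain copy counts split by coding status.
    Invariant to strain input order (components labelled by their
    lexicographically smallest member).
    """
    flanks = {}
    for m in models:
        left, right, truncated = _flanks(m, genomes[m.strain], flank_len)
        if truncated:
            m.notes.append("single-flank mode: gene within flank_len of contig end")
        flanks[m.gene_id] = (left, right)
    kmers = {gid: (None if l is None else _kmer_set(l),
                   None if r is None else _kmer_set(r))
             for gid, (l, r) in flanks.items()}
    g = nx.Graph()
    ordered = sorted(models, key=lambda m: m.gene_id)
    for m in ordered:
        g.add_node(m.gene_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if a.strain == b.strain:
                continue
            if _flank_match(flanks[a.gene_id], flanks[b.gene_id],
                            kmers[a.gene_id], kmers[b.gene_id],
                            flank_identity_min):
                g.add_edge(a.gene_id, b.gene_id)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    locus_of = {}
    for idx, comp in enumerate(comps, start=1):
        label = f"locus_{idx:03d}"
        for gid in comp:
            locus_of[gid] = label
    strains = sorted({m.strain for m in models})
    loci = [f"locus_{i:03d}" for i in range(1, len(comps) + 1)]
    intact = pd.DataFrame(0, index=loci, columns=strains)
    pseudo = pd.DataFrame(0, index=loci, columns=strains)
    for m in models:
        m.locus_id = locus_of[m.gene_id]
        target = pseudo if m.status == "pseudogene" else intact
        target.loc[m.locus_id, m.strain] += 1
    return PresenceMatrix(intact, pseudo, locus_of)


def _flank_match(fa, fb, ka, kb, floor: float) -> bool:
    sides = []
    for sa, sb, qa, qb in ((fa[0], fb[0], ka[0], kb[0]),
                           (fa[1], fb[1], ka[1], kb[1])):
        if sa is None or sb is None:
            continue  # single-flank mode: judge on the available side(s)
        sides.append((sa, sb, qa, qb))
    if not sides:
        return False
    for sa, sb, qa, qb in sides:
        # cheap k-mer prefilter: highly divergent pairs never reach the floor
        shared = len(qa & qb)
        if shared < 0.02 * min(len(qa), len(qb)):
            return False
        if pairwise_identity(sa, sb) < floor:
            return False
    return True


# ---------------------------------------------------------------------------
# solo-LTR flags


def flag_solo_ltr(model: GeneModel, genome: SeqRecordSet,
                  ltr_library: SeqRecordSet, window: int = 500,
                  identity_min: float = 0.7, coverage_min: float = 0.5) -> bool:
    """True iff a library LTR aligns within ``window`` bp of either gene end
    at identity >= ``identity_min`` covering >= ``coverage_min`` of the LTR."""
    if len(ltr_library) == 0:
        raise ValueError("ltr_library must be non-empty")
    contig = genome[model.contig].seq
    s, e = model.span
    regions = [contig[max(0, s - 1 - window):s - 1], contig[e:e + window]]
    for ltr in ltr_library:
        for region in regions:
            if len(region) < 8:
                continue
            for target in (region, _revcomp(region)):
                aln = _LOCAL.align(ltr.seq, target)
                if len(aln) == 0:
                    continue
                best = aln[0]
                qa, ta = str(best[0]), str(best[1])
                cols = len(qa)
                if cols == 0:
                    continue
                matches = sum(1 for x, y in zip(qa, ta) if x == y and x != "-")
                q_covered = sum(1 for x in qa if x != "-")
                if (q_covered >= coverage_min * len(ltr.seq)
                        and matches / cols >= identity_min):
                    model.solo_ltr_flank = True
                    return True
    model.solo_ltr_flank = False
    return False


# ---------------------------------------------------------------------------
# One-shot pipeline


def annotate_genome(genome: SeqRecordSet, reference_models: Sequence[GeneModel],
                    strain: str, e_max: float = 1e-5, seed_length: int = 11,
                    identity_floor: float = 0.5) -> list[GeneModel]:
    """find -> transfer structure -> pseudogene call -> poison starts."""
    queries = SeqRecordSet()
    from .io_formats import SeqEntry
    for ref in reference_models:
        queries.add(SeqEntry(ref.gene_id, ref.seq))
    hits = find_family_members(genome, queries, e_max=e_max,
                               seed_length=seed_length)
    models = []
    for hit in hits:
        try:
            model = transfer_exon_structure(hit, genome, reference_models,
                                            strain=strain,
                                            identity_floor=identity_floor)
        except ValueError:
            continue  # non-member
        call_pseudogene(model)
        detect_poison_starts(model)
        models.append(model)
    return models
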