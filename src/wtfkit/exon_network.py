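"""Exon similarity networks.

All-vs-all nucleotide identity between exons, a thresholded undirected graph
(edge when identity >= threshold, default 0.50), and connected-component
clusters.  Identity comes from a global alignment with free end gaps
(match +1, mismatch -1, gap -2); the denominator excludes columns inside
terminal gap runs, so exons of different length are compared over their
overlapping aligned span, while internal gaps count as mismatching columns.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align


@dataclasses.dataclass(frozen=True)
class ExonRecord:
    gene_id: str
    exon_index: int  # 1-based
    sequence: str

    @property
    def label(self) -> str:
        return f"{self.gene_id}.e{self.exon_index}"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps: length differences are not penalized
    aligner.end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Coverage-aware nucleotide identity of the optimal free-end-gap global
    alignment of two sequences.

    identity = matched columns / length of the shorter sequence.  The
    denominator charges unaligned (terminal-gap) and internally gapped
    positions of the shorter sequence as non-matching, so a short
    high-scoring island in otherwise unrelated sequence scores low instead
    of inflating towards 1.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    if (len(b), b) < (len(a), a):
        a, b = b, a  # canonical order: optimal-score ties resolve identically
    aln = _ALIGNER.align(a, b)[0]
    ta, tb = aln[0], aln[1]  # aligned strings with '-' gaps
    matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    return matches / min(len(a), len(b))


def build_exon_graph(exons: Sequence[ExonRecord], threshold: float = 0.5,
                     strict: bool = False) -> nx.Graph:
    """Score all unordered exon pairs and keep edges at identity >= threshold.

    ``strict=True`` switches the boundary rule to identity strictly greater
    than the threshold.  Node order is deterministic (input order).
    """
    if not exons:
        raise ValueError("build_exon_graph requires at least one exon")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    g = nx.Graph(threshold=threshold, strict=strict)
    for ex in exons:
        g.add_node(ex.label, record=ex)
    labels = [ex.label for ex in exons]
    seqs = [ex.sequence for ex in exons]
    for i in range(len(exons)):
        for j in range(i + 1, len(exons)):
            ident = pairwise_identity(seqs[i], seqs[j])
            keep = ident > threshold if strict else ident >= threshold
            if keep:
                g.add_edge(labels[i], labels[j], identity=ident)
    return g


def extract_clusters(g: nx.Graph, min_cluster_size: int = 2
                     ) -> tuple[list[list[str]], list[str]]:
    """Connected components split into multi-member clusters and singletons.

    Clusters are ordered by decreasing size then lexicographically smallest
    member; members within a cluster are sorted.
    """
    comps = [sorted(c) for c in nx.connected_components(g)]
    clusters = [c for c in comps if len(c) >= min_cluster_size]
    singletons = sorted(m for c in comps if len(c) < min_cluster_size for m in c)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters, singletons


def identity_heatmap_table(exons: Sequence[ExonRecord]) -> pd.DataFrame:
    """Full symmetric identity matrix over exons with unit diagonal."""
    if len(exons) < 2:
        raise ValueError("identity_heatmap_table requires at least two exons")
    labels = [ex.label for ex in exons]
    n = len(exons)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(
                exons[i].sequence, exons[j].sequence)
    return pd.DataFrame(mat, index=labels, columns=labels)


def exons_from_gene_models(models: Iterable) -> list[ExonRecord]:
    """Collect spliced exon sequences from annotation GeneModel objects."""
    out = []
    for m in models:
        for k, seq in enumerate(m.exon_sequences(), start=1):
            out.append(ExonRecord(m.gene_id, k, seq))
    return out
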