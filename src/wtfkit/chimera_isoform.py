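"""Exon-swap chimeras and the two-isoform (poison/antidote) coding logic.

A family member encodes two products from one gene: the long isoform
(antidote) translated from the exon-1 start codon, and a short isoform
(poison) translated from an alternative downstream start — an in-frame ATG
near the start of exon 2, or an ATG in the tail of intron 1 that reads
through the retained intron tail into exon 2's frame.  Chimeras join the
first k exons of parent A to the remaining exons of parent B at the
intervening intron.

Detoxification is a wet-lab phenotype; ``compare_poison_antidote`` reports
only sequence identity of the swapped C-terminal segments as a stated proxy
and never claims functional rescue.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotation import GeneModel, detect_poison_starts
from .exon_network import pairwise_identity

_PY_MOTIF = re.compile(r"(?=([LP]P.Y))")


@dataclasses.dataclass
class ChimeraSpec:
    parent_a: GeneModel
    parent_b: GeneModel
    k: int  # last exon index (1-based) taken from parent A

    def validate(self) -> None:
        if not 1 <= self.k < self.parent_a.n_exons:
            raise ValueError(
                f"k={self.k} outside [1, {self.parent_a.n_exons - 1}] for "
                f"parent A ({self.parent_a.gene_id})")
        if self.parent_b.n_exons < self.k + 1:
            raise ValueError(
                f"parent B ({self.parent_b.gene_id}) has no exons "
                f"{self.k + 1}..end")


@dataclasses.dataclass
class IsoformPair:
    antidote_cds: str
    poison_cds: str
    start_used: str  # exon2_atg | intron1_atg | none

    def antidote_protein(self) -> str:
        return _translate(self.antidote_cds)

    def poison_protein(self) -> str:
        return _translate(self.poison_cds) if self.poison_cds else ""


def _translate(cds: str) -> str:
    trimmed = cds[:len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def build_chimera(spec: ChimeraSpec) -> GeneModel:
    """Join exons 1..k of parent A (with A's introns) to exons k+1..end of
    parent B (with B's introns); the junction sits where A's exon k ends and
    B's intron k begins."""
    spec.validate()
    a, b, k = spec.parent_a, spec.parent_b, spec.k
    a_cut = a.exons[k - 1][1]                  # end of A's exon k (gene space)
    b_from = b.exons[k - 1][1] + 1             # start of B's intron k
    seq = a.seq[:a_cut] + b.seq[b_from - 1:]
    offset = a_cut - (b_from - 1)
    exons = list(a.exons[:k]) + [(s + offset, e + offset) for s, e in b.exons[k:]]
    model = GeneModel(
        gene_id=f"{a.gene_id}x{b.gene_id}_k{k}",
        strain=a.strain, contig="chimera", span=(1, len(seq)), strand="+",
        exons=exons, seq=seq,
        notes=[f"chimera: exons 1-{k} of {a.gene_id} + "
               f"exons {k + 1}-{b.n_exons} of {b.gene_id}"])
    return model


def derive_isoforms(model: GeneModel, window: int = 30) -> IsoformPair:
    """Long (antidote) and short (poison) coding sequences of a gene.

    The antidote CDS is the spliced sequence from the exon-1 start codon.
    The poison start is the exon-2 ATG when present, else the intron-1 ATG
    (the retained intron tail is then included in frame), else the gene is
    antidote-only (suppressor-like) and the poison CDS is empty.
    """
    if model.n_exons < 2:
        raise ValueError("derive_isoforms needs a model with >= 2 exons")
    spliced = model.spliced()
    if not spliced.upper().startswith("ATG"):
        raise ValueError(
            f"{model.gene_id}: antidote CDS lacks a start codon")
    flags = detect_poison_starts(model, window=window)
    exon_seqs = model.exon_sequences()
    off2 = len(exon_seqs[0])
    if flags["exon2_atg"]:
        e2 = exon_seqs[1]
        for i in range(0, min(window, len(e2) - 2)):
            if e2[i:i + 3].upper() == "ATG" and (off2 + i) % 3 == 0:
                return IsoformPair(spliced, spliced[off2 + i:], "exon2_atg")
    if flags["intron1_atg"]:
        intron1 = model.intron_sequences()[0]
        tail = intron1[-window:] if len(intron1) > window else intron1
        base = len(intron1) - len(tail)
        for i in range(len(tail) - 2):
            if tail[i:i + 3].upper() == "ATG":
                t = len(intron1) - (base + i)
                if t % 3 == off2 % 3:
                    poison = intron1[base + i:] + spliced[off2:]
                    return IsoformPair(spliced, poison, "intron1_atg")
    return IsoformPair(spliced, "", "none")


def insert_poison_start(model: GeneModel, force: bool = False) -> GeneModel:
    """Insert an in-frame ATG codon right before the start of exon 2.

    The codon becomes the 5'-most in-frame codon of exon 2 (placed at the
    first codon boundary at or after the exon 2 start, so the new Met reads
    straight through in the antidote frame); the spliced sequence grows by
    exactly 3 nt and downstream coordinates shift by 3.  A second call
    errors unless ``force`` (the gene already has a poison start).
    """
    if model.n_exons < 2:
        raise ValueError("insert_poison_start needs a model with >= 2 exons")
    flags = detect_poison_starts(model)
    if (flags["exon2_atg"] or flags["intron1_atg"]) and not force:
        raise ValueError(
            f"{model.gene_id} already has a poison start; use force=True")
    off2 = len(model.exon_sequences()[0])
    pad = (3 - off2 % 3) % 3  # exon-2 bases completing exon 1's last codon
    e2_start, e2_end = model.exons[1]
    if e2_start + pad > e2_end - 2:
        raise ValueError("insertion would disrupt the exon 2 splice boundary")
    ins_at = e2_start - 1 + pad  # 0-based gene index where ATG goes
    new_seq = model.seq[:ins_at] + "ATG" + model.seq[ins_at:]
    new_exons = [model.exons[0], (e2_start, e2_end + 3)] + \
        [(s + 3, e + 3) for s, e in model.exons[2:]]
    out = dataclasses.replace(
        model, seq=new_seq, exons=new_exons,
        span=(model.span[0], model.span[1] + 3),
        notes=model.notes + [f"poison-start ATG inserted at gene position "
                             f"{ins_at + 1}"],
        poison_starts=dict(model.poison_starts),
        disruptions=list(model.disruptions))
    detect_poison_starts(out)
    return out


def remove_poison_start(model: GeneModel) -> GeneModel:
    """Undo insert_poison_start using its recorded insertion position."""
    pos = None
    for note in model.notes:
        m = re.match(r"poison-start ATG inserted at gene position (\d+)", note)
        if m:
            pos = int(m.group(1)) - 1
    if pos is None:
        raise ValueError("model carries no recorded poison-start insertion")
    new_seq = model.seq[:pos] + model.seq[pos + 3:]
    e2s, e2e = model.exons[1]
    new_exons = [model.exons[0], (e2s, e2e - 3)] + \
        [(s - 3, e - 3) for s, e in model.exons[2:]]
    out = dataclasses.replace(
        model, seq=new_seq, exons=new_exons,
        span=(model.span[0], model.span[1] - 3),
        notes=[n for n in model.notes
               if not n.startswith("poison-start ATG inserted")],
        poison_starts=dict(model.poison_starts),
        disruptions=list(model.disruptions))
    detect_poison_starts(out)
    return out


def py_motif_scan(protein: str, n_terminal_window: int | None = None
                  ) -> list[int]:
    """1-based start positions of PY motifs ([Leu/Pro]-Pro-X-Tyr) within the
    first ``n_terminal_window`` residues (default: whole sequence)."""
    region = protein if n_terminal_window is None else protein[:n_terminal_window]
    return [m.start() + 1 for m in _PY_MOTIF.finditer(region)]


def compare_poison_antidote(chimera: GeneModel, parents: Sequence[GeneModel],
                            k: int) -> pd.DataFrame:
    """Identity of the exon-(k+1)..end protein segments between every poison
    and every antidote among the chimera and its parents.

    This is a sequence-level proxy for poison/antidote specificity: matching
    C-terminal segments are reported, not functional rescue.  The chimera
    matches its own antidote at identity 1.0 by construction.
    """
    genes = [chimera, *parents]
    segments = {}
    for g in genes:
        if g.n_exons <= k:
            raise ValueError(f"{g.gene_id} has no exons beyond {k}")
        tail_nt = "".join(g.exon_sequences()[k:])
        # keep the antidote reading frame through the segment
        lead = len("".join(g.exon_sequences()[:k]))
        frame = (3 - lead % 3) % 3
        segments[g.gene_id] = _translate(tail_nt[frame:]) or tail_nt[frame:]
    rows = []
    for gp in genes:
        for ga in genes:
            sp, sa = segments[gp.gene_id], segments[ga.gene_id]
            ident = 1.0 if sp == sa else pairwise_identity(sp, sa)
            rows.append({
                "poison_of": gp.gene_id, "antidote_of": ga.gene_id,
                "segment_identity": ident,
                "self_match": gp.gene_id == ga.gene_id,
            })
    return pd.DataFrame(rows)
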