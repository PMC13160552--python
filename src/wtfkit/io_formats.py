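"""Readers and writers for the plain-text formats the pipeline touches.

All coordinates are 1-based inclusive throughout the package (GFF3 native);
the BED writer is the single place where conversion to 0-based half-open
happens.  Sequences are stored 5'->3' on the + strand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WRAP = 60
_DNA = set("ACGTN")


@dataclasses.dataclass
class SeqEntry:
    id: str
    seq: str
    description: str = ""


class SeqRecordSet:
    """Ordered collection of uniquely identified DNA sequences."""

    def __init__(self, entries: Iterable[SeqEntry] = ()):
        self.entries: list[SeqEntry] = []
        self._index: dict[str, int] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: SeqEntry) -> None:
        if entry.id in self._index:
            raise ValueError(f"duplicate sequence identifier: {entry.id!r}")
        if not entry.seq:
            raise ValueError(f"empty sequence for identifier {entry.id!r}")
        bad = set(entry.seq.upper()) - _DNA
        if bad:
            raise ValueError(
                f"sequence {entry.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        self._index[entry.id] = len(self.entries)
        self.entries.append(SeqEntry(entry.id, entry.seq.upper(), entry.description))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> SeqEntry:
        return self.entries[self._index[seq_id]]

    def ids(self) -> list[str]:
        return [e.id for e in self.entries]


def read_fasta(path: str | Path) -> SeqRecordSet:
    """Parse a FASTA file, preserving record order.

    Raises ValueError on duplicate identifiers or empty records.
    """
    out = SeqRecordSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.add(SeqEntry(rec.id, str(rec.seq), desc))
    return out


def write_fasta(records: SeqRecordSet, path: str | Path, wrap: int = FASTA_WRAP) -> None:
    seqio_recs = [
        SeqRecord(Seq(e.seq), id=e.id, description=e.description) for e in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqio_recs)


# ---------------------------------------------------------------------------
# GFF3

FEATURE_TYPES = {"gene", "mRNA", "exon", "CDS", "LTR"}


@dataclasses.dataclass
class Feature:
    seq_id: str
    source: str
    type: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    attributes: dict[str, str]
    score: str = "."
    phase: str = "."
    dangling_parent: bool = False

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")

    def length(self) -> int:
        return self.end - self.start + 1


class FeatureTable:
    """Flat ordered list of GFF3 features with Parent links resolved or flagged."""

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: list[Feature] = list(features)
        self._resolve_parents()

    def _resolve_parents(self) -> None:
        ids = {f.id for f in self.features if f.id is not None}
        for f in self.features:
            f.dangling_parent = f.parent is not None and f.parent not in ids

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def children_of(self, feature_id: str) -> list[Feature]:
        return [f for f in self.features if f.parent == feature_id]


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            attrs[k] = v
    return attrs


def read_gff3(path: str | Path) -> FeatureTable:
    """Parse a 9-column GFF3 file; coordinates kept verbatim (1-based inclusive)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, source, ftype, start_s, end_s, score, strand, phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            feats.append(
                Feature(seq_id, source, ftype, start, end, strand,
                        _parse_attributes(attrs), score, phase)
            )
    return FeatureTable(feats)


def write_gff3(table: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write("\t".join([
                f.seq_id, f.source, f.type, str(f.start), str(f.end),
                f.score, f.strand, f.phase, attrs or ".",
            ]) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (seq_id, start_1based, end_1based, name) intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for seq_id, start, end, name in intervals:
            fh.write(f"{seq_id}\t{start - 1}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# Run configuration

DEFAULT_CONFIG: dict[str, object] = {
    "identity_threshold": 0.5,       # exon-network edge threshold
    "strict_threshold": False,       # True: edge requires identity strictly > threshold
    "flank_len": 1000,               # bp of locus-identifying flank
    "flank_identity_min": 0.8,       # flank-match floor for synteny/locus assignment
    "e_max": 1e-5,                   # homology-search E-value cutoff
    "seed_length": 11,               # k-mer seed for the homology search
    "poison_start_window": 30,       # nt window for exon-2 / intron-1 ATG detection
    "ltr_window": 500,               # bp around gene ends scanned for solo-LTRs
    "ltr_identity_min": 0.7,
    "phi_window": 100,               # bp window for the homoplasy test
    "phi_permutations": 1000,
    "seed": 0,
}

_RANGES = {
    "identity_threshold": (0.0, 1.0),
    "flank_identity_min": (0.0, 1.0),
    "ltr_identity_min": (0.0, 1.0),
}


def load_run_config(path: str | Path | None = None,
                    overrides: Mapping[str, object] | None = None) -> dict[str, object]:
    """Load a flat YAML config, fill defaults, reject unknown keys and bad ranges."""
    cfg = dict(DEFAULT_CONFIG)
    supplied: dict[str, object] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        supplied.update(loaded or {})
    if overrides:
        supplied.update(overrides)
    for key, val in supplied.items():
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config key: {key!r}")
        cfg[key] = val
    for key, (lo, hi) in _RANGES.items():
        v = cfg[key]
        if not (isinstance(v, (int, float)) and lo <= float(v) <= hi):
            raise ValueError(f"config key {key!r}={v!r} outside [{lo}, {hi}]")
    for key in ("e_max",):
        if not float(cfg[key]) > 0:
            raise ValueError(f"config key {key!r} must be > 0")
    return cfg


def write_provenance(out_dir: str | Path, config: Mapping[str, object],
                     inputs: Mapping[str, str | Path] | None = None) -> Path:
    """Record the effective config, seed and input digests for a pipeline run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests = {}
    for name, p in (inputs or {}).items():
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for block in iter(lambda: fh.read(1 << 16), b""):
                h.update(block)
        digests[name] = h.hexdigest()
    record = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dict(config),
        "input_sha256": digests,
    }
    path = out_dir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
    return path
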