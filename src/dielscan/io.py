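"""Reading, writing and validating alignments and sample metadata.

The central objects are :class:`Alignment` — an ordered set of equal-length
DNA rows over the IUPAC alphabet plus ``-`` gaps — and
:class:`SampleMetadata`, which assigns each sequence a species name, a clade
group (Haplorhini / Strepsirrhini / outgroup) and a behavior (Diurnal /
Nocturnal).  All downstream stages consume a validated alignment–metadata
pair.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_DNA = "ACGT" + "RYSWKMBDHVN"
GAP = "-"
ALLOWED = frozenset(IUPAC_DNA + GAP)

GROUPS = ("Haplorhini", "Strepsirrhini", "outgroup")
BEHAVIORS = ("Diurnal", "Nocturnal")


class DielscanIOError(ValueError):
    """Raised for malformed input files or inconsistent alignment/metadata."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named DNA sequence (possibly gapped), stored uppercase."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise DielscanIOError("sequence id must be nonempty")
        if not self.residues:
            raise DielscanIOError(f"sequence {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = [i for i, ch in enumerate(self.residues) if ch not in ALLOWED]
        if bad:
            c = bad[0]
            raise DielscanIOError(
                f"illegal character {self.residues[c]!r} in sequence {self.id!r} at column {c}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment of equal-length rows."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if len(recs) < 2:
            raise DielscanIOError("an alignment needs at least 2 sequences")
        lengths = {len(r.residues) for r in recs}
        if len(lengths) != 1:
            raise DielscanIOError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DielscanIOError(f"duplicate sequence ids: {dup}")

    @property
    def ncol(self) -> int:
        return len(self.records[0].residues)

    @property
    def nrow(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def to_array(self) -> np.ndarray:
        """Character matrix of shape (nrow, ncol), dtype '<U1'."""
        return np.array([list(r.residues) for r in self.records])

    def take_columns(self, columns: Iterable[int]) -> "Alignment":
        cols = list(columns)
        arr = self.to_array()[:, cols]
        recs = [SequenceRecord(r.id, "".join(row)) for r, row in zip(self.records, arr)]
        return Alignment(tuple(recs))


@dataclass(frozen=True)
class SampleRow:
    species: str
    group: str
    behavior: str
    in_primate_tests: bool


@dataclass
class SampleMetadata:
    """Per-sequence species/clade/behavior labels driving the group contrasts."""

    rows: dict[str, SampleRow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, row in self.rows.items():
            if row.group not in GROUPS:
                raise DielscanIOError(f"unknown group {row.group!r} for id {sid!r}; expected one of {GROUPS}")
            if row.behavior not in BEHAVIORS:
                raise DielscanIOError(
                    f"unknown behavior {row.behavior!r} for id {sid!r}; expected one of {BEHAVIORS}"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    def level_ids(self, trait: str, level: str, primates_only: bool = True) -> list[str]:
        """Ids whose `trait` ('group' or 'behavior') equals `level`.

        With ``primates_only`` (the default for statistical contrasts), ids
        flagged ``in_primate_tests=False`` (the outgroup) are excluded.
        """
        out = []
        for sid, row in self.rows.items():
            if primates_only and not row.in_primate_tests:
                continue
            if getattr(row, trait) == level:
                out.append(sid)
        return out

    def counts(self, trait: str) -> dict[str, int]:
        c: dict[str, int] = {}
        for row in self.rows.values():
            c[getattr(row, trait)] = c.get(getattr(row, trait), 0) + 1
        return c


def _canonical_enum(value: str, allowed: tuple[str, ...], column: str) -> str:
    for a in allowed:
        if value.strip().lower() == a.lower():
            return a
    raise DielscanIOError(f"unknown {column} value {value!r}; expected one of {allowed}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gapped) multi-FASTA into validated records.

    Residues are uppercased and whitespace-stripped; record order is
    preserved.  Duplicate ids, illegal characters and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DielscanIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).strip()))
    if not records:
        raise DielscanIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as canonical FASTA (uppercase, 60-column wrapped)."""
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the tab-separated sample table (columns id/species/group/behavior).

    Lines starting with ``#`` are skipped.  The outgroup rows get
    ``in_primate_tests=False`` and are excluded from the two-group contrasts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["id", "species", "group", "behavior"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DielscanIOError(f"metadata {path} is missing columns {missing}")
    rows: dict[str, SampleRow] = {}
    for _, rec in df.iterrows():
        sid = str(rec["id"]).strip()
        if not sid or sid == "nan":
            raise DielscanIOError(f"metadata {path} has a row with a missing id")
        if sid in rows:
            raise DielscanIOError(f"duplicate metadata id {sid!r}")
        group = _canonical_enum(str(rec["group"]), GROUPS, "group")
        behavior = _canonical_enum(str(rec["behavior"]), BEHAVIORS, "behavior")
        rows[sid] = SampleRow(
            species=str(rec["species"]).strip(),
            group=group,
            behavior=behavior,
            in_primate_tests=(group != "outgroup"),
        )
    if not rows:
        raise DielscanIOError(f"metadata {path} has no rows")
    return SampleMetadata(rows)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tgroup\tbehavior\n")
        for sid, row in metadata.rows.items():
            fh.write(f"{sid}\t{row.species}\t{row.group}\t{row.behavior}\n")


def validate_alignment(
    records: Iterable[SequenceRecord], metadata: SampleMetadata | Mapping[str, SampleRow]
) -> Alignment:
    """Pair sequence records with metadata, checking lengths and id matching.

    Returns the validated :class:`Alignment`; any ragged rows or unmatched
    ids on either side are reported together in the error message.
    """
    recs = tuple(records)
    meta_ids = set(metadata.rows if isinstance(metadata, SampleMetadata) else metadata)
    problems: list[str] = []
    lengths = {len(r.residues) for r in recs}
    if len(lengths) > 1:
        problems.append(f"ragged row lengths {sorted(lengths)}")
    fasta_ids = {r.id for r in recs}
    only_fasta = sorted(fasta_ids - meta_ids)
    only_meta = sorted(meta_ids - fasta_ids)
    if only_fasta:
        problems.append(f"ids in alignment but not metadata: {only_fasta}")
    if only_meta:
        problems.append(f"ids in metadata but not alignment: {only_meta}")
    if problems:
        raise DielscanIOError("alignment/metadata mismatch: " + "; ".join(problems))
    return Alignment(recs)
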