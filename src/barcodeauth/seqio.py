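"""Sequence and metadata I/O plus the small sequence utilities shared by every stage.

The package works on short nuclear ribosomal ITS2 barcodes, so everything here is
plain in-memory strings over the IUPAC nucleotide alphabet (including ambiguity
codes and the gap character ``-``).  Alignment columns and template positions are
1-based and inclusive throughout the public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq as _BioSeq

__all__ = [
    "GROUPS",
    "IUPAC_SETS",
    "ALPHABET",
    "SequenceRecord",
    "Alignment",
    "SampleTable",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "gc_content",
    "reverse_complement",
    "trim_alignment_tail",
]

#: Valid sample groups for library / query bookkeeping.
GROUPS = frozenset({"target", "congener", "adulterant", "query", "unknown"})

#: IUPAC nucleotide codes -> the set of unambiguous bases each may stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Full residue alphabet: IUPAC codes plus the alignment gap.
ALPHABET = frozenset(IUPAC_SETS) | {"-"}


def _validate_residues(residues: str, *, where: str = "sequence") -> None:
    for i, ch in enumerate(residues, start=1):
        if ch not in ALPHABET:
            raise ValueError(
                f"invalid residue {ch!r} at position {i} in {where}; "
                "allowed: IUPAC nucleotide codes and '-'"
            )


@dataclass
class SequenceRecord:
    """One sequence with its sample/species/group labels.

    ``residues`` are stored uppercase; gaps are only meaningful when the record
    lives inside an :class:`Alignment`.
    """

    id: str
    residues: str
    species: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.residues = self.residues.upper()
        _validate_residues(self.residues, where=f"record {self.id!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {sorted(GROUPS)}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class Alignment:
    """An ordered collection of equal-length gapped sequences.

    Columns are addressed 1-based.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment needs at least one record")
        lengths = {len(r.residues) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"records have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate id in alignment: {dup!r}")
        self.records = records
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, sample_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == sample_id:
                return r
        raise KeyError(sample_id)

    def column(self, pos: int) -> str:
        """States at 1-based column ``pos``, in record order."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"column {pos} out of range 1..{self.length}")
        return "".join(r.residues[pos - 1] for r in self.records)

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        wanted = set(sample_ids)
        missing = wanted - set(self.ids())
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in wanted])


class SampleTable:
    """Sample metadata: sample_id, species, group and optional accession."""

    REQUIRED = ("sample_id", "species", "group")

    def __init__(self, df: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if "accession" not in df.columns:
            df = df.assign(accession="")
        df = df[["sample_id", "species", "group", "accession"]].astype(str)
        bad = sorted(set(df["group"]) - GROUPS)
        if bad:
            raise ValueError(f"unknown group value(s) {bad}; expected one of {sorted(GROUPS)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in metadata")
        if (df["species"].str.len() == 0).any():
            raise ValueError("species labels must be non-empty")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def species_of(self, sample_id: str) -> str:
        hit = self.df.loc[self.df["sample_id"] == sample_id, "species"]
        if hit.empty:
            raise KeyError(f"sample {sample_id!r} not in metadata")
        return hit.iloc[0]

    def members(self, species: str | Iterable[str]) -> list[str]:
        labels = {species} if isinstance(species, str) else set(species)
        return list(self.df.loc[self.df["species"].isin(labels), "sample_id"])

    def species_in_group(self, group: str) -> list[str]:
        return sorted(self.df.loc[self.df["group"] == group, "species"].unique())

    def species_labels(self) -> list[str]:
        return list(dict.fromkeys(self.df["species"]))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the id; sequences are
    uppercased with line breaks and internal whitespace removed.  Duplicate ids
    and characters outside the IUPAC+gap alphabet raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = "".join(str(rec.seq).split()).upper()
        records.append(SequenceRecord(id=rec.id, residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, wrap: int = 70) -> None:
    """Write records as multi-FASTA, wrapped at ``wrap`` columns."""
    bio = [_BioSeqRecord(_BioSeq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def read_metadata(path: str | Path) -> SampleTable:
    """Read the sample metadata TSV (sample_id, species, group[, accession])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleTable(df)


def gc_content(residues: str) -> float:
    """G+C fraction over the unambiguous A/C/G/T bases of ``residues``.

    Gaps and ambiguity codes are excluded from both numerator and denominator.
    """
    _validate_residues(residues.upper())
    s = residues.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no unambiguous A/C/G/T bases in sequence")
    return (counts["G"] + counts["C"]) / denom


def reverse_complement(residues: str) -> str:
    """IUPAC-aware reverse complement; the gap character maps to itself."""
    s = residues.upper()
    _validate_residues(s)
    return _bio_revcomp(s)


def trim_alignment_tail(alignment: Alignment, n: int) -> Alignment:
    """Drop the last ``n`` columns from every record (3'-terminus harmonization)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= alignment.length:
        raise ValueError(f"cannot trim {n} columns from a length-{alignment.length} alignment")
    if n == 0:
        return alignment
    return Alignment(
        [
            SequenceRecord(r.id, r.residues[:-n], species=r.species, group=r.group)
            for r in alignment.records
        ]
    )
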