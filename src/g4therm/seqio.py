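"""Sequence, alignment, metadata and BED input/output.

All coordinates are 0-based half-open internally and in BED output; 1-based
coordinates appear only in human-readable reports.  RNA input (U) is
normalised to T so that rRNA and genomic sequences share one alphabet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


def normalize_residues(text: str, *, allow_gaps: bool = False) -> str:
    """Uppercase, map U->T, and validate against the {A,C,G,T,N} alphabet.

    Raises :class:`SequenceError` naming the offending position (0-based) if a
    character outside the alphabet (plus ``-`` when ``allow_gaps``) occurs.
    """
    s = text.upper().replace("U", "T")
    allowed = DNA_ALPHABET | ({GAP} if allow_gaps else set())
    for i, c in enumerate(s):
        if c not in allowed:
            raise SequenceError(f"illegal character {c!r} at position {i}")
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T,N} (gap-free)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class AlignedSequence:
    """A named aligned row; gaps ('-') allowed."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, allow_gaps=True)
        )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: >=2 equal-length rows."""

    records: tuple[AlignedSequence, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SequenceError("alignment needs at least 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SequenceError("duplicate record ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, seq_id: str) -> AlignedSequence:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"no record {seq_id!r} in alignment")


@dataclass(frozen=True)
class BedRecord:
    seq_id: str
    start: int
    end: int
    name: str
    score: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid BED interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def _parse_fasta(path: str | os.PathLike, allow_gaps: bool) -> list[tuple[str, str]]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            residues = normalize_residues(str(rec.seq), allow_gaps=allow_gaps)
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        out.append((rec.id, residues))
    return out


def read_fasta(path: str | os.PathLike) -> list[NucleotideSequence]:
    """Read a (gap-free) FASTA file.

    Errors on empty files, duplicate ids and characters outside {A,C,G,T,N,U}.
    """
    return [NucleotideSequence(i, s) for i, s in _parse_fasta(path, allow_gaps=False)]


def read_alignment(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA file (gaps allowed, equal lengths enforced)."""
    rows = [AlignedSequence(i, s) for i, s in _parse_fasta(path, allow_gaps=True)]
    return Alignment(tuple(rows))


def write_fasta(
    records: Sequence[NucleotideSequence | AlignedSequence],
    path: str | os.PathLike,
) -> None:
    """Write FASTA with 60-column line wrapping."""
    if not records:
        raise SequenceError("refusing to write empty FASTA")
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def reverse_complement(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N}; used for minus-strand and i-motif
    (C-rich mirror) scanning."""
    s = normalize_residues(residues)
    return s.translate(_COMPLEMENT)[::-1]


METADATA_COLUMNS = ("species_id", "t_min", "t_opt", "t_max")
METADATA_OPTIONAL = ("genome_fasta", "rrna_fasta")


def read_metadata(path: str | os.PathLike):
    """Read the species metadata TSV.

    Required columns: species_id, t_min, t_opt, t_max.  Optional per-row
    columns genome_fasta / rrna_fasta point at sequence files.  Returns a list
    of :class:`g4therm.metrics.SpeciesRecord` with thermal groups assigned.
    """
    from .metrics import SpeciesRecord, classify_topt

    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        t_min, t_opt, t_max = (float(row[c]) for c in ("t_min", "t_opt", "t_max"))
        if not (t_min <= t_opt <= t_max):
            raise ValueError(
                f"row {idx} ({row['species_id']}): temperatures must satisfy "
                f"t_min <= t_opt <= t_max, got {t_min}, {t_opt}, {t_max}"
            )
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]),
                t_min=t_min,
                t_opt=t_opt,
                t_max=t_max,
                group=classify_topt(t_opt),
                genome_fasta=_optional_path(row, "genome_fasta"),
                rrna_fasta=_optional_path(row, "rrna_fasta"),
            )
        )
    return records


def _optional_path(row, col):
    if col in row.index and isinstance(row[col], str) and row[col].strip():
        return row[col].strip()
    return None


def write_bed(items: Iterable, path: str | os.PathLike) -> None:
    """Write motifs or scored regions as 6-column BED, sorted by
    (seq_id, start, end) for deterministic output.

    G4 motifs carry their integer G-score; G-rich/C-rich propensity regions
    carry round(100 * |mean score|) with polarity as strand.
    """
    rows = []
    for i, item in enumerate(sorted(items, key=_bed_key)):
        rows.append(_to_bed(item, i + 1))
    lines = [
        f"{r.seq_id}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n"
        for r in rows
    ]
    if hasattr(path, "write"):
        path.writelines(lines)
    else:
        with open(path, "w") as fh:
            fh.writelines(lines)


def _bed_key(item):
    return (item.seq_id, item.start, item.end)


def _to_bed(item, n: int) -> BedRecord:
    if hasattr(item, "mean_score"):  # HunterRegion
        return BedRecord(
            seq_id=item.seq_id,
            start=item.start,
            end=item.end,
            name=f"HR_{n}",
            score=round(100 * abs(item.mean_score)),
            strand=item.polarity,
        )
    return BedRecord(
        seq_id=item.seq_id,
        start=item.start,
        end=item.end,
        name=f"G4_{n}",
        score=item.score,
        strand=item.strand,
    )
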