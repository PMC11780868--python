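"""Per-species and per-region summary statistics.

The motif frequency unit is motifs per kilobase throughout (a 16S gene of
~1.5 kb with 15 motifs has frequency 10).  A region is flagged as carrying a
stable quadruplex when its best G-score exceeds 25, the cut that separates
three-tetrad from two-tetrad motifs under the score formula in
:mod:`g4therm.g4detect`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite
from typing import Iterable, Optional, Sequence

THERMAL_GROUPS = ("psychrophile", "mesophile", "thermophile", "hyperthermophile")

STABLE_SCORE_THRESHOLD = 25


def classify_topt(t_opt: float) -> str:
    """Thermal group from optimal growth temperature (degC):
    < 20 psychrophile; [20, 45) mesophile; [45, 80) thermophile;
    >= 80 hyperthermophile."""
    if not isfinite(t_opt):
        raise ValueError(f"non-finite t_opt: {t_opt}")
    if t_opt < 20:
        return "psychrophile"
    if t_opt < 45:
        return "mesophile"
    if t_opt < 80:
        return "thermophile"
    return "hyperthermophile"


@dataclass
class SpeciesRecord:
    """A species with growth temperatures and (optionally) sequence stats."""

    species_id: str
    t_min: float
    t_opt: float
    t_max: float
    group: str
    genome_length: Optional[int] = None
    rrna_length: Optional[int] = None
    genome_gc: Optional[float] = None
    rrna_gc: Optional[float] = None
    genome_fasta: Optional[str] = None
    rrna_fasta: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.t_min <= self.t_opt <= self.t_max):
            raise ValueError(
                f"{self.species_id}: need t_min <= t_opt <= t_max, got "
                f"{self.t_min}, {self.t_opt}, {self.t_max}"
            )
        if self.group != classify_topt(self.t_opt):
            raise ValueError(
                f"{self.species_id}: group {self.group!r} inconsistent with "
                f"t_opt {self.t_opt}"
            )


@dataclass(frozen=True)
class RegionMetrics:
    """Motif summary for one species x region (genome or 16S)."""

    species_id: str
    region_kind: str  # "genome" | "rrna16s"
    region_length: int
    motif_count: int
    freq_per_kb: float
    mean_score: float
    max_score: int
    has_stable_g4: bool
    is_empty: bool  # True when no motif was found (mean/max reported as 0)


def gc_content(seq) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N is excluded from both
    numerator and denominator."""
    residues = seq.residues if hasattr(seq, "residues") else str(seq)
    gc = residues.count("G") + residues.count("C")
    informative = gc + residues.count("A") + residues.count("T")
    if informative == 0:
        raise ValueError("sequence has no informative (non-N) bases")
    return gc / informative


def g4_frequency(motif_count: int, length_bp: int) -> float:
    """Motifs per kilobase: 1000 * count / length."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    return 1000.0 * motif_count / length_bp


def summarize_region(
    species: SpeciesRecord | str,
    motifs: Sequence,
    region_kind: str,
    length_bp: int,
    stable_score_threshold: int = STABLE_SCORE_THRESHOLD,
) -> RegionMetrics:
    """Summarise detected motifs for one region of one species.

    An empty motif list is a legitimate data point: the count is 0, mean and
    max score are reported as 0 with ``is_empty`` set, and the stable flag is
    False.
    """
    species_id = species if isinstance(species, str) else species.species_id
    scores = [m.score for m in motifs]
    empty = not scores
    mean_score = 0.0 if empty else sum(scores) / len(scores)
    max_score = 0 if empty else max(scores)
    return RegionMetrics(
        species_id=species_id,
        region_kind=region_kind,
        region_length=length_bp,
        motif_count=len(scores),
        freq_per_kb=g4_frequency(len(scores), length_bp),
        mean_score=mean_score,
        max_score=max_score,
        has_stable_g4=(not empty) and max_score > stable_score_threshold,
        is_empty=empty,
    )


def stable_ratio(metrics: Iterable[RegionMetrics], group: str, species_groups: dict) -> float:
    """Fraction of species in ``group`` whose region carries a stable G4.

    ``species_groups`` maps species_id -> thermal group.  Raises if the group
    is empty among the given metrics.
    """
    members = [m for m in metrics if species_groups.get(m.species_id) == group]
    if not members:
        raise ValueError(f"no species with metrics in group {group!r}")
    return sum(m.has_stable_g4 for m in members) / len(members)
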