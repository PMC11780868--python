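"""Putative G-quadruplex detection and scoring.

Two complementary detectors are provided:

* a QGRS-style enumerator that lists every candidate of the form
  ``G{g} N{l1} G{g} N{l2} G{g} N{l3} G{g}`` (g >= 2, bounded loops and total
  length) and assigns each an integer G-score, suited to short regions such
  as 16S rRNA genes;
* a G4Hunter-style per-base propensity scorer with sliding-window averaging,
  suited to genome-wide scans.  Positive windows are G-rich (G4-prone on the
  given strand); negative windows are C-rich, i.e. i-motif-prone on the given
  strand and G4-prone on its complement.

The G-score used here is::

    score = 21*(g - 1) - round(mean pairwise |li - lj|) - round(mean loop length)

which increases with the number of stacked G-tetrads (g) and penalises long
and uneven loops.  It is calibrated so that minimal-loop two- and
three-tetrad motifs score 20 and 41 respectively, and so that a stability
cut at score > 25 separates three-tetrad from two-tetrad motifs (a
two-tetrad motif can score at most 21).  Exact parity with the QGRS Mapper
web service, whose formula is unpublished, is not claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import NucleotideSequence, normalize_residues, reverse_complement

log = logging.getLogger(__name__)

Strand = Literal["plus", "minus", "both"]


@dataclass(frozen=True)
class DetectionParams:
    """Detection parameters; defaults follow common QGRS practice
    (max length 30, min G-group 2, loops 0-36) and the published G4Hunter
    defaults (window 25, threshold 1.2)."""

    max_length: int = 30
    min_g: int = 2
    loop_min: int = 0
    loop_max: int = 36
    window: int = 25
    hunter_threshold: float = 1.2
    strands: Strand = "plus"

    def __post_init__(self) -> None:
        errors = []
        if self.min_g < 2:
            errors.append("min_g must be >= 2")
        if self.max_length < 4 * self.min_g:
            errors.append("max_length must be >= 4*min_g")
        if not (0 <= self.loop_min <= self.loop_max):
            errors.append("need 0 <= loop_min <= loop_max")
        if self.window < 1:
            errors.append("window must be >= 1")
        if self.hunter_threshold <= 0:
            errors.append("hunter_threshold must be > 0")
        if self.strands not in ("plus", "minus", "both"):
            errors.append(f"invalid strands {self.strands!r}")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass(frozen=True)
class G4Motif:
    """One quadruplex candidate: four G-runs of length ``g`` separated by
    loops ``loops`` = (l1, l2, l3)."""

    seq_id: str
    start: int
    end: int
    strand: str
    g: int
    loops: tuple[int, int, int]
    score: int
    motif_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != 4 * self.g + sum(self.loops):
            raise ValueError("motif span inconsistent with g and loop lengths")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HunterRegion:
    """A merged run of qualifying sliding windows with signed mean
    propensity; polarity '+' marks G-rich, '-' C-rich."""

    seq_id: str
    start: int
    end: int
    mean_score: float
    polarity: str


def score_qgrs(g: int, loops: Sequence[int]) -> int:
    """Integer G-score of a candidate with G-group size ``g`` and loop
    lengths ``loops``; strictly increasing in g, non-increasing in total loop
    length and loop-length spread."""
    if g < 2:
        raise ValueError("g must be >= 2")
    l1, l2, l3 = loops
    if min(loops) < 0:
        raise ValueError("negative loop length")
    spread = (abs(l1 - l2) + abs(l1 - l3) + abs(l2 - l3)) / 3.0
    mean_loop = (l1 + l2 + l3) / 3.0
    return 21 * (g - 1) - round(spread) - round(mean_loop)


def _g_run_from(s: str) -> list[int]:
    """run[i] = length of the maximal run of G starting at i."""
    n = len(s)
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if s[i] == "G" else 0
    return run


def enumerate_qgrs(
    seq: NucleotideSequence, params: DetectionParams = DetectionParams()
) -> list[G4Motif]:
    """Enumerate every QGRS candidate on the '+' strand of ``seq``.

    All (start, g, l1, l2, l3) decompositions within the length bounds are
    emitted, so candidates overlap freely; loops may themselves contain G.
    """
    s = seq.residues
    n = len(s)
    run = _g_run_from(s)
    lmin, lmax = params.loop_min, params.loop_max
    out: list[G4Motif] = []
    g_top = min(params.max_length // 4, max((run[i] for i in range(n)), default=0))
    for g in range(params.min_g, g_top + 1):
        budget = params.max_length - 4 * g  # total loop budget
        if budget < 3 * lmin:
            break
        for start in range(0, n - 4 * g - 3 * lmin + 1):
            if run[start] < g:
                continue
            for l1 in range(lmin, min(lmax, budget - 2 * lmin) + 1):
                p2 = start + g + l1
                if p2 + 3 * g + 2 * lmin > n:
                    break
                if run[p2] < g:
                    continue
                for l2 in range(lmin, min(lmax, budget - l1 - lmin) + 1):
                    p3 = p2 + g + l2
                    if p3 + 2 * g + lmin > n:
                        break
                    if run[p3] < g:
                        continue
                    for l3 in range(lmin, min(lmax, budget - l1 - l2) + 1):
                        p4 = p3 + g + l3
                        end = p4 + g
                        if end > n:
                            break
                        if run[p4] < g:
                            continue
                        out.append(
                            G4Motif(
                                seq_id=seq.id,
                                start=start,
                                end=end,
                                strand="+",
                                g=g,
                                loops=(l1, l2, l3),
                                score=score_qgrs(g, (l1, l2, l3)),
                                motif_sequence=s[start:end],
                            )
                        )
    return out


def select_nonoverlapping(candidates: Iterable[G4Motif]) -> list[G4Motif]:
    """Greedy best-scoring non-overlapping subset.

    Order of preference: higher score, then leftmost start, then shorter
    motif.  The result is independent of input ordering.  All candidates must
    share one seq_id and strand.
    """
    cands = list(candidates)
    if not cands:
        return []
    keys = {(c.seq_id, c.strand) for c in cands}
    if len(keys) > 1:
        raise ValueError(f"mixed seq_id/strand in candidates: {sorted(keys)}")
    chosen: list[G4Motif] = []
    for c in sorted(cands, key=lambda c: (-c.score, c.start, c.length)):
        if all(c.end <= k.start or c.start >= k.end for k in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


_HUNTER_CODE = {"A": 0, "T": 0, "N": 0, "G": 1, "C": -1}


def hunter_base_scores(residues: str) -> np.ndarray:
    """Per-base propensity: each base in a maximal G-run of length n scores
    +min(n, 4); C-runs score -min(n, 4); A/T/N score 0.  N breaks runs."""
    s = normalize_residues(residues)
    n = len(s)
    scores = np.zeros(n)
    i = 0
    while i < n:
        c = s[i]
        if c in "GC":
            j = i
            while j < n and s[j] == c:
                j += 1
            v = min(j - i, 4)
            scores[i:j] = v if c == "G" else -v
            i = j
        else:
            i += 1
    return scores


def hunter_regions(
    seq: NucleotideSequence, params: DetectionParams = DetectionParams()
) -> list[HunterRegion]:
    """Sliding-window G4Hunter scan (step 1).

    Windows whose |mean base score| >= threshold qualify; overlapping
    qualifying windows of the same sign merge into one region whose mean is
    recomputed over the merged span (and may therefore dip slightly below the
    window threshold).
    """
    w = params.window
    base = hunter_base_scores(seq.residues)
    n = len(base)
    if n < w:
        log.warning(
            "sequence %s shorter than window (%d < %d); no scan", seq.id, n, w
        )
        return []
    cums = np.concatenate([[0.0], np.cumsum(base)])
    means = (cums[w:] - cums[:-w]) / w  # means[k] = mean of base[k:k+w]
    qual = np.flatnonzero(np.abs(means) >= params.hunter_threshold)
    regions: list[HunterRegion] = []
    cur_first = cur_last = None
    cur_sign = 0
    for k in qual:
        sign = 1 if means[k] > 0 else -1
        if cur_sign != 0 and sign == cur_sign and k < cur_last + w:
            cur_last = k
        else:
            if cur_sign != 0:
                regions.append(_close_region(seq.id, cur_first, cur_last, w, cums))
            cur_first, cur_last, cur_sign = k, k, sign
    if cur_sign != 0:
        regions.append(_close_region(seq.id, cur_first, cur_last, w, cums))
    return regions


def _close_region(seq_id, first, last, w, cums) -> HunterRegion:
    start, end = int(first), int(last) + w
    mean = (cums[end] - cums[start]) / (end - start)
    return HunterRegion(
        seq_id=seq_id,
        start=start,
        end=end,
        mean_score=float(mean),
        polarity="+" if mean > 0 else "-",
    )


def scan_species(
    seq: NucleotideSequence,
    params: DetectionParams = DetectionParams(),
    method: Literal["qgrs", "hunter"] = "qgrs",
) -> list:
    """Scan one sequence with the requested detector over ``params.strands``.

    QGRS minus-strand hits are found by scanning the reverse complement and
    mapping coordinates back to the forward frame.  The Hunter scan reads
    both polarities off the forward strand (C-rich regions are reported with
    polarity '-'), so it is strand-complete by construction.
    """
    if method == "hunter":
        return hunter_regions(seq, params)
    if method != "qgrs":
        raise ValueError(f"unknown method {method!r}")
    hits: list[G4Motif] = []
    if params.strands in ("plus", "both"):
        hits.extend(enumerate_qgrs(seq, params))
    if params.strands in ("minus", "both"):
        rc = NucleotideSequence(seq.id, reverse_complement(seq.residues))
        n = len(rc.residues)
        for m in enumerate_qgrs(rc, params):
            hits.append(
                G4Motif(
                    seq_id=m.seq_id,
                    start=n - m.end,
                    end=n - m.start,
                    strand="-",
                    g=m.g,
                    loops=m.loops,
                    score=m.score,
                    motif_sequence=m.motif_sequence,
                )
            )
    hits.sort(key=lambda m: (m.start, m.end, m.strand))
    return hits
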