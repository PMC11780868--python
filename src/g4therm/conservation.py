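"""Conservation analysis of quadruplex loci across an alignment.

Covers the numeric side of sequence-logo analysis (per-column base
frequencies and information content), mapping of reference coordinate
windows through an alignment to each species, a presence/score matrix of
orthologous G4 loci, and identification of substitutions that disrupt a
motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .g4detect import DetectionParams, G4Motif, enumerate_qgrs, select_nonoverlapping
from .seqio import GAP, Alignment, NucleotideSequence

log = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class ColumnProfile:
    """Gap-excluded per-column base frequencies and information content.

    ``frequencies`` is (n_columns x 4) over A, C, G, T; all-gap columns are
    flagged and carry NaN frequencies/IC.  IC = 2 - H(column) in bits.
    """

    frequencies: np.ndarray
    information: np.ndarray
    nongap_count: np.ndarray
    all_gap: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(BASES))
        df.insert(0, "column", np.arange(len(df)))
        df["ic_bits"] = self.information
        df["nongap"] = self.nongap_count
        return df


def column_profile(alignment: Alignment) -> ColumnProfile:
    rows = np.vstack(
        [np.frombuffer(r.residues.encode(), dtype="S1") for r in alignment.records]
    )
    n_cols = rows.shape[1]
    counts = np.zeros((n_cols, 4))
    for k, b in enumerate(BASES):
        counts[:, k] = (rows == b.encode()).sum(axis=0)
    nongap = counts.sum(axis=1)
    all_gap = nongap == 0
    freqs = np.full((n_cols, 4), np.nan)
    ok = ~all_gap
    freqs[ok] = counts[ok] / nongap[ok, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    H = -plogp.sum(axis=1)
    ic = np.where(ok, 2.0 - H, np.nan)
    return ColumnProfile(
        frequencies=freqs,
        information=ic,
        nongap_count=nongap.astype(int),
        all_gap=all_gap,
    )


@dataclass(frozen=True)
class MappedWindow:
    """One species' ungapped subsequence under a reference window."""

    species_id: str
    sequence: str
    start: int  # ungapped coordinates in the species' own sequence
    end: int
    columns: tuple[int, int]  # alignment column span (half-open)


def map_window(
    alignment: Alignment, reference_id: str, ref_start: int, ref_end: int
) -> dict[str, MappedWindow]:
    """Map a reference-sequence window (0-based half-open, ungapped
    coordinates) through alignment columns onto every species.

    A window running past the reference's ungapped length is clamped with a
    warning; a window of zero usable extent raises.
    """
    ref = alignment.row(reference_id)
    col_of_base = [i for i, c in enumerate(ref.residues) if c != GAP]
    ref_len = len(col_of_base)
    if not (0 <= ref_start < ref_end):
        raise ValueError(f"invalid window [{ref_start}, {ref_end})")
    if ref_start >= ref_len:
        raise ValueError(
            f"window start {ref_start} beyond reference ungapped length {ref_len}"
        )
    if ref_end > ref_len:
        log.warning(
            "window end %d clamped to reference length %d", ref_end, ref_len
        )
        ref_end = ref_len
    col_start = col_of_base[ref_start]
    col_end = col_of_base[ref_end - 1] + 1
    out: dict[str, MappedWindow] = {}
    for rec in alignment.records:
        prefix = rec.residues[:col_start]
        sub_aln = rec.residues[col_start:col_end]
        start = len(prefix) - prefix.count(GAP)
        sub = sub_aln.replace(GAP, "")
        out[rec.id] = MappedWindow(
            species_id=rec.id,
            sequence=sub,
            start=start,
            end=start + len(sub),
            columns=(col_start, col_end),
        )
    return out


def _best_score(sequence: str, params: DetectionParams) -> Optional[int]:
    if len(sequence) < 4 * params.min_g:
        return None
    cands = enumerate_qgrs(NucleotideSequence("w", sequence), params)
    if not cands:
        return None
    return max(c.score for c in cands)


def g4_presence_matrix(
    alignment: Alignment,
    reference_id: str,
    loci: Sequence[tuple[int, int]],
    params: DetectionParams = DetectionParams(),
    flank: int = 5,
) -> pd.DataFrame:
    """Species x locus matrix of best G-scores at orthologous windows.

    Each locus is a reference-coordinate window; for every species the
    mapped subsequence (plus ``flank`` nt on each side, to tolerate small
    shifts) is rescanned with the QGRS enumerator.  Entries are the best
    candidate score, or NaN when no candidate is found or the mapping fails.
    """
    species = alignment.ids
    ungapped = {r.id: r.ungapped for r in alignment.records}
    locus_names = [f"locus_{a}_{b}" for a, b in loci]
    data = pd.DataFrame(np.nan, index=species, columns=locus_names)
    for (a, b), name in zip(loci, locus_names):
        try:
            mapped = map_window(alignment, reference_id, a, b)
        except ValueError as exc:
            log.warning("locus %s unmapped: %s", name, exc)
            continue
        for sp in species:
            w = mapped[sp]
            full = ungapped[sp]
            region = full[max(0, w.start - flank) : min(len(full), w.end + flank)]
            best = _best_score(region, params)
            if best is not None:
                data.loc[sp, name] = best
    return data


def write_presence_tsv(matrix: pd.DataFrame, path) -> None:
    """Presence matrix as TSV with '.' marking absent loci."""
    out = matrix.copy()
    out.index.name = "species_id"
    formatted = out.map(lambda v: "." if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep="\t")


@dataclass(frozen=True)
class Substitution:
    position: int  # reference ungapped coordinate
    ref_base: str  # '-' marks an insertion relative to the reference
    alt_base: str  # '-' marks a deletion in the species
    in_g_run: bool


@dataclass(frozen=True)
class DisruptionReport:
    substitutions: tuple[Substitution, ...]
    forming: bool  # species still forms a motif of at least the reference g


def _g_run_offsets(motif: G4Motif) -> set[int]:
    """Offsets (relative to motif start) lying inside the four G-runs."""
    g = motif.g
    l1, l2, l3 = motif.loops
    runs = []
    pos = 0
    for loop in (l1, l2, l3, None):
        runs.extend(range(pos, pos + g))
        pos += g + (loop or 0)
    return set(runs)


def disrupting_substitutions(
    reference_seq: str,
    species_seq: str,
    motif: G4Motif,
    params: DetectionParams = DetectionParams(),
    flank: int = 5,
) -> DisruptionReport:
    """Differences between an aligned reference/species pair inside a motif
    footprint, with G-run positions flagged, plus a forming/non-forming call
    made by rescanning the species subsequence.

    ``reference_seq`` and ``species_seq`` are the aligned rows (equal
    length, gaps allowed); ``motif`` coordinates are reference ungapped.
    """
    if len(reference_seq) != len(species_seq):
        raise ValueError("aligned pair must have equal lengths")
    ref_len = len(reference_seq) - reference_seq.count(GAP)
    if not (0 <= motif.start < motif.end <= ref_len):
        raise ValueError("motif lies outside the aligned reference window")
    g_run = _g_run_offsets(motif)
    subs: list[Substitution] = []
    sp_chars: list[str] = []
    ref_pos = 0  # ungapped reference coordinate of the next reference base
    for rc, sc in zip(reference_seq.upper(), species_seq.upper()):
        if rc == GAP and sc == GAP:
            continue
        in_window = motif.start <= (ref_pos if rc != GAP else ref_pos - 1) < motif.end
        if rc == GAP:
            if in_window and ref_pos > motif.start:
                subs.append(Substitution(ref_pos, GAP, sc, False))
                sp_chars.append(sc)
            continue
        if in_window:
            if sc != GAP:
                sp_chars.append(sc)
            if sc != rc:
                subs.append(
                    Substitution(
                        ref_pos, rc, sc, (ref_pos - motif.start) in g_run
                    )
                )
        ref_pos += 1
    species_window = "".join(sp_chars)
    # include a small flank from the species row to tolerate shifted runs
    forming = False
    if species_window:
        sp_ungapped = species_seq.replace(GAP, "")
        w_start = _species_offset(reference_seq, species_seq, motif.start)
        region = sp_ungapped[
            max(0, w_start - flank) : w_start + len(species_window) + flank
        ]
        cands = enumerate_qgrs(NucleotideSequence("w", region), params)
        forming = any(c.g >= motif.g for c in cands)
    return DisruptionReport(substitutions=tuple(subs), forming=forming)


def _species_offset(ref_aligned: str, sp_aligned: str, ref_coord: int) -> int:
    """Species ungapped coordinate aligned with reference ungapped coord."""
    ref_pos = sp_pos = 0
    for rc, sc in zip(ref_aligned, sp_aligned):
        if ref_pos == ref_coord and rc != GAP:
            return sp_pos
        if rc != GAP:
            ref_pos += 1
        if sc != GAP:
            sp_pos += 1
    return sp_pos
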