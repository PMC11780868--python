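"""End-to-end orchestration: simulate/load -> detect -> metrics -> tree ->
comparative statistics -> conservation -> report.

The pipeline is deterministic given its seed: every emitted TSV/BED/Newick
file is byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import configparser
import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .conservation import column_profile, g4_presence_matrix, write_presence_tsv
from .g4detect import DetectionParams, scan_species, select_nonoverlapping
from .metrics import (
    STABLE_SCORE_THRESHOLD,
    THERMAL_GROUPS,
    gc_content,
    summarize_region,
)
from .phylo import bootstrap_support, distance_matrix, midpoint_root, nj_tree, write_newick
from .seqio import Alignment, NucleotideSequence, read_alignment, read_fasta, write_bed
from .simulate import SyntheticDataset, build_dataset, null_params, default_params
from .stats import PGLS, anova_oneway, normality_check, pearson

log = logging.getLogger("g4therm.pipeline")

_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "g4therm_out"
    seed: int = 0
    mode: str = "simulate"  # "simulate" | "files"
    preset: str = "default"  # simulate mode: "default" | "null"
    n_species: Optional[int] = None
    metadata: Optional[str] = None  # files mode: metadata TSV path
    alignment: Optional[str] = None  # files mode: aligned FASTA path
    # detection
    max_length: int = 30
    min_g: int = 2
    loop_min: int = 0
    loop_max: int = 36
    window: int = 25
    hunter_threshold: float = 1.2
    strands: str = "plus"
    stable_score_threshold: int = STABLE_SCORE_THRESHOLD
    # analysis
    pgls_mode: str = "ml"  # "ml" | "fixed"
    lambda_fixed: Optional[float] = None
    anova_transform: str = "auto"  # "auto" | "none" | "log10"
    bootstrap: int = 0
    conservation: bool = True

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            max_length=self.max_length,
            min_g=self.min_g,
            loop_min=self.loop_min,
            loop_max=self.loop_max,
            window=self.window,
            hunter_threshold=self.hunter_threshold,
            strands=self.strands,  # type: ignore[arg-type]
        )

    def validate(self) -> None:
        errors = []
        if self.mode not in ("simulate", "files"):
            errors.append(f"mode must be simulate|files, got {self.mode!r}")
        if self.mode == "simulate" and self.preset not in ("default", "null"):
            errors.append(f"unknown preset {self.preset!r}")
        if self.mode == "files" and not self.metadata:
            errors.append("files mode requires a metadata path")
        try:
            self.detection_params()
        except ValueError as exc:
            errors.append(str(exc))
        if self.pgls_mode not in ("ml", "fixed"):
            errors.append(f"pgls_mode must be ml|fixed, got {self.pgls_mode!r}")
        if self.pgls_mode == "fixed":
            lf = self.lambda_fixed
            if lf is None or not (0.0 <= lf <= 1.0):
                errors.append("fixed pgls_mode needs lambda_fixed in [0, 1]")
        elif self.lambda_fixed is not None and not (0.0 <= self.lambda_fixed <= 1.0):
            errors.append("lambda_fixed must lie in [0, 1]")
        if self.anova_transform not in ("auto", "none", "log10"):
            errors.append(f"unknown anova_transform {self.anova_transform!r}")
        if self.bootstrap < 0:
            errors.append("bootstrap must be >= 0")
        if errors:
            raise ConfigError("; ".join(errors))


_SECTIONS = {
    "run": ("outdir", "seed", "mode", "preset", "n_species", "metadata", "alignment"),
    "detection": (
        "max_length", "min_g", "loop_min", "loop_max", "window",
        "hunter_threshold", "strands", "stable_score_threshold",
    ),
    "analysis": (
        "pgls_mode", "lambda_fixed", "anova_transform", "bootstrap", "conservation",
    ),
}

_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}
_INT_KEYS = {
    "seed", "n_species", "max_length", "min_g", "loop_min", "loop_max",
    "window", "stable_score_threshold", "bootstrap",
}
_FLOAT_KEYS = {"hunter_threshold", "lambda_fixed"}
_BOOL_KEYS = {"conservation"}


def validate_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse and validate a sectioned key=value config file.

    Unknown sections or keys are rejected; every violation is reported in a
    single aggregated :class:`ConfigError`.  An empty file yields the
    defaults-only configuration.
    """
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"unparseable config: {exc}") from exc
    errors: list[str] = []
    kwargs: dict = {}
    for section in parser.sections():
        if section not in _SECTIONS:
            errors.append(f"unknown section [{section}]")
            continue
        for key, raw in parser.items(section):
            if key not in _SECTIONS[section]:
                errors.append(f"unknown key {key!r} in [{section}]")
                continue
            try:
                kwargs[key] = _coerce(key, raw)
            except ValueError as exc:
                errors.append(f"[{section}] {key}: {exc}")
    if errors:
        raise ConfigError("; ".join(errors))
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


def _coerce(key: str, raw: str):
    raw = raw.strip()
    if key in _INT_KEYS:
        return int(raw)
    if key in _FLOAT_KEYS:
        return float(raw)
    if key in _BOOL_KEYS:
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    return raw


# ---------------------------------------------------------------------------
# analysis core (file-free; run_pipeline adds the I/O around it)
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    metrics: pd.DataFrame  # one row per species x region
    group_summary: pd.DataFrame  # per thermal group: n, means, stable ratio
    pgls: pd.DataFrame  # regression panel
    anova: pd.DataFrame  # one row per response: F, p, transform
    anova_pairwise: pd.DataFrame
    tree: object  # dendropy tree (unrooted; supports if bootstrapped)
    rrna_motifs: dict  # species_id -> selected motifs
    genome_regions: Optional[dict]
    presence: Optional[pd.DataFrame]
    profile: Optional[pd.DataFrame]
    report: dict


def analyze(
    metadata: pd.DataFrame,
    rrna: list[NucleotideSequence],
    alignment: Alignment,
    genomes: Optional[list[NucleotideSequence]] = None,
    config: PipelineConfig = PipelineConfig(),
    tree=None,
    loci=None,
) -> AnalysisResult:
    """Run detection, metrics, tree building, comparative statistics and
    (optionally) conservation on in-memory inputs."""
    config.validate()
    det = config.detection_params()
    meta = metadata.set_index("species_id", drop=False)
    species = list(meta.index)
    rrna_by_id = {r.id: r for r in rrna}
    missing = [s for s in species if s not in rrna_by_id]
    if missing:
        raise ValueError(f"metadata species without 16S sequence: {missing}")

    # -- detection + per-region metrics
    log.info("detect: QGRS scan of %d 16S sequences", len(species))
    rrna_motifs = {}
    rows = []
    for sp in species:
        seq = rrna_by_id[sp]
        motifs = select_nonoverlapping(scan_species(seq, det, method="qgrs"))
        rrna_motifs[sp] = motifs
        m = summarize_region(
            sp, motifs, "rrna16s", seq.length, config.stable_score_threshold
        )
        rows.append(_metrics_row(m, meta.loc[sp], gc_content(seq)))
    genome_regions = None
    if genomes is not None:
        log.info("detect: G4Hunter scan of %d genomes", len(genomes))
        genome_regions = {}
        genomes_by_id = {g.id: g for g in genomes}
        for sp in species:
            if sp not in genomes_by_id:
                continue
            gseq = genomes_by_id[sp]
            regions = scan_species(gseq, det, method="hunter")
            genome_regions[sp] = regions
            scored = [
                _ScoreShim(round(100 * abs(r.mean_score))) for r in regions
            ]
            m = summarize_region(
                sp, scored, "genome", gseq.length, config.stable_score_threshold
            )
            rows.append(_metrics_row(m, meta.loc[sp], gc_content(gseq)))
    metrics_df = pd.DataFrame(rows).sort_values(["region_kind", "species_id"])
    metrics_df = metrics_df.reset_index(drop=True)

    # -- tree
    if tree is None:
        log.info("tree: NJ from K2P distances (%d taxa)", len(species))
        if config.bootstrap > 0:
            tree = bootstrap_support(alignment, B=config.bootstrap, seed=config.seed)
        else:
            tree = nj_tree(distance_matrix(alignment))
    rooted = tree if tree.is_rooted else midpoint_root(tree)

    # -- group summary
    rr = metrics_df[metrics_df.region_kind == "rrna16s"].set_index("species_id")
    group_rows = []
    for grp in THERMAL_GROUPS:
        sub = rr[rr.group == grp]
        if len(sub) == 0:
            continue
        group_rows.append(
            {
                "group": grp,
                "n": len(sub),
                "mean_freq_per_kb": sub.freq_per_kb.mean(),
                "mean_score": sub.mean_score.mean(),
                "stable_ratio": sub.has_stable_g4.mean(),
            }
        )
    group_summary = pd.DataFrame(group_rows)

    # -- PGLS / Pearson panel
    log.info("stats: PGLS panel (%s lambda)", config.pgls_mode)
    from .stats import bm_covariance

    V = bm_covariance(rooted)
    panel = _stat_panel(rr, metrics_df, species, V)
    pgls_rows = []
    for resp_name, resp in panel["responses"].items():
        for pred_name in panel["predictors"]:
            x = meta.loc[resp.index, pred_name].astype(float)
            row = {"response": resp_name, "predictor": pred_name, "n": len(resp)}
            try:
                X = pd.DataFrame({"intercept": 1.0, pred_name: x})
                fit = PGLS(
                    resp, X, V=panel["V"].loc[resp.index, resp.index],
                    labels=list(resp.index),
                ).fit(
                    lambda_mode=config.pgls_mode,
                    lambda_fixed=config.lambda_fixed,
                )
                row.update(
                    beta=fit.params[pred_name],
                    se=fit.bse[pred_name],
                    t=fit.tvalues[pred_name],
                    p=fit.pvalues[pred_name],
                    lambda_=fit.lambda_,
                )
            except ValueError as exc:
                log.warning("PGLS %s ~ %s failed: %s", resp_name, pred_name, exc)
                row.update(beta=np.nan, se=np.nan, t=np.nan, p=np.nan, lambda_=np.nan)
            try:
                r, rp = pearson(x.values, resp.values)
            except ValueError:
                r, rp = np.nan, np.nan
            row.update(pearson_r=r, pearson_p=rp)
            pgls_rows.append(row)
    pgls_df = pd.DataFrame(pgls_rows)

    # -- ANOVA across thermal groups
    anova_rows, pairwise_frames = [], []
    for resp_name in ("freq_per_kb", "mean_score"):
        grouped = [
            (grp, rr.loc[rr.group == grp, resp_name].values)
            for grp in THERMAL_GROUPS
            if (rr.group == grp).sum() >= 2
        ]
        if len(grouped) < 2:
            continue
        values = np.concatenate([v for _, v in grouped])
        transform = config.anova_transform
        if transform == "auto":
            transform = "none"
            if len(values) >= 8:
                check = normality_check(values)
                if check.classification == "lognormal":
                    transform = "log10"
        if transform == "log10" and np.any(values <= 0):
            transform = "none"
        res = anova_oneway(
            [v for _, v in grouped], labels=[g for g, _ in grouped],
            transform=transform,
        )
        anova_rows.append(
            {
                "response": resp_name,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "transform": res.transform,
            }
        )
        pw = res.pairwise.copy()
        pw.insert(0, "response", resp_name)
        pairwise_frames.append(pw)
    anova_df = pd.DataFrame(anova_rows)
    pairwise_df = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame(columns=["response", "group_i", "group_j", "mean_diff", "adjusted_p"])
    )

    # -- conservation
    presence = profile = None
    if config.conservation and loci:
        log.info("conservation: presence matrix over %d loci", len(loci))
        reference_id = species[0]
        presence = g4_presence_matrix(alignment, reference_id, loci, det)
        profile = column_profile(alignment).as_dataframe()

    report = _build_report(
        config, metrics_df, group_summary, pgls_df, anova_df, species
    )
    return AnalysisResult(
        metrics=metrics_df,
        group_summary=group_summary,
        pgls=pgls_df,
        anova=anova_df,
        anova_pairwise=pairwise_df,
        tree=tree,
        rrna_motifs=rrna_motifs,
        genome_regions=genome_regions,
        presence=presence,
        profile=profile,
        report=report,
    )


class _ScoreShim:
    """Adapter giving Hunter regions the integer-score interface that
    summarize_region expects."""

    __slots__ = ("score",)

    def __init__(self, score: int):
        self.score = score


def _metrics_row(m, meta_row, gc):
    return {
        "species_id": m.species_id,
        "region_kind": m.region_kind,
        "group": meta_row["group"],
        "t_min": meta_row["t_min"],
        "t_opt": meta_row["t_opt"],
        "t_max": meta_row["t_max"],
        "gc": gc,
        "region_length": m.region_length,
        "motif_count": m.motif_count,
        "freq_per_kb": m.freq_per_kb,
        "mean_score": m.mean_score,
        "max_score": m.max_score,
        "has_stable_g4": m.has_stable_g4,
    }


def _stat_panel(rr, metrics_df, species, V):
    """Response vectors, predictors and phylogenetic covariance."""
    responses = {
        "rrna_freq_per_kb": rr.freq_per_kb,
        "rrna_mean_score": rr.mean_score,
        "rrna_gc": rr.gc,
    }
    gen = metrics_df[metrics_df.region_kind == "genome"]
    if len(gen):
        gen = gen.set_index("species_id").reindex(species).dropna(subset=["gc"])
        responses["genome_freq_per_kb"] = gen.freq_per_kb
        responses["genome_gc"] = gen.gc
    return {
        "responses": responses,
        "predictors": ("t_min", "t_opt", "t_max"),
        "V": V,
    }


def _build_report(config, metrics_df, group_summary, pgls_df, anova_df, species):
    rr = metrics_df[metrics_df.region_kind == "rrna16s"]
    gen = metrics_df[metrics_df.region_kind == "genome"]
    stage_counts = {
        "species": len(species),
        "rrna_regions": int(len(rr)),
        "genome_regions": int(len(gen)),
        "rrna_motifs_total": int(rr.motif_count.sum()),
        "genome_motifs_total": int(gen.motif_count.sum()) if len(gen) else 0,
    }
    key = pgls_df[
        (pgls_df.response == "rrna_mean_score") & (pgls_df.predictor == "t_opt")
    ]
    headline = {
        "groups": group_summary.to_dict(orient="records"),
        "pgls_slopes": pgls_df[pgls_df.predictor == "t_opt"][
            ["response", "beta", "p", "lambda_", "pearson_r"]
        ].to_dict(orient="records"),
        "anova": anova_df.to_dict(orient="records"),
        "rrna_score_topt_positive_significant": bool(
            len(key) and key.iloc[0].beta > 0 and key.iloc[0].p < 0.05
        ),
    }
    echo = asdict(config)
    for path_key in ("outdir", "metadata", "alignment"):
        echo.pop(path_key, None)  # keep the report path-independent
    return {
        "version": __version__,
        "seed": config.seed,
        "config": echo,
        "stage_counts": stage_counts,
        "headline": headline,
    }


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Execute all stages and write every artifact under ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    loci = None
    tree = None
    if config.mode == "simulate":
        log.info("simulate: preset=%s seed=%d", config.preset, config.seed)
        overrides = {}
        if config.n_species:
            overrides["n_species"] = config.n_species
        params = (
            default_params(config.seed, **overrides)
            if config.preset == "default"
            else null_params(config.seed, **overrides)
        )
        dataset = build_dataset(params)
        dataset.write(config.outdir)
        metadata = dataset.metadata
        rrna, genomes, alignment = dataset.rrna, dataset.genomes, dataset.alignment
        loci = dataset.loci
    else:
        from .seqio import read_metadata

        records = read_metadata(config.metadata)
        base = os.path.dirname(os.path.abspath(config.metadata))
        metadata = pd.DataFrame(
            [
                {
                    "species_id": r.species_id,
                    "t_min": r.t_min,
                    "t_opt": r.t_opt,
                    "t_max": r.t_max,
                    "group": r.group,
                }
                for r in records
            ]
        )
        rrna, genomes = _load_sequences(records, base)
        if config.alignment:
            alignment = read_alignment(
                config.alignment
                if os.path.isabs(config.alignment)
                else os.path.join(base, config.alignment)
            )
        else:
            raise ConfigError("files mode requires an alignment path")

    result = analyze(
        metadata, rrna, alignment, genomes=genomes, config=config,
        tree=tree, loci=loci,
    )
    _write_outputs(config, result)
    return result


def _load_sequences(records, base):
    rrna, genomes = [], []
    rrna_files, genome_files = {}, {}
    for r in records:
        if r.rrna_fasta:
            rrna_files.setdefault(os.path.join(base, r.rrna_fasta), None)
        if r.genome_fasta:
            genome_files.setdefault(os.path.join(base, r.genome_fasta), None)
    for path in rrna_files:
        rrna.extend(read_fasta(path))
    for path in genome_files:
        genomes.extend(read_fasta(path))
    return rrna, (genomes or None)


def _write_outputs(config: PipelineConfig, result: AnalysisResult) -> None:
    out = config.outdir
    all_motifs = [m for sp in sorted(result.rrna_motifs) for m in result.rrna_motifs[sp]]
    write_bed(all_motifs, os.path.join(out, "rrna_qgrs.bed"))
    log.info("detect: wrote %d 16S motifs", len(all_motifs))
    if result.genome_regions is not None:
        regions = [
            r for sp in sorted(result.genome_regions)
            for r in result.genome_regions[sp]
        ]
        write_bed(regions, os.path.join(out, "genome_hunter.bed"))
        log.info("detect: wrote %d genome regions", len(regions))
    result.metrics.to_csv(
        os.path.join(out, "metrics.tsv"), sep="\t", index=False,
        float_format=_FLOAT_FMT,
    )
    result.group_summary.to_csv(
        os.path.join(out, "group_summary.tsv"), sep="\t", index=False,
        float_format=_FLOAT_FMT,
    )
    write_newick(result.tree, os.path.join(out, "tree.nwk"))
    result.pgls.to_csv(
        os.path.join(out, "pgls.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    result.anova.to_csv(
        os.path.join(out, "anova.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    result.anova_pairwise.to_csv(
        os.path.join(out, "anova_pairwise.tsv"), sep="\t", index=False,
        float_format=_FLOAT_FMT,
    )
    if result.presence is not None:
        write_presence_tsv(result.presence, os.path.join(out, "presence.tsv"))
    if result.profile is not None:
        result.profile.to_csv(
            os.path.join(out, "profile.tsv"), sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    log.info("report: wrote %s", os.path.join(out, "report.json"))
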