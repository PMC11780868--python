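"""Synthetic comparative-genomics data with known ground truth.

The generator emulates the structure of a prokaryotic thermal-adaptation
dataset: an ultrametric pure-birth phylogeny, Brownian-motion evolution of
the optimal growth temperature (T_opt), per-species 16S-like sequences whose
GC content and planted quadruplex density/stability increase with T_opt, and
point mutations that disrupt planted motifs (more often at low T_opt).

All species share the same planted locus positions and sequence length, so
the emitted "alignment" is the sequences themselves (equal length, no gaps);
the coordinate-mapping machinery is exercised separately with hand-made
gapped fixtures.  Every random draw descends from one master seed, so a
parameter set plus seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .g4detect import score_qgrs
from .metrics import classify_topt, gc_content
from .seqio import AlignedSequence, Alignment, NucleotideSequence, write_fasta
from .stats import bm_covariance, lambda_transform

_BASES = np.array(list("ACGT"))
_NON_G = np.array(list("ACT"))

_MAX_SPAN = 4 * 3 + 3 * 7  # largest plantable motif (g=3, loops up to 7)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Defaults are the standard study preset: 96 species whose T_opt values are
    rank-matched to a fixed four-group temperature distribution dominated by
    mesophiles, with small psychrophile and hyperthermophile groups so that
    every group-level comparison is defined at desk scale.
    """

    n_species: int = 96
    seed: int = 0
    birth_rate: float = 1.0
    bm_sigma2: float = 400.0  # trait variance at the leaves (tree depth 1)
    bm_root: float = 45.0  # degC
    lambda_true: float = 1.0
    trait_mode: str = "quantile"  # "quantile" (rank-matched groups) or "bm"
    group_quotas: tuple[int, int, int, int] = (6, 63, 21, 6)
    gc_intercept: float = 0.50
    gc_slope: float = 0.0015  # per degC
    seq_length: int = 1500
    n_loci: int = 16
    # site-class mixture of the 16S-like sequences: a conserved core shared
    # by all species, a variable class evolved along the tree, and a
    # species-specific class whose composition absorbs the GC target
    frac_conserved: float = 0.50
    frac_variable: float = 0.20
    conserved_gc: float = 0.55
    subst_rate: float = 0.3  # expected substitutions/site root-to-leaf (depth 1)
    motif_rate_low: float = 1.0  # expected planted motifs at T_opt = 20 degC
    motif_rate_high: float = 8.0  # ... at T_opt = 85 degC
    p3_midpoint: float = 75.0  # logistic midpoint for P(3-tetrad | T_opt)
    p3_scale: float = 6.0
    p3_constant: Optional[float] = None  # overrides the logistic (null configs)
    disruption_low: float = 0.05  # disruption probability at high T_opt
    disruption_high: float = 0.5  # ... at low T_opt
    disruption_midpoint: float = 45.0
    disruption_scale: float = 10.0
    disruption_constant: Optional[float] = None
    make_genomes: bool = True
    genome_length: int = 20000
    genome_gc: float = 0.50
    genome_gc_slope: float = 0.0  # genomic GC decoupled from T_opt by default

    def __post_init__(self) -> None:
        errors = []
        if self.n_species < 3:
            errors.append("n_species must be >= 3")
        if self.birth_rate <= 0:
            errors.append("birth_rate must be > 0")
        if self.bm_sigma2 < 0:
            errors.append("bm_sigma2 must be >= 0")
        if not (0 <= self.lambda_true <= 1):
            errors.append("lambda_true must lie in [0, 1]")
        if self.trait_mode not in ("quantile", "bm"):
            errors.append(f"unknown trait_mode {self.trait_mode!r}")
        if self.trait_mode == "quantile" and sum(self.group_quotas) != self.n_species:
            errors.append("group_quotas must sum to n_species")
        if self.n_loci < 1:
            errors.append("n_loci must be >= 1")
        if self.seq_length < self.n_loci * (_MAX_SPAN + 10) + 100:
            errors.append("seq_length too short for n_loci planted loci")
        if self.motif_rate_low < 0 or self.motif_rate_high < 0:
            errors.append("motif rates must be >= 0")
        if not (0 <= self.frac_conserved and 0 <= self.frac_variable
                and self.frac_conserved + self.frac_variable < 1):
            errors.append("site-class fractions must be >= 0 and sum to < 1")
        if self.subst_rate < 0:
            errors.append("subst_rate must be >= 0")
        if errors:
            raise ValueError("invalid SimulationParams: " + "; ".join(errors))

    # -- the T_opt -> property links ----------------------------------------

    def motif_rate(self, t: float) -> float:
        """Expected planted motifs per sequence, linear between the anchor
        temperatures 20 and 85 degC."""
        r = self.motif_rate_low + (self.motif_rate_high - self.motif_rate_low) * (
            (t - 20.0) / 65.0
        )
        return float(np.clip(r, 0.0, self.n_loci))

    def p_three_tetrad(self, t: float) -> float:
        if self.p3_constant is not None:
            return self.p3_constant
        return float(1.0 / (1.0 + np.exp(-(t - self.p3_midpoint) / self.p3_scale)))

    def disruption_rate(self, t: float) -> float:
        if self.disruption_constant is not None:
            return self.disruption_constant
        span = self.disruption_high - self.disruption_low
        return float(
            self.disruption_low
            + span / (1.0 + np.exp((t - self.disruption_midpoint) / self.disruption_scale))
        )

    def gc_target(self, t: float) -> float:
        return float(np.clip(self.gc_intercept + self.gc_slope * t, 0.25, 0.75))


def _scaled_quotas(n: int) -> tuple[int, int, int, int]:
    """Rescale the default group quotas to ``n`` species, keeping every
    group populated with at least 2 members."""
    base = np.array([6, 63, 21, 6], dtype=float)
    q = np.maximum(2, np.round(base * n / base.sum()).astype(int))
    q[1] += n - q.sum()
    if q[1] < 2:
        raise ValueError(f"n_species={n} too small for four populated groups")
    return tuple(int(x) for x in q)


def default_params(seed: int = 0, **overrides) -> SimulationParams:
    """The default study conditions (see :class:`SimulationParams`)."""
    if "n_species" in overrides and "group_quotas" not in overrides:
        overrides["group_quotas"] = _scaled_quotas(overrides["n_species"])
    return replace(SimulationParams(seed=seed), **overrides)


def null_params(seed: int = 0, n_species: int = 64, **overrides) -> SimulationParams:
    """A null configuration: every sequence property is independent of
    T_opt (constant motif rate, tetrad mix, disruption and GC).

    The tree-evolved site class is switched off so that sequence-derived
    metrics are independent across species: the regression null hypothesis
    then holds exactly, which is what a type-I-error calibration needs.  The
    default preset keeps lineage-correlated sites.
    """
    base = SimulationParams(
        n_species=n_species,
        seed=seed,
        trait_mode="bm",
        gc_slope=0.0,
        gc_intercept=0.55,
        seq_length=900,
        n_loci=10,
        motif_rate_low=3.0,
        motif_rate_high=3.0,
        p3_constant=0.3,
        disruption_constant=0.2,
        frac_variable=0.0,
        make_genomes=False,
    )
    return replace(base, **overrides)


def yule_tree(
    n: int,
    birth_rate: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    depth: Optional[float] = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n`` extant leaves, rooted and
    ultrametric; ``depth`` rescales the root-to-leaf height."""
    if n < 3:
        raise ValueError("need n >= 3 leaves")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_final = t + rng.exponential(1.0 / (birth_rate * n))
    for node, birth in active:
        node.edge.length = t_final - birth
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"sp{i:03d}")
    if depth is not None:
        scale = depth / t_final
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float,
    root_value: float,
    lambda_true: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.Series:
    """Leaf trait values from a multivariate normal with mean ``root_value``
    and covariance ``sigma2 * lambda_transform(bm_covariance(tree))``."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    V = bm_covariance(tree)
    labels = list(V.index)
    if sigma2 == 0:
        return pd.Series(root_value, index=labels)
    C = sigma2 * lambda_transform(V, lambda_true).values
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C)
    return pd.Series(root_value + L @ rng.standard_normal(len(labels)), index=labels)


def generate_sequence(
    length: int,
    gc_target: float,
    seed: int | np.random.Generator = 0,
    seq_id: str = "seq",
) -> NucleotideSequence:
    """I.i.d. random sequence with P(G) = P(C) = gc_target / 2."""
    if not (0.0 < gc_target < 1.0):
        raise ValueError("gc_target must lie strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_gc = gc_target / 2.0
    p_at = (1.0 - gc_target) / 2.0
    draws = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return NucleotideSequence(seq_id, "".join(_BASES[draws]))


@dataclass(frozen=True)
class PlantedMotif:
    locus: int
    start: int
    end: int
    g: int
    loops: tuple[int, int, int]
    disrupted: bool
    score_intact: int  # score of the motif as planted, before any disruption


def plant_g4(
    residues: str,
    g: int,
    loops: Sequence[int],
    position: int,
    disrupted: bool,
    seed: int | np.random.Generator = 0,
    locus: int = 0,
    occupied: Optional[list[tuple[int, int]]] = None,
) -> tuple[str, PlantedMotif]:
    """Overwrite a quadruplex motif into ``residues`` at ``position``.

    Writes four G-runs of length ``g`` separated by random non-G loop bases,
    and forces the single base on each side of the motif to be non-G so the
    planted G-group size is exactly ``g``.  When ``disrupted``, the middle G
    of one randomly chosen run is replaced by A or T, guaranteeing no run of
    length ``g`` survives at the locus.  Raises if the motif does not fit or
    overlaps a previously planted interval in ``occupied``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    l1, l2, l3 = (int(x) for x in loops)
    span = 4 * g + l1 + l2 + l3
    end = position + span
    if position < 0 or end > len(residues):
        raise ValueError(f"motif [{position}, {end}) does not fit in sequence")
    if occupied is not None:
        for a, b in occupied:
            if position < b and a < end:
                raise ValueError(
                    f"locus [{position}, {end}) overlaps planted [{a}, {b})"
                )
        occupied.append((position, end))
    chars = list(residues)
    run_starts = []
    pos = position
    for loop in (l1, l2, l3, None):
        run_starts.append(pos)
        for k in range(g):
            chars[pos + k] = "G"
        pos += g
        if loop is not None:
            for k in range(loop):
                chars[pos + k] = str(rng.choice(_NON_G))
            pos += loop
    for guard in (position - 1, end):
        if 0 <= guard < len(chars) and chars[guard] == "G":
            chars[guard] = str(rng.choice(_NON_G))
    if disrupted:
        run = int(rng.integers(4))
        hit = run_starts[run] + g // 2
        chars[hit] = str(rng.choice(np.array(list("AT"))))
    entry = PlantedMotif(
        locus=locus,
        start=position,
        end=end,
        g=g,
        loops=(l1, l2, l3),
        disrupted=disrupted,
        score_intact=score_qgrs(g, (l1, l2, l3)),
    )
    return "".join(chars), entry


@dataclass
class SyntheticDataset:
    params: SimulationParams
    tree: dendropy.Tree  # true phylogeny, rooted, ultrametric, depth 1
    traits: pd.Series  # T_opt per species
    metadata: pd.DataFrame
    rrna: list[NucleotideSequence]
    genomes: Optional[list[NucleotideSequence]]
    alignment: Alignment
    truth: pd.DataFrame  # planted-motif registry
    loci: list[tuple[int, int]]  # shared locus windows (start, end)

    @property
    def species_ids(self) -> list[str]:
        return list(self.metadata["species_id"])

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Emit FASTA / TSV / Newick / manifest files; returns the paths."""
        from .phylo import write_newick

        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "rrna_fasta": os.path.join(outdir, "rrna.fasta"),
            "aligned_fasta": os.path.join(outdir, "rrna_aligned.fasta"),
            "metadata": os.path.join(outdir, "metadata.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "tree": os.path.join(outdir, "tree_true.nwk"),
            "manifest": os.path.join(outdir, "manifest.json"),
        }
        write_fasta(self.rrna, paths["rrna_fasta"])
        write_fasta(self.alignment.records, paths["aligned_fasta"])
        meta = self.metadata.copy()
        meta["rrna_fasta"] = "rrna.fasta"
        if self.genomes is not None:
            paths["genome_fasta"] = os.path.join(outdir, "genomes.fasta")
            write_fasta(self.genomes, paths["genome_fasta"])
            meta["genome_fasta"] = "genomes.fasta"
        meta.to_csv(paths["metadata"], sep="\t", index=False, float_format="%.6g")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_newick(self.tree, paths["tree"])
        manifest = {"seed": self.params.seed, "params": asdict(self.params)}
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return paths


def _target_temperatures(quotas: tuple[int, int, int, int]) -> np.ndarray:
    """Fixed within-group temperature grids for the rank-matched preset."""
    q_psy, q_mes, q_thr, q_hyp = quotas
    parts = []
    if q_psy:
        parts.append(np.linspace(8.0, 18.0, q_psy))
    if q_mes:
        parts.append(np.linspace(22.0, 44.0, q_mes))
    if q_thr:
        parts.append(np.linspace(46.0, 78.0, q_thr))
    if q_hyp:
        parts.append(np.linspace(80.0, 90.0, q_hyp))
    return np.concatenate(parts)


def _locus_slots(seq_length: int, n_loci: int) -> list[int]:
    margin = 50
    usable = seq_length - 2 * margin - _MAX_SPAN
    starts = np.linspace(margin, margin + usable, n_loci)
    return [int(round(s)) for s in starts]


def _evolve_variable(
    tree: dendropy.Tree, n_sites: int, mu: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Evolve the variable site class along the tree: per edge of length b
    each site substitutes with probability 1 - exp(-mu*b) to a uniform base."""
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._vseq = rng.integers(0, 4, n_sites)
        else:
            p = 1.0 - np.exp(-mu * (node.edge.length or 0.0))
            seq = node.parent_node._vseq.copy()
            mask = rng.random(n_sites) < p
            seq[mask] = rng.integers(0, 4, int(mask.sum()))
            node._vseq = seq
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = node._vseq
    return leaf_seqs


def build_dataset(params: SimulationParams) -> SyntheticDataset:
    """Generate a full dataset under ``params`` (tree, traits, sequences,
    planted-motif registry, metadata)."""
    master = np.random.SeedSequence(params.seed)
    s_tree, s_bm, s_misc, s_sites, s_seq = master.spawn(5)

    tree = yule_tree(params.n_species, params.birth_rate, seed=s_tree, depth=1.0)
    raw = simulate_bm(
        tree, params.bm_sigma2, params.bm_root, params.lambda_true, seed=s_bm
    )
    labels = list(raw.index)
    if params.trait_mode == "quantile":
        targets = np.sort(_target_temperatures(params.group_quotas))
        t_opt = np.empty(len(labels))
        t_opt[np.argsort(raw.values, kind="stable")] = targets
        traits = pd.Series(t_opt, index=labels)
    else:
        traits = raw

    misc_rng = np.random.default_rng(s_misc)
    slots = _locus_slots(params.seq_length, params.n_loci)
    child_seeds = s_seq.spawn(len(labels))

    # shared site-class structure plus tree-evolved variable sites, so that
    # pairwise 16S distances reflect the phylogeny without saturating
    L = params.seq_length
    sites_rng = np.random.default_rng(s_sites)
    frac_sp = 1.0 - params.frac_conserved - params.frac_variable
    classes = sites_rng.choice(
        3, size=L, p=[params.frac_conserved, params.frac_variable, frac_sp]
    )
    idx_cons = np.flatnonzero(classes == 0)
    idx_var = np.flatnonzero(classes == 1)
    idx_sp = np.flatnonzero(classes == 2)
    p_gc = params.conserved_gc / 2.0
    p_at = (1.0 - params.conserved_gc) / 2.0
    cons_codes = sites_rng.choice(4, size=len(idx_cons), p=[p_at, p_gc, p_gc, p_at])
    leaf_var = _evolve_variable(tree, len(idx_var), params.subst_rate, sites_rng)

    rrna: list[NucleotideSequence] = []
    genomes: list[NucleotideSequence] = [] if params.make_genomes else None
    truth_rows = []
    meta_rows = []
    for i, sp in enumerate(labels):
        t = float(traits[sp])
        rng = np.random.default_rng(child_seeds[i])
        codes = np.empty(L, dtype=np.int64)
        codes[idx_cons] = cons_codes
        codes[idx_var] = leaf_var[sp]
        # species-specific sites absorb the GC target (codes 1, 2 are C, G)
        fixed_gc = int(np.isin(codes[idx_cons], (1, 2)).sum()) + int(
            np.isin(codes[idx_var], (1, 2)).sum()
        )
        need = params.gc_target(t) * L - fixed_gc
        gc_s = float(np.clip(need / max(len(idx_sp), 1), 0.05, 0.95))
        ps = [(1 - gc_s) / 2, gc_s / 2, gc_s / 2, (1 - gc_s) / 2]
        codes[idx_sp] = rng.choice(4, size=len(idx_sp), p=ps)
        seq = "".join(_BASES[codes])
        p_plant = min(1.0, params.motif_rate(t) / params.n_loci)
        p3 = params.p_three_tetrad(t)
        p_disrupt = params.disruption_rate(t)
        occupied: list[tuple[int, int]] = []
        for locus, start in enumerate(slots):
            if rng.random() >= p_plant:
                continue
            g = 3 if rng.random() < p3 else 2
            loops = tuple(int(x) for x in rng.integers(1, 8, size=3))
            disrupted = rng.random() < p_disrupt
            seq, entry = plant_g4(
                seq, g, loops, start, disrupted, seed=rng, locus=locus,
                occupied=occupied,
            )
            truth_rows.append(
                {
                    "species_id": sp,
                    "locus": entry.locus,
                    "start": entry.start,
                    "end": entry.end,
                    "g": entry.g,
                    "l1": entry.loops[0],
                    "l2": entry.loops[1],
                    "l3": entry.loops[2],
                    "disrupted": entry.disrupted,
                    "score_intact": entry.score_intact,
                }
            )
        record = NucleotideSequence(sp, seq)
        rrna.append(record)
        row = {
            "species_id": sp,
            "t_min": round(t - float(misc_rng.uniform(5.0, 15.0)), 2),
            "t_opt": round(t, 2),
            "t_max": round(t + float(misc_rng.uniform(3.0, 10.0)), 2),
            "group": classify_topt(t),
            "rrna_length": record.length,
            "rrna_gc": gc_content(record),
        }
        if params.make_genomes:
            gc_g = float(
                np.clip(
                    params.genome_gc + params.genome_gc_slope * t, 0.25, 0.75
                )
            )
            genome = generate_sequence(
                params.genome_length, gc_g, seed=rng, seq_id=sp
            )
            genomes.append(genome)
            row["genome_length"] = genome.length
            row["genome_gc"] = gc_content(genome)
        meta_rows.append(row)

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "species_id", "locus", "start", "end", "g", "l1", "l2", "l3",
            "disrupted", "score_intact",
        ],
    )
    alignment = Alignment(
        tuple(AlignedSequence(r.id, r.residues) for r in rrna)
    )
    loci = [(s, s + _MAX_SPAN) for s in slots]
    return SyntheticDataset(
        params=params,
        tree=tree,
        traits=traits,
        metadata=metadata,
        rrna=rrna,
        genomes=genomes,
        alignment=alignment,
        truth=truth,
        loci=loci,
    )
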