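# Methods

This note documents the models and procedures implemented in `g4therm`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Quadruplex detection and scoring

**QGRS enumeration.**  A candidate is any substring matching
`G{g} N{l1} G{g} N{l2} G{g} N{l3} G{g}` with G-group size `g ≥ min_g`
(default 2), loop lengths in `[loop_min, loop_max]` (default 0–36), and
total length ≤ `max_length` (default 30).  Loops may themselves contain G,
so candidates overlap freely; `enumerate_qgrs` emits every distinct
`(start, g, l1, l2, l3)` decomposition and `select_nonoverlapping` reduces
them greedily (highest score, then leftmost, then shortest), a rule chosen
because it is deterministic and independent of input order.

**G-score.**  The public QGRS web tool does not publish its formula, so the
package defines its own:

    score(g, l1, l2, l3) = 21·(g−1) − round(mean pairwise |li−lj|)
                                    − round(mean loop length)

It is strictly increasing in the number of stacked tetrads and penalises
long and uneven loops.  Calibration anchors: a minimal two-tetrad motif
scores 20 and a minimal three-tetrad motif 41, and the stability cut at
score > 25 cleanly separates the classes (a two-tetrad motif can reach at
most 21).  Exact parity with any external tool's scores is *not* claimed;
only the ordering and the class separation are relied on.

**G4Hunter scan.**  Each base in a maximal G-run of length n scores
+min(n, 4); C-runs score −min(n, 4); A/T/N score 0, and N breaks runs (a
conservative choice against false positives).  Sliding windows (default 25
nt, step 1) qualify when |mean| ≥ 1.2 — the published defaults of the
method this scanner follows; overlapping same-sign windows merge into one
region whose mean is recomputed over the merged span (and may then dip
slightly below the window threshold).  Negative regions are C-rich, i.e.
i-motif-prone on the scanned strand; QGRS minus-strand hits are found by
scanning the reverse complement and mapping coordinates back.

## Per-species metrics

Motif frequency is reported per kilobase (`1000·count/length`).  GC content
excludes N from numerator and denominator.  Thermal groups follow the
standard T_opt cuts: < 20 °C psychrophile, [20, 45) mesophile, [45, 80)
thermophile, ≥ 80 °C hyperthermophile.  A region is flagged stable when its
best G-score exceeds 25; the threshold is exposed.  Empty motif lists are
valid observations: count 0, mean/max reported as 0 with an emptiness flag,
rather than an error.

## Phylogenetics

**K2P distance** with transition proportion P and transversion proportion Q
over usable sites: `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`.  Sites with a gap or N
in either sequence are excluded (pairwise deletion, the common choice for
rRNA alignments).  Outside the model's domain the distance is undefined and
the package raises a saturation error rather than silently capping — a
`cap` argument substitutes a fixed maximum when the user prefers that.

**Neighbor joining** is the standard Saitou–Nei agglomeration on
`Q(i,j) = (r−2)·d(i,j) − Rᵢ − Rⱼ`, with ties broken by the smallest matrix
index pair and negative branch-length estimates clamped to zero with the
deficit moved to the sister branch.  Trees are unrooted; midpoint rooting
is provided for display and for building the PGLS covariance.  On additive
matrices the implementation is exact (tested to 1e−9 against a path-sum
oracle).

**Bootstrap.**  Columns are resampled with replacement (default B = 1000);
support of each resolved internal bipartition of the full-data tree is the
fraction of successful replicates containing it.  Replicates hitting K2P
saturation are dropped with a warning and the denominator adjusted.
Zero-length internal edges count as unresolved, so an alignment of
identical sequences yields no supported bipartitions.

## Comparative statistics

**PGLS.**  For rooted tree covariance V (shared root-to-MRCA path lengths)
and Pagel's λ multiplying the off-diagonal entries,

    β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹y,   σ̂² = rᵀV⁻¹r/(n−p),
    logL = −½ [n·ln(2π σ̂²_ml) + ln|V| + n],  σ̂²_ml = rᵀV⁻¹r/n.

In `ml` mode λ maximises the profile likelihood over [0, 1]: a 101-point
grid locates the optimum, then bounded refinement to 1e−6 around the best
bracket.  ML is the default because it is what the widely used comparative
packages default to; fixing λ (e.g. at 1 for pure Brownian motion) is one
argument away.  With λ = 0 on an ultrametric tree the fit reduces exactly
to OLS.  t statistics and two-sided p-values use n − p degrees of freedom.
The model is exposed statsmodels-style: `PGLS(...)` with `.fit()` returning
a `PGLSResults` carrying `params`, `bse`, `tvalues`, `pvalues`, `lambda_`,
`sigma2`, `llf`, `conf_int()` and `summary()`.

**Normality pre-check** uses the D'Agostino–Pearson omnibus test on raw and
log10-transformed values (the latter only for positive data), matching the
workflow of common desktop statistics packages; the ANOVA applies a log10
transform when the check selects "lognormal".  **One-way ANOVA** is the
classical F test; pairwise comparisons use Tukey–Kramer via the studentized
range distribution (adjusted p is never smaller than the raw pairwise p).
All tests are two-sided at α = 0.05.

## Conservation analysis

Column profiles report gap-excluded base frequencies and information
content IC = 2 − H (bits) per alignment column — the numeric content of a
sequence logo; graphics are out of scope.  `map_window` maps
reference-ungapped coordinate windows through alignment columns to every
species; `g4_presence_matrix` rescans each mapped subsequence (± 5 nt
flank, to tolerate small shifts) and records the best G-score or absence.
`disrupting_substitutions` lists mismatches/indels inside a motif footprint,
flags those inside G-runs, and calls the species forming/non-forming by
rescanning for the reference's G-group size.

## The synthetic-data generator

`build_dataset` emulates a prokaryotic thermal-adaptation study:

* **Tree:** pure-birth (Yule) with n leaves, rescaled to unit depth;
  ultrametric by construction.
* **Traits:** Brownian motion with root 45 °C and leaf variance 400
  (σ ≈ 20 °C) under λ_true.  The default preset rank-matches
  the BM draw onto a fixed four-group temperature grid
  (6 psychrophiles / 63 mesophiles / 21 thermophiles / 6 hyperthermophiles
  of 96 species) so that every group comparison is defined at desk scale —
  the monotone mapping preserves the phylogenetic ordering of the trait.
* **Sequences (1.5 kb, 16S-like):** three site classes — a conserved core
  (50% of sites, GC 0.55) shared by all species; variable sites (20%)
  evolved along the tree at 0.3 expected substitutions/site root-to-leaf,
  giving pairwise distances that reflect the phylogeny without saturating
  K2P; and species-specific sites (30%) whose composition absorbs each
  species' GC target `clip(0.50 + 0.0015·T_opt, 0.25, 0.75)`.
* **Planted motifs:** 16 shared locus slots; each is planted with
  probability rate(T_opt)/16 where the expected count rises linearly from 1
  (20 °C) to 8 (85 °C); planted motifs are three-tetrad with logistic
  probability (midpoint 75 °C, scale 6 — concentrating stable G4s in
  hyperthermophiles) and two-tetrad otherwise, with loops drawn from 1–7 nt.
  A disruption (one mid-run G → A/T, guard bases forced non-G so the
  planted G-group size is exactly destroyed) is applied with probability
  decreasing in T_opt (0.5 → 0.05, logistic midpoint 45 °C).
* **Null preset:** constant motif rate (3), tetrad mix (0.3), disruption
  (0.2) and GC (0.55), trait mode plain BM, and — crucially — the
  tree-evolved site class switched off, so sequence-derived metrics are
  i.i.d. across species and the regression null hypothesis holds exactly.
  This is the configuration under which type-I error rates are calibrated;
  with lineage-correlated sites the null would be violated by construction
  (metric covariance outside the BM-λ family) and no α-level test could be
  expected to hold its size.
* **Genomes:** 20 kb i.i.d. sequences at GC 0.50 with zero temperature
  slope — the generator deliberately plants *no* genomic association, so
  the genome-level regressions act as negative controls.

Because all species share locus positions and sequence length, the emitted
"alignment" is the sequences themselves (equal length, gap-free); the
coordinate-mapping code is exercised separately with hand-made gapped
fixtures.  Everything descends from one master seed via spawned child
streams, so a parameter set plus seed reproduces the dataset bit for bit.

**What the generator does not emulate:** rRNA secondary structure,
indels (beyond motif disruption), compositional heterogeneity along the
molecule, non-stationary substitution processes, and realistic genome-scale
organisation.  Passing tests therefore demonstrate that the pipeline
recovers the *kind* of structure the study design posits, at the stated
effect sizes — not that real 16S data carry that structure.

## Problem sizes and numerical choices

Simulation-based checks use problem sizes chosen to give tight Monte-Carlo
error at desk scale: 96 species for the end-to-end preset (×100 seeds), 64
species for estimator calibration (200 recovery replicates, 500 null
seeds), 5000 replicates for BM moment checks.  The λ profile is continuous
on [0, 1]; the grid-plus-refinement optimiser is tested against a dense
10001-point grid.  Cholesky factorisation is used throughout for GLS
solves; non-positive-definite covariances and singular designs raise
errors rather than being regularised silently.  Effect sizes in the
generator (GC slope, motif-rate range, logistic parameters) are choices of
this package, made once to give a clear but not overwhelming signal at
n = 96, and documented above; no field-measured values exist for them.

## Known limitations

* The G-score is a calibrated stand-in, not a reimplementation of any web
  service's unpublished formula; absolute scores should not be compared
  across tools.
* How overlapping candidates should be counted in genome-wide totals is a
  genuine ambiguity; the package reports both all-candidate and
  best-non-overlapping counts and records which was used.
* PGLS assumes the BM-λ covariance family; traits whose covariance decays
  exponentially with phylogenetic distance (e.g. Ornstein–Uhlenbeck-like)
  are outside it, and the ML λ test can be anti-conservative there.
* Bootstrap supports are supports of the NJ/K2P pipeline, not of a
  model-based tree inference.
* Alignments are consumed, never computed; upstream alignment quality is
  the caller's responsibility.
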