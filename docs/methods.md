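# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `rootecon`, in the spirit of a statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chamber flux

A root sample sealed in a chamber of volume `V` (default 19 ml) raises the
CO₂ molar fraction approximately linearly. The flux is
`F = P·V/(R·T) · dC/dt` with `P` in kPa (default 101.325), `T` in K
(default 301.15 = 28 °C), `R = 8.31446 L kPa K⁻¹ mol⁻¹`, and `dC/dt` the
OLS slope of the water-corrected CO₂ molar fraction (µmol mol⁻¹ s⁻¹) over
the inclusive 20–90 s window; `V` is in litres inside the formula and is
corrected by subtracting the measured root volume. The first 20 s (dead
band) are discarded because the chamber equilibrates after closure; the
synthetic generator models that transient as an additive exponential decay
(amplitude 3 µmol mol⁻¹, half-life 6 s by default — configurable, since the
physical transient shape is instrument-dependent) which has decayed to
< 0.35 µmol mol⁻¹ by 20 s. Window endpoints are inclusive. Negative fluxes
are retained and flagged rather than clipped: clipping would bias batch
statistics, and negative estimates are diagnostically useful.

Pressure and temperature are treated as per-run constants from the chamber
config; a per-sample `pressure_kPa` column in the volume table overrides
the pressure where it was logged per sample. Whether the instrument logs
them per reading is left open deliberately.

## Trait derivation

The 0.3 mm diameter threshold separates axial (> 0.3 mm) from lateral
(≤ 0.3 mm) tissue. Units follow the conventions of the field: SRL in
m g⁻¹ (length converted mm → m), SRR_L in nmol s⁻¹ m⁻¹, SRR_M in
nmol s⁻¹ g⁻¹, RMF stored in percent, RTD in g cm⁻³ (volume mm³ → cm³),
BF in branch points per mm total length, BD in tips per cm axial length.
Samples with non-positive denominators (root mass, axial length, total
length or volume) are rejected with a reason, not silently dropped; no
other outlier policy is applied. Fold variation (max/min, one decimal) is
computed on genotype means; whether panel extremes should instead be taken
over individual plants is ambiguous, and genotype means were chosen as the
level at which panel statistics are reported — plant-level summaries remain
available by passing the plant table to `summarize`.

## Respiration partitioning

Total respiration is the **response**, tissue-class volumes are the
predictors: `TRR ~ ARV + (LRV − tipV) + tipV`, with an intercept. The
intercept is included so that the residual trait SRR_R has mean zero on
the fitting set and is orthogonal to the predictors — properties the
downstream heritability analysis of SRR_R relies on. Lateral tip count is
`max(tips − 4, 0)` (four seminal roots assumed per seedling; configurable)
and each tip is assigned 0.01 mm³. Negative lateral-axis volumes are
clamped to zero and counted; clamping is absent on well-formed data.
Stepwise selection minimises `AIC = n·ln(RSS/n) + 2k` bidirectionally from
the full model; this differs from the Gaussian-likelihood AIC only by a
model-independent constant, so selections agree.

SRR_R is computed per plant and then averaged to genotype level, keeping
the residual definition aligned with the plant-level measurement error
structure.

## Heritability

Plant-level values from the randomized complete block design are fit with
block as a fixed effect and genotype as a random effect. The REML profile
in the variance ratio λ = σ²_g/σ²_e is computed in closed form via the
Woodbury identity (only genotype-indexed aggregates are needed) and
minimised by bounded Brent search over log₁₀λ ∈ [−5, 5], with the λ → 0
boundary checked explicitly; variances are therefore non-negative by
construction. On balanced data this equals the ANOVA estimator
(MS_genotype − MS_error)/r truncated at zero, which the tests use as an
independent oracle. H² = σ²_g/(σ²_g + σ²_e/r) with r the number of blocks.

## Association scans

Genotype means are scanned under `y = µ + xβ + u + e`,
`u ~ N(0, σ²_g K)`, with K the centered relatedness matrix
`K = WWᵀ/p` (mean-imputed, column-centred dosages). K is eigendecomposed
once; the variance ratio is REML-estimated under the no-marker null and
reused across markers, while the residual scale is re-estimated per marker
(EMMAX-style). An exact mode re-optimises the ratio per marker; at panel
scale the two differ negligibly (tested), and the approximation makes a
25-trait × 16k-marker scan interactive. Effects are tested by Wald χ²₁.
Missing dosages are mean-imputed per marker; MAF is computed on non-missing
calls; QC drops markers with missingness > 50% or MAF < 5% (both strict,
so a marker exactly at 5% survives).

The multivariate scan stacks d traits with covariance
`V_g⊗K + V_e⊗I`. In the eigenbasis of K the rows decouple, and (V_g, V_e)
are estimated under the null by EM-REML followed by a quasi-Newton polish
of the exact REML criterion in Cholesky coordinates — EM alone converges
sublinearly when a component sits near its boundary. Traits are
standardized internally (the Wald statistic is scale-invariant; effects
are transformed back) and ordered canonically so results are exactly
invariant to the caller's column order. Per marker, the d-vector of
effects is estimated by GLS under the null covariance with a scalar
per-marker rescale, and tested by Wald χ²_d; at d = 1 this reduces exactly
to the univariate scan. Near-singular V_e (e.g. duplicated traits) is
floored to the PSD cone with a warning. Reusing the null covariance is
slightly conservative for very strong signals (the null fit absorbs part
of the marker effect into the diagonal), which is the standard trade-off
of this family of approximations.

Significance uses two flags: the raw −log₁₀ p ≥ 3.5 threshold (inclusive)
and Benjamini–Hochberg step-up FDR at q = 0.05 applied within each scan.
BH was chosen as the canonical step-up FDR procedure. Candidate-gene
lookup takes genes overlapping ±250 kb of a marker (inclusive boundaries,
window clipped at zero; annotation coordinates are 1-based inclusive).

## Trait networks and PCA

PCA uses SVD on centred, unit-scaled columns — the 25 traits carry
incommensurate units, so correlation-matrix PCA is the defensible default
(a no-scale flag exists). Explained variance is the eigenvalue share;
trait contributions are 100·loading² (unit eigenvectors), so each
component's contributions sum to 100. Component signs are fixed by making
the largest-magnitude loading positive.

The Gaussian graphical model inverts the trait correlation matrix:
`pcor_ij = −P_ij/√(P_ii·P_jj)`. Because derived traits are partly exact
linear combinations (TDW = SDW + RDW), the matrix can be numerically
singular; an escalating ridge (10⁻¹⁰ … 10⁻⁴, gated on the eigenvalue
spectrum, logged) is applied, and failure names the most collinear pair.
By default the network excludes volumes, surface areas and the two
lateral:axial ratios (17 traits remain), which removes the worst
collinearity. Centrality is computed on the unweighted thresholded graph
(|pcor| ≥ 0.15): outdegree is the retained-edge count and betweenness is
pair-count Brandes betweenness (fractional over tied shortest paths) —
count-based definitions, matching the interpretation of a trait "bridging"
others.

## Synthetic study generator

The generator defines the study conditions: 276 genotypes × 4 blocks
(1104 plants) by default, 91 chamber readings at 1 Hz, markers spread over
21 chromosomes with uniform MAF in [0.05, 0.5], i.i.d. missingness
(default 2%), Hardy–Weinberg dosages, and optional two-population
Balding–Nichols structure (Fst parameter) to exercise kinship correction.
Trait simulation plants polygenic values (optionally correlated across
traits), per-block shifts, marker effects and i.i.d. per-plant residuals —
the within-genotype error structure beyond the block design is unknown, so
i.i.d. residuals are the parsimonious choice.

Root systems are built from allometric draws anchored to typical
wheat-seedling magnitudes (axial length ≈ 1456 mm at diameter ≈ 0.46 mm,
lateral length ≈ 2670 mm at ≈ 0.20 mm, ≈ 400 tips), with cylinder geometry
giving volumes and surface areas. True respiration follows the tissue
model with default volume-specific rates in the ratio
tip : lateral-axis : axial = 30.5 : 8.1-fold-below-tip : 1, scaled so mean
TRR ≈ 0.54 nmol s⁻¹.

Two noise regimes are used deliberately. The **end-to-end fixture** adds a
biological residual (0.06 nmol s⁻¹) plus a heritable metabolic offset
(genetic SD 0.03, giving SRR_R a planted H² of 0.5), emulating a panel
where architecture explains only part of respiration. The dedicated
**slope-recovery check** uses measurement-level noise (0.02 nmol s⁻¹,
about 4% of mean TRR): with panel-realistic biological noise the 15%
ratio-recovery bound is unattainable at any feasible n, so that bound is
read as a statement about the estimator under measurement noise, not about
biological scatter. The fixture plants one QTL per latent driver (size,
lateral allocation, tissue density, metabolic offset), each explaining 25%
of its driver's variance at MAF ≈ 0.45, strong enough that a 276-genotype
scan detects it reliably.

What the generator does **not** emulate: linkage disequilibrium decay
(marker positions are independent draws), dominance or epistasis,
genotype-by-block interaction, spatially correlated chamber drift, and
image-analysis artefacts. Passing tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to those
real-data features.

## Problem sizes and determinism

Test and acceptance simulations run at the scale the models are meant
for — 276 × 4 plants and 2000–6000 markers for calibration/power, 1000
root systems for partition recovery, one full panel-scale pipeline run —
sizes at which the whole acceptance script completes in about a minute on
one CPU. All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical seed and config give bit-identical
outputs, and the pipeline itself consumes no randomness, so a rerun
produces a byte-identical summary.

## Known limitations

- Variance-component estimates at the λ search boundary (H² near 0 or 1)
  are truncated, so H² estimates are mildly biased toward the interior for
  extreme traits.
- The EMMAX-style reuse of null variance components understates very
  strong signals slightly (documented above); the exact mode exists but is
  O(markers) slower.
- The GGM is unregularized by design (ridge jitter is a numerical guard,
  not an estimator); for trait sets approaching the sample size a
  graphical-lasso approach would be preferable.
- Candidate-window lookup is purely positional; it does not rank genes by
  function.
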