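# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `metaphen`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Indirect calorimetry

**Weir equation.** Energy expenditure is computed as
EE = 1.44·(3.94·VO₂ + 1.11·VCO₂) kcal/day with VO₂/VCO₂ in mL/min. The
source literature also circulates an unscaled shorthand
(EE = 3.9·VO₂ + 1.11·VCO₂); the 1.44-scaled form with the 3.94 coefficient
is the complete day-rate equation and is what this package implements. The
function is linear and homogeneous, so the mean of per-sample EE equals the
EE of the mean gas rates — either computation order is valid and this
identity is asserted in tests to ≤1e−10 relative.

**Periods and windows.** Human sessions contain rest, cognitive-challenge
and glucose-challenge periods. Each period's first 5 minutes are excluded as
a steady-state buffer; periods are half-open `[start, end)` and the sample
at exactly `start + 300 s` is retained. REE and RER are time-weighted
(trapezoid) means over the windowed rest period, which reduces to the
midpoint value under a linear drift and tolerates the irregular sampling of
breath-by-breath carts; a simple mean is available by flag.

**AUC contrasts.** CEE and TEF are raw AUC differences (challenge minus
rest). The kcal/day signal is integrated over minutes and divided by
1440 min/day, so the AUC of a constant 1440 kcal/day over 25 min is 25 and
the unit is numerically kcal. If windowed durations differ, both periods are
rescaled to per-minute means times the shorter duration before differencing,
so unequal lengths cannot masquerade as an effect. Incremental AUC subtracts
a baseline before integrating; the default baseline is the subject's own
windowed REE, the standard choice where the definition is otherwise
underdetermined, and it is an explicit argument.

**Mouse cage analysis.** Samples are binned into 30-min interval means, then
averaged within light cycles per diet phase. Only light cycles enter the
headline summaries (activity and feeding confound the dark cycle); dark-cycle
rows are retained in the output. Mouse rates arrive in mL/h (cage
convention) and are converted to the canonical mL/min on read. Body mass is
*not* divided out of EE; mass is handled by ANCOVA (`EE ~ group + mass`)
with a group×mass interaction term testing slope homogeneity. Diet deltas
are per-animal paired differences with a one-sided test of increase per
genotype and measure; measures are tested without cross-measure multiplicity
correction (a BH helper exists).

## Extracellular flux

Segments are the cycles strictly after each injection up to the next; the
baseline is the pre-injection cycles. All metrics depend only on segment
membership, never on cycle timing. The glycolysis stress test follows the
standard definitions (glycolysis = post-glucose − baseline; capacity =
post-oligomycin − baseline; reserve = capacity − glycolysis, an identity by
construction). A negative post-2-DG mean is floored at zero with a warning
(instrument drift); it does not enter the metrics.

For the fuel-flex assay, dependency is
(baseline − target-first)/(baseline − all-inhibitors)·100. The literal
reciprocal form of capacity, `1/ratio·100`, is unbounded and breaks the
flexibility = capacity − dependency semantics, so the default is the
bounded vendor convention `(1 − (baseline − other-two)/(baseline −
all))·100`; `as_printed=True` gives the literal reciprocal. Wells are the
statistical unit (no plate-level nesting), matching the n≈24-well designs
these assays report.

## Isotope tracing

The natural-abundance correction is carbon-only: a molecule with j
tracer-labeled carbons gains i−j mass units with probability
C(n−j, i−j)·p^(i−j)·(1−p)^(n−i), giving a lower-triangular column-stochastic
matrix M with measured = M·true. The system is solved by forward
substitution; small negative components (|x| ≤ 1e−6) are clamped and the
vector renormalized, larger negatives additionally raise a data-quality
warning. p defaults to 0.0107 (natural ¹³C abundance) and is configurable;
the correction is exactly inverse to the forward convolution (property-tested
to ≤1e−8 on random simplex MIDs up to 6 carbons). Si and other
derivatization isotopes are not modelled; `nat_abund_matrix` is the hook for
a full element matrix. Fractional enrichment Σ(i/n)·fᵢ is emitted from
corrected fractions; uncorrected fractions remain available via
`normalize_mid` since some workflows report pre-correction enrichment.
Panel enrichment (e.g. "all detected TCA intermediates") takes the panel as
a configuration list and averages detected members only.

## Plasma metabolomics

The presence filter keeps metabolites measurable in strictly more than 75 %
of samples. Imputation never touches observed cells: `half-min` fills with
half the observed minimum; `knn` uses k-nearest neighbours; `rf` is
iterative chained prediction with extremely-randomized trees, seeded and
capped at 10 rounds. Abundances are natural-log transformed before testing
(half-minimum offset applied only to zeros; toggleable). Two-group designs
use Welch's t; pre/post uses a paired t within subjects; the group×time
design tests the group contrast on per-subject post−pre differences. BH
q-values control FDR at 0.05. Set enrichment is a one-sided hypergeometric
over-representation test over the measured background, excluding sets with
fewer than 3 measured members, BH-adjusted across sets — a deliberate
substitution for topology-weighted pathway-impact scoring, which needs
pathway-graph databases outside this package's scope. Whether the volcano
effect axis should be a difference or a fold change is left to the reader:
both `effect` (log-scale mean difference) and `log2_fold_change` are
emitted.

## Single-cell QC

Cells are discarded when total UMIs are below 50, above 50 000, or the
mitochondrial fraction exceeds 30 % — boundaries retained, matching the
wording of the rules ("less than", "greater than", "more than"). The filter
is idempotent and rule order cannot change the surviving set. Cluster
pruning removes clusters only when both conditions hold: fewer than 250
cells *and* positive marker expression of at least two cell types. A marker
is "positive" in a cluster when its mean counts-per-10k expression exceeds
0.25× the maximum cluster mean for that marker (threshold configurable; the
source rule gives no number), and a type is positive when a majority of its
detected markers are. Positivity and annotation use linear counts-per-10k —
log1p compresses the marker/off-marker contrast and would defeat a relative
threshold — while gene-set scoring and differential expression use
counts-per-10k + log1p, which preserves within-gene cell ranking.
Clustering and embeddings are consumed, not computed: labels arrive with the
matrix. DE is a two-sided Wilcoxon rank-sum per gene with BH correction.

## Synthetic-data generators

The generators define the study conditions; their defaults are fixed, not
tuned. All randomness flows through one `numpy.random.default_rng(seed)`
per call, so identical config + seed gives identical output, and every
generator returns the ground-truth parameters needed to score downstream
recovery.

* **Human cohort** — strata are genotype-group × sex × age-band. Default
  stratum REE 1450 kcal/day; the study-scale configuration used by the
  acceptance script plants a −150 kcal/day shift in young female carriers
  across 61 non-carriers / 33 carriers (stratum sizes 33/11/13/4 and
  20/7/5/1). The post-glucose response rises linearly inside the 5-min
  steady-state buffer and plateaus at (1 + tef_gain) on VCO₂ with the VO₂
  rise reduced by `vo2_blunt` in female carriers, so windowed means sit
  exactly on the plateau and TEF/CEE have closed-form truths. Only
  period-level means and AUC contrasts are contractual; the within-period
  response shape is a modelling convenience. Measurement noise is additive
  Gaussian on VO₂/VCO₂ (default 0; 10 mL/min in the recovery runs);
  between-subject REE spread is a separate knob (100 kcal/day in recovery
  runs). Within-subject cart variance is a synthetic choice, not an estimate
  of any instrument.
* **Mouse cages** — 12-h light/dark cycles over a chow phase and an HCD
  phase (2 days each at 30-min sampling), mL/h rates, dark-cycle multiplier
  1.25. Genotype light-cycle VO₂ means 95/85 mL/h; HCD fractional gains are
  per-genotype, with the carrier VO₂ gain set to 0 to model the failed
  oxygen-consumption response. Cohort sizes 13/20 in recovery runs.
* **Flux plates** — per-group baselines with per-injection multipliers,
  3 cycles per segment, 24 wells per group, additive Gaussian noise.
* **Labeling experiments** — raw intensities are the true MID convolved with
  binomial natural abundance, times a random log-normal scale, times
  multiplicative log-normal noise of the configured CV. Group contrasts are
  planted as per-group true MIDs (default: lactate m+3 0.40 vs 0.50).
* **Plasma tables** — log-normal abundances with additive log effects for
  group (default: lactate +0.5) and timepoint (default: glucose +0.4 post
  drink), n = 30/group, Bernoulli missingness, and a per-sample instrument
  gain that multiplies metabolites and the internal standard alike so
  standard-normalization cancels it exactly.
* **Count matrices** — multinomial expression programs per cell type over
  marker, background and mitochondrial genes (5 % mito mass), negative-
  binomial UMI totals clipped to a QC-safe band so clean cells cannot
  straddle the thresholds; planted low-UMI (5–49), high-UMI (50 001–60 000)
  and high-mito (50 % mito mass) failures, plus doublets mixing the first
  two types' programs in a dedicated small cluster.

## What passing tests do and do not show

The generators produce regular sampling, stationary plateaus, Gaussian or
log-normal noise and exactly known effects. Passing recovery tests shows the
estimators are correctly implemented and unbiased under these conditions; it
does not validate behaviour under real-world artifacts (mask leaks, breath
dropouts, chromatographic drift, ambient-CO₂ swings, doublet rates varying
by depth), which the non-goals exclude.

## Problem sizes and numerics

The acceptance script simulates the cohorts at the study's sample sizes
(94 humans, 33 mice), 1000 random MIDs for the correction round-trip,
200 plasma simulations for the lactate top-hit rate and 1000 null
replicates for type-I calibration — sizes chosen so a full run completes in
well under a minute of CPU while keeping Monte-Carlo error small relative to
the 2-SE recovery bands. Trapezoid integration uses actual timestamps; AUC
convergence under grid refinement is second-order on smooth signals.
Ill-conditioning of the correction matrix is only possible as p→1 and is
guarded explicitly. Statistical helpers raise on degenerate designs
(singular ANCOVA, constant ages, single-well groups) rather than returning
NaN.
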