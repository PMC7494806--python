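# Methods

## Experimental model

The package models a two-treatment priming experiment on a panel of
accessions. Non-primed plants are fully irrigated from transplanting to
harvest; primed plants are fully irrigated until flowering onset and then
undergo a sequence of total water restrictions of increasing length, each
followed by a fully irrigated recovery. The default schedule starts at 46
days after transplanting (DAT) with restrictions of 8, 11 and 14 days and
14-day recoveries, so the second restriction begins at 68 DAT, composite
leaf samples fall at the recovery ends (68, 93, 121 DAT) and harvest is at
121 DAT. All timestamps are integer DAT; no calendar dates are used. The
design defaults are 59 accessions × 2 treatments × 4 replicate plants, with
17 SPAD occasions, 14 leaf-temperature events and 3 isotope occasions per
treatment.

## Trait extraction

**Senescence slope (S).** Ordinary least squares of SPAD value against DAT,
restricted to the window from the plant's maximum reading (earliest
occurrence on ties — the choice that maximises the fitting window and is
deterministic) to the last reading. At least three points are required;
otherwise the plant is flagged `insufficient_post_peak_points` and excluded
from the replicate mean with the count decremented. A perfectly flat window
returns a slope of exactly 0.

**FA_max and dT_min.** Per-plant maximum foliar area and per-plant minimum
leaf-minus-air temperature, then the replicate mean — statistic first,
average second, so one exceptional plant is not diluted before the extremum
is taken. Leaf temperature events are matched to the concurrent air-logger
record by DAT; unmatched events are flagged `no_air_match` and dropped.
Foliar-area readings above 1 537.3 cm² are logged as soft validation
warnings, never rejected.

**Δ_max.** Discrimination Δ = (δₐ − δₚ)/(1 + δₚ/1000) with δₐ = −8 ‰ and
both δ values in per-mil; the /1000 in the denominator converts the tissue
signature to fractional form, which is the only dimensionally consistent
reading of the formula. Because leaf samples are composited across plants,
Δ is computed per accession × treatment: Δ per sample, mean per occasion,
maximum over occasions. δₚ ≤ −1000 ‰ is a domain error.

Missing values always carry reason codes and propagate as flagged NA;
nothing is silently imputed as zero.

## Memory indices and occurrence

STM_S is the slope difference (primed − non-primed); STM_FA, STM_dT and
STM_Δ are primed/non-primed ratios. The dT ratio is defined only when both
minima are negative: with one operand at or above zero the ratio's
direction flips and a ">1 means stronger cooling" reading would be
misleading, so such accessions get `sign_mismatch` /
`nonnegative_operand` flags and count as non-occurrence. Occurrence uses
strict inequalities (STM_S > 0, ratios > 1) with no tolerance; exact
equality is non-occurrence. Occurrence percentages divide by the full
panel by default, counting undefined indices as non-occurrence; a
`defined`-only denominator is available as a config switch and the policy
in force is logged.

## Tolerance scoring

SSI and GMP are computed from accession-mean biomass; the population
normaliser of SSI is the mean over accession means. Negative SSI (an
accession that gained biomass under priming while the population lost) is
valid and ranks as most resilient. The 1–10 score conversion is
deterministic decile ranking: units sorted by tolerance (SSI inverted, GMP
direct, ties broken by accession id), score = 1 + ⌊10·(rank−1)/n⌋. In
replicate mode the indices are computed per paired replicate (primed
replicate *j* against non-primed replicate *j*), scored per replicate slot
across the population, and averaged — with four replicates the scores move
in quarter steps. One population normaliser (from accession means) is used
for all replicate slots. Replicate pairs or accessions whose non-primed
biomass is zero cannot form a susceptibility ratio and are dropped with a
logged count. An all-equal index population is refused
(`degenerate_population`) rather than scored arbitrarily. Fernandez groups
compare RCI and PCI against their population medians: A both high, B only
PCI, C only RCI, D neither.

## Multivariate structure

The feature matrix holds the four memory indices plus RCI and PCI; rows
with any undefined cell are excluded listwise with a logged count.
Correlations are Pearson r with two-sided t-distribution p-values (stars at
0.05 / 0.01). PCA is an eigen-decomposition of the correlation matrix of
z-standardized variables (so eigenvalues sum to the number of variables);
components are sign-fixed so each component's largest-magnitude loading is
positive. Ward clustering runs on the scores of the leading components
covering ≥ 70 % of total variance (configurable; clustering on raw
standardized features is a switch), cut at k = 3 by default with k
user-settable. Cluster ids are renumbered by descending cluster-mean PCI
then RCI so labels are stable under row permutations, and each cluster gets
a Fernandez label from its mean scores against the population medians.
Cluster summaries report mean ± standard error (sd/√n, undefined for
singletons) of all features plus primed/non-primed biomass and the fraction
of members with Δ-memory occurrence.

## Synthetic data generator

The generator emulates the design above with accession-level memory effects
drawn once per accession: additive on the senescence slope, multiplicative
on FA_max, dT_min and Δ_max. Trajectory shapes are the simplest forms that
make the downstream summary statistics well defined:

* **SPAD** rises logistically to the accession peak exactly at flowering
  onset (an observation event is forced onto that day) and declines
  linearly at the accession × treatment slope. The primed slope is the
  non-primed slope plus the memory effect, truncated to stay a decline
  (≤ −0.02 SPAD/day) — a rising post-peak trajectory would leave "peak to
  harvest" undefined; the truncated value is what ground truth records.
* **Foliar area** grows logistically toward the treatment maximum, with a
  30 % proportional dip at events falling inside a primed restriction
  window; the series maximum is attained at the final (recovery) event, so
  the treatment ratio of estimated maxima equals the true ratio.
* **dT** follows a Gaussian-bell seasonal curve whose minimum falls at the
  end of the last restriction (an event is forced there), scaled per
  treatment; air temperature is drawn once per event and shared across all
  plants, mirroring shared greenhouse loggers.
* **δ¹³C** occasion means are scaled per treatment and inverted through the
  discrimination formula to tissue signatures; two composite samples per
  accession × treatment × occasion.
* **Biomass** is lognormal across accessions (strictly positive — a panel
  with near-zero control plants would produce unbounded susceptibility
  indices, outside any realistic screening population), with a fractional
  primed reduction per accession.

Default population parameters: SPAD peak 45 ± 3, non-primed slope
−0.25 ± 0.08 SPAD/day, memory effect on S 0.12 ± 0.12 SPAD/day, FA_max
700 ± 250 cm², FA ratio 0.93 ± 0.10, dT_min −8 ± 2 °C, dT ratio
0.94 ± 0.11, tissue δ¹³C −28 ± 1 ‰, Δ ratio 1.00 ± 0.03, biomass
30 ± 12 g with 30 ± 15 % primed reduction. The memory-effect distributions
were chosen so the expected occurrence rates match a panel in which
senescence memory is nearly universal (~84 % > 0), discrimination memory
splits the panel (~50 %), and foliar-area/thermoregulation memory is the
exception (~24 % / ~29 %). Measurement noise defaults: 1.5 SPAD, 30 cm²,
0.5 °C, 0.15 ‰, 3 g.

**What the generator does not emulate.** Replicates within an accession ×
treatment share one biological trajectory and differ only through
measurement noise — there is no plant-level biological variation, no
spatial/greenhouse block structure, no missing-at-random dropout, and no
correlation between memory effects across traits. Passing recovery tests
therefore demonstrate that the estimators invert the generative model, not
that they are robust to every feature of real phenotyping data. The
flowering-onset staggering of real panels is collapsed to a single start
day: all indices are summaries relative to the plant's own trajectory, so
they remain comparable across start dates.

## Numerical choices and verification

With all noise standard deviations at zero the pipeline reproduces every
ground-truth index to machine precision (no rounding is applied to
in-memory tables; CSV serialisation round-trips full precision). Parameter
recovery under noise is checked two ways: estimation error must be
non-decreasing in the noise level (a grid of noise multipliers, MAE
averaged over 20 seeds), and the default-noise MAE over 20 panels must stay
within 1.5× the MAE of an independent Monte-Carlo oracle that perturbs the
generator's noiseless trajectories and recomputes the indices directly with
numpy primitives. Problem sizes in the test suite (10–59 accessions, 20
seeds) keep the full suite under a minute while leaving the Monte-Carlo
comparisons well resolved.

Determinism: one `numpy` Generator seeded from the config drives every
draw, so identical configs give byte-identical output files; analysis is
deterministic given its inputs (ties in scoring broken by accession id,
cluster labels renumbered by cluster-mean scores).

## Known limitations

* The decile construction of RCI/PCI is this package's documented choice of
  score-values method; other binnings (equal-width, jenks) would shift
  scores for skewed index distributions.
* The squared correlation between raw indices and their decile scores on
  default synthetic panels is typically 0.89–0.97; rank-based scores track
  skewed raw indices imperfectly by construction.
* The dT ratio guard discards information when exactly one treatment fails
  to cool below air temperature; an additive dT contrast would avoid the
  guard but is not the ratio convention implemented here.
* Listwise deletion for multivariate analysis is simple and logged, but
  biased if missingness correlates with the traits; no imputation is
  provided.
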