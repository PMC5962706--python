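# Methods

## Setting

A pan-pathogen two-channel microarray experiment yields, per probe and
sample, a green signal g (Cy3, sample material) and a red signal r (Cy5,
co-hybridized human reference DNA). Probes map to organism-level
"signatures" — viral families or bacterial/fungal/parasitic genera — with
several probes per organism, plus a set of human reference probes. The
analysis contrasts each case group against a common control group and asks
which organisms are detected significantly and prevalently in cases but not
controls.

## Normalization

The per-array scale factor is the ratio of summed green to summed red
human-probe signals, `sf = Σ g_h / Σ r_h`, computed independently for every
hybridization. Two normalizations of the microbial probes are implemented:

- **literal** (default): `N = log2 g − sf · log2 r`. This is the exactly
  printed form of the formula the pipeline follows; it multiplies the log
  red signal by sf.
- **ratio**: `N = log2 g − log2(sf · r)`, i.e. `log2(g/(sf·r))`, which
  treats sf as a correction of the red channel itself.

The two coincide exactly when sf = 1 and the test suite pins both to hand
oracles. Which reading the original analyses of such arrays intended is not
decidable from their descriptions, so both are kept behind
`normalization.mode`, with the literal form as default because it is the
only explicitly printed expression. A consequence of the literal form worth
knowing: deviations of sf from 1 shift *all* of a sample's normalized
signals by `(sf − 1)·log2 r`, so sf noise is amplified by the magnitude of
the red signal (~6 log2 units at the default background). With hundreds of
human probes sf is tight and the shift is small; with very few human probes
the per-sample offsets it induces dominate the microbial noise. The
generator's default of 100 human probes keeps the relative SD of sf below
~4%.

Non-positive raw signals (scanner exports can contain zeros) are floored at
a configurable ε = 1.0 fluorescence unit before any log2, with a logged
warning. Human probes are excluded from all statistics after sf is
computed.

## Detection and the joint filter

Per case group vs controls, each microbial probe gets a one-sided
two-sample t-test (case > control) on N. Welch's unequal-variance form is
the default (a pooled-variance option exists): the sidedness is fixed by
the detection question, and Welch is the safer default when case and
control dispersions differ. Probes constant in both groups with equal means
get t = 0, p = 0.5 by convention; constant with different means, an
infinite t in the direction of the difference with a logged warning.

P-values are Benjamini–Hochberg adjusted *within* one case-group-vs-control
comparison (each cancer type is analysed against the controls separately,
so the multiplicity unit is the comparison, not the union of all four).
The step-up is implemented directly (sort, q_i = p_i·m/i, enforce
monotonicity from the largest rank, cap at 1) and is cross-checked against
statsmodels and an O(m²) brute force.

Prevalence needs a per-sample detection rule that array descriptions leave
implicit; this package's rule is declared: probe detected in sample s iff
`N[probe, s] − mean(N[probe, controls]) ≥ presence_delta`, default 1 log2
unit, mirroring the probe-level log2FC ≥ 1 cut-off at sample level. Control
samples are called against the same baseline. Organism prevalence within a
group is, by default, the **union** rule — the percentage of group samples
in which at least one of the organism's probes is detected, i.e. the size
of the union of the probes' detected-sample sets. The phrase "maximum
number of samples that contained even one of the probes" also admits a
**max-over-probes** reading (best single probe's detected count); both are
implemented, selectable by `detection.prevalence_rule`.

The joint filter reports an organism iff it has ≥ 1 probe with log2FC ≥ 1
and adjusted p ≤ 0.01, case prevalence ≥ 40% and control prevalence ≤ 25%.
The adj-p ≤ 0.01 default follows the stricter of the two thresholds that
circulate for this kind of screen (0.01 in methods descriptions, 0.05 in
results prose); both are plain config knobs.

## Aggregation, shares, Venn partition

A reported organism's signal is the mean over its significant probes of the
per-probe mean over the group's samples. Percent-of-total-signal shares are
computed within one (cancer type, organism class) cell: `100·m_i/Σm_j`.
Normalized means can be negative; when a cell contains a negative mean, all
means in the cell are shifted up by the cell minimum before the share is
taken (logged) — percent-of-total presumes non-negative totals and no
convention is stated for this case, so the uniform shift is this package's
choice. The cross-type Venn partition assigns each organism to the exact
subset of cancer types reporting it; cells are disjoint and cover the
union by construction, property-tested against brute-force membership.

## Clustering

Samples are clustered on the samples × organisms matrix of per-sample mean
significant-probe signal (matching the organism-level heatmaps such screens
publish; a probe-level matrix can be passed just as well), with Euclidean
distance, complete linkage, and no standardization. scipy's agglomeration
is used; it is deterministic, and its merge heights are verified against a
naive O(n³) agglomeration oracle on random instances (with continuous data,
exact distance ties — where scipy's tie order could differ from a
smallest-index rule — occur with probability zero).

The cluster count is chosen by maximizing the Calinski–Harabasz index
`CH(k) = [B/(k−1)]/[W/(n−k)]` over cuts of the same tree, k from 2 to
min(10, n−1) by default, smallest k on ties; W = 0 (duplicate-point
clusters) returns a +∞ sentinel with a warning. One structural caveat
found while validating the selector: for effectively one-dimensional
profiles with extremely tight clusters, splitting a cluster into m slices
divides its within-scatter by ~m², so CH keeps rising with k and the
selector saturates at the top of the k range. With profiles of ≥ 2
informative dimensions and separations around 10–15 within-cluster SDs —
the regime the recovery studies use (3-D blobs, unit SD, centers 15
apart) — the planted count is recovered essentially always. Cluster pairs
are contrasted per organism with two-sided Welch t-tests by default (the
sidedness of published cluster contrasts is unstated; one-sided is a flag),
`logFC = mean_a − mean_b`; swapping clusters negates both.

## Outcome association

Within one cancer type, samples with known outcome are split into deceased
and alive; each reported organism's aggregated signal is tested with
one-sided Welch t-tests in both directions, unknown outcomes excluded
listwise. Nominal p-values are the primary report (matching how such
outcome tables are printed), with a BH-adjusted column for completeness;
organisms with p ≥ 0.05 are retained and flagged "trend" rather than
dropped. `logFC = mean(deceased) − mean(alive)` regardless of direction.
Per cluster, alive/deceased/unknown counts and the deceased percentage of
known outcomes are tabulated (NaN when a cluster has no known outcomes).

## Synthetic-data generator

The generator emulates the screen the pipeline targets: default group
sizes 50 (BRER), 34 (BRHR), 24 (BRTP), 40 (BRTN) cases plus 20 controls;
100 human probes bright in both channels (log2 mean 14); microbial probes
at a cross-hybridization background (log2 mean 6) in both channels; 5
probes per organism; 20 decoy organisms with no planted effect so
specificity is measurable. Signals are log-normal: raw =
`2^(mean + Normal(0, σ))` independently per probe, sample and channel.
Planted signatures add `effect_log2` to the green-channel mean of their
probes in carrier samples only; the red channel is the common human
reference and never carries a planted effect. Carriers are chosen as
exactly `round(frac × group size)` samples by seeded permutation, so
realized prevalences are exact and the prevalence filters are exactly
testable. Outcomes (deceased/alive) are assigned by seeded permutation
within each case group, independent of signals; controls are unknown.

The per-channel noise SD defaults to σ = 0.35, which puts the normalized
signal's SD at `√2·0.35 ≈ 0.5` — the scale on which every downstream
statistic operates. This value is chosen so that the presence-call rule
(1 log2 unit over the control mean) has a per-probe control
false-detection rate of ~2%, i.e. a regime where the 25%-control-prevalence
filter is informative rather than saturated; at σ_N ≈ 0.7 the union of five
probes' ~8% false detections already pushes expected control prevalence
above the filter, and detection of anything becomes impossible by
construction.

What the generator does **not** model: probe-sequence effects and
cross-hybridization structure between related organisms, spatial array
artifacts, dye bias, FFPE degradation, correlated noise between channels,
and heavy-tailed signal distributions. Passing tests therefore demonstrate
that the statistics do what they claim under a clean log-normal truth
model, not that the pipeline is robust to every artifact of real scanner
data.

## Study sizes used by the replication studies

The calibration and power studies (`pathosig.evaluation`, also behind
`scripts/acceptance.py` and `analysis/04_operating_characteristics.py`)
use: null calibration — the full emulated design with 500 microbial probes
and per-channel noise 0.5, 100 replicates; planted recovery — 10 planted
organisms (effect 2.0, case prevalence 60%, control 0%) among 40 decoys,
50 replicates; cluster-count recovery — 2/3/4 blobs of 20 points in 3
dimensions, unit SD, centers 15 apart, 100 replicates each; outcome power —
one organism elevated 1.5 log2 units in 20 deceased vs 20 alive samples
(SD 1) among 20 null organisms, 100 replicates, with a label-permutation
rerun measuring the false-positive rate over 2,000 null tests. Replicate
seeds derive from a single master seed via `numpy.random.SeedSequence`.

## Known limitations

- The literal normalization's sensitivity to sf noise (above) makes
  analyses with very few human probes fragile; the ratio mode does not
  share this amplification.
- The presence-call rule and the union/max prevalence readings are
  declared stand-ins for conventions the original array descriptions leave
  unstated; both knobs are exposed.
- CH-based cluster-count selection is only meaningful for multivariate
  profiles (see above) and tends toward larger k on continuous
  carrier/non-carrier mixtures, as visible in the demonstration cohort.
- Percent-signal shares after the negative-shift rule send the cell
  minimum to 0%, which overstates contrast when all means are negative.
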