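# Methods

This note documents the statistical procedures `wmcap` implements, the
generative model behind its synthetic data, the defaults and why they were
chosen, and the places where a genuinely open design choice was made.

## Task model and conventions

Six screen locations, 1–3 in the left hemifield and 4–6 in the right, each
carry one of two session-specific colors labelled A and B. A trial shows
`n_left + n_right` items (1–3 per hemifield, 2–5 total; (3,3) is excluded
by the five-item maximum), holds them for an 800 ms sample phase, blanks
for a 1000 ms delay, and probes with one color exchanged. Time is in
seconds with sample onset at 0; all bins are half-open `[a, b)`.
"Ipsilateral" means the hemifield of the behavioral target for behavioral
analyses, and the hemifield of the neuron's favorite location for neural
analyses.

## Behavior

Performance is aggregated per session (the experimental unit) and
ipsilateral load. Aborted and no-response trials are excluded; empty
(session, load) cells are reported missing, never as zero. Capacity uses
Cowan's estimator `K = n·p` with `n` the total array size and `p` the
overall proportion correct at that size; per-hemifield K is not computed.
The load effect across sessions is tested with the Friedman rank test
(sessions as blocks; fully tied tables return χ² = 0 where the generic
tie correction would be undefined). The load model is ordinary least
squares on session-level proportions — Gaussian error with identity link,
matching the t-statistics and adjusted R² this analysis conventionally
reports — with predictors ipsilateral load, contralateral load and their
product on the raw 1–3 scale (centering is available as an option but off
by default). The reduced model drops the contralateral main effect but
keeps the interaction; the comparison statistic is the absolute
log-likelihood difference. A trial-level logistic variant was considered
and rejected as the default because session proportions are the unit the
downstream statistics expect.

## Information (ω² PEV)

Information about color identity is the ω² effect size of a one-way
decomposition of spike counts by the color shown at one location:

    ω² = (SS_effect − df_effect·MS_error) / (SS_total + MS_error)

with `df_effect = groups − 1`. ω² is slightly negative in expectation
under the null; negative values are preserved, and constant data (zero
total variance) is flagged undefined (NaN) rather than forced to zero.
Counts are taken in non-overlapping 200 ms bins: four over the sample and,
by the same scheme, five over the delay.

The favorite location of a neuron is the candidate location (the three
contralateral to the recorded hemisphere; locations 4–6 by default) with
the largest cumulative ω² over the four sample bins on load-1 trials;
exact ties break to the lowest location index. Candidates without usable
load-1 trials are skipped; a neuron with no usable candidate raises.

Significance per bin is a label-permutation test: the color labels are
permuted 1000 times, and

    p = (1 + #{permuted ω² ≥ observed ω²}) / (n_perm + 1).

The add-one estimator avoids exact-zero p-values, and ties count against
rejection, which makes the test slightly conservative on discrete counts
(its realized false-positive rate on Poisson nulls is ≈ 4–4.5% at the 5%
criterion; the acceptance script measures this). No correction across
bins is applied by default — including weakly informative neurons
deliberately — with a stricter two-consecutive-significant-bins criterion
available as an option. A neuron is significant for a phase at a load if
at least one bin in that phase passes (or two consecutive bins under the
strict option). The 2×2×2 truth table of loads 1–3 maps to seven groups
(I–VII); pooled group g contains every neuron significant at load g, and
neurons significant during the sample or delay phase form the sample and
delay populations. Whether a population's size exceeds the 5% chance rate
is an exact binomial upper-tail test.

Load conditions for a neuron pool over the opposite hemifield: a load-g
ipsilateral timecourse uses all correct trials where the favorite location
is displayed and its hemifield holds g items. Contralateral-load
timecourses hold the ipsilateral load fixed at 1 (configurable) while the
opposite hemifield's load varies. Permutation seeds derive from
(master seed, neuron, axis, load, bin), so results are independent of
evaluation order.

## Population analyses

Window tables pool counts over early/late sample (0–0.4, 0.4–0.8 s) and
early/late delay (0.8–1.3, 1.3–1.8 s) and run one ω² decomposition per
(neuron, window, load). The load effect on per-neuron window ω² is a
one-way ANOVA whose effect size is the same ω² formula applied at this
level; pairwise load contrasts are independent t-tests with Bonferroni
correction (m = number of pairs). Above-zero information is a one-sample
t-test; degenerate zero-variance inputs are flagged (t = 0 or ±∞) rather
than raised mid-pipeline.

Error-trial comparisons subsample correct trials without replacement, per
color and matched to the error-trial counts, 1000 times per neuron; the
per-neuron averages are compared to the error-trial ω² with a dependent
t-test plus Cohen's d. Neurons with fewer than two error trials of any
color (or more error than correct trials) are excluded and logged — in
practice this removes load-1 conditions, where errors are rare.

Clustering of load-1 ω² timecourses uses 1 − Pearson correlation as the
distance and average (UPGMA) linkage. Traces are z-normalized per neuron
first; the correlation distance makes any per-trace affine normalization
inert, which is exactly why this choice is safe. The within-cluster
sum-of-squares is reported for k = 1..10 so the elbow can be inspected;
the default cut is k = 7, a reporting convention rather than an enforced
elbow criterion. Clusters are renumbered in dendrogram leaf order, which
places similar clusters adjacently. Constant traces (undefined
correlation) are excluded with a warning.

## Divisive normalization (SE/SI)

Whole-phase condition rates are measured per neuron over the entire sample
(800 ms) or delay (1000 ms): REF_i (favorite location alone showing color
i), PROBE_j,c (one other ipsilateral location alone), and PAIR_i,j,c
(favorite plus one probe, ipsilateral load 2). Contralateral items are
ignored throughout (hemifield independence is a modeling assumption here,
and the generator enforces it). The rates are normalized by the
neuron-phase maximum condition mean — the choice that guarantees
SE = PROBE − REF and SI = PAIR − REF lie in [−1, 1] exactly; a min-max
variant is available. A complete design gives 2 reference colors × 2 probe
locations × 2 probe colors = 8 index pairs per neuron and phase; missing
conditions drop their pairs.

The pooled regression of SI on SE across all index pairs of a neuron group
is ordinary least squares. Under weighted-mean normalization,
PAIR = (w_ref·REF + w_probe·PROBE)/(w_ref + w_probe) implies
SI = [w_probe/(w_ref + w_probe)]·SE identically, so the slope reads out
the normalization weighting: 0.5 for equal weights, below 0.5 for
reference-dominated weighting. Comparison against 0.5 (and 0) is by 95%
CI inclusion. Groups are formed from whole-phase single-bin permutation
tests: information-carrying (significant at load 1), information-gaining
(not at load 1, significant at load 2), non-informative (neither); the
groups are disjoint by construction.

## Synthetic-data generator

The generator exists so that every downstream statistic can be tested
against known ground truth.

*Trials.* The eight valid (n_left, n_right) combinations are cycled so
they appear equally often up to rounding; displayed locations, colors and
the target are drawn uniformly.

*Behavior.* The probability of a correct response depends only on
ipsilateral load, with defaults (0.9588, 0.7831, 0.5821) for loads 1–3 —
the observed median performances of the study conditions the generator
emulates. An optional interaction term adds
`interaction·(ipsi−1)·(contra−1)` (default 0; no functional form for the
interaction is established, so the knob exists but stays off). Errors are
uniform over non-target displayed locations.

*Spikes.* Piecewise-homogeneous Poisson: baseline rate (default 5 Hz)
during fixation and a short post-delay window; during the sample (and the
delay, for delay-tuned neurons) the rate is the weighted mean of the
single-item rates of all items in the neuron's favorite hemifield, with
weight `w_ref` on the favorite-location item and `w_probe` on others.
Contralateral items never enter the rate law. A single item at the
favorite location therefore yields that item's rate regardless of weights,
and `w_probe = 0` preserves the reference rate at every load.
Poisson spiking has no refractoriness or autocorrelation — the simplest
process consistent with count-based ω² analysis. Neuron kinds:
"carrying" (color A minus color B rate difference `tuning_gain`, default
8 Hz — large enough for reliable favorite-location recovery at ~30 trials
per color), "gaining" (equal single-item rates but pair weights that
depend on the reference color, so selectivity emerges only at load 2),
and "nonselective". Non-reference rates get per-neuron uniform jitter so
a population spans a realistic range of selectivity — without it the
SE/SI regression would be degenerate. Every stream derives from explicit
seeds by fixed offsets: identical (config, seed) reproduce bit-identical
outputs, and adding neurons never perturbs existing ones.

A condition-level shortcut (`simulate_index_pairs`) draws single-item
rates uniformly, forms pair rates by the same weighted mean, and either
uses exact rates (noiseless: the slope identity holds to machine
precision) or Poisson condition means, feeding the same index-building
code as the full pipeline.

*What the generator does not emulate:* reaction times, eye/head movement,
spike-sorting artifacts, firing-rate adaptation, trial-to-trial rate
correlations, and oscillatory structure. Tests passing on generated data
therefore validate the statistics and their implementation, not the
biological assumptions themselves.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest problem sizes — a few
sessions of a few hundred trials, tens of neurons, 100–1000 permutations —
chosen so the statistical claims under test (calibration bands, slope
identities, orderings) are already stable at those sizes. The acceptance
script uses 2000 Monte Carlo neuron-bins for the permutation-calibration
estimate (standard error ≈ 0.5 percentage points) and 220 neurons × 8
index pairs for the stochastic slope.

Numerical conventions worth knowing: half-open bins everywhere (a spike
exactly on an edge belongs to the later bin); permutation tie comparison
uses a 1e-12 tolerance; Friedman on fully tied tables returns 0;
favorite-location ties break to the lowest index; Bonferroni p-values cap
at 1; cluster WCSS is computed on the z-normalized traces.

## Known limitations

- The OLS behavior model can predict proportions outside [0, 1] for
  extreme loads; the logistic alternative is not implemented as a default.
- The permutation test's conservatism on heavily tied (low-count) data
  means its realized level sits below 5%; this is inherent to the ≥-with-
  ties convention, not a bug.
- Whole-phase DNR grouping at α = 0.05 misassigns ~5% of null neurons by
  construction; group-level slopes are robust to this, single-neuron
  labels are not.
- The clustering default k = 7 is a reporting convention; nothing in the
  elbow curve is tested automatically.
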