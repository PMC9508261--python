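# Methods

## The analysis model

The pipeline treats a resting-state scan as an n-parcel multivariate time
series. Functional connectivity between parcels i and j is the Pearson
correlation of their mean signal time courses, Fisher-z transformed
(`z = atanh(r)`, with |r| clipped to 1 − 1e−7 so degenerate inputs stay
finite) and with negative edges set to zero — an absent-edge convention
that avoids interpreting anticorrelations as connection strength. Hub
centrality is *composite weighted degree*: the connectivity matrix is
thresholded proportionally at edge densities 0.02–0.10 in 0.01 steps
(keeping the `m = max(1, floor(d·n(n−1)/2))` strongest edges, ties broken
by ascending index so the computation is deterministic), weighted degree
`k_i = Σ_j a_ij` is computed at each density, and the nine values are
summed. Because proportional thresholds are nested, each edge contributes
its weight times the number of densities at which it survives; the
implementation uses that identity and is tested against a brute-force
edge-enumeration oracle.

Within- and between-network degree reuse the same globally thresholded
graphs: every surviving edge is attributed to the within component when its
endpoints share a community label, otherwise to the between component, so
`within + between = total` holds exactly (property-tested).

## Quality control and cleaning

Framewise displacement at volume t is the sum of absolute derivatives of
the three translations (mm) plus the three rotations converted to arc
length on a 50 mm sphere; FD at the first volume is 0. Subjects with mean
FD > 0.25 mm are excluded; volumes with FD > 0.5 mm are scrubbed. Order of
operations: confound regression first (OLS residuals against an intercept,
the six motion parameters and the global signal; rank-deficient confound
sets are handled by least squares with a logged warning), then zero-phase
band-pass, then scrubbing applied at the correlation step — filters need a
contiguous series, while the Pearson correlation only needs the retained
samples (duplicating a scrubbed volume provably leaves the matrix
unchanged). The filter is a second-order Butterworth band-pass (0.01–0.08
Hz) run forward-backward (`sosfiltfilt`) to avoid phase distortion; its
empirical frequency response is asserted in the tests (≥ 0.9 passband gain
at 0.05 Hz, ≤ 0.1 at 0.005 Hz, TR = 3 s).

## Inference

Group differences in composite degree use label-permutation tests
(default 5000 reshuffles, one shared schedule across parcels per iteration
so the null preserves cross-parcel dependence). The p-value is the plain
proportion of permuted |mean differences| ≥ the observed |difference|
(two-sided by default; the one-sided reading and a (b+1)/(m+1) correction
are available switches). Degree–behavior correlations use
behavior-permutation: the SD of the permuted correlation coefficients
estimates the standard error, z = r/SE is referred to the standard normal
two-tailed. Both are corrected across parcels with Benjamini–Hochberg
(via statsmodels, validated against a brute-force step-up oracle);
correlation families over the two behavioral outcomes use the
Bonferroni-tightened q < 0.025 flag. Cohen's d uses the pooled-SD
(n_a + n_b − 2) convention, and the two-sample t-test defaults to pooled
variance with Welch as an option; both are callable from raw samples or
printed summary statistics.

The post-hoc within/between stage analyzes parcels associated with
behavior *exclusively* in one group, operationalized as q < 0.025 in the
focus group and p ≥ 0.05 (not even nominally significant) in the other;
both cutoffs are configurable since "exclusive" admits several readings.

## Prediction

The degree-based predictive model follows the standard
connectome-predictive-modeling recipe with a combined score: per training
fold, parcels correlated with behavior at two-tailed parametric p < 0.01
enter a positive (r > 0) or negative (r < 0) set; the summary score is the
positive-set sum minus the negative-set sum; a one-variable least-squares
line maps score to behavior; the held-out subject is predicted from its own
score. Folds in which nothing is selected predict the training mean rather
than failing, so null simulations complete. Prediction power is the Pearson
correlation of predicted vs observed across folds, and significance is the
proportion of ≥-observed prediction correlations over full LOOCV reruns on
permuted behavior (default 1000 permutations). The LOOCV is computed with
leave-one-out sum downdating (per-fold correlations and regression lines
from full-sample sums minus the held-out row), which is algebraically
identical to refitting per fold — the equivalence is property-tested — and
fast enough to rerun inside the permutation loop. A two-predictor variant
(positive and negative sums as separate regressors) is available behind
`mode="separate"`.

## Synthetic cohort generator

The generator emulates the second-order structure the analysis assumes and
nothing more. Parcel time series are zero-mean multivariate normal with a
block covariance: rho_within = 0.30 inside a community, rho_between = 0.05
across communities, designated hub parcels with all correlations set to
rho_hub = 0.25 plus a per-group offset (the planted group effect).
Negative eigenvalues introduced by the hub rows are clipped to 1e−8 and the
matrix re-symmetrized. The default parcellation has 333 parcels in 12
communities plus an unassigned class; the default cohort is 29 patients and
29 controls with 120 volumes at TR = 3 s.

Motion traces are AR(0.95) random walks in the six parameters (step SDs
0.03 mm / 2e−4 rad, giving mean FD ≈ 0.10 mm) with Bernoulli (rate 0.01)
persistent 0.7 mm translation repositionings that exceed the scrubbing
threshold at exactly one volume (~1% of volumes scrubbed). Rotational
spikes are not modeled — translation jumps already exercise both QC rules.

Behavior: combined working-memory accuracy equals an intercept (91.5% for
controls) plus beta times the subject's mean composite degree over the
coupling parcels — *centered across subjects*, so the intercept remains the
group mean whatever the degree scale and accuracies stay inside [0, 100] —
plus a group offset (−7 for patients) and Gaussian noise. When a target R²
is set, the noise SD is calibrated from the realized score spread
(`sigma = |beta|·sd(score)·sqrt((1−R²)/R²)`). Per-load accuracies scatter
around the combined value with fixed offsets (+6, +2, −2, −6 at loads
1/3/5/7) and the combined column is recomputed as their exact mean.
Reaction times carry only a group offset (+70 ms for patients) and noise.
Crucially, the coupling degree is computed through the pipeline's own
cleaning path (motion + global-signal regression, band-pass, scrubbing):
coupling to raw connectivity does not survive global-signal regression, so
raw coupling would leave nothing for the downstream analysis to find. All
randomness flows from one top-level seed through `SeedSequence.spawn`.

The `study_model()` defaults plant six hubs spread over the major
communities with a patient-side correlation offset of 0.05 — producing
medium-to-large standardized hub-degree differences (|d| ≈ 0.7–1.2 at
n = 29 + 29) that do not generally survive FDR at this sample size — and
couple accuracy to three ventral-attention parcels at true R² = 0.25.

What the generator does **not** emulate: hemodynamics, spatial
autocorrelation, scanner drift, physiological noise, distance-dependent
motion artifacts, or any anatomical meaning for specific parcels. Passing
tests therefore demonstrate that the statistical machinery is calibrated
and recovers planted effects of realistic size — not that any particular
anatomical claim about real data would replicate.

## Test and acceptance problem sizes

Stochastic checks run at scaled sizes chosen to keep the suite fast while
preserving the quantities of interest: null calibration pools 3 × 1000
parcels of group-permutation p-values (58 subjects, 1000 permutations) for
the uniformity test and 100 replicates of 500-parcel correlation tests for
the family-threshold bound; planted-shift recovery uses d = 1.5 at one of
200 parcels (29 + 29 subjects, 100 replicates); CPM recovery uses N = 60
with a 33-parcel (10×-scaled) parcellation, three coupled parcels sharing
0.45 of their variance (matching the coupled-degree correlations the full
generator realizes), noise calibrated to true R² = 0.25, and 1000
significance permutations. At these conditions the measured pass rate of
the r > 0, p < 0.05 recovery criterion is at the 80% bound — the bound sits
near the true power of the combined-score CPM under a 0.25-R² signal, which
is worth knowing before applying the method at comparable sample sizes.

## Known limitations

* Permutation p-values use the plain proportion, so p = 0 is possible;
  enable the (b+1)/(m+1) correction where exact validity matters.
* Proportional thresholding with the minimum-one-edge rule means density
  sweeps on near-empty matrices keep a single arbitrary strongest edge.
* Binary degree is intentionally not provided; the degree definition sums
  Fisher-z weights.
* The pipeline's exclusive-significance rule and the per-load behavioral
  comparisons are reported uncorrected across loads.
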