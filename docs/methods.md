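# Methods

This note records the models, estimators, conventions and numerical choices
behind `rsndyn`, and what the synthetic benchmark does and does not
establish about real data.

## Data model

A session is a T×N matrix of network activity sampled every `dt` seconds
(defaults T = 208, N = 14, dt = 2 s — a 7-minute resting-state fMRI run
reduced to 14 large-scale networks). All metric APIs work in seconds; no
frame-index arithmetic leaks out. Cohorts enforce shared labels and
sampling, unique (subject, session) keys, and a group label that is a
property of the subject. Cohort I/O is delimited text (one CSV matrix per
session plus a manifest); a schema-configurable MATLAB reader is provided
as a convenience for externally deposited data.

## Static functional connectivity

Whole-record Pearson correlation. Vectorization uses row-major
upper-triangle order over the label ordering — a fixed, documented choice;
only the count (N(N−1)/2) is intrinsic. Pearson correlation is invariant
to per-channel affine rescaling (up to sign), so no further normalization
is exposed.

## Conditional Granger causality

Convention: `G[i, j]` is the causality of source j on target i,
F_{j→i|rest}. Estimation is OLS on per-column demeaned series; the full
model is a VAR(p) over all N series, and for each (target, source) the
reduced model refits the target's equation with the source's lags removed
(the other N−2 networks stay in both models, making the measure
conditional). g = ln(RSS_reduced/RSS_full); separate estimation can
produce slightly negative values, which are clamped to zero. One common
order p is selected on the full model by BIC (default; AIC available,
maximum order 10) and floored at 1 for causality estimation; for short
records with many networks, orders above 3 trigger a degrees-of-freedom
warning. Order selection itself delegates to the standard VAR machinery in
`statsmodels`.

Naming resolves the directed entries per unordered pair A<B in label
order: `A->B` = F_{A→B} (entry `G[b, a]`), `A<-B` = F_{B→A} (`G[a, b]`),
and `netgc_A->B` = F_{A→B} − F_{B→A}, so `netgc` is always the named
difference of the two directed features. Degrees: DegIn = row sums (total
inflow under the source-on-target convention), DegOut = column sums,
NetDeg = DegOut − DegIn, which telescopes to zero over networks.

## Wavelet coherence and time-of-coherence

The continuous wavelet transform uses the analytic Morlet wavelet with
nondimensional frequency ω₀ = 6, evaluated in the frequency domain over
log2-spaced scales (12 sub-octaves per octave) spanning Fourier periods
4–128 s (truncated, with a warning, to half the record duration). The cone
of influence is the e-folding time √2·s per scale; cells outside it never
count toward any feature — excluding them avoids edge artifacts that would
otherwise inflate the long-period bands on a 416 s record.

Squared coherence is the smoothed cross-power normalized by smoothed
auto-powers. Smoothing is scale-dependent Gaussian in time (standard
deviation = one scale) and a 0.6-octave boxcar in scale. The time
smoothing runs as a frequency-domain multiplication with zero padding for
all scales at once; the amplitude droop this causes near the record edges
multiplies numerator and denominator identically and cancels in the
coherence ratio.

Phase θ = arg of the smoothed cross-spectrum, with the cross-wavelet
defined as W_x·conj(W_y) so that θ > 0 means signal 1 leads. The four
phase classes are quadrants with half-open lower boundaries —
in-phase [−π/4, π/4), leading [π/4, 3π/4), anti-phase [3π/4, π] ∪
[−π, −3π/4), lagging [−3π/4, −π/4) — which partition (−π, π] exactly
(purely open intervals would not).

Significance is pointwise per scale: the (1−α) quantile (α = 0.05 default)
of coherence pooled over inside-COI time points of AR(1) surrogate pairs
matched to each input's lag-1 autocorrelation (coherence is
variance-invariant, so amplitude matching is unnecessary). Default 300
surrogates; calibration studies use 100–150. Because the null depends only
on the record geometry and the two AR(1) coefficients, whole-cohort
extraction shares surrogate ensembles through a cache keyed by the
coefficients quantized to 0.05; each cache entry derives its own seed so
results are independent of evaluation order.

Time-of-coherence: per period band ([4,8), [8,16), [16,32), [32,64),
[64,128] s) and phase class, the percentage of time points at which some
in-band scale is significant inside the COI, with ties across scales
resolved by the maximal-coherence cell. By construction the four phase
values of a band sum to its total significant-time percentage. A
per-(scale,time)-cell counting variant is available
(`time_of_coherence(per_cell=True)`); under the null its per-cell mean is
α/4·100, whereas the default per-time-point union over the ~12 scales of a
band has a higher null floor (~4% per cell at α = 0.05) — the cellwise
rejection rate inside the COI is α either way.

Resolution bias: the time smoothing dilates a genuinely coherent window by
roughly one wavelet support (about one period of the underlying rhythm)
per edge. At T = 208 samples a planted 50%-of-record window at 20 s period
reads ≈60%; at T = 416 it reads ≈55%. Recovery studies therefore use
416-sample records, where the planted-window oracle is valid; on 208-sample
study data, short windows at long periods are systematically overestimated
by a few points.

## Emulative power (replicator-dynamics fit)

Activity is first affinely mapped per channel onto [ε, 1−ε] (ε = 0.05;
ε = 0 is refused because replicator dynamics are degenerate on the
boundary). The adopted model is the canonical two-strategy replicator form
on a weighted directed graph,

    ẋ_i = x_i(1 − x_i) · Σ_{j≠i} a_ij (2x_j − 1),

in which a_ij > 0 drives network i toward network j's current strategy
(emulation) and a_ij < 0 away from it. This form preserves the properties
the analysis uses — directed pairwise weights, sign-coded emulation, and
coupling through the rate of change of activity — without committing to a
particular payoff parameterization. The forward simulator (explicit Euler
with additive state noise and clipping) and the fitter share this one
form, so recovery studies are internally valid.

Fitting: derivatives by central differences (endpoints dropped); each row
of A solves ridge-regularized least squares of ẋ_i on the regressors
x_i(1−x_i)(2x_j−1), with the dimensionless ridge λ = 1e−3 scaled by the
mean regressor energy. Samples where the target's gate x_i(1−x_i) falls
below 0.05 are excluded from that row: near the boundary the gate
annihilates the deterministic signal, so saturated stretches contribute
noise only and would otherwise dominate long records (a trajectory that
saturates early keeps >90% sign recovery with the screen, ~85% without).
If too few samples survive, the row falls back to all samples; a row with
identically zero gate energy (constant state) yields zeros.

Identifiability note: a little state noise keeps the dynamics persistently
excited, so sign recovery actually peaks at moderate noise; with zero
noise only the initial transient informs the fit.

Powers: OutEP_i = Σ_j a_ij (row sum; how strongly i emulates the others),
InEP_j = Σ_i a_ij (column sum; how strongly j is emulated),
NetEP = OutEP − InEP, which sums to zero over networks for every matrix.
Both orientations of the "power" reading are exposed through the profile
object; the row/column assignment above is the package's fixed convention.

## Permutation screening and coherence reduction

Statistic: absolute difference of group means — two-sided by construction;
p = (1 + #{permuted ≥ observed})/(P + 1), valid at finite P (minimum
attainable p with 5000 permutations is 1/5001). Screening is per feature
at uncorrected α = 0.05, mirroring the small-cohort design; a
Benjamini–Hochberg option exists but is off by default. Group tests run
per session with a shared permutation ensemble; a feature counts as
significant when it passes in either session.

Coherence features then pass three reduction rules: (i) drop features that
also differ significantly between the controls' two sessions (a
test-retest inconsistency signal); then keep a feature only if (ii) its
pair is significant in ≥2 period bands for the same phase or in ≥2 phases,
or (iii) its own minimum session p is below 0.01. The combination is
(i) AND ((ii) OR (iii)), configurable.

## Classifier benchmark

Algorithms at fixed default set-ups (no hyper-parameter search): SVM with
Gaussian kernel, C = 1 and median-heuristic bandwidth
γ = 1/(2·median²(pairwise distances)); LDA with pooled covariance,
switching to the lsqr solver with Ledoit–Wolf shrinkage when features ≥
observations (unavoidable when dozens of features meet 24 subjects); 1-NN;
CART with Gini impurity and no pruning. Features are z-scored by
training-fold statistics for SVM/LDA/KNN; trees consume raw values.

Five validation schemes: cross-session train/validate in both directions,
leave-one-observation-out within each session, and leave-one-out over the
48 concatenated observations. The concatenated scheme holds out one
session, not one subject, so the held-out subject's other session remains
in training — a deliberate replication of the 48-fold design, with the
optimistic bias that implies. Sensitivity is the fraction of patients
(positive class) recovered; specificity the fraction of controls; the
accuracy identity acc = (sens·n₊ + spec·n₋)/n holds exactly per row. Best
set-ups are chosen by the highest average accuracy over the five schemes,
ties broken by average sensitivity, then name.

Greedy subset refinement starts from two admission pools — predictors used
by a fitted CART tree, and features naming any of a configured network set
(default DMN, DAN, SN) — and alternates remove/add passes that keep a
change only if the best average accuracy improves, for a bounded number of
iterations with a full audit trail. It is a declared reconstruction of an
interactive procedure, not a replication of any particular search path.

## Synthetic benchmark: what it shows and what it does not

The benchmark cohort (14 controls + 10 patients, two sessions, 208×14 at
2 s) plants three patient-specific effects: a lag-1 VAR coupling
DMN→AUDI (coefficient 0.5), a 20 s in-phase oscillation shared by DMN and
MVISU over 60% of the record (amplitude 1.2 against unit-variance AR(1)
background, random carrier phase per session), and a DMN/DAN
replicator-coupled component whose emulation weight flips sign between
groups (±0.12, embedded as a z-scored state trajectory). Controls are the
pure null process: diagonal AR(1) with coefficient 0.3 — a standard
stand-in for BOLD autocorrelation at TR = 2 s — and unit innovation
variance. One master seed spawns per-subject/session streams by hashing
the textual keys, so enlarging the cohort never perturbs existing
subjects.

Passing the end-to-end checks shows that each stage recovers the kind of
structure it claims to measure at study-realistic dimensions and that the
pipeline's false-positive behaviour is calibrated (label-permuted accuracy
at chance given the 10:14 imbalance, where a majority-leaning algorithm's
chance level is 14/24). It does not show that real cohorts separate this
cleanly: the generator has no hemodynamics, no shared physiological
confounds, no between-subject heterogeneity in effect size, and its
planted effects are stronger and purer than plausible clinical effects.
Reported real-data accuracies of comparable studies require their original
recordings and are deliberately outside this package's claims.

## Problem sizes and determinism

Default analyses: 300 coherence surrogates, 5000 permutations. The bundled
studies and the acceptance script scale down where Monte-Carlo error
allows — 100 surrogates, 1000 permutations, 50 simulation seeds per
recovery study, 208–2000-sample records — sizes chosen so each study's
sampling error is small against its acceptance band. Every stochastic
stage receives a seed derived from one master seed and the stage name via
SHA-256, so identical configurations reproduce byte-identical outputs
regardless of execution order.
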