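# Methods

## Problem and model

We quantify how much information continuous features of evoked
potentials carry about a discrete stimulus.  The stimulus S is a tone
frequency drawn from a finite set (32 log-spaced tones from 2 kHz to
46,731 Hz, uniformly presented); the response R is a per-trial scalar
feature of a voltage sweep (amplitude in mV or latency in ms) from a
PSP (whole-cell) or LFP (extracellular) recording.  The quantity of
interest is the mixed discrete–continuous mutual information

I(S;R) = H(S) − E_r[H(S | R = r)]  (bits),

estimated per cell, per signal type, per feature, and then compared
across cells with nonparametric paired/unpaired tests.

## Estimators

**Nearest-neighbour (primary).**  Ross-style estimator for a discrete
label and a 1-D continuous response.  Per point i with label class
size `N_Si`: the effective neighbour count is `k_i = min(k, N_Si − 1)`
(so unbalanced designs remain estimable); `d_i` is the distance to the
k_i-th nearest *same-label* neighbour; `m_i` counts points of any
label, excluding i, in the closed ball of radius `d_i`; the point's
contribution is ψ(N) − ψ(N_Si) + ψ(k_i) − ψ(m_i) nats, and the
estimate is the mean over points, in bits.  Conventions:

* `m_i` counts over *all* labels.  (An alternative reading — counting
  within the same label only — breaks the estimator: it would make the
  single-class case nonzero.  All-label counting gives exactly 0 bits
  for single-class data, as it must.)
* Ties: closed ball, so points at exactly `d_i` count.  Exact ties
  inflate `m_i` and thus bias the estimate down slightly; continuous
  features make exact ties rare.  Ball membership is decided by the
  exact float comparison |r_j − r_i| ≤ d_i, never by interval
  endpoints r_i ± d_i, which lose boundary points to rounding.
* Singleton classes have no same-label neighbour; their points are
  skipped, counted, and warned about.
* Default k = 3; the calibration sweep shows the estimate is nearly
  flat over k = 1..10, so the choice is uncritical.
* The estimator is exactly invariant under affine response maps
  (neighbour sets are preserved), and can be slightly negative on
  null data; negatives are clamped to zero per cell/feature *before*
  any averaging across cells (`clamp_mi`), with the flag recorded.

**Binned plugin + QE (reference).**  Equal-width bins over the
observed response range (the max lands in the last bin; a constant
response collapses to one occupied bin), relative frequencies plugged
into the discrete MI formula, 0·log 0 ≡ 0.  The quadratic
extrapolation correction computes naive estimates on the full data,
on 2 random halves (averaged) and on 4 random quarters (averaged) —
one seeded partition per level — and solves the exactly determined
3×3 system I_true + a/N + b/N² through the three (N, I) points.  These
estimators exist to demonstrate, on known-MI data, why the neighbour
method is preferred.

## Ground-truth mixtures

Calibration uses two-class mixtures with analytic MI, computed as
H(S) − E_r[H(S|r)]:

* all-uniform mixtures: exact, by summing over the piecewise-constant
  segments between support edges (for two equiprobable width-4
  uniforms centred at 1 and 2, the overlap region carries marginal
  mass 3/4 and one full bit of posterior entropy, so I = 0.25 bit
  exactly);
* any mixture: adaptive quadrature (`scipy.integrate.quad`) of the
  per-class KL divergences Σ_s p(s) KL(p(r|s) ‖ m(r)), integrated
  over each component's support (Gaussians: ±9 sd) with breakpoints
  at all support edges; absolute tolerance well below 1e-6 bits.  The
  quadrature route reproduces the uniform closed form to 1e-9.

The two canonical calibration models are pinned to their conventional
truth values: uniform pair of total width 4 (0.25 bit) and Gaussian
pair at means 1, 2 with sd √2 (0.0849 → 0.08 bit).  The narrower
*literal* variants of the same shapes (width 2; unit sd) carry exactly
twice the squared spread and hence double the MI (0.5 and 0.1607 bit);
both parameterisations are exported because descriptions of these
benchmarks in the literature mix the two conventions while quoting the
0.25/0.08 values.  The unit-sd value 0.1607 bits was verified against
an independent 2×10⁶-draw Monte Carlo average of log2 p(r|s)/m(r).

## Signal front-end

* **Filter**: linear-phase least-squares FIR low-pass, order 39
  (40 taps), cutoff 300 Hz at 4 kHz sampling, transition band 15% of
  the cutoff, applied forward and backward (`filtfilt`, reflect
  padding of 3× the order) for zero phase.  Because 40 taps is an
  even-length (type II) design, the least-squares fit is solved
  directly on a dense frequency grid in the symmetric linear-phase
  basis (passband [0, fc] desired 1, stopband [1.15 fc, Nyquist]
  desired 0); taps are normalised to unit DC gain.  The contract is
  stated in measurable terms — DC gain 1 ± 1e-3, sinusoid steady-state
  amplitudes matching the designed filter's own two-pass magnitude
  response — rather than in coefficients.
* **Baseline**: subtract the mean potential over [0, onset), onset
  15 ms by default.
* **Features**, on the filtered, baseline-corrected sweep, over the
  half-open window [15 ms, 100 ms): amplitude = max − min (≥ 0);
  latency = time from onset to the window maximum (PSP) or minimum
  (LFP), ties to the earliest sample, hence latency ∈ [0, 85] ms.
  Min-to-max amplitude is used for both signal types.  A flat window
  yields amplitude 0/latency 0 flagged degenerate instead of an
  error, so batch runs survive dead sweeps.

Times are seconds internally, milliseconds at reporting boundaries;
sample indexing is 0-based.

## Synthetic experiments

The generator emulates the *structure* of the tone study, not its
biophysics: per cell and trial, an alpha-shaped evoked transient
a·(t′/τ)·e^(1−t′/τ) (τ = 10 ms) whose peak value a is drawn from a
Gaussian around a log-frequency Gaussian tuning curve
(baseline + (max − baseline)·exp(−½ (log2(f/f_pref)/width)²)), peak
latency jittered around a base value, plus white background noise;
LFP models flip polarity and apply a gain.  Defaults (few-mV
amplitudes: baseline 3, max 6 mV; amplitude noise 0.7 mV; latency
25 ± 1.5 ms; background noise 0.1 mV) match the few-mV, tens-of-ms
scale of published example sweeps.  Tones follow a balanced
pseudo-random order (a fresh permutation of all 32 tones per block),
and the whole experiment is reproducible from one seed.

Because the amplitude feature is then Gaussian given the tone, the
cell's true amplitude MI is computable by the mixture quadrature
(`model_true_mi`: 32 equiprobable Gaussians at gain·tuning(f_i), sd
gain·noise).  This enables end-to-end parameter recovery: at 100
trials/tone, the pipeline estimate averaged over 20 seeds lands within
0.05 bit of the model truth (the residual gap is upward kNN bias at 32
classes plus small feature-extraction noise).  The stock population
builder gives LFP models a gain of 3 with lower pre-gain amplitude
noise (0.55 vs 0.8 mV), so LFP amplitudes carry strictly more
information by construction — the qualitative LFP > PSP amplitude
ordering is therefore a *structural* property the pipeline must
recover, not an empirical claim about any real dataset.

What the generator does **not** model: spikes, adaptation or
inter-trial dependence, anesthesia effects, latency tuning (latency
carries no stimulus information in synthetic cells, so latency MI
clamps to ~0 there), non-Gaussian amplitude noise, or correlated
background noise.  Passing tests on synthetic data therefore validate
the estimator chain and its calibration, not any neurophysiological
conclusion about real recordings.

## Group comparisons

Per-cell MI values (clamped) are tabulated by (cell, signal, feature,
group) and summarised as mean ± SEM (sd/√n; a single value reports
SEM 0 with n = 1).  Matched contrasts (e.g. LFP amplitude vs PSP
amplitude within cells) use the Wilcoxon signed-rank test: zero
differences are dropped and counted; for n ≤ 15 the null is enumerated
exactly over all 2ⁿ sign assignments (with average ranks for ties),
otherwise a normal approximation with tie-corrected variance and
continuity correction is used.  Between-group contrasts (e.g.
pentobarbital vs urethane cells) use the Wilcoxon rank-sum test,
exact by enumeration of all C(m+n, m) assignments for m + n ≤ 12,
tie-corrected normal approximation otherwise.  The thresholds put
study-scale inputs (33 pairs, 16 vs 17) on the approximation path —
as any standard implementation would — while the exact modes double
as enumeration oracles.  The approximations agree with
scipy.stats.wilcoxon/mannwhitneyu to machine precision.  No
multiple-testing correction is applied in the standard contrasts
(an optional Bonferroni helper exists); one- vs two-tailed and the
direction are configuration per contrast, not hard-coded.

## Pipeline and reproducibility

`run_pipeline` composes simulate/load → filter → baseline → features →
per-cell MI (k = 3, clamped) → summaries → contrasts.  Outputs carry a
provenance header (sha-256 config hash — excluding the output path —
seed, package version), reruns with the same config are byte-identical,
and the config embedded in `results.json` reproduces the run.  Per-cell
estimator failures are logged and skipped, never silently dropped.

## Problem sizes used in the checks

Calibration checks use 100 replicate datasets of N = 400 with the bin
grid thinned to every 5th value of 1–400 (the thinning does not change
any verdict); estimator-vs-oracle equivalence uses 200 random
instances with N ≤ 50; recovery uses one cell × 100 trials/tone × 20
seeds, and the population ordering check 33 cells × 20 trials/tone ×
10 seeds.

## Known limitations

* The neighbour estimator handles 1-D responses only (amplitude and
  latency separately); no multivariate or continuous–continuous MI.
* Closed-ball tie handling biases estimates down on heavily
  discretised responses.
* QE uses one random partition per level; replicate partitions would
  reduce the (already secondary) estimator's variance.
* No reader for the original study's raw files is bundled (their
  format is unpublished); `read_crcns_recording` is a stub interface,
  and conclusions about real recordings are out of scope for the
  test-suite.
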