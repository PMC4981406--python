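# evokedmi

Tools for asking how much information about a sensory stimulus is
carried by continuous features of evoked potentials.  The concrete
setting is auditory: anesthetized-rat A1 recordings in which 32 tone
frequencies (log-spaced, 2 kHz–46,731 Hz, 25 ms tones) are presented in
pseudo-random order while a whole-cell electrode records postsynaptic
potentials (PSPs) and a nearby patch electrode records the local field
potential (LFP), both at 4 kHz.  Each trial sweep is reduced to two
features — amplitude (window max − min, mV) and latency (tone onset to
the window extremum, ms) — and the package estimates the mutual
information (MI) between the discrete tone variable S and each
continuous feature R.

The package is aimed at electrophysiologists and methods people who
need a *calibrated* MI estimate for discrete-stimulus / continuous-
response designs, with the whole chain testable on synthetic data.

## The estimator

For mixed discrete–continuous pairs,

```
I(S;R) = Σ_s ∫ μ(s,r) log[ μ(s,r) / (p(s) μ_R(r)) ] dr .
```

The workhorse is the nearest-neighbour estimator for this setting
(Ross's method).  For each sample *i*: let `N_Si` be the number of
samples sharing its stimulus label, `d_i` the distance to its k-th
nearest neighbour *within that label*, and `m_i` the number of samples
of *any* label within `d_i`.  Then

```
I_i = ψ(N) − ψ(N_Si) + ψ(k) − ψ(m_i),     I = ⟨I_i⟩ / ln 2   (bits)
```

with ψ the digamma function.  The classical alternative — binning R
and plugging relative frequencies into the discrete MI formula — is
also provided, together with its quadratic-extrapolation (QE) bias
correction, which fits `I_naive(N) = I_true + a/N + b/N²` through
naive estimates at N, N/2 and N/4.  Calibration on mixture models with
known MI shows why the neighbour estimator is preferred: its estimates
barely depend on k, while the binned estimate swings with the bin
count even after QE correction.  Small negative neighbour estimates (a
known artifact) can be clamped to zero per cell before averaging.

## Worked example

`examples/02_estimator_calibration.py` draws 30 replicate datasets of
N=400 from the two-Gaussian calibration model (true MI 0.0849 bits)
and sweeps both estimators' parameters:

```
true MI: 0.0849 bits (N=400, 30 replicate datasets)

neighbour estimator            binned + quadratic extrapolation
  k   mean [q10, q90]            bins   mean [q10, q90]
  1   0.094 [ 0.018,  0.153]    1    0.000 [  0.000,   0.000]
  3   0.087 [ 0.044,  0.141]   10    0.085 [  0.042,   0.123]
  5   0.084 [ 0.041,  0.136]   50    0.092 [  0.010,   0.147]
 10   0.089 [ 0.058,  0.124]  400    0.276 [  0.165,   0.420]

Range of means across the grid: knn 0.014 bits, binned-QE 0.276 bits.
```

The neighbour estimator stays within ~0.01 bit of the truth across the
whole k grid; the binned estimator is only right for a lucky choice of
bins and overshoots badly as bins grow.  Other examples cover the
analytic ground truths (`01`), the sweep front-end (`03`) and a full
synthetic experiment with the study-style group comparisons (`04`):

```
MI summaries (mean +/- SEM over cells, bits):
  lfp_amplitude   1.063 +/- 0.070  (n=12)
  psp_amplitude   0.754 +/- 0.059  (n=12)
Paired one-tailed signed-rank contrasts:
  lfp_amp_vs_psp_amp   p = 0.0002
```

Here the synthetic LFP models are built with better amplitude SNR than
their paired PSP models, so the pipeline recovers the expected
ordering: LFP amplitudes carry more stimulus information than PSP
amplitudes.

There is also a thin CLI mirroring the library
(`evokedmi simulate|calibrate|features|mi|compare|analyze`).

## Data

The package ships no recordings.  Sweeps live in a simple HDF5 store
(`/cells/{cell}/trials/{trial}` with per-trial attributes) or a
one-CSV-per-cell text format; `evokedmi.simulate` generates complete
synthetic experiments with the study's structure and *known* per-cell
information content, which is what the test-suite runs on.
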