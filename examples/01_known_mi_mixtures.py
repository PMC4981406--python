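"""Ground-truth MI of the calibration mixtures, and a first estimate.

Builds the two canonical two-class calibration models (uniform and
Gaussian conditionals), prints their analytic MI, then samples one
dataset from each and estimates MI with the nearest-neighbour method.
The estimate should land close to the analytic truth at N=400.
"""

import evokedmi as em

for name, spec in [
    ("uniform (width 4)", em.uniform_calibration_spec(4.0)),
    ("uniform (width 2)", em.uniform_calibration_spec(2.0)),
    ("gaussian (sd sqrt2)", em.gaussian_calibration_spec()),
    ("gaussian (sd 1)", em.gaussian_calibration_spec(sd=1.0)),
]:
    truth = em.true_mi(spec)
    data = em.sample_mixture(spec, n=400, rng_seed=1)
    est = em.knn_mi(data, k=3)
    print(f"{name:22s} true {truth:.4f} bits | knn(k=3, N=400) {est.value_bits:.4f} bits")

print()
print("The width-4 / sd-sqrt(2) variants are the canonical calibration")
print("models (true MI 0.25 and ~0.08 bit); the narrower literal variants")
print("carry exactly twice the information.")
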