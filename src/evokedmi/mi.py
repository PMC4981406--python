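"""Mutual information between a discrete stimulus and a continuous response.

Three estimators are provided:

``knn_mi``
    The nearest-neighbour estimator for discrete-continuous pairs
    (Ross-style).  For each point *i* with stimulus label *s_i*, let
    ``d_i`` be the distance to its *k*-th nearest neighbour **among
    points sharing its label**, ``N_Si`` the size of that label class,
    and ``m_i`` the number of points of **any** label (excluding *i*
    itself) within the closed ball of radius ``d_i``.  The per-point
    contribution in nats is

        I_i = psi(N) - psi(N_Si) + psi(k_i) - psi(m_i)

    and the estimate is the mean of ``I_i`` over points, converted to
    bits.  Classes with a single member cannot contribute (no same-label
    neighbour exists) and are skipped with a warning.

``binned_mi_naive``
    The classical plugin estimator: discretise the response into
    equal-width bins over its observed range and apply the discrete MI
    formula to relative frequencies.  Positively biased at small N.

``qe_correct``
    Quadratic-extrapolation bias correction of the plugin estimator:
    fit I_naive(N) = I_true + a/N + b/N**2 through the naive estimates
    at the full sample size, at halves, and at quarters, and report the
    extrapolated I_true.

Negative estimates (a known small-sample artifact of the neighbour
estimator) can be clamped to zero with :func:`clamp_mi`; clamping is
applied per estimate, before any averaging across cells.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma

from .samples import SampleSet

_LN2 = np.log(2.0)


@dataclass
class KnnDiagnostics:
    """Per-point records of the neighbour estimator (retained points only)."""

    n_si: np.ndarray  # same-label class size per retained point
    k_i: np.ndarray  # effective neighbour count used per point
    d_i: np.ndarray  # k-th same-label neighbour distance
    m_i: np.ndarray  # all-label neighbour count within d_i (excluding self)
    i_i: np.ndarray  # per-point contribution, nats
    skipped_points: int  # points excluded (singleton classes)


@dataclass
class BinnedJoint:
    """Stimulus x response-bin contingency table with its bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray  # shape (n_labels, n_bins), rows follow sorted alphabet


@dataclass
class QEFit:
    """Coefficients of the quadratic-extrapolation fit I_true + a/N + b/N^2."""

    i_true: float
    a: float
    b: float
    inputs: Sequence[tuple[float, float]]  # (sample size, naive estimate) pairs

    def predict(self, n: float) -> float:
        return self.i_true + self.a / n + self.b / n**2


@dataclass
class MIEstimate:
    """An MI value in bits plus estimator identity and diagnostics."""

    value_bits: float
    estimator: str  # 'knn' | 'binned_naive' | 'binned_qe'
    params: dict
    n_samples: int
    clamped: bool = False
    diagnostics: object = None

    def to_dict(self) -> dict:
        d = {
            "estimator": self.estimator,
            "params": self.params,
            "n_samples": self.n_samples,
            "value_bits": self.value_bits,
            "clamped": self.clamped,
        }
        if isinstance(self.diagnostics, KnnDiagnostics):
            d["skipped_points"] = self.diagnostics.skipped_points
        return d


def knn_mi(data: SampleSet, k: int = 3) -> MIEstimate:
    """Nearest-neighbour MI estimate between labels and responses, in bits.

    Parameters
    ----------
    data
        The labeled sample.
    k
        Nominal neighbour count.  Within a class of size ``N_Si`` the
        effective count is ``k_i = min(k, N_Si - 1)`` so that unbalanced
        designs remain estimable.

    Notes
    -----
    Distances are absolute differences on the response axis.  The
    all-label count ``m_i`` uses a closed ball (ties at exactly ``d_i``
    are counted); exact ties therefore inflate ``m_i`` slightly.
    The estimate is exactly invariant under affine response maps
    ``r -> a*r + c`` (a != 0) because all neighbour sets are preserved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    r = data.responses
    n = len(data)
    labels = data.labels
    order = np.argsort(r, kind="stable")
    r_sorted = r[order]

    n_si_out: list[np.ndarray] = []
    k_out: list[np.ndarray] = []
    d_out: list[np.ndarray] = []
    m_out: list[np.ndarray] = []
    i_out: list[np.ndarray] = []
    skipped = 0

    for lab in data.alphabet:
        idx = np.flatnonzero(labels == lab)
        n_s = idx.size
        if n_s < 2:
            skipped += n_s
            continue
        rv = np.sort(r[idx], kind="stable")
        k_i = min(k, n_s - 1)
        d_i = np.empty(n_s)
        m_i = np.empty(n_s, dtype=int)
        pad = 4.0 * np.finfo(float).eps
        for p in range(n_s):
            lo = max(0, p - k_i)
            hi = min(n_s, p + k_i + 1)
            w = np.abs(rv[lo:hi] - rv[p])
            # self distance 0 is always present once; the k_i-th order
            # statistic after it is the k_i-th same-label neighbour
            d = np.partition(w, k_i)[k_i]
            d_i[p] = d
            # candidate slab is padded so boundary points whose computed
            # |r_j - r_i| equals d are never lost to rounding of r +- d;
            # the exact closed-ball test then decides membership
            slack = pad * (abs(rv[p]) + d + 1.0)
            j0 = np.searchsorted(r_sorted, rv[p] - d - slack, side="left")
            j1 = np.searchsorted(r_sorted, rv[p] + d + slack, side="right")
            m_i[p] = int(
                (np.abs(r_sorted[j0:j1] - rv[p]) <= d).sum() - 1
            )
        i_i = digamma(n) - digamma(n_s) + digamma(k_i) - digamma(m_i)
        n_si_out.append(np.full(n_s, n_s))
        k_out.append(np.full(n_s, k_i))
        d_out.append(d_i)
        m_out.append(m_i)
        i_out.append(i_i)

    if not i_out:
        raise ValueError("no estimable points: every stimulus class has < 2 members")
    if skipped:
        warnings.warn(
            f"knn_mi: skipped {skipped} point(s) in singleton stimulus classes",
            stacklevel=2,
        )

    i_all = np.concatenate(i_out)
    diag = KnnDiagnostics(
        n_si=np.concatenate(n_si_out),
        k_i=np.concatenate(k_out),
        d_i=np.concatenate(d_out),
        m_i=np.concatenate(m_out),
        i_i=i_all,
        skipped_points=skipped,
    )
    return MIEstimate(
        value_bits=float(i_all.mean() / _LN2),
        estimator="knn",
        params={"k": k},
        n_samples=n,
        diagnostics=diag,
    )


def bin_responses(data: SampleSet, n_bins: int) -> BinnedJoint:
    """Equal-width binning of the responses over their observed range.

    The maximum response is assigned to the last bin; if every response
    is identical the single occupied bin is bin 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    r = data.responses
    lo, hi = float(r.min()), float(r.max())
    if hi > lo:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    else:
        edges = np.array([lo, lo])
        bins = np.zeros(len(data), dtype=int)
    alphabet, codes = np.unique(data.labels, return_inverse=True)
    counts = np.zeros((alphabet.size, n_bins), dtype=int)
    np.add.at(counts, (codes, bins), 1)
    return BinnedJoint(bin_edges=edges, counts=counts)


def _plugin_mi_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    ps = p.sum(axis=1, keepdims=True)
    pr = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (ps @ pr)[nz])))


def binned_mi_naive(data: SampleSet, n_bins: int) -> MIEstimate:
    """Plugin (naive) MI estimate from equal-width binned responses, bits."""
    joint = bin_responses(data, n_bins)
    return MIEstimate(
        value_bits=_plugin_mi_bits(joint.counts),
        estimator="binned_naive",
        params={"n_bins": n_bins},
        n_samples=len(data),
        diagnostics=joint,
    )


def qe_fit(points: Sequence[tuple[float, float]]) -> QEFit:
    """Solve I_naive(N) = I_true + a/N + b/N^2 through three (N, I) points."""
    if len(points) != 3:
        raise ValueError("qe_fit needs exactly three (N, I) points")
    ns = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    a_mat = np.column_stack([np.ones(3), 1.0 / ns, 1.0 / ns**2])
    try:
        coef = np.linalg.solve(a_mat, ys)
    except np.linalg.LinAlgError as exc:  # identical sample sizes
        raise ValueError(f"singular extrapolation system: {exc}") from exc
    return QEFit(i_true=float(coef[0]), a=float(coef[1]), b=float(coef[2]), inputs=list(points))


def qe_correct(data: SampleSet, n_bins: int, rng_seed: int) -> MIEstimate:
    """Quadratic-extrapolation-corrected binned MI estimate, in bits.

    The sample is split (seeded) into 2 random halves and, independently,
    4 random quarters; the naive estimates at N, N/2 (mean of halves) and
    N/4 (mean of quarters) determine the extrapolation to infinite N.
    """
    n = len(data)
    rng = np.random.default_rng(rng_seed)
    halves = np.array_split(rng.permutation(n), 2)
    quarters = np.array_split(rng.permutation(n), 4)
    if min(part.size for part in quarters) < 2:
        raise ValueError("sample too small to partition into quarters of >= 2")
    i_full = binned_mi_naive(data, n_bins).value_bits
    i_half = float(
        np.mean([binned_mi_naive(data.subset(p), n_bins).value_bits for p in halves])
    )
    i_quarter = float(
        np.mean([binned_mi_naive(data.subset(p), n_bins).value_bits for p in quarters])
    )
    fit = qe_fit([(n, i_full), (n / 2, i_half), (n / 4, i_quarter)])
    return MIEstimate(
        value_bits=fit.i_true,
        estimator="binned_qe",
        params={"n_bins": n_bins, "rng_seed": rng_seed},
        n_samples=n,
        diagnostics=fit,
    )


def clamp_mi(estimate: MIEstimate) -> MIEstimate:
    """Replace a negative MI value with zero and set the clamped flag.

    Applied per cell/feature estimate, before averaging across cells.
    """
    return dataclasses.replace(
        estimate, value_bits=max(0.0, estimate.value_bits), clamped=True
    )
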