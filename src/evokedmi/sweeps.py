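"""Trial sweeps and the evoked-potential feature front-end.

A :class:`Sweep` is one trial's voltage trace (PSP: whole-cell membrane
potential; LFP: nearby extracellular field), sampled at 4 kHz with the
tone onset 15 ms into the trace.  The front-end turns a raw sweep into
two scalar features per trial:

1. zero-phase low-pass filtering (least-squares FIR, order 39, 300 Hz
   cutoff, applied forward and backward),
2. baseline correction (subtract the mean potential over the first
   15 ms, i.e. the pre-stimulus interval),
3. feature extraction over the 15-100 ms analysis window:
   amplitude = window maximum - window minimum (mV), and
   latency = time from stimulus onset to the window maximum for PSP
   sweeps or the window minimum for LFP sweeps (ms).

Sweeps are stored on disk in an HDF5 layout
``/cells/{cell_id}/trials/{name}`` with per-trial attributes, or in a
plain-text one-CSV-per-cell format.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

SIGNAL_TYPES = ("PSP", "LFP")


@dataclass
class Sweep:
    """One trial's voltage trace with its acquisition metadata."""

    values: np.ndarray  # mV
    stimulus_freq_hz: float
    signal_type: str  # 'PSP' | 'LFP'
    cell_id: str = "cell0"
    trial_id: int = 0
    sampling_rate: float = 4000.0  # Hz
    onset_s: float = 0.015  # stimulus onset within the sweep

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"signal_type must be one of {SIGNAL_TYPES}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate


@dataclass
class FeatureRecord:
    """Per-trial evoked features: min-to-max amplitude and extremum latency."""

    cell_id: str
    trial_id: int
    stimulus_freq_hz: float
    amplitude_mv: float
    latency_ms: float
    degenerate: bool = False  # flat analysis window (dead sweep)


def design_lowpass_fir(
    cutoff_hz: float,
    sampling_rate: float,
    order: int = 39,
    transition: float = 0.15,
) -> np.ndarray:
    """Least-squares linear-phase low-pass FIR coefficients (order+1 taps).

    Desired response is 1 over [0, cutoff] and 0 over
    [cutoff*(1+transition), Nyquist]; the transition band is left free.
    The least-squares fit is solved on a dense frequency grid in the
    symmetric (type I/II) linear-phase basis, which supports both odd
    and even tap counts; taps are normalised to unit DC gain.
    """
    nyq = sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    numtaps = order + 1
    fp = cutoff_hz / nyq
    fs_ = min(1.0, fp * (1.0 + transition))
    npts = 2048
    w = np.pi * np.concatenate(
        [np.linspace(0.0, fp, npts), np.linspace(fs_, 1.0, npts)]
    )
    d = np.concatenate([np.ones(npts), np.zeros(npts)])
    if numtaps % 2:  # type I: h[M +- n], A(w) = c0 + sum 2 c_n cos(wn)
        m = (numtaps - 1) // 2
        basis = np.column_stack(
            [np.ones_like(w)] + [2.0 * np.cos(w * nn) for nn in range(1, m + 1)]
        )
        c, *_ = np.linalg.lstsq(basis, d, rcond=None)
        h = np.empty(numtaps)
        h[m] = c[0]
        for nn in range(1, m + 1):
            h[m + nn] = h[m - nn] = c[nn]
    else:  # type II: A(w) = sum 2 c_n cos(w(n+1/2))
        q = numtaps // 2
        basis = np.column_stack(
            [2.0 * np.cos(w * (nn + 0.5)) for nn in range(q)]
        )
        c, *_ = np.linalg.lstsq(basis, d, rcond=None)
        h = np.empty(numtaps)
        for nn in range(q):
            h[q + nn] = h[q - 1 - nn] = c[nn]
    return h / h.sum()  # exact unit DC gain


def fir_gain(
    taps: np.ndarray, freq_hz: float, sampling_rate: float, passes: int = 2
) -> float:
    """Magnitude response of the (two-pass, by default) filter at freq_hz."""
    _, resp = sps.freqz(taps, worN=[2 * np.pi * freq_hz / sampling_rate])
    return float(np.abs(resp[0]) ** passes)


def _filtfilt(taps: np.ndarray, values: np.ndarray, order: int) -> np.ndarray:
    # reflect padding, 3x filter order, as the front-end's edge convention
    return sps.filtfilt(taps, [1.0], values, padtype="even", padlen=3 * order, axis=-1)


def lowpass_filter(sweep: Sweep, cutoff_hz: float = 300.0, order: int = 39) -> Sweep:
    """Zero-phase low-pass filter a sweep (forward-backward FIR)."""
    taps = design_lowpass_fir(cutoff_hz, sweep.sampling_rate, order)
    if len(sweep.values) < 3 * len(taps):
        raise ValueError("sweep too short to filter")
    return dataclasses.replace(sweep, values=_filtfilt(taps, sweep.values, order))


def lowpass_filter_batch(
    values: np.ndarray,
    sampling_rate: float = 4000.0,
    cutoff_hz: float = 300.0,
    order: int = 39,
) -> np.ndarray:
    """Filter a (trials x samples) matrix of equal-length sweeps in one pass."""
    taps = design_lowpass_fir(cutoff_hz, sampling_rate, order)
    if values.shape[-1] < 3 * len(taps):
        raise ValueError("sweep too short to filter")
    return _filtfilt(taps, values, order)


def baseline_correct(sweep: Sweep) -> Sweep:
    """Subtract the mean potential over the pre-stimulus interval [0, onset)."""
    n0 = int(round(sweep.onset_s * sweep.sampling_rate))
    if n0 < 1:
        raise ValueError("no baseline interval (onset_s must be > 0)")
    return dataclasses.replace(sweep, values=sweep.values - sweep.values[:n0].mean())


def extract_features(
    sweep: Sweep, window: tuple[float, float] = (0.015, 0.100)
) -> FeatureRecord:
    """Amplitude and latency of a filtered, baseline-corrected sweep.

    The analysis window is half-open, ``[window[0], window[1])`` in
    seconds from the start of the sweep.  Amplitude is max - min over
    the window.  Latency runs from stimulus onset to the window maximum
    (PSP) or minimum (LFP); ties resolve to the earliest sample.  A flat
    window yields amplitude 0 / latency 0 flagged degenerate rather than
    an error, so batch runs survive dead sweeps.
    """
    fs = sweep.sampling_rate
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    if i0 < 0 or i1 > len(sweep.values) or i1 <= i0:
        raise ValueError("analysis window outside sweep")
    seg = sweep.values[i0:i1]
    amplitude = float(seg.max() - seg.min())
    ext = int(np.argmax(seg) if sweep.signal_type == "PSP" else np.argmin(seg))
    latency_ms = ((i0 + ext) / fs - sweep.onset_s) * 1000.0
    return FeatureRecord(
        cell_id=sweep.cell_id,
        trial_id=sweep.trial_id,
        stimulus_freq_hz=sweep.stimulus_freq_hz,
        amplitude_mv=amplitude,
        latency_ms=latency_ms,
        degenerate=amplitude == 0.0,
    )


def features_to_frame(records: Iterable[FeatureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "trial_id": r.trial_id,
                "stimulus_freq_hz": r.stimulus_freq_hz,
                "amplitude_mv": r.amplitude_mv,
                "latency_ms": r.latency_ms,
            }
            for r in records
        ]
    )


# -- sweep store (HDF5) ------------------------------------------------


def write_sweep_store(path, sweeps: Iterable[Sweep]) -> None:
    """Write sweeps to ``/cells/{cell_id}/trials/{name}`` HDF5 layout."""
    with h5py.File(path, "w") as f:
        for sw in sweeps:
            grp = f.require_group(f"cells/{sw.cell_id}/trials")
            ds = grp.create_dataset(
                f"t{sw.trial_id:06d}_{sw.signal_type}", data=sw.values
            )
            ds.attrs["stimulus_freq_hz"] = sw.stimulus_freq_hz
            ds.attrs["signal_type"] = sw.signal_type
            ds.attrs["onset_s"] = sw.onset_s
            ds.attrs["sampling_rate"] = sw.sampling_rate
            ds.attrs["trial_id"] = sw.trial_id


def read_sweep_store(path) -> list[Sweep]:
    sweeps = []
    with h5py.File(path, "r") as f:
        for cell_id in sorted(f["cells"]):
            trials = f[f"cells/{cell_id}/trials"]
            for name in sorted(trials):
                ds = trials[name]
                sweeps.append(
                    Sweep(
                        values=ds[...],
                        stimulus_freq_hz=float(ds.attrs["stimulus_freq_hz"]),
                        signal_type=str(ds.attrs["signal_type"]),
                        cell_id=cell_id,
                        trial_id=int(ds.attrs["trial_id"]),
                        sampling_rate=float(ds.attrs["sampling_rate"]),
                        onset_s=float(ds.attrs["onset_s"]),
                    )
                )
    return sweeps


def read_sweeps_csv(
    path,
    cell_id: str,
    signal_type: str,
    sampling_rate: float = 4000.0,
    onset_s: float = 0.015,
) -> list[Sweep]:
    """Plain-text alternative store: one CSV per cell.

    Columns: ``trial_id,stimulus_freq_hz,t0,t1,...`` with one row per
    trial and the voltage samples in the ``t*`` columns.
    """
    df = pd.read_csv(path, comment="#")
    sample_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    return [
        Sweep(
            values=row[sample_cols].to_numpy(dtype=float),
            stimulus_freq_hz=float(row["stimulus_freq_hz"]),
            signal_type=signal_type,
            cell_id=cell_id,
            trial_id=int(row["trial_id"]),
            sampling_rate=sampling_rate,
            onset_s=onset_s,
        )
        for _, row in df.iterrows()
    ]


def read_crcns_recording(path):  # pragma: no cover - stub interface
    """Adapter stub for the original whole-cell/LFP recordings.

    The on-disk format of the original dataset is not published with the
    analysis; this hook exists so a reader can be plugged in by users
    who obtain the recordings, and deliberately does nothing else.
    """
    raise NotImplementedError(
        "no reader for the original recordings is bundled; "
        "convert them to the HDF5/CSV sweep store instead"
    )
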