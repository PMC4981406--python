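"""Synthetic tone-mapping experiments with known information content.

Emulates the structure of the whole-cell + field-potential tone study:
32 tone frequencies logarithmically spaced from 2 kHz to 46,731 Hz,
25 ms tones presented in pseudo-random order, and simultaneous PSP and
LFP sweeps per trial (4 kHz sampling, onset 15 ms into the sweep).

Each simulated cell is a pair of :class:`TuningModel` s (one per signal
type).  A model maps tone frequency to a mean evoked amplitude through
a Gaussian tuning curve in log-frequency; per-trial amplitudes add
Gaussian noise, the evoked deflection is an alpha-shaped transient
(peak value equal to the drawn amplitude), latencies jitter around a
base value, and white background noise is added to the trace.  LFP
models flip polarity (downward deflection) and scale by a gain factor,
reflecting the summation of many neurons' subthreshold activity.

Because the amplitude feature of such a cell is (near-)Gaussian given
the tone, the true stimulus-response MI of a model is computable with
the mixture machinery (:func:`model_true_mi`), which makes end-to-end
parameter recovery testable without any real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mixtures import Gaussian, MixtureSpec, true_mi
from .sweeps import Sweep


@dataclass
class TuningModel:
    """Frequency-tuned evoked-response model for one signal type.

    The mean (pre-gain) evoked amplitude at tone frequency f is

        baseline + (max - baseline) * exp(-0.5 * (log2(f/pref) / width)**2)

    in mV; the realised deflection is ``polarity * gain * a`` with
    ``a ~ N(mean, amplitude_noise_sd**2)``.  The baseline keeps draws
    well away from zero so the amplitude feature stays Gaussian.
    """

    preferred_freq_hz: float = 9600.0
    tuning_width_octaves: float = 1.5
    max_amplitude_mv: float = 6.0
    baseline_amplitude_mv: float = 3.0
    amplitude_noise_sd_mv: float = 0.7
    latency_base_ms: float = 25.0
    latency_jitter_sd_ms: float = 1.5
    background_noise_sd_mv: float = 0.1
    polarity: int = 1  # +1 PSP (upward), -1 LFP (downward)
    gain: float = 1.0  # LFP amplitude multiplier

    def __post_init__(self) -> None:
        if self.tuning_width_octaves <= 0 or self.gain <= 0:
            raise ValueError("tuning width and gain must be positive")
        if self.amplitude_noise_sd_mv < 0 or self.background_noise_sd_mv < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")

    def mean_amplitude_mv(self, freq_hz) -> np.ndarray:
        """Mean pre-gain evoked amplitude (mV) at the given frequencies."""
        z = np.log2(np.asarray(freq_hz, dtype=float) / self.preferred_freq_hz)
        shape = np.exp(-0.5 * (z / self.tuning_width_octaves) ** 2)
        return self.baseline_amplitude_mv + (
            self.max_amplitude_mv - self.baseline_amplitude_mv
        ) * shape

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CellModel:
    """One simulated cell: paired PSP and LFP tuning models plus a group tag."""

    cell_id: str
    psp: TuningModel
    lfp: TuningModel
    group: str = "all"  # e.g. anesthetic group label


@dataclass
class ExperimentSpec:
    """Layout of a synthetic tone experiment."""

    n_freqs: int = 32
    freq_lo_hz: float = 2000.0
    freq_hi_hz: float = 46731.0
    tone_dur_ms: float = 25.0
    trials_per_freq: int = 50
    cells: Sequence[CellModel] = field(default_factory=list)
    sampling_rate: float = 4000.0
    onset_s: float = 0.015
    sweep_duration_s: float = 0.110
    rise_tau_ms: float = 10.0  # alpha-function time-to-peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_freqs < 2 or self.trials_per_freq < 1:
            raise ValueError("need >= 2 frequencies and >= 1 trial per frequency")
        if self.sweep_duration_s < self.onset_s + 0.085:
            raise ValueError("sweep must cover the 15-100 ms analysis window")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "cells"
        }
        d["cells"] = [
            {
                "cell_id": c.cell_id,
                "group": c.group,
                "psp": c.psp.to_dict(),
                "lfp": c.lfp.to_dict(),
            }
            for c in self.cells
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        d = dict(d)
        cells = [
            CellModel(
                cell_id=c["cell_id"],
                group=c.get("group", "all"),
                psp=TuningModel(**c["psp"]),
                lfp=TuningModel(**c["lfp"]),
            )
            for c in d.pop("cells", [])
        ]
        return cls(cells=cells, **d)


def make_frequency_grid(spec: ExperimentSpec) -> np.ndarray:
    """The tone frequencies: a geometric progression with exact endpoints."""
    return np.geomspace(spec.freq_lo_hz, spec.freq_hi_hz, spec.n_freqs)


def _stimulus_order(rng: np.random.Generator, spec: ExperimentSpec) -> np.ndarray:
    # balanced pseudo-random order: a fresh permutation of all 32 tones
    # per block, so every tone appears exactly trials_per_freq times
    return np.concatenate(
        [rng.permutation(spec.n_freqs) for _ in range(spec.trials_per_freq)]
    )


def generate_sweeps(spec: ExperimentSpec) -> list[Sweep]:
    """Simulate all PSP and LFP sweeps of an experiment, reproducibly.

    Per cell: one pseudo-random stimulus order shared by both signal
    types (the recordings are simultaneous), then per signal a vector
    of drawn amplitudes, jittered latencies and background noise.  The
    evoked transient is ``a * (t'/tau) * exp(1 - t'/tau)`` for
    ``t' = t - t_start > 0``, which peaks at exactly ``a`` one tau after
    its start; ``t_start`` is placed so the peak lands at the drawn
    latency after stimulus onset.
    """
    if not spec.cells:
        raise ValueError("spec has no cells")
    rng = np.random.default_rng(spec.seed)
    freqs = make_frequency_grid(spec)
    n_samp = int(round(spec.sweep_duration_s * spec.sampling_rate))
    t = np.arange(n_samp) / spec.sampling_rate
    tau = spec.rise_tau_ms / 1000.0
    sweeps: list[Sweep] = []
    for cell in spec.cells:
        order = _stimulus_order(rng, spec)
        n_trials = order.size
        for signal_type, model in (("PSP", cell.psp), ("LFP", cell.lfp)):
            amps = rng.normal(
                model.mean_amplitude_mv(freqs[order]),
                model.amplitude_noise_sd_mv,
            )
            lats_s = (
                rng.normal(model.latency_base_ms, model.latency_jitter_sd_ms, n_trials)
                / 1000.0
            )
            noise = rng.normal(0.0, model.background_noise_sd_mv, (n_trials, n_samp))
            t_start = spec.onset_s + lats_s - tau  # peak at onset + latency
            x = (t[None, :] - t_start[:, None]) / tau
            shape = np.where(x > 0, x * np.exp(1.0 - np.clip(x, None, 500.0)), 0.0)
            traces = model.polarity * model.gain * amps[:, None] * shape + noise
            for ti in range(n_trials):
                sweeps.append(
                    Sweep(
                        values=traces[ti],
                        stimulus_freq_hz=float(freqs[order[ti]]),
                        signal_type=signal_type,
                        cell_id=cell.cell_id,
                        trial_id=ti,
                        sampling_rate=spec.sampling_rate,
                        onset_s=spec.onset_s,
                    )
                )
    return sweeps


def model_true_mi(model: TuningModel, spec: ExperimentSpec) -> float:
    """True MI (bits) between the uniform tone variable and the amplitude feature.

    The amplitude feature of the model is Gaussian given the tone:
    mean ``gain * mean_amplitude(f)``, SD ``gain * amplitude_noise_sd``
    (polarity does not affect a min-to-max amplitude).  The 32-component
    Gaussian mixture is handed to the quadrature ground-truth machinery.
    """
    if model.amplitude_noise_sd_mv <= 0:
        raise ValueError("amplitude noise SD must be > 0 for a finite MI")
    freqs = make_frequency_grid(spec)
    means = model.gain * model.mean_amplitude_mv(freqs)
    sd = model.gain * model.amplitude_noise_sd_mv
    mix = MixtureSpec(
        np.full(spec.n_freqs, 1.0 / spec.n_freqs),
        [Gaussian(float(m), sd) for m in means],
    )
    return true_mi(mix, method="quadrature")


def default_population(
    n_cells: int = 33,
    seed: int = 0,
    lfp_gain: float = 3.0,
    lfp_noise_sd_mv: float = 0.55,
    psp_noise_sd_mv: float = 0.8,
) -> list[CellModel]:
    """A study-scale population of paired PSP/LFP models.

    Preferred frequencies are log-uniform over the tone range and tuning
    widths vary between 1 and 2 octaves, so cells differ in how much
    stimulus information their amplitudes carry.  LFP models share each
    cell's tuning but carry a gain > 1 and a smaller pre-gain amplitude
    noise, encoding the population-summation picture in which the field
    signal has the better amplitude signal-to-noise; the LFP > PSP
    amplitude-information ordering is therefore built in.  The first
    ``n_cells // 2`` cells are tagged ``pentobarbital`` and the rest
    ``urethane`` (16/17 at the default population size).
    """
    rng = np.random.default_rng(seed)
    cells = []
    n_pent = n_cells // 2
    for i in range(n_cells):
        pref = float(np.exp(rng.uniform(np.log(2000.0), np.log(46731.0))))
        width = float(rng.uniform(1.0, 2.0))
        max_amp = float(rng.uniform(5.0, 7.0))
        common = dict(
            preferred_freq_hz=pref,
            tuning_width_octaves=width,
            max_amplitude_mv=max_amp,
            baseline_amplitude_mv=2.5,
        )
        cells.append(
            CellModel(
                cell_id=f"cell{i:02d}",
                psp=TuningModel(
                    **common, amplitude_noise_sd_mv=psp_noise_sd_mv, polarity=1
                ),
                lfp=TuningModel(
                    **common,
                    amplitude_noise_sd_mv=lfp_noise_sd_mv,
                    polarity=-1,
                    gain=lfp_gain,
                ),
                group="pentobarbital" if i < n_pent else "urethane",
            )
        )
    return cells
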