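"""Containers for labeled (stimulus, response) data.

A :class:`SampleSet` holds paired observations of a discrete stimulus
(e.g. a tone-frequency index, or a simulated mixture class) and a
continuous scalar response (e.g. an evoked-potential amplitude in mV or
a latency in ms).  It is the common currency of the mutual-information
estimators, the mixture sampler and the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd


class LabeledSample(NamedTuple):
    """One (stimulus category, continuous response) observation."""

    stimulus: object
    response: float


@dataclass
class SampleSet:
    """Paired stimulus labels and continuous responses.

    Parameters
    ----------
    labels
        Discrete stimulus labels, one per observation.  Any hashable
        dtype; typically small integers (tone index, mixture class).
    responses
        Continuous responses, one per observation.  Must be finite.
    """

    labels: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.labels.shape != self.responses.shape or self.labels.ndim != 1:
            raise ValueError("labels and responses must be 1-D and the same length")
        if self.labels.size < 1:
            raise ValueError("SampleSet needs at least one sample")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def alphabet(self) -> np.ndarray:
        """Distinct stimulus labels, sorted."""
        return np.unique(self.labels)

    @property
    def samples(self) -> Iterator[LabeledSample]:
        for s, r in zip(self.labels, self.responses):
            yield LabeledSample(s, float(r))

    def subset(self, indices: np.ndarray) -> "SampleSet":
        indices = np.asarray(indices)
        return SampleSet(self.labels[indices], self.responses[indices])

    # -- CSV interchange (columns: stimulus,response) ------------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"stimulus": self.labels, "response": self.responses}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        df = pd.read_csv(path, comment="#")
        return cls(df["stimulus"].to_numpy(), df["response"].to_numpy())
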