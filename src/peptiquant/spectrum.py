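"""The Spectrum container shared by the generator, the processors and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict

import numpy as np

from .errors import InputError


@dataclass
class Spectrum:
    """An (m/z, intensity) trace with acquisition metadata.

    Invariants: equal-length arrays, strictly increasing m/z, finite
    non-negative intensities. Enforced at construction.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise InputError("m/z and intensity must be 1-D arrays")
        if self.mz.shape != self.intensity.shape:
            raise InputError("m/z and intensity arrays must have equal length")
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            raise InputError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise InputError("intensities must be finite")
        if np.any(self.intensity < 0):
            raise InputError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def copy_with(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.mz.copy(), intensity, dict(self.metadata))
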