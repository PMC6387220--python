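"""Core signal containers shared by the whole pipeline.

A trial is captured as a :class:`Recording` (one array per electrode
channel); the per-channel conditioning stage turns each channel into a
:class:`CleanSignal`, the zero-mean, activity-only sequence every feature
extractor downstream assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sampling rate of the study protocol, Hz.
DEFAULT_FS = 500.0

#: The six hand-grasp classes, in canonical order.
GESTURES = ("spherical", "tip", "palmar", "lateral", "cylindrical", "hook")


def _as_samples(x, name: str = "samples") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"{name} must contain at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class RawSignal:
    """Single-channel raw sEMG amplitude sequence.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values (arbitrary units, typically mV).
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", _as_samples(self.samples))
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class CleanSignal:
    """Zero-mean, onset-trimmed single-channel signal.

    The zero-mean invariant is enforced at construction: the mean must be
    negligible relative to the signal RMS (|mean| <= 1e-9 * (RMS + eps)).
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    n_trimmed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", _as_samples(self.samples))
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.n_trimmed < 0:
            raise ValueError("n_trimmed must be non-negative")
        rms = float(np.sqrt(np.mean(self.samples**2)))
        mean = float(np.mean(self.samples))
        if abs(mean) > 1e-9 * (rms + np.finfo(float).eps):
            raise ValueError(
                f"CleanSignal must be zero-mean: |mean|={abs(mean):.3e}, rms={rms:.3e}"
            )

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Recording:
    """One multi-channel sEMG trial with its provenance.

    channels maps channel name -> raw sample array; insertion order is the
    channel concatenation order used when patterns are built.
    """

    channels: dict = field(default_factory=dict)
    fs: float = DEFAULT_FS
    label: str = ""
    subject: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Recording needs at least one channel")
        coerced = {
            name: _as_samples(samples, name=f"channel {name!r}")
            for name, samples in self.channels.items()
        }
        object.__setattr__(self, "channels", coerced)
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, name: str) -> RawSignal:
        return RawSignal(self.channels[name], fs=self.fs)
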