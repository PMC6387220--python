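"""Signal conditioning: onset trimming and mean removal.

The recordings begin with a stretch in which the muscle is not yet active
and the trace carries only baseline noise.  Conditioning (i) drops that
leading inactive segment and (ii) subtracts the arithmetic mean, because
the linear-prediction machinery downstream (Burg / Yule-Walker) assumes a
zero-mean process.  Both steps are linear in the signal length.

The onset rule is a sliding-window RMS detector: the signal is kept from
the first window whose RMS reaches ``onset_fraction`` of the whole-signal
RMS.  The rule is scale-invariant and never removes more than half the
signal, so a degenerate noise-only input still yields a usable sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import CleanSignal, RawSignal


@dataclass(frozen=True)
class TrimConfig:
    """Onset-trimming parameters.

    window_len : int
        Sliding-window length in samples (25 samples = 50 ms at 500 Hz).
    onset_fraction : float
        Window-RMS threshold as a fraction of whole-signal RMS, in (0, 1].
    enabled : bool
        When False, trimming is the identity.
    """

    window_len: int = 25
    onset_fraction: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not (0.0 < self.onset_fraction <= 1.0):
            raise ValueError("onset_fraction must lie in (0, 1]")


def trim_inactive(signal: RawSignal, cfg: TrimConfig = TrimConfig()) -> RawSignal:
    """Drop the leading low-activity segment of a raw signal.

    Returns the suffix starting at the first sliding window whose RMS is at
    least ``cfg.onset_fraction`` times the whole-signal RMS.  At most half
    the signal is ever removed; if no window qualifies or trimming is
    disabled the input is returned unchanged.
    """
    if not cfg.enabled:
        return signal
    x = signal.samples
    n = x.size
    if n < cfg.window_len:
        raise ValueError(
            f"signal length {n} is shorter than trim window {cfg.window_len}"
        )
    global_rms = float(np.sqrt(np.mean(x**2)))
    if global_rms == 0.0:
        return signal
    # window mean-square via cumulative sum: O(N)
    sq = np.concatenate(([0.0], np.cumsum(x**2)))
    w = cfg.window_len
    win_ms = (sq[w:] - sq[:-w]) / w  # mean square of windows starting at 0..n-w
    threshold_ms = (cfg.onset_fraction * global_rms) ** 2
    hits = np.nonzero(win_ms >= threshold_ms)[0]
    start = int(hits[0]) if hits.size else 0
    start = min(start, n // 2)  # never drop more than half the signal
    if start == 0:
        return signal
    return RawSignal(x[start:], fs=signal.fs)


def remove_mean(signal: RawSignal, n_trimmed: int = 0) -> CleanSignal:
    """Subtract the arithmetic mean, yielding a zero-mean CleanSignal."""
    x = signal.samples
    centred = x - np.mean(x)
    # guard against accumulated rounding on huge offsets
    centred = centred - np.mean(centred)
    return CleanSignal(centred, fs=signal.fs, n_trimmed=n_trimmed)


def preprocess(signal: RawSignal, cfg: TrimConfig = TrimConfig()) -> CleanSignal:
    """Full conditioning: trim the inactive onset, then remove the mean."""
    trimmed = trim_inactive(signal, cfg)
    n_trimmed = len(signal) - len(trimmed)
    return remove_mean(trimmed, n_trimmed=n_trimmed)
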