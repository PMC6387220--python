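"""Time-domain sEMG features.

Ten standard descriptors of a conditioned (zero-mean) signal:

* energy/amplitude statistics — IEMG, MAV, SSI, VAR, RMS, WL;
* thresholded event counts — ZC (zero crossings), SSC (slope-sign
  changes), WAMP (Willison amplitude), MYOP (myopulse percentage rate).

Conventions, with x_0..x_{N-1} the samples:

    IEMG = sum |x_n|                       MAV  = IEMG / N
    SSI  = sum x_n^2                       VAR  = SSI / (N - 1)
    RMS  = sqrt(SSI / N)                   WL   = sum_{n<N-1} |x_{n+1}-x_n|
    ZC   = #{n : x_n * x_{n+1} < -zc_th and |x_n - x_{n+1}| >= zc_th}
    SSC  = #{n : (x_n - x_{n-1})(x_n - x_{n+1}) >= ssc_th}   (strict > 0 when th = 0)
    WAMP = #{n : |x_n - x_{n+1}| >= wamp_th} / N
    MYOP = #{n : |x_n| >= myop_th} / N

VAR keeps the zero-mean convention of the conditioning stage (no internal
mean re-subtraction).  The event-count thresholds exist to ignore baseline
noise; the amplitude-scale thresholds default to 5% of the signal RMS so
they track the recording's gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signals import CleanSignal

#: Canonical serialization order of the time-domain block.
TD_FEATURE_NAMES = ("IEMG", "MAV", "SSI", "VAR", "RMS", "WL", "WAMP", "SSC", "ZC", "MYOP")

#: Default relative threshold (fraction of signal RMS) for WAMP and MYOP.
DEFAULT_RELATIVE_TH = 0.05


@dataclass(frozen=True)
class ThresholdConfig:
    """Event-count thresholds.

    ``wamp_th`` / ``myop_th`` set to None mean "5% of the signal RMS",
    resolved per signal; explicit values are absolute amplitudes.
    """

    zc_th: float = 0.0
    ssc_th: float = 0.0
    wamp_th: Optional[float] = None
    myop_th: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("zc_th", "ssc_th", "wamp_th", "myop_th"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def resolve(self, rms: float) -> "ThresholdConfig":
        """Replace relative (None) thresholds by absolute values for a given RMS."""
        rel = DEFAULT_RELATIVE_TH * rms
        return ThresholdConfig(
            zc_th=self.zc_th,
            ssc_th=self.ssc_th,
            wamp_th=rel if self.wamp_th is None else self.wamp_th,
            myop_th=rel if self.myop_th is None else self.myop_th,
        )


@dataclass(frozen=True)
class TDVector:
    """The ten time-domain features, in canonical order."""

    iemg: float
    mav: float
    ssi: float
    var: float
    rms: float
    wl: float
    wamp: float
    ssc: int
    zc: int
    myop: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.iemg, self.mav, self.ssi, self.var, self.rms, self.wl,
             self.wamp, self.ssc, self.zc, self.myop],
            dtype=float,
        )


def energy_features(signal: CleanSignal):
    """IEMG, MAV, SSI, VAR, RMS and waveform length of a signal."""
    x = signal.samples
    n = x.size
    iemg = float(np.sum(np.abs(x)))
    ssi = float(np.sum(x**2))
    return (
        iemg,
        iemg / n,
        ssi,
        ssi / (n - 1),
        float(np.sqrt(ssi / n)),
        float(np.sum(np.abs(np.diff(x)))),
    )


def count_features(signal: CleanSignal, th: ThresholdConfig = ThresholdConfig()):
    """Thresholded event counts: ZC, SSC, WAMP, MYOP."""
    x = signal.samples
    n = x.size
    if n < 3:
        raise ValueError("count features need at least 3 samples")
    t = th.resolve(float(np.sqrt(np.mean(x**2))))

    prod = x[:-1] * x[1:]
    step = np.abs(np.diff(x))
    zc = int(np.count_nonzero((prod < -t.zc_th) & (step >= t.zc_th)))

    slope_prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    if t.ssc_th > 0:
        ssc = int(np.count_nonzero(slope_prod >= t.ssc_th))
    else:
        ssc = int(np.count_nonzero(slope_prod > 0))

    wamp = float(np.count_nonzero(step >= t.wamp_th)) / n if t.wamp_th > 0 else float(
        np.count_nonzero(step > 0)) / n
    myop = float(np.count_nonzero(np.abs(x) >= t.myop_th)) / n if t.myop_th > 0 else float(
        np.count_nonzero(np.abs(x) > 0)) / n
    return zc, ssc, wamp, myop


def td_vector(signal: CleanSignal, th: ThresholdConfig = ThresholdConfig()) -> TDVector:
    """All ten time-domain features in the canonical order."""
    iemg, mav, ssi, var, rms, wl = energy_features(signal)
    zc, ssc, wamp, myop = count_features(signal, th)
    return TDVector(iemg=iemg, mav=mav, ssi=ssi, var=var, rms=rms, wl=wl,
                    wamp=wamp, ssc=ssc, zc=zc, myop=myop)
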