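"""Burg maximal-entropy AR estimation via the lattice prediction filter.

The estimator fits an autoregressive model of order ``p`` to a zero-mean
signal by minimising, stage by stage, the summed power of the forward and
backward prediction errors of a lattice filter:

    f_0(n) = b_0(n) = x(n)
    f_m(n) = f_{m-1}(n) + K_m b_{m-1}(n-1)
    b_m(n) = K_m f_{m-1}(n) + b_{m-1}(n-1)

Minimising  eps_m = sum_n [ f_m(n)^2 + b_m(n)^2 ]  over K_m gives the
reflection coefficient of stage m as a harmonic-mean-normalised
cross-correlation of the stage m-1 errors,

    K_m = -2 sum_n f_{m-1}(n) b_{m-1}(n-1)
          / sum_n [ f_{m-1}(n)^2 + b_{m-1}(n-1)^2 ],

with the sums over the n where both terms exist (n = m..N-1, 0-based).
By the AM-GM inequality |K_m| <= 1 always, and eps_m is non-increasing
in m.  The AR coefficients follow from the reflection coefficients by the
Levinson step-up recursion

    a_m(k) = a_{m-1}(k) + K_m a_{m-1}(m-k),   a_m(m) = K_m.

Sign convention
---------------
``K`` and ``a`` are stored in the lattice (monic prediction-error-filter)
convention: A(z) = 1 + sum_k a_k z^-k whitens the signal, i.e.
e[n] = x[n] + sum_k a_k x[n-k].  The coefficients of the generative form
x[n] = sum_k phi_k x[n-k] + e[n] used by most AR references (and by
:func:`yule_walker` here) are the negation; results expose them as
``arcoefs_ar``.  Under this convention an alternating signal
+1,-1,+1,... has K_1 = +1 and a constant signal has K_1 = -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import statsmodels.api as _sm

from .signals import CleanSignal

ArrayLike = Union[np.ndarray, Sequence[float], CleanSignal]


def _signal_array(x: ArrayLike) -> np.ndarray:
    if isinstance(x, CleanSignal):
        return x.samples
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# lattice primitives


@dataclass(frozen=True)
class LatticeState:
    """Forward/backward prediction errors at one lattice stage.

    ``f`` and ``b`` hold f_m(n) and b_m(n) for n = stage..N-1, so both
    arrays have length N - stage.
    """

    f: np.ndarray
    b: np.ndarray
    stage: int

    def __post_init__(self) -> None:
        if self.f.shape != self.b.shape:
            raise ValueError("forward/backward error arrays must match in shape")
        if self.stage < 0:
            raise ValueError("stage must be >= 0")


def lattice_errors(signal: ArrayLike, k: Sequence[float], stage: int) -> LatticeState:
    """Run the lattice recursion up to ``stage`` with given reflection coefficients.

    Stage 0 returns f_0 = b_0 = x.  Exposed for inspection and testing of
    the recursion itself; the estimator recomputes these internally.
    """
    x = _signal_array(signal)
    k = np.asarray(k, dtype=float)
    if stage > k.size:
        raise ValueError(f"stage {stage} exceeds the {k.size} supplied coefficients")
    f = x.copy()
    b = x.copy()
    for m in range(1, stage + 1):
        f_prev = f[1:]       # f_{m-1}(n), n = m..
        b_prev = b[:-1]      # b_{m-1}(n-1), n = m..
        f = f_prev + k[m - 1] * b_prev
        b = k[m - 1] * f_prev + b_prev
    return LatticeState(f=f, b=b, stage=stage)


def prediction_error_power(state: LatticeState) -> float:
    """Summed forward+backward squared prediction error of a lattice stage."""
    return float(np.sum(state.f**2) + np.sum(state.b**2))


def levinson_from_reflection(k: Sequence[float]) -> np.ndarray:
    """Levinson step-up: reflection coefficients -> final-order AR coefficients.

    Returns a_p(1..p) in the lattice convention (a_m(m) = K_m).  Rejects
    any |K_m| > 1, which would correspond to an unstable model.
    """
    k = np.asarray(k, dtype=float)
    if k.ndim != 1 or k.size == 0:
        raise ValueError("need a non-empty 1-D sequence of reflection coefficients")
    if np.any(np.abs(k) > 1.0 + 1e-12):
        bad = int(np.argmax(np.abs(k) > 1.0 + 1e-12)) + 1
        raise ValueError(f"|K_{bad}| > 1: unstable reflection coefficients")
    a = np.zeros(0)
    for m, km in enumerate(k, start=1):
        a_new = np.empty(m)
        a_new[: m - 1] = a + km * a[::-1]
        a_new[m - 1] = km
        a = a_new
    return a


# ---------------------------------------------------------------------------
# model / results


class BurgAR:
    """Autoregressive model of a zero-mean signal, fitted by the Burg lattice.

    Parameters
    ----------
    endog : array-like or CleanSignal
        The (zero-mean) sample sequence.
    order : int
        AR model order p (number of reflection coefficients); the study
        default is 10 per channel.

    Examples
    --------
    >>> import numpy as np
    >>> x = np.sin(0.3 * np.arange(200)) + 0.01
    >>> res = BurgAR(x - x.mean(), order=2).fit()
    >>> res.k.shape
    (2,)
    """

    def __init__(self, endog: ArrayLike, order: int = 10):
        self.endog = _signal_array(endog)
        if order < 1:
            raise ValueError("order must be >= 1")
        if self.endog.size <= order:
            raise ValueError(
                f"need more samples ({self.endog.size}) than the model order ({order})"
            )
        self.order = int(order)

    @classmethod
    def from_signal(cls, signal: CleanSignal, order: int = 10) -> "BurgAR":
        return cls(signal, order=order)

    def fit(self) -> "BurgARResults":
        x = self.endog
        p = self.order
        n = x.size
        if not np.any(x != 0.0):
            raise ValueError("zero-energy signal: reflection coefficients undefined")
        f = x.copy()
        b = x.copy()
        k = np.zeros(p)
        eps = np.zeros(p + 1)
        eps[0] = 2.0 * float(np.sum(x**2))
        for m in range(1, p + 1):
            f_prev = f[1:]
            b_prev = b[:-1]
            den = float(np.sum(f_prev**2) + np.sum(b_prev**2))
            if den == 0.0:
                # signal already perfectly predicted; remaining stages carry
                # no information
                k[m - 1 :] = 0.0
                eps[m:] = 0.0
                break
            km = -2.0 * float(np.sum(f_prev * b_prev)) / den
            k[m - 1] = km
            f = f_prev + km * b_prev
            b = km * f_prev + b_prev
            eps[m] = float(np.sum(f**2) + np.sum(b**2))
        a = levinson_from_reflection(k)
        return BurgARResults(model=self, k=k, arcoefs=a, eps=eps, nobs=n)


@dataclass(frozen=True)
class BurgARResults:
    """Fitted Burg AR model.

    Attributes
    ----------
    k : ndarray
        Reflection coefficients K_1..K_p; |K_m| <= 1.
    arcoefs : ndarray
        AR coefficients a_p(1..p) in the lattice convention
        (prediction-error filter A(z) = 1 + sum a_k z^-k).
    eps : ndarray
        Per-stage summed forward+backward error powers eps_0..eps_p,
        non-increasing.
    nobs : int
        Number of samples the model was fitted to.
    """

    model: BurgAR
    k: np.ndarray
    arcoefs: np.ndarray
    eps: np.ndarray
    nobs: int

    @property
    def order(self) -> int:
        return self.k.size

    @property
    def arcoefs_ar(self) -> np.ndarray:
        """Coefficients of the generative form x[n] = sum phi_k x[n-k] + e[n]."""
        return -self.arcoefs

    @property
    def sigma2(self) -> float:
        """Innovation-variance estimate from the final-stage error power."""
        # eps_p sums forward+backward squared errors over nobs - order terms
        n_terms = self.nobs - self.order
        return float(self.eps[-1] / (2.0 * max(n_terms, 1)))

    def summary(self) -> str:
        lines = [
            "Burg AR model (lattice / maximal entropy)",
            f"  order: {self.order}    nobs: {self.nobs}    sigma2: {self.sigma2:.6g}",
            f"  {'stage':>5}  {'K_m':>12}  {'a_p(m)':>12}  {'eps_m':>14}",
        ]
        for m in range(self.order):
            lines.append(
                f"  {m + 1:>5}  {self.k[m]:>12.6f}  {self.arcoefs[m]:>12.6f}"
                f"  {self.eps[m + 1]:>14.6g}"
            )
        return "\n".join(lines)


def burg_reflection(signal: ArrayLike, order: int = 10) -> BurgARResults:
    """Convenience wrapper: fit a :class:`BurgAR` model and return its results."""
    return BurgAR(signal, order=order).fit()


# ---------------------------------------------------------------------------
# Yule-Walker comparison estimator


@dataclass(frozen=True)
class YWModel:
    """Yule-Walker AR fit: generative-convention coefficients and ACF estimates.

    ``a`` follows the generative convention x[n] = sum a_k x[n-k] + e[n]
    (negate to compare with the lattice-convention Burg coefficients).
    """

    a: np.ndarray
    sigma_w2: float
    r_hat: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma_w2 < 0:
            raise ValueError("innovation variance must be >= 0")


def yule_walker(signal: ArrayLike, order: int = 10) -> YWModel:
    """Fit AR coefficients from biased autocorrelation estimates.

    Solves the Toeplitz normal equations built from the biased sample
    autocorrelation (Levinson-Durbin path in statsmodels).  Serves as the
    classical comparison point for the Burg estimates: for Gaussian data
    the two agree as N grows.
    """
    x = _signal_array(signal)
    if x.size <= order:
        raise ValueError("need more samples than the model order")
    if not np.any(x != 0.0):
        raise ValueError("zero-energy signal")
    r_hat = np.array(
        [float(np.dot(x[: x.size - lag], x[lag:])) / x.size for lag in range(order + 1)]
    )
    rho, sigma = _sm.regression.linear_model.yule_walker(
        x, order=order, method="mle", demean=False
    )
    return YWModel(a=np.asarray(rho, dtype=float), sigma_w2=float(sigma**2), r_hat=r_hat)
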