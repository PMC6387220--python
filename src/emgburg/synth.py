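"""Synthetic multi-channel sEMG corpus generator.

Each gesture class is modelled as a stationary AR process with its own
reflection-coefficient vector per channel; a trial is synthesised by
stepping those coefficients up to AR form, driving the recursion with
unit-variance Gaussian innovations, shaping the result with an
attack/hold amplitude envelope, prepending a low-activity lead-in, and
adding white measurement noise.  Subject identity perturbs the class
coefficients slightly (inter-subject variability).

The default protocol mirrors the study corpus: 5 subjects x 6 gestures x
30 repetitions x 2 channels, 6 s at 500 Hz — 900 two-channel trials,
1800 single-channel series.

The generator emulates the statistical structure the feature pipeline
assumes (per-class AR signatures, activity onset, additive noise); it does
not attempt physiological realism such as motor-unit action-potential
trains or within-trial non-stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import signal as _spsignal

from .burg import levinson_from_reflection
from .signals import DEFAULT_FS, GESTURES, Recording

#: Stability margin: class reflection coefficients stay inside |K| <= 0.98.
STABILITY_MARGIN = 0.98


@dataclass(frozen=True)
class ClassParams:
    """Per-gesture generator parameters.

    k_true : per-channel reflection-coefficient vectors, shape
        (n_channels, p); entries within the stability margin.
    envelope : (attack_fraction, hold_level) of the amplitude profile —
        linear rise over the first fraction of the trial, then flat.
    noise_sd : additive white-noise standard deviation relative to the
        RMS of the noise-free signal.
    silence_len : leading low-activity samples prepended to the trial.
    """

    name: str
    k_true: np.ndarray
    envelope: tuple = (0.15, 1.0)
    noise_sd: float = 0.05
    silence_len: int = 250

    def __post_init__(self) -> None:
        k = np.atleast_2d(np.asarray(self.k_true, dtype=float))
        object.__setattr__(self, "k_true", k)
        if np.any(np.abs(k) > STABILITY_MARGIN):
            raise ValueError(f"class {self.name!r}: |K| exceeds stability margin")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.silence_len < 0:
            raise ValueError("silence_len must be >= 0")


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition-protocol layout of the corpus."""

    n_subjects: int = 5
    n_classes: int = 6
    n_trials: int = 30
    n_channels: int = 2
    fs: float = DEFAULT_FS
    duration: float = 6.0
    subject_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_classes", "n_trials", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer number of samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def default_class_bank(p: int = 10, n_channels: int = 2) -> List[ClassParams]:
    """Six well-separated gesture parameter sets.

    Each gesture gets a distinct dominant pole pair (distinct first two
    reflection coefficients) plus a small class-specific tail, keeping all
    entries within the stability margin.  Pairwise Euclidean separation of
    the per-channel K vectors is at least 0.3 by construction.
    """
    if p < 1:
        raise ValueError("order must be >= 1")
    # leading coefficients chosen on a grid with >= 0.3 separation
    leads = [
        (-0.80, 0.55),
        (-0.40, 0.20),
        (0.00, 0.60),
        (0.40, 0.25),
        (0.75, 0.55),
        (0.20, -0.30),
    ]
    bank = []
    for i, name in enumerate(GESTURES):
        k = np.zeros((n_channels, p))
        for ch in range(n_channels):
            k1, k2 = leads[i]
            k[ch, 0] = np.clip(k1 + 0.05 * ch, -STABILITY_MARGIN, STABILITY_MARGIN)
            if p >= 2:
                k[ch, 1] = np.clip(k2 - 0.05 * ch, -STABILITY_MARGIN, STABILITY_MARGIN)
            # small decaying class-specific tail
            for j in range(2, p):
                k[ch, j] = 0.1 * np.sin(0.7 * (i + 1) * (j + 1) + ch) / (j + 1)
        bank.append(ClassParams(name=name, k_true=k))
    return bank


def _ar_filter_coeffs(k: np.ndarray) -> np.ndarray:
    """Monic prediction-error polynomial [1, a_1..a_p] for driving lfilter."""
    a = levinson_from_reflection(k)
    return np.concatenate(([1.0], a))


def simulate_ar(k: Sequence[float], n: int, rng: np.random.Generator,
                burn_in: int = 500) -> np.ndarray:
    """Stationary AR series with the given reflection coefficients.

    Drives 1/A(z) with unit-variance Gaussian innovations and discards a
    burn-in transient.
    """
    poly = _ar_filter_coeffs(np.asarray(k, dtype=float))
    e = rng.standard_normal(n + burn_in)
    x = _spsignal.lfilter([1.0], poly, e)
    return x[burn_in:]


def _jitter_k(k: np.ndarray, scale: float, rng: np.random.Generator,
              max_retries: int = 20) -> np.ndarray:
    """Perturb reflection coefficients, staying within the stability margin."""
    if scale == 0:
        return k
    for _ in range(max_retries):
        kj = k + scale * rng.standard_normal(k.shape)
        if np.all(np.abs(kj) <= STABILITY_MARGIN):
            return kj
    raise RuntimeError("could not draw stable jittered coefficients")


def _envelope(n: int, attack_fraction: float, hold_level: float) -> np.ndarray:
    n_attack = max(int(round(attack_fraction * n)), 1)
    env = np.full(n, hold_level)
    env[:n_attack] = np.linspace(0.0, hold_level, n_attack, endpoint=False)
    # keep the envelope away from exact zero so the AR structure survives
    return np.maximum(env, 0.05 * hold_level)


def simulate_recording(params: ClassParams, protocol: ProtocolConfig,
                       subject: int, trial: int, seed: int,
                       apply_envelope: bool = True,
                       include_silence: bool = True) -> Recording:
    """Synthesise one multi-channel trial.

    Deterministic given (seed, subject, trial, class, channel): every
    channel derives its own child RNG from those identifiers.  The
    per-subject jitter of the class coefficients is drawn from a stream
    keyed by (seed, subject) only, so a subject's signature is consistent
    across trials.
    """
    n = protocol.n_samples
    channels = {}
    class_idx = GESTURES.index(params.name) if params.name in GESTURES else hash(params.name) % 997
    for ch in range(params.k_true.shape[0]):
        subj_rng = np.random.default_rng([seed, subject, class_idx, ch, 7919])
        k_subj = _jitter_k(params.k_true[ch], protocol.subject_jitter, subj_rng)
        rng = np.random.default_rng([seed, subject, class_idx, trial, ch])
        x = simulate_ar(k_subj, n, rng)
        if apply_envelope:
            x = x * _envelope(n, *params.envelope)
        if include_silence and params.silence_len > 0:
            rms = float(np.sqrt(np.mean(x**2)))
            silence = 0.02 * rms * rng.standard_normal(params.silence_len)
            x = np.concatenate([silence, x])
        if params.noise_sd > 0:
            rms = float(np.sqrt(np.mean(x**2)))
            x = x + params.noise_sd * rms * rng.standard_normal(x.size)
        channels[f"ch{ch + 1}"] = x
    return Recording(channels=channels, fs=protocol.fs, label=params.name,
                     subject=subject, trial=trial)


def simulate_corpus(protocol: ProtocolConfig = ProtocolConfig(),
                    class_bank: Sequence[ClassParams] | None = None,
                    seed: int | None = None) -> List[Recording]:
    """Full synthetic corpus: n_subjects x n_classes x n_trials recordings.

    With the default protocol this yields 900 two-channel recordings,
    i.e. 1800 single-channel series.
    """
    if class_bank is None:
        class_bank = default_class_bank(n_channels=protocol.n_channels)
    if len(class_bank) < protocol.n_classes:
        raise ValueError("class bank smaller than n_classes")
    if seed is None:
        seed = protocol.seed
    corpus = []
    for subject in range(1, protocol.n_subjects + 1):
        for params in class_bank[: protocol.n_classes]:
            for trial in range(1, protocol.n_trials + 1):
                corpus.append(
                    simulate_recording(params, protocol, subject, trial, seed)
                )
    return corpus
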