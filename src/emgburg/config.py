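"""Structured run configuration shared by the CLI subcommands.

A single YAML file carries every tunable of the pipeline under the
sections below; unknown keys are rejected so typos fail loudly.

    seed: 42
    trim:      {window_len: 25, onset_fraction: 0.1, enabled: true}
    features:  {zc_th: 0.0, ssc_th: 0.0, wamp_th: null, myop_th: null}
    ar:        {order: 10}
    selection: {tolerance: 0.0, evaluator_folds: 10}
    classify:  {folds: 10, model: knn, k: 1, kernel: rbf}
    protocol:  {subjects: 5, classes: 6, trials: 30, channels: 2,
                fs: 500, duration: 6.0, subject_jitter: 0.02}

``null`` for the WAMP/MYOP thresholds means "5% of the signal RMS".
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .datasets import FeatureConfig
from .preprocess import TrimConfig
from .selection import SelectionConfig
from .synth import ProtocolConfig
from .td_features import ThresholdConfig

_SCHEMA = {
    "seed": None,
    "trim": {"window_len", "onset_fraction", "enabled"},
    "features": {"zc_th", "ssc_th", "wamp_th", "myop_th"},
    "ar": {"order"},
    "selection": {"tolerance", "evaluator_folds"},
    "classify": {"folds", "model", "k", "kernel"},
    "protocol": {"subjects", "classes", "trials", "channels", "fs", "duration",
                 "subject_jitter"},
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 42
    trim: TrimConfig = TrimConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    ar_order: int = 10
    selection: SelectionConfig = SelectionConfig()
    classify_folds: int = 10
    classify_model: str = "knn"
    classify_k: int = 1
    classify_kernel: str = "rbf"
    protocol: ProtocolConfig = ProtocolConfig()

    @property
    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(trim=self.trim, thresholds=self.thresholds,
                             ar_order=self.ar_order)

    def resolved(self) -> dict:
        """Plain-dict view of every setting, for provenance logging."""
        return {
            "seed": self.seed,
            "trim": asdict(self.trim),
            "features": asdict(self.thresholds),
            "ar": {"order": self.ar_order},
            "selection": {"tolerance": self.selection.tolerance,
                          "evaluator_folds": self.selection.evaluator_folds},
            "classify": {"folds": self.classify_folds, "model": self.classify_model,
                         "k": self.classify_k, "kernel": self.classify_kernel},
            "protocol": {
                "subjects": self.protocol.n_subjects,
                "classes": self.protocol.n_classes,
                "trials": self.protocol.n_trials,
                "channels": self.protocol.n_channels,
                "fs": self.protocol.fs,
                "duration": self.protocol.duration,
                "subject_jitter": self.protocol.subject_jitter,
            },
        }


def load_config(path) -> RunConfig:
    """Parse a YAML config file, rejecting unknown sections or keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for section, value in raw.items():
        if section not in _SCHEMA:
            raise ValueError(f"{path}: unknown config section {section!r}")
        allowed = _SCHEMA[section]
        if allowed is not None:
            if not isinstance(value, dict):
                raise ValueError(f"{path}: section {section!r} must be a mapping")
            unknown = set(value) - allowed
            if unknown:
                raise ValueError(
                    f"{path}: unknown keys in {section!r}: {sorted(unknown)}"
                )

    def sec(name):
        return raw.get(name, {}) or {}

    trim = TrimConfig(
        window_len=sec("trim").get("window_len", 25),
        onset_fraction=sec("trim").get("onset_fraction", 0.1),
        enabled=sec("trim").get("enabled", True),
    )
    th = ThresholdConfig(
        zc_th=sec("features").get("zc_th", 0.0),
        ssc_th=sec("features").get("ssc_th", 0.0),
        wamp_th=sec("features").get("wamp_th", None),
        myop_th=sec("features").get("myop_th", None),
    )
    seed = raw.get("seed", 42)
    selection = SelectionConfig(
        tolerance=sec("selection").get("tolerance", 0.0),
        evaluator_folds=sec("selection").get("evaluator_folds", 10),
        seed=seed,
    )
    proto = sec("protocol")
    protocol = ProtocolConfig(
        n_subjects=proto.get("subjects", 5),
        n_classes=proto.get("classes", 6),
        n_trials=proto.get("trials", 30),
        n_channels=proto.get("channels", 2),
        fs=proto.get("fs", 500.0),
        duration=proto.get("duration", 6.0),
        subject_jitter=proto.get("subject_jitter", 0.02),
        seed=seed,
    )
    return RunConfig(
        seed=seed, trim=trim, thresholds=th,
        ar_order=sec("ar").get("order", 10),
        selection=selection,
        classify_folds=sec("classify").get("folds", 10),
        classify_model=sec("classify").get("model", "knn"),
        classify_k=sec("classify").get("k", 1),
        classify_kernel=sec("classify").get("kernel", "rbf"),
        protocol=protocol,
    )
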