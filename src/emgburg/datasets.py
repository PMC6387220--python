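"""Pattern and dataset assembly, plus CSV/ARFF interchange.

A *pattern* is the labelled feature vector of one trial: per channel the
requested feature block is extracted from the conditioned signal, and the
channel blocks are concatenated in channel order, e.g. for the ``K``
variant on two channels:  K1_ch1..K10_ch1, K1_ch2..K10_ch2.

Dataset variants (features per channel, order-10 models):

    TD      10   [IEMG MAV SSI VAR RMS WL WAMP SSC ZC MYOP]
    Arb     10   [Arb1 .. Arb10]           (Burg AR coefficients)
    K       10   [K1 .. K10]               (Burg reflection coefficients)
    K+TD    20   [TD | K]
    K+Arb   20   [Arb | K]
    X       30   [TD | Arb | K]

so a two-channel X pattern has 60 features.  Blocks always appear in the
TD, Arb, K order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .burg import burg_reflection
from .preprocess import TrimConfig, preprocess
from .signals import GESTURES, Recording
from .td_features import TD_FEATURE_NAMES, ThresholdConfig, td_vector

VARIANTS = ("TD", "Arb", "K", "K+TD", "K+Arb", "X")

_META_COLUMNS = ("subject", "trial", "class")


@dataclass(frozen=True)
class FeatureConfig:
    """Everything the per-channel extraction needs."""

    trim: TrimConfig = TrimConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    ar_order: int = 10


@dataclass(frozen=True)
class Pattern:
    """One labelled feature vector."""

    values: np.ndarray
    feature_names: tuple
    label: str
    subject: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        names = tuple(self.feature_names)
        object.__setattr__(self, "feature_names", names)
        if v.size != len(names):
            raise ValueError("values and feature_names lengths differ")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")


@dataclass(frozen=True)
class Dataset:
    """Rectangular labelled feature table.

    Thin wrapper over a pandas DataFrame of features plus aligned label /
    subject / trial vectors; ``variant`` records which feature blocks the
    columns came from.
    """

    features: pd.DataFrame
    labels: pd.Series
    subjects: pd.Series
    trials: pd.Series
    variant: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.features)
        for name, s in (("labels", self.labels), ("subjects", self.subjects),
                        ("trials", self.trials)):
            if len(s) != n:
                raise ValueError(f"{name} length {len(s)} != {n} instances")
        if self.features.isna().any().any():
            raise ValueError("dataset contains missing values")
        if len(set(self.features.columns)) != len(self.features.columns):
            raise ValueError("duplicate feature names")

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> List[str]:
        return sorted(set(self.labels))

    def __len__(self) -> int:
        return len(self.features)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    def select(self, feature_names: Sequence[str]) -> "Dataset":
        """Column subset, preserving instance order and metadata."""
        missing = [f for f in feature_names if f not in self.features.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return replace(self, features=self.features[list(feature_names)].copy(),
                       variant="custom")

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df["subject"] = self.subjects.to_numpy()
        df["trial"] = self.trials.to_numpy()
        df["class"] = self.labels.to_numpy()
        return df


def _variant_blocks(variant: str):
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    blocks = []
    if variant in ("TD", "K+TD", "X"):
        blocks.append("TD")
    if variant in ("Arb", "K+Arb", "X"):
        blocks.append("Arb")
    if variant in ("K", "K+TD", "K+Arb", "X"):
        blocks.append("K")
    return blocks


def build_pattern(recording: Recording, variant: str = "X",
                  cfg: FeatureConfig = FeatureConfig()) -> Pattern:
    """Extract one labelled pattern from a multi-channel recording."""
    blocks = _variant_blocks(variant)
    values: List[float] = []
    names: List[str] = []
    for ch_index, (ch_name, samples) in enumerate(recording.channels.items(), start=1):
        clean = preprocess(recording.channel(ch_name), cfg.trim)
        if len(clean) <= cfg.ar_order and ("Arb" in blocks or "K" in blocks):
            raise ValueError(
                f"channel {ch_name!r}: {len(clean)} samples after conditioning, "
                f"too short for order-{cfg.ar_order} estimation"
            )
        burg = None
        if "Arb" in blocks or "K" in blocks:
            burg = burg_reflection(clean, order=cfg.ar_order)
        for block in blocks:
            if block == "TD":
                values.extend(td_vector(clean, cfg.thresholds).as_array())
                names.extend(f"{f}_ch{ch_index}" for f in TD_FEATURE_NAMES)
            elif block == "Arb":
                values.extend(burg.arcoefs)
                names.extend(f"Arb{j + 1}_ch{ch_index}" for j in range(cfg.ar_order))
            else:
                values.extend(burg.k)
                names.extend(f"K{j + 1}_ch{ch_index}" for j in range(cfg.ar_order))
    return Pattern(values=np.array(values), feature_names=tuple(names),
                   label=recording.label, subject=recording.subject,
                   trial=recording.trial)


def build_dataset(corpus: Sequence[Recording], variant: str = "X",
                  cfg: FeatureConfig = FeatureConfig()) -> Dataset:
    """One pattern per recording, ordered deterministically by (subject, class, trial)."""
    if not corpus:
        raise ValueError("empty corpus")
    n_channels = {r.n_channels for r in corpus}
    if len(n_channels) != 1:
        raise ValueError(f"mixed channel counts in corpus: {sorted(n_channels)}")
    ordered = sorted(corpus, key=lambda r: (r.subject, r.label, r.trial))
    patterns = [build_pattern(r, variant, cfg) for r in ordered]
    names = patterns[0].feature_names
    for p in patterns[1:]:
        if p.feature_names != names:
            raise ValueError("inconsistent feature names across patterns")
    return Dataset(
        features=pd.DataFrame(np.vstack([p.values for p in patterns]),
                              columns=list(names)),
        labels=pd.Series([p.label for p in patterns], name="class"),
        subjects=pd.Series([p.subject for p in patterns], name="subject"),
        trials=pd.Series([p.trial for p in patterns], name="trial"),
        variant=variant,
    )


def merge_datasets(a: Dataset, b: Dataset, variant: Optional[str] = None) -> Dataset:
    """Horizontal concatenation of two feature sets over the same instances.

    Instances are matched by (subject, label, trial); feature names must be
    disjoint.
    """
    if b.n_features == 0:
        return a
    if a.n_features == 0:
        return b
    overlap = set(a.feature_names) & set(b.feature_names)
    if overlap:
        raise ValueError(f"duplicate feature names in merge: {sorted(overlap)}")
    key_a = list(zip(a.subjects, a.labels, a.trials))
    key_b = list(zip(b.subjects, b.labels, b.trials))
    if key_a != key_b:
        raise ValueError("datasets cover different instances (subject/class/trial mismatch)")
    feats = pd.concat(
        [a.features.reset_index(drop=True), b.features.reset_index(drop=True)], axis=1
    )
    return Dataset(features=feats, labels=a.labels.reset_index(drop=True),
                   subjects=a.subjects.reset_index(drop=True),
                   trials=a.trials.reset_index(drop=True),
                   variant=variant or f"{a.variant}+{b.variant}")


# ---------------------------------------------------------------------------
# interchange formats


def write_dataset(dataset: Dataset, path, fmt: Optional[str] = None) -> None:
    """Write a dataset to CSV or ARFF (inferred from the extension)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        dataset.to_frame().to_csv(path, index=False, lineterminator="\n")
    elif fmt == "arff":
        _write_arff(dataset, path)
    else:
        raise ValueError(f"unsupported format {fmt!r} (csv or arff)")


def read_dataset(path, fmt: Optional[str] = None, variant: str = "custom") -> Dataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        if "class" not in df.columns:
            raise ValueError(f"{path}: missing 'class' column")
        na_rows = df.index[df.isna().any(axis=1)]
        if len(na_rows):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: missing value at line {int(na_rows[0]) + 2}")
        return _frame_to_dataset(df, variant)
    if fmt == "arff":
        return _read_arff(path, variant)
    raise ValueError(f"unsupported format {fmt!r} (csv or arff)")


def _frame_to_dataset(df: pd.DataFrame, variant: str) -> Dataset:
    subjects = df["subject"] if "subject" in df else pd.Series([0] * len(df))
    trials = df["trial"] if "trial" in df else pd.Series([0] * len(df))
    feats = df.drop(columns=[c for c in _META_COLUMNS if c in df.columns])
    return Dataset(features=feats, labels=df["class"].astype(str),
                   subjects=subjects.astype(int), trials=trials.astype(int),
                   variant=variant)


def _write_arff(dataset: Dataset, path: Path) -> None:
    classes = dataset.classes
    lines = ["@relation semg"]
    for name in dataset.feature_names:
        lines.append(f"@attribute {name} numeric")
    lines.append("@attribute subject numeric")
    lines.append("@attribute trial numeric")
    lines.append("@attribute class {" + ",".join(classes) + "}")
    lines.append("@data")
    for i in range(len(dataset)):
        row = [repr(float(v)) for v in dataset.features.iloc[i]]
        row.append(str(int(dataset.subjects.iloc[i])))
        row.append(str(int(dataset.trials.iloc[i])))
        row.append(str(dataset.labels.iloc[i]))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_arff(path: Path, variant: str) -> Dataset:
    attrs: List[str] = []
    nominal: dict = {}
    rows: List[list] = []
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            m = re.match(r"@attribute\s+(\S+)\s+(.+)", line, flags=re.IGNORECASE)
            if not m:
                raise ValueError(f"{path}:{lineno}: malformed @attribute")
            name, spec = m.group(1), m.group(2).strip()
            attrs.append(name)
            if spec.startswith("{"):
                nominal[name] = [v.strip() for v in spec.strip("{}").split(",")]
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if not in_data:
            raise ValueError(f"{path}:{lineno}: unexpected line before @data")
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != len(attrs):
            raise ValueError(
                f"{path}:{lineno}: expected {len(attrs)} values, got {len(parts)}"
            )
        if "?" in parts:
            raise ValueError(f"{path}:{lineno}: missing value")
        rows.append(parts)
    if not in_data or not rows:
        raise ValueError(f"{path}: no data section")
    df = pd.DataFrame(rows, columns=attrs)
    for col in attrs:
        if col not in nominal:
            df[col] = df[col].astype(float)
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing class attribute")
    return _frame_to_dataset(df, variant)


# ---------------------------------------------------------------------------
# optional UCI .mat corpus reader

#: Variable-name prefixes of the public basic-hand-movements container.
UCI_CLASS_PREFIXES = {
    "spher": "spherical", "tip": "tip", "palm": "palmar",
    "lat": "lateral", "cyl": "cylindrical", "hook": "hook",
}


def load_mat_corpus(path, fs: float = 500.0, subject: int = 0,
                    class_prefixes: Optional[dict] = None) -> List[Recording]:
    """Read one subject's trials from a MATLAB container of per-class matrices.

    Expects variables ``<prefix>_ch1`` / ``<prefix>_ch2`` holding
    trials x samples matrices, one pair per gesture class.  Requires
    scipy.io; guarded as an optional extra because the public corpus is an
    external download.
    """
    from scipy import io as spio

    mapping = class_prefixes or UCI_CLASS_PREFIXES
    mat = spio.loadmat(path)
    recordings: List[Recording] = []
    for prefix, label in mapping.items():
        ch_vars = sorted(v for v in mat if v.startswith(prefix + "_ch"))
        if not ch_vars:
            continue
        mats = [np.atleast_2d(mat[v]) for v in ch_vars]
        n_trials = mats[0].shape[0]
        for t in range(n_trials):
            channels = {f"ch{i + 1}": m[t, :] for i, m in enumerate(mats)}
            recordings.append(Recording(channels=channels, fs=fs, label=label,
                                        subject=subject, trial=t + 1))
    if not recordings:
        raise ValueError(f"{path}: no per-class channel matrices found")
    return recordings
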