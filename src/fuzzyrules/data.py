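"""Expression-matrix I/O, normalization, feature ranking and synthetic data.

Datasets are sample × feature matrices with a binary label per sample
(+1 / −1, e.g. tumour vs. normal). Real microarray or mass-spectrometry
matrices arrive as delimited text with a header row and a label column;
the synthetic generator emulates their shape — tens of samples, hundreds
to thousands of features, a small informative subset whose class-conditional
means separate the classes, and the rest pure noise.

All modelling code downstream assumes values in [0, 1]; ``normalize_unit_interval``
performs per-feature min–max scaling, fitted on training data and applied to
held-out data with clipping so test values never leave the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "NormalizationStats",
    "SyntheticSpec",
    "read_dataset",
    "write_dataset",
    "normalize_unit_interval",
    "rank_features",
    "generate_synthetic",
]

VALID_LABELS = (1, -1)


@dataclass
class ExpressionDataset:
    """An m × n expression matrix with per-sample binary labels.

    ``values`` may contain NaN for missing measurements. ``normalized``
    records whether values are already min–max scaled to [0, 1];
    ``norm_stats`` carries the fitted per-feature statistics when so.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    normalized: bool = False
    norm_stats: "NormalizationStats | None" = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples × features)")
        m, n = self.values.shape
        if len(self.feature_names) != n:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {n} columns"
            )
        if self.labels.shape != (m,):
            raise ValueError("labels must be one per sample")
        bad = set(np.unique(self.labels)) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"labels must be in {{1, -1}}, found {sorted(bad)}")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def require_both_classes(self) -> None:
        present = set(np.unique(self.labels))
        if present != set(VALID_LABELS):
            raise ValueError(
                f"training data must contain both classes, found {sorted(present)}"
            )

    def subset_features(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = list(indices)
        return ExpressionDataset(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=self.labels.copy(),
            normalized=self.normalized,
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature min/max fitted on training data; constant features flagged."""

    minima: np.ndarray
    maxima: np.ndarray
    constant: np.ndarray  # boolean mask of max == min features


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class synthetic expression dataset.

    ``class_mean_shift`` is the separation of class-conditional means of
    informative features, in units of the within-class standard deviation
    ``noise_sd``. Noise features are identically distributed in both classes.
    """

    m_per_class: int = 30
    n_features: int = 200
    n_informative: int = 5
    class_mean_shift: float = 3.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    m_test_per_class: int = 30

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.class_mean_shift < 0:
            raise ValueError("class_mean_shift must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.m_per_class < 1 or self.m_test_per_class < 0:
            raise ValueError("sample counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def read_dataset(
    path: str | Path,
    label_column: str = "class",
    delimiter: str = ",",
    label_map: Mapping[object, int] | None = None,
) -> ExpressionDataset:
    """Read a delimited samples × features matrix with a label column.

    ``label_map`` translates arbitrary class names (e.g. ``{"MPM": 1,
    "ADCA": -1}``) onto the internal {1, −1} coding; without it the label
    column must already hold 1 / −1.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty file") from e
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed delimited text: {e}") from e
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if label_column not in df.columns:
        raise ValueError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    raw_labels = df[label_column]
    if label_map is not None:
        unknown = set(raw_labels.unique()) - set(label_map)
        if unknown:
            raise ValueError(
                f"{path}: labels {sorted(map(str, unknown))} missing from label_map"
            )
        labels = raw_labels.map(label_map).to_numpy()
    else:
        labels = pd.to_numeric(raw_labels, errors="coerce").to_numpy()
        bad_rows = np.flatnonzero(
            np.isnan(labels) | ~np.isin(labels, VALID_LABELS)
        )
        if bad_rows.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: unmappable label at data line(s) "
                f"{[int(r) + 2 for r in bad_rows[:5]]}; expected 1 or -1"
            )
    feat = df.drop(columns=[label_column])
    values = feat.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ExpressionDataset(
        values=values,
        feature_names=[str(c) for c in feat.columns],
        labels=labels.astype(int),
    )


def write_dataset(
    d: ExpressionDataset,
    path: str | Path,
    label_column: str = "class",
    delimiter: str = ",",
) -> None:
    df = pd.DataFrame(d.values, columns=d.feature_names)
    df[label_column] = d.labels
    df.to_csv(path, sep=delimiter, index=False)


def normalize_unit_interval(
    d: ExpressionDataset, stats: NormalizationStats | None = None
) -> ExpressionDataset:
    """Min–max scale every feature to [0, 1].

    With ``stats=None`` the statistics are fitted on ``d`` itself (the
    training partition); pass the training dataset's ``norm_stats`` to
    transform held-out data, whose values are clipped into [0, 1].
    Constant features carry no ranking signal and are mapped to 0.5.
    """
    if stats is None:
        if np.any(np.all(np.isnan(d.values), axis=0)):
            bad = [
                d.feature_names[i]
                for i in np.flatnonzero(np.all(np.isnan(d.values), axis=0))
            ]
            raise ValueError(f"all-missing feature(s): {bad[:5]}")
        minima = np.nanmin(d.values, axis=0)
        maxima = np.nanmax(d.values, axis=0)
        stats = NormalizationStats(
            minima=minima, maxima=maxima, constant=(maxima == minima)
        )
    span = np.where(stats.constant, 1.0, stats.maxima - stats.minima)
    scaled = (d.values - stats.minima) / span
    scaled[:, stats.constant] = 0.5
    scaled = np.clip(scaled, 0.0, 1.0)
    scaled[np.isnan(d.values)] = np.nan
    return ExpressionDataset(
        values=scaled,
        feature_names=list(d.feature_names),
        labels=d.labels.copy(),
        normalized=True,
        norm_stats=stats,
    )


def rank_features(d: ExpressionDataset, top_k: int) -> np.ndarray:
    """Rank features by the signal-to-noise statistic and return the top k.

    The score is |mean₁ − mean₋₁| / (sd₁ + sd₋₁) per feature (a classical
    class-separation filter for expression data); ties break on the lower
    feature index so the ranking is deterministic.
    """
    d.require_both_classes()
    if not (1 <= top_k <= d.n):
        raise ValueError(f"top_k must be in [1, {d.n}], got {top_k}")
    pos = d.values[d.labels == 1]
    neg = d.values[d.labels == -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_gap = np.abs(np.nanmean(pos, axis=0) - np.nanmean(neg, axis=0))
        sd_sum = np.nanstd(pos, axis=0, ddof=0) + np.nanstd(neg, axis=0, ddof=0)
        score = np.where(sd_sum > 0, mean_gap / np.where(sd_sum > 0, sd_sum, 1.0), 0.0)
    score = np.nan_to_num(score, nan=0.0)
    order = np.lexsort((np.arange(d.n), -score))
    return order[:top_k]


def generate_synthetic(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, np.ndarray]:
    """Draw a reproducible train/test pair with known informative features.

    Informative features are Gaussian with class-conditional means
    ``0`` (class −1) and ``shift · sd`` (class +1); noise features are
    N(0, sd²) in both classes. Values are min–max normalized with training
    statistics (test values clipped). Returns (train, test, informative
    feature indices) so recovery of the planted signal can be scored.
    """
    rng = np.random.default_rng(spec.seed)
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )

    def draw(m_per_class: int) -> ExpressionDataset:
        m = 2 * m_per_class
        labels = np.concatenate(
            [np.ones(m_per_class, dtype=int), -np.ones(m_per_class, dtype=int)]
        )
        values = rng.normal(0.0, spec.noise_sd, size=(m, spec.n_features))
        shift = spec.class_mean_shift * spec.noise_sd
        values[np.ix_(labels == 1, informative)] += shift
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) < spec.missing_rate
            values[mask] = np.nan
        return ExpressionDataset(
            values=values,
            feature_names=[f"g{i}" for i in range(spec.n_features)],
            labels=labels,
        )

    train = draw(spec.m_per_class)
    test = draw(spec.m_test_per_class) if spec.m_test_per_class else None
    train = normalize_unit_interval(train)
    if test is not None:
        test = normalize_unit_interval(test, stats=train.norm_stats)
    return train, test, informative
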