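"""Deterministic clinical encoding and volume size/intensity normalization.

Clinical records carry seven features in a fixed order — age, race, ER, PR,
HR, HER2, molecular subtype.  Encoding rules:

* age: Z-scored with mean/SD fitted on the *training* records only (observed
  ages only); missing age encodes as the sentinel -1;
* binary markers (ER/PR/HR/HER2): passed through as 0/1; missing -> -1;
* categoricals (race, subtype): one-hot over K+1 slots, where slot K is the
  explicit "missing" category.

Volumes are symmetrically zero-padded then center-cropped to a fixed target
shape, and Z-score normalized over all voxels.  Missing values are
represented as NaN throughout the raw tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ClinicalStats",
    "fit_clinical_stats",
    "encode_clinical",
    "encode_table",
    "clinical_vector_length",
    "slot_layout",
    "pad_crop_volume",
    "zscore_volume",
    "ClinicalEncoder",
    "VolumeNormalizer",
]

MISSING_SENTINEL = -1.0
BINARY_COLUMNS = ("er", "pr", "hr", "her2")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        np.isscalar(value) and pd.isna(value)
    )


@dataclass(frozen=True)
class ClinicalStats:
    """Age mean/SD fitted on training records (observed ages only)."""

    age_mean: float
    age_sd: float
    degenerate: bool = False


def fit_clinical_stats(records: pd.DataFrame, ddof: int = 1) -> ClinicalStats:
    """Fit age statistics on training-split records only.

    ``ddof=1`` (sample SD) is the default scaling convention; ``ddof=0``
    selects the population convention.  Zero spread flags the statistics as
    degenerate (SD forced to 1 so encoding stays total).
    """
    ages = pd.to_numeric(records["age"], errors="coerce").dropna().to_numpy(float)
    if ages.size < 2:
        raise ValueError("need at least two records with observed age")
    mean = float(ages.mean())
    sd = float(ages.std(ddof=ddof))
    if sd == 0.0:
        return ClinicalStats(age_mean=mean, age_sd=1.0, degenerate=True)
    return ClinicalStats(age_mean=mean, age_sd=sd)


def clinical_vector_length(k_race: int = 3, k_subtype: int = 4) -> int:
    return 1 + (k_race + 1) + 4 + (k_subtype + 1)


def slot_layout(k_race: int = 3, k_subtype: int = 4) -> dict[str, list[int]]:
    """Index ranges of each feature block in the encoded vector."""
    layout, cursor = {}, 0

    def block(name: str, width: int):
        nonlocal cursor
        layout[name] = list(range(cursor, cursor + width))
        cursor += width

    block("age", 1)
    block("race", k_race + 1)
    for column in BINARY_COLUMNS:
        block(column, 1)
    block("subtype", k_subtype + 1)
    return layout


def encode_clinical(
    record,
    stats: ClinicalStats,
    k_race: int = 3,
    k_subtype: int = 4,
) -> np.ndarray:
    """Encode one clinical record into the fixed-order numeric vector.

    ``record`` is a mapping (dict / pandas Series) with NaN/None marking
    missing entries.
    """
    parts: list[np.ndarray] = []

    age = record["age"]
    if _is_missing(age):
        parts.append(np.array([MISSING_SENTINEL]))
    else:
        parts.append(np.array([(float(age) - stats.age_mean) / stats.age_sd]))

    for column, k in (("race", k_race),):
        parts.append(_one_hot(record[column], k, column))

    for column in BINARY_COLUMNS:
        value = record[column]
        if _is_missing(value):
            parts.append(np.array([MISSING_SENTINEL]))
        else:
            value = float(value)
            if value not in (0.0, 1.0):
                raise ValueError(f"{column} must be 0/1 or missing, got {value}")
            parts.append(np.array([value]))

    parts.append(_one_hot(record["subtype"], k_subtype, "subtype"))
    return np.concatenate(parts)


def _one_hot(value, k: int, name: str) -> np.ndarray:
    out = np.zeros(k + 1)
    if _is_missing(value):
        out[k] = 1.0  # explicit missing category at index K
        return out
    code = int(value)
    if not 0 <= code < k:
        raise ValueError(f"{name} code {code} outside [0, {k})")
    out[code] = 1.0
    return out


def encode_table(
    table: pd.DataFrame,
    stats: ClinicalStats,
    k_race: int = 3,
    k_subtype: int = 4,
) -> np.ndarray:
    """Encode every row of a clinical table; returns (n, d_clin_in)."""
    return np.stack(
        [
            encode_clinical(row, stats, k_race=k_race, k_subtype=k_subtype)
            for _, row in table.iterrows()
        ]
    )


# -- volumes -------------------------------------------------------------------


def pad_crop_volume(volume: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Symmetric zero-pad then central crop to ``target`` shape.

    Odd padding remainders place the extra voxel on the high-index side; odd
    cropping remainders likewise remove the extra voxel from the high side.
    Pad and crop compose, so any input size is accepted.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D single-channel volume")
    pads = []
    for size, want in zip(volume.shape, target):
        deficit = max(want - size, 0)
        pads.append((deficit // 2, deficit - deficit // 2))
    padded = np.pad(volume, pads, mode="constant", constant_values=0.0)
    slices = []
    for size, want in zip(padded.shape, target):
        start = (size - want) // 2
        slices.append(slice(start, start + want))
    return padded[tuple(slices)]


def zscore_volume(volume: np.ndarray) -> np.ndarray:
    """Z-score over all voxels; a zero-variance volume maps to all zeros."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size == 0:
        raise ValueError("empty volume")
    sd = volume.std()
    if sd == 0.0:
        return np.zeros_like(volume)
    return (volume - volume.mean()) / sd


# -- sklearn-style transformers ------------------------------------------------


class ClinicalEncoder(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`fit_clinical_stats` + :func:`encode_table`.

    Fitting touches only the rows passed to :meth:`fit`, so fitting on the
    training split and transforming the test split never leaks test
    statistics into the encoding.
    """

    def __init__(self, k_race: int = 3, k_subtype: int = 4, age_ddof: int = 1):
        self.k_race = k_race
        self.k_subtype = k_subtype
        self.age_ddof = age_ddof

    def fit(self, X: pd.DataFrame, y=None):
        self.stats_ = fit_clinical_stats(X, ddof=self.age_ddof)
        self.n_features_out_ = clinical_vector_length(self.k_race, self.k_subtype)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "stats_"):
            raise ValueError("ClinicalEncoder is not fitted")
        return encode_table(X, self.stats_, k_race=self.k_race, k_subtype=self.k_subtype)

    def save_layout(self, path) -> None:
        layout = slot_layout(self.k_race, self.k_subtype)
        with open(path, "w") as fh:
            json.dump(layout, fh, indent=2)


class VolumeNormalizer(BaseEstimator, TransformerMixin):
    """Pad/crop every volume to ``target_shape`` and optionally Z-score it.

    Stateless (``fit`` records nothing); both steps are per-volume.
    """

    def __init__(self, target_shape: tuple[int, int, int] = (32, 32, 16),
                 zscore: bool = True):
        self.target_shape = target_shape
        self.zscore = zscore

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((len(X), *self.target_shape), dtype=np.float64)
        for i, volume in enumerate(X):
            vol = pad_crop_volume(volume, self.target_shape)
            out[i] = zscore_volume(vol) if self.zscore else vol
        return out
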