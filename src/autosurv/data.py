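"""Input readers, normalization, variance filtering, splits, clinical encoding.

Expression matrices are plain pandas DataFrames with samples as rows and
features (genes or miRNAs) as columns.  The preprocessing protocol is:

1. split samples into a 20% external test set and an 80% tuning set, the
   tuning set being further divided 10 times into 80/20 train/validation
   parts (64% / 16% of the whole data);
2. min-max normalize each feature to [0, 1] within each split independently;
3. drop features whose variance on the normalized tuning set is below 0.02,
   freezing the retained feature list for all splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_tsv",
    "read_clinical_csv",
    "minmax_normalize",
    "MinMaxNormalizer",
    "VarianceFilter",
    "variance_filter",
    "SplitPlan",
    "make_splits",
    "ClinicalEncoder",
    "encode_clinical",
]

DEFAULT_VARIANCE_THRESHOLD = 0.02


# ---------------------------------------------------------------------------
# IO

def read_expression_tsv(
    path: str | Path,
    orientation: str = "auto",
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a TSV expression matrix into a samples x features DataFrame.

    ``orientation`` may be "samples", "features" (rows are features), or
    "auto".  Auto-detection prefers a ``sample_ids`` hint (which axis the
    known sample identifiers lie on); without one, the wide axis is taken to
    be features.  The detected orientation is recorded in ``df.attrs``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "auto":
        if sample_ids is not None:
            known = set(map(str, sample_ids))
            on_rows = len(known & set(df.index))
            on_cols = len(known & set(df.columns))
            orientation = "samples" if on_rows >= on_cols else "features"
        else:
            orientation = "features" if df.shape[0] > df.shape[1] else "samples"
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    _check_unique(df.index, "sample")
    _check_unique(df.columns, "feature")
    df.attrs["orientation"] = orientation
    return df


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Read the clinical/survival CSV indexed by sample_id.

    Expects at least ``sample_id``, ``time`` (days) and ``event`` (1 = death
    observed, 0 = censored) columns; remaining columns are covariates.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("clinical CSV must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    _check_unique(df.index, "sample")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical CSV must have a {col!r} column")
    if (df["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def _check_unique(index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][:3].tolist()
        raise ValueError(f"duplicate {what} identifiers: {dup}")


# ---------------------------------------------------------------------------
# Normalization and filtering

class MinMaxNormalizer:
    """Per-feature min-max rescaling to [0, 1].

    ``fit`` records per-feature min/max; ``transform`` applies
    (v - min) / (max - min).  Constant features map to 0.  When transforming
    data other than the fitting set (the leakage-safe deployment mode),
    values are clipped back into [0, 1].
    """

    def __init__(self):
        self.min_: pd.Series | None = None
        self.max_: pd.Series | None = None

    def fit(self, df: pd.DataFrame) -> "MinMaxNormalizer":
        _check_finite(df)
        self.min_ = df.min(axis=0)
        self.max_ = df.max(axis=0)
        return self

    def transform(self, df: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        if self.min_ is None:
            raise RuntimeError("normalizer is not fitted")
        _check_finite(df)
        df = df[self.min_.index]
        span = self.max_ - self.min_
        out = (df - self.min_).div(span.replace(0.0, np.inf), axis=1)
        if clip:
            out = out.clip(0.0, 1.0)
        return out

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df, clip=False)


def minmax_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Rescale each feature to [0, 1] using its min/max within ``df``.

    Constant features map to 0 everywhere (they carry no information and are
    removed downstream by the variance filter).  Non-finite values are
    rejected with the offending feature named.
    """
    return MinMaxNormalizer().fit_transform(df)


def _check_finite(df: pd.DataFrame) -> None:
    finite = np.isfinite(df.to_numpy(dtype=float))
    if not finite.all():
        bad = df.columns[~finite.all(axis=0)][:3].tolist()
        raise ValueError(f"non-finite values in features: {bad}")


class VarianceFilter:
    """Feature filter on unbiased sample variance of the (normalized) fit set.

    The retained feature list is frozen at fit time and reapplied unchanged to
    any other split, so train/validation/test always share one feature set.
    """

    def __init__(self, threshold: float = DEFAULT_VARIANCE_THRESHOLD):
        self.threshold = threshold
        self.features_: list[str] | None = None

    def fit(self, df: pd.DataFrame) -> "VarianceFilter":
        variances = df.var(axis=0, ddof=1)
        keep = variances[variances >= self.threshold].index.tolist()
        if not keep:
            raise ValueError(
                f"no feature has variance >= {self.threshold}; filter would be empty"
            )
        self.features_ = keep
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.features_ is None:
            raise RuntimeError("filter is not fitted")
        return df[self.features_]

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def variance_filter(df: pd.DataFrame, threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> pd.DataFrame:
    """Drop features with unbiased sample variance below ``threshold``."""
    return VarianceFilter(threshold).fit_transform(df)


# ---------------------------------------------------------------------------
# Splits

@dataclass
class SplitPlan:
    """20% test / 80% tuning split plus 10 train/valid divisions of tuning."""

    test_ids: list[str]
    tuning_ids: list[str]
    divisions: list[tuple[list[str], list[str]]]
    seed: int
    stratified: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "stratified": self.stratified,
            "test_ids": self.test_ids,
            "tuning_ids": self.tuning_ids,
            "divisions": [
                {"train_ids": tr, "valid_ids": va} for tr, va in self.divisions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            test_ids=d["test_ids"],
            tuning_ids=d["tuning_ids"],
            divisions=[(x["train_ids"], x["valid_ids"]) for x in d["divisions"]],
            seed=d["seed"],
            stratified=d.get("stratified", True),
        )


def _stratified_take(rng, ids_by_stratum: list[np.ndarray], fraction: float):
    """Randomly take ~fraction of ids within each stratum; returns (taken, rest)."""
    taken, rest = [], []
    for ids in ids_by_stratum:
        perm = rng.permutation(ids)
        k = int(round(fraction * len(ids)))
        taken.extend(perm[:k])
        rest.extend(perm[k:])
    return sorted(map(str, taken)), sorted(map(str, rest))


def make_splits(
    sample_ids: Sequence[str],
    events: Sequence[int] | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    valid_fraction: float = 0.2,
    n_divisions: int = 10,
    stratify: bool = True,
) -> SplitPlan:
    """Build the test/tuning split and the repeated train/valid divisions.

    Splits are stratified by the event indicator by default so that deaths are
    represented in every part; pass ``stratify=False`` for purely random
    splits.  Deterministic given ``seed``.
    """
    sample_ids = [str(s) for s in sample_ids]
    n = len(sample_ids)
    if n < 25:
        raise ValueError(f"need at least 25 samples to split, got {n}")
    if len(set(sample_ids)) != n:
        raise ValueError("duplicate sample ids")
    rng = np.random.default_rng(seed)

    if stratify and events is not None:
        ev = np.asarray(events)
        ids = np.asarray(sample_ids)
        strata = [ids[ev == v] for v in np.unique(ev)]
    else:
        strata = [np.asarray(sample_ids)]
        stratify = False

    test_ids, tuning_ids = _stratified_take(rng, strata, test_fraction)
    tuning_set = set(tuning_ids)
    tuning_strata = [np.asarray([s for s in st if s in tuning_set]) for st in strata]
    tuning_strata = [st for st in tuning_strata if len(st)]

    divisions = []
    for _ in range(n_divisions):
        valid_ids, train_ids = _stratified_take(rng, tuning_strata, valid_fraction)
        divisions.append((train_ids, valid_ids))

    return SplitPlan(
        test_ids=test_ids,
        tuning_ids=tuning_ids,
        divisions=divisions,
        seed=seed,
        stratified=stratify,
    )


# ---------------------------------------------------------------------------
# Clinical encoding

@dataclass
class ClinicalEncoder:
    """Encode clinical covariates: numeric pass-through, categoricals one-hot.

    One-hot encoding drops a declared reference level per categorical column
    (default: lexicographically first observed level).  Missing values and
    categories unseen at fit time raise, naming the offender; set
    ``allow_missing=True`` to encode missing as an explicit indicator level.
    """

    numeric: Sequence[str] = ("age",)
    categorical: Sequence[str] = ("stage", "race")
    reference: dict[str, str] = field(default_factory=dict)
    standardize: bool = False
    allow_missing: bool = False
    levels_: dict[str, list[str]] | None = None
    numeric_stats_: dict[str, tuple[float, float]] | None = None
    columns_: list[str] | None = None

    _MISSING = "__missing__"

    def fit(self, table: pd.DataFrame) -> "ClinicalEncoder":
        self.levels_ = {}
        self.numeric_stats_ = {}
        for col in self.numeric:
            vals = pd.to_numeric(table[col], errors="raise")
            self._check_missing(vals, col)
            self.numeric_stats_[col] = (float(vals.mean()), float(vals.std(ddof=0)) or 1.0)
        for col in self.categorical:
            vals = table[col].astype(object)
            vals = self._handle_missing(vals, col)
            levels = sorted(map(str, vals.unique()))
            # the explicit-missing level never serves as the implicit reference
            candidates = [lv for lv in levels if lv != self._MISSING] or levels
            ref = self.reference.get(col, candidates[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed in {col!r}")
            self.levels_[col] = [lv for lv in levels if lv != ref]
            self.reference[col] = ref
        self.columns_ = list(self.numeric) + [
            f"{col}_{lv}" for col in self.categorical for lv in self.levels_[col]
        ]
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("encoder is not fitted")
        out = {}
        for col in self.numeric:
            vals = pd.to_numeric(table[col], errors="raise")
            self._check_missing(vals, col)
            if self.standardize:
                mean, sd = self.numeric_stats_[col]
                vals = (vals - mean) / sd
            out[col] = vals.astype(float)
        for col in self.categorical:
            vals = self._handle_missing(table[col].astype(object), col).astype(str)
            known = set(self.levels_[col]) | {self.reference[col]}
            unseen = sorted(set(vals.unique()) - known)
            if unseen:
                raise ValueError(f"unseen categories in {col!r}: {unseen}")
            for lv in self.levels_[col]:
                out[f"{col}_{lv}"] = (vals == lv).astype(float)
        return pd.DataFrame(out, index=table.index)[self.columns_]

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)

    def _check_missing(self, vals: pd.Series, col: str) -> None:
        if vals.isna().any():
            bad = vals.index[vals.isna()][:3].tolist()
            raise ValueError(f"missing values in {col!r} for samples {bad}")

    def _handle_missing(self, vals: pd.Series, col: str) -> pd.Series:
        if vals.isna().any():
            if not self.allow_missing:
                bad = vals.index[vals.isna()][:3].tolist()
                raise ValueError(f"missing values in {col!r} for samples {bad}")
            vals = vals.fillna(self._MISSING)
        return vals


def encode_clinical(table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """One-shot fit+transform clinical encoding (see ClinicalEncoder)."""
    return ClinicalEncoder(**kwargs).fit_transform(table)
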