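"""Training protocol: cyclic KL-annealing, grid search over repeated
train/valid divisions, and Wilcoxon comparison of testing metrics.

The annealing schedule divides training into ``n_cycles`` cycles of equal
length (the last cycle absorbs any remainder).  Within each cycle the KL
weight beta ramps linearly from 0 to 1 over the first ``cutting_ratio``
fraction of the cycle, then stays at 1 so the full VAE objective is optimized
for the rest of the cycle.

Grid search follows the repeated-division protocol: for each of the (by
default 10) train/valid divisions of the tuning set, every grid point is
trained on the train part and scored on the valid part; the division's best
point is then refit on the whole tuning set and scored on the external test
set, yielding one testing metric per division (mean +/- sd reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnnealingSchedule", "beta_at", "TuningResult", "grid_search", "compare_cindices"]


@dataclass
class AnnealingSchedule:
    n_cycles: int = 3
    cutting_ratio: float = 0.5
    total_steps: int = 100
    ramp: str = "linear"  # or "cosine"

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 < self.cutting_ratio <= 1.0:
            raise ValueError("cutting_ratio must be in (0, 1]")
        if self.total_steps < self.n_cycles:
            raise ValueError("total_steps must be >= n_cycles")

    @property
    def cycle_length(self) -> int:
        return self.total_steps // self.n_cycles

    def betas(self) -> np.ndarray:
        return np.array([beta_at(s, self) for s in range(self.total_steps)])


def beta_at(step: int, schedule: AnnealingSchedule) -> float:
    """KL weight at ``step``: linear 0->1 ramp then plateau at 1, per cycle."""
    if not 0 <= step < schedule.total_steps:
        raise ValueError(
            f"step {step} out of range [0, {schedule.total_steps})"
        )
    L = schedule.cycle_length
    cycle = min(step // L, schedule.n_cycles - 1)
    pos = step - cycle * L  # last cycle absorbs the remainder; ramp uses L
    # capped at L-1 so every cycle attains beta = 1 even at cutting_ratio = 1
    ramp_len = min(int(np.ceil(schedule.cutting_ratio * L)), max(L - 1, 1))
    if pos >= ramp_len:
        return 1.0
    frac = pos / ramp_len
    if schedule.ramp == "cosine":
        return float(0.5 * (1.0 - np.cos(np.pi * frac)))
    return float(frac)


@dataclass
class TuningResult:
    """Per-division validation metrics, selected points, and test metrics."""

    validation: pd.DataFrame  # columns: division, grid_index, metric
    best_points: list[dict]   # one selected grid point per division
    test_metrics: np.ndarray | None = None
    maximize: bool = True
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.test_metrics))

    @property
    def sd(self) -> float:
        return float(np.std(self.test_metrics, ddof=1))


def grid_search(
    grid: Sequence[dict],
    divisions: Sequence[tuple[list[str], list[str]]],
    train_fn: Callable[[dict, list[str], list[str]], object],
    metric_fn: Callable[[object, list[str]], float],
    refit_fn: Callable[[dict], object] | None = None,
    test_fn: Callable[[object], float] | None = None,
    maximize: bool = True,
) -> TuningResult:
    """Repeated-division grid search (see module docstring).

    ``train_fn(point, train_ids, valid_ids)`` returns a fitted model;
    ``metric_fn(model, valid_ids)`` scores it; ties and equal metrics select
    the first grid point in declared order.  A grid point whose training
    raises is recorded in ``failures`` and excluded for that division.  When
    ``refit_fn``/``test_fn`` are given, each division's best point is refit
    (on the whole tuning set) and scored on the test set.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    rows, best_points, failures, test_metrics = [], [], [], []
    for d, (train_ids, valid_ids) in enumerate(divisions):
        metrics = []
        for gi, point in enumerate(grid):
            try:
                model = train_fn(point, train_ids, valid_ids)
                metric = float(metric_fn(model, valid_ids))
            except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
                warnings.warn(
                    f"grid point {gi} failed on division {d}: {exc}", stacklevel=2
                )
                failures.append((d, gi, str(exc)))
                metric = np.nan
            metrics.append(metric)
            rows.append({"division": d, "grid_index": gi, "metric": metric})
        arr = np.asarray(metrics)
        if np.isnan(arr).all():
            raise RuntimeError(f"all grid points failed on division {d}")
        score = np.where(np.isnan(arr), -np.inf if maximize else np.inf, arr)
        best = int(np.argmax(score) if maximize else np.argmin(score))
        best_points.append(grid[best])
        if refit_fn is not None and test_fn is not None:
            test_metrics.append(float(test_fn(refit_fn(grid[best]))))
    return TuningResult(
        validation=pd.DataFrame(rows),
        best_points=best_points,
        test_metrics=np.asarray(test_metrics) if test_metrics else None,
        maximize=maximize,
        failures=failures,
    )


def compare_cindices(c_a, c_b, alternative: str = "greater") -> float:
    """One-tailed Wilcoxon signed-rank p-value for paired testing metrics.

    Zero differences are dropped (standard convention); the distribution is
    exact for n <= 25 remaining pairs, otherwise a normal approximation with
    continuity correction is used.  All-zero differences give p = 1 with a
    warning.
    """
    a = np.asarray(c_a, dtype=float)
    b = np.asarray(c_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("c_a and c_b must be 1-d arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired metrics")
    diffs = a - b
    nonzero = np.count_nonzero(diffs)
    if nonzero == 0:
        warnings.warn("all paired differences are zero; p-value = 1", stacklevel=2)
        return 1.0
    try:
        res = stats.wilcoxon(a, b, alternative=alternative,
                             zero_method="wilcox", method="exact" if nonzero <= 25 else "approx",
                             correction=nonzero > 25)
    except ValueError:
        res = stats.wilcoxon(a, b, alternative=alternative,
                             zero_method="wilcox", method="approx", correction=True)
    return float(res.pvalue)
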