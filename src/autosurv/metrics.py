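"""Survival evaluation: Harrell's C-index, median-PI risk groups, KM, log-rank.

The concordance index is computed with the conventions: a pair (i, j) is
comparable if T_i < T_j and patient i died, or if T_i = T_j and exactly one of
the two died (the death is known to precede the censored patient's true time);
a comparable pair is concordant when the shorter-lived patient has the higher
prognostic index, and tied prognostic indices earn half credit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["c_index", "RiskAssignment", "assign_risk", "km_curve", "logrank_test"]


def c_index(pi, times, events) -> float:
    """Harrell's concordance index between a prognostic index and survival."""
    pi = np.asarray(pi, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (pi.shape == t.shape == e.shape):
        raise ValueError("pi, times, events must have equal length")

    # comparable[i, j]: patient i's death is known to precede j's survival
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None].astype(bool), e[None, :].astype(bool)
    comparable = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    np.fill_diagonal(comparable, False)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs (need at least one event before "
                         "another subject's observed time)")
    dpi = pi[:, None] - pi[None, :]
    concordant = (dpi > 0) & comparable
    tied = (dpi == 0) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


@dataclass
class RiskAssignment:
    """High/low risk labels from the strict comparison PI > PI_med."""

    group: pd.Series  # values "high"/"low"
    pi_med: float


def assign_risk(pi_test: pd.Series | np.ndarray, pi_med_tuning: float) -> RiskAssignment:
    """Label samples high-risk iff PI strictly exceeds the tuning-set median."""
    pi = pd.Series(pi_test)
    group = pd.Series(np.where(pi > pi_med_tuning, "high", "low"), index=pi.index)
    return RiskAssignment(group=group, pi_med=float(pi_med_tuning))


def km_curve(times, events, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival estimate with a 95% confidence band.

    Returns a DataFrame indexed by time with columns ``survival``, ``lower``,
    ``upper`` (Greenwood-based band on the log(-log) scale).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    out = kmf.survival_function_.copy()
    out.columns = ["survival"]
    ci = kmf.confidence_interval_survival_function_
    out["lower"] = ci.iloc[:, 0].to_numpy()
    out["upper"] = ci.iloc[:, 1].to_numpy()
    out.index.name = "time"
    return out


def logrank_test(groups, times, events) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    from lifelines.statistics import logrank_test as _lr

    groups = np.asarray(groups)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two nonempty groups, got {list(labels)}")
    a, b = (groups == labels[0]), (groups == labels[1])
    res = _lr(t[a], t[b], event_observed_A=e[a], event_observed_B=e[b])
    return float(res.test_statistic), float(res.p_value)
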