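"""Kaplan-Meier estimation, log-rank comparison and best-expression-cutoff
stratification.

A cohort is a table of (subject, time, event, per-gene FPKM).  For a gene of
interest the cohort is split at an expression cutoff into high (> cutoff)
and low groups and compared with the log-rank test; the *best* cutoff is the
candidate minimizing the log-rank p over the observed expression values
inside a central percentile window (20th-80th by default).  No multiplicity
correction is applied across scanned cutoffs — the resulting optimism of the
minimum p is a documented property of the procedure, not corrected away.

Eligibility follows the cohort-level FPKM rule: a gene enters survival
analysis only when its median cohort FPKM exceeds 1 (``eligibility="any"``
switches to requiring any subject above the threshold).  Overall-survival
association is evaluated after administrative truncation at a horizon
(5 years by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DataError

DAYS_PER_YEAR = 365.0
HIGH_WORSE = "high-worse"
HIGH_BETTER = "high-better"


@dataclass
class CutoffResult:
    gene_id: str
    best_cutoff: float
    logrank_p: float
    logrank_stat: float
    direction: str | None
    eligible: bool
    n_high: int = 0
    n_low: int = 0
    n_scanned: int = 0


def km_estimate(time, event) -> tuple[pd.DataFrame, float]:
    """Product-limit survival curve plus the median survival time.

    The curve has one row per observed event time (steps only); the median
    is the smallest time with S(t) <= 0.5 and NaN when S never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise DataError("Kaplan-Meier needs at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    curve = pd.DataFrame(
        {
            "time": steps.index.values,
            "at_risk": steps["at_risk"].values.astype(int),
            "n_events": steps["observed"].values.astype(int),
            "survival": kmf.survival_function_at_times(steps.index.values).values,
        }
    )
    # smallest event time with S(t) <= 0.5; the tolerance absorbs float
    # round-off when the product lands exactly on one half
    reached = curve[curve["survival"] <= 0.5 + 1e-12]
    median = float(reached["time"].iloc[0]) if len(reached) else float("nan")
    return curve, median


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p-value)."""
    time_a, time_b = np.asarray(time_a, float), np.asarray(time_b, float)
    event_a, event_b = np.asarray(event_a, int), np.asarray(event_b, int)
    if time_a.size == 0 or time_b.size == 0:
        raise DataError("log-rank needs two non-empty groups")
    if event_a.sum() + event_b.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a,
                      event_observed_B=event_b)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):
        return 0.0, 1.0
    return stat, p


def _direction(time, event, high_mask) -> str | None:
    """Which group's KM curve sits lower at the last time both groups reach."""
    t_star = min(time[high_mask].max(), time[~high_mask].max())
    kmf_hi, kmf_lo = KaplanMeierFitter(), KaplanMeierFitter()
    kmf_hi.fit(time[high_mask], event[high_mask])
    kmf_lo.fit(time[~high_mask], event[~high_mask])
    s_hi = float(kmf_hi.survival_function_at_times([t_star]).iloc[0])
    s_lo = float(kmf_lo.survival_function_at_times([t_star]).iloc[0])
    if s_hi == s_lo:
        return None
    return HIGH_WORSE if s_hi < s_lo else HIGH_BETTER


def best_cutoff_scan(
    time,
    event,
    expression,
    gene_id: str = "",
    pct_range: tuple[float, float] = (20.0, 80.0),
    min_subjects: int = 20,
) -> CutoffResult:
    """Scan observed expression values for the log-rank-optimal split.

    Candidates are the unique observed expression values inside the
    percentile window; subjects with expression strictly above a candidate
    form the high group.  Ties in p resolve to the lower cutoff.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    expr = np.asarray(expression, float)
    if time.size < min_subjects:
        raise DataError(f"best-cutoff scan needs >= {min_subjects} subjects")
    lo, hi = np.percentile(expr, pct_range)
    candidates = np.unique(expr[(expr >= lo) & (expr <= hi)])
    candidates = candidates[candidates < expr.max()]
    if candidates.size == 0:
        return CutoffResult(gene_id, float("nan"), float("nan"), float("nan"),
                            None, eligible=False)

    best = None
    for c in candidates:  # ascending, so the first minimum is the lowest cutoff
        high = expr > c
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        stat, p = logrank_test(time[~high], event[~high], time[high], event[high])
        if best is None or p < best[1]:
            best = (c, p, stat)
    if best is None:
        return CutoffResult(gene_id, float("nan"), float("nan"), float("nan"),
                            None, eligible=False)
    cutoff, p, stat = best
    high = expr > cutoff
    return CutoffResult(
        gene_id=gene_id,
        best_cutoff=float(cutoff),
        logrank_p=p,
        logrank_stat=stat,
        direction=_direction(time, event, high),
        eligible=True,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        n_scanned=int(candidates.size),
    )


def truncate_followup(time, event, horizon_days: float):
    """Administratively censor every subject at the horizon."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    over = time > horizon_days
    return np.where(over, horizon_days, time), np.where(over, 0, event)


def os_association(
    cohort: pd.DataFrame,
    gene_id: str,
    horizon_years: float = 5.0,
    pct_range: tuple[float, float] = (20.0, 80.0),
    eligibility: str = "median",
    fpkm_threshold: float = 1.0,
    min_subjects: int = 20,
) -> CutoffResult:
    """Best-cutoff overall-survival association for one gene.

    Expects columns ``time_days``, ``event`` and ``fpkm_<gene_id>``.
    Follow-up is truncated at the horizon; a gene is eligible only when the
    cohort FPKM rule holds (median > threshold, or any subject > threshold
    with ``eligibility="any"``).  Ineligible genes are flagged and skipped.
    """
    col = f"fpkm_{gene_id}"
    if col not in cohort.columns:
        raise DataError(f"cohort has no expression column for {gene_id!r}")
    expr = cohort[col].to_numpy(float)
    if eligibility == "median":
        eligible = bool(np.median(expr) > fpkm_threshold)
    elif eligibility == "any":
        eligible = bool((expr > fpkm_threshold).any())
    else:
        raise ValueError(f"unknown eligibility rule {eligibility!r}")
    if not eligible or np.unique(expr).size == 1:
        return CutoffResult(gene_id, float("nan"), float("nan"), float("nan"),
                            None, eligible=False)
    time, event = truncate_followup(
        cohort["time_days"], cohort["event"], horizon_years * DAYS_PER_YEAR
    )
    return best_cutoff_scan(time, event, expr, gene_id=gene_id,
                            pct_range=pct_range, min_subjects=min_subjects)
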