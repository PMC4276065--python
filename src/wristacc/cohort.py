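"""Stratified descriptive cohort tables.

Group means with normal-approximation 95% confidence intervals
(mean ± z * sd / sqrt(n)) for each outcome, stratified by birth cohort, sex,
SES quintile and weight status; proportions meeting the 30-min/day MVPA
guideline carry a binomial normal-approximation CI. Inferential tests are
out of scope here — the tables are descriptive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

OUTCOMES = (
    "mean_enmo_mg",
    "mvpa_min_per_day_bout5",
    "mvpa_min_per_day_bout10",
)

_META_COLS = ["participant_id", "sex", "cohort", "ses_quintile", "weight_status"]


def group_mean_ci(values, level: float = 0.95) -> tuple[int, float, float, float]:
    """(n, mean, ci_low, ci_high) under the normal approximation.

    With n < 2 the CI is undefined and returned as NaN.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return 0, float("nan"), float("nan"), float("nan")
    mean = float(v.mean())
    if n < 2:
        return n, mean, float("nan"), float("nan")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * v.std(ddof=1) / np.sqrt(n)
    return n, mean, mean - half, mean + half


def proportion_ci(flags, level: float = 0.95) -> tuple[int, float, float, float]:
    """(n, pct, ci_low, ci_high) for a binary outcome, in percent."""
    f = np.asarray(flags, dtype=float)
    n = f.size
    if n == 0:
        return 0, float("nan"), float("nan"), float("nan")
    p = float(f.mean())
    if n < 2:
        return n, 100 * p, float("nan"), float("nan")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1 - p) / n)
    return n, 100 * p, 100 * max(p - half, 0.0), 100 * min(p + half, 1.0)


def _rows_for(df: pd.DataFrame, by: list[str], table: str, level: float) -> list[dict]:
    rows = []
    for keys, grp in df.groupby(by, sort=True, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        labels = dict(zip(by, keys))
        for outcome in OUTCOMES:
            n, mean, lo, hi = group_mean_ci(grp[outcome], level)
            rows.append({"table": table, **labels, "outcome": outcome,
                         "n": n, "mean": mean, "ci_low": lo, "ci_high": hi})
        n, pct, lo, hi = proportion_ci(grp["meets_30min"], level)
        rows.append({"table": table, **labels, "outcome": "pct_meeting_30min",
                     "n": n, "mean": pct, "ci_low": lo, "ci_high": hi})
    return rows


def build_tables(
    persons: pd.DataFrame,
    meta: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Long-format stratified table covering the four published shapes:
    cohort x sex; SES quintile within cohort x sex; weight status within
    cohort x sex; and MVPA by bout length across all strata (the bout-length
    contrast is carried by the two MVPA outcome rows of every stratum).

    ``persons`` must contain the PersonSummary columns; ineligible persons
    (fewer than the protocol's minimum valid days) are dropped. Every person
    must have metadata; unmatched ids are a hard error.
    """
    cfg = cfg or PipelineConfig()
    p = persons.copy()
    if "eligible" in p.columns:
        p = p[p["eligible"]]
    else:
        p = p[p["n_valid_days"] >= cfg.min_valid_days]
    missing = set(p["participant_id"]) - set(meta["participant_id"])
    if missing:
        raise ValueError(f"participants without metadata: {sorted(missing)[:10]}"
                         f" ({len(missing)} total)")
    df = p.merge(meta[_META_COLS], on="participant_id", validate="one_to_one")

    rows: list[dict] = []
    rows += _rows_for(df, ["cohort", "sex"], "by_cohort_sex", level)
    rows += _rows_for(df, ["cohort", "sex", "ses_quintile"], "by_ses", level)
    rows += _rows_for(df, ["cohort", "sex", "weight_status"], "by_weight", level)
    out = pd.DataFrame(rows)
    front = ["table", "cohort", "sex", "ses_quintile", "weight_status",
             "outcome", "n", "mean", "ci_low", "ci_high"]
    cols = [c for c in front if c in out.columns]
    return out[cols]


def pooled_mean(table: pd.DataFrame, outcome: str, subtable: str = "by_cohort_sex") -> float:
    """n-weighted mean over the strata of one subtable; equals the
    unstratified mean exactly."""
    t = table[(table["table"] == subtable) & (table["outcome"] == outcome)]
    return float((t["n"] * t["mean"]).sum() / t["n"].sum())
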