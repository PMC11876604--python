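"""In vitro spheroid growth metrics.

The relative growth rate (rgr) of a cancer population is the average
hourly change in log abundance between two observation times:

    rgr = (ln N(t_end) - ln N(t_start)) / (t_end - t_start)

with natural logarithms, so an exact exponential N(t) = N0 exp(r t)
returns r.  Dose-response summaries report per-condition means with
standard errors and a rank-correlation trend of rgr against IL-15 dose
within each (line, culture, ribociclib) stratum.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITION_COLUMNS = ["line", "culture", "ribo_uM", "il15_ng_ml"]

#: endpoint matching slack in hours (imaging every 24-72 h)
ENDPOINT_TOLERANCE_H = 6.0


def relative_growth_rate(
    series: pd.DataFrame, t_start: float = 0.0, t_end: float = 75.0
) -> float:
    """Average hourly change in log abundance over [t_start, t_end].

    ``series`` has columns ``time_h`` and ``abundance`` for one replicate.
    If an endpoint is not observed exactly, the nearest observation within
    +/- 6 h is used (logged); otherwise an error is raised.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    times = series["time_h"].to_numpy(dtype=float)
    values = series["abundance"].to_numpy(dtype=float)

    def endpoint(t_req: float) -> tuple[float, float]:
        i = int(np.argmin(np.abs(times - t_req)))
        if abs(times[i] - t_req) > ENDPOINT_TOLERANCE_H:
            raise ValueError(
                f"no observation within {ENDPOINT_TOLERANCE_H} h of t={t_req}"
            )
        if times[i] != t_req:
            logger.info("using nearest observed time %.1f h for requested %.1f h", times[i], t_req)
        return times[i], values[i]

    t0, n0 = endpoint(t_start)
    t1, n1 = endpoint(t_end)
    if n0 <= 0 or n1 <= 0:
        raise ValueError("abundance must be positive at both endpoints")
    if t1 <= t0:
        raise ValueError("matched endpoints are not increasing in time")
    return (math.log(n1) - math.log(n0)) / (t1 - t0)


def rgr_table(
    curves: pd.DataFrame, t_start: float = 0.0, t_end: float = 75.0
) -> pd.DataFrame:
    """rgr per (condition, replicate) from a long abundance table."""
    rows = []
    for key, grp in curves.groupby(CONDITION_COLUMNS + ["replicate"], observed=True):
        rows.append(
            dict(zip(CONDITION_COLUMNS + ["replicate"], key))
            | {"rgr": relative_growth_rate(grp, t_start, t_end)}
        )
    return pd.DataFrame(rows)


def dose_response_summary(rgr: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-condition means and IL-15 dose trends.

    Returns ``means`` (per-condition mean rgr with standard error and the
    difference versus the zero-dose control of the same stratum) and
    ``trends`` (per (line, culture, ribo_uM) stratum, the Spearman rank
    correlation of rgr against IL-15 dose; strata with a single dose level
    have no defined trend and are reported with NaN statistics).
    """
    from scipy.stats import spearmanr

    counts = rgr.groupby(CONDITION_COLUMNS, observed=True)["rgr"].count()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"conditions with < 2 replicates: {list(thin.index)}")
    means = (
        rgr.groupby(CONDITION_COLUMNS, observed=True)["rgr"]
        .agg(mean_rgr="mean", se_rgr=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count")
        .reset_index()
    )
    controls = means[means["il15_ng_ml"] == 0].set_index(["line", "culture", "ribo_uM"])["mean_rgr"]
    means["diff_vs_control"] = [
        row["mean_rgr"] - controls.get((row["line"], row["culture"], row["ribo_uM"]), np.nan)
        for _, row in means.iterrows()
    ]
    trend_rows = []
    for key, grp in rgr.groupby(["line", "culture", "ribo_uM"], observed=True):
        if grp.empty:
            raise ValueError(f"empty stratum: {key}")
        doses = grp["il15_ng_ml"].astype(float)
        if doses.nunique() < 2:
            rho, p = np.nan, np.nan
        else:
            rho, p = spearmanr(doses, grp["rgr"])
        trend_rows.append(
            dict(zip(["line", "culture", "ribo_uM"], key))
            | {"spearman_rho": rho, "p": p, "n": len(grp)}
        )
    return {"means": means, "trends": pd.DataFrame(trend_rows)}
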