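"""Cohort-level statistics: group comparisons, correlations, binned calibration.

Reproduces the descriptive analyses around the recurrence model: per-group
mean +/- SD of each survival surrogate with a two-sided t test (Welch by
default, since the group SDs differ substantially), Pearson correlation
between surrogates (notably mean pre-treatment SUV vs mean SUV decrease), and
a three-bin calibration of observed recurrence fractions against the fitted
sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import PETTCPError

__all__ = [
    "GroupComparison",
    "compare_groups",
    "correlate",
    "binned_calibration",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (0.2, 0.4, 0.6)
ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Responder vs nonresponder comparison of one surrogate."""

    surrogate: str
    responder_mean: float
    responder_sd: float
    nonresponder_mean: float
    nonresponder_sd: float
    t_statistic: float
    p_value: float
    significant: bool
    welch: bool

    def as_dict(self) -> dict:
        return {
            "surrogate": self.surrogate,
            "responder_mean": self.responder_mean,
            "responder_sd": self.responder_sd,
            "nonresponder_mean": self.nonresponder_mean,
            "nonresponder_sd": self.nonresponder_sd,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "welch": self.welch,
        }


def compare_groups(
    table: pd.DataFrame,
    surrogate: str = "mean_ratio",
    welch: bool = True,
    alternative: str = "two-sided",
) -> GroupComparison:
    """t test of a surrogate between responders (R=0) and nonresponders.

    Sample SDs use n-1. Welch (unequal variance) and two-sided are the
    defaults; set ``welch=False`` for the pooled-variance test, or
    ``alternative`` to ``"less"``/``"greater"`` (responders minus
    nonresponders) for a one-sided test. Each group needs >= 2 members for a
    defined variance.
    """
    resp = table.loc[table["R"] == 0, surrogate].to_numpy(dtype=float)
    nonresp = table.loc[table["R"] == 1, surrogate].to_numpy(dtype=float)
    if len(resp) < 2 or len(nonresp) < 2:
        raise PETTCPError(
            f"both groups need >= 2 patients for a t test "
            f"(responders={len(resp)}, nonresponders={len(nonresp)})"
        )
    t, p = sps.ttest_ind(resp, nonresp, equal_var=not welch, alternative=alternative)
    return GroupComparison(
        surrogate=surrogate,
        responder_mean=float(resp.mean()),
        responder_sd=float(resp.std(ddof=1)),
        nonresponder_mean=float(nonresp.mean()),
        nonresponder_sd=float(nonresp.std(ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p <= ALPHA),
        welch=welch,
    )


def compare_all_surrogates(table: pd.DataFrame, welch: bool = True) -> pd.DataFrame:
    """Group comparison for every surrogate column, one row each."""
    cols = ["mean_ratio", "ratio_of_means", "mean_diff", "mean_pre", "mean_post"]
    rows = [compare_groups(table, c, welch=welch).as_dict() for c in cols if c in table.columns]
    return pd.DataFrame(rows)


def correlate(
    table: pd.DataFrame,
    x_surrogate: str = "mean_pre",
    y_surrogate: str = "mean_diff",
    subset: str | None = None,
) -> tuple[float, float]:
    """Sample Pearson r between two surrogates with a two-sided p value.

    The p value uses the exact t transform with n-2 degrees of freedom.
    ``subset`` restricts to ``"responders"`` or ``"nonresponders"``.
    """
    if subset == "responders":
        table = table[table["R"] == 0]
    elif subset == "nonresponders":
        table = table[table["R"] == 1]
    elif subset is not None:
        raise PETTCPError(f"unknown subset {subset!r}")
    x = table[x_surrogate].to_numpy(dtype=float)
    y = table[y_surrogate].to_numpy(dtype=float)
    if len(x) < 3:
        raise PETTCPError("correlation needs at least 3 patients")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PETTCPError("correlation undefined: a variable has zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def binned_calibration(
    table: pd.DataFrame,
    results,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    surrogate: str = "mean_ratio",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Observed recurrence fraction per surrogate bin vs the fitted sigmoid.

    Bins are (lo, hi] over ``edges`` with a final open bin above the last
    edge; values at or below the first edge fall into a flagged underflow bin
    (never silently dropped). Each bin reports the observed tumor-recurrence
    fraction with a Wilson ``ci_level`` interval and the model TRP at the bin
    midpoint (the open top bin uses the midpoint between its lower edge and
    the data maximum). Empty bins are reported with n=0 and NaN fractions.
    """
    if len(table) == 0:
        raise PETTCPError("cannot calibrate an empty cohort")
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise PETTCPError("bin edges must be strictly increasing with >= 2 values")
    x = table[surrogate].to_numpy(dtype=float)
    r = table["R"].to_numpy(dtype=int)
    data_max = float(x.max())

    bins: list[dict] = []
    underflow = x <= edges[0]
    if underflow.any():
        bins.append(
            _bin_row(-np.inf, edges[0], x, r, underflow, results, edges[0] / 2, True, ci_level)
        )
    for lo, hi in zip(edges, edges[1:]):
        sel = (x > lo) & (x <= hi)
        bins.append(_bin_row(lo, hi, x, r, sel, results, (lo + hi) / 2, False, ci_level))
    lo = edges[-1]
    sel = x > lo
    mid = (lo + max(data_max, lo)) / 2
    bins.append(_bin_row(lo, np.inf, x, r, sel, results, mid, False, ci_level))

    out = pd.DataFrame(bins)
    assert int(out["n"].sum()) == len(table), "bins must conserve the cohort"
    return out


def _bin_row(lo, hi, x, r, sel, results, midpoint, underflow, ci_level: float = 0.95):
    n = int(sel.sum())
    events = int(r[sel].sum())
    if n > 0:
        observed = events / n
        w_lo, w_hi = proportion_confint(events, n, alpha=1 - ci_level, method="wilson")
    else:
        observed, w_lo, w_hi = np.nan, np.nan, np.nan
    return {
        "lo": lo,
        "hi": hi,
        "n": n,
        "n_nonresponders": events,
        "observed_trp": observed,
        "ci_lo": float(w_lo) if n else np.nan,
        "ci_hi": float(w_hi) if n else np.nan,
        "midpoint": float(midpoint),
        "model_trp": float(results.predict_trp(midpoint)),
        "underflow": bool(underflow),
    }
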