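"""Sedentary-behaviour exposure construction.

Weekday/weekend questionnaire hours are combined into mean daily hours
(weekdays weighted 5/7, weekend days 2/7), screen time and other sedentary
activities are summed into total sedentary behaviour, and each variable is
categorised into tertiles on the analysis sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TERTILE_LABELS = ("low", "middle", "high")


def daily_mean(weekday_hours, weekend_hours):
    """Mean daily hours from weekday and weekend questionnaire hours.

    Computes ``((wd * 5) + (we * 2)) / 7`` elementwise. Inputs must lie in
    [0, 24] hours.
    """
    wd = np.asarray(weekday_hours, dtype=float)
    we = np.asarray(weekend_hours, dtype=float)
    for name, arr in (("weekday", wd), ("weekend", we)):
        if np.any(arr < 0) or np.any(arr > 24) or np.any(~np.isfinite(arr)):
            raise ValueError(f"{name} hours must lie in [0, 24]")
    out = (wd * 5.0 + we * 2.0) / 7.0
    return float(out) if out.ndim == 0 else out


def total_sb(screen_daily, other_daily):
    """Total sedentary behaviour: sum of screen and other daily hours."""
    s = np.asarray(screen_daily, dtype=float)
    o = np.asarray(other_daily, dtype=float)
    if np.any(s < 0) or np.any(o < 0):
        raise ValueError("daily hours must be non-negative")
    out = s + o
    return float(out) if out.ndim == 0 else out


@dataclass
class TertileResult:
    labels: pd.Series          # low / middle / high per observation
    cutpoints: tuple           # (q1, q2) empirical 1/3 and 2/3 quantiles
    sizes: dict                # group sizes (ties at a cut go to the lower group)


def assign_tertiles(values, quantile_method: str = "linear",
                    labels=TERTILE_LABELS) -> TertileResult:
    """Categorise values into tertiles at the empirical 1/3 and 2/3 quantiles.

    A value equal to a cut-point is assigned to the lower category, so heavy
    ties at a cut produce unequal group sizes (as questionnaire data with
    coarse granularity typically do).

    Parameters
    ----------
    values : array-like
        One value per subject; order is preserved in the returned labels.
    quantile_method : str
        Quantile interpolation passed to :func:`numpy.quantile`.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    if len(v) < 3:
        raise ValueError("need at least 3 observations to form tertiles")
    if v.nunique() < 2:
        raise ValueError("tertiles undefined: all values identical")
    q1, q2 = np.quantile(v.to_numpy(), [1 / 3, 2 / 3], method=quantile_method)
    lab = np.where(v <= q1, labels[0], np.where(v <= q2, labels[1], labels[2]))
    out = pd.Series(pd.Categorical(lab, categories=list(labels)), index=v.index)
    sizes = out.value_counts().reindex(list(labels)).fillna(0).astype(int).to_dict()
    return TertileResult(labels=out, cutpoints=(float(q1), float(q2)), sizes=sizes)


def build_exposures(sb: pd.DataFrame, quantile_method: str = "linear") -> tuple[pd.DataFrame, dict]:
    """Derive daily means, totals and tertiles from an SB questionnaire table.

    Parameters
    ----------
    sb : DataFrame
        Columns ``child_id, screen_wd, screen_we, other_wd, other_we``
        (hours/day).

    Returns
    -------
    exposures : DataFrame
        Per child: the four raw columns, ``screen_daily``, ``other_daily``,
        ``total_daily`` and a ``*_tertile`` label for each.
    cutpoints : dict
        Tertile cut-points per variable, for reporting (they depend on the
        quantile convention and on the analysis sample).
    """
    out = sb.copy()
    out["screen_daily"] = daily_mean(sb["screen_wd"], sb["screen_we"])
    out["other_daily"] = daily_mean(sb["other_wd"], sb["other_we"])
    out["total_daily"] = total_sb(out["screen_daily"], out["other_daily"])
    cutpoints = {}
    for var in ("screen", "other", "total"):
        res = assign_tertiles(out[f"{var}_daily"], quantile_method=quantile_method)
        out[f"{var}_tertile"] = res.labels.to_numpy()
        cutpoints[var] = {"q1": res.cutpoints[0], "q2": res.cutpoints[1],
                          "sizes": res.sizes, "quantile_method": quantile_method}
    return out, cutpoints
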