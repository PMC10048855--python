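"""Rank-based telomere tracking between two ages.

Because T/S ratios measured with different assay chemistries are not
directly comparable across cohorts or visits, longitudinal change is
expressed in rank space: TL is ranked within cohort from longest (rank 1)
to shortest (rank n) at each age, and the tracking statistic is the scaled
rank change

    delta_R = (R1 - R2) / (n - 1) * 100,

in percentage points, negative when a child declines in the cohort's
telomere ranking (relative shortening). Over a complete paired cohort the
statistic has mean exactly 0, and it is invariant to any strictly monotone
transform of the underlying TL values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def rank_tl(values, method: str = "average") -> np.ndarray:
    """Rank TL values from longest (rank 1) to shortest (rank n).

    Ties receive the average of the spanned ranks by default, which keeps
    each ranking a tie-averaged permutation of 1..n and the tracking
    statistic's zero-mean property exact. ``method='ordinal'`` gives strict
    integer ranks instead.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to rank")
    if np.any(~np.isfinite(v)):
        raise ValueError("TL values must be finite; drop missing values first")
    return stats.rankdata(-v, method=method)


def delta_r(r1, r2, n: int):
    """Scaled rank change ``(R1 - R2) / (n - 1) * 100`` in percentage points."""
    if n < 2:
        raise ValueError("ranked sample size must be at least 2")
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any((r1 < 1) | (r1 > n)) or np.any((r2 < 1) | (r2 > n)):
        raise ValueError("ranks must lie in [1, n]")
    out = (r1 - r2) / (n - 1) * 100.0
    return float(out) if out.ndim == 0 else out


def rank_correlation(r1, r2) -> tuple[float, float]:
    """Spearman correlation between baseline and follow-up rankings (QC)."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("rank vectors must be paired (equal length)")
    if r1.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = stats.spearmanr(r1, r2)
    return float(rho), float(p)


def build_tracking(tl4: pd.DataFrame, tl8: pd.DataFrame,
                   rank_on_full_baseline: bool = False,
                   tie_method: str = "average") -> pd.DataFrame:
    """Per-child tracking table from TL tables at the two ages.

    Parameters
    ----------
    tl4, tl8 : DataFrame
        Columns ``child_id, cohort, tl`` (CNRQ units; units may differ
        between the two tables and between cohorts — only within-cohort
        order is used).
    rank_on_full_baseline : bool
        If True, baseline ranks use all children with a baseline TL rather
        than only those measured at both ages. The default (False) ranks the
        complete-pairs set at both ages, which keeps the cohort mean of the
        statistic exactly zero.

    Returns
    -------
    DataFrame with ``child_id, cohort, r1, r2, n, delta_r``.
    """
    paired = tl4.merge(tl8, on=["child_id", "cohort"], suffixes=("_4", "_8")).dropna()
    out = []
    for coh, grp in paired.groupby("cohort", observed=True):
        if len(grp) < 2:
            raise ValueError(f"cohort {coh!r} has fewer than 2 paired children")
        n = len(grp)
        if rank_on_full_baseline:
            # baseline ranks over every child with a baseline TL; each ranking
            # is rescaled to [0, 1] so the two scales remain comparable
            base = tl4[tl4["cohort"] == coh].dropna()
            base_ranks = pd.Series(rank_tl(base["tl"], method=tie_method).astype(float),
                                   index=base["child_id"].to_numpy())
            r1 = base_ranks.reindex(grp["child_id"].to_numpy()).to_numpy()
            r2 = rank_tl(grp["tl_8"], method=tie_method)
            n_base = len(base)
            dr = ((r1 - 1) / (n_base - 1) - (r2 - 1) / (n - 1)) * 100.0
            out.append(pd.DataFrame({"child_id": grp["child_id"], "cohort": coh,
                                     "r1": r1, "r2": r2, "n": n, "delta_r": dr}))
        else:
            r1 = rank_tl(grp["tl_4"], method=tie_method)
            r2 = rank_tl(grp["tl_8"], method=tie_method)
            out.append(pd.DataFrame({"child_id": grp["child_id"], "cohort": coh,
                                     "r1": r1, "r2": r2, "n": n,
                                     "delta_r": delta_r(r1, r2, n)}))
    return pd.concat(out, ignore_index=True)
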