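"""Descriptive screening: cross-time-point Spearman matrices with FDR control.

Correlations are computed on pairwise-complete observations (no imputation
at this stage) with average ranks for ties and the t-approximation p-value.
Benjamini-Hochberg correction is applied over a configurable set of
"hypothesized" cells — typically the exposure -> zBMI pairs at the same and
next time point — rather than over every cell of the matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman", "bh_adjust", "correlation_matrix", "default_hypothesis_mask"]


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho, p (t-approximation) and pairwise-complete n.

    Returns ``(nan, nan, n)`` when fewer than 3 complete pairs exist —
    a missing cell, not an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return (float("nan"), float("nan"), n)
    res = stats.spearmanr(x[ok], y[ok])
    return (float(res.statistic), float(res.pvalue), n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Rejection at level alpha corresponds to adjusted p <= alpha.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def default_hypothesis_mask(
    exposure_tps, zbmi_tps, same_and_next: bool = True
) -> set[tuple[str, str]]:
    """The a-priori cells: exposure at t vs zBMI at t and at the next time point."""
    cells = set()
    zlist = list(zbmi_tps)
    for tp in exposure_tps:
        if tp in zlist:
            cells.add((tp, tp))
            i = zlist.index(tp)
            if same_and_next and i + 1 < len(zlist):
                cells.add((tp, zlist[i + 1]))
    return cells


def correlation_matrix(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_name: str = "exposure",
    outcome_name: str = "zbmi",
    hypothesis_cells: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """All exposure-time x outcome-time Spearman cells, BH over the mask.

    Parameters
    ----------
    exposure, outcome : DataFrame
        Subjects as rows (aligned on index), time points as columns.
    hypothesis_cells : set of (exposure_tp, outcome_tp), optional
        Cells entering the FDR correction; defaults to same- and
        next-time-point pairs.  Cells outside the mask keep ``p_adj`` NaN.

    Returns
    -------
    DataFrame with columns
    ``var_a, time_a, var_b, time_b, rho, p, n, hypothesized, p_adj``.
    """
    exposure, outcome = exposure.align(outcome, join="outer", axis=0)
    if hypothesis_cells is None:
        hypothesis_cells = default_hypothesis_mask(exposure.columns, outcome.columns)
    rows = []
    for tp_a in exposure.columns:
        for tp_b in outcome.columns:
            rho, p, n = spearman(exposure[tp_a], outcome[tp_b])
            rows.append(
                {
                    "var_a": exposure_name, "time_a": tp_a,
                    "var_b": outcome_name, "time_b": tp_b,
                    "rho": rho, "p": p, "n": n,
                    "hypothesized": (tp_a, tp_b) in hypothesis_cells,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    mask = out["hypothesized"] & out["p"].notna()
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
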