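"""Absolute differences between subsequent rank positions, with contrasts vs DI2.

A hierarchy is more than an ordering: the spacing between adjacent ranks says
how clearly an animal is separated from the one below it.  All parameters are
first mapped to a common [0, 1] scale (dominance indices affinely, the
centralities are already standardized), then within each pen the animals are
sorted descending per parameter and the differences between subsequent rank
positions ("comparison 1:2", "2:3", ...) are recorded up to an age-group
cutoff (8:9 for the small piglet pens, 20:21 / 18:19 for the larger fattener
and gilt pens).

Whether any parameter spaces ranks differently from the opponent-weighted
dominance index DI2 is tested with a fixed-effects two-way least-squares
model ``abs_diff ~ parameter + comparison + parameter:comparison`` with pens
as replicates; each parameter is contrasted against DI2 within each
comparison level using cell means and the pooled residual variance, and the
contrast family is Holm-adjusted.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .temporal import PARAMETERS

__all__ = [
    "COMPARISON_CUTOFFS",
    "standardize_parameter",
    "rank_differences",
    "holm_adjust",
    "contrast_vs_di2",
]

# Highest adjacent-rank comparison retained per age group (lower-ranked
# comparisons have too few observations in smaller pens).
COMPARISON_CUTOFFS = {"piglet": 8, "fattener": 20, "gilt": 18}


def standardize_parameter(values: Sequence[float], parameter: str) -> np.ndarray:
    """Map a parameter's values onto the common [0, 1] scale.

    Dominance indices live on [-1, 1] and are mapped by ``(x + 1) / 2``;
    standardized degrees, closeness and betweenness are already in [0, 1]
    and pass through.  Missing values stay missing.
    """
    arr = np.asarray(values, dtype=float)
    if parameter in ("di1", "di2"):
        return (arr + 1.0) / 2.0
    return arr


def rank_differences(
    panel: pd.DataFrame,
    cutoff: int,
    parameters: Sequence[str] = PARAMETERS,
) -> pd.DataFrame:
    """Per pen and parameter, differences between subsequent rank positions.

    Standardized values are sorted descending (ties broken by animal id,
    which leaves the differences unaffected); ``abs_diff`` for comparison
    ``k:(k+1)`` is value-at-rank-k minus value-at-rank-(k+1), for
    ``k = 1 .. min(cutoff, available - 1)``.  Animals with a missing value
    are excluded from that parameter's ranking only.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    rows = []
    for pen_id, group in panel.groupby("pen_id", sort=True):
        for param in parameters:
            std = standardize_parameter(group[param].to_numpy(), param)
            order = sorted(
                zip(std, group["animal"]), key=lambda t: (-t[0], t[1])
            )
            vals = [v for v, _ in order if not math.isnan(v)]
            for k in range(1, min(cutoff, len(vals) - 1) + 1):
                rows.append(
                    {
                        "pen_id": pen_id,
                        "parameter": param,
                        "comparison": f"{k}:{k + 1}",
                        "comparison_index": k,
                        "abs_diff": vals[k - 1] - vals[k],
                    }
                )
    return pd.DataFrame(rows)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment of a family of raw p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def contrast_vs_di2(
    records: pd.DataFrame, reference: str = "di2", alpha: float = 0.05
) -> pd.DataFrame:
    """Contrast every parameter against DI2 within each comparison level.

    Fits the saturated fixed-effects model (parameter, comparison and their
    interaction; pens as replicates), whose fitted values are the cell means;
    the pooled residual variance from that fit scales each cell-mean contrast.
    Holm adjusts the whole family of parameter-vs-reference contrasts.
    Raises if no residual degrees of freedom remain (e.g. a single pen).
    """
    required = {"parameter", "comparison", "abs_diff"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    cells = records.groupby(["parameter", "comparison"])["abs_diff"]
    means = cells.mean()
    counts = cells.count()
    # pooled residual variance of the saturated two-way OLS fit
    fitted = means.reindex(
        pd.MultiIndex.from_frame(records[["parameter", "comparison"]])
    ).to_numpy()
    resid_ss = float(((records["abs_diff"].to_numpy() - fitted) ** 2).sum())
    df_resid = int(len(records) - len(means))
    if df_resid <= 0:
        raise ValueError(
            "no residual degrees of freedom: need at least two pens per cell"
        )
    s2 = resid_ss / df_resid

    rows = []
    comparisons = sorted(
        records["comparison"].unique(), key=lambda c: int(c.split(":")[0])
    )
    parameters = [p for p in records["parameter"].unique() if p != reference]
    for comp in comparisons:
        if (reference, comp) not in means.index:
            continue
        ref_mean = means[(reference, comp)]
        ref_n = counts[(reference, comp)]
        for param in sorted(parameters):
            if (param, comp) not in means.index:
                continue
            est = means[(param, comp)] - ref_mean
            n1 = counts[(param, comp)]
            se = math.sqrt(s2 * (1.0 / n1 + 1.0 / ref_n))
            if se == 0.0:
                t_stat, p_raw = 0.0, 1.0
            else:
                t_stat = est / se
                p_raw = 2.0 * stats.t.sf(abs(t_stat), df_resid)
            rows.append(
                {
                    "parameter": param,
                    "comparison": comp,
                    "estimate": est,
                    "se": se,
                    "t": t_stat,
                    "p_raw": p_raw,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p_raw"])
        out["significant"] = out["p_holm"] < alpha
    return out
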