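"""Scale scoring and descriptive statistics.

Questionnaire scales are item × subject integer matrices on a declared
bounded range.  The analyzed phenotype is the per-subject total; internal
consistency is summarized by Cronbach's alpha and scale interrelations by a
pairwise-complete Pearson correlation table with two-sided significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScaleData:
    """Item responses for one scale: items (rows) × subjects (columns)."""

    items: pd.DataFrame
    scale_name: str = ""
    item_range: tuple = (1, 7)

    def __post_init__(self) -> None:
        lo, hi = self.item_range
        vals = self.items.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite < lo) | (finite > hi)).any():
            raise ValueError(f"item responses outside declared range [{lo}, {hi}]")


def score_total(s: ScaleData) -> pd.Series:
    """Per-subject scale total (sum over items).

    A subject with any missing item receives a missing total — totals are
    only comparable when every item contributes.
    """
    if s.items.shape[0] == 0:
        raise ValueError("empty scale")
    vals = s.items.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    totals[np.isnan(vals).any(axis=0)] = np.nan
    return pd.Series(totals, index=s.items.columns, name=s.scale_name or "total")


def cronbach_alpha(s: ScaleData) -> float:
    """Cronbach's alpha: k/(k-1) · (1 − Σ item variance / total variance).

    Sample variances use the n−1 denominator.  Subjects with any missing
    item are excluded (listwise within the scale).
    """
    items = s.items.dropna(axis=1)
    k, n = items.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if n < 3:
        raise ValueError("Cronbach's alpha needs at least 3 complete subjects")
    vals = items.to_numpy(dtype=float)
    item_var = vals.var(axis=1, ddof=1).sum()
    total_var = vals.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def correlation_table(variables: Mapping) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns a long-format DataFrame with columns ``var1, var2, n, r, p,
    sig`` where ``sig`` is ``**`` (p<0.01), ``*`` (p<0.05) or empty.  The
    p-value uses t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    names = list(variables)
    series = {k: pd.Series(v).astype(float) for k, v in variables.items()}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = series[a].align(series[b], join="inner")
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            xs, ys = x[ok], y[ok]
            if xs.std(ddof=1) == 0 or ys.std(ddof=1) == 0:
                raise ValueError(f"constant variable in pair ({a}, {b})")
            r, p = stats.pearsonr(xs, ys)
            sig = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            rows.append({"var1": a, "var2": b, "n": n, "r": float(r), "p": float(p), "sig": sig})
    return pd.DataFrame(rows)


def descriptives(variables: Mapping) -> pd.DataFrame:
    """Mean and SD (n−1) per variable, ignoring missing values."""
    rows = []
    for name, v in variables.items():
        ser = pd.Series(v).astype(float).dropna()
        rows.append({"variable": name, "mean": ser.mean(), "sd": ser.std(ddof=1), "n": len(ser)})
    return pd.DataFrame(rows)
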