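"""Per-locus ANOVA screening.

Step 1 of the pipeline: a one-way ANOVA of the phenotype across genotype
classes at every retained locus, with Fisher-LSD post hoc pairwise
comparisons, nominating loci at an uncorrected screening threshold
(default p < 0.05) for the joint regression model.  An equivalent ANOVA
from published summary statistics (group mean, SD, N) supports verification
against printed association tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .qc import class_codes


@dataclass(frozen=True)
class GroupSummary:
    """Summary of the phenotype within one genotype class."""

    label: str
    mean: float
    sd: float  # n-1 denominator; NaN when n < 2
    n: int


@dataclass
class ScreenResult:
    locus: str
    groups: list
    F: float
    df_between: int
    df_within: int
    p: float
    posthoc: list = field(default_factory=list)  # (pair, direction, p)
    selected: bool = False


def _f_from_ss(ssb: float, ssw: float, dfb: int, dfw: int) -> tuple:
    if dfw <= 0 or ssw <= 0:
        raise ValueError("within-group variance is zero or degrees of freedom exhausted")
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), float(stats.f.sf(F, dfb, dfw))


def anova_from_summary(groups: Sequence[GroupSummary]) -> dict:
    """One-way ANOVA from per-group (mean, SD, N).

    Exactly reproduces the raw-data ANOVA of any dataset with these group
    summaries: SSB = Σ nᵢ(mᵢ − m̄)², SSW = Σ (nᵢ−1)sᵢ².
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("summary ANOVA requires every group n >= 2")
    ns = np.array([g.n for g in groups], dtype=float)
    ms = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N = ns.sum()
    grand = float((ns * ms).sum() / N)
    ssb = float((ns * (ms - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb, dfw = k - 1, int(N) - k
    F, p = _f_from_ss(ssb, ssw, dfb, dfw)
    return {"F": F, "df_between": dfb, "df_within": dfw, "p": p, "grand_mean": grand}


def summarize_groups(y: pd.Series, classes: pd.Series) -> list:
    """Per-class GroupSummary list, pairwise-complete, in class order."""
    ok = y.notna() & classes.notna()
    ys, cs = y[ok], classes[ok]
    out = []
    for label in pd.unique(cs):
        vals = ys[cs == label].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
        out.append(GroupSummary(label=str(label), mean=float(vals.mean()), sd=sd, n=len(vals)))
    return out


def anova_oneway(
    y: pd.Series,
    classes: pd.Series,
    locus: str = "",
    alpha: float = 0.05,
) -> ScreenResult:
    """Classic one-way ANOVA of ``y`` across genotype classes.

    Subjects with missing phenotype or class are excluded pairwise.  Raw
    sums of squares are computed directly (not via group summaries) so the
    summary-statistic route is an independent check.
    """
    ok = y.notna() & classes.notna()
    ys = y[ok].to_numpy(dtype=float)
    cs = classes[ok].to_numpy()
    labels = pd.unique(cs)
    k = len(labels)
    if k < 2:
        raise ValueError(f"all subjects fall in one genotype class at {locus or '<locus>'}")
    N = len(ys)
    grand = ys.mean()
    ssb = 0.0
    ssw = 0.0
    for lab in labels:
        grp = ys[cs == lab]
        ssb += len(grp) * (grp.mean() - grand) ** 2
        ssw += ((grp - grp.mean()) ** 2).sum()
    dfb, dfw = k - 1, N - k
    F, p = _f_from_ss(ssb, ssw, dfb, dfw)
    groups = summarize_groups(y, classes)
    posthoc = posthoc_pairwise(groups, ms_within=ssw / dfw, df_within=dfw)
    return ScreenResult(
        locus=locus,
        groups=groups,
        F=F,
        df_between=dfb,
        df_within=dfw,
        p=p,
        posthoc=posthoc,
        selected=bool(p < alpha),
    )


def posthoc_pairwise(
    groups: Sequence[GroupSummary],
    ms_within: Optional[float] = None,
    df_within: Optional[int] = None,
    alpha: float = 0.05,
) -> list:
    """Fisher-LSD pairwise comparisons using the pooled ANOVA error variance.

    Uncorrected two-sample t tests with the pooled within-group mean square;
    each entry is ``(pair, direction, p)`` where ``direction`` (e.g.
    ``"CC<AA"``) is filled only when p < alpha.
    """
    if ms_within is None or df_within is None:
        ns = np.array([g.n for g in groups], dtype=float)
        sds = np.array([g.sd for g in groups], dtype=float)
        df_within = int(ns.sum()) - len(groups)
        ms_within = float(((ns - 1) * sds**2).sum() / df_within)
    out = []
    for ga, gb in combinations(groups, 2):
        se = np.sqrt(ms_within * (1.0 / ga.n + 1.0 / gb.n))
        t = (ga.mean - gb.mean) / se
        p = float(2 * stats.t.sf(abs(t), df_within))
        direction = ""
        if p < alpha:
            direction = f"{ga.label}<{gb.label}" if ga.mean < gb.mean else f"{gb.label}<{ga.label}"
        out.append(((ga.label, gb.label), direction, p))
    return out


def screen_panel(
    g: GenotypeTable,
    y: pd.Series,
    alpha_screen: float = 0.05,
    vntr_rules: Optional[dict] = None,
) -> list:
    """Run the screening ANOVA at every retained locus.

    Genotype classes are the same partitions the coding stage uses (1/2/3
    classes for autosomal SNPs, two pooled-sex groups for X-linked loci,
    rule-defined groups for VNTRs), so screening and regression can never
    disagree about group membership.  Loci whose observed data collapse to a
    single class are reported unselected with F = NaN.
    """
    codes, labels = class_codes(g, vntr_rules)
    y = y.reindex(g.subjects)
    results = []
    for spec in g.loci:
        lid = spec.locus_id
        cls = codes[lid]
        named = cls.map(lambda c, lab=labels[lid]: lab[c] if c >= 0 else np.nan)
        try:
            res = anova_oneway(y, named, locus=lid, alpha=alpha_screen)
        except ValueError:
            res = ScreenResult(
                locus=lid,
                groups=summarize_groups(y, named),
                F=float("nan"),
                df_between=0,
                df_within=0,
                p=float("nan"),
                selected=False,
            )
        results.append(res)
    return results


def screen_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Association-table-style frame: group summaries, F, p, post hoc."""
    rows = []
    for r in results:
        row: dict = {"locus": r.locus, "F": r.F, "p": r.p, "selected": r.selected}
        for j, grp in enumerate(r.groups, start=1):
            row[f"group{j}"] = grp.label
            row[f"mean{j}"] = grp.mean
            row[f"sd{j}"] = grp.sd
            row[f"n{j}"] = grp.n
        row["posthoc"] = "; ".join(d for _, d, _ in r.posthoc if d)
        rows.append(row)
    return pd.DataFrame(rows)
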