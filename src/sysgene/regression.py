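"""System-level regression models.

Step 2 of the pipeline.  Model 1 enters the main effects of every screened
locus simultaneously; Model 2 adds pairwise SNP×SNP interaction terms —
products of de-meaned genotype codes — chosen by forward stepwise selection
on the partial-F p-value.  Subsystem-restricted fits decompose the system
R², environment covariates are offered to the model by the same stepwise
rule, and nested models are compared by the change in −2 log-likelihood
against a chi-square reference, with AIC/BIC reported as
−2LL + 2p and −2LL + p·ln n (p = predictor count excluding the intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .loci import SUBSYSTEMS
from .qc import CodedDesign


# ---------------------------------------------------------------------------
# information-criterion and LRT primitives (Table-5-style arithmetic)
# ---------------------------------------------------------------------------


def gaussian_neg2ll(rss: float, n: int) -> float:
    """−2 log-likelihood of a Gaussian linear model with MLE variance RSS/n."""
    return float(n * np.log(2 * np.pi) + n * np.log(rss / n) + n)


def aic(neg2ll: float, n_predictors: int) -> float:
    """AIC = −2LL + 2p, with p excluding the intercept."""
    return float(neg2ll + 2 * n_predictors)


def bic(neg2ll: float, n_predictors: int, n_rows: int) -> float:
    """BIC = −2LL + p·ln(n), with p excluding the intercept."""
    return float(neg2ll + n_predictors * np.log(n_rows))


def lrt_pvalue(delta_neg2ll: float, df_diff: int) -> float:
    """Upper-tail chi-square probability of a −2LL drop between nested fits."""
    if df_diff == 0:
        return 1.0
    return float(stats.chi2.sf(delta_neg2ll, df=df_diff))


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """An OLS fit with the bookkeeping the pipeline reports."""

    predictors: list
    params: pd.Series  # includes 'const'
    tvalues: pd.Series
    pvalues: pd.Series
    R2: float
    adjR2: float
    F_overall: float
    df_model: int
    df_resid: int
    neg2LL: float
    AIC: float
    BIC: float
    n_rows: int
    row_index: pd.Index
    X: pd.DataFrame  # predictor matrix on analysis rows (no constant)
    y: pd.Series
    entered: list = field(default_factory=list)  # stepwise entry order
    empty: bool = False  # True for the intercept-only convention fit

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.params, "T": self.tvalues, "p": self.pvalues}
        ).rename_axis("regressor")

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "t": {k: float(v) for k, v in self.tvalues.items()},
            "p": {k: float(v) for k, v in self.pvalues.items()},
            "R2": self.R2,
            "adjR2": self.adjR2,
            "F": self.F_overall,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "neg2LL": self.neg2LL,
            "AIC": self.AIC,
            "BIC": self.BIC,
            "n_rows": self.n_rows,
            "entered": list(self.entered),
            "empty": self.empty,
        }


@dataclass
class ModelComparison:
    base: ModelFit
    augmented: ModelFit
    delta_R2: float
    delta_neg2LL: float
    df_diff: int
    p: float

    def to_dict(self) -> dict:
        return {
            "delta_R2": self.delta_R2,
            "delta_neg2LL": self.delta_neg2LL,
            "df_diff": self.df_diff,
            "p": self.p,
        }


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


def _complete_rows(y: pd.Series, X: pd.DataFrame) -> pd.Index:
    ok = y.notna()
    if X.shape[1]:
        ok &= X.notna().all(axis=1)
    return y.index[ok]


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list:
    """Greedy scan naming columns that do not increase matrix rank."""
    bad = []
    kept = np.ones((X.shape[0], 1))
    rank = 1
    for j, name in enumerate(names):
        trial = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept, rank = trial, r
        else:
            bad.append(name)
    return bad


def _intercept_only_fit(y: pd.Series) -> ModelFit:
    rows = y.index[y.notna()]
    yv = y.loc[rows].to_numpy(dtype=float)
    n = len(yv)
    rss = float(((yv - yv.mean()) ** 2).sum())
    neg2ll = gaussian_neg2ll(rss, n)
    params = pd.Series({"const": float(yv.mean())})
    nan = pd.Series({"const": float("nan")})
    return ModelFit(
        predictors=[],
        params=params,
        tvalues=nan,
        pvalues=nan,
        R2=0.0,
        adjR2=0.0,
        F_overall=float("nan"),
        df_model=0,
        df_resid=n - 1,
        neg2LL=neg2ll,
        AIC=aic(neg2ll, 0),
        BIC=bic(neg2ll, 0, n),
        n_rows=n,
        row_index=rows,
        X=pd.DataFrame(index=rows),
        y=y.loc[rows],
        empty=True,
    )


def fit_ols(y: pd.Series, X: pd.DataFrame, rows: Optional[pd.Index] = None) -> ModelFit:
    """Ordinary least squares with intercept on listwise-complete rows.

    Reports per-coefficient t and two-sided p on the residual degrees of
    freedom, R²/adjusted R², the overall F, and the Gaussian −2LL with the
    AIC/BIC conventions of this package.  Raises on rank deficiency, naming
    the collinear columns.
    """
    X = X.copy()
    if rows is None:
        rows = _complete_rows(y, X)
    if X.shape[1] == 0:
        return _intercept_only_fit(y.loc[rows])
    if len(rows) < X.shape[1] + 2:
        raise ValueError("too few complete rows for the requested predictors")
    Xv = X.loc[rows].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(rows)), Xv])) < Xv.shape[1] + 1:
        bad = _collinear_columns(Xv, list(X.columns))
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    yv = y.loc[rows]
    exog = sm.add_constant(X.loc[rows], has_constant="add")
    res = sm.OLS(yv.to_numpy(dtype=float), exog.to_numpy(dtype=float)).fit()
    names = list(exog.columns)
    n = len(rows)
    p = Xv.shape[1]
    neg2ll = float(-2.0 * res.llf)
    return ModelFit(
        predictors=list(X.columns),
        params=pd.Series(res.params, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        R2=float(res.rsquared),
        adjR2=float(res.rsquared_adj),
        F_overall=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        neg2LL=neg2ll,
        AIC=aic(neg2ll, p),
        BIC=bic(neg2ll, p, n),
        n_rows=n,
        row_index=rows,
        X=X.loc[rows],
        y=yv,
    )


# ---------------------------------------------------------------------------
# forward stepwise (partial-F entry)
# ---------------------------------------------------------------------------


def _rss(yv: np.ndarray, Xv: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = yv - Xv @ beta
    return float(resid @ resid)


def stepwise_select(
    yv: np.ndarray,
    base: np.ndarray,
    candidates: Sequence,
    alpha_enter: float = 0.05,
) -> tuple:
    """Numpy core of forward stepwise selection.

    ``base`` already includes the intercept column.  ``candidates`` is a
    sequence of ``(name, matrix)`` pairs; multi-column matrices enter as a
    yoked block (one partial-F test with df = block width).  At each step
    the candidate with the smallest partial-F p-value enters while that
    p-value is below ``alpha_enter``; ties break in candidate order; blocks
    that do not increase the design rank are skipped.  Returns
    ``(entered_names, rss, X)``.
    """
    n = len(yv)
    X = base
    rank = np.linalg.matrix_rank(X)
    rss0 = _rss(yv, X)
    remaining = list(candidates)
    entered: list = []
    while remaining:
        best = None  # (p, order_idx, name, mat, rss1, q)
        for idx, (name, mat) in enumerate(remaining):
            q = mat.shape[1]
            trial = np.column_stack([X, mat])
            if np.linalg.matrix_rank(trial) < rank + q:
                continue
            rss1 = _rss(yv, trial)
            df2 = n - trial.shape[1]
            if df2 <= 0 or rss1 <= 0:
                continue
            F = ((rss0 - rss1) / q) / (rss1 / df2)
            p = float(stats.f.sf(F, q, df2))
            if best is None or p < best[0]:
                best = (p, idx, name, mat, rss1, q)
        if best is None or best[0] >= alpha_enter:
            break
        p, idx, name, mat, rss1, q = best
        X = np.column_stack([X, mat])
        rank += q
        rss0 = rss1
        entered.append(name)
        remaining = [c for c in remaining if c[0] != name]
    return entered, rss0, X


def forward_stepwise(
    y: pd.Series,
    X_base: pd.DataFrame,
    candidates: Sequence,
    alpha_enter: float = 0.05,
    rows: Optional[pd.Index] = None,
) -> ModelFit:
    """Forward stepwise selection over candidate predictor blocks.

    ``candidates`` is a sequence of ``(name, DataFrame)`` pairs (one or more
    columns each; multi-column blocks are yoked).  Base columns are always
    retained; no backward elimination.  Returns the final fit with the entry
    order in ``ModelFit.entered``.
    """
    base_cols = set(X_base.columns)
    for name, df_ in candidates:
        if set(df_.columns) & base_cols:
            raise ValueError(f"candidate {name!r} overlaps the base columns")
    if rows is None:
        rows = _complete_rows(y, X_base)
        for _, df_ in candidates:
            rows = rows.intersection(_complete_rows(y, df_), sort=False)
    yv = y.loc[rows].to_numpy(dtype=float)
    base = np.column_stack(
        [np.ones(len(rows))] + [X_base.loc[rows, c].to_numpy(dtype=float) for c in X_base.columns]
    ) if X_base.shape[1] else np.ones((len(rows), 1))
    cand = [(name, df_.loc[rows].to_numpy(dtype=float)) for name, df_ in candidates]
    entered, _, _ = stepwise_select(yv, base, cand, alpha_enter)
    chosen = {name: df_ for name, df_ in candidates}
    X_final = pd.concat([X_base.loc[rows]] + [chosen[n].loc[rows] for n in entered], axis=1)
    fit = fit_ols(y, X_final, rows=rows)
    fit.entered = entered
    return fit


# ---------------------------------------------------------------------------
# pipeline models
# ---------------------------------------------------------------------------


def design_columns(design: CodedDesign, loci: Sequence[str]) -> pd.DataFrame:
    cols: list = []
    for lid in loci:
        cols.extend(design.locus_columns[lid])
    return design.values[cols]


def build_model1(design: CodedDesign, selected_loci: Sequence[str], y: pd.Series) -> ModelFit:
    """Main-effects model: every screened locus entered simultaneously."""
    selected_loci = list(selected_loci)
    if not selected_loci:
        raise ValueError("no loci passed screening")
    X = design_columns(design, selected_loci)
    return fit_ols(y, X)


def interaction_candidates(
    design: CodedDesign,
    loci: Sequence[str],
    rows: pd.Index,
) -> list:
    """All pairwise interaction blocks of the given loci.

    Each term is the product of de-meaned codes, itself re-centered over the
    analysis rows (the raw product has mean equal to the factors' sample
    covariance; re-centering zeroes it without changing any fit statistic
    except the intercept).  For a locus coded by multiple dummy columns, all
    cross products with the partner locus form one yoked block offered to
    the stepwise search together.
    """
    centered = {}
    for lid in loci:
        block = design.values.loc[rows, design.locus_columns[lid]]
        centered[lid] = block - block.mean(axis=0)
    out = []
    for a, b in combinations(loci, 2):
        cols = {}
        for ca in centered[a].columns:
            for cb in centered[b].columns:
                prod = centered[a][ca] * centered[b][cb]
                cols[f"{ca}×{cb}"] = prod - prod.mean()
        out.append((f"{a}×{b}", pd.DataFrame(cols, index=rows)))
    return out


def build_model2(
    design: CodedDesign,
    selected_loci: Sequence[str],
    y: pd.Series,
    alpha_enter: float = 0.05,
    model1: Optional[ModelFit] = None,
) -> ModelFit:
    """Model 1 plus forward-stepwise pairwise interaction terms.

    Candidates are the C(k, 2) de-meaned products of the Model 1 loci,
    evaluated on the Model 1 analysis rows.  An interaction is only
    reachable when both parent loci passed screening.
    """
    if model1 is None:
        model1 = build_model1(design, selected_loci, y)
    rows = model1.row_index
    X_base = design_columns(design, list(selected_loci)).loc[rows]
    cands = interaction_candidates(design, list(selected_loci), rows)
    return forward_stepwise(y, X_base, cands, alpha_enter=alpha_enter, rows=rows)


def fit_subsystems(
    design: CodedDesign,
    selected_loci: Sequence[str],
    y: pd.Series,
    alpha_enter: Optional[float] = None,
) -> dict:
    """Model-1-style fit per subsystem, restricted to its selected loci.

    With ``alpha_enter`` set, each subsystem additionally receives stepwise
    within-subsystem interaction terms (Model-2 style).  Subsystems with no
    selected loci get the intercept-only convention fit (R² = 0,
    ``empty=True``).
    """
    sub_of = {}
    for lid in selected_loci:
        col = design.locus_columns[lid][0]
        sub_of.setdefault(design.subsystem_of[col], []).append(lid)
    out = {}
    for subsystem in SUBSYSTEMS:
        loci = sub_of.get(subsystem, [])
        if not loci:
            out[subsystem] = _intercept_only_fit(y)
            continue
        m1 = build_model1(design, loci, y)
        if alpha_enter is None or len(loci) < 2:
            out[subsystem] = m1
        else:
            out[subsystem] = build_model2(design, loci, y, alpha_enter=alpha_enter, model1=m1)
    return out


def add_environment(
    y: pd.Series,
    genetic_fit: ModelFit,
    env: pd.DataFrame,
    alpha_enter: float = 0.05,
) -> tuple:
    """Offer environment covariates to a genetic model by forward stepwise.

    Covariates enter raw (unstandardized).  Rows are the genetic model's
    analysis rows intersected with environment-complete rows; the genetic
    base is refit on those rows so the comparison is between nested models
    on identical data.  Returns ``(fit, comparison-vs-genetic-base)``.
    """
    rows = genetic_fit.row_index.intersection(_complete_rows(y, env), sort=False)
    base_X = genetic_fit.X.loc[rows]
    base = fit_ols(y, base_X, rows=rows) if len(rows) != genetic_fit.n_rows else genetic_fit
    cands = [(c, env[[c]]) for c in env.columns]
    fit = forward_stepwise(y, base_X, cands, alpha_enter=alpha_enter, rows=rows)
    return fit, compare_models(base, fit)


def compare_models(base: ModelFit, augmented: ModelFit) -> ModelComparison:
    """Likelihood-ratio comparison of nested OLS fits on identical rows."""
    if not set(base.predictors) <= set(augmented.predictors):
        raise ValueError("models are not nested")
    if len(base.row_index) != len(augmented.row_index) or not base.row_index.equals(
        augmented.row_index
    ):
        raise ValueError("models were fit on different rows")
    df_diff = augmented.n_predictors - base.n_predictors
    delta = max(base.neg2LL - augmented.neg2LL, 0.0)
    return ModelComparison(
        base=base,
        augmented=augmented,
        delta_R2=float(augmented.R2 - base.R2),
        delta_neg2LL=float(delta),
        df_diff=df_diff,
        p=lrt_pvalue(delta, df_diff),
    )


def comparison_table(rows: Sequence) -> pd.DataFrame:
    """Model-comparison table: R², ΔR², −2LL, df, p, AIC, BIC per model."""
    out = []
    for name, fit, comp in rows:
        out.append(
            {
                "model": name,
                "R2": fit.R2,
                "delta_R2": float("nan") if comp is None else comp.delta_R2,
                "neg2LL": fit.neg2LL,
                "df": fit.n_predictors,
                "p": float("nan") if comp is None else comp.p,
                "AIC": fit.AIC,
                "BIC": fit.BIC,
            }
        )
    return pd.DataFrame(out)
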