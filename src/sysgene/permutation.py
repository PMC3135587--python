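"""Whole-pipeline permutation inference.

Step 3.  The phenotype is shuffled across subjects while the genotype and
environment structure stays intact; the *entire* selection-and-fit pipeline
(per-locus ANOVA screening at the uncorrected threshold, Model 1 on whatever
loci the shuffled data nominate, Model 2 via forward stepwise over their
interactions, subsystem-restricted fits) is re-run on each shuffle.  The
null distribution of model R² therefore carries the full selection optimism
of the procedure, and the empirical p-value
(#{null ≥ observed} + 1) / (B + 1) is honest about post-selection inflation
where a parametric p on the screened model would not be.

Permutations are seeded from a root seed through counter-based Philox keys,
so the result is independent of evaluation order and reproducible bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .loci import SUBSYSTEMS
from .qc import class_codes, code_loci
from .regression import stepwise_select
from .simulate import make_rng

SCOPES = ("whole",) + SUBSYSTEMS
MODELS = ("model1", "model2")


def empirical_p(null: Sequence[float], observed: float) -> float:
    """(#{null ≥ observed} + 1) / (B + 1); ties count as ≥."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    return float((np.sum(null >= observed) + 1) / (null.size + 1))


def permute_phenotype(y: pd.Series, seed: int = 0) -> pd.Series:
    """Uniform random permutation of phenotype values across subjects."""
    rng = make_rng(seed, 5)
    vals = y.to_numpy(copy=True)
    return pd.Series(rng.permutation(vals), index=y.index, name=y.name)


def _adj_r2(r2: float, n: int, p: int) -> float:
    if p == 0:
        return 0.0
    denom = n - p - 1
    if denom <= 0:
        return float("nan")
    return float(1.0 - (1.0 - r2) * (n - 1) / denom)


@dataclass
class PermutationResult:
    """Null R² distributions and empirical p-values per model and scope."""

    B: int
    seed: int
    observed: dict  # model -> scope -> {"R2", "adjR2", "n_selected"}
    null_R2: dict  # model -> scope -> np.ndarray (B,)
    null_adjR2: dict
    empirical_p: dict = field(default_factory=dict)  # model -> scope -> {"R2", "adjR2"}

    def finalize(self) -> "PermutationResult":
        self.empirical_p = {
            m: {
                s: {
                    "R2": empirical_p(self.null_R2[m][s], self.observed[m][s]["R2"]),
                    "adjR2": empirical_p(self.null_adjR2[m][s], self.observed[m][s]["adjR2"]),
                }
                for s in SCOPES
            }
            for m in MODELS
        }
        return self

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "seed": self.seed,
            "observed": self.observed,
            "empirical_p": self.empirical_p,
            "null_R2": {m: {s: list(map(float, v)) for s, v in d.items()} for m, d in self.null_R2.items()},
            "null_adjR2": {
                m: {s: list(map(float, v)) for s, v in d.items()} for m, d in self.null_adjR2.items()
            },
        }


class PipelineEngine:
    """Precomputed screening-and-fit machinery for repeated evaluation.

    Genotype class partitions, coded predictor columns and subsystem labels
    are fixed once from a QC'd genotype table; :meth:`evaluate` then runs the
    full screen → Model 1 → Model 2 → subsystem decomposition for any
    phenotype vector (observed or permuted) without touching pandas.
    """

    def __init__(self, g: GenotypeTable, vntr_rules: Optional[dict] = None):
        codes, _ = class_codes(g, vntr_rules)
        design = code_loci(g, vntr_rules)
        self.design = design
        self.subjects = g.subjects
        self.loci = [s.locus_id for s in g.loci]
        self.codes = {lid: codes[lid].to_numpy(dtype=np.int64) for lid in self.loci}
        self.n_classes = {lid: int(self.codes[lid].max()) + 1 for lid in self.loci}
        self.columns = {
            lid: design.values[design.locus_columns[lid]].to_numpy(dtype=float)
            for lid in self.loci
        }
        self.subsystem = {
            lid: design.subsystem_of[design.locus_columns[lid][0]] for lid in self.loci
        }
        self._crit_cache: dict = {}

    # -- screening -------------------------------------------------------

    def _crit(self, dfb: int, dfw: int, alpha: float) -> float:
        key = (dfb, dfw, alpha)
        if key not in self._crit_cache:
            self._crit_cache[key] = float(stats.f.isf(alpha, dfb, dfw))
        return self._crit_cache[key]

    def screen(self, yv: np.ndarray, alpha_screen: float) -> list:
        """Locus ids whose one-way ANOVA on ``yv`` has p < alpha_screen."""
        y_ok = ~np.isnan(yv)
        selected = []
        for lid in self.loci:
            cls = self.codes[lid]
            mask = (cls >= 0) & y_ok
            c = cls[mask]
            yy = yv[mask]
            k = self.n_classes[lid]
            counts = np.bincount(c, minlength=k)
            present = counts > 0
            kp = int(present.sum())
            N = yy.size
            if kp < 2 or N <= kp:
                continue
            sums = np.bincount(c, weights=yy, minlength=k)
            ssq = np.bincount(c, weights=yy * yy, minlength=k)
            grand = sums.sum() / N
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(present, sums / np.maximum(counts, 1), 0.0)
            ssb = float((counts * (means - grand) ** 2)[present].sum())
            ssw = float(ssq.sum() - (counts * means**2)[present].sum())
            dfb, dfw = kp - 1, N - kp
            if ssw <= 0:
                continue
            F = (ssb / dfb) / (ssw / dfw)
            if F > self._crit(dfb, dfw, alpha_screen):
                selected.append(lid)
        return selected

    # -- fitting -----------------------------------------------------------

    def _fit_scope(
        self, yv: np.ndarray, loci: list, alpha_enter: float, with_model2: bool
    ) -> dict:
        out = {
            "model1": {"R2": 0.0, "adjR2": 0.0, "p": 0},
            "model2": {"R2": 0.0, "adjR2": 0.0, "p": 0},
            "n_selected": len(loci),
        }
        if not loci:
            return out
        X = np.column_stack([self.columns[lid] for lid in loci])
        rows = ~(np.isnan(X).any(axis=1) | np.isnan(yv))
        Xr, yr = X[rows], yv[rows]
        n = len(yr)
        p1 = Xr.shape[1]
        if n < p1 + 2:
            return out
        tss = float(((yr - yr.mean()) ** 2).sum())
        if tss <= 0:
            return out
        base = np.column_stack([np.ones(n), Xr])
        beta, _, _, _ = np.linalg.lstsq(base, yr, rcond=None)
        resid = yr - base @ beta
        rss1 = float(resid @ resid)
        r2_1 = 1.0 - rss1 / tss
        out["model1"] = {"R2": r2_1, "adjR2": _adj_r2(r2_1, n, p1), "p": p1}
        if not with_model2:
            out["model2"] = dict(out["model1"])
            return out
        # interaction candidates: de-meaned products, yoked per locus pair
        cols = {lid: Xr[:, i : i + self.columns[lid].shape[1]] for lid, i in
                zip(loci, np.cumsum([0] + [self.columns[l].shape[1] for l in loci[:-1]]))}
        cands = []
        for a, b in combinations(loci, 2):
            ca = cols[a] - cols[a].mean(axis=0)
            cb = cols[b] - cols[b].mean(axis=0)
            prod = np.einsum("ni,nj->nij", ca, cb).reshape(n, -1)
            cands.append((f"{a}×{b}", prod - prod.mean(axis=0)))
        entered, rss2, X2 = stepwise_select(yr, base, cands, alpha_enter)
        p2 = X2.shape[1] - 1
        r2_2 = 1.0 - rss2 / tss
        out["model2"] = {"R2": r2_2, "adjR2": _adj_r2(r2_2, n, p2), "p": p2}
        return out

    def evaluate(
        self,
        yv: np.ndarray,
        alpha_screen: float = 0.05,
        alpha_enter: float = 0.05,
    ) -> dict:
        """Full pipeline pass: returns per-scope Model 1/2 R² summaries."""
        selected = self.screen(yv, alpha_screen)
        result = {"selected": selected, "scopes": {}}
        result["scopes"]["whole"] = self._fit_scope(yv, selected, alpha_enter, True)
        for subsystem in SUBSYSTEMS:
            sub_loci = [lid for lid in selected if self.subsystem[lid] == subsystem]
            result["scopes"][subsystem] = self._fit_scope(yv, sub_loci, alpha_enter, True)
        return result


def run_null_pipeline(
    g: GenotypeTable,
    y: pd.Series,
    B: int = 1000,
    seed: int = 0,
    alpha_screen: float = 0.05,
    alpha_enter: float = 0.05,
    vntr_rules: Optional[dict] = None,
    engine: Optional[PipelineEngine] = None,
) -> PermutationResult:
    """Permutation null of the whole screen-then-fit pipeline.

    Per permutation the phenotype is shuffled and screening, Model 1 and the
    stepwise Model 2 are re-run from scratch (the number of selected loci
    varies freely; shuffles selecting no locus contribute R² = 0).  One
    shuffle per iteration feeds the whole-system and all subsystem scopes, so
    scopes differ only in their statistic, not their Monte Carlo noise.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if engine is None:
        engine = PipelineEngine(g, vntr_rules)
    yv = y.reindex(engine.subjects).to_numpy(dtype=float)
    obs = engine.evaluate(yv, alpha_screen, alpha_enter)
    observed = {
        m: {
            s: {
                "R2": obs["scopes"][s][m]["R2"],
                "adjR2": obs["scopes"][s][m]["adjR2"],
                "n_selected": obs["scopes"][s]["n_selected"],
            }
            for s in SCOPES
        }
        for m in MODELS
    }
    null_R2 = {m: {s: np.empty(B) for s in SCOPES} for m in MODELS}
    null_adj = {m: {s: np.empty(B) for s in SCOPES} for m in MODELS}
    for b in range(B):
        rng = make_rng(seed, 5, b)
        perm = engine_evaluate_permuted(engine, yv, rng, alpha_screen, alpha_enter)
        for m in MODELS:
            for s in SCOPES:
                null_R2[m][s][b] = perm["scopes"][s][m]["R2"]
                null_adj[m][s][b] = perm["scopes"][s][m]["adjR2"]
    return PermutationResult(
        B=B, seed=seed, observed=observed, null_R2=null_R2, null_adjR2=null_adj
    ).finalize()


def engine_evaluate_permuted(
    engine: PipelineEngine,
    yv: np.ndarray,
    rng: np.random.Generator,
    alpha_screen: float,
    alpha_enter: float,
) -> dict:
    return engine.evaluate(rng.permutation(yv), alpha_screen, alpha_enter)


def fixed_model_null_r2(
    g: GenotypeTable,
    y: pd.Series,
    loci: Sequence[str],
    B: int = 100,
    seed: int = 0,
    vntr_rules: Optional[dict] = None,
) -> np.ndarray:
    """Null R² of a *pre-declared* locus set (no screening) under permutation.

    The contrast between this distribution and the screened-pipeline null
    exhibits selection optimism: screening inflates null R² because each
    permutation gets to keep whichever loci happened to correlate with the
    shuffled phenotype.
    """
    engine = PipelineEngine(g, vntr_rules)
    yv = y.reindex(engine.subjects).to_numpy(dtype=float)
    out = np.empty(B)
    for b in range(B):
        rng = make_rng(seed, 6, b)
        res = engine._fit_scope(rng.permutation(yv), list(loci), alpha_enter=1e-12, with_model2=False)
        out[b] = res["model1"]["R2"]
    return out
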