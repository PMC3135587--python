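"""Synthetic cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: a subject × locus genotype table with within-gene LD blocks,
X-linked hemizygous male calls and a multi-allelic VNTR; a quantitative
phenotype carrying small additive and pairwise-interaction genetic effects
plus an environmental contribution; Likert item-level responses with a
target internal consistency; and count-valued life-event covariates with a
target correlation structure (Gaussian copula over Poisson marginals).

All randomness flows through counter-based Philox generators keyed on an
explicit seed — no global state; identical seed and configuration give a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import FEMALE, MALE, GenotypeTable, make_call
from .loci import LocusSpec, default_panel
from .qc import code_loci

ENV_COLUMNS = ("parental_warmth", "events_primary", "events_secondary", "events_college")

# Default environment structure: scale means and the inter-scale correlation
# targets of the emulated study population (warmth negatively related to
# stressful events; event counts in the three life periods positively
# inter-correlated).
ENV_MEANS = {
    "parental_warmth": 53.0,
    "events_primary": 2.7,
    "events_secondary": 4.5,
    "events_college": 2.5,
}
ENV_CORR = pd.DataFrame(
    [
        [1.00, -0.11, -0.10, -0.18],
        [-0.11, 1.00, 0.34, 0.24],
        [-0.10, 0.34, 1.00, 0.41],
        [-0.18, 0.24, 0.41, 1.00],
    ],
    index=list(ENV_COLUMNS),
    columns=list(ENV_COLUMNS),
)

PHENOTYPE_MEAN = 122.3
PHENOTYPE_SD = 15.7


def make_rng(seed: int, *keys: int) -> np.random.Generator:
    """Philox generator keyed on (seed, *keys); independent per key path."""
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), *map(int, keys)])))


# ---------------------------------------------------------------------------
# effect specification
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Generative truth for the phenotype.

    ``additive_effects`` act on the 1/2/3 (or 1/2) genotype codes;
    ``interaction_effects`` on products of de-meaned codes of locus pairs;
    ``environment_effects`` on raw covariate columns; Gaussian noise with
    ``noise_sd`` closes the model.  When ``target_total_genetic_R2`` is set,
    all genetic coefficients are rescaled at simulation time so the realized
    genetic variance fraction matches it.
    """

    intercept: float = 0.0
    additive_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)  # (a, b) -> coef
    environment_effects: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    target_total_genetic_R2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        declared = set(self.additive_effects)
        for a, b in self.interaction_effects:
            declared.update((a, b))
        self.causal_loci = sorted(declared)


def study_effects(panel: Optional[Sequence[LocusSpec]] = None) -> EffectSpec:
    """Default generative truth mirroring the emulated study's findings.

    Ten causal autosomal SNPs spread over the four subsystems carry additive
    effects whose signs and relative sizes follow the study's reported
    coefficient pattern, analytically rescaled (coded-genotype variance
    2q(1-q) under HWE) so main effects explain ~12% of phenotype variance;
    three cross-subsystem interactions add ~3%; recent stressful life events
    contribute ~1 phenotype point per event.  Intercept and noise place the
    phenotype at mean ≈ 122.3, SD ≈ 15.7.
    """
    if panel is None:
        panel = default_panel()
    maf = {s.locus_id: s.target_maf for s in panel}
    total_var = PHENOTYPE_SD**2
    raw_additive = {
        "rsTH01": 6.77,
        "rsTH06": -0.9,
        "rsDBH01": -2.88,
        "rsSLC6A301": 0.88,
        "rsDRD201": 4.57,
        "rsNLN01": 3.98,
        "rsNLN02": -3.14,
        "rsNLN05": 2.90,
        "rsNTSR101": -5.36,
        "rsNTSR201": -2.79,
    }
    raw_inter = {
        ("rsNTSR201", "rsSLC6A301"): -6.77,
        ("rsSLC6A301", "rsNLN05"): -4.95,
        ("rsTH01", "rsDRD201"): 8.18,
    }
    code_var = {lid: 2 * maf[lid] * (1 - maf[lid]) for lid in raw_additive}
    v_main_raw = sum(b**2 * code_var[lid] for lid, b in raw_additive.items())
    s_main = float(np.sqrt(0.12 * total_var / v_main_raw))
    additive = {lid: b * s_main for lid, b in raw_additive.items()}
    v_int_raw = sum(
        g**2 * (2 * maf[a] * (1 - maf[a])) * (2 * maf[b] * (1 - maf[b]))
        for (a, b), g in raw_inter.items()
    )
    s_int = float(np.sqrt(0.03 * total_var / v_int_raw))
    interactions = {pair: g * s_int for pair, g in raw_inter.items()}
    env_beta = 1.03
    v_env = env_beta**2 * ENV_MEANS["events_college"]  # Poisson variance = mean
    noise_sd = float(np.sqrt(total_var * (1 - 0.15) - v_env))
    intercept = (
        PHENOTYPE_MEAN
        - sum(b * (1 + 2 * maf[lid]) for lid, b in additive.items())
        - env_beta * ENV_MEANS["events_college"]
    )
    return EffectSpec(
        intercept=float(intercept),
        additive_effects=additive,
        interaction_effects=interactions,
        environment_effects={"events_college": env_beta},
        noise_sd=noise_sd,
    )


def null_effects(noise_sd: float = PHENOTYPE_SD, intercept: float = PHENOTYPE_MEAN) -> EffectSpec:
    """All genetic and environmental coefficients zero (pure noise)."""
    return EffectSpec(intercept=intercept, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _call_matrix(labels: Sequence[str]) -> np.ndarray:
    """Lookup table of canonical call strings per allele-index pair."""
    k = len(labels)
    mat = np.empty((k, k), dtype=object)
    for i in range(k):
        for j in range(k):
            mat[i, j] = make_call((labels[i], labels[j]))
    return mat


def _pool_haplotypes(block_loci: Sequence[LocusSpec], pool_size: int) -> np.ndarray:
    """Haplotype pool (pool_size × loci) of allele indices.

    Minor alleles are placed on the leading haplotypes (nested layout), so
    loci of one block are maximally correlated given their frequencies; each
    locus keeps at least one haplotype of either allele so the pool is never
    monomorphic.  Pool allele frequencies are target frequencies quantized
    to multiples of 1/pool_size.
    """
    pool = np.zeros((pool_size, len(block_loci)), dtype=np.int64)
    for j, spec in enumerate(block_loci):
        m = int(np.clip(round(spec.target_maf * pool_size), 1, pool_size - 1))
        pool[:m, j] = 1  # allele index 1 = minor
    return pool


def simulate_genotypes(
    loci: Sequence[LocusSpec],
    n_subjects: int,
    sex_ratio: float = 208.0 / 480.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    with_quality: bool = False,
    low_quality_rate: float = 0.005,
    pool_sizes: Optional[dict] = None,
    default_pool_size: int = 2,
) -> GenotypeTable:
    """Draw a subject × locus genotype table.

    Loci sharing an ``ld_block`` are drawn from a common haplotype pool of
    ``pool_sizes[block]`` (default ``default_pool_size``) haplotypes — the
    smaller the pool, the higher the within-block r².  Unblocked loci are
    independent draws at their allele frequencies, so realized minor-allele
    frequencies converge to targets as n grows.  X-linked loci yield a
    single-allele call for males.  ``sex_ratio`` is the male fraction.
    """
    loci = list(loci)
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not loci:
        raise ValueError("locus panel is empty")
    known_blocks = {s.ld_block for s in loci if s.ld_block is not None}
    pool_sizes = dict(pool_sizes or {})
    for blk in pool_sizes:
        if blk not in known_blocks:
            raise ValueError(f"unknown block reference: {blk!r}")
    rng = make_rng(seed, 1)
    subjects = pd.Index([f"S{i + 1:04d}" for i in range(n_subjects)], name="subject")
    male = rng.random(n_subjects) < sex_ratio
    sex = pd.Series(np.where(male, MALE, FEMALE), index=subjects, name="sex")

    calls = pd.DataFrame(index=subjects, columns=[s.locus_id for s in loci], dtype=object)

    # blocked loci: shared haplotype draws
    blocks: dict = {}
    for s in loci:
        if s.ld_block is not None:
            blocks.setdefault(s.ld_block, []).append(s)
    drawn: dict = {}
    for blk, members in blocks.items():
        classes = {m.chromosome_class for m in members}
        if len(classes) > 1:
            raise ValueError(f"LD block {blk!r} mixes autosomal and X-linked loci")
        if any(m.locus_class != "snp" for m in members):
            raise ValueError(f"LD block {blk!r} must contain SNPs only")
        pool = _pool_haplotypes(members, pool_sizes.get(blk, default_pool_size))
        h1 = rng.integers(0, pool.shape[0], size=n_subjects)
        h2 = rng.integers(0, pool.shape[0], size=n_subjects)
        x_linked = classes == {"x_linked"}
        for j, spec in enumerate(members):
            a = pool[h1, j]
            b = pool[h2, j]
            drawn[spec.locus_id] = (a, b, x_linked)

    for spec in loci:
        labels = list(spec.allele_labels)
        callmat = _call_matrix(labels)
        if spec.locus_id in drawn:
            a, b, x_linked = drawn[spec.locus_id]
        else:
            freqs = np.asarray(spec.frequencies, dtype=float)
            a = rng.choice(len(labels), size=n_subjects, p=freqs)
            b = rng.choice(len(labels), size=n_subjects, p=freqs)
            x_linked = spec.chromosome_class == "x_linked"
        col = callmat[a, b]
        if x_linked:
            lab_arr = np.asarray(labels, dtype=object)
            col = np.where(male, lab_arr[a], col)
        calls[spec.locus_id] = col

    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.mask(pd.DataFrame(mask, index=calls.index, columns=calls.columns))

    quality = None
    if with_quality:
        low = rng.random(calls.shape) < low_quality_rate
        q = np.where(low, rng.uniform(0.0, 0.25, calls.shape), rng.uniform(0.25, 1.0, calls.shape))
        quality = pd.DataFrame(q, index=calls.index, columns=calls.columns)

    return GenotypeTable(loci=loci, calls=calls, sex=sex, quality=quality)


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------


def simulate_phenotype(
    genotypes: GenotypeTable,
    effects: EffectSpec,
    environment: Optional[pd.DataFrame] = None,
    seed: int = 0,
) -> pd.Series:
    """Phenotype = intercept + additive + interaction + environment + noise.

    Genotypes are coded exactly as the QC coding stage codes them
    (:func:`sysgene.qc.code_loci`); interaction terms multiply de-meaned
    codes.  Missing causal-locus codes are mean-imputed for generation only.
    """
    design = code_loci(genotypes)
    n = genotypes.n_subjects

    def coded(locus_id: str) -> np.ndarray:
        if locus_id not in design.locus_columns:
            raise KeyError(f"causal locus {locus_id} absent from genotypes")
        cols = design.locus_columns[locus_id]
        if len(cols) != 1:
            raise ValueError(f"additive/interaction effects need single-column loci: {locus_id}")
        x = design.values[cols[0]].to_numpy(dtype=float)
        m = np.nanmean(x)
        return np.where(np.isnan(x), m, x)

    genetic = np.zeros(n)
    for lid, beta in effects.additive_effects.items():
        genetic += beta * coded(lid)
    for (a, b), gamma in effects.interaction_effects.items():
        xa, xb = coded(a), coded(b)
        genetic += gamma * (xa - xa.mean()) * (xb - xb.mean())

    env_part = np.zeros(n)
    if effects.environment_effects:
        if environment is None:
            raise ValueError("environment_effects declared but no environment table given")
        for name, beta in effects.environment_effects.items():
            if name not in environment.columns:
                raise KeyError(f"environment column {name!r} missing")
            env_part += beta * environment[name].reindex(genotypes.subjects).to_numpy(dtype=float)

    if effects.target_total_genetic_R2 is not None:
        t = effects.target_total_genetic_R2
        v_g = genetic.var()
        v_rest = env_part.var() + effects.noise_sd**2
        if v_g <= 0:
            raise ValueError("cannot rescale: genetic component has zero variance")
        genetic = genetic * np.sqrt(t * v_rest / (v_g * (1 - t)))

    rng = make_rng(seed, 2)
    noise = rng.normal(0.0, effects.noise_sd, size=n)
    y = effects.intercept + genetic + env_part + noise
    return pd.Series(y, index=genotypes.subjects, name="hsp_total")


# ---------------------------------------------------------------------------
# items
# ---------------------------------------------------------------------------


def simulate_items(
    totals: pd.Series,
    n_items: int = 27,
    target_alpha: float = 0.817,
    item_range: tuple = (1, 7),
    seed: int = 0,
) -> pd.DataFrame:
    """Integer item responses whose totals track ``totals`` and whose
    internal consistency approximates ``target_alpha``.

    A one-factor model: item_j = sqrt(r)·z + sqrt(1−r)·e_j with the
    inter-item correlation r solved from the Spearman-Brown relation
    alpha = k·r / (1 + (k−1)·r), then discretized onto the item scale.
    Rounding attenuates alpha slightly below target (by ~1% of item variance
    per unit of rounding noise).
    """
    k = int(n_items)
    if k < 2:
        raise ValueError("n_items must be >= 2")
    if not (0.0 < target_alpha < 1.0):
        raise ValueError("target_alpha must lie in (0, 1)")
    lo, hi = item_range
    if hi - lo < 2:
        raise ValueError("alpha target unreachable: item scale too narrow")
    r = target_alpha / (k - target_alpha * (k - 1))
    if not (0.0 < r < 1.0):
        raise ValueError("alpha target unreachable at this item count")
    z = (totals - totals.mean()) / totals.std(ddof=1)
    zv = z.to_numpy(dtype=float)
    rng = make_rng(seed, 3)
    e = rng.normal(size=(k, len(zv)))
    latent = np.sqrt(r) * zv[None, :] + np.sqrt(1 - r) * e
    mid = (lo + hi) / 2.0
    spread = (hi - lo) / 4.0
    scores = np.clip(np.rint(mid + spread * latent), lo, hi)
    scores[:, np.isnan(zv)] = np.nan
    return pd.DataFrame(
        scores, index=[f"item{j + 1:02d}" for j in range(k)], columns=totals.index
    )


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


def simulate_environment(
    n_subjects: int,
    correlation_targets: Optional[pd.DataFrame] = None,
    means: Optional[dict] = None,
    warmth_sd: float = 7.5,
    seed: int = 0,
    subjects: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Environment covariates via a Gaussian copula.

    Life-event columns get Poisson marginals (non-negative integer counts)
    with the given means; parental warmth gets a rounded normal marginal.
    The latent normal correlation equals the target, so realized Pearson
    correlations are mildly attenuated by the discrete marginals.
    """
    corr = ENV_CORR if correlation_targets is None else pd.DataFrame(correlation_targets)
    if correlation_targets is not None and list(corr.columns) == list(range(corr.shape[1])):
        corr.index = corr.columns = list(ENV_COLUMNS)[: corr.shape[1]]
    names = list(corr.columns)
    C = corr.to_numpy(dtype=float)
    if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("correlation target must be symmetric with unit diagonal")
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError("correlation target matrix is not positive semi-definite")
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = make_rng(seed, 4)
    Z = rng.normal(size=(n_subjects, len(names))) @ L.T
    U = stats.norm.cdf(Z)
    mu = dict(ENV_MEANS)
    if means:
        mu.update(means)
    if subjects is None:
        subjects = pd.Index([f"S{i + 1:04d}" for i in range(n_subjects)], name="subject")
    out = {}
    for j, name in enumerate(names):
        u = np.clip(U[:, j], 1e-12, 1 - 1e-12)
        if name == "parental_warmth":
            vals = np.clip(np.rint(mu[name] + warmth_sd * stats.norm.ppf(u)), 11, 66)
        else:
            vals = stats.poisson.ppf(u, mu[name])
        out[name] = vals.astype(float)
    return pd.DataFrame(out, index=subjects)


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions of the emulated design."""

    n_subjects: int = 480
    sex_ratio: float = 208.0 / 480.0  # male fraction
    panel: Optional[list] = None  # default: 98-locus dopamine panel
    effects: Optional[EffectSpec] = None  # default: study_effects
    missing_rate: float = 0.002
    with_quality: bool = True
    low_quality_rate: float = 0.005
    n_items: int = 27
    target_alpha: float = 0.817
    item_range: tuple = (1, 7)
    make_items: bool = True
    pool_sizes: Optional[dict] = None
    default_pool_size: int = 2

    def resolved_panel(self) -> list:
        return list(self.panel) if self.panel is not None else default_panel()

    def resolved_effects(self, panel: list) -> EffectSpec:
        return self.effects if self.effects is not None else study_effects(panel)


@dataclass
class CohortBundle:
    """One simulated cohort plus its generative truth."""

    genotypes: GenotypeTable
    phenotype: pd.Series
    environment: pd.DataFrame
    sex: pd.Series
    truth: EffectSpec
    items: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        idx = self.genotypes.subjects
        if not (self.phenotype.index.equals(idx) and self.environment.index.equals(idx)):
            raise ValueError("cohort tables must share one subject roster")
        if (self.environment[[c for c in self.environment.columns if c.startswith("events")]] < 0).any().any():
            raise ValueError("life-event counts must be non-negative")


def simulate_cohort(config: Optional[CohortConfig] = None, seed: int = 0) -> CohortBundle:
    """Generate a full cohort bundle under the given study conditions."""
    config = config or CohortConfig()
    panel = config.resolved_panel()
    effects = config.resolved_effects(panel)
    genotypes = simulate_genotypes(
        panel,
        config.n_subjects,
        sex_ratio=config.sex_ratio,
        seed=seed,
        missing_rate=config.missing_rate,
        with_quality=config.with_quality,
        low_quality_rate=config.low_quality_rate,
        pool_sizes=config.pool_sizes,
        default_pool_size=config.default_pool_size,
    )
    environment = simulate_environment(
        config.n_subjects, seed=seed, subjects=genotypes.subjects
    )
    phenotype = simulate_phenotype(genotypes, effects, environment=environment, seed=seed)
    items = None
    if config.make_items:
        items = simulate_items(
            phenotype,
            n_items=config.n_items,
            target_alpha=config.target_alpha,
            item_range=config.item_range,
            seed=seed,
        )
    return CohortBundle(
        genotypes=genotypes,
        phenotype=phenotype,
        environment=environment,
        sex=genotypes.sex,
        truth=effects,
        items=items,
    )


# ---------------------------------------------------------------------------
# hand-built QC fixture
# ---------------------------------------------------------------------------


def planted_qc_cohort() -> tuple:
    """Deterministic genotype table with known QC violations.

    Plants exactly: 2 subjects above 10% missingness, 7 calls below the 0.25
    quality cutoff (on retained subjects), one locus needing het/minor-hom
    collapsing, one still-rare locus, one monomorphic locus, and one
    LD-redundant duplicate locus.  Returns ``(table, expected)`` where
    ``expected`` records the planted counts.
    """
    n = 60
    subjects = pd.Index([f"P{i + 1:03d}" for i in range(n)], name="subject")
    sex = pd.Series([FEMALE] * n, index=subjects, name="sex")
    loci = [
        LocusSpec("L_ok", "GENE1", "synthesis", allele_labels=("A", "G"), target_maf=0.35),
        LocusSpec("L_collapse", "GENE2", "receptor", allele_labels=("C", "T"), target_maf=0.2),
        LocusSpec("L_stillrare", "GENE3", "modulation", allele_labels=("G", "T"), target_maf=0.05),
        LocusSpec("L_mono", "GENE4", "modulation", allele_labels=("A", "C"), target_maf=0.01),
        LocusSpec("L_dup1", "GENELD", "degradation_transport", allele_labels=("A", "G"), target_maf=0.3),
        LocusSpec("L_dup2", "GENELD", "degradation_transport", allele_labels=("A", "G"), target_maf=0.3),
    ]

    def snp_column(counts: dict, major: str, minor: str) -> list:
        col = []
        col += [f"{major}/{major}"] * counts["hom_maj"]
        col += [make_call((major, minor))] * counts["het"]
        col += [f"{minor}/{minor}"] * counts["hom_min"]
        return col

    n_kept = 58
    cols: dict = {}
    cols["L_ok"] = snp_column({"hom_maj": 25, "het": 23, "hom_min": 10}, "A", "G")
    cols["L_collapse"] = snp_column({"hom_maj": 42, "het": 10, "hom_min": 6}, "C", "T")
    cols["L_stillrare"] = snp_column({"hom_maj": 53, "het": 3, "hom_min": 2}, "G", "T")
    cols["L_mono"] = ["A/A"] * n_kept
    dup = snp_column({"hom_maj": 30, "het": 18, "hom_min": 10}, "A", "G")
    cols["L_dup1"] = list(dup)
    cols["L_dup2"] = list(dup)

    calls = pd.DataFrame(index=subjects, columns=[s.locus_id for s in loci], dtype=object)
    for lid, col in cols.items():
        # last two subjects: one missing call each (1/6 > 10% missing)
        calls[lid] = col + ([np.nan, np.nan] if lid == "L_ok" else [col[0], col[0]])
    quality = pd.DataFrame(0.9, index=subjects, columns=calls.columns)
    low_cells = [(subjects[i], "L_ok") for i in range(7)]
    for subj, lid in low_cells:
        quality.loc[subj, lid] = 0.10

    table = GenotypeTable(loci=loci, calls=calls, sex=sex, quality=quality)
    expected = {
        "subjects_dropped": 2,
        "calls_masked": 7,
        "collapsed": ["L_collapse"],
        "still_rare": ["L_stillrare"],
        "monomorphic": ["L_mono"],
        "ld_pruned": {"L_dup2": "L_dup1"},
        "n_loci_retained": 3,
    }
    return table, expected
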