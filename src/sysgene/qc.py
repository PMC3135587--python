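"""Genotype quality control and numeric coding.

The QC chain mirrors standard candidate-gene practice:

1. drop subjects whose missing-call fraction exceeds a threshold,
2. mask individual calls below a confidence-score cutoff,
3. collapse rare genotype classes (heterozygote / minor homozygote observed
   in fewer than ``min_group`` subjects are merged; still-rare or monomorphic
   loci are dropped),
4. test Hardy-Weinberg equilibrium per locus (chi-square, df = 1; females
   only for X-linked loci) — report only, deviating loci are retained,
5. prune loci in strong linkage disequilibrium (r² above threshold within
   the same gene, keeping the first locus in panel order).

Coding of retained loci for regression:

* autosomal SNPs: major homozygote / heterozygote / minor homozygote coded
  1 / 2 / 3 (collapsed loci: 1 / 2),
* X-linked loci: 1 for major-allele homozygotes (females) or major-allele
  hemizygotes (males), 2 for all others, pooling the sexes,
* autosomal VNTRs: dummy-coded genotype groups against a reference group
  (default DRD4 48-bp rule: "4R/4R" vs. any-2R-carrier "2R+" vs. others,
  with "others" as reference).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import FEMALE, MALE, GenotypeTable, split_call
from .loci import LocusSpec

logger = logging.getLogger(__name__)

LINEAR_123 = "linear_123"
X_TWO_GROUP = "x_two_group"
VNTR_DUMMY = "vntr_dummy"


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    """Accounting record of every QC action."""

    subjects_dropped: list = field(default_factory=list)  # (subject, reason)
    calls_masked: int = 0
    loci_collapsed: dict = field(default_factory=dict)  # locus -> merged-class label
    loci_dropped: list = field(default_factory=list)  # (locus, reason)
    hwe: dict = field(default_factory=dict)  # locus -> {chi2, p, df}
    ld_pairs: dict = field(default_factory=dict)  # (a, b) -> r2

    def merge(self, other: "QcReport") -> "QcReport":
        self.subjects_dropped.extend(other.subjects_dropped)
        self.calls_masked += other.calls_masked
        self.loci_collapsed.update(other.loci_collapsed)
        self.loci_dropped.extend(other.loci_dropped)
        self.hwe.update(other.hwe)
        self.ld_pairs.update(other.ld_pairs)
        return self

    @property
    def dropped_locus_ids(self) -> list:
        return [l for l, _ in self.loci_dropped]

    def to_dict(self) -> dict:
        return {
            "subjects_dropped": [[str(s), r] for s, r in self.subjects_dropped],
            "calls_masked": int(self.calls_masked),
            "loci_collapsed": dict(self.loci_collapsed),
            "loci_dropped": [[l, r] for l, r in self.loci_dropped],
            "hwe": {l: {k: float(v) for k, v in d.items()} for l, d in self.hwe.items()},
            "ld_pairs": {f"{a}|{b}": float(r2) for (a, b), r2 in self.ld_pairs.items()},
        }


# ---------------------------------------------------------------------------
# subject / call filters
# ---------------------------------------------------------------------------


def filter_subjects_by_missingness(
    g: GenotypeTable, max_null_fraction: float = 0.10
) -> tuple:
    """Drop subjects whose fraction of missing calls exceeds the threshold."""
    if not (0.0 < max_null_fraction < 1.0):
        raise ValueError("max_null_fraction must lie in (0, 1)")
    frac = g.calls.isna().mean(axis=1)
    drop = frac.index[frac > max_null_fraction]
    if len(drop) == g.n_subjects:
        raise ValueError("all subjects exceed the missingness threshold")
    report = QcReport(
        subjects_dropped=[(s, f"missingness {frac[s]:.3f} > {max_null_fraction}") for s in drop]
    )
    keep = [s for s in g.subjects if s not in set(drop)]
    return g.subset_subjects(keep), report


def mask_low_quality_calls(g: GenotypeTable, min_score: float = 0.25) -> tuple:
    """Set calls with quality score below ``min_score`` to missing."""
    report = QcReport()
    if g.quality is None:
        logger.warning("no quality layer present; mask_low_quality_calls is a no-op")
        return g, report
    low = (g.quality < min_score) & g.calls.notna()
    report.calls_masked = int(low.to_numpy().sum())
    calls = g.calls.mask(low)
    return replace(g, calls=calls), report


# ---------------------------------------------------------------------------
# rare-genotype collapsing
# ---------------------------------------------------------------------------


def _snp_class_counts(g: GenotypeTable, locus_id: str) -> tuple:
    """(n_major_hom, n_het, n_minor_hom, major, minor) for a biallelic locus."""
    major, minor = g.major_minor(locus_id)
    counts = g.genotype_counts(locus_id)
    hom_maj = counts.get(f"{major}/{major}", 0)
    het = counts.get("/".join(sorted((major, minor))), 0)
    hom_min = counts.get(f"{minor}/{minor}", 0)
    return hom_maj, het, hom_min, major, minor


def collapse_rare_genotypes(g: GenotypeTable, min_group: int = 10) -> tuple:
    """Merge rare heterozygote/minor-homozygote classes; drop hopeless loci.

    Autosomal SNPs whose heterozygote or minor-homozygote class is present
    but carried by fewer than ``min_group`` subjects have those two classes
    merged (downstream coding becomes two-level).  If the merged class is
    still below ``min_group`` the locus is dropped as ``still_rare``.
    Monomorphic loci are dropped outright.  X-linked and VNTR loci are left
    to their own two-group / dummy-group coding rules.
    """
    if min_group < 1:
        raise ValueError("min_group must be >= 1")
    report = QcReport()
    collapsed = set(g.collapsed_loci)
    drop: list = []
    for spec in g.loci:
        lid = spec.locus_id
        alleles = g.allele_counts(lid)
        if len(alleles) < 2:
            drop.append(lid)
            report.loci_dropped.append((lid, "monomorphic"))
            continue
        if spec.locus_class != "snp" or spec.chromosome_class != "autosomal":
            continue
        hom_maj, het, hom_min, major, minor = _snp_class_counts(g, lid)
        rare_present = (0 < het < min_group) or (0 < hom_min < min_group)
        if not rare_present:
            continue
        merged = het + hom_min
        if merged < min_group:
            drop.append(lid)
            report.loci_dropped.append((lid, "still_rare"))
            continue
        collapsed.add(lid)
        report.loci_collapsed[lid] = f"het+minor_hom merged (n={merged})"
    keep = [s.locus_id for s in g.loci if s.locus_id not in set(drop)]
    out = g.subset_loci(keep)
    out = replace(out, collapsed_loci=frozenset(collapsed))
    return out, report


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


def hwe_chi2(g: GenotypeTable, locus_id: str) -> dict:
    """Chi-square HWE test (df = 1) from uncollapsed genotype counts.

    Expected counts come from the sample allele frequencies (n·p², 2npq,
    n·q²).  For X-linked loci only female subjects enter, since male
    hemizygous calls carry no Hardy-Weinberg information.
    """
    spec = g.spec(locus_id)
    females_only = spec.chromosome_class == "x_linked"
    col = g.calls[locus_id]
    if females_only:
        col = col[g.sex == FEMALE]
    observed = col.dropna()
    allele_counts: dict = {}
    for call in observed:
        for a in split_call(call):
            allele_counts[a] = allele_counts.get(a, 0) + 1
    if len(allele_counts) < 2:
        raise ValueError(f"locus {locus_id} has <2 alleles observed for HWE")
    if len(allele_counts) > 2:
        raise ValueError(f"HWE chi-square (df=1) requires a biallelic locus: {locus_id}")
    (a1, c1), (a2, c2) = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(observed)
    p = c1 / (c1 + c2)
    q = 1.0 - p
    exp = {
        f"{a1}/{a1}": n * p * p,
        "/".join(sorted((a1, a2))): 2 * n * p * q,
        f"{a2}/{a2}": n * q * q,
    }
    obs_counts = observed.value_counts().to_dict()
    chi2 = 0.0
    for cell, e in exp.items():
        o = obs_counts.get(cell, 0)
        if e > 0:
            chi2 += (o - e) ** 2 / e
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, df=1)), "df": 1}


def hwe_report(g: GenotypeTable) -> QcReport:
    """HWE statistics for every biallelic-observed SNP locus (report only)."""
    report = QcReport()
    for spec in g.loci:
        if spec.locus_class != "snp":
            continue
        try:
            report.hwe[spec.locus_id] = hwe_chi2(g, spec.locus_id)
        except ValueError:
            continue
    return report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def additive_codes(g: GenotypeTable, locus_id: str) -> np.ndarray:
    """Minor-allele dosage per subject (0/1/2; male X hemizygotes 0/2),
    NaN where missing.  Used for composite-genotype LD."""
    major, minor = g.major_minor(locus_id)
    spec = g.spec(locus_id)
    out = np.full(g.n_subjects, np.nan)
    male = (g.sex == MALE).to_numpy()
    for i, call in enumerate(g.calls[locus_id]):
        if pd.isna(call):
            continue
        alleles = split_call(call)
        dose = sum(a == minor for a in alleles)
        if spec.chromosome_class == "x_linked" and male[i]:
            dose *= 2
        out[i] = dose
    return out


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(g: GenotypeTable, r2_threshold: float = 0.8) -> tuple:
    """Drop loci in strong LD with an earlier locus of the same gene.

    r² is the squared Pearson correlation of additive genotype codes
    (composite LD; haplotype phase is not observed).  Within each gene the
    first locus in panel order is kept and later loci with r² above the
    threshold against any kept locus are dropped, recording the kept partner.
    Only SNP loci participate; VNTRs are never pruned.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    report = QcReport()
    codes = {
        s.locus_id: additive_codes(g, s.locus_id)
        for s in g.loci
        if s.locus_class == "snp"
    }
    drop: set = set()
    by_gene: dict = {}
    for s in g.loci:
        if s.locus_class == "snp":
            by_gene.setdefault(s.gene, []).append(s.locus_id)
    for gene, ids in by_gene.items():
        kept: list = []
        for lid in ids:
            partner = None
            for k in kept:
                r2 = _pairwise_r2(codes[lid], codes[k])
                report.ld_pairs[(k, lid)] = r2
                if not math.isnan(r2) and r2 > r2_threshold and partner is None:
                    partner = k
            if partner is None:
                kept.append(lid)
            else:
                drop.add(lid)
                report.loci_dropped.append((lid, f"ld_pruned:{partner}"))
    keep = [s.locus_id for s in g.loci if s.locus_id not in drop]
    return g.subset_loci(keep), report


# ---------------------------------------------------------------------------
# coding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VntrRule:
    """Genotype-grouping rule for a multi-allelic repeat locus."""

    name: str
    groups: tuple  # ordered group labels; reference last by convention
    reference: str
    assign: Callable  # call string -> group label

    def dummy_groups(self) -> tuple:
        return tuple(gr for gr in self.groups if gr != self.reference)


def _drd4_assign(call: str) -> str:
    alleles = split_call(call)
    if "2R" in alleles:
        return "2R+"
    if call == "4R/4R":
        return "4R/4R"
    return "others"


DRD4_RULE = VntrRule(
    name="drd4_48bp",
    groups=("4R/4R", "2R+", "others"),
    reference="others",
    assign=_drd4_assign,
)


@dataclass
class CodedDesign:
    """Numeric predictor matrix after QC and coding.

    ``values`` holds one column per predictor (subjects × columns, NaN for
    missing genotypes); ``column_map`` maps each column to its source locus
    and coding rule; ``locus_columns`` gives the (possibly multi-column)
    block of each locus; ``class_labels`` records the genotype-class
    partition behind each locus, ordered to match the integer class codes.
    """

    values: pd.DataFrame
    column_map: dict  # column -> (locus_id, rule)
    subsystem_of: dict  # column -> subsystem
    locus_columns: dict  # locus_id -> [columns]
    class_labels: dict  # locus_id -> list of class labels

    @property
    def columns(self) -> list:
        return list(self.values.columns)

    def loci(self) -> list:
        return list(self.locus_columns)


def _resolve_vntr_rules(g: GenotypeTable, vntr_rules: Optional[dict]) -> dict:
    rules: dict = {}
    for spec in g.loci:
        if spec.locus_class != "vntr" or spec.chromosome_class == "x_linked":
            continue
        if vntr_rules is None:
            rules[spec.locus_id] = DRD4_RULE
        else:
            if spec.locus_id not in vntr_rules:
                raise KeyError(f"no VNTR coding rule supplied for {spec.locus_id}")
            rules[spec.locus_id] = vntr_rules[spec.locus_id]
    return rules


def class_codes(g: GenotypeTable, vntr_rules: Optional[dict] = None) -> tuple:
    """Integer genotype-class codes per locus.

    Returns ``(codes, labels)`` where ``codes`` is a subject × locus
    DataFrame of int8 class indices (-1 = missing) and ``labels`` maps each
    locus to its ordered class labels.  This partition is shared by the
    screening ANOVA and by :func:`code_loci`, so the two stages can never
    disagree about group membership.
    """
    rules = _resolve_vntr_rules(g, vntr_rules)
    male = (g.sex == MALE).to_numpy()
    codes = pd.DataFrame(
        np.full((g.n_subjects, len(g.loci)), -1, dtype=np.int8),
        index=g.subjects,
        columns=g.locus_ids,
    )
    labels: dict = {}
    for spec in g.loci:
        lid = spec.locus_id
        col = g.calls[lid]
        if spec.chromosome_class == "x_linked":
            major, _ = g.major_minor(lid)
            hom = f"{major}/{major}"
            lab = [f"{major}-major", "others"]
            vals = np.full(g.n_subjects, -1, dtype=np.int8)
            for i, call in enumerate(col):
                if pd.isna(call):
                    continue
                ref = major if male[i] else hom
                vals[i] = 0 if call == ref else 1
        elif spec.locus_class == "vntr":
            rule = rules[lid]
            lab = list(rule.groups)
            index = {grp: j for j, grp in enumerate(rule.groups)}
            vals = np.full(g.n_subjects, -1, dtype=np.int8)
            for i, call in enumerate(col):
                if pd.isna(call):
                    continue
                vals[i] = index[rule.assign(call)]
        else:
            major, minor = g.major_minor(lid)
            het = "/".join(sorted((major, minor)))
            if lid in g.collapsed_loci:
                lab = [f"{major}{major}", "others"]
                mapping = {f"{major}/{major}": 0}
                default = 1
            else:
                lab = [f"{major}{major}", "".join(sorted((major, minor))), f"{minor}{minor}"]
                mapping = {f"{major}/{major}": 0, het: 1, f"{minor}/{minor}": 2}
                default = None
            vals = np.full(g.n_subjects, -1, dtype=np.int8)
            for i, call in enumerate(col):
                if pd.isna(call):
                    continue
                code = mapping.get(call, default)
                if code is None:
                    raise ValueError(f"unexpected genotype {call} at {lid}")
                vals[i] = code
        codes[lid] = vals
        labels[lid] = lab
    return codes, labels


def code_loci(g: GenotypeTable, vntr_rules: Optional[dict] = None) -> CodedDesign:
    """Numeric coding of a QC'd genotype table for regression.

    Autosomal SNPs become a single 1/2/3 column (1/2 when collapsed),
    X-linked loci a single 1/2 column pooling the sexes, and autosomal
    VNTRs one 0/1 dummy column per non-reference genotype group.
    """
    rules = _resolve_vntr_rules(g, vntr_rules)
    codes, labels = class_codes(g, vntr_rules)
    values: dict = {}
    column_map: dict = {}
    subsystem_of: dict = {}
    locus_columns: dict = {}
    for spec in g.loci:
        lid = spec.locus_id
        cls = codes[lid].to_numpy().astype(float)
        cls[cls < 0] = np.nan
        if spec.chromosome_class == "x_linked":
            values[lid] = cls + 1.0
            column_map[lid] = (lid, X_TWO_GROUP)
            subsystem_of[lid] = spec.subsystem
            locus_columns[lid] = [lid]
        elif spec.locus_class == "vntr":
            rule = rules[lid]
            cols = []
            for grp in rule.dummy_groups():
                name = f"{lid}[{grp}]"
                j = rule.groups.index(grp)
                dummy = np.where(np.isnan(cls), np.nan, (cls == j).astype(float))
                values[name] = dummy
                column_map[name] = (lid, VNTR_DUMMY)
                subsystem_of[name] = spec.subsystem
                cols.append(name)
            locus_columns[lid] = cols
        else:
            values[lid] = cls + 1.0
            column_map[lid] = (lid, LINEAR_123)
            subsystem_of[lid] = spec.subsystem
            locus_columns[lid] = [lid]
    frame = pd.DataFrame(values, index=g.subjects)
    return CodedDesign(
        values=frame,
        column_map=column_map,
        subsystem_of=subsystem_of,
        locus_columns=locus_columns,
        class_labels=labels,
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def run_qc(
    g: GenotypeTable,
    max_missing: float = 0.10,
    min_quality: float = 0.25,
    min_group: int = 10,
    ld_r2: float = 0.8,
) -> tuple:
    """Full QC chain: missingness → call quality → collapsing → HWE (report
    only) → LD pruning.  Returns the cleaned table and a merged report."""
    report = QcReport()
    g, r = filter_subjects_by_missingness(g, max_missing)
    report.merge(r)
    g, r = mask_low_quality_calls(g, min_quality)
    report.merge(r)
    g, r = collapse_rare_genotypes(g, min_group)
    report.merge(r)
    report.merge(hwe_report(g))
    g, r = ld_prune(g, ld_r2)
    report.merge(r)
    return g, report
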