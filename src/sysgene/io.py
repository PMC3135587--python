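"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as TSV (subjects as rows; calls ``A/G``, male X ``A``,
missing empty) beside a locus annotation TSV; phenotype and environment share
one table keyed by subject.  A minimal VCF 4.2 export (GT only, ploidy 1 for
male X calls) is provided for SNP loci; reading VCF requires the optional
``cyvcf2`` dependency.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, split_call
from .loci import LocusSpec
from .qc import CodedDesign, QcReport


# ---------------------------------------------------------------------------
# locus annotation
# ---------------------------------------------------------------------------


def write_loci_tsv(loci, path, collapsed: Optional[set] = None) -> None:
    collapsed = collapsed or set()
    rows = []
    for s in loci:
        rows.append(
            {
                "locus_id": s.locus_id,
                "gene": s.gene,
                "subsystem": s.subsystem,
                "chromosome_class": s.chromosome_class,
                "locus_class": s.locus_class,
                "allele_labels": ",".join(s.allele_labels),
                "target_maf": s.target_maf,
                "allele_freqs": "" if s.allele_freqs is None else ",".join(map(str, s.allele_freqs)),
                "ld_block": s.ld_block or "",
                "collapsed": int(s.locus_id in collapsed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path) -> tuple:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    loci, collapsed = [], set()
    for _, row in df.iterrows():
        freqs = row.get("allele_freqs", "")
        loci.append(
            LocusSpec(
                locus_id=row["locus_id"],
                gene=row["gene"],
                subsystem=row["subsystem"],
                chromosome_class=row["chromosome_class"],
                locus_class=row["locus_class"],
                allele_labels=tuple(row["allele_labels"].split(",")),
                target_maf=float(row["target_maf"]),
                allele_freqs=tuple(map(float, freqs.split(","))) if freqs else None,
                ld_block=row["ld_block"] or None,
            )
        )
        if str(row.get("collapsed", "0")) in ("1", "1.0", "True"):
            collapsed.add(row["locus_id"])
    return loci, collapsed


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_genotypes_tsv(g: GenotypeTable, calls_path, loci_path, quality_path=None) -> None:
    frame = g.calls.copy()
    frame.insert(0, "sex", g.sex)
    frame.to_csv(calls_path, sep="\t", index=True, na_rep="")
    write_loci_tsv(g.loci, loci_path, collapsed=set(g.collapsed_loci))
    if quality_path is not None and g.quality is not None:
        g.quality.to_csv(quality_path, sep="\t", index=True, float_format="%.6f")


def read_genotypes_tsv(calls_path, loci_path, quality_path=None) -> GenotypeTable:
    frame = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
    loci, collapsed = read_loci_tsv(loci_path)
    sex = frame.pop("sex")
    order = [s.locus_id for s in loci]
    calls = frame[order].where(frame[order].notna() & (frame[order] != ""), np.nan)
    quality = None
    if quality_path is not None and Path(quality_path).exists():
        quality = pd.read_csv(quality_path, sep="\t", index_col=0).astype(float)
        quality = quality[order]
        quality.index = calls.index
    return GenotypeTable(
        loci=loci, calls=calls, sex=sex, quality=quality, collapsed_loci=frozenset(collapsed)
    )


# ---------------------------------------------------------------------------
# phenotype / environment / items
# ---------------------------------------------------------------------------


def write_phenotype_tsv(phenotype: pd.Series, environment: pd.DataFrame, path) -> None:
    out = environment.copy()
    out.insert(0, phenotype.name or "phenotype", phenotype)
    out.to_csv(path, sep="\t", index=True)


def read_phenotype_tsv(path) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col=0)
    pheno = df.iloc[:, 0]
    return pheno, df.iloc[:, 1:]


def write_items_tsv(items: pd.DataFrame, path) -> None:
    items.to_csv(path, sep="\t", index=True)


def read_items_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# QC report / coded design
# ---------------------------------------------------------------------------


def write_qc_report(report: QcReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))


def write_coded_design(design: CodedDesign, path) -> None:
    design.values.to_csv(path, sep="\t", index=True)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.Index):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# minimal VCF 4.2 (SNP loci, GT only)
# ---------------------------------------------------------------------------


def write_vcf(g: GenotypeTable, path) -> None:
    """Minimal VCF 4.2 export of SNP loci (GT field only).

    Positions are synthetic ordinals (the panel carries no physical map);
    X-linked male calls are written with ploidy 1.
    """
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    subjects = list(g.subjects)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects))
    male = (g.sex == "male").to_numpy()
    pos = 0
    for spec in g.loci:
        if spec.locus_class != "snp":
            continue
        pos += 1000
        ref, alt = spec.allele_labels
        chrom = "X" if spec.chromosome_class == "x_linked" else "1"
        fields = [chrom, str(pos), spec.locus_id, ref, alt, ".", "PASS", ".", "GT"]
        col = g.calls[spec.locus_id]
        for i, call in enumerate(col):
            if pd.isna(call):
                fields.append("." if (spec.chromosome_class == "x_linked" and male[i]) else "./.")
                continue
            alleles = split_call(call)
            idx = ["0" if a == ref else "1" for a in alleles]
            fields.append("/".join(sorted(idx)))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, loci_path) -> GenotypeTable:
    """Read a GT-only VCF against a locus annotation table.

    Requires ``cyvcf2``.  Half-calls (e.g. ``./0``) are rejected.  Sex is
    inferred from ploidy at X-linked loci (haploid call = male); subjects
    never haploid on X default to female.
    """
    from cyvcf2 import VCF  # optional dependency

    loci, collapsed = read_loci_tsv(loci_path)
    by_id = {s.locus_id: s for s in loci}
    vcf = VCF(str(path))
    subjects = pd.Index(vcf.samples, name="subject")
    calls = pd.DataFrame(index=subjects, columns=[s.locus_id for s in loci], dtype=object)
    male = pd.Series(False, index=subjects)
    seen = []
    for variant in vcf:
        spec = by_id.get(variant.ID)
        if spec is None:
            raise ValueError(f"VCF variant {variant.ID} absent from locus table")
        seen.append(spec.locus_id)
        alleles = [variant.REF] + list(variant.ALT)
        col = []
        for gt in variant.genotypes:  # [a, b, phased] or [a, phased]
            raw = [a for a in gt[:-1] if a is not None]
            valid = [a for a in raw if a >= 0]
            if valid and len(valid) < len(raw):
                raise ValueError(f"half-call at {variant.ID}")
            if not valid:
                col.append(np.nan)
                continue
            labels = [alleles[a] for a in valid]
            col.append(labels[0] if len(labels) == 1 else "/".join(sorted(labels)))
        calls[spec.locus_id] = col
        if spec.chromosome_class == "x_linked":
            ploidy1 = [len([a for a in gt[:-1] if a is not None and a >= 0]) == 1 for gt in variant.genotypes]
            male |= pd.Series(ploidy1, index=subjects)
    missing = [lid for lid in calls.columns if lid not in set(seen)]
    if missing:
        loci = [s for s in loci if s.locus_id in set(seen)]
        calls = calls[[s.locus_id for s in loci]]
    sex = pd.Series(np.where(male, "male", "female"), index=subjects, name="sex")
    return GenotypeTable(
        loci=loci, calls=calls, sex=sex, collapsed_loci=frozenset(collapsed)
    )
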