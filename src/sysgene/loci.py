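"""Locus metadata and the default dopamine-system candidate panel.

A *locus* is a polymorphic site typed in the cohort: a biallelic SNP, or a
multi-allelic VNTR (variable number tandem repeat).  Each locus belongs to a
gene and to one of four functional subsystems of the dopamine pathway
(synthesis, degradation/transport, receptor, modulation).  X-linked loci are
hemizygous in males and carry a single allele per male call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

SUBSYSTEMS = ("synthesis", "degradation_transport", "receptor", "modulation")
CHROMOSOME_CLASSES = ("autosomal", "x_linked")
LOCUS_CLASSES = ("snp", "vntr")


@dataclass(frozen=True)
class LocusSpec:
    """Static description of one typed polymorphism.

    Parameters
    ----------
    locus_id : str
        Identifier (rs number or marker name); unique within a panel.
    gene : str
        Gene symbol the locus belongs to.
    subsystem : str
        One of ``synthesis``, ``degradation_transport``, ``receptor``,
        ``modulation``.
    chromosome_class : str
        ``autosomal`` or ``x_linked``.
    locus_class : str
        ``snp`` (exactly two alleles) or ``vntr`` (two or more).
    allele_labels : tuple of str
        Allele names.  For SNPs ``allele_labels[0]`` is the intended major
        allele and ``allele_labels[1]`` the minor allele of the generator;
        observed major/minor status is always re-derived from sample counts.
    target_maf : float
        Generator minor-allele frequency, in (0, 0.5].  Ignored when
        ``allele_freqs`` is given.
    allele_freqs : tuple of float, optional
        Full allele-frequency vector (multi-allelic loci); must sum to 1 and
        align with ``allele_labels``.
    ld_block : str, optional
        Loci sharing a block label are simulated from a common haplotype
        pool and are therefore in linkage disequilibrium.
    """

    locus_id: str
    gene: str
    subsystem: str
    chromosome_class: str = "autosomal"
    locus_class: str = "snp"
    allele_labels: tuple = ("A", "G")
    target_maf: float = 0.3
    allele_freqs: Optional[tuple] = None
    ld_block: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(f"unknown subsystem {self.subsystem!r} for {self.locus_id}")
        if self.chromosome_class not in CHROMOSOME_CLASSES:
            raise ValueError(f"unknown chromosome_class {self.chromosome_class!r}")
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus_class {self.locus_class!r}")
        labels = tuple(self.allele_labels)
        object.__setattr__(self, "allele_labels", labels)
        if self.locus_class == "snp" and len(labels) != 2:
            raise ValueError(f"SNP {self.locus_id} must have exactly 2 alleles")
        if self.locus_class == "vntr" and len(labels) < 2:
            raise ValueError(f"VNTR {self.locus_id} must have >=2 alleles")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate allele labels at {self.locus_id}")
        if self.allele_freqs is not None:
            freqs = tuple(float(f) for f in self.allele_freqs)
            object.__setattr__(self, "allele_freqs", freqs)
            if len(freqs) != len(labels):
                raise ValueError(f"allele_freqs length mismatch at {self.locus_id}")
            if abs(sum(freqs) - 1.0) > 1e-9 or min(freqs) < 0:
                raise ValueError(f"allele_freqs must be a probability vector at {self.locus_id}")
        else:
            if not (0.0 < self.target_maf <= 0.5):
                raise ValueError(
                    f"monomorphic locus requested: target_maf={self.target_maf} at {self.locus_id}"
                )

    @property
    def frequencies(self) -> tuple:
        """Allele-frequency vector aligned with ``allele_labels``."""
        if self.allele_freqs is not None:
            return self.allele_freqs
        return (1.0 - self.target_maf, self.target_maf)


def _maf_series(i: int) -> float:
    # Deterministic, panel-stable spread of minor-allele frequencies in
    # [0.08, 0.48]; arbitrary but fixed, standing in for the study's
    # unreported per-locus frequencies.
    return 0.08 + 0.40 * ((i * 37) % 97) / 96.0


def default_panel() -> list[LocusSpec]:
    """The 98-locus dopamine-system panel used as the default study design.

    Mirrors the typed panel of the study the package emulates: 25 synthesis
    loci (TH, DDC, DBH), 24 degradation/transport loci (COMT, SLC6A3, plus
    nine X-linked MAOA/MAOB loci including the MAOA VNTR), 29 receptor loci
    (DRD1-DRD5 including the DRD4 48-bp VNTR), and 20 modulation loci
    (NLN, NTS, NTSR1, NTSR2).  Six within-gene LD blocks of perfectly linked
    loci plant exactly 11 redundant loci for the pruning step, leaving 87.
    """
    plan = [
        # (gene, subsystem, chromosome_class, n_snps)
        ("TH", "synthesis", "autosomal", 8),
        ("DDC", "synthesis", "autosomal", 9),
        ("DBH", "synthesis", "autosomal", 8),
        ("COMT", "degradation_transport", "autosomal", 6),
        ("SLC6A3", "degradation_transport", "autosomal", 9),
        ("MAOA", "degradation_transport", "x_linked", 5),
        ("MAOB", "degradation_transport", "x_linked", 3),
        ("DRD1", "receptor", "autosomal", 5),
        ("DRD2", "receptor", "autosomal", 8),
        ("DRD3", "receptor", "autosomal", 6),
        ("DRD4", "receptor", "autosomal", 4),
        ("DRD5", "receptor", "autosomal", 5),
        ("NLN", "modulation", "autosomal", 6),
        ("NTS", "modulation", "autosomal", 4),
        ("NTSR1", "modulation", "autosomal", 5),
        ("NTSR2", "modulation", "autosomal", 5),
    ]
    # gene -> (block name, member SNP ordinals within gene); members beyond the
    # first are redundant under pruning: 3+2+2+2+1+1 = 11 pruned loci.
    blocks = {
        "TH": ("blk_TH", (1, 2, 3, 4)),
        "DBH": ("blk_DBH", (2, 3, 4)),
        "SLC6A3": ("blk_SLC6A3", (1, 2, 3)),
        "DRD2": ("blk_DRD2", (3, 4, 5)),
        "NLN": ("blk_NLN", (2, 3)),
        "DDC": ("blk_DDC", (5, 6)),
    }
    alleles = (("A", "G"), ("C", "T"), ("G", "C"), ("T", "A"))
    panel: list[LocusSpec] = []
    i = 0
    for gene, subsystem, chrom, n_snps in plan:
        blk_name, blk_members = blocks.get(gene, (None, ()))
        for j in range(n_snps):
            in_block = j in blk_members
            panel.append(
                LocusSpec(
                    locus_id=f"rs{gene}{j + 1:02d}",
                    gene=gene,
                    subsystem=subsystem,
                    chromosome_class=chrom,
                    locus_class="snp",
                    allele_labels=alleles[i % len(alleles)],
                    target_maf=round(_maf_series(i), 3),
                    ld_block=blk_name if in_block else None,
                )
            )
            i += 1
        if gene == "MAOA":
            panel.append(
                LocusSpec(
                    locus_id="MAOA_VNTR",
                    gene="MAOA",
                    subsystem="degradation_transport",
                    chromosome_class="x_linked",
                    locus_class="vntr",
                    allele_labels=("3R", "4R", "3.5R"),
                    allele_freqs=(0.55, 0.40, 0.05),
                )
            )
        if gene == "DRD4":
            # East-Asian-like DRD4 48-bp repeat frequencies: 4R common,
            # 2R the main alternative, 7R nearly absent.
            panel.append(
                LocusSpec(
                    locus_id="DRD4_VNTR",
                    gene="DRD4",
                    subsystem="receptor",
                    chromosome_class="autosomal",
                    locus_class="vntr",
                    allele_labels=("4R", "2R", "3R", "5R", "7R"),
                    allele_freqs=(0.76, 0.195, 0.025, 0.015, 0.005),
                )
            )
    assert len(panel) == 98
    return panel


def subsystem_counts(panel: Sequence[LocusSpec]) -> dict:
    out: dict = {s: 0 for s in SUBSYSTEMS}
    for spec in panel:
        out[spec.subsystem] += 1
    return out
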