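"""Subject-by-locus genotype container.

Calls are stored as strings: ``"A/G"`` for a diploid call (alleles sorted, so
heterozygotes have one canonical spelling), a bare allele ``"A"`` for a male
X-linked call, and missing values as NaN.  An optional per-call quality layer
(e.g. array GenCall scores in [0, 1]) shares the same shape.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .loci import LocusSpec

MALE = "male"
FEMALE = "female"


def make_call(alleles: Sequence[str]) -> str:
    """Canonical call string from one or two allele labels."""
    if len(alleles) == 1:
        return str(alleles[0])
    if len(alleles) != 2:
        raise ValueError("a call carries one or two alleles")
    a, b = sorted(str(x) for x in alleles)
    return f"{a}/{b}"


def split_call(call: str) -> tuple:
    """Allele tuple of a call string (length 1 for hemizygous calls)."""
    return tuple(call.split("/"))


@dataclass
class GenotypeTable:
    """Subject × locus genotype calls with locus metadata.

    Attributes
    ----------
    loci : list of LocusSpec
        Panel in column order of ``calls``.
    calls : pandas.DataFrame
        Subjects (rows, index = subject ids) × loci (columns = locus ids);
        entries are canonical call strings or NaN.
    sex : pandas.Series
        ``"male"``/``"female"`` per subject, aligned with ``calls.index``.
    quality : pandas.DataFrame, optional
        Per-call confidence scores in [0, 1], same shape as ``calls``.
    collapsed_loci : frozenset of str
        Loci whose heterozygote and minor-homozygote classes were merged by
        rare-genotype collapsing (affects downstream class coding only; the
        raw call strings are untouched).
    """

    loci: list
    calls: pd.DataFrame
    sex: pd.Series
    quality: Optional[pd.DataFrame] = None
    collapsed_loci: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [s.locus_id for s in self.loci]
        if list(self.calls.columns) != ids:
            raise ValueError("calls columns must match loci order")
        if not self.calls.index.equals(self.sex.index):
            raise ValueError("sex index must match subject roster")
        if not self.sex.isin([MALE, FEMALE]).all():
            raise ValueError("sex entries must be 'male' or 'female'")
        if self.quality is not None:
            if self.quality.shape != self.calls.shape:
                raise ValueError("quality layer shape mismatch")

    # -- basic accessors -------------------------------------------------

    @property
    def subjects(self) -> pd.Index:
        return self.calls.index

    @property
    def n_subjects(self) -> int:
        return len(self.calls.index)

    @property
    def locus_ids(self) -> list:
        return [s.locus_id for s in self.loci]

    def spec(self, locus_id: str) -> LocusSpec:
        for s in self.loci:
            if s.locus_id == locus_id:
                return s
        raise KeyError(locus_id)

    def validate_calls(self) -> None:
        """Check every call against its locus allele labels and sex ploidy."""
        male = (self.sex == MALE).to_numpy()
        for spec_ in self.loci:
            col = self.calls[spec_.locus_id]
            ok = set(spec_.allele_labels)
            for i, call in enumerate(col):
                if pd.isna(call):
                    continue
                alleles = split_call(call)
                if any(a not in ok for a in alleles):
                    raise ValueError(f"allele outside labels at {spec_.locus_id}: {call}")
                if spec_.chromosome_class == "x_linked" and male[i] and len(alleles) != 1:
                    raise ValueError(
                        f"male X-linked call must carry one allele at {spec_.locus_id}: {call}"
                    )

    # -- derived summaries ----------------------------------------------

    def allele_counts(self, locus_id: str) -> Counter:
        """Observed allele counts at a locus (males contribute 1 on X)."""
        counts: Counter = Counter()
        for call in self.calls[locus_id].dropna():
            counts.update(split_call(call))
        return counts

    def major_minor(self, locus_id: str) -> tuple:
        """(major, minor) alleles by sample frequency; ties broken so the
        lexicographically smaller label is major.  Biallelic-observed loci
        only."""
        counts = self.allele_counts(locus_id)
        if len(counts) < 2:
            raise ValueError(f"locus {locus_id} has <2 alleles observed")
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[0][0], ranked[1][0]

    def genotype_counts(self, locus_id: str, females_only: bool = False) -> Counter:
        col = self.calls[locus_id]
        if females_only:
            col = col[self.sex == FEMALE]
        return Counter(col.dropna())

    def subset_subjects(self, keep: Sequence) -> "GenotypeTable":
        keep_idx = self.calls.index[self.calls.index.isin(keep)]
        return replace(
            self,
            calls=self.calls.loc[keep_idx],
            sex=self.sex.loc[keep_idx],
            quality=None if self.quality is None else self.quality.loc[keep_idx],
        )

    def subset_loci(self, keep_ids: Sequence[str]) -> "GenotypeTable":
        keep_ids = list(keep_ids)
        loci = [s for s in self.loci if s.locus_id in set(keep_ids)]
        order = [s.locus_id for s in loci]
        return replace(
            self,
            loci=loci,
            calls=self.calls[order],
            quality=None if self.quality is None else self.quality[order],
            collapsed_loci=frozenset(l for l in self.collapsed_loci if l in set(order)),
        )
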