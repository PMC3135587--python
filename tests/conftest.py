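import numpy as np
import pandas as pd
import pytest

import sysgene as sg
from sysgene.genotypes import FEMALE, GenotypeTable
from sysgene.loci import LocusSpec


def make_snp_table(counts, major="A", minor="G", gene="GENE", locus_id="L1",
                   subsystem="receptor", extra_loci=()):
    """Genotype table with exact genotype counts at one autosomal SNP."""
    hom_maj, het, hom_min = counts
    col = (
        [f"{major}/{major}"] * hom_maj
        + ["/".join(sorted((major, minor)))] * het
        + [f"{minor}/{minor}"] * hom_min
    )
    n = len(col)
    subjects = pd.Index([f"S{i:03d}" for i in range(n)], name="subject")
    loci = [LocusSpec(locus_id, gene, subsystem, allele_labels=(major, minor), target_maf=0.3)]
    calls = pd.DataFrame({locus_id: col}, index=subjects)
    for spec, column in extra_loci:
        loci.append(spec)
        calls[spec.locus_id] = column
    sex = pd.Series([FEMALE] * n, index=subjects, name="sex")
    return GenotypeTable(loci=loci, calls=calls[[s.locus_id for s in loci]], sex=sex)


@pytest.fixture(scope="session")
def small_panel():
    """20 independent autosomal SNPs across the four subsystems."""
    return [
        LocusSpec(
            f"rs{i:02d}", f"G{i % 5}", sg.SUBSYSTEMS[i % 4],
            target_maf=0.10 + 0.35 * (i % 8) / 7,
        )
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def study_cohort():
    """One default-condition cohort: 480 subjects x 98 loci, truth effects."""
    return sg.simulate_cohort(seed=20260927)


@pytest.fixture(scope="session")
def study_cohort_qc(study_cohort):
    g_qc, report = sg.run_qc(study_cohort.genotypes)
    return study_cohort, g_qc, report
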