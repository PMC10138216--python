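import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ovresponse.cohort import (
    CLINICAL_COLUMNS,
    Cohort,
    GenotypeMatrix,
    VariantDef,
)


def make_panel(n, chrom="chr1", start=1000, gene="TST"):
    return [
        VariantDef(f"rs{chrom}_{i}", gene, chrom, start + 100 * i, "A", "G")
        for i in range(n)
    ]


def make_cohort(dosage, mii, patient_ids=None, panel=None, clinical=None):
    """Toy cohort from a dosage matrix and an MII vector."""
    dosage = np.asarray(dosage, dtype=float)
    n = len(dosage)
    pids = [f"p{i}" for i in range(n)]
    if panel is None:
        panel = make_panel(dosage.shape[1])
    geno = GenotypeMatrix(pids, panel, dosage)
    df = pd.DataFrame(index=pd.Index(pids, name="process_id"))
    for col in CLINICAL_COLUMNS:
        df[col] = np.nan
    df["patient_id"] = patient_ids if patient_ids is not None else pids
    df["age"] = 33.0
    df["bmi"] = 23.0
    df["amh"] = 3.0
    df["pcos"] = False
    df["mii_count"] = np.asarray(mii, dtype=int)
    if clinical:
        for k, v in clinical.items():
            df[k] = v
    return Cohort(clinical=df, genotypes=geno)


@pytest.fixture(scope="session")
def small_cohort():
    """Medium synthetic cohort with the default planted effects."""
    from ovresponse.simulate import GeneratorConfig, generate_cohort

    cohort, truth = generate_cohort(GeneratorConfig(seed=11, n_patients=250))
    return cohort, truth
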