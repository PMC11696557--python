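import numpy as np
import pandas as pd
import pytest

import cytoqc as cq


@pytest.fixture(scope="session")
def panel():
    return cq.simulate_snp_panel(1000, seed=7)


@pytest.fixture(scope="session")
def patient(panel):
    return cq.simulate_genotypes(panel, seed=11)


@pytest.fixture(scope="session")
def contaminant(panel):
    return cq.simulate_genotypes(panel, seed=13)


def make_mixture(panel, patient, contaminant, alpha, mean_depth=500.0,
                 error_rate=0.001, seed=0):
    """Simulated tumor counts plus a clean normal-derived genotype profile."""
    tumor = cq.simulate_allele_counts(
        patient, contaminant,
        cq.MixtureSpec(alpha=alpha, mean_depth=mean_depth,
                       error_rate=error_rate, seed=seed),
        panel,
    )
    normal = cq.simulate_allele_counts(
        patient, contaminant,
        cq.MixtureSpec(alpha=0.0, mean_depth=mean_depth,
                       error_rate=error_rate, seed=seed + 1),
        panel,
    )
    profile = cq.call_genotypes(normal)
    return tumor, profile


@pytest.fixture(scope="session")
def hom_panel():
    """A 1000-site panel with a patient who is homozygous-reference everywhere.

    Isolates the contamination signal: every site is informative.
    """
    panel = cq.simulate_snp_panel(1000, seed=17)
    profile = pd.DataFrame(
        {"genotype": "hom_ref", "alt_dosage": 0.0},
        index=pd.Index(panel["site_id"], name="site_id"),
    )
    return panel, profile
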