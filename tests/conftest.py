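import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pregmr.summary_data import (AssociationTable, HarmonizedSet,
                                 SnpAssociation)

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def snp(rsid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.05, pvalue=0.01,
        n=1000.0, scale="log-odds", trait=""):
    return SnpAssociation(rsid=rsid, effect_allele=ea, other_allele=oa,
                          eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
                          scale=scale, trait=trait)


def make_table(rows, **kwargs):
    """Build an AssociationTable from dicts of SnpAssociation overrides."""
    records = []
    for i, row in enumerate(rows):
        defaults = {"rsid": f"rs{i + 1}"}
        defaults.update(row)
        records.append(snp(**defaults))
    return AssociationTable(records, **kwargs)


def make_harmonized(g, G, se_out, se_exp=None, **kwargs):
    g = np.asarray(g, dtype=float)
    se_exp = np.full_like(g, 0.01) if se_exp is None else se_exp
    return HarmonizedSet.from_arrays(g, se_exp, G, se_out, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """Tiny deterministic cohort: 2 SNPs, binary exposure/outcome, covariate."""
    from pregmr.simulate import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(seed=42, n_subjects=4000, n_snps=2,
                           target_r2=0.02, causal_effect=0.5,
                           outcome_prevalence=0.2)
    return simulate_cohort(cfg)
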