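import numpy as np
import pandas as pd
import pytest

from bnomics import ingest, simulate
from bnomics import network as net
from bnomics.datatypes import SyntheticConfig
from bnomics.simulate import PHENOTYPE_NODE


def planted_config(seed: int = 1, n_subjects: int = 200, n_snps: int = 12,
                   n_metabolites: int = 12) -> SyntheticConfig:
    """Compact planted cohort: no degenerate features, complete data."""
    return SyntheticConfig(
        n_subjects=n_subjects, n_snps=n_snps, n_expr_probes=0,
        n_cpg_sites=0, n_metabolites=n_metabolites,
        n_zero_variance_metabolites=0, n_high_missing_metabolites=0,
        metabolite_block_spec=(), missing_rate=0.0, modality_overlap={},
        seed=seed,
    )


def network_table(dataset) -> tuple[pd.DataFrame, list[net.NodeSpec]]:
    """SNPs + log-metabolites + phenotype as a CGBN-ready table."""
    z = ingest.zscore(np.log2(dataset.metabolites))
    cols = {m: z.loc[m].to_numpy() for m in z.index}
    specs = [net.NodeSpec(m, "continuous") for m in z.index]
    for s in dataset.genotypes.index:
        cols[s] = dataset.genotypes.loc[s].to_numpy()
        specs.append(net.NodeSpec(s, "discrete", (0, 1, 2)))
    cols[PHENOTYPE_NODE] = dataset.phenotype.to_numpy()
    specs.append(net.NodeSpec(PHENOTYPE_NODE, "discrete", (0, 1)))
    return pd.DataFrame(cols), specs


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the default study structure (20 subjects, 68
    metabolites, reduced genome-scale widths)."""
    cfg = SyntheticConfig(n_snps=150, n_expr_probes=150, n_cpg_sites=150,
                          seed=11)
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Compact fully-observed cohort with the planted Markov blanket."""
    return simulate.generate_cohort(planted_config(seed=1))
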