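import numpy as np
import pandas as pd
import pytest

from hapblocks import GenotypePanel, PopulationPartition, simulate_panel, wheat_like_scenario


def make_panel(calls, chroms=None, cms=None, line_prefix="L", snp_prefix="s"):
    """Small helper: build a panel from an int matrix (codes -1/0/1/2)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    line_ids = [f"{line_prefix}{i+1}" for i in range(n_lines)]
    snp_ids = [f"{snp_prefix}{j+1}" for j in range(n_snps)]
    chroms = chroms or ["1A"] * n_snps
    cms = cms if cms is not None else list(range(n_snps))
    gmap = pd.DataFrame({"chrom": chroms, "cm": cms}, index=snp_ids)
    return GenotypePanel(tuple(line_ids), tuple(snp_ids), calls, gmap)


@pytest.fixture(scope="session")
def sim_scenario():
    return wheat_like_scenario(7, snps_per_chrom=40, n_landrace=80, n_modern=60)


@pytest.fixture(scope="session")
def sim_panel(sim_scenario):
    panel, partition, truth = simulate_panel(sim_scenario)
    return panel, partition, truth
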