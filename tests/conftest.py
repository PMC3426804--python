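"""Shared fixtures: the scaled-down trend grids and a null dataset.

The trend grids (G = 2000 genes, 20 replicates per configuration,
frozen base seeds, all blocks transcriptionally active so that the true
null proportion is 1 - psi) are computed once per session and shared by
every test that asserts a qualitative trend.
"""

import numpy as np
import pytest

from fdrsim import SimulationConfig, gene_ttests, simulate_experiment
from fdrsim.driver import GridSpec, run_grid

TREND_G = 2000
TREND_REPS = 20
_COMMON = dict(
    n_reps=TREND_REPS,
    n_genes=TREND_G,
    config_overrides={"active_fraction": 1.0},
)


@pytest.fixture(scope="session")
def trend_grids():
    """Four sub-grids covering the psi, sample-size, block-size and theta sweeps."""
    psi = run_grid(
        GridSpec(
            sample_sizes=[25],
            block_sizes=[1, 100],
            theta_scenarios=["tent"],
            psi_levels=[0.0, 0.05, 0.10, 0.20, 0.40],
            base_seed=101,
            **_COMMON,
        )
    )
    n_sweep = run_grid(
        GridSpec(
            sample_sizes=[10, 100],
            block_sizes=[10],
            theta_scenarios=["tent"],
            psi_levels=[0.10],
            base_seed=102,
            **_COMMON,
        )
    )
    big_block = run_grid(
        GridSpec(
            sample_sizes=[25],
            block_sizes=[1000],
            theta_scenarios=["tent"],
            psi_levels=[0.10],
            base_seed=103,
            **_COMMON,
        )
    )
    theta = run_grid(
        GridSpec(
            sample_sizes=[25],
            block_sizes=[10],
            theta_scenarios=[0.0, 0.1, 0.25, "tent"],
            psi_levels=[0.10],
            base_seed=104,
            **_COMMON,
        )
    )
    for name, table in (("psi", psi), ("n", n_sweep), ("big", big_block),
                        ("theta", theta)):
        failed = table[table["failed"] != ""]
        assert failed.empty, f"{name} grid had failures:\n{failed['failed']}"
    return {"psi": psi, "n": n_sweep, "big": big_block, "theta": theta}


@pytest.fixture(scope="session")
def null_experiment():
    """Singleton blocks, no differential expression: every gene is null."""
    cfg = SimulationConfig(
        n_genes=5000, n_per_group=25, mean_block_size=1, psi=0.0, seed=7
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def null_pvalues(null_experiment):
    return gene_ttests(null_experiment.log2_matrix, null_experiment.group_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120824)
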