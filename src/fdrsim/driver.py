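"""Factorial simulation grids and per-dataset summary records.

One grid row = one simulated dataset analysed end to end: simulate,
gene-wise t-tests, BUM fit (alpha_hat, lambda_hat, pi_ub), observed FDP
at a few cutoffs against truth, and the z-value dispersion summaries
(sigma0, A, corr.std).  Failures are recorded in the row's ``failed``
column, never silently dropped, and the whole table is deterministic
given the grid's base seed.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bum import fit_bum
from .config import SimulationConfig
from .efron import correlation_sd, dispersion_A, estimate_null_width
from .exceptions import InvalidInputError, InvalidParameterError
from .fdp import confusion_at_cutoff
from .simulate import simulate_experiment
from .ttests import gene_ttests, t_to_z

__all__ = ["GridSpec", "run_grid", "summarize_grid", "derive_seed"]

logger = logging.getLogger(__name__)

#: Factorial levels of the main study grid: 4 sample sizes x 8 mean
#: block sizes x 4 theta scenarios = 128 configurations.
STUDY_SAMPLE_SIZES = (10, 25, 50, 100)
STUDY_BLOCK_SIZES = (1, 5, 10, 50, 100, 250, 500, 1000)
STUDY_THETA_SCENARIOS = (0.0, 0.1, 0.25, "tent")
STUDY_PSI_LEVELS = (0.0, 0.05, 0.10, 0.20, 0.40)


@dataclass(frozen=True)
class GridSpec:
    """A factorial grid over (N, xi, theta, psi) with replicates."""

    sample_sizes: Sequence[int]
    block_sizes: Sequence[float]
    theta_scenarios: Sequence = ("tent",)
    psi_levels: Sequence[float] = (0.10,)
    n_reps: int = 1
    base_seed: int = 0
    n_genes: int = 2000
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sample_sizes", "block_sizes", "theta_scenarios", "psi_levels"):
            if len(getattr(self, name)) == 0:
                raise InvalidParameterError(f"{name} must be nonempty")
        if self.n_reps < 1:
            raise InvalidParameterError(f"n_reps must be >= 1, got {self.n_reps}")

    @property
    def n_configurations(self) -> int:
        return (
            len(self.sample_sizes)
            * len(self.block_sizes)
            * len(self.theta_scenarios)
            * len(self.psi_levels)
        )

    def configurations(self):
        return itertools.product(
            self.sample_sizes, self.block_sizes, self.theta_scenarios, self.psi_levels
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


def derive_seed(base_seed: int, config_index: int, rep: int) -> int:
    """Deterministic, stream-independent per-dataset seed below 2^31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(config_index, rep))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_grid(
    spec: GridSpec,
    cutoffs: Sequence[float] = (0.001, 0.01, 0.05),
    n_pairs: int = 50_000,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Run every configuration x replicate and collect one record each.

    Columns: the configuration (N, xi, theta, psi, rep, seed), the BUM
    estimates, observed FDP at each requested cutoff, sigma0, A,
    corr_std, and a ``failed`` column holding the error message for rows
    whose analysis raised (their summary fields are NaN).
    """
    records = []
    t_start = time.perf_counter()
    for ci, (n, xi, theta, psi) in enumerate(spec.configurations()):
        for rep in range(spec.n_reps):
            seed = derive_seed(spec.base_seed, ci, rep)
            row = {
                "N": int(n),
                "xi": float(xi),
                "theta": str(theta),
                "psi": float(psi),
                "rep": rep,
                "seed": seed,
                "failed": "",
            }
            try:
                row.update(
                    _analyze_one(
                        SimulationConfig(
                            n_genes=spec.n_genes,
                            n_per_group=int(n),
                            mean_block_size=float(xi),
                            theta_scenario=theta,
                            psi=float(psi),
                            seed=seed,
                            **spec.config_overrides,
                        ),
                        cutoffs=cutoffs,
                        n_pairs=n_pairs,
                        variant=variant,
                    )
                )
            except Exception as exc:  # recorded, never dropped
                row["failed"] = f"{type(exc).__name__}: {exc}"
                logger.warning("grid row (config %d, rep %d) failed: %s", ci, rep, exc)
            records.append(row)
        logger.info(
            "configuration %d/%d (N=%s xi=%s theta=%s psi=%s) done at %.1fs",
            ci + 1, spec.n_configurations, n, xi, theta, psi,
            time.perf_counter() - t_start,
        )
    return pd.DataFrame(records)


def _analyze_one(
    config: SimulationConfig,
    cutoffs: Sequence[float],
    n_pairs: int,
    variant: str,
) -> dict:
    exp = simulate_experiment(config)
    pset = gene_ttests(exp.log2_matrix, exp.group_labels, variant=variant)
    fit = fit_bum(pset.p_values)
    out = {
        "alpha_hat": fit.alpha_hat,
        "lambda_hat": fit.lambda_hat,
        "pi_ub": fit.pi_ub,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "true_pi": float(np.mean(~exp.truth["is_de"].to_numpy())),
    }
    truth = exp.truth["is_de"].to_numpy()
    for tau in cutoffs:
        out[f"fdp_{tau:g}"] = confusion_at_cutoff(pset.p_values, truth, tau).fdp
    z = t_to_z(pset)
    sigma0 = estimate_null_width(z)
    out["sigma0"] = sigma0
    out["A"] = dispersion_A(sigma0)
    corr_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999,))
    )
    out["corr_std"] = correlation_sd(exp.log2_matrix, n_pairs=n_pairs, rng=corr_rng)
    return out


def summarize_grid(
    records: pd.DataFrame,
    group_by: Sequence[str],
    stats: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Groupwise mean, sd and count of summary statistics.

    Groups with a single row get NaN sd (pandas' convention for an
    undefined sample sd).
    """
    if records.empty:
        raise InvalidInputError("records table is empty")
    if stats is None:
        skip = set(group_by) | {"rep", "seed", "failed", "converged", "theta"}
        stats = [
            c for c in records.columns
            if c not in skip and pd.api.types.is_numeric_dtype(records[c])
        ]
    for col in list(group_by) + list(stats):
        if col not in records.columns:
            raise InvalidInputError(f"unknown field name: {col!r}")
    grouped = records.groupby(list(group_by), dropna=False)[list(stats)].agg(
        ["mean", "std", "count"]
    )
    grouped.columns = [f"{col}_{stat}" for col, stat in grouped.columns]
    return grouped.reset_index()
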