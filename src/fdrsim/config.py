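"""Configuration objects for the block-correlated expression simulator.

The generator mimics "clumpy" correlation in microarray data: genes fall
into independent blocks (pathways/networks), genes within a block are
correlated — a fraction ``theta`` of them negatively — and only
transcriptionally active blocks produce signal.  Differential expression
is injected block-wise: a fraction ``psi`` of the active blocks shifts
its mean log2 expression in the cancer group, with per-gene magnitudes
drawn from a Gamma distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Union

import yaml

from .exceptions import InvalidParameterError

ThetaScenario = Union[float, str]

#: Tag selecting a random per-block theta: 0.5 − |x − 0.5| with x ~ U(0,1),
#: i.e. a tent-shaped draw that is uniform on [0, 0.5].
TENT = "tent"


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model on the raw intensity scale.

    Observed intensity is ``Y = S * exp(H) + E`` with multiplicative
    log-noise ``H ~ N(0, mult_sd^2)`` and additive background
    ``E ~ N(add_mean, add_sd^2)``, clipped below at ``floor`` before the
    log2 transform.
    """

    mult_sd: float = 0.1
    add_mean: float = 2.0
    add_sd: float = 1.0
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.mult_sd < 0:
            raise InvalidParameterError(f"mult_sd must be >= 0, got {self.mult_sd}")
        if self.add_sd < 0:
            raise InvalidParameterError(f"add_sd must be >= 0, got {self.add_sd}")
        if self.floor <= 0:
            raise InvalidParameterError(f"floor must be > 0, got {self.floor}")


def validate_theta_scenario(scenario: ThetaScenario) -> None:
    if isinstance(scenario, str):
        if scenario != TENT:
            raise InvalidParameterError(
                f"theta_scenario must be a number in [0, 0.5] or '{TENT}', got {scenario!r}"
            )
        return
    value = float(scenario)
    if not 0.0 <= value <= 0.5:
        raise InvalidParameterError(
            f"fixed theta must lie in [0, 0.5], got {value}"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the two-group block-correlated expression generator.

    Parameters
    ----------
    n_genes
        Number of genes G.
    n_per_group
        Samples per group N; both groups have the same size.
    mean_block_size
        Mean correlation-block size xi; sizes are 1 + Poisson(xi - 1).
    theta_scenario
        Fraction of negatively correlated genes per block: either a fixed
        value in [0, 0.5] or :data:`TENT` for a random per-block draw.
    psi
        Fraction of *active* blocks made differentially expressed.
    active_fraction
        Probability that a block is transcriptionally active.
    de_shape, de_rate
        Gamma(shape, rate) parameters of the absolute log2 fold change
        |Delta| of DE genes.  The defaults (10, 10) give mean |Delta| = 1,
        i.e. an average two-fold change with a long right tail.
    baseline_mean, baseline_sd
        Normal parameters of the per-gene baseline log2 mean expression.
    gene_sd_mean, gene_sd_shape
        Per-gene biological log2 standard deviations are drawn from a
        Gamma with mean ``gene_sd_mean`` and shape ``gene_sd_shape``.
    rho_a, rho_b
        Beta parameters of the per-block correlation magnitude rho.
    noise
        Raw-scale measurement-noise parameters.
    seed
        Top-level RNG seed; identical config + seed gives a bit-identical
        dataset.
    """

    n_genes: int
    n_per_group: int
    mean_block_size: float = 1.0
    theta_scenario: ThetaScenario = TENT
    psi: float = 0.0
    active_fraction: float = 0.7
    de_shape: float = 10.0
    de_rate: float = 10.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    gene_sd_mean: float = 0.5
    gene_sd_shape: float = 4.0
    rho_a: float = 4.0
    rho_b: float = 4.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidParameterError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_per_group < 1:
            raise InvalidParameterError(
                f"n_per_group must be >= 1, got {self.n_per_group}"
            )
        if self.mean_block_size < 1:
            raise InvalidParameterError(
                f"mean_block_size must be >= 1, got {self.mean_block_size}"
            )
        if not 0.0 <= self.psi <= 1.0:
            raise InvalidParameterError(f"psi must lie in [0, 1], got {self.psi}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise InvalidParameterError(
                f"active_fraction must lie in [0, 1], got {self.active_fraction}"
            )
        for name in ("de_shape", "de_rate", "baseline_sd", "gene_sd_mean",
                     "gene_sd_shape", "rho_a", "rho_b"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )
        validate_theta_scenario(self.theta_scenario)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = dataclasses.asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        noise = d.pop("noise", None)
        if noise is not None and not isinstance(noise, NoiseParams):
            noise = NoiseParams(**noise)
        if noise is None:
            noise = NoiseParams()
        return cls(noise=noise, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
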