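"""Two-group, block-correlated log2 expression data with known truth.

The generative model, in pipeline order:

1.  Genes are partitioned into correlation blocks with sizes
    1 + Poisson(xi - 1); distinct blocks are independent.
2.  Each block is transcriptionally active with probability
    ``active_fraction``; inactive blocks emit no signal in either group.
3.  Each block gets a correlation magnitude rho ~ Beta(rho_a, rho_b), a
    negative-correlation fraction theta (fixed or tent-drawn), and a
    ±1 sign vector with round(theta * size) genes negative.  The block
    correlation matrix is the one-factor form (1-rho) I + rho s s',
    which is positive semi-definite for any sign pattern.
4.  A fraction psi of the active blocks (round-half-up count) is flagged
    differentially expressed: every gene in such a block gets an
    absolute log2 shift |Delta| ~ Gamma(de_shape, de_rate) and a fair
    ±1 direction.
5.  Active genes are sampled from a multivariate normal with mean
    mu_g (+ Delta_g in the cancer group) and covariance
    sigma_g sigma_h C_gh; inactive genes carry zero raw signal.
6.  Raw intensities S = 2^X receive multiplicative and additive noise
    and are clipped at a positive floor before the final log2.

The per-stage RNG streams are derived from the single config seed, so
changing psi alters only the differential-expression stage and leaves
the block layout, correlation structure and noise untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import NoiseParams, SimulationConfig, validate_theta_scenario
from .exceptions import DegenerateInputError, InvalidParameterError

__all__ = [
    "BlockSpec",
    "ExpressionExperiment",
    "partition_blocks",
    "draw_theta",
    "build_block_correlation",
    "inject_de",
    "apply_noise",
    "sample_correlated_block",
    "simulate_experiment",
]

# Fixed stage order for sub-stream derivation; never reorder, or seeds
# stop being comparable across versions.
_STAGES = ("blocks", "structure", "baseline", "sigma", "de", "signal", "noise")


def _stage_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class BlockSpec:
    """One correlation block and its differential-expression state."""

    block_id: int
    size: int
    rho: float
    signs: np.ndarray          # ±1 per gene; fraction theta equal to -1
    active: bool
    de: bool
    deltas: np.ndarray         # signed log2 shifts; zeros unless de
    theta: float

    def __post_init__(self) -> None:
        if len(self.signs) != self.size or len(self.deltas) != self.size:
            raise InvalidParameterError("signs/deltas length must equal block size")
        if self.de and not self.active:
            raise InvalidParameterError("a DE block must be active")


@dataclass
class ExpressionExperiment:
    """A simulated two-group dataset with per-gene ground truth.

    ``log2_matrix`` is G x 2N (genes by samples), ``group_labels`` holds
    'normal'/'cancer' per column, and ``truth`` is a DataFrame with one
    row per gene: gene_id, block_id, active, is_de, delta.
    """

    log2_matrix: np.ndarray
    group_labels: np.ndarray
    truth: pd.DataFrame
    config: SimulationConfig

    @property
    def gene_ids(self) -> np.ndarray:
        return self.truth["gene_id"].to_numpy()


def partition_blocks(
    n_genes: int, mean_block_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw block sizes 1 + Poisson(xi - 1) summing exactly to ``n_genes``.

    The last block is truncated so that sizes conserve the gene count;
    the long-run mean size is exactly ``mean_block_size``.
    """
    if n_genes < 1:
        raise InvalidParameterError(f"n_genes must be >= 1, got {n_genes}")
    if mean_block_size < 1:
        raise InvalidParameterError(
            f"mean_block_size must be >= 1, got {mean_block_size}"
        )
    lam = mean_block_size - 1.0
    sizes: List[int] = []
    total = 0
    chunk = max(16, int(2 * n_genes / mean_block_size) + 1)
    while total < n_genes:
        draws = 1 + rng.poisson(lam, size=chunk)
        for s in draws:
            sizes.append(int(s))
            total += int(s)
            if total >= n_genes:
                break
    excess = total - n_genes
    if excess:
        sizes[-1] -= excess
        if sizes[-1] == 0:
            sizes.pop()
    return np.asarray(sizes, dtype=np.int64)


def draw_theta(scenario, rng: np.random.Generator) -> float:
    """Return the negative-correlation fraction for one block.

    A fixed scenario returns its constant; the tent scenario returns
    0.5 − |x − 0.5| with x ~ U(0, 1), which is uniform on [0, 0.5].
    """
    validate_theta_scenario(scenario)
    if isinstance(scenario, str):  # tent
        x = rng.uniform()
        return 0.5 - abs(x - 0.5)
    return float(scenario)


def build_block_correlation(
    size: int, rho: float, signs: Sequence[float]
) -> np.ndarray:
    """One-factor block correlation matrix (1-rho) I + rho s s'.

    Unit diagonal, off-diagonal (i, j) = rho * s_i * s_j; positive
    semi-definite by construction for any sign pattern.
    """
    signs = np.asarray(signs, dtype=float)
    if len(signs) != size:
        raise InvalidParameterError("signs length must equal size")
    if not 0.0 <= rho <= 1.0:
        raise InvalidParameterError(f"rho must lie in [0, 1], got {rho}")
    corr = rho * np.outer(signs, signs)
    np.fill_diagonal(corr, 1.0)
    return corr


def _make_signs(size: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    signs = np.ones(size)
    n_neg = _round_half_up(theta * size)
    if n_neg:
        idx = rng.choice(size, size=n_neg, replace=False)
        signs[idx] = -1.0
    return signs


def make_blocks(config: SimulationConfig, rng: np.random.Generator,
                sizes: np.ndarray) -> List[BlockSpec]:
    """Assign activity, correlation magnitude, theta and signs per block."""
    n_blocks = len(sizes)
    active = rng.random(n_blocks) < config.active_fraction
    rhos = rng.beta(config.rho_a, config.rho_b, size=n_blocks)
    blocks = []
    for b, size in enumerate(sizes):
        theta = draw_theta(config.theta_scenario, rng)
        signs = _make_signs(int(size), theta, rng)
        blocks.append(
            BlockSpec(
                block_id=b,
                size=int(size),
                rho=float(rhos[b]),
                signs=signs,
                active=bool(active[b]),
                de=False,
                deltas=np.zeros(int(size)),
                theta=theta,
            )
        )
    return blocks


def inject_de(
    blocks: Sequence[BlockSpec],
    psi: float,
    de_shape: float,
    de_rate: float,
    rng: np.random.Generator,
) -> List[BlockSpec]:
    """Flag round(psi * n_active) active blocks as differentially expressed.

    Every gene in a flagged block receives |Delta| ~ Gamma(shape, rate)
    and an independent fair ±1 direction (up- or down-regulated in the
    cancer group).  Inactive blocks are never flagged.
    """
    if not 0.0 <= psi <= 1.0:
        raise InvalidParameterError(f"psi must lie in [0, 1], got {psi}")
    if de_shape <= 0 or de_rate <= 0:
        raise InvalidParameterError("de_shape and de_rate must be > 0")
    active_idx = [i for i, b in enumerate(blocks) if b.active]
    if psi > 0 and not active_idx:
        raise DegenerateInputError("psi > 0 but no block is transcriptionally active")
    n_de = _round_half_up(psi * len(active_idx))
    chosen = set()
    if n_de:
        chosen = set(
            int(i) for i in rng.choice(len(active_idx), size=n_de, replace=False)
        )
        chosen = {active_idx[i] for i in chosen}
    out = []
    for i, b in enumerate(blocks):
        if i in chosen:
            mags = rng.gamma(de_shape, 1.0 / de_rate, size=b.size)
            dirs = np.where(rng.random(b.size) < 0.5, 1.0, -1.0)
            out.append(dataclasses.replace(b, de=True, deltas=mags * dirs))
        else:
            out.append(b)
    return out


def apply_noise(
    raw_signal: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Observed raw intensity Y = S exp(H) + E, clipped below at the floor."""
    raw_signal = np.asarray(raw_signal, dtype=float)
    if np.any(raw_signal < 0):
        raise InvalidParameterError("raw_signal entries must be nonnegative")
    h = rng.normal(0.0, noise.mult_sd, size=raw_signal.shape)
    e = rng.normal(noise.add_mean, noise.add_sd, size=raw_signal.shape)
    return np.maximum(raw_signal * np.exp(h) + e, noise.floor)


def sample_correlated_block(
    size: int,
    rho: float,
    signs: Sequence[float],
    n_samples: int,
    rng: np.random.Generator,
    sigmas: Optional[Sequence[float]] = None,
    means: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Sample one block from N(mean, sigma_g sigma_h C) via its one-factor form.

    X_gs = mu_g + sigma_g (sqrt(1-rho) Z_gs + sqrt(rho) s_g F_s) with a
    common factor F per sample, which realises exactly the covariance of
    :func:`build_block_correlation` without a Cholesky factorisation.
    """
    signs = np.asarray(signs, dtype=float)
    if not 0.0 <= rho <= 1.0:
        raise InvalidParameterError(f"rho must lie in [0, 1], got {rho}")
    z = rng.standard_normal((size, n_samples))
    f = rng.standard_normal(n_samples)
    x = np.sqrt(1.0 - rho) * z + np.sqrt(rho) * signs[:, None] * f[None, :]
    if sigmas is not None:
        x = np.asarray(sigmas, dtype=float)[:, None] * x
    if means is not None:
        x = x + np.asarray(means, dtype=float)[:, None]
    return x


def simulate_experiment(config: SimulationConfig) -> ExpressionExperiment:
    """Generate a full two-group experiment with ground truth.

    Returns a G x 2N log2 matrix (first N columns 'normal', last N
    'cancer'), the group labels, and the per-gene truth table.
    """
    rngs = _stage_rngs(config.seed)
    g, n = config.n_genes, config.n_per_group

    sizes = partition_blocks(g, config.mean_block_size, rngs["blocks"])
    blocks = make_blocks(config, rngs["structure"], sizes)
    blocks = inject_de(blocks, config.psi, config.de_shape, config.de_rate,
                       rngs["de"])

    # flatten block attributes to per-gene vectors
    block_id = np.repeat([b.block_id for b in blocks], sizes)
    active = np.repeat([b.active for b in blocks], sizes)
    rho_g = np.repeat([b.rho for b in blocks], sizes)
    sign_g = np.concatenate([b.signs for b in blocks])
    delta_g = np.concatenate([b.deltas for b in blocks])
    is_de = np.repeat([b.de for b in blocks], sizes)

    mu = rngs["baseline"].normal(config.baseline_mean, config.baseline_sd, size=g)
    sigma = rngs["sigma"].gamma(
        config.gene_sd_shape, config.gene_sd_mean / config.gene_sd_shape, size=g
    )

    n_cols = 2 * n
    sig_rng = rngs["signal"]
    factors = sig_rng.standard_normal((len(blocks), n_cols))
    z = sig_rng.standard_normal((g, n_cols))

    cancer = np.zeros(n_cols, dtype=bool)
    cancer[n:] = True
    mean_matrix = mu[:, None] + np.where(cancer[None, :], delta_g[:, None], 0.0)
    x = mean_matrix + sigma[:, None] * (
        np.sqrt(1.0 - rho_g)[:, None] * z
        + np.sqrt(rho_g)[:, None] * sign_g[:, None] * factors[block_id, :]
    )

    raw = np.where(active[:, None], np.exp2(x), 0.0)
    observed = apply_noise(raw, config.noise, rngs["noise"])
    log2_matrix = np.log2(observed)

    width = max(4, len(str(g)))
    gene_ids = np.array([f"g{i + 1:0{width}d}" for i in range(g)])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "block_id": block_id,
            "active": active,
            "is_de": is_de,
            "delta": delta_g,
        }
    )
    labels = np.array(["normal"] * n + ["cancer"] * n)
    return ExpressionExperiment(log2_matrix, labels, truth, config)
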