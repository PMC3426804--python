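"""Empirical-null dispersion of z-values and the pairwise-correlation sd.

Inter-gene correlation (and, it turns out, the sheer proportion of true
signals) widens or narrows the central peak of the z-value histogram
relative to the theoretical N(0, 1) null.  The central width sigma0 is
estimated by central matching: a quadratic fit to log bin counts near
zero.  The dispersion variate

    A = (sigma0^2 - 1) / sqrt(2)

is the coefficient of the second Hermite polynomial in the expansion of
the empirical null around N(0, 1): A > 0 means a widened peak, A < 0 a
narrowed one.  The companion summary corr.std is the standard deviation
of sampled pairwise gene-gene Pearson correlations; for independent
genes observed over n arrays it is approximately 1/sqrt(n - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import EstimationError, InvalidInputError, InvalidParameterError

__all__ = [
    "DispersionSummary",
    "estimate_null_width",
    "dispersion_A",
    "correlation_sd",
    "dispersion_summary",
]


@dataclass(frozen=True)
class DispersionSummary:
    """Central-width, dispersion-variate and correlation-sd summaries."""

    sigma0: float
    A: float
    n_z: int
    corr_std: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise InvalidParameterError("sigma0 must be > 0")
        if self.corr_std < 0 or self.n_pairs < 1:
            raise InvalidParameterError("corr_std must be >= 0 and n_pairs >= 1")


def estimate_null_width(
    z_values,
    bin_width: float = 0.1,
    z_range: tuple = (-2.0, 2.0),
    min_count: int = 5,
    min_bins: int = 5,
) -> float:
    """Central-matching estimate of the empirical-null width sigma0.

    z-values are histogrammed in ``bin_width`` bins over ``z_range``;
    a least-squares quadratic is fitted to the log counts of bins with
    at least ``min_count`` observations, and sigma0 = (-2 c2)^(-1/2)
    where c2 is the fitted curvature (for a Gaussian centre,
    log f = const - z^2 / (2 sigma0^2)).
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise EstimationError("no finite z-values")
    if z.size < 1000:
        warnings.warn(
            f"estimating the null width from only {z.size} z-values",
            stacklevel=2,
        )
    lo, hi = z_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(z, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts >= min_count
    if keep.sum() < min_bins:
        raise EstimationError(
            f"only {int(keep.sum())} central bins have >= {min_count} observations"
        )
    coefs = np.polyfit(centers[keep], np.log(counts[keep]), 2)
    c2 = coefs[0]
    if c2 >= 0:
        raise EstimationError(
            f"nonnegative curvature ({c2:.4g}) in the central log-count fit"
        )
    return float((-2.0 * c2) ** -0.5)


def dispersion_A(sigma0: float) -> float:
    """Dispersion variate A = (sigma0^2 - 1) / sqrt(2)."""
    if sigma0 <= 0:
        raise InvalidParameterError(f"sigma0 must be > 0, got {sigma0}")
    return (sigma0**2 - 1.0) / np.sqrt(2.0)


def _pair_index_to_ij(k: np.ndarray, g: int) -> tuple:
    """Map linear pair index k in [0, g(g-1)/2) to (i, j) with i < j."""
    k = np.asarray(k, dtype=np.int64)
    i = ((2 * g - 1) - np.sqrt((2 * g - 1) ** 2 - 8 * k.astype(float))) // 2
    i = i.astype(np.int64)
    # guard against float rounding at row boundaries
    off = i * (2 * g - i - 1) // 2
    too_big = off > k
    i[too_big] -= 1
    off = i * (2 * g - i - 1) // 2
    too_small = k - off >= (g - i - 1)
    i[too_small] += 1
    off = i * (2 * g - i - 1) // 2
    j = k - off + i + 1
    return i, j


def correlation_sd(
    matrix,
    n_pairs: int = 50_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Sd of Pearson correlations over sampled distinct gene pairs.

    All pairs are used when there are at most ``n_pairs`` of them;
    otherwise ``n_pairs`` distinct pairs are sampled uniformly.  Genes
    with zero variance across samples cannot enter a correlation and are
    excluded from the sampling frame (with a warning).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InvalidInputError("matrix must be 2-D with at least 2 genes")
    n = x.shape[1]
    if n < 4:
        raise InvalidInputError(f"need at least 4 samples, got {n}")
    if rng is None:
        rng = np.random.default_rng()

    sd = x.std(axis=1, ddof=1)
    valid = sd > 0
    if not np.all(valid):
        warnings.warn(
            f"excluding {int(np.sum(~valid))} zero-variance genes from "
            "correlation sampling",
            stacklevel=2,
        )
        x = x[valid]
        sd = sd[valid]
    g = x.shape[0]
    if g < 2:
        raise InvalidInputError("fewer than 2 genes with nonzero variance")

    total = g * (g - 1) // 2
    if total <= n_pairs:
        ii, jj = np.triu_indices(g, k=1)
    elif total <= 5_000_000:
        ks = rng.choice(total, size=n_pairs, replace=False)
        ii, jj = _pair_index_to_ij(ks, g)
    else:
        seen = set()
        while len(seen) < n_pairs:
            cand = rng.integers(0, total, size=n_pairs - len(seen))
            seen.update(int(c) for c in cand)
        ii, jj = _pair_index_to_ij(np.fromiter(seen, dtype=np.int64), g)

    xs = (x - x.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(n - 1))
    corr = np.einsum("ij,ij->i", xs[ii], xs[jj])
    if corr.size < 2:
        raise InvalidInputError("need at least 2 pairs to compute an sd")
    return float(np.std(corr, ddof=1))


def dispersion_summary(
    matrix,
    z_values,
    n_pairs: int = 50_000,
    rng: Optional[np.random.Generator] = None,
) -> DispersionSummary:
    """Convenience wrapper computing sigma0, A and corr.std in one pass."""
    z = np.asarray(z_values, dtype=float)
    sigma0 = estimate_null_width(z)
    x = np.asarray(matrix)
    g = x.shape[0]
    n_sampled = min(n_pairs, g * (g - 1) // 2)
    return DispersionSummary(
        sigma0=sigma0,
        A=dispersion_A(sigma0),
        n_z=int(z.size),
        corr_std=correlation_sd(matrix, n_pairs=n_pairs, rng=rng),
        n_pairs=int(n_sampled),
    )
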