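"""Gene-by-gene two-sample t statistics, p-values and the z-transform.

The t-test is the classical pooled-variance two-sample test by default
(a Welch variant is available).  Genes with zero variance in both groups
cannot be tested; they are retained with t = 0, p = 1 and flagged, so
that downstream mixture fits see the full gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import InvalidInputError

__all__ = ["PValueSet", "gene_ttests", "t_to_z"]

_Z_CLAMP = 1e-15


@dataclass
class PValueSet:
    """Per-gene test results for a two-group comparison."""

    gene_ids: np.ndarray
    t_stats: np.ndarray
    dfs: np.ndarray
    p_values: np.ndarray
    n1: int
    n2: int
    zero_variance: np.ndarray
    z_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("t_stats", "dfs", "p_values", "zero_variance"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"{name} length does not match gene_ids")
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise InvalidInputError("p-values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "t": self.t_stats,
                "df": self.dfs,
                "p": self.p_values,
                "zero_variance": self.zero_variance,
            }
        )
        out["z"] = self.z_values if self.z_values is not None else t_to_z(self)
        return out


def gene_ttests(
    matrix: np.ndarray,
    labels: Sequence,
    variant: str = "pooled",
    gene_ids: Optional[Sequence[str]] = None,
) -> PValueSet:
    """Two-sided two-sample t-test per gene (row) between two label groups.

    ``variant`` selects the pooled-variance test (df = n1 + n2 - 2) or
    Welch's test with Satterthwaite degrees of freedom.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if matrix.ndim != 2:
        raise InvalidInputError("matrix must be 2-dimensional (genes x samples)")
    if len(labels) != matrix.shape[1]:
        raise InvalidInputError(
            f"label count ({len(labels)}) does not match column count "
            f"({matrix.shape[1]})"
        )
    if variant not in ("pooled", "welch"):
        raise InvalidInputError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    # groups ordered by value so the sign of t is label-assignment invariant:
    # swapping the group labels negates t and leaves p unchanged
    groups = np.unique(labels)
    if len(groups) != 2:
        raise InvalidInputError(f"expected exactly two groups, got {list(groups)}")
    a = matrix[:, labels == groups[0]]
    b = matrix[:, labels == groups[1]]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InvalidInputError("each group needs at least 2 samples")

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)

    zero_var = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    bad = zero_var | ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    df = np.where(np.isfinite(df), df, float(a.shape[1] + b.shape[1] - 2))

    if gene_ids is None:
        width = max(4, len(str(matrix.shape[0])))
        gene_ids = np.array([f"g{i + 1:0{width}d}" for i in range(matrix.shape[0])])
    else:
        gene_ids = np.asarray(gene_ids)
        if len(gene_ids) != matrix.shape[0]:
            raise InvalidInputError("gene_ids length does not match matrix rows")
    return PValueSet(
        gene_ids=gene_ids,
        t_stats=t,
        dfs=df,
        p_values=np.clip(p, 0.0, 1.0),
        n1=int(a.shape[1]),
        n2=int(b.shape[1]),
        zero_variance=np.asarray(bad),
    )


def t_to_z(pset_or_t, dfs: Optional[np.ndarray] = None) -> np.ndarray:
    """Map t statistics to z-values via z = Phi^-1(F_t(t; df)).

    The transform is monotone in t and median-preserving (t = 0 maps to
    z = 0).  The t CDF is clamped away from {0, 1} so z stays finite.
    """
    if dfs is None:
        t, dfs = pset_or_t.t_stats, pset_or_t.dfs
    else:
        t = np.asarray(pset_or_t, dtype=float)
        dfs = np.asarray(dfs, dtype=float)
    cdf = special.stdtr(np.asarray(dfs, dtype=float), np.asarray(t, dtype=float))
    cdf = np.clip(cdf, _Z_CLAMP, 1.0 - _Z_CLAMP)
    return special.ndtri(cdf)
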