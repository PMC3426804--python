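"""Observed false discovery proportion (FDP) against simulation truth.

At a p-value cutoff tau, genes with p <= tau are called positive and
cross-tabulated against the known DE status, giving
FDP = FP / (FP + TP).  FDR is the marginal average of the FDP across
replicate datasets, so replicate summaries (pointwise mean and sd over
a shared cutoff grid) are the study's main output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "ConfusionCounts",
    "FDPCurve",
    "default_cutoff_grid",
    "confusion_at_cutoff",
    "fdp_curve",
    "summarize_replicates",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Positive/negative calls cross-tabulated against truth at one cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fdp(self) -> float:
        """FP / (FP + TP); 0 by convention when nothing is called positive."""
        called = self.tp + self.fp
        return self.fp / called if called else 0.0


@dataclass
class FDPCurve:
    """FDP and confusion counts along an increasing cutoff grid."""

    cutoffs: np.ndarray
    fdp: np.ndarray
    counts: List[ConfusionCounts]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutoffs) <= 0):
            raise InvalidInputError("cutoffs must be strictly increasing")
        if np.any((self.fdp < 0) | (self.fdp > 1)):
            raise InvalidInputError("fdp values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "tp": [c.tp for c in self.counts],
                "fp": [c.fp for c in self.counts],
                "tn": [c.tn for c in self.counts],
                "fn": [c.fn for c in self.counts],
                "fdp": self.fdp,
            }
        )


def default_cutoff_grid(n: int = 50, lo: float = 1e-6) -> np.ndarray:
    """Log-spaced cutoff grid from ``lo`` to 1."""
    return np.geomspace(lo, 1.0, n)


def _check_inputs(p_values, truth_is_de):
    p = np.asarray(p_values, dtype=float)
    truth = np.asarray(truth_is_de, dtype=bool)
    if p.shape != truth.shape:
        raise InvalidInputError(
            f"p_values (len {p.size}) and truth (len {truth.size}) differ in length"
        )
    return p, truth


def confusion_at_cutoff(p_values, truth_is_de, tau: float) -> ConfusionCounts:
    """Cross-tabulate calls (p <= tau) against true DE status."""
    if not 0.0 < tau <= 1.0:
        raise InvalidParameterError(f"tau must lie in (0, 1], got {tau}")
    p, truth = _check_inputs(p_values, truth_is_de)
    pos = p <= tau
    return ConfusionCounts(
        tp=int(np.sum(pos & truth)),
        fp=int(np.sum(pos & ~truth)),
        tn=int(np.sum(~pos & ~truth)),
        fn=int(np.sum(~pos & truth)),
    )


def fdp_curve(p_values, truth_is_de, cutoffs=None) -> FDPCurve:
    """Observed FDP = FP / (FP + TP) over a cutoff grid.

    FDP is defined as 0 at cutoffs where no gene is called positive —
    the convention under which FDR equals the expectation of FDP.
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0:
        raise InvalidInputError("cutoff grid must be nonempty")
    counts = [confusion_at_cutoff(p_values, truth_is_de, float(t)) for t in cutoffs]
    fdp = np.array([c.fdp for c in counts])
    return FDPCurve(cutoffs=cutoffs, fdp=fdp, counts=counts)


def summarize_replicates(curves: Sequence[FDPCurve]) -> pd.DataFrame:
    """Pointwise mean and sample sd of FDP across replicate curves."""
    if len(curves) < 2:
        raise InvalidInputError("need at least 2 replicate curves for an sd")
    grid = curves[0].cutoffs
    for c in curves[1:]:
        if len(c.cutoffs) != len(grid) or not np.allclose(c.cutoffs, grid):
            raise InvalidInputError("replicate curves must share the same cutoff grid")
    stack = np.vstack([c.fdp for c in curves])
    return pd.DataFrame(
        {
            "cutoff": grid,
            "mean_fdp": stack.mean(axis=0),
            "sd_fdp": stack.std(axis=0, ddof=1),
            "n_reps": len(curves),
        }
    )
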