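"""Resampling stability of the BUM cutoff for a target FDR.

The protocol mirrors a tumor-versus-normal stability experiment: draw a
fixed number of samples per group without replacement, run gene-wise
t-tests, fit a BUM model, and record the p-value cutoff that achieves a
target model-based FDR.  After all resamples, the pooled median cutoff
is applied back to every resample's fit to obtain the "effective FDR at
the median cutoff" — the spread of that quantity is the instability the
experiment measures.  When simulation truth is available, the realized
FDP at the median cutoff is recorded as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bum import bum_fdr_at_cutoff, cutoff_for_target_fdr, fit_bum
from .exceptions import InvalidInputError
from .fdp import confusion_at_cutoff
from .ttests import gene_ttests

__all__ = ["ResamplingResult", "run_resampling"]


@dataclass
class ResamplingResult:
    """Per-resample records plus the pooled median cutoff."""

    per_resample: pd.DataFrame
    median_tau: float
    settings: dict

    def summary(self) -> pd.DataFrame:
        df = self.per_resample
        rows = []
        for col in ("alpha_hat", "lambda_hat", "pi_ub", "tau_at_target",
                    "effective_fdr_at_median_tau", "true_fdp_at_median_tau"):
            if col not in df or df[col].isna().all():
                continue
            q1, q3 = np.nanpercentile(df[col], [25, 75])
            rows.append(
                {
                    "quantity": col,
                    "mean": float(np.nanmean(df[col])),
                    "sd": float(np.nanstd(df[col], ddof=1)),
                    "median": float(np.nanmedian(df[col])),
                    "q1": float(q1),
                    "q3": float(q3),
                    "min": float(np.nanmin(df[col])),
                    "max": float(np.nanmax(df[col])),
                }
            )
        return pd.DataFrame(rows)


def run_resampling(
    matrix,
    labels,
    n_per_group: int,
    n_resamples: int = 300,
    target_fdr: float = 0.10,
    truth_is_de: Optional[Sequence[bool]] = None,
    seed: int = 0,
    variant: str = "pooled",
) -> ResamplingResult:
    """Repeatedly subsample the columns and track the target-FDR cutoff.

    Each resample draws ``n_per_group`` columns per group without
    replacement (independent across resamples, deterministic given
    ``seed``), computes t-test p-values, fits a BUM model and inverts it
    for the cutoff achieving ``target_fdr``.  A second pass evaluates
    every resample's model FDR (and true FDP, when truth is given) at
    the pooled median cutoff.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != matrix.shape[1]:
        raise InvalidInputError("label count does not match column count")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise InvalidInputError(f"expected exactly two groups, got {list(groups)}")
    idx_by_group = [np.flatnonzero(labels == grp) for grp in groups]
    for grp, idx in zip(groups, idx_by_group):
        if len(idx) < n_per_group:
            raise InvalidInputError(
                f"group {grp!r} has {len(idx)} samples, fewer than "
                f"n_per_group={n_per_group}"
            )
    if truth_is_de is not None:
        truth_is_de = np.asarray(truth_is_de, dtype=bool)
        if truth_is_de.size != matrix.shape[0]:
            raise InvalidInputError("truth length does not match gene count")

    children = np.random.SeedSequence(seed).spawn(n_resamples)
    fits, taus, pvals, seeds = [], [], [], []
    for r in range(n_resamples):
        rng = np.random.default_rng(children[r])
        cols = np.concatenate(
            [rng.choice(idx, size=n_per_group, replace=False) for idx in idx_by_group]
        )
        pset = gene_ttests(matrix[:, cols], labels[cols], variant=variant)
        fit = fit_bum(pset.p_values)
        fits.append(fit)
        taus.append(cutoff_for_target_fdr(fit, target_fdr))
        pvals.append(pset.p_values)
        seeds.append(int(children[r].generate_state(1)[0] & 0x7FFFFFFF))

    median_tau = float(np.median(taus))
    records = []
    for r, fit in enumerate(fits):
        eff = (
            float(bum_fdr_at_cutoff(fit, median_tau)) if median_tau > 0 else np.nan
        )
        true_fdp = np.nan
        if truth_is_de is not None and median_tau > 0:
            true_fdp = confusion_at_cutoff(pvals[r], truth_is_de, median_tau).fdp
        records.append(
            {
                "resample_id": r,
                "seed": seeds[r],
                "alpha_hat": fit.alpha_hat,
                "lambda_hat": fit.lambda_hat,
                "pi_ub": fit.pi_ub,
                "tau_at_target": taus[r],
                "effective_fdr_at_median_tau": eff,
                "true_fdp_at_median_tau": true_fdp,
            }
        )
    return ResamplingResult(
        per_resample=pd.DataFrame(records),
        median_tau=median_tau,
        settings={
            "n_per_group": int(n_per_group),
            "n_resamples": int(n_resamples),
            "target_fdr": float(target_fdr),
            "seed": int(seed),
            "variant": variant,
        },
    )
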