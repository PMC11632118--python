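"""Multivariable MR: joint direct effects of K exposures on the outcome.

Weighted least squares (weights 1/se_Y^2, no intercept) of the per-SNP
outcome associations on the K-vector of exposure associations. The
coefficient of each exposure is its direct effect, holding the other
exposures fixed — this is how the exposure-adjusted mediator->outcome
effect of the two-step mediation decomposition is obtained. SEs come from
the weighted normal equations, inflated by max(1, sqrt(Q/(J-K))) so
residual heterogeneity widens them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .harmonization import HarmonizedInstrument, retained
from .uvmr import (DegenerateDesignError, InsufficientInstrumentsError,
                   MrResult, Z95)

#: Condition numbers above this raise a degenerate-design error.
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class MvmrExposureEffect:
    name: str
    estimate: float
    se: float
    pval: float

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se


@dataclass(frozen=True)
class MvmrResult:
    """Direct effects of all exposures plus design diagnostics."""

    effects: tuple[MvmrExposureEffect, ...]
    n_snps: int
    q_stat: float
    design_condition: float

    def __getitem__(self, name: str) -> MvmrExposureEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def mvmr_fit(
    instruments: Sequence[HarmonizedInstrument],
    exposure_names: Sequence[str],
) -> MvmrResult:
    """Fit the multivariable model over harmonized multi-exposure instruments.

    Each instrument must carry ``beta_exposure`` (the first-listed
    exposure) and, for every further exposure name, an entry in
    ``beta_mediators``; all betas aligned to the first exposure's effect
    allele. Requires strictly more SNPs than exposures.
    """
    kept = retained(instruments)
    k = len(exposure_names)
    if k < 2:
        raise ValueError("multivariable fit needs at least 2 exposures")
    j = len(kept)
    if j <= k:
        raise InsufficientInstrumentsError(
            f"mvmr needs more SNPs than exposures, got J={j}, K={k}")

    first = exposure_names[0]
    cols = []
    for name in exposure_names:
        if name == first:
            cols.append([h.beta_exposure for h in kept])
        else:
            cols.append([h.beta_mediators[name][0] for h in kept])
    X_full = np.array(cols, dtype=float).T  # J x K
    y = np.array([h.beta_outcome for h in kept], dtype=float)
    w = np.array([h.se_outcome for h in kept], dtype=float) ** -2.0

    # an exposure with no instrument signal at all contributes nothing to
    # the fit; excluding its zero column keeps the design full-rank and
    # reduces the model to the remaining exposures
    active = [idx for idx in range(k) if np.any(X_full[:, idx] != 0.0)]
    if not active:
        raise DegenerateDesignError("all exposure betas are zero")
    X = X_full[:, active]
    k_fit = len(active)

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    sv = np.linalg.svd(Xw, compute_uv=False)
    condition = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    if not math.isfinite(condition) or condition > CONDITION_LIMIT:
        raise DegenerateDesignError(
            f"rank-deficient weighted design (condition {condition:.3g})")

    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, math.sqrt(q / (j - k_fit)))
    cov = np.linalg.inv(xtwx)
    by_idx = {col: pos for pos, col in enumerate(active)}
    effects = []
    for idx, name in enumerate(exposure_names):
        if idx not in by_idx:
            effects.append(MvmrExposureEffect(name, math.nan, math.nan, math.nan))
            continue
        pos = by_idx[idx]
        se = math.sqrt(cov[pos, pos]) * scale
        b = float(coef[pos])
        effects.append(MvmrExposureEffect(
            name=name, estimate=b, se=se, pval=float(2.0 * norm.sf(abs(b) / se))))
    return MvmrResult(effects=tuple(effects), n_snps=j, q_stat=q,
                      design_condition=condition)


def mvmr_to_mr_results(result: MvmrResult) -> list[MrResult]:
    """Per-exposure rows in the common results-table shape."""
    return [MrResult(f"mvmr:{e.name}", e.estimate, e.se, e.pval, result.n_snps)
            for e in result.effects]


__all__ = ["MvmrResult", "MvmrExposureEffect", "mvmr_fit",
           "mvmr_to_mr_results", "CONDITION_LIMIT"]
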