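"""Univariable two-sample MR estimators and sensitivity diagnostics.

Five estimators over harmonized per-SNP effect pairs (beta_X, beta_Y):

* inverse-variance weighted (IVW) — weighted regression through the
  origin of beta_Y on beta_X with weights 1/se_Y^2, algebraically equal
  to the inverse-variance-weighted mean of per-SNP Wald ratios under the
  first-order ratio SE;
* MR-Egger — the same regression with a free intercept; the intercept is
  a test for directional pleiotropy;
* weighted median — consistent when instruments carrying at least half
  of the weight are valid;
* simple and weighted mode — argmax of a kernel-smoothed density of the
  ratio estimates.

Standard errors default to multiplicative random effects: the fixed-
effect SE is inflated by max(1, sqrt(Q/df)) so between-SNP heterogeneity
widens, never narrows, the interval. Bootstrap SEs (median, modes) are
parametric: each ratio is redrawn from Normal(ratio_j, se_j^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import chi2, norm, t as t_dist

from .harmonization import HarmonizedInstrument, retained

Z95 = 1.959964

ReMode = Literal["fixed", "multiplicative_random"]


class InsufficientInstrumentsError(ValueError):
    """Fewer SNPs than the estimator's minimum."""


class DegenerateDesignError(ValueError):
    """The weighted design matrix is rank-deficient."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio beta_Y/beta_X with first-order SE se_Y/|beta_X|."""

    rsid: str
    beta_ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return self.se_ratio ** -2


@dataclass(frozen=True)
class MrResult:
    """A named estimator's causal estimate on the log-odds scale."""

    method: str
    estimate: float
    se: float
    pval: float
    n_snps: int

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) — exact exponentials of the log scale."""
        return (math.exp(self.estimate), math.exp(self.ci_low),
                math.exp(self.ci_high))


@dataclass(frozen=True)
class SensitivityResult:
    """Cochran's Q heterogeneity and the Egger intercept pleiotropy test."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    kept = retained(instruments)
    bx = np.array([h.beta_exposure for h in kept], dtype=float)
    by = np.array([h.beta_outcome for h in kept], dtype=float)
    sy = np.array([h.se_outcome for h in kept], dtype=float)
    rs = [h.rsid for h in kept]
    return rs, bx, by, sy


def ratio_estimates(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[list[RatioEstimate], list[str]]:
    """Per-SNP Wald ratios; SNPs with beta_exposure == 0 are excluded.

    Returns (estimates, excluded_rsids) — exclusions are the SNPs with a
    zero exposure effect, for which the ratio is undefined.
    """
    rs, bx, by, sy = _arrays(instruments)
    out, excluded = [], []
    for rsid, x, y, s in zip(rs, bx, by, sy):
        if x == 0.0:
            excluded.append(rsid)
        else:
            out.append(RatioEstimate(rsid, y / x, s / abs(x)))
    return out, excluded


def _require(n: int, minimum: int, method: str) -> None:
    if n < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} instruments, got {n}")


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    re_mode: ReMode = "multiplicative_random",
) -> MrResult:
    """Inverse-variance-weighted estimate.

    b = sum(bx*by/se_y^2) / sum(bx^2/se_y^2); fixed SE is
    (sum bx^2/se_y^2)^(-1/2); under multiplicative random effects the SE
    is inflated by max(1, sqrt(Q/(J-1))). p from the normal distribution.
    """
    _, bx, by, sy = _arrays(instruments)
    j = len(bx)
    _require(j, 2, "ivw")
    w = sy ** -2.0
    denom = float(np.sum(bx * bx * w))
    if denom == 0.0:
        raise DegenerateDesignError("all exposure betas are zero")
    b = float(np.sum(bx * by * w)) / denom
    se = denom ** -0.5
    if re_mode == "multiplicative_random":
        q = float(np.sum(w * (by - b * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (j - 1)))
    p = float(2.0 * norm.sf(abs(b) / se))
    return MrResult("ivw", b, se, p, j)


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
    re_mode: ReMode = "multiplicative_random",
) -> tuple[MrResult, SensitivityResult]:
    """MR-Egger regression: weighted fit of by = alpha + b*bx.

    Requires exposure orientation (all beta_exposure >= 0); the intercept
    alpha estimates the average directional pleiotropic effect and its
    two-sided p comes from t(J-2). Both SEs are inflated by
    max(1, sqrt(Q_egger/(J-2))) under multiplicative random effects.
    """
    _, bx, by, sy = _arrays(instruments)
    j = len(bx)
    _require(j, 3, "mr_egger")
    if np.any(bx < 0):
        raise ValueError("mr_egger requires orient_positive_exposure first")
    if np.ptp(bx) == 0.0:
        raise DegenerateDesignError("zero variance in exposure betas")
    w = sy ** -2.0
    X = np.column_stack([np.ones(j), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    alpha, b = float(coef[0]), float(coef[1])
    resid = by - X @ coef
    q = float(np.sum(w * resid ** 2))
    cov = np.linalg.inv(xtwx)
    scale = max(1.0, math.sqrt(q / (j - 2))) if re_mode == "multiplicative_random" else 1.0
    se_alpha = math.sqrt(cov[0, 0]) * scale
    se_b = math.sqrt(cov[1, 1]) * scale
    p_b = float(2.0 * t_dist.sf(abs(b) / se_b, df=j - 2))
    p_alpha = float(2.0 * t_dist.sf(abs(alpha) / se_alpha, df=j - 2))
    result = MrResult("egger", b, se_b, p_b, j)
    sens = SensitivityResult(
        q_stat=q, q_df=j - 2, q_pval=float(chi2.sf(q, j - 2)),
        egger_intercept=alpha, intercept_se=se_alpha, intercept_pval=p_alpha,
    )
    return result, sens


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratios (weights need not be normed)."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    centred = np.cumsum(w) - 0.5 * w
    if centred[0] >= 0.5:
        return float(r[0])
    if centred[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(centred, 0.5, side="right")) - 1
    frac = (0.5 - centred[k]) / (centred[k + 1] - centred[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def _bootstrap_se(
    point_fn, ratios: np.ndarray, ses: np.ndarray, n_boot: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, ses, size=(n_boot, len(ratios)))
    stats = np.array([point_fn(d) for d in draws])
    return float(stats.std(ddof=1))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
    weighted: bool = True,
) -> MrResult:
    """Weighted (or, with weighted=False, simple) median of Wald ratios.

    The estimate interpolates adjacent sorted ratios where the centred
    cumulative weight crosses one half; the SE is a parametric bootstrap
    over redrawn ratios.
    """
    ests, _ = ratio_estimates(instruments)
    j = len(ests)
    _require(j, 3, "weighted_median")
    ratios = np.array([e.beta_ratio for e in ests])
    ses = np.array([e.se_ratio for e in ests])
    weights = ses ** -2.0 if weighted else np.ones(j)
    b = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(lambda r: _weighted_median_point(r, weights),
                       ratios, ses, n_boot, seed)
    p = float(2.0 * norm.sf(abs(b) / se))
    name = "weighted_median" if weighted else "simple_median"
    return MrResult(name, b, se, p, j)


def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                bandwidth_phi: float) -> float:
    """Argmax of the weighted normal-kernel density on a 512-point grid.

    Bandwidth h = phi * 0.9 * min(sd, 1.4826*MAD) * J^(-1/5); if all
    ratios coincide (h = 0) the common ratio is returned. Grid spans
    [min-3h, max+3h]; argmax ties break toward the smallest grid value.
    """
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) * 1.4826
    spread = min(sd, mad) if mad > 0 else sd
    h = bandwidth_phi * 0.9 * spread * j ** (-1 / 5)
    if h <= 0.0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = (np.exp(-0.5 * z ** 2) * weights[None, :]).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = False,
    bandwidth_phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrResult:
    """Mode-based estimate (simple or inverse-variance weighted).

    Consistent when the largest group of SNPs sharing a common ratio are
    valid instruments (zero modal pleiotropy assumption).
    """
    ests, _ = ratio_estimates(instruments)
    j = len(ests)
    _require(j, 3, "mode_estimator")
    ratios = np.array([e.beta_ratio for e in ests])
    ses = np.array([e.se_ratio for e in ests])
    weights = ses ** -2.0 if weighted else np.ones(j)
    weights = weights / weights.sum()
    b = _mode_point(ratios, weights, bandwidth_phi)
    se = _bootstrap_se(lambda r: _mode_point(r, weights, bandwidth_phi),
                       ratios, ses, n_boot, seed)
    p = float(2.0 * norm.sf(abs(b) / se))
    return MrResult("weighted_mode" if weighted else "simple_mode", b, se, p, j)


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    reference_estimate: float | None = None,
) -> SensitivityResult:
    """Cochran's Q over Wald ratios about the IVW (or given) estimate.

    Q = sum w_j (ratio_j - b)^2 with w_j the inverse ratio variances;
    df = J-1; p is the upper chi-square tail.
    """
    ests, _ = ratio_estimates(instruments)
    j = len(ests)
    _require(j, 2, "cochran_q")
    if reference_estimate is None:
        reference_estimate = ivw(instruments, re_mode="fixed").estimate
    ratios = np.array([e.beta_ratio for e in ests])
    w = np.array([e.weight for e in ests])
    q = float(np.sum(w * (ratios - reference_estimate) ** 2))
    return SensitivityResult(q_stat=q, q_df=j - 1, q_pval=float(chi2.sf(q, j - 1)))


def all_estimators(
    instruments: Sequence[HarmonizedInstrument],
    re_mode: ReMode = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_phi: float = 1.0,
) -> tuple[list[MrResult], SensitivityResult, SensitivityResult]:
    """Run all five estimators plus Q and the Egger intercept test.

    Returns (results in the order ivw, egger, weighted_median,
    simple_mode, weighted_mode; IVW-based Q; Egger sensitivity).
    """
    from .harmonization import orient_positive_exposure

    oriented = orient_positive_exposure(instruments)
    res_ivw = ivw(oriented, re_mode)
    res_egger, sens_egger = mr_egger(oriented, re_mode)
    res_wm = weighted_median(oriented, n_boot=n_boot, seed=seed)
    res_sm = mode_estimator(oriented, weighted=False, bandwidth_phi=bandwidth_phi,
                            n_boot=n_boot, seed=seed + 1)
    res_wmode = mode_estimator(oriented, weighted=True, bandwidth_phi=bandwidth_phi,
                               n_boot=n_boot, seed=seed + 2)
    q = cochran_q(oriented, res_ivw.estimate if re_mode == "fixed" else None)
    return [res_ivw, res_egger, res_wm, res_sm, res_wmode], q, sens_egger


__all__ = [
    "RatioEstimate", "MrResult", "SensitivityResult", "ReMode",
    "InsufficientInstrumentsError", "DegenerateDesignError",
    "ratio_estimates", "ivw", "mr_egger", "weighted_median",
    "mode_estimator", "cochran_q", "all_estimators", "Z95",
]
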