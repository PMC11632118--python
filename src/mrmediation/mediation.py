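"""Two-step MR mediation: product of coefficients, delta-method and
bootstrap SEs, proportion mediated.

The total exposure->outcome effect (beta_total, univariable IVW) is
decomposed into an indirect path through the mediator and a direct
remainder. Step one estimates the exposure->mediator effect beta_xz by
univariable MR; step two estimates the exposure-adjusted
mediator->outcome effect beta_zy' by multivariable MR of {exposure,
mediator} on the outcome. The mediated (indirect) effect is the product

    beta_mediating = beta_xz * beta_zy'

with SE by the first-order delta method
sqrt(beta_xz^2 se_zy'^2 + beta_zy'^2 se_xz^2) (an exact variant adds the
cross term se_xz^2 se_zy'^2) and, independently, by a parametric
bootstrap over the two coefficients. The proportion mediated is
beta_mediating / beta_total, with a percentile bootstrap CI. The two
sampled coefficients are treated as independent — they come from
separate two-sample fits — which is an assumption, flagged in output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gwas_io import SummaryStatRecord, LdTable
from .harmonization import harmonize, harmonize_multi, retained
from .instrument_selection import SelectionConfig, select_instruments
from .mvmr import mvmr_fit
from .uvmr import ivw, ReMode


class UndefinedProportionError(ZeroDivisionError):
    """Proportion mediated is undefined when the total effect is zero."""


def indirect_effect(
    beta_xz: float, se_xz: float, beta_zy_adj: float, se_zy_adj: float,
    exact: bool = False,
) -> tuple[float, float]:
    """Product-of-coefficients indirect effect and its delta-method SE.

    With ``exact=True`` the second-order term se_xz^2*se_zy'^2 is added
    inside the square root, which can only enlarge the SE.
    """
    for v in (beta_xz, se_xz, beta_zy_adj, se_zy_adj):
        if not math.isfinite(v):
            raise ValueError(f"non-finite mediation input: {v}")
    if se_xz <= 0 or se_zy_adj <= 0:
        raise ValueError("mediation SEs must be > 0")
    product = beta_xz * beta_zy_adj
    var = beta_xz ** 2 * se_zy_adj ** 2 + beta_zy_adj ** 2 * se_xz ** 2
    if exact:
        var += se_xz ** 2 * se_zy_adj ** 2
    return product, math.sqrt(var)


def bootstrap_indirect(
    beta_xz: float, se_xz: float, beta_zy_adj: float, se_zy_adj: float,
    n_boot: int = 5000, seed: int = 0,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Parametric bootstrap of the product of two normal coefficients.

    Returns (se_boot, (ci_low, ci_high), draws); the draws are reused for
    the proportion CI so total and indirect are sampled coherently.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    xz = rng.normal(beta_xz, se_xz, n_boot)
    zy = rng.normal(beta_zy_adj, se_zy_adj, n_boot)
    products = xz * zy
    se_boot = float(products.std(ddof=1)) if products.std(ddof=1) > 0 else 0.0
    lo, hi = np.percentile(products, [2.5, 97.5])
    return se_boot, (float(lo), float(hi)), products


def proportion_mediated(
    beta_mediating: float,
    beta_total: float,
    se_total: float,
    indirect_draws: np.ndarray,
    seed: int = 0,
) -> tuple[float, tuple[float, float], list[str]]:
    """Point estimate and paired-bootstrap percentile CI of the proportion.

    Total-effect draws are sampled as Normal(beta_total, se_total^2) and
    paired with the indirect-effect draws. Flags: ``inconsistent-mediation``
    when indirect and total effects have opposite signs, ``proportion-gt-1``
    when |proportion| exceeds one.
    """
    if beta_total == 0.0:
        raise UndefinedProportionError("total effect is zero")
    point = beta_mediating / beta_total
    rng = np.random.default_rng(seed)
    totals = rng.normal(beta_total, se_total, len(indirect_draws))
    ok = totals != 0.0
    ratios = indirect_draws[ok] / totals[ok]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    flags = []
    if beta_mediating * beta_total < 0:
        flags.append("inconsistent-mediation")
    if abs(point) > 1:
        flags.append("proportion-gt-1")
    return float(point), (float(lo), float(hi)), flags


@dataclass
class MediationResult:
    """Everything the two-step decomposition produces.

    The exact identities beta_mediating == beta_xz*beta_zy_adj and
    proportion*beta_total == beta_mediating hold to machine precision.
    """

    beta_total: float
    se_total: float
    beta_xz: float
    se_xz: float
    beta_zy_adj: float
    se_zy_adj: float
    beta_mediating: float
    se_delta: float
    se_boot: float
    ci_delta: tuple[float, float]
    ci_boot: tuple[float, float]
    proportion: float
    proportion_ci: tuple[float, float]
    flags: list[str]
    n_boot: int
    seed: int
    n_snps_total: int = 0
    n_snps_xz: int = 0
    n_snps_mvmr: int = 0
    assumptions: tuple[str, ...] = (
        "bootstrap treats the two coefficient estimates as independent",
    )


def mediate_from_coefficients(
    beta_total: float, se_total: float,
    beta_xz: float, se_xz: float,
    beta_zy_adj: float, se_zy_adj: float,
    n_boot: int = 5000, seed: int = 0, exact_delta: bool = False,
) -> MediationResult:
    """Mediation summary from the three fitted coefficients."""
    product, se_delta = indirect_effect(beta_xz, se_xz, beta_zy_adj, se_zy_adj,
                                        exact=exact_delta)
    se_boot, ci_boot, draws = bootstrap_indirect(
        beta_xz, se_xz, beta_zy_adj, se_zy_adj, n_boot=n_boot, seed=seed)
    z = 1.959964
    ci_delta = (product - z * se_delta, product + z * se_delta)
    prop, prop_ci, flags = proportion_mediated(
        product, beta_total, se_total, draws, seed=seed + 1)
    return MediationResult(
        beta_total=beta_total, se_total=se_total,
        beta_xz=beta_xz, se_xz=se_xz,
        beta_zy_adj=beta_zy_adj, se_zy_adj=se_zy_adj,
        beta_mediating=product, se_delta=se_delta, se_boot=se_boot,
        ci_delta=ci_delta, ci_boot=ci_boot,
        proportion=prop, proportion_ci=prop_ci, flags=flags,
        n_boot=n_boot, seed=seed,
    )


@dataclass
class TwoStepStages:
    """Intermediate per-stage outputs of the orchestrated analysis."""

    instruments_xy: list = field(default_factory=list)
    instruments_xm: list = field(default_factory=list)
    instruments_mvmr: list = field(default_factory=list)
    selection_reports: dict = field(default_factory=dict)


def run_two_step_mediation(
    exposure: Sequence[SummaryStatRecord],
    mediator: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    selection: SelectionConfig = SelectionConfig(),
    ld: LdTable | None = None,
    re_mode: ReMode = "multiplicative_random",
    n_boot: int = 5000,
    seed: int = 0,
    exact_delta: bool = False,
) -> tuple[MediationResult, TwoStepStages]:
    """Full two-step mediation from three summary-statistic sets.

    Orchestrates: instrument selection per trait -> harmonization ->
    univariable IVW for the total exposure->outcome effect and for the
    exposure->mediator effect -> multivariable MR of {exposure, mediator}
    on the outcome for the adjusted mediator effect -> the product
    decomposition. The MVMR instrument set is the union of the exposure's
    and mediator's selected instruments, re-clumped jointly.
    """
    stages = TwoStepStages()
    from .instrument_selection import clump

    iv_x, rep_x = select_instruments(exposure, selection, ld)
    iv_m, rep_m = select_instruments(mediator, selection, ld)
    stages.selection_reports = {"exposure": rep_x, "mediator": rep_m}

    outcome_by = {r.rsid: r for r in outcome}
    mediator_by = {r.rsid: r for r in mediator}
    exposure_by = {r.rsid: r for r in exposure}

    # total effect: exposure instruments vs outcome
    hx_y, _ = harmonize(iv_x, [outcome_by[r.rsid] for r in iv_x
                               if r.rsid in outcome_by])
    stages.instruments_xy = hx_y
    total = ivw(hx_y, re_mode)

    # step 1: exposure instruments vs mediator
    hx_m, _ = harmonize(iv_x, [mediator_by[r.rsid] for r in iv_x
                               if r.rsid in mediator_by])
    stages.instruments_xm = hx_m
    xz = ivw(hx_m, re_mode)

    # step 2: union instrument set, re-clumped jointly, complete-case
    union_rsids = {r.rsid for r in iv_x} | {r.rsid for r in iv_m}
    pooled = [exposure_by[rs] for rs in sorted(union_rsids)
              if rs in exposure_by and rs in mediator_by and rs in outcome_by]
    pooled = clump(pooled, selection.clump_kb, selection.clump_r2, ld)
    hm, _ = harmonize_multi(
        pooled,
        {"mediator": [mediator_by[r.rsid] for r in pooled],
         "outcome": [outcome_by[r.rsid] for r in pooled]},
        outcome="outcome",
    )
    stages.instruments_mvmr = hm
    mv = mvmr_fit(hm, ["exposure", "mediator"])
    zy = mv["mediator"]

    result = mediate_from_coefficients(
        total.estimate, total.se, xz.estimate, xz.se, zy.estimate, zy.se,
        n_boot=n_boot, seed=seed, exact_delta=exact_delta,
    )
    result.n_snps_total = total.n_snps
    result.n_snps_xz = xz.n_snps
    result.n_snps_mvmr = mv.n_snps
    return result, stages


__all__ = [
    "MediationResult", "TwoStepStages", "UndefinedProportionError",
    "indirect_effect", "bootstrap_indirect", "proportion_mediated",
    "mediate_from_coefficients", "run_two_step_mediation",
]
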