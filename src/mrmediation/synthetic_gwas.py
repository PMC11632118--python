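"""Synthetic GWAS summary statistics under a known causal-mediation graph.

Emulates the three-trait setting of the analysis — a binary exposure X
(asthma), a quantitative mediator M (eosinophil count) and a binary
outcome Y (colon cancer) — on summary-statistic level only:

    X --a--> M --b--> Y      plus a direct path X --c'--> Y

Each of J exposure instruments has a per-allele effect gamma_j on X;
each of J_m mediator-specific instruments has an effect alpha_j on M
only. True marginal effects are gamma_j on X, a*gamma_j + alpha_j on M,
and c'*gamma_j + b*(a*gamma_j + alpha_j) + delta_j on Y, where delta_j
is an optional pleiotropic direct effect on exposure instruments
(balanced: zero-mean; directional: non-zero mean). Observed betas add
Normal(0, se_j^2) noise with se_j = 1/sqrt(2*maf*(1-maf)*n) for the
study's sample size n — the three studies' noise is independent,
matching the two-sample design. Allele pairs include configurable
fractions of palindromic SNPs and of strand-flipped reporting in the
mediator and outcome studies, to stress harmonization.

Instruments are mutually independent (placed >10 Mb apart, no LD), the
regime real instruments are in after clumping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.stats import norm

from .gwas_io import SummaryStatRecord

_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PAL_PAIRS = [("A", "T"), ("C", "G")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: total effect matching an odds ratio of 0.830 and a mediated share of
#: roughly 52%, the magnitudes of the motivating asthma -> eosinophil ->
#: colon-cancer analysis
_PAPER_LIKE = dict(a=0.31, b=-0.3108, c_prime=-0.09)


@dataclass(frozen=True)
class Pleiotropy:
    """Direct SNP->outcome effects bypassing both exposure and mediator."""

    kind: Literal["none", "balanced", "directional"] = "none"
    mean: float = 0.0
    sd: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one simulated three-study dataset.

    Sample sizes default to large-biobank scale (exposure ~360k, blood-
    cell trait ~170k, cancer outcome ~200k); the mean instrument F at the
    exposure study defaults to 300, i.e. well-powered instruments of the
    kind that survive genome-wide selection.
    """

    J: int = 150
    J_m: int = 150
    a: float = _PAPER_LIKE["a"]
    b: float = _PAPER_LIKE["b"]
    c_prime: float = _PAPER_LIKE["c_prime"]
    pleiotropy: Pleiotropy = Pleiotropy()
    n_x: int = 360_000
    n_m: int = 170_000
    n_y: int = 200_000
    maf_range: tuple[float, float] = (0.05, 0.45)
    mean_f: float = 300.0
    palindromic_fraction: float = 0.10
    strand_flip_fraction: float = 0.10
    eaf_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 3:
            raise ValueError(f"J must be >= 3, got {self.J}")
        if self.J_m < 0:
            raise ValueError(f"J_m must be >= 0, got {self.J_m}")
        if min(self.n_x, self.n_m, self.n_y) <= 0:
            raise ValueError("sample sizes must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.mean_f <= 0:
            raise ValueError("mean_f must be > 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth a simulation run must allow recovering."""

    a: float
    b: float
    c_prime: float
    gamma: tuple[float, ...] = ()
    alpha: tuple[float, ...] = ()
    delta: tuple[float, ...] = ()

    @property
    def total(self) -> float:
        return self.c_prime + self.a * self.b

    @property
    def proportion_true(self) -> float:
        return self.a * self.b / self.total


def _positions(n_snps: int) -> list[tuple[str, int]]:
    """Spread SNPs over chromosomes 1..22 with >10 Mb spacing."""
    out = []
    for i in range(n_snps):
        chrom = str(i % 22 + 1)
        rank = i // 22
        out.append((chrom, 10_500_000 * (rank + 1)))
    return out


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_summary_stats(
    config: SimConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord],
           list[SummaryStatRecord], SimTruth]:
    """Generate (exposure, mediator, outcome) studies and the truth.

    Fully reproducible from ``config.seed``. Instrument effects gamma_j
    are Normal(0, sigma^2) with sigma chosen so the mean per-SNP F
    statistic at the exposure study equals ``mean_f``; mediator-specific
    effects alpha_j are scaled the same way against the mediator study.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.J + config.J_m
    maf = rng.uniform(*config.maf_range, n_total)
    info_x = 2.0 * maf * (1.0 - maf) * config.n_x
    info_m = 2.0 * maf * (1.0 - maf) * config.n_m

    sigma_gamma = math.sqrt(config.mean_f / float(np.mean(info_x[:config.J])))
    gamma = np.zeros(n_total)
    gamma[:config.J] = rng.normal(0.0, sigma_gamma, config.J)

    alpha = np.zeros(n_total)
    if config.J_m:
        sigma_alpha = math.sqrt(config.mean_f / float(np.mean(info_m[config.J:])))
        alpha[config.J:] = rng.normal(0.0, sigma_alpha, config.J_m)

    delta = np.zeros(n_total)
    if config.pleiotropy.kind == "balanced":
        delta[:config.J] = rng.normal(0.0, config.pleiotropy.sd, config.J)
    elif config.pleiotropy.kind == "directional":
        delta[:config.J] = rng.normal(config.pleiotropy.mean,
                                      config.pleiotropy.sd, config.J)

    true_x = gamma
    true_m = config.a * gamma + alpha
    # pleiotropic effects are specified relative to the exposure-raising
    # allele (the orientation Egger regression analyses instruments in);
    # expressed on the raw allele they carry the sign of gamma_j
    delta_oriented = np.where(gamma < 0, -delta, delta)
    true_y = config.c_prime * gamma + config.b * true_m + delta_oriented

    se_x = _se(maf, config.n_x)
    se_m = _se(maf, config.n_m)
    se_y = _se(maf, config.n_y)
    obs_x = true_x + rng.normal(0.0, se_x)
    obs_m = true_m + rng.normal(0.0, se_m)
    obs_y = true_y + rng.normal(0.0, se_y)

    pal = rng.random(n_total) < config.palindromic_fraction
    pair_idx = rng.integers(0, 2, n_total)
    nonpal_idx = rng.integers(0, len(_NONPAL_PAIRS), n_total)
    flip_m = rng.random(n_total) < config.strand_flip_fraction
    flip_y = rng.random(n_total) < config.strand_flip_fraction
    swap_m = rng.random(n_total) < 0.5
    swap_y = rng.random(n_total) < 0.5
    positions = _positions(n_total)

    def eaf_obs(f: float) -> float:
        noisy = f + rng.normal(0.0, config.eaf_noise_sd)
        return float(min(max(noisy, 1e-4), 1.0 - 1e-4))

    def record(i: int, beta: float, se: float, n: int,
               flip: bool, swap: bool) -> SummaryStatRecord:
        if pal[i]:
            ea, oa = _PAL_PAIRS[pair_idx[i]]
        else:
            ea, oa = _NONPAL_PAIRS[nonpal_idx[i]]
        eaf = maf[i]
        if flip:  # reported on the opposite strand
            ea, oa = _COMP[ea], _COMP[oa]
        if swap:  # reported with the other allele as effect allele
            ea, oa = oa, ea
            beta, eaf = -beta, 1.0 - eaf
        z = abs(beta) / se
        pval = float(max(2.0 * norm.sf(z), 5e-324))
        chrom, pos = positions[i]
        return SummaryStatRecord(
            rsid=f"rs{i + 1:06d}", effect_allele=ea, other_allele=oa,
            beta=float(beta), se=float(se), chrom=chrom, pos=pos,
            eaf=eaf_obs(eaf), pval=pval, n=float(n),
        )

    exposure = [record(i, obs_x[i], se_x[i], config.n_x,
                       False, False) for i in range(n_total)]
    mediator = [record(i, obs_m[i], se_m[i], config.n_m,
                       bool(flip_m[i] and not pal[i]), bool(swap_m[i]))
                for i in range(n_total)]
    outcome = [record(i, obs_y[i], se_y[i], config.n_y,
                      bool(flip_y[i] and not pal[i]), bool(swap_y[i]))
               for i in range(n_total)]

    truth = SimTruth(a=config.a, b=config.b, c_prime=config.c_prime,
                     gamma=tuple(gamma), alpha=tuple(alpha),
                     delta=tuple(delta))
    return exposure, mediator, outcome, truth


SCENARIOS = {
    "paper-like": {},
    "no-mediation": dict(a=0.0, b=-0.31, c_prime=-0.186),
    "full-mediation": dict(a=0.31, b=-0.60, c_prime=0.0),
    "directional-pleiotropy": dict(
        pleiotropy=Pleiotropy("directional", mean=0.02, sd=0.005)),
    "weak-instruments": dict(mean_f=15.0),
}


def scenario_library(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named, documented configurations for the study conditions.

    ``paper-like`` sets (a, b, c') so the total effect is about
    ln(0.830) and the true mediated proportion about 0.52, echoing the
    motivating estimates; ``no-mediation`` sets a=0; ``full-mediation``
    sets c'=0; ``directional-pleiotropy`` adds mean-0.02 direct effects;
    ``weak-instruments`` drops the mean instrument F to 15.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    kwargs = dict(SCENARIOS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)


__all__ = ["SimConfig", "SimTruth", "Pleiotropy", "simulate_summary_stats",
           "scenario_library", "SCENARIOS", "replace"]
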