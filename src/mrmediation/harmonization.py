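"""Allele harmonization across two-sample MR studies.

Every SNP shared between an exposure study and another study (outcome or
mediator) is aligned so both betas refer to the exposure study's effect
allele. Four reconciliations are possible: the alleles already match
(``as-is``), the studies report opposite effect alleles (``allele-swap``:
negate the other study's beta, complement its frequency), the other study
is on the opposite strand (``strand-flip``: relabel, betas unchanged), or
both (``swap+flip``). Palindromic SNPs (A/T or G/C) are strand-ambiguous:
strand is inferred from effect-allele-frequency concordance when both
frequencies are available and informative (outside the ambiguity window
around 0.5), otherwise the SNP is dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .gwas_io import SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf interval around 0.5 inside which a palindromic SNP's strand cannot
#: be inferred from frequency.
AMBIGUITY_WINDOW = (0.42, 0.58)
FREQ_TOLERANCE = 0.08


def complement_allele(allele: str) -> str | None:
    """Reverse complement; None if any base is not A/C/G/T (e.g. indel tokens)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


def is_palindromic(ea: str, oa: str) -> bool:
    return complement_allele(ea) == oa


@dataclass
class HarmonizedInstrument:
    """One SNP's aligned effects on the exposure and one other study.

    All betas refer to the exposure study's effect allele. ``dropped``
    instruments are excluded from every downstream estimator; ``reason``
    says why. ``beta_mediators`` holds per-mediator aligned effects when
    more than one non-exposure study is aligned (multivariable use).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float | None = None
    se_outcome: float | None = None
    beta_mediators: dict[str, tuple[float, float]] = field(default_factory=dict)
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    action_taken: str = "as-is"
    palindromic: bool = False
    dropped: bool = False
    reason: str | None = None


@dataclass
class HarmonizationReport:
    n_exposure: int = 0
    n_other: int = 0
    n_shared: int = 0
    n_retained: int = 0
    drop_reasons: Counter = field(default_factory=Counter)
    actions: Counter = field(default_factory=Counter)


def _multiallelic_rsids(records: Sequence[SummaryStatRecord]) -> set[str]:
    seen: dict[str, frozenset] = {}
    bad: set[str] = set()
    for r in records:
        pair = frozenset((r.effect_allele, r.other_allele))
        if r.rsid in seen and seen[r.rsid] != pair:
            bad.add(r.rsid)
        seen.setdefault(r.rsid, pair)
    # duplicated rsid with the same allele pair is also unusable
    counts = Counter(r.rsid for r in records)
    bad |= {rs for rs, c in counts.items() if c > 1}
    return bad


def _align_one(
    exp: SummaryStatRecord,
    oth: SummaryStatRecord,
    freq_tolerance: float,
    ambiguity_window: tuple[float, float],
) -> tuple[float | None, float | None, str, bool, str | None]:
    """Return (aligned_beta, aligned_eaf, action, palindromic, drop_reason)."""
    ea, oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = oth.effect_allele, oth.other_allele
    palindromic = is_palindromic(ea, oa)

    if not palindromic:
        if (o_ea, o_oa) == (ea, oa):
            return oth.beta, oth.eaf, "as-is", False, None
        if (o_ea, o_oa) == (oa, ea):
            return -oth.beta, _comp_eaf(oth.eaf), "allele-swap", False, None
        c_ea, c_oa = complement_allele(o_ea), complement_allele(o_oa)
        if (c_ea, c_oa) == (ea, oa):
            return oth.beta, oth.eaf, "strand-flip", False, None
        if (c_ea, c_oa) == (oa, ea):
            return -oth.beta, _comp_eaf(oth.eaf), "swap+flip", False, None
        return None, None, "none", False, "incompatible-alleles"

    # palindromic: textual match cannot distinguish strand; use frequencies
    if {o_ea, o_oa} != {ea, oa}:
        return None, None, "none", True, "incompatible-alleles"
    if (o_ea, o_oa) == (ea, oa):
        beta, eaf, action = oth.beta, oth.eaf, "as-is"
    else:
        beta, eaf, action = -oth.beta, _comp_eaf(oth.eaf), "allele-swap"

    lo, hi = ambiguity_window
    f_exp, f_oth = exp.eaf, eaf
    if f_exp is None or f_oth is None:
        return None, None, action, True, "palindromic-ambiguous"
    if lo <= f_exp <= hi or lo <= f_oth <= hi:
        return None, None, action, True, "palindromic-ambiguous"
    if abs(f_exp - f_oth) <= freq_tolerance:
        return beta, eaf, action, True, None
    if abs(f_exp - (1.0 - f_oth)) <= freq_tolerance:
        # frequencies concordant only under the opposite strand: the textual
        # match picked the wrong orientation, so flip it
        flipped = "swap+flip" if action == "as-is" else "strand-flip"
        return -beta, _comp_eaf(f_oth), flipped, True, None
    return None, None, action, True, "palindromic-ambiguous"


def _comp_eaf(eaf: float | None) -> float | None:
    return None if eaf is None else 1.0 - eaf


def harmonize(
    exposure_records: Sequence[SummaryStatRecord],
    other_records: Sequence[SummaryStatRecord],
    freq_tolerance: float = FREQ_TOLERANCE,
    ambiguity_window: tuple[float, float] = AMBIGUITY_WINDOW,
) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Align the other study's effects to the exposure study's effect alleles.

    Only rsids present in both studies are processed. Irreconcilable or
    ambiguous SNPs are returned with ``dropped=True`` and a reason rather
    than raising. Idempotent: harmonizing already-aligned records is a
    no-op (all actions ``as-is``).
    """
    report = HarmonizationReport(n_exposure=len(exposure_records),
                                 n_other=len(other_records))
    multi = _multiallelic_rsids(exposure_records) | _multiallelic_rsids(other_records)
    oth_by_rsid = {r.rsid: r for r in other_records}

    out: list[HarmonizedInstrument] = []
    for exp in exposure_records:
        oth = oth_by_rsid.get(exp.rsid)
        if oth is None:
            continue
        report.n_shared += 1
        inst = HarmonizedInstrument(
            rsid=exp.rsid, effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exposure=exp.beta, se_exposure=exp.se,
            eaf_exposure=exp.eaf,
        )
        if exp.rsid in multi:
            inst.dropped, inst.reason = True, "multiallelic"
        else:
            beta, eaf, action, pal, reason = _align_one(
                exp, oth, freq_tolerance, ambiguity_window)
            inst.action_taken = action
            inst.palindromic = pal
            if reason is not None:
                inst.dropped, inst.reason = True, reason
            else:
                inst.beta_outcome, inst.se_outcome = beta, oth.se
                inst.eaf_outcome = eaf
        if inst.dropped:
            report.drop_reasons[inst.reason] += 1
        else:
            report.n_retained += 1
            report.actions[inst.action_taken] += 1
        out.append(inst)
    return out, report


def harmonize_multi(
    exposure_records: Sequence[SummaryStatRecord],
    other_studies: Mapping[str, Sequence[SummaryStatRecord]],
    outcome: str,
    freq_tolerance: float = FREQ_TOLERANCE,
    ambiguity_window: tuple[float, float] = AMBIGUITY_WINDOW,
) -> tuple[list[HarmonizedInstrument], dict[str, HarmonizationReport]]:
    """Align several studies to the exposure's effect alleles at once.

    ``other_studies`` maps study name -> records; the study named by
    ``outcome`` fills ``beta_outcome``, every other one goes into
    ``beta_mediators``. A SNP missing from any study, or dropped in any
    pairwise alignment, is dropped (complete-case) with the reason of the
    first failing study.
    """
    reports: dict[str, HarmonizationReport] = {}
    per_study: dict[str, dict[str, HarmonizedInstrument]] = {}
    for name, recs in other_studies.items():
        aligned, rep = harmonize(exposure_records, recs,
                                 freq_tolerance, ambiguity_window)
        reports[name] = rep
        per_study[name] = {h.rsid: h for h in aligned}

    out: list[HarmonizedInstrument] = []
    for exp in exposure_records:
        parts = {name: per_study[name].get(exp.rsid) for name in other_studies}
        if any(p is None for p in parts.values()):
            continue  # not shared across all studies
        inst = HarmonizedInstrument(
            rsid=exp.rsid, effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exposure=exp.beta, se_exposure=exp.se, eaf_exposure=exp.eaf,
        )
        failed = next((p for p in parts.values() if p.dropped), None)
        if failed is not None:
            inst.dropped, inst.reason = True, failed.reason
        else:
            oc = parts[outcome]
            inst.beta_outcome, inst.se_outcome = oc.beta_outcome, oc.se_outcome
            inst.eaf_outcome = oc.eaf_outcome
            inst.action_taken = oc.action_taken
            inst.palindromic = oc.palindromic
            for name, p in parts.items():
                if name != outcome:
                    inst.beta_mediators[name] = (p.beta_outcome, p.se_outcome)
        out.append(inst)
    return out, reports


def retained(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    return [h for h in instruments if not h.dropped]


def orient_positive_exposure(
    instruments: Iterable[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Re-orient every instrument so the exposure beta is non-negative.

    Joint negation of (beta_exposure, beta_outcome, mediator betas) leaves
    every ratio-based estimate unchanged; MR-Egger requires it as a
    pre-condition. Frequencies are complemented alongside, since negation
    corresponds to re-labelling the effect allele.
    """
    out = []
    for h in instruments:
        if h.dropped or h.beta_exposure >= 0:
            out.append(replace(h, beta_mediators=dict(h.beta_mediators)))
            continue
        out.append(replace(
            h,
            effect_allele=h.other_allele,
            other_allele=h.effect_allele,
            beta_exposure=-h.beta_exposure,
            beta_outcome=None if h.beta_outcome is None else -h.beta_outcome,
            eaf_exposure=_comp_eaf(h.eaf_exposure),
            eaf_outcome=_comp_eaf(h.eaf_outcome),
            beta_mediators={k: (-b, s) for k, (b, s) in h.beta_mediators.items()},
        ))
    return out


def write_harmonization_report(
    instruments: Sequence[HarmonizedInstrument], path: str | Path
) -> None:
    """TSV: rsid, action, dropped, reason — one row per processed SNP."""
    with open(path, "w") as fh:
        fh.write("rsid\taction\tdropped\treason\n")
        for h in instruments:
            fh.write(f"{h.rsid}\t{h.action_taken}\t{h.dropped}\t{h.reason or 'NA'}\n")


__all__ = [
    "HarmonizedInstrument", "HarmonizationReport", "harmonize",
    "harmonize_multi", "orient_positive_exposure", "retained",
    "complement_allele", "is_palindromic", "write_harmonization_report",
    "AMBIGUITY_WINDOW", "FREQ_TOLERANCE",
]
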