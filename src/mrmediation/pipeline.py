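"""End-to-end pipeline orchestration, run configuration and the
Wald-consistency utility for published OR/CI/p triplets."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from scipy.stats import norm

from . import __version__
from .gwas_io import (ConfigurationError, LdTable, read_ld_table,
                      read_summary_stats)
from .harmonization import write_harmonization_report
from .instrument_selection import SelectionConfig, read_exclusion_list
from .mediation import MediationResult, run_two_step_mediation
from .uvmr import Z95, all_estimators

Z = {0.95: Z95}


def wald_p_from_or_ci(or_point: float, ci_low: float, ci_high: float,
                      level: float = 0.95) -> float:
    """Recompute the two-sided p-value implied by an OR and its CI.

    Inverts the symmetric normal interval on the log scale:
    se = (ln hi - ln lo) / (2 z), z = ln OR / se, p = 2 Phi(-|z|). Used
    to check published OR (CI) p triplets for internal consistency.
    """
    if not 0.0 < ci_low < or_point < ci_high:
        raise ValueError(
            f"need 0 < ci_low < OR < ci_high, got ({or_point}, {ci_low}, {ci_high})")
    z_level = Z.get(level) or float(norm.ppf(0.5 + level / 2.0))
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z_level)
    z = math.log(or_point) / se
    return float(2.0 * norm.sf(abs(z)))


@dataclass
class RunConfig:
    """Paths and options for a full pipeline run."""

    exposure_path: str
    outcome_path: str
    mediator_path: str | None = None
    ld_path: str | None = None
    exclusion_path: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    re_mode: str = "multiplicative_random"
    n_boot: int = 1000
    bandwidth_phi: float = 1.0
    mediation_n_boot: int = 5000
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        for label, p in (("exposure", self.exposure_path),
                         ("outcome", self.outcome_path),
                         ("mediator", self.mediator_path),
                         ("ld", self.ld_path),
                         ("exclusion", self.exclusion_path)):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{label} file not found: {p}")


def _results_table(results) -> str:
    lines = ["method\tn_snps\testimate\tse\tci_low\tci_high\tpval\tOR\tOR_ci_low\tOR_ci_high"]
    for r in results:
        orp, lo, hi = r.or_scale
        lines.append(
            f"{r.method}\t{r.n_snps}\t{r.estimate:.6g}\t{r.se:.6g}\t"
            f"{r.ci_low:.6g}\t{r.ci_high:.6g}\t{r.pval:.4g}\t"
            f"{orp:.4g}\t{lo:.4g}\t{hi:.4g}")
    return "\n".join(lines) + "\n"


def _mediation_report(m: MediationResult) -> str:
    d = dataclasses.asdict(m)
    return json.dumps(d, indent=2, default=list) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Selection -> harmonization -> five UVMR estimators -> sensitivity
    -> (optionally) MVMR-based mediation; everything persisted under
    ``config.out_dir`` with a reproducibility manifest.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exposure, _ = read_summary_stats(config.exposure_path)
    outcome, _ = read_summary_stats(config.outcome_path)
    ld: LdTable | None = None
    if config.ld_path:
        ld, _ = read_ld_table(config.ld_path)
    selection = config.selection
    if config.exclusion_path:
        selection = dataclasses.replace(
            selection,
            exclusion_list=read_exclusion_list(config.exclusion_path))

    from .instrument_selection import select_instruments
    from .harmonization import harmonize

    iv_x, sel_report = select_instruments(exposure, selection, ld)
    outcome_by = {r.rsid: r for r in outcome}
    hx, _ = harmonize(iv_x, [outcome_by[r.rsid] for r in iv_x
                             if r.rsid in outcome_by])
    results, q, egger_sens = all_estimators(
        hx, re_mode=config.re_mode, n_boot=config.n_boot,
        seed=config.seed, bandwidth_phi=config.bandwidth_phi)

    (out_dir / "mr_results.tsv").write_text(_results_table(results))
    write_harmonization_report(hx, out_dir / "harmonization.tsv")
    sel_report.write(out_dir / "selection.tsv")
    (out_dir / "sensitivity.tsv").write_text(
        "stat\tvalue\n"
        f"q_stat\t{q.q_stat:.6g}\nq_df\t{q.q_df}\nq_pval\t{q.q_pval:.4g}\n"
        f"egger_intercept\t{egger_sens.egger_intercept:.6g}\n"
        f"egger_intercept_se\t{egger_sens.intercept_se:.6g}\n"
        f"egger_intercept_pval\t{egger_sens.intercept_pval:.4g}\n")

    bundle = {"results": results, "q": q, "egger": egger_sens}

    if config.mediator_path:
        mediator, _ = read_summary_stats(config.mediator_path)
        mediation, _stages = run_two_step_mediation(
            exposure, mediator, outcome, selection=selection, ld=ld,
            re_mode=config.re_mode, n_boot=config.mediation_n_boot,
            seed=config.seed)
        (out_dir / "mediation.json").write_text(_mediation_report(mediation))
        bundle["mediation"] = mediation

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["selection"]["exclusion_list"] = sorted(
        cfg_dict["selection"]["exclusion_list"])
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle


__all__ = ["RunConfig", "run_pipeline", "wald_p_from_or_ci"]
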