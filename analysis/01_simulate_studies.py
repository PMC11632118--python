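"""Generate the three simulated GWAS summary-statistic studies.

Simulates the paper-like scenario — exposure (asthma-like), mediator
(eosinophil-count-like) and outcome (colon-cancer-like) — under the
causal graph X -> M -> Y with a direct X -> Y path, and writes the three
TSV studies plus the generative truth to results/sim/.
"""

import json
from pathlib import Path

from mrmediation.gwas_io import write_summary_stats
from mrmediation.synthetic_gwas import scenario_library, simulate_summary_stats

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    cfg = scenario_library("paper-like", seed=SEED)
    exposure, mediator, outcome, truth = simulate_summary_stats(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_summary_stats(exposure, OUT / "exposure.tsv")
    write_summary_stats(mediator, OUT / "mediator.tsv")
    write_summary_stats(outcome, OUT / "outcome.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "a": truth.a, "b": truth.b, "c_prime": truth.c_prime,
        "total": truth.total, "proportion_true": truth.proportion_true,
        "seed": SEED}, indent=2) + "\n")
    print(f"wrote {cfg.J + cfg.J_m} SNPs x 3 studies to {OUT}")
    print(f"truth: total={truth.total:.4f} (OR {2.718281828**truth.total:.3f}), "
          f"proportion mediated={truth.proportion_true:.3f}")


if __name__ == "__main__":
    main()
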