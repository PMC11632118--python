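"""Univariable MR of the simulated exposure on the outcome.

Selects instruments (p < 5e-8, 10,000 kb / r2 < 0.001 clumping),
harmonizes them to the outcome study, runs the five estimators plus
Cochran's Q and the Egger intercept test, and writes the forest-plot-
shaped results table. Requires 01_simulate_studies.py to have run.
"""

from pathlib import Path

from mrmediation.pipeline import RunConfig, run_pipeline

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig(exposure_path=str(BASE / "sim" / "exposure.tsv"),
                    outcome_path=str(BASE / "sim" / "outcome.tsv"),
                    seed=1, out_dir=str(BASE / "uvmr"))
    bundle = run_pipeline(cfg)
    print(f"{'method':16s} {'OR':>6s} {'95% CI':>15s} {'p':>9s}  J")
    for r in bundle["results"]:
        orp, lo, hi = r.or_scale
        print(f"{r.method:16s} {orp:6.3f} ({lo:.3f}, {hi:.3f}) "
              f"{r.pval:9.3g}  {r.n_snps}")
    q, egger = bundle["q"], bundle["egger"]
    print(f"Cochran Q = {q.q_stat:.1f} (df {q.q_df}, p = {q.q_pval:.3f})")
    print(f"Egger intercept = {egger.egger_intercept:.4f} "
          f"(p = {egger.intercept_pval:.3f})")
    print(f"tables in {BASE / 'uvmr'}")


if __name__ == "__main__":
    main()
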