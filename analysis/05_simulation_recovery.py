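#!/usr/bin/env python
"""Parameter-recovery validation of the estimators on synthetic GWAS data.

Three seeded scenarios, 200 replicates each:
  A  causal effect 0.11, no pleiotropy      -> IVW should be nearly unbiased
  B  null effect, no pleiotropy             -> IVW 95% CI coverage near 0.95
  C  null effect, directional pleiotropy
     (mean 0.02)                            -> IVW is biased; the Egger slope
                                               is not, and the Egger intercept
                                               recovers the pleiotropy mean

Writes the metrics table under results/ and prints it.
"""
from pathlib import Path

from summarymr import recovery_study

RESULTS = Path(__file__).resolve().parents[1] / "results"

SCENARIOS = [
    dict(n_variants=50, theta=0.11),
    dict(n_variants=50, theta=0.0),
    dict(n_variants=100, theta=0.0, pleiotropy_mean=0.02, pleiotropy_sd=0.01),
]


def main() -> None:
    out = RESULTS / "recovery"
    out.mkdir(parents=True, exist_ok=True)
    table = recovery_study(
        SCENARIOS, n_reps=200,
        estimators=("ivw", "ivw_penalized_robust", "egger"), seed=20260930)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    cols = ["scenario", "estimator", "theta", "pleiotropy_mean", "bias",
            "empirical_se", "rmse", "ci_coverage", "intercept_mean"]
    print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
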