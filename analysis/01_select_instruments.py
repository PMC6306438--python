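#!/usr/bin/env python
"""Select genetic instruments for CRP from the packaged association tables.

Five variants reach genome-wide significance for CRP; one (rs4420638, APOE
locus) is itself associated with T2DM and is removed, leaving four valid
instruments.  The T1DM table provides three of the five.  Writes the
harmonized instrument tables and the exclusion log under results/.
"""
from pathlib import Path

import pandas as pd

from summarymr import datasets, select_instruments
from summarymr.instruments import exclusions_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = RESULTS / "instruments"
    out.mkdir(parents=True, exist_ok=True)
    for label, harmonized in (
        ("t2dm", datasets.crp_t2dm_harmonized()),
        ("t1dm", datasets.crp_t1dm_harmonized()),
    ):
        kept, log = select_instruments(harmonized)
        frame = pd.DataFrame([vars(v) for v in kept])
        frame.to_csv(out / f"{label}_instruments.tsv", sep="\t", index=False)
        exclusions_frame(log).to_csv(out / f"{label}_exclusions.tsv", sep="\t", index=False)
        print(f"{label}: {len(harmonized)} candidates -> {len(kept)} instruments "
              f"({', '.join(v.variant_id for v in kept)})")
        for rec in log:
            print(f"  removed {rec.variant_id}: {rec.reason.value} ({rec.detail})")


if __name__ == "__main__":
    main()
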