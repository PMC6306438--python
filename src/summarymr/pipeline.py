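"""End-to-end analysis pipeline: read -> harmonize -> select -> estimate -> report.

Stages are logged to standard error with input/output counts and wall time;
results go only to the report object and, when an output directory is given,
to TSV/JSON files there.  The report is deterministic for fixed inputs and
configuration, timestamps aside.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .estimators import (
    EggerResult,
    EstimationError,
    HeterogeneityResult,
    PooledEstimate,
    WaldEstimate,
    cochran_q,
    egger_regression,
    pool,
    wald_ratios,
)
from .instruments import (
    ExclusionReason,
    ExclusionRecord,
    LDMatrix,
    exclusions_frame,
    read_ld,
    select_instruments,
)
from .sensitivity import LeaveOneOutTable, leave_one_out
from .summary_io import HarmonizedVariant, harmonize_tables, read_summary_stats

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, message: str, exclusions: Sequence[ExclusionRecord] = ()):
        super().__init__(message)
        self.exclusions = list(exclusions)


@dataclass
class AnalysisReport:
    provenance: dict
    harmonized: list[HarmonizedVariant]
    instruments: list[HarmonizedVariant]
    exclusions: list[ExclusionRecord]
    wald: list[WaldEstimate]
    pooled: dict[str, PooledEstimate]
    heterogeneity: Optional[HeterogeneityResult]
    egger: Optional[EggerResult]
    egger_skipped_reason: Optional[str] = None
    loo: Optional[LeaveOneOutTable] = None
    primary_method: str = "ivw_penalized_robust"

    def variant_table(self) -> pd.DataFrame:
        """Per-variant forest-plot content for the primary method."""
        primary = self.pooled[self.primary_method]
        qc = (dict(zip(self.heterogeneity.variant_ids,
                       self.heterogeneity.q_contributions))
              if self.heterogeneity else {})
        rows = []
        for i, e in enumerate(self.wald):
            rows.append({
                "variant_id": e.variant_id,
                "ratio": e.beta_xy,
                "se": e.se_xy,
                "weight": e.weight,
                "penalty_factor": float(primary.penalty_factors[i]),
                "robust_weight": float(primary.robust_weights[i]),
                "q_j": qc.get(e.variant_id, float("nan")),
            })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_harmonized": len(self.harmonized),
            "n_instruments": len(self.instruments),
            "instrument_ids": [v.variant_id for v in self.instruments],
            "exclusions": [
                {"variant_id": r.variant_id, "reason": r.reason.value, "detail": r.detail}
                for r in self.exclusions
            ],
            "variants": self.variant_table().to_dict(orient="records"),
            "pooled": {m: p.to_dict() for m, p in self.pooled.items()},
            "heterogeneity": self.heterogeneity.to_dict() if self.heterogeneity else None,
            "egger": self.egger.to_dict() if self.egger else None,
            "egger_skipped_reason": self.egger_skipped_reason,
            "leave_one_out": (
                self.loo.to_dataframe().to_dict(orient="records") if self.loo else None
            ),
        }


def _stage(name: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info("stage=%s in=%d out=%d wall=%.3fs", name, n_in, n_out, time.perf_counter() - t0)


def run_pipeline(
    exposure_path: str | Path,
    outcome_path: str | Path,
    ld_path: Optional[str | Path] = None,
    *,
    exposure_dialect: Optional[dict] = None,
    outcome_dialect: Optional[dict] = None,
    p_exposure_max: float = 5e-8,
    p_outcome_min: float = 5e-2,
    r2_max: float = 0.2,
    methods: Sequence[str] = ("ivw_penalized_robust",),
    penalty_mult: float = 20.0,
    palindrome_policy: str = "keep",
    se_method: str = "delta",
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
    formats: Sequence[str] = ("tsv", "json"),
) -> AnalysisReport:
    """Run the full two-sample MR analysis and optionally write the report."""
    if not methods:
        raise ValueError("at least one pooling method must be requested")
    config = {
        "exposure": str(exposure_path),
        "outcome": str(outcome_path),
        "ld": str(ld_path) if ld_path else None,
        "p_exposure_max": p_exposure_max,
        "p_outcome_min": p_outcome_min,
        "r2_max": r2_max,
        "methods": list(methods),
        "penalty_mult": penalty_mult,
        "palindrome_policy": palindrome_policy,
        "se_method": se_method,
        "seed": seed,
    }
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]

    t0 = time.perf_counter()
    exposure = read_summary_stats(exposure_path, exposure_dialect)
    outcome = read_summary_stats(outcome_path, outcome_dialect)
    _stage("read", -1, len(exposure) + len(outcome), t0)

    t0 = time.perf_counter()
    harmonized, dropped = harmonize_tables(exposure, outcome, palindrome_policy)
    _stage("harmonize", len(exposure), len(harmonized), t0)
    exclusions = [
        ExclusionRecord(vid, ExclusionReason.unharmonizable, why)
        for vid, why in dropped
    ]

    t0 = time.perf_counter()
    ld: Optional[LDMatrix] = read_ld(ld_path) if ld_path else None
    kept, sel_log = select_instruments(
        harmonized, p_exposure_max, p_outcome_min, ld, r2_max)
    exclusions.extend(sel_log)
    _stage("select_instruments", len(harmonized), len(kept), t0)
    if not kept:
        raise PipelineError(
            "no instruments survived selection; see exclusion log", exclusions)

    t0 = time.perf_counter()
    wald = wald_ratios(kept, se_method)
    pooled = {m: pool(wald, m, penalty_mult) for m in methods}
    _stage("estimate", len(kept), len(pooled), t0)

    heterogeneity = cochran_q(wald) if len(wald) >= 2 else None

    egger = None
    egger_skipped = None
    if len(kept) >= 3:
        primary = methods[0]
        egger = egger_regression(
            kept,
            penalized="penalized" in primary,
            robust="robust" in primary,
            penalty_mult=penalty_mult,
            se_method=se_method,
        )
    else:
        egger_skipped = f"MR-Egger requires >= 3 instruments, have {len(kept)}"
        logger.info(egger_skipped)

    loo = (
        leave_one_out(kept, methods[0], penalty_mult, se_method)
        if len(kept) >= 2 else None
    )

    report = AnalysisReport(
        provenance={
            "package": f"summarymr {__version__}",
            "config": config,
            "config_hash": config_hash,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        harmonized=harmonized,
        instruments=kept,
        exclusions=exclusions,
        wald=wald,
        pooled=pooled,
        heterogeneity=heterogeneity,
        egger=egger,
        egger_skipped_reason=egger_skipped,
        loo=loo,
        primary_method=methods[0],
    )
    if out_dir is not None:
        write_report(report, out_dir, formats)
    return report


def write_report(
    report: AnalysisReport, out_dir: str | Path, formats: Sequence[str] = ("tsv", "json")
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "json" in formats:
        (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1))
    if "tsv" in formats:
        exclusions_frame(report.exclusions).to_csv(
            out / "exclusions.tsv", sep="\t", index=False)
        report.variant_table().to_csv(out / "variants.tsv", sep="\t", index=False)
        pd.DataFrame([p.to_dict() for p in report.pooled.values()]).to_csv(
            out / "estimates.tsv", sep="\t", index=False)
        if report.egger is not None:
            pd.DataFrame([report.egger.to_dict()]).to_csv(
                out / "egger.tsv", sep="\t", index=False)
        if report.loo is not None:
            report.loo.to_dataframe().to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
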