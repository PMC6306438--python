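"""Instrument selection: significance filters and LD pruning with an audit trail.

Candidate instruments pass three filters in order: (1) genome-wide
significance on the exposure (default p < 5e-8), (2) absence of association
with the outcome (default: removed when p_outcome < 0.05), and (3) LD pruning
against a user-supplied r-squared matrix.  Every input variant lands either in
the kept set or in the exclusion log, never both.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .summary_io import HarmonizedVariant

logger = logging.getLogger(__name__)


class ExclusionReason(str, enum.Enum):
    exposure_not_significant = "exposure_not_significant"
    outcome_associated = "outcome_associated"
    ld_pruned = "ld_pruned"
    unharmonizable = "unharmonizable"


@dataclass(frozen=True)
class ExclusionRecord:
    variant_id: str
    reason: ExclusionReason
    detail: str


@dataclass(frozen=True)
class LDMatrix:
    """Symmetric matrix of squared allelic correlations with unit diagonal."""

    ids: tuple[str, ...]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        n = len(self.ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 shape {r2.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate variant ids in LD matrix")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be exactly 1")
        if np.any(r2 < 0) or np.any(r2 > 1):
            raise ValueError("r2 entries must lie in [0, 1]")

    def covers(self, ids: Sequence[str]) -> bool:
        return set(ids) <= set(self.ids)

    def value(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "LDMatrix":
        return cls(ids=tuple(ids), r2=np.eye(len(ids)))

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "LDMatrix":
        """Build from long-format columns ``id_a, id_b, r2`` (symmetrized)."""
        cols = {c.lower(): c for c in frame.columns}
        for need in ("id_a", "id_b", "r2"):
            if need not in cols:
                raise ValueError(f"long LD table missing column {need!r}")
        ids: list[str] = []
        for col in ("id_a", "id_b"):
            for v in frame[cols[col]].astype(str):
                if v not in ids:
                    ids.append(v)
        n = len(ids)
        idx = {v: i for i, v in enumerate(ids)}
        r2 = np.eye(n)
        for _, row in frame.iterrows():
            a, b = idx[str(row[cols["id_a"]])], idx[str(row[cols["id_b"]])]
            val = float(row[cols["r2"]])
            r2[a, b] = r2[b, a] = val
        np.fill_diagonal(r2, 1.0)
        return cls(ids=tuple(ids), r2=r2)

    @classmethod
    def from_square_frame(cls, frame: pd.DataFrame) -> "LDMatrix":
        """Build from a square TSV whose first column holds variant ids."""
        ids = tuple(str(v) for v in frame.iloc[:, 0])
        r2 = frame.iloc[:, 1:].to_numpy(dtype=float)
        return cls(ids=ids, r2=r2)


def read_ld(path: str | Path) -> LDMatrix:
    """Read an LD table, auto-detecting long (id_a/id_b/r2) vs square layout."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower() for c in frame.columns}
    if {"id_a", "id_b", "r2"} <= lower:
        return LDMatrix.from_long_frame(frame)
    return LDMatrix.from_square_frame(frame)


def ld_prune(
    candidates: Sequence[HarmonizedVariant],
    ld: LDMatrix,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy LD pruning: keep the most significant representative per LD block.

    Candidates are visited in ascending exposure p-value (ties broken
    lexicographically by variant id); each is accepted iff its r-squared with
    every already-accepted candidate is below ``r2_max``.  Returns kept ids.
    """
    ids = [v.variant_id for v in candidates]
    if not ld.covers(ids):
        missing = sorted(set(ids) - set(ld.ids))
        raise ValueError(f"LD matrix missing candidate id(s): {missing}")
    order = sorted(candidates, key=lambda v: (v.p_exposure, v.variant_id))
    kept: list[str] = []
    for cand in order:
        if all(ld.value(cand.variant_id, k) < r2_max for k in kept):
            kept.append(cand.variant_id)
    return kept


def select_instruments(
    variants: Sequence[HarmonizedVariant],
    p_exposure_max: float = 5e-8,
    p_outcome_min: float = 5e-2,
    ld: Optional[LDMatrix] = None,
    r2_max: float = 0.2,
) -> tuple[list[HarmonizedVariant], list[ExclusionRecord]]:
    """Apply the three instrument filters, logging every removal.

    Kept variants satisfy ``p_exposure < p_exposure_max`` and
    ``p_outcome >= p_outcome_min``; survivors are then LD-pruned when an LD
    matrix is supplied (otherwise pruning is skipped with a logged notice).
    """
    for name, thr in (("p_exposure_max", p_exposure_max), ("p_outcome_min", p_outcome_min)):
        if not (0 < thr < 1):
            raise ValueError(f"{name} must lie in (0, 1), got {thr}")
    log: list[ExclusionRecord] = []
    stage1: list[HarmonizedVariant] = []
    for v in variants:
        if v.p_exposure < p_exposure_max:
            stage1.append(v)
        else:
            log.append(ExclusionRecord(
                v.variant_id, ExclusionReason.exposure_not_significant,
                f"p_exposure={v.p_exposure:.6g}"))
    stage2: list[HarmonizedVariant] = []
    for v in stage1:
        if v.p_outcome >= p_outcome_min:
            stage2.append(v)
        else:
            log.append(ExclusionRecord(
                v.variant_id, ExclusionReason.outcome_associated,
                f"p_outcome={v.p_outcome:.6g}"))
    if ld is None:
        logger.info("no LD matrix supplied; pruning skipped")
        kept = list(stage2)
    else:
        kept_ids = set(ld_prune(stage2, ld, r2_max))
        kept = [v for v in stage2 if v.variant_id in kept_ids]
        for v in stage2:
            if v.variant_id not in kept_ids:
                worst = max(
                    ld.value(v.variant_id, k) for k in kept_ids
                ) if kept_ids else float("nan")
                log.append(ExclusionRecord(
                    v.variant_id, ExclusionReason.ld_pruned,
                    f"max_r2_with_kept={worst:.6g}"))
    logger.info(
        "instrument selection: %d in, %d kept, %d excluded",
        len(variants), len(kept), len(log))
    return kept, log


def exclusions_frame(log: Sequence[ExclusionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variant_id, r.reason.value, r.detail) for r in log],
        columns=["variant_id", "reason", "detail"],
    )
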