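"""Packaged instrument tables for the CRP -> type 2 / type 1 diabetes analyses.

Two fixture TSVs ship with the package, transcribed from the published
per-variant association tables.  Each file carries the variant, its alleles
(already aligned to a single shared effect allele for both traits), the
effect-allele frequency, and beta/SE/p for the CRP association and for the
disease association:

* ``crp_t2dm.tsv`` — five genome-wide-significant CRP variants with their
  T2DM associations (DIAGRAM-scale meta-analysis, log-OR betas).
* ``crp_t1dm.tsv`` — the three of those variants available with T1DM
  associations.

Both traits share the allele columns, so the per-trait views are read through
the dialect mechanism of :mod:`summarymr.summary_io`.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .summary_io import (
    HarmonizedVariant,
    VariantAssociation,
    harmonize_tables,
    read_summary_stats,
    write_summary_stats,
)

_ALLELE_COLS = {
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
}


def fixture_path(name: str) -> Path:
    path = resources.files("summarymr") / "data" / name
    return Path(str(path))


def crp_t2dm_path() -> Path:
    return fixture_path("crp_t2dm.tsv")


def crp_t1dm_path() -> Path:
    return fixture_path("crp_t1dm.tsv")


def load_crp_t2dm() -> pd.DataFrame:
    """The raw five-variant CRP/T2DM table."""
    return pd.read_csv(crp_t2dm_path(), sep="\t")


def load_crp_t1dm() -> pd.DataFrame:
    """The raw three-variant CRP/T1DM table."""
    return pd.read_csv(crp_t1dm_path(), sep="\t")


def _trait_dialect(trait: str) -> dict[str, str]:
    return {"beta": f"beta_{trait}", "se": f"se_{trait}", "pvalue": f"p_{trait}",
            **_ALLELE_COLS}


def crp_t2dm_associations() -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """(exposure, outcome) per-trait views of the CRP/T2DM fixture."""
    path = crp_t2dm_path()
    exposure = read_summary_stats(path, dialect=_trait_dialect("crp"))
    outcome = read_summary_stats(path, dialect=_trait_dialect("t2dm"))
    return exposure, outcome


def crp_t1dm_associations() -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """(exposure, outcome) per-trait views of the CRP/T1DM fixture."""
    path = crp_t1dm_path()
    exposure = read_summary_stats(path, dialect=_trait_dialect("crp"))
    outcome = read_summary_stats(path, dialect=_trait_dialect("t1dm"))
    return exposure, outcome


def crp_t2dm_harmonized() -> list[HarmonizedVariant]:
    kept, _ = harmonize_tables(*crp_t2dm_associations())
    return kept


def crp_t1dm_harmonized() -> list[HarmonizedVariant]:
    kept, _ = harmonize_tables(*crp_t1dm_associations())
    return kept


def write_trait_tables(
    dataset: str, exposure_path: str | Path, outcome_path: str | Path
) -> None:
    """Emit per-trait TSVs in the default dialect for ``"t2dm"`` or ``"t1dm"``."""
    if dataset == "t2dm":
        exposure, outcome = crp_t2dm_associations()
    elif dataset == "t1dm":
        exposure, outcome = crp_t1dm_associations()
    else:
        raise ValueError("dataset must be 't2dm' or 't1dm'")
    write_summary_stats(exposure, exposure_path)
    write_summary_stats(outcome, outcome_path)
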