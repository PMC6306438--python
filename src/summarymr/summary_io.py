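"""Reading, validation, and harmonization of GWAS summary statistics.

Summary-statistic tables are tab-separated with a header row, one variant per
line, and ``.`` or the empty string for missing values.  Column names are
resolved through a *dialect*: a mapping from the canonical field names used
throughout this package to the column headers actually present in the file.
The default dialect expects ``snp, chr, bp, effect_allele, other_allele, eaf,
beta, se, pvalue``.

Harmonization aligns the outcome association to the exposure's effect allele:
if the outcome reports the same allele pair in swapped order, its beta is
negated and its effect-allele frequency complemented.  Palindromic variants
(A/T or C/G) cannot be strand-resolved from alleles alone and are handled
according to an explicit policy.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical field -> default column header
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "snp",
    "chrom": "chr",
    "pos": "bp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
}

_MISSING = {"", ".", "NA", "nan"}


class SummaryStatsError(ValueError):
    """A summary-statistic file or record violates the input contract."""


class HarmonizationError(ValueError):
    """Exposure and outcome records cannot be placed on a shared effect allele."""


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: a log odds ratio
    for binary traits, trait units for quantitative traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        problems = self.violations()
        if problems:
            raise ValueError("; ".join(problems))

    def violations(self) -> list[str]:
        out = []
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} is not one of A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"other_allele {self.other_allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not math.isfinite(self.beta):
            out.append(f"beta {self.beta!r} is not finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            out.append(f"se {self.se!r} must be finite and > 0")
        if not (0 < self.pvalue <= 1):
            out.append(f"pvalue {self.pvalue!r} outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            out.append(f"eaf {self.eaf!r} outside (0, 1)")
        return out

    @property
    def is_palindromic(self) -> bool:
        return _is_palindromic(self.effect_allele, self.other_allele)


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome associations for one variant on a shared effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    p_exposure: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float
    flipped: bool
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.se_exposure > 0:
            raise ValueError(f"{self.variant_id}: se_exposure must be > 0")
        if not self.se_outcome > 0:
            raise ValueError(f"{self.variant_id}: se_outcome must be > 0")


def resolve_dialect(dialect: Optional[Mapping[str, str]]) -> dict[str, str]:
    """Merge a partial user dialect over the defaults, rejecting unknown fields."""
    d = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise SummaryStatsError(f"unknown dialect fields: {sorted(unknown)}")
        d.update(dialect)
    return d


def _parse_float(raw: str, field: str, row: int) -> Optional[float]:
    if raw in _MISSING:
        return None
    try:
        return float(raw)
    except ValueError:
        raise SummaryStatsError(f"row {row}: unparseable {field} value {raw!r}") from None


def associations_from_frame(
    frame: pd.DataFrame,
    dialect: Optional[Mapping[str, str]] = None,
    on_invalid: str = "drop",
    source: str = "<frame>",
) -> list[VariantAssociation]:
    """Build :class:`VariantAssociation` records from a string-typed DataFrame.

    Rows violating record invariants are rejected with a row-numbered warning
    (``on_invalid="drop"``, default) or raise (``on_invalid="raise"``).  Row
    numbers count the header as line 1, matching the file layout.
    """
    if on_invalid not in {"drop", "raise"}:
        raise ValueError("on_invalid must be 'drop' or 'raise'")
    d = resolve_dialect(dialect)
    missing = [col for col in d.values() if col not in frame.columns]
    if missing:
        raise SummaryStatsError(f"{source}: missing required column(s) {missing}")

    records: list[VariantAssociation] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        row_no = i + 2  # 1-based, header is line 1
        get = lambda field: str(row[d[field]])  # noqa: E731
        vid = get("variant_id")
        try:
            pos_raw = get("pos")
            try:
                pos = int(pos_raw)
            except ValueError:
                raise SummaryStatsError(
                    f"row {row_no}: unparseable bp position {pos_raw!r}"
                ) from None
            rec = VariantAssociation(
                variant_id=vid,
                chrom=get("chrom"),
                pos=pos,
                effect_allele=get("effect_allele").upper(),
                other_allele=get("other_allele").upper(),
                eaf=_parse_float(get("eaf"), "eaf", row_no),
                beta=_require(_parse_float(get("beta"), "beta", row_no), "beta", row_no),
                se=_require(_parse_float(get("se"), "se", row_no), "se", row_no),
                pvalue=_require(_parse_float(get("pvalue"), "pvalue", row_no), "pvalue", row_no),
            )
        except (ValueError, SummaryStatsError) as exc:
            msg = f"{source} row {row_no} ({vid}): {exc}"
            if on_invalid == "raise" or isinstance(exc, SummaryStatsError):
                raise SummaryStatsError(msg) from None
            logger.warning("rejected %s", msg)
            continue
        records.append(rec)
    return records


def _require(value: Optional[float], field: str, row: int) -> float:
    if value is None:
        raise SummaryStatsError(f"row {row}: required field {field} is missing")
    return value


def read_summary_stats(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    on_invalid: str = "drop",
) -> list[VariantAssociation]:
    """Read a TSV of per-variant associations, preserving row order.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Partial mapping of canonical field names to this file's column headers.
    on_invalid
        ``"drop"`` rejects rows that fail record invariants with a logged,
        row-numbered diagnostic; ``"raise"`` turns the first such row into
        :class:`SummaryStatsError`.  Structural problems (missing columns,
        unparseable numbers) always raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return associations_from_frame(frame, dialect, on_invalid=on_invalid, source=str(path))


def write_summary_stats(
    records: Sequence[VariantAssociation],
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
) -> None:
    """Write records as TSV in the given dialect; round-trips all numerics exactly."""
    d = resolve_dialect(dialect)
    fields = list(DEFAULT_DIALECT)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(d[f] for f in fields) + "\n")
        for rec in records:
            vals = []
            for f in fields:
                v = getattr(rec, f)
                if v is None:
                    vals.append(".")
                elif isinstance(v, float):
                    vals.append(repr(v))  # shortest exact decimal round-trip
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_policy: str = "keep",
) -> Optional[HarmonizedVariant]:
    """Align an outcome association to the exposure's effect allele.

    Returns the harmonized record, or ``None`` when a palindromic variant is
    dropped under ``palindrome_policy="drop"``.

    Raises
    ------
    HarmonizationError
        On variant-id mismatch, incompatible allele sets, or a palindromic
        pair under ``palindrome_policy="error"``.
    """
    if palindrome_policy not in {"keep", "drop", "error"}:
        raise ValueError("palindrome_policy must be keep, drop, or error")
    if exposure.variant_id != outcome.variant_id:
        raise HarmonizationError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    vid = exposure.variant_id
    if exposure.is_palindromic or outcome.is_palindromic:
        if palindrome_policy == "error":
            raise HarmonizationError(f"{vid}: palindromic allele pair")
        if palindrome_policy == "drop":
            logger.info("%s: palindromic allele pair dropped", vid)
            return None
        logger.warning(
            "%s: palindromic allele pair kept; strand cannot be verified from alleles",
            vid,
        )

    exp_pair = (exposure.effect_allele, exposure.other_allele)
    out_pair = (outcome.effect_allele, outcome.other_allele)
    if out_pair == exp_pair:
        flipped = False
        beta_out, eaf_out = outcome.beta, outcome.eaf
    elif out_pair == exp_pair[::-1]:
        flipped = True
        beta_out = -outcome.beta
        eaf_out = None if outcome.eaf is None else 1.0 - outcome.eaf
    else:
        raise HarmonizationError(
            f"{vid}: allele sets incompatible ({exp_pair} vs {out_pair})"
        )
    return HarmonizedVariant(
        variant_id=vid,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        p_exposure=exposure.pvalue,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        p_outcome=outcome.pvalue,
        flipped=flipped,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
    )


def harmonize_tables(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "keep",
) -> tuple[list[HarmonizedVariant], list[tuple[str, str]]]:
    """Harmonize two per-trait tables on their shared variants.

    Variants present in only one table, palindromic drops, and incompatible
    allele pairs are excluded (not errors) and reported as
    ``(variant_id, reason)`` tuples in input (exposure) order.
    """
    out_by_id: dict[str, VariantAssociation] = {}
    for rec in outcome:
        out_by_id.setdefault(rec.variant_id, rec)
    kept: list[HarmonizedVariant] = []
    dropped: list[tuple[str, str]] = []
    exp_ids = set()
    for exp in exposure:
        exp_ids.add(exp.variant_id)
        out = out_by_id.get(exp.variant_id)
        if out is None:
            logger.info("%s: absent from outcome table, excluded", exp.variant_id)
            dropped.append((exp.variant_id, "absent from outcome table"))
            continue
        try:
            h = harmonize(exp, out, palindrome_policy=palindrome_policy)
        except HarmonizationError as exc:
            logger.warning("%s excluded: %s", exp.variant_id, exc)
            dropped.append((exp.variant_id, str(exc)))
            continue
        if h is None:
            dropped.append((exp.variant_id, "palindromic allele pair dropped"))
            continue
        kept.append(h)
    for rec in outcome:
        if rec.variant_id not in exp_ids:
            logger.info("%s: absent from exposure table, excluded", rec.variant_id)
            dropped.append((rec.variant_id, "absent from exposure table"))
    return kept, dropped
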