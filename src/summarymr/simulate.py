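"""Synthetic two-sample GWAS summary statistics with known causal effect.

The generator embodies the instrumental-variable causal diagram: each variant
j has a true per-allele effect b_j on the exposure and reaches the outcome
only through the exposure (times the causal effect theta) plus an optional
direct, pleiotropic effect alpha_j drawn independently of b_j — so the InSIDE
condition (instrument strength independent of direct effect) holds by
construction.  Observed summary statistics add independent Gaussian
estimation noise to each sample:

    beta_x_j = b_j + N(0, se_exposure^2)
    beta_y_j = theta * b_j + alpha_j + N(0, se_outcome^2)

Defaults mirror the scale of CRP-lowering instruments: per-allele exposure
effects around 0.15 standard-deviation units (coded to the exposure-raising
allele), exposure SEs near 0.015 and outcome (log-OR) SEs near 0.012, and a
causal effect of 0.11 log-OR per exposure unit.  Betas are simulated directly
on the summary-statistic scale; no individual-level genotypes exist.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import egger_regression, pool, wald_ratios
from .instruments import select_instruments
from .summary_io import DEFAULT_DIALECT, associations_from_frame, harmonize_tables

#: effect/other allele pairs that are never palindromic
_ALLELE_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("T", "G"))

#: smallest true exposure effect magnitude; keeps every Wald ratio defined
MIN_EXPOSURE_BETA = 1e-3

_TINY_P = 5e-324  # two-sided normal p-values are clipped into (0, 1]


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario for one synthetic two-sample GWAS."""

    n_variants: int = 50
    theta: float = 0.11
    exposure_beta_mean: float = 0.15
    exposure_beta_sd: float = 0.04
    se_exposure: Union[float, Sequence[float]] = 0.015
    se_outcome: Union[float, Sequence[float]] = 0.012
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.exposure_beta_sd < 0:
            raise ValueError("exposure_beta_sd must be >= 0")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        for name in ("se_exposure", "se_outcome"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v <= 0):
                raise ValueError(f"{name} must be > 0")
            if v.size not in (1, self.n_variants):
                raise ValueError(f"{name} must be scalar or length n_variants")

    def se_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        sx = np.broadcast_to(
            np.atleast_1d(np.asarray(self.se_exposure, float)), (self.n_variants,))
        sy = np.broadcast_to(
            np.atleast_1d(np.asarray(self.se_outcome, float)), (self.n_variants,))
        return np.array(sx), np.array(sy)


def _two_sided_p(beta: float, se: float) -> float:
    return max(float(2.0 * stats.norm.sf(abs(beta / se))), _TINY_P)


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one synthetic exposure/outcome summary-statistic pair.

    Returns two DataFrames in the default summary-statistic dialect plus a
    truth record holding theta, the pleiotropy mean, and every per-variant
    b_j and alpha_j.  A single seeded stream is consumed variant by variant in
    a fixed order, so extending ``n_variants`` preserves earlier variants.
    """
    rng = np.random.default_rng(config.seed)
    sx, sy = config.se_arrays()
    exp_rows, out_rows = [], []
    b_true, alpha_true = [], []
    for j in range(config.n_variants):
        b = rng.normal(config.exposure_beta_mean, config.exposure_beta_sd)
        while abs(b) <= MIN_EXPOSURE_BETA:
            b = rng.normal(config.exposure_beta_mean, config.exposure_beta_sd)
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd)
        eaf = rng.uniform(0.05, 0.95)
        beta_x = b + rng.normal(0.0, sx[j])
        beta_y = config.theta * b + alpha + rng.normal(0.0, sy[j])
        ea, oa = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        vid = f"rs{10000000 + j}"
        chrom = str(j % 22 + 1)
        pos = 1_000_000 + 1000 * j
        common = (vid, chrom, pos, ea, oa, round(eaf, 4))
        exp_rows.append((*common, beta_x, sx[j], _two_sided_p(beta_x, sx[j])))
        out_rows.append((*common, beta_y, sy[j], _two_sided_p(beta_y, sy[j])))
        b_true.append(b)
        alpha_true.append(alpha)
    cols = list(DEFAULT_DIALECT.values())
    exposure = pd.DataFrame(exp_rows, columns=cols)
    outcome = pd.DataFrame(out_rows, columns=cols)
    truth = {
        "theta": config.theta,
        "pleiotropy_mean": config.pleiotropy_mean,
        "pleiotropy_sd": config.pleiotropy_sd,
        "seed": config.seed,
        "b": b_true,
        "alpha": alpha_true,
    }
    return exposure, outcome, truth


def simulate_to_files(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write exposure.tsv, outcome.tsv, and truth.json under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = simulate_summary_stats(config)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
        "truth": out_dir / "truth.json",
    }
    exposure.to_csv(paths["exposure"], sep="\t", index=False)
    outcome.to_csv(paths["outcome"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


def _harmonized_from_sim(exposure: pd.DataFrame, outcome: pd.DataFrame):
    exp = associations_from_frame(exposure.astype(str))
    out = associations_from_frame(outcome.astype(str))
    kept, _ = harmonize_tables(exp, out)
    return kept


def _rep_metrics(variants, estimator: str, truth_theta: float, penalty_mult: float):
    wald = wald_ratios(variants)
    if estimator == "egger":
        res = egger_regression(variants, penalized=False, robust=False)
        tq = stats.t.ppf(0.975, res.n_variants - 2)
        covered = abs(res.slope - truth_theta) <= tq * res.slope_se
        return res.slope, covered, res.slope_p < 0.05, res.intercept
    est = pool(wald, method=estimator, penalty_mult=penalty_mult)
    covered = est.ci_low <= np.exp(truth_theta) <= est.ci_high
    return est.beta, covered, est.pvalue < 0.05, np.nan


def recovery_study(
    scenarios: Sequence[Union[SimulationConfig, Mapping]],
    n_reps: int,
    estimators: Sequence[str] = ("ivw",),
    seed: int = 0,
    p_exposure_max: float = 0.999999,
    p_outcome_min: float = 1e-300,
) -> pd.DataFrame:
    """Parameter-recovery metrics over a scenario grid.

    For every scenario and replicate the full pipeline runs — simulate,
    harmonize, select instruments with permissive thresholds, estimate — and
    per-estimator bias, empirical SE, RMSE, 95% CI coverage, and rejection
    rate are aggregated.  Deterministic given ``seed``: replicate seeds are
    spawned per scenario from a SeedSequence.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scen_children = np.random.SeedSequence(seed).spawn(len(scenarios))
    rows = []
    for s_idx, scen in enumerate(scenarios):
        cfg = scen if isinstance(scen, SimulationConfig) else SimulationConfig(**scen)
        rep_seeds = scen_children[s_idx].generate_state(n_reps) & 0x7FFFFFFF
        per_est: dict[str, dict[str, list]] = {
            e: {"est": [], "cover": [], "reject": [], "intercept": []}
            for e in estimators
        }
        for rep in range(n_reps):
            rep_cfg = dataclasses.replace(cfg, seed=int(rep_seeds[rep]))
            exposure, outcome, truth = simulate_summary_stats(rep_cfg)
            harmonized = _harmonized_from_sim(exposure, outcome)
            kept, _ = select_instruments(
                harmonized, p_exposure_max=p_exposure_max,
                p_outcome_min=p_outcome_min, ld=None)
            for e in estimators:
                val, cov, rej, icept = _rep_metrics(kept, e, truth["theta"], 20.0)
                per_est[e]["est"].append(val)
                per_est[e]["cover"].append(cov)
                per_est[e]["reject"].append(rej)
                per_est[e]["intercept"].append(icept)
        for e in estimators:
            est = np.asarray(per_est[e]["est"], dtype=float)
            icept = np.asarray(per_est[e]["intercept"], dtype=float)
            rows.append({
                "scenario": s_idx,
                "estimator": e,
                "n_variants": cfg.n_variants,
                "theta": cfg.theta,
                "pleiotropy_mean": cfg.pleiotropy_mean,
                "pleiotropy_sd": cfg.pleiotropy_sd,
                "n_reps": n_reps,
                "mean_estimate": float(np.mean(est)),
                "bias": float(np.mean(est) - cfg.theta),
                "empirical_se": float(np.std(est, ddof=1)) if n_reps > 1 else 0.0,
                "rmse": float(np.sqrt(np.mean((est - cfg.theta) ** 2))),
                "ci_coverage": float(np.mean(per_est[e]["cover"])),
                "rejection_rate": float(np.mean(per_est[e]["reject"])),
                "intercept_mean": float(np.nanmean(icept)) if e == "egger" else np.nan,
                "intercept_bias": (
                    float(np.nanmean(icept) - cfg.pleiotropy_mean)
                    if e == "egger" else np.nan),
            })
    return pd.DataFrame(rows)
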