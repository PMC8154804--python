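"""Coefficient-of-variation statistics and quantification-parameter tuning.

The reproducibility of the GABA+/tCr ratio is summarized by two metrics:

* CoV^intra — sd/mean of the ratio over the repeated (consecutive)
  measurements of one subject; mCoV^intra averages this over subjects.
* CoV^inter — sd/mean of the ratio across subjects within one measurement
  index; mCoV^inter is the mean of the per-index values and its error bar
  their sd.

The quantification parameters are tuned in two steps on a grid:
first the initial Gaussian damping beta_s is chosen by minimizing the
average (over two reference preprocessing routines) of the median
mCoV^intra over all n_s pairs; then, at the chosen beta_s, the
(n_s_diff, n_s_off) pair minimizing the median mCoV^intra over the
preprocessing variants is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import SpectralAxis
from .preprocess import VARIANTS, PipelineVariant, ProcessedPair, run_pipeline
from .quantify import (
    FitConfig,
    fit_spectrum,
    fwhm_naa,
    gaba_tcr_ratio,
    make_basis_set,
    snr_naa,
)
from .synthetic import GroundTruth, RegionTable, default_resonance_tables

__all__ = [
    "GridSpec",
    "OptimizationReport",
    "COHORT_COLUMNS",
    "cov_intra",
    "m_cov_intra",
    "cov_inter",
    "optimize_beta",
    "optimize_start_points",
    "decile_summary",
    "quantify_cohort",
    "compare_pipelines",
]

#: schema of the long-format cohort table
COHORT_COLUMNS = (
    "subject",
    "measurement",
    "variant",
    "ns_diff",
    "ns_off",
    "beta",
    "ratio",
    "crlb_gaba",
    "fwhm_hz",
    "snr",
)

DEFAULT_BETA_GRID = (200.0, 300.0, 450.0, 600.0, 900.0, 1200.0, 1500.0, 2000.0, 3000.0, 5000.0)
DEFAULT_NS_GRID = (1, 2, 3, 4, 5, 6, 8, 10, 15, 20, 30, 40, 50)

#: reference routines used for the beta_s optimization step
BETA_STEP_VARIANTS = ("SR", "ECC+SR+DAS")
#: the six studied preprocessing routines
SIX_VARIANTS = ("SR", "ECC+SR", "SR+DAS", "ECC+SR+DAS", "SR+DO", "ECC+SR+DO")


@dataclass(frozen=True)
class GridSpec:
    """Quantification-parameter grid: beta_s values and n_s values.

    The n_s grid is applied independently to the difference and edit-off
    fits, so ``len(ns_values)**2`` (n_s_diff, n_s_off) pairs are tested
    (13 x 13 = 169 at the default grid).
    """

    beta_values: Tuple[float, ...] = DEFAULT_BETA_GRID
    ns_values: Tuple[int, ...] = DEFAULT_NS_GRID

    def __post_init__(self) -> None:
        for name in ("beta_values", "ns_values"):
            v = getattr(self, name)
            if len(set(v)) != len(v) or list(v) != sorted(v):
                raise ValueError(f"{name} must be sorted and unique")
        if not self.beta_values or not self.ns_values:
            raise ValueError("grids must be non-empty")

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        return [(d, o) for d in self.ns_values for o in self.ns_values]


@dataclass
class OptimizationReport:
    """Outcome of the two-step parameter optimization and variant comparison."""

    chosen_beta: float
    chosen_ns: Tuple[int, int]
    mcov_intra: Dict[str, float]  # per variant, at chosen parameters
    mcov_inter: Dict[str, Tuple[float, float]]  # per variant, (mean, error)
    deciles: Dict[str, float]  # per variant, first decile of mCoV^intra
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"chosen beta_s: {self.chosen_beta:g}",
            f"chosen (n_s diff, n_s off): {self.chosen_ns}",
            "variant            mCoV_intra  mCoV_inter (err)   1st decile",
        ]
        for v in self.mcov_intra:
            inter, err = self.mcov_inter.get(v, (float("nan"), float("nan")))
            dec = self.deciles.get(v, float("nan"))
            lines.append(
                f"{v:<18s} {self.mcov_intra[v]:10.4f}  {inter:.4f} ({err:.4f})   {dec:.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CoV statistics
# ---------------------------------------------------------------------------

def cov_intra(ratios: Sequence[float]) -> float:
    """sd/mean of one subject's repeated-measurement ratios (ddof=1)."""
    vals = np.asarray(ratios, dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 repeated measurements")
    if not np.all(np.isfinite(vals)):
        raise ValueError("ratios must be finite")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean ratio must be positive")
    return float(vals.std(ddof=1) / mean)


def _select(table: pd.DataFrame, key: Dict[str, object]) -> pd.DataFrame:
    sub = table
    for col, val in key.items():
        sub = sub[sub[col] == val]
    return sub


def _check_complete(sub: pd.DataFrame) -> None:
    counts = sub.groupby("subject")["measurement"].nunique()
    n_meas = sub["measurement"].nunique()
    if len(sub) == 0 or (counts != n_meas).any():
        raise ValueError("cohort table has missing (subject, measurement) cells")


def m_cov_intra(table: pd.DataFrame, key: Dict[str, object]) -> float:
    """Mean over subjects of the intra-session CoV at one grid key.

    Subjects whose fits failed at this grid point (NaN ratios leaving fewer
    than two finite measurements) are excluded pairwise with a warning;
    structurally missing rows raise.
    """
    sub = _select(table, key)
    _check_complete(sub)
    covs = []
    excluded = []
    for subject, grp in sub.groupby("subject"):
        vals = grp["ratio"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2 and vals.mean() > 0:
            covs.append(cov_intra(vals))
        else:
            excluded.append(subject)
    if excluded:
        warnings.warn(
            f"excluding subjects with failed fits at {key}: {excluded}", stacklevel=2
        )
    if not covs:
        warnings.warn(f"no subject has >= 2 successful fits at {key}", stacklevel=2)
        return float("nan")
    return float(np.mean(covs))


def cov_inter(table: pd.DataFrame, key: Dict[str, object]) -> Tuple[float, float]:
    """Inter-subject CoV: (mean, sd) over the per-measurement-index CoVs."""
    sub = _select(table, key)
    _check_complete(sub)
    per_meas = []
    for _, grp in sub.groupby("measurement"):
        vals = grp["ratio"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warnings.warn(
                f"fewer than two successful fits in a measurement index at {key}",
                stacklevel=2,
            )
            return float("nan"), float("nan")
        mean = vals.mean()
        if mean <= 0:
            raise ValueError("mean ratio must be positive")
        per_meas.append(vals.std(ddof=1) / mean)
    per_meas = np.asarray(per_meas)
    err = float(per_meas.std(ddof=1)) if len(per_meas) > 1 else 0.0
    return float(per_meas.mean()), err


# ---------------------------------------------------------------------------
# two-step parameter optimization
# ---------------------------------------------------------------------------

def _median_mcov_per_beta(
    table: pd.DataFrame, variant: str, grid: GridSpec, beta: float
) -> float:
    vals = [
        m_cov_intra(
            table,
            {"variant": variant, "beta": beta, "ns_diff": d, "ns_off": o},
        )
        for d, o in grid.pairs
    ]
    return float(np.nanmedian(vals))


def optimize_beta(
    table: pd.DataFrame,
    grid: GridSpec,
    variants: Sequence[str] = BETA_STEP_VARIANTS,
) -> float:
    """Step 1: choose beta_s.

    For each beta and each reference routine, the median mCoV^intra over all
    n_s pairs is computed; the beta minimizing the average of the routine
    medians is returned (ties break toward the smaller beta).
    """
    scores = []
    for beta in grid.beta_values:
        med = [_median_mcov_per_beta(table, v, grid, beta) for v in variants]
        scores.append(float(np.mean(med)))
    scores = np.asarray(scores)
    if np.all(np.isnan(scores)):
        raise ValueError("no grid point produced a usable mCoV")
    scores = np.where(np.isnan(scores), np.inf, scores)
    return float(grid.beta_values[int(np.argmin(scores))])


def optimize_start_points(
    table: pd.DataFrame,
    grid: GridSpec,
    variants: Sequence[str] = SIX_VARIANTS,
    beta: Optional[float] = None,
) -> Tuple[int, int]:
    """Step 2: choose the (n_s_diff, n_s_off) pair at the chosen beta_s.

    Per pair, the median mCoV^intra over the preprocessing variants is
    computed; the argmin pair is returned, ties breaking toward the smaller
    n_s_diff, then n_s_off.
    """
    best: Optional[Tuple[int, int]] = None
    best_score = np.inf
    for d, o in grid.pairs:  # grid.pairs is lexicographically sorted
        key = {"ns_diff": d, "ns_off": o}
        if beta is not None:
            key["beta"] = beta
        vals = [m_cov_intra(table, {**key, "variant": v}) for v in variants]
        score = float(np.nanmedian(vals)) if not np.all(np.isnan(vals)) else np.inf
        if score < best_score:
            best_score = score
            best = (d, o)
    if best is None or not np.isfinite(best_score):
        raise ValueError("no start-point pair produced a usable mCoV")
    return best


def decile_summary(values_per_variant: Dict[str, Sequence[float]]) -> Dict[str, float]:
    """First decile (10th percentile, linear interpolation) per variant.

    With lower-is-better mCoV the 10th percentile marks the boundary of the
    best tenth of grid points.
    """
    return {
        v: float(np.percentile(np.asarray(vals, dtype=float), 10.0, method="linear"))
        for v, vals in values_per_variant.items()
    }


# ---------------------------------------------------------------------------
# cohort quantification sweep
# ---------------------------------------------------------------------------

def quantify_cohort(
    pairs: Sequence[ProcessedPair],
    grid: GridSpec,
    table: Optional[RegionTable] = None,
    betas: Optional[Sequence[float]] = None,
    base_config: Optional[FitConfig] = None,
) -> pd.DataFrame:
    """Fit every processed measurement over the parameter grid.

    The edit-off fit depends only on (beta, n_s_off) and the difference fit
    only on (beta, n_s_diff), so each measurement needs 2 * len(ns_values)
    fits per beta rather than one per pair; rows for all pairs are assembled
    from the cached fits.
    """
    table = table or default_resonance_tables("hippocampus")
    base = base_config or FitConfig()
    betas = tuple(betas) if betas is not None else grid.beta_values
    rows: List[dict] = []
    for pair in pairs:
        axis = pair.off_fid.axis
        off_basis = make_basis_set(axis, "off", table)
        diff_basis = make_basis_set(axis, "diff", table)
        for beta in betas:
            off_fits = {}
            diff_fits = {}
            for ns in grid.ns_values:
                cfg = FitConfig(
                    start_point=ns,
                    init_gaussian=beta,
                    freq_bound_hz=base.freq_bound_hz,
                    max_iterations=base.max_iterations,
                    max_fit_samples=base.max_fit_samples,
                    noise_span_ppm=base.noise_span_ppm,
                )
                off_fits[ns] = fit_spectrum(pair.off_fid, off_basis, cfg)
                diff_fits[ns] = fit_spectrum(pair.diff_fid, diff_basis, cfg)
            for d, o in grid.pairs:
                off_fit, diff_fit = off_fits[o], diff_fits[d]
                try:
                    ratio = gaba_tcr_ratio(diff_fit, off_fit)
                except ValueError:
                    ratio = np.nan
                try:
                    fwhm = fwhm_naa(off_fit)[0]
                except ValueError:
                    fwhm = np.nan
                rows.append(
                    {
                        "subject": pair.subject_id,
                        "measurement": pair.measurement_index,
                        "variant": pair.variant.label,
                        "ns_diff": d,
                        "ns_off": o,
                        "beta": beta,
                        "ratio": ratio,
                        "crlb_gaba": diff_fit.crlb_percent.get("GABA", np.nan),
                        "fwhm_hz": fwhm,
                        "snr": snr_naa(off_fit, pair.off_fid),
                    }
                )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def compare_pipelines(
    cohort_sets: Sequence[Tuple[object, GroundTruth]],
    grid: Optional[GridSpec] = None,
    table: Optional[RegionTable] = None,
    variants: Sequence[str] = ("plain",) + SIX_VARIANTS,
    base_config: Optional[FitConfig] = None,
) -> OptimizationReport:
    """Run the full variant comparison on a (coil-combined) cohort.

    ``cohort_sets`` holds (TransientSet, GroundTruth) tuples as produced by
    the simulator; multi-coil sets must be coil-combined upstream. Executes
    preprocessing per variant, sweeps the grid, runs both optimization steps
    and assembles the per-variant report.
    """
    from .preprocess import combine_coils, estimate_coil_weights

    grid = grid or GridSpec()
    table = table or default_resonance_tables("hippocampus")
    processed: List[ProcessedPair] = []
    for ts, _gt in cohort_sets:
        if ts.n_coils > 1:
            ts = combine_coils(ts, estimate_coil_weights(ts))
        for vname in variants:
            processed.append(run_pipeline(ts, VARIANTS[vname]))

    full = quantify_cohort(processed, grid, table, base_config=base_config)

    beta_variants = [v for v in BETA_STEP_VARIANTS if v in variants]
    if len(beta_variants) >= 1:
        step1 = full[full["variant"].isin(beta_variants)]
        chosen_beta = optimize_beta(step1, grid, beta_variants)
    else:
        chosen_beta = float(grid.beta_values[0])

    six = [v for v in SIX_VARIANTS if v in variants] or list(variants)
    at_beta = full[full["beta"] == chosen_beta]
    chosen_ns = optimize_start_points(at_beta, grid, six, beta=chosen_beta)

    mcov_intra: Dict[str, float] = {}
    mcov_inter: Dict[str, Tuple[float, float]] = {}
    deciles_values: Dict[str, List[float]] = {}
    for v in variants:
        key = {
            "variant": v,
            "beta": chosen_beta,
            "ns_diff": chosen_ns[0],
            "ns_off": chosen_ns[1],
        }
        mcov_intra[v] = m_cov_intra(full, key)
        mcov_inter[v] = cov_inter(full, key)
        deciles_values[v] = [
            m_cov_intra(
                at_beta,
                {"variant": v, "beta": chosen_beta, "ns_diff": d, "ns_off": o},
            )
            for d, o in grid.pairs
        ]
    return OptimizationReport(
        chosen_beta=chosen_beta,
        chosen_ns=chosen_ns,
        mcov_intra=mcov_intra,
        mcov_inter=mcov_inter,
        deciles=decile_summary(deciles_values),
        table=full,
    )
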