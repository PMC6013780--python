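"""Cohort-style analyses of per-crypt OXPHOS-deficiency tables.

Reproduces the study's data-analysis pipeline on any cohort table: crypt
classification (normal / partial / full), decade binning, exponential growth
fits of class prevalences, the partial:full ratio trend, partial-fraction
histograms, conversion of fractions to stem-cell counts, and the grid fit of
the asymmetric-fate probability against simulated ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cohort import DECADES
from .mtdna import DeficiencyThreshold, MutationRateSchedule
from .niche import FateParams, NicheConfig, simulate_ensemble
from .observation import (
    DispersionParams,
    FractionHistogram,
    bin_fraction_to_sc_count,
    observe_fractions,
)

__all__ = [
    "GrowthFit",
    "TrendResult",
    "FateFitResult",
    "classify_observed_crypt",
    "decade_summary",
    "decade_k_table",
    "fit_exponential_growth",
    "partial_full_ratio_trend",
    "partial_fraction_histogram",
    "fit_simulation_to_cohort",
]

FULL_THRESHOLD = 1.0  # a crypt is 'full' when the whole circumference is deficient


def classify_observed_crypt(
    fraction: float,
    detection_floor: float = 0.05,
    full_threshold: float = FULL_THRESHOLD,
) -> str:
    """Classify an observed deficiency fraction.

    full: fraction >= full_threshold (default exactly 1.0 — fixed crypts
    emit exactly 1 under the observation model; lower the threshold, e.g.
    0.99, for measured data).  normal: fraction <= detection_floor.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction >= full_threshold:
        return "full"
    if fraction <= detection_floor:
        return "normal"
    return "partial"


def _classify_array(frac: np.ndarray, detection_floor: float, full_threshold: float):
    full = frac >= full_threshold
    normal = (~full) & (frac <= detection_floor)
    partial = ~(full | normal)
    return normal, partial, full


def _binned_k(frac: np.ndarray, n_sc: int, detection_floor: float) -> np.ndarray:
    """Observed fractions -> stem-cell counts (floor-censored fractions -> 0)."""
    k = np.array([bin_fraction_to_sc_count(f, n_sc) for f in frac], dtype=int)
    k[frac <= detection_floor] = 0
    return k


def decade_summary(
    cohort: pd.DataFrame,
    detection_floor: float = 0.05,
    n_sc: int = 5,
    full_threshold: float = FULL_THRESHOLD,
) -> pd.DataFrame:
    """Decade-binned class and stem-cell-count percentages.

    One row per age bracket that contains crypts (empty brackets are
    omitted, not reported as zero): patient and crypt counts, percent
    partial/full, and percent of crypts with k = 1..N deficient stem cells
    (observed fraction binned in increments of 1/N).  Percentages are pooled
    across crypts within the bracket.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    ages = cohort["age_years"].to_numpy(dtype=float)
    for (lo, hi) in DECADES:
        sel = (ages >= lo) & (ages <= hi)
        if not sel.any():
            continue
        sub = cohort.loc[sel]
        frac = sub["oxphos_fraction"].to_numpy(dtype=float)
        normal, partial, full = _classify_array(frac, detection_floor, full_threshold)
        k = _binned_k(frac, n_sc, detection_floor)
        n_crypts = len(sub)
        row = {
            "decade": f"{lo}-{hi}",
            "age": (lo + hi) / 2,
            "n_patients": sub["patient_id"].nunique(),
            "n_crypts": n_crypts,
            "pct_partial": 100.0 * partial.mean(),
            "pct_full": 100.0 * full.mean(),
        }
        for kk in range(1, n_sc + 1):
            row[f"pct_k{kk}"] = 100.0 * np.mean(k == kk)
        rows.append(row)
    out = pd.DataFrame(rows)
    outside = np.sum([decade_contains(a) is None for a in np.unique(ages)])
    if outside:
        warnings.warn(
            f"{outside} distinct patient age(s) fall outside the study brackets "
            "and were ignored",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def decade_contains(age: float):
    for i, (lo, hi) in enumerate(DECADES):
        if lo <= age <= hi:
            return i
    return None


def decade_k_table(
    cohort: pd.DataFrame,
    n_sc: int = 5,
    detection_floor: float = 0.05,
) -> pd.DataFrame:
    """Decade x deficient-SC-count percentage table (k = 1..N columns)."""
    summary = decade_summary(cohort, detection_floor=detection_floor, n_sc=n_sc)
    cols = ["decade", "age", "n_patients", "n_crypts"] + [
        f"pct_k{k}" for k in range(1, n_sc + 1)
    ]
    return summary[cols]


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit y = amplitude * exp(rate * t)."""

    amplitude: float
    rate: float
    r_squared: float


def fit_exponential_growth(ages, percentages) -> GrowthFit:
    """Nonlinear least-squares fit of an exponential growth curve.

    Fitted directly (not log-linearised) so zero-valued early bins are
    handled; requires at least 3 points and a non-degenerate response.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(percentages, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 points")
    if np.all(y == y[0]) and y[0] == 0:
        raise ValueError("degenerate input: all responses are zero")
    order = np.argsort(ages)
    ages, y = ages[order], y[order]
    pos = y > 0
    if pos.sum() >= 2:
        b0, loga0 = np.polyfit(ages[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(loga0)), float(b0))
    else:
        p0 = (max(y.max(), 1e-6), 0.05)
    popt, _ = curve_fit(
        lambda t, a, b: a * np.exp(b * t), ages, y, p0=p0, maxfev=20000
    )
    pred = popt[0] * np.exp(popt[1] * ages)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return GrowthFit(amplitude=float(popt[0]), rate=float(popt[1]), r_squared=r2)


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    n_used: int


def partial_full_ratio_trend(binned: pd.DataFrame) -> TrendResult:
    """OLS regression of the partial:full crypt ratio against age.

    Accepts a decade summary (or a cohort table, which is summarised
    first).  Brackets without full crypts are excluded with a warning;
    at least 3 usable brackets are required.  The reported p-value tests
    the age slope against zero.
    """
    import statsmodels.api as sm

    if "oxphos_fraction" in binned.columns:
        binned = decade_summary(binned)
    usable = binned["pct_full"] > 0
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} age bracket(s) without full crypts excluded "
            "from the ratio trend",
            RuntimeWarning,
            stacklevel=2,
        )
    sub = binned.loc[usable]
    if len(sub) < 3:
        raise ValueError("need at least 3 age brackets with full crypts")
    ratio = sub["pct_partial"].to_numpy() / sub["pct_full"].to_numpy()
    x = sm.add_constant(sub["age"].to_numpy())
    res = sm.OLS(ratio, x).fit()
    return TrendResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        n_used=len(sub),
    )


def partial_fraction_histogram(
    cohort: pd.DataFrame,
    bin_width: float = 0.05,
    detection_floor: float = 0.05,
    full_threshold: float = FULL_THRESHOLD,
    by_decade: bool = False,
):
    """Histogram of observed deficiency fractions over partial crypts.

    Returns a :class:`FractionHistogram` (or a dict bracket-label ->
    histogram when ``by_decade``).
    """
    frac = cohort["oxphos_fraction"].to_numpy(dtype=float)
    _, partial, _ = _classify_array(frac, detection_floor, full_threshold)
    if not partial.any():
        raise ValueError("cohort has no partial crypt")
    if not by_decade:
        return FractionHistogram.from_fractions(frac[partial], bin_width)
    out = {}
    ages = cohort["age_years"].to_numpy(dtype=float)
    for (lo, hi) in DECADES:
        sel = partial & (ages >= lo) & (ages <= hi)
        if sel.any():
            out[f"{lo}-{hi}"] = FractionHistogram.from_fractions(frac[sel], bin_width)
    return out


@dataclass
class FateFitResult:
    """Grid fit of the asymmetric fate-outcome probability."""

    best_p_asym: float | None
    scores: pd.DataFrame  # columns p_asym, score
    target_table: pd.DataFrame
    sim_tables: dict[float, pd.DataFrame] = field(default_factory=dict)
    tied: bool = False
    tied_candidates: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _table_discrepancy(
    target: pd.DataFrame, sim: pd.DataFrame, n_sc: int
) -> float:
    """Patient-count-weighted SSD between two decade x k percentage tables."""
    cols = [f"pct_k{k}" for k in range(1, n_sc + 1)]
    merged = target.merge(sim, on="decade", suffixes=("_obs", "_sim"))
    w = merged["n_patients"].to_numpy(dtype=float)
    w = w / w.sum()
    score = 0.0
    for c in cols:
        d = merged[f"{c}_obs"].to_numpy() - merged[f"{c}_sim"].to_numpy()
        score += float(np.sum(w * d**2))
    return score


def fit_simulation_to_cohort(
    cohort: pd.DataFrame,
    p_asym_grid,
    niche: NicheConfig | None = None,
    schedule: MutationRateSchedule | None = None,
    threshold: DeficiencyThreshold | None = None,
    disp: DispersionParams | None = None,
    n_runs: int = 2000,
    rng=None,
    detection_floor: float | None = None,
    min_runs_warning: int = 500,
) -> FateFitResult:
    """Fit the asymmetric fate-outcome probability on a grid.

    For each candidate p_asym an ensemble of ``n_runs`` crypts is simulated,
    its deficient-SC counts are pushed through the same observation and
    binning pipeline as the data, and the decade x k-count percentage table
    is scored against the cohort's by patient-count-weighted sum of squared
    differences.  Ties are reported, never broken silently.

    ``cohort`` may be a raw cohort table or a precomputed decade x k table
    (with pct_k columns), enabling self-scoring diagnostics.
    """
    niche = niche or NicheConfig()
    schedule = schedule or MutationRateSchedule()
    threshold = threshold or DeficiencyThreshold()
    disp = disp or DispersionParams()
    floor = disp.detection_floor if detection_floor is None else detection_floor
    p_asym_grid = list(p_asym_grid)
    if not p_asym_grid:
        raise ValueError("empty p_asym grid")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n = niche.n_sc
    if "oxphos_fraction" in cohort.columns:
        target = decade_k_table(cohort, n_sc=n, detection_floor=floor)
    else:
        target = cohort.copy()
    mids = target["age"].to_numpy(dtype=float)

    warn_msgs = []
    if n_runs < min_runs_warning:
        se = 100.0 * np.sqrt(0.01 * 0.99 / n_runs)
        msg = (
            f"ensemble size {n_runs} is small; percentage standard errors "
            f"around {se:.2f} points for 1% classes"
        )
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        warn_msgs.append(msg)

    rows = []
    sim_tables: dict[float, pd.DataFrame] = {}
    for p in p_asym_grid:
        fate = FateParams(p_asym=float(p))
        summ = simulate_ensemble(
            niche, fate, schedule, threshold,
            n_runs=n_runs, record_ages=list(mids), rng=rng,
        )
        sim_rows = []
        for a_idx, age in enumerate(summ.record_ages):
            k_true = summ.k_deficient[:, a_idx]
            f = observe_fractions(k_true, n, disp, rng)
            f[f <= disp.detection_floor] = 0.0
            k_obs = _binned_k(f, n, floor)
            row = {"decade": target["decade"].iloc[a_idx], "age": float(age)}
            for kk in range(1, n + 1):
                row[f"pct_k{kk}"] = 100.0 * np.mean(k_obs == kk)
            sim_rows.append(row)
        sim = pd.DataFrame(sim_rows)
        sim_tables[float(p)] = sim
        rows.append(
            {"p_asym": float(p), "score": _table_discrepancy(target, sim, n)}
        )
    scores = pd.DataFrame(rows)
    best = scores["score"].min()
    tied = scores.loc[scores["score"] <= best + 1e-12, "p_asym"].tolist()
    if len(tied) > 1:
        return FateFitResult(
            best_p_asym=None,
            scores=scores,
            target_table=target,
            sim_tables=sim_tables,
            tied=True,
            tied_candidates=tied,
            warnings=warn_msgs,
        )
    return FateFitResult(
        best_p_asym=tied[0],
        scores=scores,
        target_table=target,
        sim_tables=sim_tables,
        warnings=warn_msgs,
    )
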