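"""Synthetic biopsy cohorts with the statistical structure of the study data.

The emulated cohort has 148 patients spread over seven age brackets
(17-20: 2, 21-30: 10, 31-40: 25, 41-50: 44, 51-60: 37, 61-70: 21,
71-80: 9), roughly 1,000 scored crypts per biopsy, patient-to-patient
variability in mutation burden (a mean-one gamma multiplier on the mutation
or induction rate), and per-crypt observed OXPHOS-deficiency fractions
produced either by the multiscale simulator or by the analytic clone model,
then passed through the section observation model.  Adjacent fully-deficient
crypt clusters are already single clones here because crypt fission is not
simulated, so cluster collapsing is a no-op.

The cohort table is a plain pandas DataFrame with columns
``patient_id, age_years, crypt_id, oxphos_fraction`` and round-trips through
delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .drift import DriftParams, InductionParams, expected_size_masses
from .mtdna import DeficiencyThreshold, MutationRateSchedule
from .niche import FateParams, NicheConfig, simulate_ensemble
from .observation import DispersionParams, observe_fractions

__all__ = [
    "DECADES",
    "DEFAULT_DECADE_COUNTS",
    "CohortDesign",
    "decade_of_age",
    "decade_midpoints",
    "sample_patient_ages",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "sample_binned_percentages",
]

#: age brackets of the study cohort (inclusive bounds, years)
DECADES: tuple[tuple[int, int], ...] = (
    (17, 20),
    (21, 30),
    (31, 40),
    (41, 50),
    (51, 60),
    (61, 70),
    (71, 80),
)
DEFAULT_DECADE_COUNTS: tuple[int, ...] = (2, 10, 25, 44, 37, 21, 9)

COHORT_COLUMNS = ["patient_id", "age_years", "crypt_id", "oxphos_fraction"]


def decade_of_age(age: float) -> int | None:
    """Index of the study age bracket containing ``age`` (None if outside)."""
    for i, (lo, hi) in enumerate(DECADES):
        if lo <= age <= hi:
            return i
    return None


def decade_midpoints() -> np.ndarray:
    return np.array([(lo + hi) / 2 for lo, hi in DECADES])


@dataclass(frozen=True)
class CohortDesign:
    """Size and composition of a synthetic cohort.

    decade_counts: patients per age bracket (defaults to the study
    composition, 148 patients in total).  crypts_per_patient: crypts scored
    per biopsy (1,000 by default, ~148,000 crypts per cohort).
    patient_dispersion: gamma shape of the mean-one multiplier applied to
    each patient's mutation/induction rate (None disables heterogeneity).
    """

    decade_counts: tuple[int, ...] = DEFAULT_DECADE_COUNTS
    crypts_per_patient: int = 1000
    patient_dispersion: float | None = 4.0

    def __post_init__(self) -> None:
        if len(self.decade_counts) != len(DECADES):
            raise ValueError(f"decade_counts must have {len(DECADES)} entries")
        if any(c < 0 for c in self.decade_counts):
            raise ValueError("decade_counts must be non-negative")
        if self.crypts_per_patient < 1:
            raise ValueError("crypts_per_patient must be >= 1")
        if self.patient_dispersion is not None and self.patient_dispersion <= 0:
            raise ValueError("patient_dispersion must be positive (or None)")

    @property
    def n_patients(self) -> int:
        return int(sum(self.decade_counts))


def _normalise_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_patient_ages(design: CohortDesign, rng) -> np.ndarray:
    """Patient ages: per bracket, the designed count of patients with ages
    uniform over the bracket's integer years."""
    rng = _normalise_rng(rng)
    ages = []
    for (lo, hi), count in zip(DECADES, design.decade_counts):
        ages.extend(int(a) for a in rng.integers(lo, hi + 1, size=count))
    return np.array(ages, dtype=int)


def _patient_multipliers(design: CohortDesign, rng: np.random.Generator) -> np.ndarray:
    n = design.n_patients
    if design.patient_dispersion is None:
        return np.ones(n)
    shape = design.patient_dispersion
    return rng.gamma(shape, 1.0 / shape, size=n)


def _sample_analytic_k(
    drift: DriftParams,
    induction: InductionParams,
    age: float,
    n_crypts: int,
    rate_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Deficient-SC counts per crypt sampled from the analytic clone model.

    Clones arrive as a Poisson process (expected size masses m_n scaled by
    the patient multiplier); a crypt with any fixed clone is full, otherwise
    its count is the summed size of its partial clones capped at N - 1.
    """
    n = drift.n_sc
    m = expected_size_masses(drift, induction, age, rate_scale=rate_scale)
    m_fix = m[-1]
    m_part = m[1:-1]
    m_tot = m_part.sum()
    k = np.zeros(n_crypts, dtype=np.int64)
    full = rng.random(n_crypts) < (1.0 - np.exp(-m_fix))
    k[full] = n
    rest = ~full
    n_rest = int(rest.sum())
    if m_tot > 0 and n_rest:
        counts = rng.poisson(m_tot, size=n_rest)
        sizes = np.arange(1, n)
        q = m_part / m_tot
        totals = np.zeros(n_rest, dtype=np.int64)
        todo = counts > 0
        while todo.any():
            draw = rng.choice(sizes, size=int(todo.sum()), p=q)
            totals[todo] += draw
            counts[todo] -= 1
            todo = counts > 0
        k[rest] = np.minimum(totals, n - 1)
    return k


def generate_cohort(
    design: CohortDesign,
    engine: str = "simulator",
    niche: NicheConfig | None = None,
    fate: FateParams | None = None,
    schedule: MutationRateSchedule | None = None,
    threshold: DeficiencyThreshold | None = None,
    drift: DriftParams | None = None,
    induction: InductionParams | None = None,
    disp: DispersionParams | None = None,
    rng=None,
    replace_any: bool = False,
    scheme: str = "binary",
) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic cohort table and its reproducibility metadata.

    engine="simulator" runs the multiscale mtDNA + niche model per patient;
    engine="analytic" samples crypt states from the analytic clone model.
    Both push stem-cell counts through the section observation model and
    apply the detection floor (fractions at or below it are recorded as 0).
    """
    if engine not in ("simulator", "analytic"):
        raise ValueError(f"unknown engine {engine!r}")
    rng = _normalise_rng(rng)
    niche = niche or NicheConfig()
    fate = fate or FateParams()
    schedule = schedule or MutationRateSchedule()
    threshold = threshold or DeficiencyThreshold()
    disp = disp or DispersionParams()
    if disp.detection_floor >= 1.0 / niche.n_sc:
        raise ValueError("detection_floor must be below 1/N")
    drift = drift or DriftParams(n_sc=niche.n_sc)
    induction = induction or InductionParams()

    ages = sample_patient_ages(design, rng)
    mult = _patient_multipliers(design, rng)
    frames = []
    crypt0 = 0
    for pid, (age, g) in enumerate(zip(ages, mult)):
        ncr = design.crypts_per_patient
        if engine == "simulator":
            summ = simulate_ensemble(
                niche,
                fate,
                schedule,
                threshold,
                n_runs=ncr,
                record_ages=[age],
                rng=rng,
                mu_scale=g,
                replace_any=replace_any,
                scheme=scheme,
            )
            k = summ.k_deficient[:, -1]
        else:
            k = _sample_analytic_k(drift, induction, age, ncr, g, rng)
        f = observe_fractions(k, niche.n_sc, disp, rng)
        f[f <= disp.detection_floor] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "age_years": int(age),
                    "crypt_id": np.arange(crypt0, crypt0 + ncr),
                    "oxphos_fraction": f,
                }
            )
        )
        crypt0 += ncr
    cohort = pd.concat(frames, ignore_index=True)
    meta = {
        "package_version": _pkg_version,
        "engine": engine,
        "n_patients": design.n_patients,
        "crypts_per_patient": design.crypts_per_patient,
        "patient_dispersion": design.patient_dispersion,
        "n_sc": niche.n_sc,
        "p_asym": fate.p_asym,
        "mu_start": schedule.mu_start,
        "mu_end": schedule.mu_end,
        "theta": threshold.theta,
        "lambda_rate": drift.lambda_rate,
        "bias": drift.bias,
        "r0": induction.r0,
        "eta": induction.eta,
        "sigma": disp.sigma,
        "detection_floor": disp.detection_floor,
        "replication_scheme": scheme,
        "neighbourhood": "any" if replace_any else "ring",
        "cluster_collapsing": "no-op (fission not simulated)",
    }
    return cohort, meta


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as delimited text with a header."""
    cohort.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table; malformed rows are reported with
    their line numbers (header = line 1)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns: {missing}")
    df = df[COHORT_COLUMNS]
    frac = pd.to_numeric(df["oxphos_fraction"], errors="coerce")
    age = pd.to_numeric(df["age_years"], errors="coerce")
    bad = frac.isna() | (frac < 0) | (frac > 1) | age.isna() | (age < 0)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(
            f"invalid cohort rows (fraction outside [0,1] or bad age) at "
            f"line(s) {lines[:10]}{'...' if len(lines) > 10 else ''}"
        )
    df["oxphos_fraction"] = frac
    df["age_years"] = age
    return df


def sample_binned_percentages(
    design: CohortDesign,
    drift: DriftParams,
    induction: InductionParams,
    rng,
    n_quad: int = 48,
) -> pd.DataFrame:
    """Decade-binned partial/full percentages from the analytic model with
    multinomial sampling noise at cohort scale.

    Each patient contributes ``crypts_per_patient`` crypts drawn
    multinomially from the model class probabilities at the decade midpoint;
    counts are pooled per decade.  Returns a binned summary table with
    columns age, n_patients, n_crypts, pct_partial, pct_full.
    """
    from .drift import class_probabilities

    rng = _normalise_rng(rng)
    rows = []
    for (lo, hi), n_pat in zip(DECADES, design.decade_counts):
        if n_pat == 0:
            continue
        mid = (lo + hi) / 2
        p = class_probabilities(drift, induction, mid, n_quad=n_quad)
        probs = np.array([p["normal"], p["partial"], p["full"]])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        n_crypts = n_pat * design.crypts_per_patient
        counts = rng.multinomial(n_crypts, probs)
        rows.append(
            {
                "decade": f"{lo}-{hi}",
                "age": mid,
                "n_patients": n_pat,
                "n_crypts": n_crypts,
                "pct_partial": 100.0 * counts[1] / n_crypts,
                "pct_full": 100.0 * counts[2] / n_crypts,
            }
        )
    return pd.DataFrame(rows)
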