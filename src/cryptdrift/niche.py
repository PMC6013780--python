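"""Crypt stem-cell niche dynamics.

The effective stem-cell compartment of a colonic crypt is modelled as a ring
of N cells at the crypt base.  Once per division interval (a week by
default) every stem cell divides synchronously.  With probability ``p_asym``
the fate outcome is *asymmetric*: one daughter stays in the niche, the other
is displaced into the differentiation stream, and the clonal configuration
of the ring is unchanged.  Otherwise the outcome is *symmetric*: both
daughters are retained and one ring neighbour (left or right with equal
probability) is expunged with all its content, so the niche size N is
conserved per event.  Symmetric events are the engine of neutral drift: a
clone expands or contracts by chance until it is lost or takes over the
whole ring (niche succession).

Each stem cell embeds the mtDNA dynamics of :mod:`cryptdrift.mtdna`; a crypt
is classified *normal* (no OXPHOS-deficient stem cell), *partial*
(0 < k < N) or *full* (k = N).

Single-crypt operations here are a plain-Python reference implementation;
:func:`simulate_ensemble` runs the identical update rule through the numba
kernels in :mod:`cryptdrift._kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel
from .mtdna import (
    DeficiencyThreshold,
    LineageIdAllocator,
    MtDnaState,
    MutationRateSchedule,
    divide_cell,
    is_oxphos_deficient,
)

__all__ = [
    "NicheConfig",
    "FateParams",
    "CryptState",
    "CryptClass",
    "CryptTrajectory",
    "EnsembleSummary",
    "init_crypt",
    "step_generation",
    "run_crypt",
    "classify_crypt",
    "clonality_of_deficiency",
    "simulate_ensemble",
    "simulate_induction_ensemble",
    "simulate_labelled_clone",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class NicheConfig:
    """Geometry and tempo of the stem-cell niche.

    Defaults: N = 5 effective stem cells dividing weekly over an 80-year
    lifespan, i.e. floor(80 * 365 / 7) = 4171 synchronous division rounds.
    """

    n_sc: int = 5
    division_interval_days: float = 7.0
    lifespan_years: float = 80.0
    copy_number: int = 200

    def __post_init__(self) -> None:
        if self.n_sc < 2:
            raise ValueError("n_sc must be at least 2")
        if self.division_interval_days <= 0 or self.lifespan_years <= 0:
            raise ValueError("durations must be positive")
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")

    @property
    def n_divisions(self) -> int:
        """Whole number of division intervals in the lifespan (365-day years)."""
        return int(self.lifespan_years * DAYS_PER_YEAR / self.division_interval_days)

    @property
    def divisions_per_year(self) -> float:
        return DAYS_PER_YEAR / self.division_interval_days

    @property
    def years_per_division(self) -> float:
        return self.division_interval_days / DAYS_PER_YEAR

    def generation_at_age(self, age_years: float) -> int:
        g = int(round(age_years / self.years_per_division))
        return min(max(g, 0), self.n_divisions)


@dataclass(frozen=True)
class FateParams:
    """Per-division probability of asymmetric fate outcome."""

    p_asym: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_asym <= 1.0):
            raise ValueError("p_asym must lie in [0, 1]")

    @property
    def p_sym(self) -> float:
        return 1.0 - self.p_asym

    def replacement_rate_per_year(self, divisions_per_year: float) -> float:
        """Stem-cell loss/replacement rate implied by the symmetric fraction.

        Each symmetric division expunges exactly one neighbour, so a given
        stem cell is lost at rate p_sym per division round.
        """
        return self.p_sym * divisions_per_year


@dataclass
class CryptState:
    """Ordered ring of N stem cells with their mtDNA populations."""

    cells: list[MtDnaState]
    age: float = 0.0
    crypt_id: int = 0

    @property
    def n_sc(self) -> int:
        return len(self.cells)

    def deficiency_flags(
        self, threshold: DeficiencyThreshold = DeficiencyThreshold()
    ) -> list[bool]:
        return [is_oxphos_deficient(c, threshold) for c in self.cells]


@dataclass(frozen=True)
class CryptClass:
    label: str  # "normal" | "partial" | "full"
    k_deficient: int


@dataclass
class CryptTrajectory:
    record_ages: np.ndarray
    k_deficient: np.ndarray
    classes: list[CryptClass]
    n_generations: int


def init_crypt(config: NicheConfig, crypt_id: int = 0) -> CryptState:
    """A newborn crypt: N all-wild-type stem cells at age 0."""
    return CryptState(
        cells=[MtDnaState.wild_type(config.copy_number) for _ in range(config.n_sc)],
        age=0.0,
        crypt_id=crypt_id,
    )


def classify_crypt(
    crypt: CryptState, threshold: DeficiencyThreshold = DeficiencyThreshold()
) -> CryptClass:
    k = sum(crypt.deficiency_flags(threshold))
    n = crypt.n_sc
    label = "normal" if k == 0 else ("full" if k == n else "partial")
    return CryptClass(label=label, k_deficient=k)


def clonality_of_deficiency(
    crypt: CryptState, threshold: DeficiencyThreshold = DeficiencyThreshold()
) -> int:
    """Distinct mutation lineages that dominate the deficient stem cells.

    The dominant lineage of a deficient cell is the mutant lineage with the
    largest molecule count (ties broken towards the older, i.e. smaller, id).
    Raises ``ValueError`` when the crypt holds no deficient cell.
    """
    doms = []
    for cell, flag in zip(crypt.cells, crypt.deficiency_flags(threshold)):
        if not flag:
            continue
        best = min(
            cell.mutant_counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        doms.append(best[0])
    if not doms:
        raise ValueError("crypt has no OXPHOS-deficient stem cell")
    return len(set(doms))


def step_generation(
    crypt: CryptState,
    t: float,
    fate: FateParams,
    schedule: MutationRateSchedule,
    rng: np.random.Generator,
    id_allocator: LineageIdAllocator | None = None,
    replace_any: bool = False,
    scheme: str = "binary",
) -> CryptState:
    """One synchronous division round; returns a new CryptState.

    Positions are visited in uniformly random order.  A position overwritten
    by a symmetric neighbour event before its turn does not divide that round
    (its division is pre-empted by the expulsion).
    """
    n = crypt.n_sc
    cells = list(crypt.cells)
    order = rng.permutation(n)
    replaced = [False] * n
    for i in order:
        if replaced[i]:
            continue
        d1, d2 = divide_cell(
            cells[i], t, schedule, rng, id_allocator=id_allocator, scheme=scheme
        )
        if rng.random() < fate.p_asym:
            cells[i] = d1 if rng.random() < 0.5 else d2
        else:
            if replace_any:
                j = int(rng.integers(n - 1))
                j = j if j < i else j + 1
            else:
                j = (i + 1) % n if rng.random() < 0.5 else (i - 1) % n
            if rng.random() < 0.5:
                cells[i], cells[j] = d1, d2
            else:
                cells[i], cells[j] = d2, d1
            replaced[j] = True
    return CryptState(cells=cells, age=crypt.age + 0.0, crypt_id=crypt.crypt_id)


def run_crypt(
    config: NicheConfig,
    fate: FateParams,
    schedule: MutationRateSchedule,
    threshold: DeficiencyThreshold,
    rng: np.random.Generator,
    record_ages: Sequence[float] = (80.0,),
    replace_any: bool = False,
    scheme: str = "binary",
) -> CryptTrajectory:
    """Simulate a single crypt over its lifespan (reference implementation)."""
    record_ages = np.asarray(sorted(record_ages), dtype=float)
    record_gens = [config.generation_at_age(a) for a in record_ages]
    crypt = init_crypt(config)
    ids = LineageIdAllocator()
    ks: list[int] = []
    classes: list[CryptClass] = []
    ptr = 0
    n_gens = config.n_divisions
    while ptr < len(record_gens) and record_gens[ptr] == 0:
        cl = classify_crypt(crypt, threshold)
        ks.append(cl.k_deficient)
        classes.append(cl)
        ptr += 1
    for g in range(1, n_gens + 1):
        t = g * config.years_per_division
        crypt = step_generation(
            crypt, t, fate, schedule, rng, id_allocator=ids,
            replace_any=replace_any, scheme=scheme,
        )
        crypt.age = t
        while ptr < len(record_gens) and record_gens[ptr] == g:
            cl = classify_crypt(crypt, threshold)
            ks.append(cl.k_deficient)
            classes.append(cl)
            ptr += 1
        if ptr >= len(record_gens):
            break
    return CryptTrajectory(
        record_ages=record_ages,
        k_deficient=np.array(ks),
        classes=classes,
        n_generations=n_gens,
    )


@dataclass
class EnsembleSummary:
    """Per-age deficient-SC counts for an ensemble of independent crypts."""

    record_ages: np.ndarray  # years actually recorded
    k_deficient: np.ndarray  # (n_runs, n_ages)
    clonality: np.ndarray  # (n_runs, n_ages) dominant-lineage multiplicity
    n_sc: int
    n_runs: int
    n_generations: int
    years_simulated: float
    n_replacements: int
    metadata: dict = field(default_factory=dict)

    def class_percentages(self) -> "pd.DataFrame":
        """Tidy table (age, k, count, percent, label) over the ensemble."""
        import pandas as pd

        rows = []
        n = self.n_sc
        for a_idx, age in enumerate(self.record_ages):
            ks = self.k_deficient[:, a_idx]
            for k in range(n + 1):
                count = int(np.sum(ks == k))
                label = "normal" if k == 0 else ("full" if k == n else "partial")
                rows.append(
                    {
                        "age": float(age),
                        "k": k,
                        "count": count,
                        "percent": 100.0 * count / self.n_runs,
                        "label": label,
                    }
                )
        return pd.DataFrame(rows)

    def percent_of_class(self, label: str) -> np.ndarray:
        """Percentage of crypts in a class (normal/partial/full) per age."""
        n = self.n_sc
        out = np.zeros(len(self.record_ages))
        for a_idx in range(len(self.record_ages)):
            ks = self.k_deficient[:, a_idx]
            if label == "normal":
                sel = ks == 0
            elif label == "full":
                sel = ks == n
            elif label == "partial":
                sel = (ks > 0) & (ks < n)
            else:
                raise ValueError(f"unknown class {label!r}")
            out[a_idx] = 100.0 * np.mean(sel)
        return out

    def replacement_rate_per_sc_year(self) -> float:
        denom = self.n_runs * self.n_sc * self.years_simulated
        return self.n_replacements / denom if denom > 0 else float("nan")


def _normalise_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_ensemble(
    config: NicheConfig,
    fate: FateParams,
    schedule: MutationRateSchedule,
    threshold: DeficiencyThreshold,
    n_runs: int,
    record_ages: Sequence[float],
    rng,
    mu_scale: np.ndarray | float = 1.0,
    init_mut_count: int = 0,
    replace_any: bool = False,
    scheme: str = "binary",
) -> EnsembleSummary:
    """Simulate ``n_runs`` independent crypts with the multiscale engine.

    ``mu_scale`` optionally rescales the mutation-rate schedule per crypt
    (scalar or array of length n_runs), which is how patient-to-patient
    variability enters cohort generation.  ``init_mut_count`` seeds cell 0 of
    every crypt with that many mutant molecules of a single lineage (used for
    heteroplasmy-drift experiments).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _normalise_rng(rng)
    record_ages = np.asarray(sorted(record_ages), dtype=float)
    record_gens = np.array(
        sorted({config.generation_at_age(a) for a in record_ages}), dtype=np.int64
    )
    scale = np.broadcast_to(np.asarray(mu_scale, dtype=float), (n_runs,)).copy()
    n_gens = int(record_gens.max(initial=0))
    seed = _kernel_seed(rng)
    k_def, clon, n_repl = _kernel.run_mtdna_ensemble(
        n_runs,
        config.n_sc,
        config.copy_number,
        n_gens,
        config.years_per_division,
        schedule.mu_start,
        schedule.mu_end,
        schedule.t_end,
        fate.p_asym,
        threshold.count_for(config.copy_number),
        record_gens,
        scale,
        init_mut_count,
        replace_any,
        scheme == "resample",
        seed,
    )
    return EnsembleSummary(
        record_ages=record_gens * config.years_per_division,
        k_deficient=k_def,
        clonality=clon,
        n_sc=config.n_sc,
        n_runs=n_runs,
        n_generations=n_gens,
        years_simulated=n_gens * config.years_per_division,
        n_replacements=int(n_repl),
        metadata={
            "engine": "multiscale",
            "replication_scheme": scheme,
            "neighbourhood": "any" if replace_any else "ring",
            "p_asym": fate.p_asym,
            "n_sc": config.n_sc,
            "copy_number": config.copy_number,
            "mu_start": schedule.mu_start,
            "mu_end": schedule.mu_end,
            "mu_t_end": schedule.t_end,
            "theta": threshold.theta,
            "kernel_seed": seed,
        },
    )


def simulate_induction_ensemble(
    config: NicheConfig,
    fate: FateParams,
    r0_abs: float,
    eta: float,
    n_runs: int,
    record_ages: Sequence[float],
    rng,
    rate_scale: np.ndarray | float = 1.0,
    init_labelled: bool = False,
    replace_any: bool = False,
) -> EnsembleSummary:
    """Niche dynamics with irreversible Poisson labelling (induction engine).

    ``r0_abs`` is the absolute induction rate per crypt per year at t = 0,
    growing as exp(eta t).  This is the stochastic counterpart of the
    analytic clone model: labelled cells play the role of OXPHOS-deficient
    cells, without the mtDNA layer.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _normalise_rng(rng)
    record_ages = np.asarray(sorted(record_ages), dtype=float)
    record_gens = np.array(
        sorted({config.generation_at_age(a) for a in record_ages}), dtype=np.int64
    )
    scale = np.broadcast_to(np.asarray(rate_scale, dtype=float), (n_runs,)).copy()
    n_gens = int(record_gens.max(initial=0))
    seed = _kernel_seed(rng)
    k_lab, clon, n_repl = _kernel.run_induction_ensemble(
        n_runs,
        config.n_sc,
        n_gens,
        config.years_per_division,
        r0_abs,
        eta,
        fate.p_asym,
        record_gens,
        scale,
        init_labelled,
        replace_any,
        seed,
    )
    return EnsembleSummary(
        record_ages=record_gens * config.years_per_division,
        k_deficient=k_lab,
        clonality=clon,
        n_sc=config.n_sc,
        n_runs=n_runs,
        n_generations=n_gens,
        years_simulated=n_gens * config.years_per_division,
        n_replacements=int(n_repl),
        metadata={
            "engine": "induction",
            "r0_abs": r0_abs,
            "eta": eta,
            "p_asym": fate.p_asym,
            "n_sc": config.n_sc,
            "kernel_seed": seed,
        },
    )


def simulate_labelled_clone(
    config: NicheConfig,
    fate: FateParams,
    n_runs: int,
    record_ages: Sequence[float],
    rng,
    replace_any: bool = False,
) -> EnsembleSummary:
    """Pure neutral drift of one initially labelled stem cell per crypt."""
    return simulate_induction_ensemble(
        config,
        fate,
        r0_abs=0.0,
        eta=0.0,
        n_runs=n_runs,
        record_ages=record_ages,
        rng=rng,
        init_labelled=True,
        replace_any=replace_any,
    )
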