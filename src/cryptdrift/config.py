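"""Run configuration: a flat, human-editable key-value document.

Every pipeline entry point consumes a :class:`RunConfig`, which carries the
simulation parameter defaults, the cohort design, the master seed and the
engine/scheme switches, and can be loaded from a flat YAML mapping.  Unknown
keys are errors, not warnings.  Each run writes a metadata record containing
the full configuration so it can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .cohort import DEFAULT_DECADE_COUNTS, CohortDesign
from .drift import DriftParams, InductionParams
from .mtdna import DeficiencyThreshold, MutationRateSchedule
from .niche import FateParams, NicheConfig
from .observation import DispersionParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # niche / mtDNA layer
    n_sc: int = 5
    copy_number: int = 200
    mu_start: float = 1.0e-5
    mu_end: float = 6.0e-5
    mu_t_end: float = 80.0
    division_interval_days: float = 7.0
    lifespan_years: float = 80.0
    p_asym: float = 0.99
    theta: float = 0.75
    # observation layer
    sigma: float = 0.03
    detection_floor: float = 0.05
    # analytic model
    lambda_rate: float = 0.6
    bias: float = 0.0
    r0: float = 0.05
    eta: float = 0.05
    # ensembles and cohorts
    n_runs: int = 30000
    record_ages: tuple[float, ...] = (18.5, 25.5, 35.5, 45.5, 55.5, 65.5, 75.5, 80.0)
    crypts_per_patient: int = 1000
    patient_dispersion: float | None = 4.0
    decade_counts: tuple[int, ...] = DEFAULT_DECADE_COUNTS
    # engines and schemes
    engine: str = "simulator"
    neighbourhood: str = "ring"  # or "any"
    replication_scheme: str = "binary"  # or "resample"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.record_ages = tuple(self.record_ages)
        self.decade_counts = tuple(self.decade_counts)
        if self.engine not in ("simulator", "analytic"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.neighbourhood not in ("ring", "any"):
            raise ValueError(f"unknown neighbourhood {self.neighbourhood!r}")
        if self.replication_scheme not in ("binary", "resample"):
            raise ValueError(
                f"unknown replication_scheme {self.replication_scheme!r}"
            )
        # delegate range validation to the component parameter classes
        self.niche()
        self.fate()
        self.schedule()
        self.threshold()
        self.disp()
        self.drift()
        self.induction()
        self.design()

    # -- component parameter objects ------------------------------------
    def niche(self) -> NicheConfig:
        return NicheConfig(
            n_sc=self.n_sc,
            division_interval_days=self.division_interval_days,
            lifespan_years=self.lifespan_years,
            copy_number=self.copy_number,
        )

    def fate(self) -> FateParams:
        return FateParams(p_asym=self.p_asym)

    def schedule(self) -> MutationRateSchedule:
        return MutationRateSchedule(
            mu_start=self.mu_start, mu_end=self.mu_end, t_end=self.mu_t_end
        )

    def threshold(self) -> DeficiencyThreshold:
        return DeficiencyThreshold(theta=self.theta)

    def disp(self) -> DispersionParams:
        return DispersionParams(
            sigma=self.sigma, detection_floor=self.detection_floor
        )

    def drift(self) -> DriftParams:
        return DriftParams(
            n_sc=self.n_sc, lambda_rate=self.lambda_rate, bias=self.bias
        )

    def induction(self) -> InductionParams:
        return InductionParams(r0=self.r0, eta=self.eta)

    def design(self) -> CohortDesign:
        return CohortDesign(
            decade_counts=tuple(self.decade_counts),
            crypts_per_patient=self.crypts_per_patient,
            patient_dispersion=self.patient_dispersion,
        )

    @property
    def replace_any(self) -> bool:
        return self.neighbourhood == "any"

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["record_ages"] = list(self.record_ages)
        d["decade_counts"] = list(self.decade_counts)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("record_ages", "decade_counts"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)
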