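"""Within-cell mtDNA dynamics: mutation, relaxed replication and segregation.

Each crypt stem cell carries a fixed population of ``copy_number`` mtDNA
molecules.  At every cell division the population is doubled by replication
(each molecule copied exactly once under the default scheme), newly
synthesised copies of wild-type templates acquire a fresh somatic mutation
with probability ``mu``, and the doubled pool is partitioned at random into
the two daughters (multivariate hypergeometric segregation).  A cell whose
mutant fraction (heteroplasmy) reaches the deficiency threshold is scored
OXPHOS-deficient.

Mutant molecules are tracked per *mutation lineage*: every mutation event
mints a globally unique identifier, so the clonal origin of deficiency can be
audited downstream.  Lineage identity has no effect on the dynamics — there
is a single phenotype readout and no back-mutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MtDnaState",
    "MoleculePool",
    "MutationRateSchedule",
    "DeficiencyThreshold",
    "LineageIdAllocator",
    "mutation_rate_at",
    "replicate_pool",
    "segregate",
    "divide_cell",
    "is_oxphos_deficient",
]

DEFAULT_COPY_NUMBER = 200


class LineageIdAllocator:
    """Mints globally unique mutation-lineage identifiers for one run."""

    def __init__(self, start: int = 1):
        self._counter = itertools.count(start)

    def __call__(self) -> int:
        return next(self._counter)


#: module-level fallback allocator; simulations that need reproducible ids
#: pass their own allocator.
_GLOBAL_IDS = LineageIdAllocator()


@dataclass
class MtDnaState:
    """mtDNA complement of a single stem cell.

    Parameters
    ----------
    wild_type_count
        Number of wild-type molecules.
    mutant_counts
        Mapping lineage id -> number of molecules of that mutant lineage.
    copy_number
        Total molecules per cell (M); conserved outside the transient
        doubled pool.
    """

    wild_type_count: int
    mutant_counts: dict[int, int] = field(default_factory=dict)
    copy_number: int = DEFAULT_COPY_NUMBER

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
        if self.wild_type_count < 0 or any(c < 0 for c in self.mutant_counts.values()):
            raise ValueError("molecule counts must be non-negative")
        if self.wild_type_count + sum(self.mutant_counts.values()) != self.copy_number:
            raise ValueError(
                "wild_type_count + sum(mutant_counts) must equal copy_number"
            )

    @property
    def mutant_total(self) -> int:
        return sum(self.mutant_counts.values())

    @property
    def heteroplasmy(self) -> float:
        """Mutant fraction of the cell's mtDNA population."""
        return self.mutant_total / self.copy_number

    @classmethod
    def wild_type(cls, copy_number: int = DEFAULT_COPY_NUMBER) -> "MtDnaState":
        return cls(wild_type_count=copy_number, copy_number=copy_number)


@dataclass
class MoleculePool:
    """Transient doubled molecule pool between replication and segregation."""

    wild_type_count: int
    mutant_counts: dict[int, int]
    copy_number: int  # M of the parent cell; pool holds 2M molecules

    @property
    def size(self) -> int:
        return self.wild_type_count + sum(self.mutant_counts.values())


@dataclass(frozen=True)
class MutationRateSchedule:
    """Exponentially increasing per-replication mutation probability.

    mu(t) = mu_start * (mu_end / mu_start) ** (t / t_end), i.e. geometric
    interpolation in calendar time between the rate at birth and the rate at
    ``t_end`` years; beyond ``t_end`` the same law extrapolates.
    """

    mu_start: float = 1.0e-5
    mu_end: float = 6.0e-5
    t_end: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 < self.mu_start <= self.mu_end < 1.0):
            raise ValueError("require 0 < mu_start <= mu_end < 1")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


@dataclass(frozen=True)
class DeficiencyThreshold:
    """Heteroplasmy level at which a cell is scored OXPHOS-deficient.

    The comparison is inclusive: a cell *reaching* the threshold is deficient.
    """

    theta: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must lie in (0, 1]")

    def count_for(self, copy_number: int) -> int:
        """Smallest mutant-molecule count that makes a cell deficient."""
        return int(np.ceil(self.theta * copy_number - 1e-9))


def mutation_rate_at(t: float, schedule: MutationRateSchedule) -> float:
    """Per-replication mutation probability at age ``t`` years."""
    if t < 0:
        raise ValueError("t must be non-negative")
    ratio = schedule.mu_end / schedule.mu_start
    return schedule.mu_start * ratio ** (t / schedule.t_end)


def replicate_pool(
    state: MtDnaState,
    mu: float,
    rng: np.random.Generator,
    id_allocator: LineageIdAllocator | None = None,
    scheme: str = "binary",
) -> MoleculePool:
    """Replicate every molecule once, doubling the population to 2M.

    Under the default ``binary`` scheme each molecule is copied exactly once.
    Each newly synthesised copy of a wild-type template mutates with
    probability ``mu`` and founds a fresh lineage; copies of mutant templates
    breed true (no back-mutation).  The alternative ``resample`` scheme draws
    the 2M pool with replacement from the parent composition (a looser
    reading of relaxed replication, kept for sensitivity analysis); newly
    drawn wild-type molecules mutate with the same probability.
    """
    if not (0.0 <= mu < 1.0):
        raise ValueError("mu must lie in [0, 1)")
    ids = id_allocator if id_allocator is not None else _GLOBAL_IDS

    if scheme == "binary":
        pool_mut = {lin: 2 * c for lin, c in state.mutant_counts.items()}
        n_new = rng.binomial(state.wild_type_count, mu) if mu > 0 else 0
        wt_pool = 2 * state.wild_type_count - n_new
    elif scheme == "resample":
        m = state.copy_number
        counts = np.array(
            [state.wild_type_count] + list(state.mutant_counts.values()), dtype=float
        )
        draw = rng.multinomial(2 * m, counts / m)
        pool_mut = {
            lin: int(c)
            for lin, c in zip(state.mutant_counts.keys(), draw[1:])
            if c > 0
        }
        n_new = rng.binomial(int(draw[0]), mu) if mu > 0 else 0
        wt_pool = int(draw[0]) - n_new
    else:
        raise ValueError(f"unknown replication scheme: {scheme!r}")

    for _ in range(int(n_new)):
        pool_mut[ids()] = 1  # each new mutant founds a singleton lineage
    return MoleculePool(
        wild_type_count=int(wt_pool),
        mutant_counts=pool_mut,
        copy_number=state.copy_number,
    )


def segregate(
    pool: MoleculePool, rng: np.random.Generator
) -> tuple[MtDnaState, MtDnaState]:
    """Partition a doubled pool uniformly at random into two daughters of M.

    Per-lineage daughter counts follow the multivariate hypergeometric law;
    the two daughters jointly contain every pool molecule.
    """
    m = pool.copy_number
    if pool.size != 2 * m:
        raise ValueError(f"pool must hold exactly 2M={2 * m} molecules, got {pool.size}")
    lineages = list(pool.mutant_counts.keys())
    colors = np.array([pool.wild_type_count] + [pool.mutant_counts[l] for l in lineages])
    take = rng.multivariate_hypergeometric(colors, m)
    d1 = MtDnaState(
        wild_type_count=int(take[0]),
        mutant_counts={l: int(c) for l, c in zip(lineages, take[1:]) if c > 0},
        copy_number=m,
    )
    rest = colors - take
    d2 = MtDnaState(
        wild_type_count=int(rest[0]),
        mutant_counts={l: int(c) for l, c in zip(lineages, rest[1:]) if c > 0},
        copy_number=m,
    )
    return d1, d2


def divide_cell(
    state: MtDnaState,
    t: float,
    schedule: MutationRateSchedule,
    rng: np.random.Generator,
    id_allocator: LineageIdAllocator | None = None,
    scheme: str = "binary",
) -> tuple[MtDnaState, MtDnaState]:
    """Replicate then segregate: one stem-cell division at age ``t`` years."""
    mu = mutation_rate_at(t, schedule)
    pool = replicate_pool(state, mu, rng, id_allocator=id_allocator, scheme=scheme)
    return segregate(pool, rng)


def is_oxphos_deficient(
    state: MtDnaState, threshold: DeficiencyThreshold = DeficiencyThreshold()
) -> bool:
    """True iff the cell's mutant fraction has reached the threshold."""
    return state.mutant_total >= threshold.count_for(state.copy_number)
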