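"""Analytic one-dimensional neutral-drift model of crypt clone dynamics.

Clone size ``n`` (number of stem cells carrying the clonal mark, out of N
around the crypt circumference) performs a continuous-time birth--death walk
with absorbing boundaries at 0 (clone loss) and N (niche succession /
fixation).  With per-stem-cell loss/replacement rate ``lambda_rate`` (events
per SC per year) and fate bias ``bias`` = delta, the transition rates are

    n -> n + 1 at rate lambda_rate * (1 + delta)
    n -> n - 1 at rate lambda_rate * (1 - delta)        for 0 < n < N.

This convention makes ``lambda_rate`` exactly the rate at which any given
stem cell is lost and replaced by a neighbour, so a symmetric-division
probability p_sym per weekly division round corresponds to
lambda_rate = p_sym * divisions_per_year (0.01 -> 0.52/yr).

New clones are seeded at size n0 = 1 by an induction rate that grows
exponentially with age, R(t) = R0 * exp(eta * t).  Unit convention: the
induction constants are expressed in percent of crypts per year (the scale
on which crypt prevalences are reported); the absolute per-crypt rate is
R(t)/100.  Taken as absolute rates the same constants would imply that every
crypt carries deficient clones by age ~20, inconsistent with the observed
late, few-percent prevalence of deficient crypts.

The expected abundance of partial and fixed crypts follows by integrating
the induction rate against the chain's transition probabilities; clones
within a crypt are treated as independent (Poisson overlap correction, valid
while the cumulative induction per crypt is modest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "DriftParams",
    "InductionParams",
    "ClonePMF",
    "induction_rate",
    "clone_size_distribution",
    "fixation_probability",
    "quasi_steady_partial_pmf",
    "expected_size_masses",
    "expected_class_fractions",
    "class_probabilities",
    "CryptDriftModel",
    "CryptDriftResults",
    "fit_analytic",
    "calibrate_induction",
]

PERCENT_SCALE = 100.0  # induction constants are percent-of-crypts per year


@dataclass(frozen=True)
class DriftParams:
    """Neutral-drift chain parameters.

    n_sc: effective stem cells around the circumference (N).
    lambda_rate: loss/replacement events per stem cell per year.
    bias: fate bias delta of marked cells, in (-1, 1); 0 = strictly neutral.
    """

    n_sc: int = 5
    lambda_rate: float = 0.6
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sc < 2:
            raise ValueError("n_sc must be >= 2")
        if self.lambda_rate < 0:
            raise ValueError("lambda_rate must be >= 0")
        if not (-1.0 < self.bias < 1.0):
            raise ValueError("bias must lie in (-1, 1)")

    @property
    def up_rate(self) -> float:
        return self.lambda_rate * (1.0 + self.bias)

    @property
    def down_rate(self) -> float:
        return self.lambda_rate * (1.0 - self.bias)


@dataclass(frozen=True)
class InductionParams:
    """Exponentially growing clone induction rate R(t) = r0 * exp(eta * t).

    r0 is expressed in percent of crypts per year (see module docstring);
    eta in 1/year.  Defaults correspond to R0/N = 0.01 with N = 5 and
    eta = 0.05/yr, i.e. 0.14 at age 20 and ~1.7 at age 70.
    """

    r0: float = 0.05
    eta: float = 0.05

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.eta < 0:
            raise ValueError("r0 and eta must be >= 0")

    def rate(self, t: float) -> float:
        return self.r0 * np.exp(self.eta * t)

    def absolute_rate(self, t):
        """Induction events per crypt per year (absolute probability scale)."""
        return self.r0 / PERCENT_SCALE * np.exp(self.eta * np.asarray(t, dtype=float))

    def cumulative_absolute(self, t: float) -> float:
        """Expected clones induced per crypt by age t."""
        r0 = self.r0 / PERCENT_SCALE
        if self.eta == 0:
            return r0 * t
        return r0 / self.eta * (np.exp(self.eta * t) - 1.0)


@dataclass
class ClonePMF:
    """Distribution of clone size n in {0, ..., N} at one time point."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def n_sc(self) -> int:
        return len(self.probabilities) - 1

    def __getitem__(self, n: int) -> float:
        return float(self.probabilities[n])


def induction_rate(t: float, params: InductionParams) -> float:
    """Clone induction rate at age ``t`` (same units as ``params.r0``)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    return params.rate(t)


def _generator(params: DriftParams) -> np.ndarray:
    n = params.n_sc
    q = np.zeros((n + 1, n + 1))
    up, down = params.up_rate, params.down_rate
    for i in range(1, n):
        q[i, i + 1] = up
        q[i, i - 1] = down
        q[i, i] = -(up + down)
    return q


def _propagator(params: DriftParams, times: np.ndarray, n0: int) -> np.ndarray:
    """Rows P_{n0, .}(s) of the chain's transition matrix for each s in times.

    Uses the eigendecomposition of the (small) generator, validated against
    a direct matrix exponential; falls back to expm per time point if the
    decomposition is ill-conditioned.
    """
    q = _generator(params)
    times = np.asarray(times, dtype=float)
    n = params.n_sc
    try:
        w, v = np.linalg.eig(q)
        vinv = np.linalg.inv(v)
        coef = v[n0, :]  # row of V for the start state
        out = np.real(
            (coef[None, :] * np.exp(np.outer(times, w))) @ vinv
        )
        # validate at the largest time against expm
        smax = float(times.max(initial=0.0))
        ref = expm(q * smax)[n0]
        if np.max(np.abs(out[np.argmax(times)] - ref)) > 1e-8:
            raise np.linalg.LinAlgError("eigendecomposition inaccurate")
    except np.linalg.LinAlgError:
        out = np.vstack([expm(q * s)[n0] for s in times])
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return out


def clone_size_distribution(params: DriftParams, t: float, n0: int) -> ClonePMF:
    """Clone-size distribution at time ``t`` for a clone started at ``n0``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if not (0 <= n0 <= params.n_sc):
        raise ValueError("n0 must lie in {0, ..., N}")
    row = _propagator(params, np.array([t]), n0)[0]
    return ClonePMF(row)


def fixation_probability(params: DriftParams, n0: int) -> float:
    """Probability that a clone of initial size n0 eventually fixes (n = N).

    Closed-form biased gambler's ruin; reduces to n0/N in the neutral case.
    """
    n = params.n_sc
    if not (0 <= n0 <= n):
        raise ValueError("n0 must lie in {0, ..., N}")
    if n0 == 0:
        return 0.0
    if n0 == n:
        return 1.0
    d = params.bias
    rho = (1.0 - d) / (1.0 + d)  # down/up
    if rho == 1.0:  # neutral, including bias below float resolution
        return n0 / n
    return float((1.0 - rho**n0) / (1.0 - rho**n))


def quasi_steady_partial_pmf(params: DriftParams) -> np.ndarray:
    """Steady-state size distribution of surviving partial clones.

    Relative occupancy of the transient states n = 1..N-1 under constant
    unit injection at n = 1.  In the strictly neutral case the occupancy is
    proportional to (N - n) — a linearly decaying size distribution whose
    shape is independent of the loss/replacement rate, peaking at a fraction
    1/N of the circumference.  Returned normalised to sum to 1.
    """
    n = params.n_sc
    if n == 2:
        return np.array([1.0])
    if params.lambda_rate == 0:
        out = np.zeros(n - 1)
        out[0] = 1.0
        return out
    up, down = params.up_rate, params.down_rate
    a = np.zeros((n - 1, n - 1))  # balance equations for states 1..N-1
    for idx in range(n - 1):
        a[idx, idx] = -(up + down)
        if idx > 0:
            a[idx, idx - 1] = up
        if idx < n - 2:
            a[idx, idx + 1] = down
    b = np.zeros(n - 1)
    b[0] = -1.0  # unit injection at n = 1
    occ = np.linalg.solve(a, b)
    occ = np.clip(occ, 0.0, None)
    return occ / occ.sum()


def _gauss_nodes(age: float, n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n_quad)
    return 0.5 * age * (x + 1.0), 0.5 * age * w


def expected_size_masses(
    drift: DriftParams,
    induction: InductionParams,
    age: float,
    n_quad: int = 48,
    rate_scale: float = 1.0,
) -> np.ndarray:
    """Expected number of clones of size n = 0..N per crypt at ``age``.

    m_n(age) = integral_0^age R_abs(t) P_{1 -> n}(age - t) dt, evaluated by
    Gauss-Legendre quadrature; clones are seeded at size 1 and treated as
    independent.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    n = drift.n_sc
    if age == 0 or induction.r0 == 0:
        return np.zeros(n + 1)
    t, w = _gauss_nodes(age, n_quad)
    rates = induction.absolute_rate(t) * rate_scale
    probs = _propagator(drift, age - t, 1)  # (n_quad, N+1)
    return (w * rates) @ probs


def expected_class_fractions(
    drift: DriftParams,
    induction: InductionParams,
    age: float,
    n_quad: int = 48,
) -> tuple[float, float]:
    """Expected (partial, full) clone counts per crypt at ``age``.

    Clone overlap within a crypt is neglected, so the values are expected
    counts rather than probabilities; a warning is emitted once the
    cumulative induction per crypt exceeds one event (use
    :func:`class_probabilities` for bounded probabilities).
    """
    m = expected_size_masses(drift, induction, age, n_quad=n_quad)
    total = induction.cumulative_absolute(age)
    if total > 1.0:
        warnings.warn(
            "cumulative induction per crypt exceeds 1; the clone-overlap "
            "approximation is strained — consider class_probabilities()",
            RuntimeWarning,
            stacklevel=2,
        )
    partial = float(m[1:-1].sum())
    full = float(m[-1])
    return partial, full


def class_probabilities(
    drift: DriftParams,
    induction: InductionParams,
    age: float,
    n_quad: int = 48,
    rate_scale: float = 1.0,
) -> dict:
    """Crypt class probabilities at ``age`` with Poisson overlap correction.

    Clones arrive as a Poisson process; a crypt is *full* when at least one
    clone has fixed, *partial* when no clone has fixed but deficient cells
    are present.  The distribution over the number of deficient stem cells k
    sums independent clone sizes, capped at N - 1 (overlapping clones
    compete in reality; the cap only matters when induction is heavy).
    """
    n = drift.n_sc
    m = expected_size_masses(drift, induction, age, n_quad=n_quad, rate_scale=rate_scale)
    m_fix = float(m[-1])
    m_part = m[1:-1]  # sizes 1..N-1
    m_tot = float(m_part.sum())
    p_full = 1.0 - np.exp(-m_fix)
    if m_tot <= 0:
        partial_k = np.zeros(n - 1)
        p_partial = 0.0
    else:
        # pmf of the summed size S of a Poisson number of iid partial clones
        q = m_part / m_tot
        pmf_s = np.zeros(n)  # S = 0..N-1 (cap)
        pmf_s[0] = np.exp(-m_tot)
        conv = np.ones(1)  # q^{*0}
        fact = 1.0
        for j in range(1, n):
            conv = np.convolve(conv, q)
            fact *= j
            term = np.exp(-m_tot) * m_tot**j / fact
            sizes = np.arange(j, j * (n - 1) + 1)
            for s_val, p in zip(sizes, conv):
                pmf_s[min(s_val, n - 1)] += term * p
        pmf_s[n - 1] += max(0.0, 1.0 - pmf_s.sum())  # j >= N lumped at cap
        p_partial_given_nofix = 1.0 - pmf_s[0]
        partial_k = pmf_s[1:] * (1.0 - p_full)
        p_partial = p_partial_given_nofix * (1.0 - p_full)
    return {
        "normal": float(max(0.0, 1.0 - p_full - p_partial)),
        "partial": float(p_partial),
        "full": float(p_full),
        "partial_k": partial_k,  # P(k = 1..N-1 deficient SCs, crypt not full)
    }


# ---------------------------------------------------------------------------
# Model / Results interface for fitting the analytic model to binned data
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("lambda_rate", "bias", "r0", "eta")
_BOUNDS = {
    "lambda_rate": (1e-4, 50.0),
    "bias": (-0.95, 0.95),
    "r0": (1e-8, 1e3),
    "eta": (0.0, 1.0),
}


class CryptDriftModel:
    """Neutral-drift + induction model for decade-binned crypt frequencies.

    Parameters
    ----------
    data
        DataFrame with one row per age bin and columns ``age`` (bin
        midpoint, years), ``pct_partial`` and/or ``pct_full`` (observed
        percentages of crypts) and optionally ``n_patients`` (fit weights).
    n_sc
        Effective stem-cell number N (held fixed during fitting).
    lambda_rate, bias, r0, eta
        Starting/fixed values of the model parameters.
    use
        Which observables enter the objective: subset of
        ``("partial", "full")``.

    The fit minimises patient-count-weighted least squares between model and
    observed percentages, mirroring the curve-fit style of the source
    analyses.  ``fit`` returns a :class:`CryptDriftResults`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        n_sc: int = 5,
        lambda_rate: float = 0.6,
        bias: float = 0.0,
        r0: float = 0.05,
        eta: float = 0.05,
        use: tuple[str, ...] = ("partial", "full"),
        n_quad: int = 48,
    ):
        data = pd.DataFrame(data).reset_index(drop=True)
        if "age" not in data.columns:
            raise ValueError("data must have an 'age' column (bin midpoints)")
        if len(data) < 2:
            raise ValueError("need at least 2 age groups")
        for obs in use:
            col = f"pct_{obs}"
            if col not in data.columns:
                raise ValueError(f"data lacks column {col!r}")
        self.data = data
        self.n_sc = n_sc
        self.use = tuple(use)
        self.n_quad = n_quad
        self.start = {
            "lambda_rate": lambda_rate,
            "bias": bias,
            "r0": r0,
            "eta": eta,
        }
        if "n_patients" in data.columns:
            w = data["n_patients"].to_numpy(dtype=float)
        else:
            w = np.ones(len(data))
        self.weights = w / w.sum()

    def predict(self, params: dict, ages=None) -> pd.DataFrame:
        """Model percentages of partial and full crypts at the given ages."""
        if ages is None:
            ages = self.data["age"].to_numpy(dtype=float)
        drift = DriftParams(
            n_sc=self.n_sc,
            lambda_rate=params["lambda_rate"],
            bias=params["bias"],
        )
        induction = InductionParams(r0=params["r0"], eta=params["eta"])
        rows = []
        for a in np.asarray(ages, dtype=float):
            p = class_probabilities(drift, induction, a, n_quad=self.n_quad)
            rows.append(
                {
                    "age": a,
                    "pct_partial": 100.0 * p["partial"],
                    "pct_full": 100.0 * p["full"],
                }
            )
        return pd.DataFrame(rows)

    def _residuals(self, params: dict) -> np.ndarray:
        pred = self.predict(params)
        res = []
        sw = np.sqrt(self.weights)
        for obs in self.use:
            col = f"pct_{obs}"
            res.append(sw * (pred[col].to_numpy() - self.data[col].to_numpy()))
        return np.concatenate(res)

    def fit(
        self,
        free: tuple[str, ...] = ("lambda_rate",),
        start: dict | None = None,
        bounds: dict | None = None,
    ) -> "CryptDriftResults":
        free = tuple(free)
        for name in free:
            if name not in _PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
        if len(free) >= 3 and len(self.data) < 3:
            raise ValueError(
                "non-identifiable request: 3+ free parameters need >= 3 age bins"
            )
        values = dict(self.start)
        if start:
            values.update(start)
        bnds = dict(_BOUNDS)
        if bounds:
            bnds.update(bounds)
        x0 = np.array([values[n] for n in free], dtype=float)
        lo = np.array([bnds[n][0] for n in free])
        hi = np.array([bnds[n][1] for n in free])
        x0 = np.clip(x0, lo, hi)

        def objective(x):
            p = dict(values)
            p.update(dict(zip(free, x)))
            return self._residuals(p)

        sol = least_squares(objective, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        fitted = dict(values)
        fitted.update(dict(zip(free, sol.x)))
        resid = sol.fun
        return CryptDriftResults(
            model=self,
            params=pd.Series(fitted)[list(_PARAM_NAMES)],
            free=free,
            rss=float(np.sum(resid**2)),
            residuals=resid,
            success=bool(sol.success),
            nfev=int(sol.nfev),
        )


@dataclass
class CryptDriftResults:
    """Fit result: estimates, residual sum of squares and diagnostics."""

    model: CryptDriftModel
    params: pd.Series
    free: tuple[str, ...]
    rss: float
    residuals: np.ndarray
    success: bool
    nfev: int

    @property
    def fittedvalues(self) -> pd.DataFrame:
        return self.model.predict(self.params.to_dict())

    def profile(self, name: str, values) -> pd.DataFrame:
        """RSS along a grid of one parameter with the others held at the fit."""
        rows = []
        for v in values:
            p = self.params.to_dict()
            p[name] = v
            r = self.model._residuals(p)
            rows.append({name: v, "rss": float(np.sum(r**2))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Neutral-drift clone model fit",
            "=" * 46,
            f"observables:      {', '.join(self.model.use)}",
            f"age bins:         {len(self.model.data)}",
            f"N (fixed):        {self.model.n_sc}",
            f"free parameters:  {', '.join(self.free)}",
            f"converged:        {self.success}  (nfev={self.nfev})",
            f"weighted RSS:     {self.rss:.6g}",
            "-" * 46,
        ]
        units = {
            "lambda_rate": "per SC per year",
            "bias": "(dimensionless)",
            "r0": "% crypts per year",
            "eta": "per year",
        }
        for name in _PARAM_NAMES:
            tag = "free " if name in self.free else "fixed"
            lines.append(
                f"{name:<12} {self.params[name]:>12.6g}  [{tag}] {units[name]}"
            )
        return "\n".join(lines)


def fit_analytic(
    binned: pd.DataFrame,
    free: tuple[str, ...] = ("lambda_rate",),
    fixed: dict | None = None,
    n_sc: int = 5,
    use: tuple[str, ...] = ("partial", "full"),
    **kwargs,
) -> CryptDriftResults:
    """Weighted least-squares fit of the analytic model to binned frequencies."""
    fixed = dict(fixed or {})
    model = CryptDriftModel(binned, n_sc=n_sc, use=use, **fixed, **kwargs)
    return model.fit(free=free)


def calibrate_induction(ages, mean_deficient_per_crypt) -> InductionParams:
    """Fit (r0, eta) to the cumulative deficient-cell burden of a
    pure-asymmetric ensemble.

    Under invariant asymmetric fate outcome deficient stem cells accumulate
    without clone spread or loss, so the mean number per crypt approximates
    the cumulative induction C(a) = (r0_abs/eta) (exp(eta a) - 1).  Returns
    InductionParams in the package's percent units.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(mean_deficient_per_crypt, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 ages to calibrate")

    def model(a, r0_abs, eta):
        eta = max(eta, 1e-9)
        return r0_abs / eta * (np.exp(eta * a) - 1.0)

    r0_guess = max(y[-1], 1e-6) / max(ages[-1], 1.0)
    popt, _ = curve_fit(
        model, ages, y, p0=(r0_guess, 0.03), bounds=([1e-12, 1e-6], [10.0, 1.0]),
        maxfev=20000,
    )
    return InductionParams(r0=popt[0] * PERCENT_SCALE, eta=popt[1])
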