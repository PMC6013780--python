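"""Mapping stem-cell clone states to histological section fractions.

A transverse section through a crypt shows a contiguous OXPHOS-deficient
patch whose circumference fraction reflects the number k of deficient stem
cells at the crypt base earlier in time.  The base fraction k/N is blurred
by lateral dispersion of the deficient progeny as cells migrate up the
crypt; this is modelled as zero-mean Gaussian jitter of scale ``sigma``
truncated to (0, 1).  Crypts with k = 0 show fraction 0 exactly and fixed
crypts (k = N) fraction 1 exactly.

The inverse operation bins an observed fraction back onto stem-cell counts
(increments of 1/N with inclusive upper edges), and ``scan_sc_number``
compares candidate stem-cell numbers N = 3..8 against an observed
partial-fraction histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .drift import DriftParams, quasi_steady_partial_pmf

__all__ = [
    "DispersionParams",
    "FractionHistogram",
    "ScanResult",
    "observe_section_fraction",
    "observe_fractions",
    "bin_fraction_to_sc_count",
    "predicted_fraction_histogram",
    "scan_sc_number",
]


@dataclass(frozen=True)
class DispersionParams:
    """Lateral dispersion scale and histological detection floor.

    sigma: s.d. of the circumferential jitter, as a fraction of the
    circumference.  detection_floor: observed fractions at or below this are
    scored as normal crypts (thin patches cannot be resolved); it must stay
    well below 1/N so stem-cell-count binning is not distorted.
    """

    sigma: float = 0.03
    detection_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.detection_floor < 1.0):
            raise ValueError("detection_floor must lie in [0, 1)")


def observe_section_fraction(
    k: int, n_sc: int, disp: DispersionParams, rng: np.random.Generator
) -> float:
    """Observed deficiency fraction for a crypt with k deficient SCs of N."""
    if not (0 <= k <= n_sc):
        raise ValueError("k must lie in {0, ..., N}")
    if k == 0:
        return 0.0
    if k == n_sc:
        return 1.0
    if disp.sigma == 0:
        return k / n_sc
    mu = k / n_sc
    while True:  # truncated normal on (0, 1) by rejection (rarely repeats)
        f = mu + disp.sigma * rng.standard_normal()
        if 0.0 < f < 1.0:
            return float(f)


def observe_fractions(
    k: np.ndarray, n_sc: int, disp: DispersionParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised :func:`observe_section_fraction` over an array of counts."""
    k = np.asarray(k)
    if k.size and (k.min() < 0 or k.max() > n_sc):
        raise ValueError("k must lie in {0, ..., N}")
    f = k / n_sc
    interior = (k > 0) & (k < n_sc)
    if disp.sigma > 0 and interior.any():
        vals = f[interior] + disp.sigma * rng.standard_normal(interior.sum())
        bad = (vals <= 0.0) | (vals >= 1.0)
        while bad.any():
            vals[bad] = f[interior][bad] + disp.sigma * rng.standard_normal(bad.sum())
            bad = (vals <= 0.0) | (vals >= 1.0)
        f = f.astype(float)
        f[interior] = vals
    return f.astype(float)


def bin_fraction_to_sc_count(fraction: float, n_sc: int) -> int:
    """Convert an observed fraction to a stem-cell count estimate.

    Bins of width 1/N with inclusive upper edges: the smallest k with
    fraction <= k/N (0 maps to 0, 1 maps to N).  A small epsilon guards the
    bin edges against floating-point representation error.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return 0
    return int(np.ceil(fraction * n_sc - 1e-9))


@dataclass
class FractionHistogram:
    """Histogram of partial-crypt deficiency fractions on (0, 1)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_fractions(
        cls, fractions, bin_width: float = 0.05
    ) -> "FractionHistogram":
        edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
        counts, _ = np.histogram(np.asarray(fractions, dtype=float), bins=edges)
        return cls(bin_edges=edges, counts=counts)

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError("empty histogram")
        return self.counts / tot

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FractionHistogram":
        edges = np.append(
            frame["bin_left"].to_numpy(dtype=float),
            frame["bin_right"].to_numpy(dtype=float)[-1],
        )
        col = "count" if "count" in frame.columns else "frequency"
        return cls(bin_edges=edges, counts=frame[col].to_numpy(dtype=float))


def predicted_fraction_histogram(
    n_sc: int,
    bin_edges: np.ndarray,
    disp: DispersionParams,
    size_pmf: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted partial-fraction bin probabilities for a candidate N.

    The partial clone-size distribution (quasi-steady neutral law, i.e.
    proportional to N - k, unless ``size_pmf`` is given) is pushed through
    the section observation analytically: each size k contributes the
    truncated-Gaussian mass around k/N falling in each bin.  Mass at or
    below the detection floor is unobservable and removed before
    normalisation.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if size_pmf is None:
        size_pmf = quasi_steady_partial_pmf(DriftParams(n_sc=n_sc, lambda_rate=1.0))
    size_pmf = np.asarray(size_pmf, dtype=float)
    mass = np.zeros(len(bin_edges) - 1)
    for k in range(1, n_sc):
        mu = k / n_sc
        w = size_pmf[k - 1]
        if disp.sigma == 0:
            idx = np.searchsorted(bin_edges, mu, side="left") - 1
            idx = min(max(idx, 0), len(mass) - 1)
            if mu > disp.detection_floor:
                mass[idx] += w
            continue
        z = norm.cdf((bin_edges - mu) / disp.sigma)
        lo = norm.cdf((max(0.0, disp.detection_floor) - mu) / disp.sigma)
        hi = norm.cdf((1.0 - mu) / disp.sigma)
        if hi - lo <= 0:
            continue
        binmass = np.diff(np.clip(z, lo, hi)) / (hi - lo)
        mass += w * binmass
    tot = mass.sum()
    return mass / tot if tot > 0 else mass


@dataclass
class ScanResult:
    """Outcome of the stem-cell-number scan."""

    best_n: int | None
    scores: dict[int, float]
    tied: bool = False
    tied_candidates: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_sc": list(self.scores), "score": list(self.scores.values())}
        )


def scan_sc_number(
    observed_hist: FractionHistogram,
    candidate_ns=range(3, 9),
    disp: DispersionParams = DispersionParams(),
) -> ScanResult:
    """Score candidate effective stem-cell numbers against an observed
    partial-fraction histogram.

    For each candidate N the predicted histogram (quasi-steady size law
    pushed through the observation model) is compared with the observed
    frequencies by the sum of squared differences over common bins above the
    detection floor.  Exact ties are reported explicitly rather than broken
    silently.
    """
    if observed_hist.counts.sum() == 0:
        raise ValueError("empty histogram")
    edges = observed_hist.bin_edges
    usable = edges[1:] > disp.detection_floor
    obs = observed_hist.counts[usable]
    if obs.sum() == 0:
        raise ValueError("histogram has no mass above the detection floor")
    obs = obs / obs.sum()
    scores: dict[int, float] = {}
    for n in candidate_ns:
        pred_all = predicted_fraction_histogram(n, edges, disp)
        pred = pred_all[usable]
        s = pred.sum()
        pred = pred / s if s > 0 else pred
        scores[int(n)] = float(np.sum((pred - obs) ** 2))
    vals = np.array(list(scores.values()))
    best = float(vals.min())
    tied = [n for n, s in scores.items() if s <= best + 1e-12]
    if len(tied) > 1:
        return ScanResult(best_n=None, scores=scores, tied=True, tied_candidates=tied)
    return ScanResult(best_n=tied[0], scores=scores)
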