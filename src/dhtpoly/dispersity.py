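"""Dispersity statistics of length samples and Poisson fitting of label-count
histograms.

The summary statistics are the standard polymer-characterization moments over
a sample of object lengths L_i with multiplicities N_i:

    Ln  = sum(N_i L_i) / sum(N_i)          (number-averaged length)
    Lw  = sum(N_i L_i^2) / sum(N_i L_i)    (weight-averaged length)
    sigma = sqrt( (1/N) sum N_i (L_i - Ln)^2 )   (population form, 1/N)
    PDI = Lw / Ln

Label counts per filament (streptavidin decorations, photobleaching steps)
are fitted by a Poisson law; because a filament with zero labels is invisible
on the surface, the zero-truncated variant solves the truncated likelihood
equation  lambda / (1 - exp(-lambda)) = sample mean  numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .chain_growth import PopulationState

__all__ = [
    "LengthSample",
    "DispersitySummary",
    "LabelHistogram",
    "PoissonFit",
    "dispersity_summary",
    "fit_poisson",
    "label_counts",
    "zero_truncated_poisson_pmf",
]


@dataclass
class LengthSample:
    """Lengths L_i (nm or tile counts) with multiplicities N_i.

    Lengths must be positive; measured objects always are.  allow_zero admits
    zero-length entries for per-initiator-site bookkeeping (a never-initiated
    site has zero tiles) — zeros then enter Eq. 1's denominator only.
    """

    values: np.ndarray
    multiplicities: np.ndarray
    allow_zero: bool = False

    def __init__(
        self,
        values: Sequence[float],
        multiplicities: Optional[Sequence[float]] = None,
        allow_zero: bool = False,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        if multiplicities is None:
            self.multiplicities = np.ones_like(self.values)
        else:
            self.multiplicities = np.asarray(multiplicities, dtype=float)
        self.allow_zero = allow_zero
        if self.values.size == 0:
            raise ValueError("empty length sample")
        if self.values.shape != self.multiplicities.shape:
            raise ValueError("values and multiplicities must align")
        if np.any(self.multiplicities < 0):
            raise ValueError("multiplicities must be >= 0")
        floor = 0.0 if allow_zero else None
        if floor is None and np.any(self.values <= 0):
            raise ValueError("lengths must be > 0")
        if allow_zero and np.any(self.values < 0):
            raise ValueError("lengths must be >= 0")

    @property
    def N(self) -> float:
        return float(self.multiplicities.sum())


@dataclass(frozen=True)
class DispersitySummary:
    Ln: float
    Lw: float
    sigma: float
    PDI: float
    N: float


@dataclass
class LabelHistogram:
    """Map from label count k to observed frequency.

    truncated marks a histogram whose k = 0 class is unobservable (unlabeled
    filaments leave no mark on the surface).
    """

    counts: dict[int, int] = field(default_factory=dict)
    truncated: bool = False

    def __post_init__(self) -> None:
        for k, f in self.counts.items():
            if k < 0 or f < 0:
                raise ValueError("label counts and frequencies must be >= 0")
        if self.truncated and self.counts.get(0, 0) > 0:
            raise ValueError("truncated histogram cannot contain k = 0")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def mean(self) -> float:
        if self.n == 0:
            raise ValueError("empty histogram")
        return sum(k * f for k, f in self.counts.items()) / self.n

    @classmethod
    def from_counts(cls, raw: Sequence[int], truncated: bool = False) -> "LabelHistogram":
        counts: dict[int, int] = {}
        for k in raw:
            k = int(k)
            if truncated and k == 0:
                continue
            counts[k] = counts.get(k, 0) + 1
        return cls(counts=counts, truncated=truncated)


@dataclass(frozen=True)
class PoissonFit:
    lambda_hat: float
    log_likelihood: float
    truncated: bool
    converged: bool = True
    message: str = ""


def dispersity_summary(sample: LengthSample) -> DispersitySummary:
    """Number/weight-averaged lengths, population sigma, and PDI = Lw/Ln."""
    w = sample.multiplicities
    x = sample.values
    N = w.sum()
    if N <= 0:
        raise ValueError("sample has zero total multiplicity")
    wx = float(np.dot(w, x))
    if wx <= 0:
        raise ValueError("sample has zero total length; Lw undefined")
    Ln = wx / N
    Lw = float(np.dot(w, x * x)) / wx
    sigma = math.sqrt(float(np.dot(w, (x - Ln) ** 2)) / N)
    return DispersitySummary(Ln=Ln, Lw=Lw, sigma=sigma, PDI=Lw / Ln, N=float(N))


def zero_truncated_poisson_pmf(k: np.ndarray, lam: float) -> np.ndarray:
    """pmf of a Poisson(lam) conditioned on k >= 1."""
    k = np.asarray(k)
    pmf = stats.poisson.pmf(k, lam) / -math.expm1(-lam)
    return np.where(k >= 1, pmf, 0.0)


def _loglik(hist: LabelHistogram, lam: float) -> float:
    ks = np.array(sorted(hist.counts))
    fs = np.array([hist.counts[k] for k in ks], dtype=float)
    logpmf = stats.poisson.logpmf(ks, lam)
    if hist.truncated:
        logpmf = logpmf - math.log(-math.expm1(-lam))
    return float(np.dot(fs, logpmf))


def fit_poisson(hist: LabelHistogram, tol: float = 1e-8) -> PoissonFit:
    """Maximum-likelihood Poisson fit of a label-count histogram.

    Untruncated: lambda is the weighted sample mean.  Zero-truncated: lambda
    solves  lambda / (1 - exp(-lambda)) = mean  by a bracketed scalar solve to
    *tol*.  A truncated sample with mean at (or below) the minimal support of
    1 sits on the lambda -> 0 boundary; this is reported, not silently
    returned as a fake optimum.
    """
    if hist.n == 0:
        raise ValueError("histogram has no observations")
    m = hist.mean()
    if not hist.truncated:
        if m <= 0:
            raise ValueError("all mass at k = 0: Poisson mean is degenerate")
        lam = m
        return PoissonFit(lam, _loglik(hist, lam), truncated=False)

    if m <= 1.0 + tol:
        return PoissonFit(
            lambda_hat=0.0,
            log_likelihood=float("-inf"),
            truncated=True,
            converged=False,
            message="sample mean at minimal support: lambda at the 0 boundary",
        )
    # lambda/(1-e^-lambda) is increasing from 1; bracket above by the mean.
    f = lambda lam: lam / -math.expm1(-lam) - m
    lo, hi = tol, m
    while f(hi) < 0:  # pragma: no cover - hi = m always brackets
        hi *= 2
    lam = float(optimize.brentq(f, lo, hi, xtol=tol))
    return PoissonFit(lam, _loglik(hist, lam), truncated=True)


def label_counts(
    pop: PopulationState,
    labeling_efficiency: float = 1.0,
    seed: Optional[int] = None,
    truncated: bool = True,
) -> LabelHistogram:
    """Streptavidin/biotin label counts per chain.

    Each A tile carries one biotin; labels per chain are
    Binomial(n_A, efficiency).  With the truncated flag, zero-label chains are
    dropped (they are invisible on the surface).
    """
    if not (0.0 <= labeling_efficiency <= 1.0):
        raise ValueError("labeling efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_A = np.array([c.n_A for c in pop.chains], dtype=int)
    if labeling_efficiency == 1.0:
        labels = n_A
    else:
        labels = rng.binomial(n_A, labeling_efficiency)
    return LabelHistogram.from_counts(labels, truncated=truncated)
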