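"""Equalized-quality ideal distribution and tolerance design.

The ideal distribution ``n*`` (in the spirit of the ideal free distribution)
equalizes the failure probability across all *actively used* goods:
``P_a^F(n_a*) = p*`` for every active good, while goods whose failure
probability exceeds ``p*`` even at vanishing load stay unused (``n_b* = 0``).
The solver is a water-filling bisection on the common level ``p*``.

Tolerance design inverts the problem: which per-good tolerance weights make a
Win-Stay, Lose-Shift population settle on ``n*``?  The attainability
condition is ``sum_k Nu(k) * T_i(k)/sum_j T_j(k) = n_i*``, i.e. the
size-weighted mixture of normalized tolerance rows equals the ideal
occupancies.  For a hybrid population (nonselective type with a flat
tolerance, selective type with designed weights) the selective weights exist
iff the selective fraction ``gamma`` reaches a critical value
``gamma_c = (Nu - Ng * min_i n_i*)/Nu``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .quality import SystemSpec, failure_probability, limiting_failure_probability

__all__ = [
    "IdealDistribution",
    "HybridSpec",
    "ideal_distribution",
    "tolerance_profile_for",
    "verify_tolerance_profile",
    "critical_selective_fraction",
    "hybrid_tolerances",
    "integer_tolerances",
]


class InfeasibleError(ValueError):
    """Raised when no tolerance design can attain the requested distribution."""


@dataclass(frozen=True)
class IdealDistribution:
    """Equalized-quality occupancies and their common failure probability."""

    n_star: np.ndarray
    active: np.ndarray    # indices with n* > 0
    inactive: np.ndarray  # indices with n* = 0
    p_star: float
    n_min: float          # min_i n_i* over all goods (0 if any good is unused)

    @property
    def mean_failure(self) -> float:
        return self.p_star


@dataclass(frozen=True)
class HybridSpec:
    """Two-type hybrid population: nonselective (flat T) + selective weights."""

    gamma: float
    T_nonselective: float
    tol_selective: np.ndarray  # normalized weights on the simplex

    def __post_init__(self) -> None:
        w = np.asarray(self.tol_selective, dtype=float)
        object.__setattr__(self, "tol_selective", w)
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.gamma > 0 and (np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9):
            raise ValueError("selective tolerance weights must lie on the simplex")


def ideal_distribution(system: SystemSpec) -> IdealDistribution:
    """Water-filling solution of the equalized-quality distribution.

    Bisects on the common failure probability ``p``: each good contributes
    the load at which its failure curve reaches ``p`` (zero if its vanishing-
    load failure probability already exceeds ``p``), and ``p*`` is the level
    at which the contributions sum to the population size.
    """
    nu = float(system.nu)
    goods = system.goods
    p0 = np.array([limiting_failure_probability(g, system) for g in goods])

    def pf(i: int, n: float) -> float:
        return failure_probability(goods[i], n, system).p_fail

    p_top = np.array([pf(i, nu) for i in range(len(goods))])

    def load_at(i: int, p: float) -> float:
        if p <= p0[i]:
            return 0.0
        if p >= p_top[i]:
            return nu
        return brentq(lambda n: pf(i, n) - p, 0.0, nu, xtol=1e-12, rtol=1e-14)

    def total(p: float) -> float:
        return sum(load_at(i, p) for i in range(len(goods)))

    lo, hi = float(p0.min()), float(p_top.max())
    if total(hi) < nu - 1e-9:
        raise InfeasibleError("failure curves cannot absorb the population at any common level")
    p_star = brentq(lambda p: total(p) - nu, lo, hi, xtol=1e-16, rtol=1e-15)
    n_star = np.array([load_at(i, p_star) for i in range(len(goods))])
    n_star *= nu / n_star.sum()
    active = np.flatnonzero(n_star > 1e-12 * nu)
    inactive = np.flatnonzero(n_star <= 1e-12 * nu)
    n_star[inactive] = 0.0
    return IdealDistribution(
        n_star=n_star, active=active, inactive=inactive,
        p_star=float(p_star), n_min=float(n_star.min()),
    )


def tolerance_profile_for(
    ideal: IdealDistribution, sizes: Sequence[float]
) -> np.ndarray:
    """Normalized tolerance rows (one per type) attaining ``n*``.

    The attainability condition constrains only the size-weighted mixture of
    the rows, so the constructive solution assigns every type the same
    weights ``n_i*/Nu`` (for a single type this is the unique normalized
    profile).  A good with ``n_i* = 0`` receives zero weight for all types:
    no tolerance to failure there means leaving without submitting requests.
    """
    sizes = np.asarray(sizes, dtype=float)
    nu = ideal.n_star.sum()
    if not np.isclose(sizes.sum(), nu, rtol=1e-9):
        raise ValueError("type sizes must sum to the population size")
    w = ideal.n_star / nu
    if np.any(w < 0):
        i = int(np.argmin(w))
        raise InfeasibleError(f"required weight on good {i} is negative")
    return np.tile(w, (sizes.size, 1))


def verify_tolerance_profile(
    weights: np.ndarray,
    sizes: Sequence[float],
    ideal: IdealDistribution,
    tol: float = 1e-9,
) -> bool:
    """Check an arbitrary profile against the attainability condition.

    ``weights`` rows are normalized internally, so raw tolerance vectors may
    be passed.  Returns True iff
    ``sum_k Nu(k) * w_i(k) = n_i*`` within ``tol`` (absolute, per good).
    """
    sizes = np.asarray(sizes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != sizes.size or w.shape[1] != ideal.n_star.size:
        raise ValueError("weights must have shape (n_types, n_goods)")
    row_sums = w.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("every type needs positive total tolerance")
    mix = sizes @ (w / row_sums)
    return bool(np.all(np.abs(mix - ideal.n_star) <= tol * max(1.0, ideal.n_star.sum())))


def critical_selective_fraction(ideal: IdealDistribution, system: SystemSpec) -> float:
    """Smallest selective fraction for which equalized quality is attainable.

    ``gamma_c = (Nu - Ng * n_min*) / Nu``: below it, the least-used good
    necessarily carries more than its ideal share because the nonselective
    type spreads uniformly.
    """
    nu = float(system.nu)
    gc = (nu - system.ng * ideal.n_min) / nu
    return float(min(max(gc, 0.0), 1.0))


def hybrid_tolerances(
    ideal: IdealDistribution,
    gamma: float,
    system: SystemSpec,
    T_nonselective: float = 5.0,
) -> HybridSpec:
    """Selective tolerance weights for a two-type hybrid population.

    Solves ``(1-gamma) Nu / Ng + gamma Nu w_i = n_i*`` for the selective
    weights ``w``.  Feasible (all ``w_i >= 0``) exactly when
    ``gamma >= gamma_c``; at ``gamma = gamma_c`` the least-used good gets
    weight zero, and at ``gamma = 1`` the weights are ``n_i*/Nu``.
    """
    nu = float(system.nu)
    ng = system.ng
    gc = critical_selective_fraction(ideal, system)
    if gamma < gc - 1e-12:
        raise InfeasibleError(
            f"gamma={gamma:.6g} below the critical selective fraction gamma_c={gc:.6g}: "
            "the least-used good would necessarily exceed its ideal usage"
        )
    if gamma == 0.0:
        # only a perfectly symmetric ideal distribution is attainable (gc = 0)
        w = np.full(ng, 1.0 / ng)
        return HybridSpec(gamma=0.0, T_nonselective=T_nonselective, tol_selective=w)
    w = (ideal.n_star - (1.0 - gamma) * nu / ng) / (gamma * nu)
    w = np.where((w < 0) & (w > -1e-9), 0.0, w)
    if np.any(w < 0):
        i = int(np.argmin(w))
        raise InfeasibleError(f"required selective weight on good {i} is negative")
    return HybridSpec(gamma=float(gamma), T_nonselective=T_nonselective, tol_selective=w)


def integer_tolerances(weights: Sequence[float], total: int = 15) -> np.ndarray:
    """Integer tolerance counts summing to ``total`` (largest-remainder).

    The dynamics constrain only tolerance *ratios*; simulations need integer
    failure counts, obtained by scaling the normalized weights to a total
    budget (default ``Ng * T0 = 15`` for the three-server reference system).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    scaled = w / w.sum() * total
    base = np.floor(scaled).astype(int)
    short = total - base.sum()
    order = np.argsort(-(scaled - base))
    base[order[:short]] += 1
    return base
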