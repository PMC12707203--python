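"""Mean-field population dynamics of Win-Stay, Lose-Shift common-good usage.

With a large population the occupancy ``n_i`` of good ``i`` is treated as
continuous.  Each user attempts to use its current good at rate ``lambda_u``;
a failed attempt makes it shift to one of the other ``Ng - 1`` goods
uniformly at random, giving

    dn_i/dt = -lambda_u n_i P_i^F(n_i) + 1/(Ng-1) * sum_{j != i} lambda_u n_j P_j^F(n_j)

whose equilibrium equalizes the shift fluxes ``n_i P_i^F(n_i)`` across goods.
The typed variant divides each flux by the type's tolerance ``T_i(k)`` (a
user of type ``k`` tolerates ``T_i(k)`` failures on good ``i`` before
shifting, so a random attempt triggers a shift with probability
``P_i^F / T_i(k)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .quality import SystemSpec, failure_probability

__all__ = [
    "PopulationState",
    "TypedPopulation",
    "wsls_rhs",
    "typed_rhs",
    "integrate_trajectory",
    "solve_equilibrium",
    "solve_typed_equilibrium",
    "assert_monotone_failure",
]


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver cannot bracket or verify a solution."""


@dataclass
class PopulationState:
    """Continuous occupancies over the goods, summing to the population size."""

    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if np.any(self.n < -1e-9):
            raise ValueError("occupancies must be nonnegative")

    def validate(self, nu: float, rtol: float = 1e-9) -> None:
        if not np.isclose(self.n.sum(), nu, rtol=rtol):
            raise ValueError(f"occupancies sum to {self.n.sum()}, expected {nu}")


@dataclass
class TypedPopulation:
    """Per-type occupancies ``occ[k, i]`` with tolerance matrix ``tol[k, i]``.

    A zero tolerance on a good means the type never enters it (its occupancy
    there must be zero).
    """

    sizes: np.ndarray  # Nu(k), length Nt
    tol: np.ndarray    # T_i(k), shape (Nt, Ng)
    occ: np.ndarray    # n_ik,   shape (Nt, Ng)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.tol = np.asarray(self.tol, dtype=float)
        self.occ = np.asarray(self.occ, dtype=float)
        if self.tol.shape != self.occ.shape or self.tol.shape[0] != self.sizes.size:
            raise ValueError("inconsistent shapes for sizes/tol/occ")
        if np.any(self.tol < 0):
            raise ValueError("tolerances must be nonnegative")
        bad = (self.tol == 0) & (self.occ > 1e-12)
        if np.any(bad):
            k, i = np.argwhere(bad)[0]
            raise ValueError(f"type {k} occupies good {i} but has zero tolerance there")

    @property
    def totals(self) -> np.ndarray:
        """Total occupancy per good, summed over types."""
        return self.occ.sum(axis=0)


def _fluxes(n: np.ndarray, system: SystemSpec) -> np.ndarray:
    """Shift fluxes lambda_u * n_i * P_i^F(n_i)."""
    p = np.array(
        [failure_probability(g, ni, system).p_fail for g, ni in zip(system.goods, n)]
    )
    return system.lambda_u * n * p


def wsls_rhs(state: PopulationState | np.ndarray, system: SystemSpec) -> np.ndarray:
    """Right-hand side of the single-type WSLS occupancy ODE."""
    n = state.n if isinstance(state, PopulationState) else np.asarray(state, float)
    out = _fluxes(np.maximum(n, 0.0), system)
    ng = n.size
    return -out + (out.sum() - out) / (ng - 1)


def typed_rhs(pop: TypedPopulation, system: SystemSpec) -> np.ndarray:
    """Right-hand side of the typed-tolerance ODE (matrix, types x goods).

    Failure probabilities are evaluated at the *total* occupancy of each
    good.  Goods on which a type has zero tolerance carry no flux for that
    type; the type's inflow is then redistributed uniformly over its own
    supported destinations (such users leave a zero-tolerance good without
    submitting requests, so it is never a destination for them).
    """
    n_tot = np.maximum(pop.totals, 0.0)
    p = np.array(
        [failure_probability(g, ni, system).p_fail for g, ni in zip(system.goods, n_tot)]
    )
    nt, ng = pop.occ.shape
    rates = np.zeros((nt, ng))
    for k in range(nt):
        support = pop.tol[k] > 0
        occk = pop.occ[k]
        if np.any(~support & (occk > 1e-9)):
            i = int(np.argwhere(~support & (occk > 1e-9))[0])
            raise ZeroDivisionError(
                f"type {k} occupies good {i} with zero tolerance: flux undefined"
            )
        out = np.zeros(ng)
        out[support] = system.lambda_u * occk[support] * p[support] / pop.tol[k][support]
        n_dest = support.sum() - 1 if support.sum() < ng else ng - 1
        if n_dest < 1:
            rates[k] = 0.0
            continue
        inflow = np.where(support, (out.sum() - out) / n_dest, 0.0)
        rates[k] = -out + inflow
    return rates


def integrate_trajectory(
    rhs: Callable,
    initial: np.ndarray,
    t_grid: Sequence[float],
    system: SystemSpec,
    schedule: Sequence[tuple[float, float]] | None = None,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Integrate an occupancy ODE over ``t_grid``.

    ``rhs(state_array, system)`` may return a vector (single-type) or a
    matrix (typed); the state is flattened internally.  ``schedule`` is an
    optional list of ``(interval_length, rho)`` pairs defining a
    piecewise-constant workload; integration restarts at each breakpoint so
    the discontinuities are exact.  Occupancies are renormalized to the
    population size at every output sample to suppress integrator drift.

    Returns an array of shape ``(len(t_grid),) + initial.shape``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    y0 = np.asarray(initial, dtype=float)
    shape = y0.shape
    nu = y0.sum()

    if schedule is None:
        segments = [(t_grid[0], t_grid[-1], system)]
    else:
        segments = []
        t0 = t_grid[0]
        for length, rho in schedule:
            segments.append((t0, t0 + length, system.with_rho(rho)))
            t0 += length
        if t0 < t_grid[-1] - 1e-12:
            raise ValueError("schedule does not cover the time grid")

    def flat_rhs(sys_spec):
        def f(_t, y):
            return np.asarray(rhs(y.reshape(shape), sys_spec), float).ravel()
        return f

    out = np.empty((t_grid.size,) + shape)
    y = y0.ravel().copy()
    done = 0
    for (ta, tb, sys_spec) in segments:
        mask = (t_grid >= ta - 1e-12) & (t_grid <= tb + 1e-12)
        t_eval = t_grid[mask]
        # always integrate the full segment so the next one starts at tb
        sol = solve_ivp(
            flat_rhs(sys_spec), (ta, tb), y, method="LSODA",
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol, atol=1e-10 * max(nu, 1.0),
        )
        if not sol.success:
            raise EquilibriumError(f"ODE integration failed near t={sol.t[-1] if sol.t.size else ta}: {sol.message}")
        for j in range(t_eval.size):
            yi = sol.y[:, j].reshape(shape)
            out[done + j] = yi * (nu / yi.sum())
        done += t_eval.size
        # state at segment end
        sol_end = sol.y[:, -1] if (t_eval.size and abs(t_eval[-1] - tb) < 1e-9) else solve_ivp(
            flat_rhs(sys_spec), (ta, tb), y, method="LSODA", rtol=rtol,
            atol=1e-10 * max(nu, 1.0),
        ).y[:, -1]
        y = sol_end * (nu / sol_end.sum())
        if done >= t_grid.size:
            break
    return out


def assert_monotone_failure(system: SystemSpec, grid_points: int = 64) -> None:
    """Check that every good's P_F is nondecreasing on a load grid [0, Nu]."""
    grid = np.linspace(0.0, system.nu, grid_points)
    for idx, g in enumerate(system.goods):
        pf = np.array([failure_probability(g, n, system).p_fail for n in grid])
        if np.any(np.diff(pf) < -1e-10):
            raise EquilibriumError(f"good {idx}: failure probability is not nondecreasing in load")


def _invert_monotone(f: Callable[[float], float], target: float, hi: float) -> float:
    """Leftmost n in [0, hi] with f(n) = target, for nondecreasing f."""
    f0 = f(0.0)
    if target <= f0:
        return 0.0
    fhi = f(hi)
    if target >= fhi:
        return hi
    return brentq(lambda n: f(n) - target, 0.0, hi, xtol=1e-12, rtol=1e-14)


def solve_equilibrium(system: SystemSpec, check_monotone: bool = True) -> PopulationState:
    """Equilibrium of the single-type WSLS dynamics.

    At equilibrium the shift fluxes are equal across goods:
    ``n_1 P_1^F(n_1) = ... = n_Ng P_Ng^F(n_Ng) = phi``.  Each good's
    occupancy is a monotone function of the common value ``phi``, so the
    solver bisects on ``phi`` to match the population constraint
    ``sum_i n_i(phi) = Nu``.
    """
    if check_monotone:
        assert_monotone_failure(system)
    nu = float(system.nu)
    goods = system.goods

    def g(i: int, n: float) -> float:
        return n * failure_probability(goods[i], n, system).p_fail

    g_top = np.array([g(i, nu) for i in range(len(goods))])
    if np.any(g_top <= 0):
        raise EquilibriumError("a good never fails even at full load; equilibrium flux is degenerate")
    phi_hi = g_top.min()

    def total(phi: float) -> float:
        return sum(_invert_monotone(lambda n: g(i, n), phi, nu) for i in range(len(goods)))

    if total(phi_hi) < nu - 1e-9:
        phi = phi_hi  # every good saturates at Nu only jointly; cap
    else:
        phi = brentq(lambda p: total(p) - nu, 0.0, phi_hi, xtol=1e-16, rtol=1e-15)
    n = np.array([_invert_monotone(lambda x: g(i, x), phi, nu) for i in range(len(goods))])
    n *= nu / n.sum()
    state = PopulationState(n)
    fluxes = np.array([g(i, n[i]) for i in range(len(goods))])
    if fluxes.max() - fluxes.min() > 1e-8 * max(fluxes.mean(), 1e-300):
        raise EquilibriumError("equilibrium residual too large; failure curves may be ill-conditioned")
    return state


def solve_typed_equilibrium(
    system: SystemSpec,
    sizes: Sequence[float],
    tol: np.ndarray,
    check_monotone: bool = True,
) -> TypedPopulation:
    """Equilibrium of the typed-tolerance dynamics.

    At equilibrium the per-type split over goods has the closed form
    ``n_ik = Nu(k) * (T_i(k)/P_i^F(n_i)) / sum_j (T_j(k)/P_j^F(n_j))`` with
    ``n_i = sum_k n_ik``.  The solver finds the total occupancies as the root
    of ``n - F(n)`` (population constraint eliminated), started from the
    uniform state, then splits per type by the closed form.
    """
    if check_monotone:
        assert_monotone_failure(system)
    sizes = np.asarray(sizes, dtype=float)
    tol = np.asarray(tol, dtype=float)
    nt, ng = tol.shape
    if sizes.size != nt or ng != system.ng:
        raise ValueError("shape mismatch between sizes/tol and system")
    if not np.isclose(sizes.sum(), system.nu, rtol=1e-9):
        raise ValueError("type sizes must sum to the population size")
    if np.any(tol < 0):
        raise ValueError("tolerances must be nonnegative")
    if np.any(tol.sum(axis=1) == 0):
        raise ValueError("every type needs positive tolerance on at least one good")

    nu = float(system.nu)

    def split(n_tot: np.ndarray) -> np.ndarray:
        p = np.array(
            [failure_probability(g, x, system).p_fail for g, x in zip(system.goods, n_tot)]
        )
        p = np.maximum(p, 1e-300)
        w = tol / p  # (Nt, Ng)
        return sizes[:, None] * w / w.sum(axis=1, keepdims=True)

    def residual(x: np.ndarray) -> np.ndarray:
        n_full = np.concatenate([x, [nu - x.sum()]])
        n_full = np.clip(n_full, 0.0, nu)
        return (n_full - split(n_full).sum(axis=0))[:-1]

    x0 = np.full(ng - 1, nu / ng)
    sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
    n = np.concatenate([sol.x, [nu - sol.x.sum()]])
    if not sol.success or np.any(n < -1e-6) or np.any(n > nu + 1e-6):
        raise EquilibriumError(f"typed equilibrium root-finding failed: {sol.message}")
    n = np.clip(n, 0.0, nu)
    occ = split(n)
    pop = TypedPopulation(sizes=sizes, tol=tol, occ=occ)
    _check_typed_residual(pop, system)
    return pop


def _check_typed_residual(pop: TypedPopulation, system: SystemSpec, rtol: float = 1e-8) -> None:
    """Verify the typed balance: n_ik P_i^F / T_i(k) equal across each type's support."""
    n_tot = pop.totals
    p = np.array(
        [failure_probability(g, x, system).p_fail for g, x in zip(system.goods, n_tot)]
    )
    for k in range(pop.sizes.size):
        sup = pop.tol[k] > 0
        v = pop.occ[k][sup] * p[sup] / pop.tol[k][sup]
        if v.size and (v.max() - v.min()) > rtol * max(v.mean(), 1e-300):
            raise EquilibriumError(f"typed equilibrium residual too large for type {k}")
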