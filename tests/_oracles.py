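"""Independent oracles used by the tests.

Kept deliberately free of the package's analytic machinery: the queue oracle
is a direct single-queue simulation, and the equilibrium oracle is a damped
fixed-point iteration.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from wsls_commons.quality import failure_probability


def mm1k_oracle(mu, k, arrival_rate, t_free, n_arrivals, seed):
    """Monte-Carlo M/M/1/k queue: (p_loss, p_delay, p_fail) estimates + s.e.

    Simulates ``n_arrivals`` Poisson arrivals through a single FCFS
    exponential server with ``k`` total places.  ``t_free`` is the sojourn
    budget (timeout minus network latency); an accepted request is late when
    its sojourn exceeds it.
    """
    rng = np.random.default_rng(seed)
    inter = rng.exponential(1.0 / arrival_rate, n_arrivals)
    svc = rng.exponential(1.0 / mu, n_arrivals)
    arrivals = np.cumsum(inter)
    in_system: deque[float] = deque()  # completion times of requests present
    blocked = late = accepted = 0
    for t, s in zip(arrivals, svc):
        while in_system and in_system[0] <= t:
            in_system.popleft()
        if len(in_system) >= k:
            blocked += 1
            continue
        start = in_system[-1] if in_system else t
        comp = (start if start > t else t) + s
        in_system.append(comp)
        accepted += 1
        if comp - t > t_free:
            late += 1
    n = n_arrivals
    p_loss = blocked / n
    p_delay = late / accepted if accepted else 0.0
    p_fail = (blocked + late) / n
    se = lambda p, m: np.sqrt(max(p * (1 - p), 1e-12) / m)
    return {
        "p_loss": p_loss, "se_loss": se(p_loss, n),
        "p_delay": p_delay, "se_delay": se(p_delay, max(accepted, 1)),
        "p_fail": p_fail, "se_fail": se(p_fail, n),
    }


def fixed_point_equilibrium(system, max_iter=200000, damping=0.2, tol=1e-12):
    """Damped fixed-point iteration for the equal-flux equilibrium.

    Uses the map n_i' ∝ 1 / P_i^F(n_i) (whose fixed points have equal
    fluxes n_i P_i^F) started from the uniform distribution; no bisection or
    inversion involved.
    """
    nu = float(system.nu)
    ng = system.ng
    n = np.full(ng, nu / ng)
    for _ in range(max_iter):
        p = np.array([
            failure_probability(g, x, system).p_fail
            for g, x in zip(system.goods, n)
        ])
        u = 1.0 / np.maximum(p, 1e-300)
        target = nu * u / u.sum()
        new = (1 - damping) * n + damping * target
        if np.max(np.abs(new - n)) < tol * nu:
            return new
        n = new
    raise RuntimeError("fixed-point oracle did not converge")


def latency_corrected_equilibrium(system):
    """Mean-field equilibrium including the failure-detection delay.

    The plain flux-balance equilibrium assumes an agent leaves the instant an
    attempt fails; in the discrete-event system the stay also includes the
    time to *learn* of the failure (round-trip latency, plus the sojourn for
    late responses).  The per-agent departure rate from good i is therefore
    lam*P / (1 + lam*P*D) with D the expected detection delay of the failed
    attempt, computed from the stationary queue law.  Reduces to the plain
    equilibrium as D -> 0.
    """
    from scipy.optimize import brentq
    from scipy.special import gammaincc

    from wsls_commons.quality import stationary_distribution

    lam = system.lambda_u
    nu = float(system.nu)

    def detection_delay(g, n):
        pi = stationary_distribution(g, n * lam)
        acc = pi[:-1] / pi[:-1].sum()
        t = system.tau - system.latency_trips() * g.d
        m = np.arange(1, g.k + 1)          # accepted sojourns are Erlang(j+1, mu)
        p_late_j = gammaincc(m, g.mu * t)
        e_late_j = (m / g.mu) * gammaincc(m + 1, g.mu * t)
        p_late = acc @ p_late_j
        e_late = (acc @ e_late_j) / p_late if p_late > 0 else 0.0
        met = failure_probability(g, n, system)
        w_late = (1 - met.p_loss) * met.p_delay / met.p_fail if met.p_fail > 0 else 0.0
        return 2 * g.d + w_late * e_late

    def eff_flux(i, n):
        g = system.goods[i]
        p = failure_probability(g, n, system).p_fail
        d = detection_delay(g, n)
        return lam * n * p / (1.0 + lam * p * d)

    def invert(i, phi):
        if phi <= 0:
            return 0.0
        return brentq(lambda n: eff_flux(i, n) - phi, 0.0, nu, xtol=1e-10)

    ng = system.ng
    phi_hi = min(eff_flux(i, nu) for i in range(ng))
    phi = brentq(lambda p: sum(invert(i, p) for i in range(ng)) - nu,
                 0.0, phi_hi, xtol=1e-12)
    return np.array([invert(i, phi) for i in range(ng)])
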