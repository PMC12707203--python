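"""Per-good quality models.

A common good here is anything whose per-user failure probability grows with
the number of simultaneous users.  Two concrete models are provided:

* :class:`QueueServerSpec` — a server modelled as an M/M/c/k queue.  A request
  fails either because it is *lost* (it arrives to a full buffer) or because
  it is returned too late to be useful (*excessive delay*: round-trip latency
  plus sojourn time exceeds the timeout ``tau``).  The two failure modes
  compose as ``P_F = P_L + (1 - P_L) * P_D``.
* :class:`GenericGoodSpec` — an arbitrary monotone load → failure-probability
  curve, for commons that are not queueing systems.

The load ``n`` (number of concurrent users) is treated as a continuous
variable so the same formulas serve the mean-field dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.special import gammainc, gammaincc, gammaln

__all__ = [
    "QueueServerSpec",
    "GenericGoodSpec",
    "GoodSpec",
    "SystemSpec",
    "QueueMetrics",
    "loss_probability",
    "excess_delay_probability",
    "failure_probability",
    "limiting_failure_probability",
]


class SpecValidationError(ValueError):
    """Raised when a good or system specification is inconsistent."""


@dataclass(frozen=True)
class QueueServerSpec:
    """An M/M/c/k server: Poisson arrivals, exponential service.

    Parameters
    ----------
    mu : float
        Service capacity of one processor, requests served per second.
    c : int
        Number of processors (each serves one request at a time).
    k : int
        Total number of places in the system (in service + waiting);
        arrivals that find ``k`` requests present are lost.
    d : float
        One-way network latency between user and server, seconds.
    """

    mu: float
    c: int = 1
    k: int = 10
    d: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise SpecValidationError(f"service capacity mu must be > 0, got {self.mu}")
        if int(self.c) != self.c or self.c < 1:
            raise SpecValidationError(f"processor count c must be an integer >= 1, got {self.c}")
        if int(self.k) != self.k or self.k < self.c:
            raise SpecValidationError(f"buffer size k must be an integer >= c, got k={self.k}, c={self.c}")
        if self.d < 0:
            raise SpecValidationError(f"latency d must be >= 0, got {self.d}")


@dataclass(frozen=True)
class GenericGoodSpec:
    """A common good described only by a monotone failure curve.

    ``failure_fn`` maps load ``n >= 0`` to a failure probability in [0, 1];
    it must be nondecreasing (checked on a grid at construction).
    """

    failure_fn: Callable[[float], float]
    check_grid: tuple = field(default=(0.0, 1.0, 10.0, 100.0, 1000.0), compare=False)

    def __post_init__(self) -> None:
        vals = [float(self.failure_fn(n)) for n in self.check_grid]
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise SpecValidationError("failure_fn must map load to [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise SpecValidationError("failure_fn must be nondecreasing in load")


GoodSpec = Union[QueueServerSpec, GenericGoodSpec]


@dataclass(frozen=True)
class SystemSpec:
    """A population of users sharing a set of common goods.

    Exactly one of ``rho`` (system workload, population request rate over
    total capacity) and ``lambda_u`` (per-user request rate, requests/s) is
    given; the other is derived through ``lambda_u = rho * mu_total / nu``.
    For systems of generic goods (no capacities) ``lambda_u`` must be given
    directly.
    """

    goods: tuple
    nu: int
    tau: float
    rho: float | None = None
    lambda_u: float | None = None
    latency_mode: str = "round-trip"  # or "one-way"

    def __post_init__(self) -> None:
        object.__setattr__(self, "goods", tuple(self.goods))
        if len(self.goods) < 2:
            raise SpecValidationError("a system needs at least 2 goods")
        if self.nu < 1:
            raise SpecValidationError("population size nu must be >= 1")
        if not self.tau > 0:
            raise SpecValidationError("timeout tau must be > 0")
        if self.latency_mode not in ("round-trip", "one-way"):
            raise SpecValidationError(f"unknown latency_mode {self.latency_mode!r}")
        if (self.rho is None) == (self.lambda_u is None):
            raise SpecValidationError("give exactly one of rho / lambda_u")
        if self.rho is not None:
            object.__setattr__(self, "lambda_u", self.rho * self.mu_total / self.nu)
        else:
            mu = self.mu_total
            object.__setattr__(self, "rho", self.nu * self.lambda_u / mu if mu > 0 else None)
        if self.lambda_u < 0:
            raise SpecValidationError("lambda_u must be >= 0")

    @property
    def ng(self) -> int:
        return len(self.goods)

    @property
    def mu_total(self) -> float:
        """Total service capacity (sum of mu over queue-server goods)."""
        mu = sum(g.mu for g in self.goods if isinstance(g, QueueServerSpec))
        if mu == 0 and self.lambda_u is None:
            raise SpecValidationError("rho given but system has no capacity; give lambda_u")
        return mu

    def with_rho(self, rho: float) -> "SystemSpec":
        return SystemSpec(self.goods, self.nu, self.tau, rho=rho,
                          latency_mode=self.latency_mode)

    def latency_trips(self) -> int:
        return 2 if self.latency_mode == "round-trip" else 1


@dataclass(frozen=True)
class QueueMetrics:
    """Failure decomposition of one good at one load level."""

    p_loss: float
    p_delay: float
    p_fail: float
    quality: float

    @classmethod
    def compose(cls, p_loss: float, p_delay: float) -> "QueueMetrics":
        p_fail = p_loss + (1.0 - p_loss) * p_delay
        return cls(p_loss=p_loss, p_delay=p_delay, p_fail=p_fail, quality=1.0 - p_fail)


def _log_stationary_weights(a: float, c: int, k: int) -> np.ndarray:
    """Unnormalized log-weights of the M/M/c/k birth-death stationary law.

    pi_j ∝ a^j/j!              for j <= c
    pi_j ∝ a^c/c! (a/c)^(j-c)  for j > c,   a = arrival rate / mu.
    """
    j = np.arange(k + 1, dtype=float)
    if a == 0:
        return np.where(j == 0, 0.0, -np.inf)
    loga = math.log(a)
    return np.where(
        j <= c,
        j * loga - gammaln(j + 1),
        c * loga - gammaln(c + 1.0) + (j - c) * (loga - math.log(c)),
    )


def stationary_distribution(spec: QueueServerSpec, arrival_rate: float) -> np.ndarray:
    """Stationary distribution over 0..k requests in system."""
    if arrival_rate < 0:
        raise ValueError("arrival rate must be >= 0")
    a = arrival_rate / spec.mu
    logw = _log_stationary_weights(a, spec.c, spec.k)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def loss_probability(spec: QueueServerSpec, n: float, lambda_u: float) -> float:
    """Stationary blocking probability with aggregate arrival rate ``n * lambda_u``."""
    if n < 0 or lambda_u < 0:
        raise ValueError("load and per-user rate must be >= 0")
    if n * lambda_u == 0:
        return 0.0
    return float(stationary_distribution(spec, n * lambda_u)[-1])


def _sojourn_tail(spec: QueueServerSpec, j: int, t: float) -> float:
    """P(sojourn > t) for an accepted arrival that finds j in the system.

    For c = 1 the sojourn is Erlang(j+1, mu).  For c > 1 and j >= c it is the
    sum of an Erlang(j-c+1, c*mu) wait and an Exp(mu) service, whose tail has
    the closed form below (valid because c*mu > mu).
    """
    mu, c = spec.mu, spec.c
    if j < c:
        return float(np.exp(-mu * t))
    if c == 1:
        return float(gammaincc(j + 1, mu * t))
    m = j - c + 1
    nu = c * mu
    r = nu / (nu - mu)
    return float(gammaincc(m, nu * t) + math.exp(-mu * t) * r**m * gammainc(m, (nu - mu) * t))


def excess_delay_probability(
    spec: QueueServerSpec, n: float, lambda_u: float, tau: float, trips: int = 2
) -> float:
    """Probability that an accepted request returns later than ``tau``.

    The return delay is ``trips * d`` of network latency plus the sojourn
    (queueing wait + service).  PASTA: an accepted Poisson arrival sees the
    stationary distribution conditioned on not being blocked.
    """
    if not tau > 0:
        raise ValueError("tau must be > 0")
    if n < 0 or lambda_u < 0:
        raise ValueError("load and per-user rate must be >= 0")
    t = tau - trips * spec.d
    if t <= 0:
        return 1.0
    if not math.isfinite(t):
        return 0.0
    pi = stationary_distribution(spec, n * lambda_u)
    acc = pi[:-1]
    s = acc.sum()
    if s <= 0:  # blocked with probability one: no accepted arrivals
        return 0.0
    acc = acc / s
    tails = np.array([_sojourn_tail(spec, j, t) for j in range(spec.k)])
    return float(np.clip(acc @ tails, 0.0, 1.0))


def failure_probability(spec: GoodSpec, n: float, system: SystemSpec) -> QueueMetrics:
    """Full failure decomposition of one good at load ``n``.

    Queue servers compose loss and excessive delay as
    ``P_F = P_L + (1 - P_L) P_D``; generic goods report their curve directly
    (all failure attributed to the loss channel).
    """
    if isinstance(spec, GenericGoodSpec):
        p = float(np.clip(spec.failure_fn(n), 0.0, 1.0))
        return QueueMetrics(p_loss=p, p_delay=0.0, p_fail=p, quality=1.0 - p)
    p_l = loss_probability(spec, n, system.lambda_u)
    p_d = excess_delay_probability(spec, n, system.lambda_u, system.tau, system.latency_trips())
    return QueueMetrics.compose(p_l, p_d)


def limiting_failure_probability(spec: GoodSpec, system: SystemSpec) -> float:
    """Failure probability in the limit of vanishing load, lim n→0+ P_F(n).

    For a queue server this is the probability that a single isolated request
    is late: P(trips*d + Exp(mu) > tau).  It is the threshold deciding
    whether a good can belong to the active set of the equalized-quality
    ideal distribution.
    """
    if isinstance(spec, GenericGoodSpec):
        return float(np.clip(spec.failure_fn(0.0), 0.0, 1.0))
    t = system.tau - system.latency_trips() * spec.d
    if t <= 0:
        return 1.0
    return float(math.exp(-spec.mu * t))


def failure_curve(
    spec: GoodSpec, loads: Sequence[float], system: SystemSpec
) -> np.ndarray:
    """Vector of P_F over a grid of loads (convenience for solvers/plots)."""
    return np.array([failure_probability(spec, n, system).p_fail for n in loads])
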