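"""Discrete-event agent-based simulation of Win-Stay, Lose-Shift users.

Each of the ``Nu`` agents emits an open-loop Poisson stream of service
requests (rate ``lambda_u``) to its currently chosen server.  A request
travels the one-way latency ``d_i``, is blocked if the buffer is full (a
*loss* failure, learned by the agent after the return latency), otherwise is
served FCFS by one of ``c_i`` exponential processors; an accepted response is
an *excessive delay* failure when its return delay exceeds the timeout
``tau``.  When an agent's failure count on its current server reaches its
tolerance there, it shifts to another server and resets the counter.

Two strategy modes:

* ``fixed`` — a constant per-good tolerance vector (tolerance 1 is the plain
  Win-Stay, Lose-Shift rule: shift on every failure).
* ``adaptive`` — each agent keeps a per-good tolerance vector (initialized at
  ``T0``, total budget ``Ng*T0`` conserved) and a per-good failure-rate
  estimate (initialized at ``x0``).  At each shift it updates the estimate of
  the good it leaves from the experienced rate ``T/R`` (exponential smoothing
  with learning rate ``beta``) and moves one tolerance unit from that good to
  the good with the lowest estimate, when that estimate is strictly lower and
  a unit can be spared.

Identical configurations (including the seed) produce bit-identical output:
the event queue orders ties by insertion sequence and all randomness flows
from one seeded generator consumed in event order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .quality import QueueServerSpec, SystemSpec

__all__ = [
    "SimConfig",
    "AgentState",
    "TimeSeries",
    "SteadyStateSummary",
    "run_simulation",
    "update_estimate",
    "update_tolerance",
    "shift_destination",
    "summarize_steady_state",
]

# event kinds
_EMIT, _ARRIVE, _DEPART, _RESPOND, _BREAK = 0, 1, 2, 3, 4


@dataclass
class AgentState:
    """Strategy state of one agent (exposed for inspection and tests)."""

    good: int
    fail_count: int = 0
    attempts: int = 0                     # R: usage attempts since last shift
    tol: np.ndarray | None = None         # per-good tolerance (adaptive)
    est: np.ndarray | None = None         # per-good failure-probability estimate


@dataclass
class SimConfig:
    """Fully specified, seeded simulation run."""

    system: SystemSpec
    duration: float
    seed: int = 0
    mode: str = "fixed"                       # "fixed" | "adaptive"
    tolerance: float | Sequence[float] = 1    # fixed mode: scalar or per-good
    T0: int = 5
    x0: float = 0.0
    beta: float = 0.1
    shift_rule: str = "uniform"               # "uniform" | "proportional"
    schedule: Sequence[tuple[float, float]] | None = None  # (length, rho)
    sample_dt: float = 1.0
    initial_assignment: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.shift_rule not in ("uniform", "proportional"):
            raise ValueError(f"unknown shift_rule {self.shift_rule!r}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if int(self.T0) != self.T0 or self.T0 < 1:
            raise ValueError("T0 must be an integer >= 1")
        if self.system.ng < 2:
            raise ValueError("shifting needs at least 2 goods")
        if not all(isinstance(g, QueueServerSpec) for g in self.system.goods):
            raise ValueError("the discrete-event simulator needs queue-server goods")
        if self.schedule is not None:
            total = sum(length for length, _ in self.schedule)
            if total < self.duration - 1e-9:
                raise ValueError("schedule intervals must cover the duration")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")
        if self.initial_assignment is not None:
            init = np.asarray(self.initial_assignment, dtype=int)
            if init.size != self.system.nu or init.min() < 0 or init.max() >= self.system.ng:
                raise ValueError("initial_assignment must give a valid good per agent")


@dataclass
class TimeSeries:
    """Sampled trajectories of one run (one row per sampling window)."""

    t: np.ndarray
    occupancy: np.ndarray   # (samples, Ng) agents assigned per good at window end
    fail_rate: np.ndarray   # (samples, Ng) failures/attempts within the window
    sys_fail: np.ndarray    # (samples,) system-level failures/attempts
    mean_tol: np.ndarray    # (samples, Ng) population-mean tolerance per good
    attempts: np.ndarray    # (samples, Ng) usage attempts within the window

    def to_dataframe(self) -> pd.DataFrame:
        ng = self.occupancy.shape[1]
        data = {"t": self.t}
        for i in range(ng):
            data[f"n_{i + 1}"] = self.occupancy[:, i]
        for i in range(ng):
            data[f"fail_{i + 1}"] = self.fail_rate[:, i]
        data["fail_sys"] = self.sys_fail
        for i in range(ng):
            data[f"meanT_{i + 1}"] = self.mean_tol[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SteadyStateSummary:
    """Trailing-window summary of a run (see :func:`summarize_steady_state`)."""

    sys_fail: float
    per_good_fail: np.ndarray
    fail_range: float
    occupancy_mean: np.ndarray
    occupancy_cv: np.ndarray
    window: float
    tail_fraction: float


def update_estimate(est_i: float, tol_i: int, attempts: int, beta: float) -> float:
    """Smoothed failure-probability estimate after one stay.

    The experienced failure rate of the stay is ``tol_i / attempts`` (the
    stay ends at the ``tol_i``-th failure out of ``attempts`` usage
    attempts); the new estimate blends it with the previous one:
    ``(1 - beta) * est + beta * tol_i / attempts``.
    """
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    if tol_i < 1 or attempts < tol_i:
        raise ValueError(f"inconsistent stay: {tol_i} failures in {attempts} attempts")
    return (1.0 - beta) * est_i + beta * tol_i / attempts


def update_tolerance(
    tol: np.ndarray, est: np.ndarray, i: int, rng: np.random.Generator
) -> np.ndarray:
    """Move one tolerance unit from the good being left to the best estimate.

    With ``l = argmin_j est_j`` (ties broken uniformly at random), a unit
    moves from ``i`` to ``l`` iff ``est_l < est_i`` strictly and ``tol_i > 1``;
    otherwise the vector is returned unchanged.  The total is conserved.
    """
    tol = np.asarray(tol).copy()
    est = np.asarray(est, dtype=float)
    if tol.shape != est.shape:
        raise ValueError("tol and est must have the same length")
    m = est.min()
    candidates = np.flatnonzero(est == m)
    l = int(candidates[rng.integers(candidates.size)]) if candidates.size > 1 else int(candidates[0])
    if est[l] < est[i] and tol[i] > 1:
        tol[i] -= 1
        tol[l] += 1
    return tol


def shift_destination(
    good: int,
    ng: int,
    rule: str,
    rng: np.random.Generator,
    tol: np.ndarray | None = None,
) -> int:
    """Choose the next good, never the current one.

    ``uniform``: equal probability over the other ``ng - 1`` goods.
    ``proportional``: probability proportional to the tolerance of each other
    good; zero-tolerance goods are never chosen.
    """
    if ng < 2:
        raise ValueError("need at least 2 goods to shift")
    if rule == "uniform":
        j = int(rng.integers(ng - 1))
        return j + 1 if j >= good else j
    if rule != "proportional":
        raise ValueError(f"unknown shift rule {rule!r}")
    w = np.asarray(tol, dtype=float).copy()
    w[good] = 0.0
    s = w.sum()
    if s <= 0:
        raise ValueError("all other goods have zero tolerance weight")
    cum = np.cumsum(w / s)
    return int(np.searchsorted(cum, rng.random(), side="right"))


class _ExpPool:
    """Buffered standard-exponential draws from one generator."""

    __slots__ = ("rng", "buf", "i", "block")

    def __init__(self, rng: np.random.Generator, block: int = 1 << 16):
        self.rng = rng
        self.block = block
        self.buf = rng.standard_exponential(block)
        self.i = 0

    def next(self) -> float:
        i = self.i
        if i >= self.block:
            self.buf = self.rng.standard_exponential(self.block)
            i = 0
        self.i = i + 1
        return self.buf[i]


def run_simulation(config: SimConfig, return_state: bool = False):
    """Run one seeded discrete-event simulation.

    Returns a :class:`TimeSeries`; with ``return_state=True`` also returns
    the list of final :class:`AgentState` objects.
    """
    system = config.system
    ng = system.ng
    nu = system.nu
    goods = system.goods
    mu = [g.mu for g in goods]
    dd = [g.d for g in goods]
    kk = [g.k for g in goods]
    cc = [g.c for g in goods]
    tau = system.tau
    trips = system.latency_trips()
    adaptive = config.mode == "adaptive"

    rng = np.random.default_rng(config.seed)
    pool = _ExpPool(rng)

    # strategy state
    if config.initial_assignment is not None:
        good = np.asarray(config.initial_assignment, dtype=int).tolist()
    else:
        good = rng.integers(ng, size=nu).tolist()
    fail = [0] * nu
    attempts = [0] * nu
    stay = [0] * nu          # per-agent stay epoch; outcomes of older stays are discarded
    if adaptive:
        tol = np.full((nu, ng), int(config.T0), dtype=np.int64)
        est = np.full((nu, ng), float(config.x0))
        tol_colsum = tol.sum(axis=0).astype(float)   # for mean-tolerance sampling
        fixed_tol = None
    else:
        ft = np.asarray(config.tolerance, dtype=float)
        fixed_tol = (np.full(ng, float(ft)) if ft.ndim == 0 else ft.copy())
        if fixed_tol.size != ng or np.any(fixed_tol < 1):
            raise ValueError("fixed tolerance must be >= 1 per good")
        tol = est = None
        tol_colsum = fixed_tol * nu

    # per-server queue state: number in system and processor free-times
    in_sys = [0] * ng
    free = [[0.0] * c for c in cc]  # maintained as small heaps when c > 1

    # workload schedule -> piecewise-constant per-user rate
    if config.schedule is not None:
        seg_lam = [system.with_rho(rho).lambda_u for _, rho in config.schedule]
        seg_t = np.concatenate([[0.0], np.cumsum([L for L, _ in config.schedule])])
    else:
        seg_lam = [system.lambda_u]
        seg_t = np.array([0.0, config.duration])

    heap: list[tuple] = []
    seq = 0
    occ_count = [0] * ng
    for g_idx in good:
        occ_count[g_idx] += 1

    lam = seg_lam[0]
    gen = 0  # emission generation, bumped at workload breakpoints

    def push(t, kind, a=0, b=0, c=0, d=0.0):
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, a, b, c, d))
        seq += 1

    if lam > 0:
        inv = 1.0 / lam
        for h in range(nu):
            push(pool.next() * inv, _EMIT, h, gen)
    for idx in range(1, len(seg_lam)):
        if seg_t[idx] < config.duration:
            push(float(seg_t[idx]), _BREAK, idx)

    # sampling state
    duration = config.duration
    sample_dt = config.sample_dt
    n_samples = int(math.floor(duration / sample_dt + 1e-9))
    s_t = np.empty(n_samples)
    s_occ = np.empty((n_samples, ng))
    s_frate = np.zeros((n_samples, ng))
    s_sys = np.zeros(n_samples)
    s_mtol = np.empty((n_samples, ng))
    s_att = np.zeros((n_samples, ng))
    w_att = [0] * ng
    w_fail = [0] * ng
    s_idx = 0
    next_sample = sample_dt

    def flush_sample():
        nonlocal s_idx, next_sample, w_att, w_fail
        s_t[s_idx] = next_sample
        s_occ[s_idx] = occ_count
        ta = sum(w_att)
        tf = sum(w_fail)
        for g_ in range(ng):
            s_frate[s_idx, g_] = (w_fail[g_] / w_att[g_]) if w_att[g_] else 0.0
            s_att[s_idx, g_] = w_att[g_]
        s_sys[s_idx] = (tf / ta) if ta else 0.0
        s_mtol[s_idx] = tol_colsum
        w_att = [0] * ng
        w_fail = [0] * ng
        s_idx += 1
        next_sample += sample_dt

    uniform_shift = config.shift_rule == "uniform"

    while heap:
        t, _, kind, a, b, c, d = heapq.heappop(heap)
        if t > duration:
            break
        while t > next_sample and s_idx < n_samples:
            flush_sample()

        if kind == _EMIT:
            h = a
            if b != gen:
                continue  # stale emission from before a workload change
            gi = good[h]
            push(t + dd[gi], _ARRIVE, h, gi, stay[h], t)
            push(t + pool.next() / lam, _EMIT, h, gen)

        elif kind == _ARRIVE:
            h, gi, sep, t_emit = a, b, c, d
            if in_sys[gi] >= kk[gi]:
                # loss: agent learns after the return latency
                push(t + dd[gi], _RESPOND, h, gi, sep + (1 << 32), t)
                continue
            in_sys[gi] += 1
            fr = free[gi]
            if cc[gi] == 1:
                start = fr[0] if fr[0] > t else t
                comp = start + pool.next() / mu[gi]
                fr[0] = comp
            else:
                earliest = min(fr)
                start = earliest if earliest > t else t
                comp = start + pool.next() / mu[gi]
                fr[fr.index(earliest)] = comp
            push(comp, _DEPART, gi)
            delay = comp + dd[gi] - t_emit if trips == 2 else comp - t_emit
            late = delay > tau
            push(comp + dd[gi], _RESPOND, h, gi, sep + ((1 << 32) if late else 0), t_emit)

        elif kind == _DEPART:
            in_sys[a] -= 1

        elif kind == _RESPOND:
            h, gi = a, b
            failed = c >= (1 << 32)
            sep = c & ((1 << 32) - 1)
            w_att[gi] += 1
            if failed:
                w_fail[gi] += 1
            if sep != stay[h] or gi != good[h]:
                continue  # outcome of a previous stay: metrics only
            attempts[h] += 1
            if not failed:
                continue
            fail[h] += 1
            limit = tol[h, gi] if adaptive else fixed_tol[gi]
            if fail[h] < limit:
                continue
            # tolerance reached: adapt (if adaptive), then shift
            if adaptive:
                est[h, gi] = update_estimate(est[h, gi], int(tol[h, gi]), attempts[h], config.beta)
                old = tol[h].copy()
                tol[h] = update_tolerance(tol[h], est[h], gi, rng)
                if tol[h, gi] != old[gi]:
                    tol_colsum += tol[h] - old
            dest = shift_destination(
                gi, ng, config.shift_rule if not uniform_shift else "uniform", rng,
                tol[h] if adaptive else fixed_tol,
            )
            occ_count[gi] -= 1
            occ_count[dest] += 1
            good[h] = dest
            stay[h] += 1
            fail[h] = 0
            attempts[h] = 0

        else:  # _BREAK: workload change
            gen += 1
            lam = seg_lam[a]
            if lam > 0:
                inv = 1.0 / lam
                for h in range(nu):
                    push(t + pool.next() * inv, _EMIT, h, gen)

    while s_idx < n_samples:
        flush_sample()

    ts = TimeSeries(
        t=s_t,
        occupancy=s_occ,
        fail_rate=s_frate,
        sys_fail=s_sys,
        mean_tol=s_mtol / nu,
        attempts=s_att,
    )
    if not return_state:
        return ts
    agents = [
        AgentState(
            good=good[h], fail_count=fail[h], attempts=attempts[h],
            tol=tol[h].copy() if adaptive else fixed_tol.copy(),
            est=est[h].copy() if adaptive else None,
        )
        for h in range(nu)
    ]
    return ts, agents


def summarize_steady_state(
    ts: TimeSeries,
    tail_fraction: float = 0.1,
    smooth: float = 0.01,
    cv_window: float = 2000.0,
) -> SteadyStateSummary:
    """Steady-state summary of a run.

    The system failure-probability series is low-pass filtered with an
    exponential smoother (``y_t = (1 - smooth) y_{t-1} + smooth x_t``,
    ``smooth = 1`` disables filtering) and averaged over the trailing
    ``tail_fraction`` of samples.  Per-good occupancy and failure-rate means
    and coefficients of variation are computed over the trailing
    ``cv_window`` seconds.
    """
    if not (0.0 < tail_fraction <= 1.0):
        raise ValueError("tail_fraction must lie in (0, 1]")
    if not (0.0 < smooth <= 1.0):
        raise ValueError("smooth must lie in (0, 1]")
    n = ts.sys_fail.size
    if n == 0:
        raise ValueError("empty time series")
    if smooth == 1.0:
        y = ts.sys_fail.astype(float)
    else:
        y = np.empty(n)
        y[0] = ts.sys_fail[0]
        om = 1.0 - smooth
        for i in range(1, n):
            y[i] = om * y[i - 1] + smooth * ts.sys_fail[i]
    m = max(1, int(math.ceil(tail_fraction * n)))
    steady = float(y[-m:].mean())

    w = ts.t > ts.t[-1] - cv_window
    if not np.any(w):
        raise ValueError("empty trailing window")
    occ = ts.occupancy[w]
    fr = ts.fail_rate[w]
    occ_mean = occ.mean(axis=0)
    occ_std = occ.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        occ_cv = np.where(occ_mean > 0, occ_std / occ_mean, 0.0)
    pg = fr.mean(axis=0)
    return SteadyStateSummary(
        sys_fail=steady,
        per_good_fail=pg,
        fail_range=float(pg.max() - pg.min()),
        occupancy_mean=occ_mean,
        occupancy_cv=occ_cv,
        window=float(cv_window),
        tail_fraction=float(tail_fraction),
    )
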