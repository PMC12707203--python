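"""Discrete-event simulator: learning rules, determinism, queue fidelity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wsls_commons import (
    QueueServerSpec,
    SimConfig,
    SystemSpec,
    loss_probability,
    failure_probability,
    run_simulation,
    scale_system,
    shift_destination,
    summarize_steady_state,
    update_estimate,
    update_tolerance,
)
from wsls_commons.simulator import TimeSeries


@pytest.fixture(scope="module")
def small_system(table1_system):
    return scale_system(table1_system, 0.1)


# ---------------------------------------------------------------- learning rules

def test_estimate_update_examples():
    assert update_estimate(0.0, 5, 50, beta=0.1) == pytest.approx(0.01)
    # experienced rate equal to the estimate is a fixed point
    assert update_estimate(0.1, 5, 50, beta=0.3) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        update_estimate(0.0, 5, 4, beta=0.1)  # fewer attempts than failures


def test_estimate_converges_geometrically():
    beta, target, x = 0.1, 5 / 40, 0.7
    xs = [x]
    for _ in range(25):
        xs.append(update_estimate(xs[-1], 5, 40, beta))
    m = np.arange(26)
    assert np.allclose(np.abs(np.array(xs) - target),
                       (1 - beta) ** m * abs(0.7 - target), atol=1e-12)


def test_tolerance_transfer_examples():
    rng = np.random.default_rng(0)
    out = update_tolerance([5, 5, 5], [0.10, 0.02, 0.05], 0, rng)
    assert list(out) == [4, 6, 5]
    # a good never gives away its last unit
    assert list(update_tolerance([1, 5, 9], [0.10, 0.02, 0.05], 0, rng)) == [1, 5, 9]
    # no strictly better estimate: no move
    assert list(update_tolerance([5, 5, 5], [0.02, 0.02, 0.05], 0, rng)) == [5, 5, 5]


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    tol=st.lists(st.integers(1, 13), min_size=3, max_size=3),
    est=st.lists(st.floats(0, 1), min_size=3, max_size=3),
    i=st.integers(0, 2),
)
def test_tolerance_transfer_conserves_budget(tol, est, i):
    rng = np.random.default_rng(1)
    out = update_tolerance(tol, est, i, rng)
    assert out.sum() == sum(tol)
    assert np.all(out >= 1) or np.any(np.asarray(tol) < 1)


def test_shift_destination_two_goods():
    rng = np.random.default_rng(2)
    assert all(shift_destination(0, 2, "uniform", rng) == 1 for _ in range(20))
    assert shift_destination(1, 2, "uniform", rng) == 0


def test_shift_destination_uniform_frequencies():
    from scipy.stats import chisquare

    rng = np.random.default_rng(3)
    draws = np.array([shift_destination(1, 4, "uniform", rng) for _ in range(100_000)])
    assert 1 not in draws
    counts = np.bincount(draws, minlength=4)[[0, 2, 3]]
    assert chisquare(counts).pvalue > 0.01


def test_shift_destination_proportional():
    rng = np.random.default_rng(4)
    tol = np.array([3.0, 0.0, 4.0])
    draws = [shift_destination(1, 3, "proportional", rng, tol=np.array([2.0, 5.0, 0.0]))
             for _ in range(500)]
    assert 2 not in draws and 1 not in draws  # zero weight / current good never chosen
    draws = np.array([shift_destination(1, 3, "proportional", rng, tol=tol)
                      for _ in range(30_000)])
    frac0 = (draws == 0).mean()
    assert frac0 == pytest.approx(3 / 7, abs=0.02)
    with pytest.raises(ValueError):
        shift_destination(0, 2, "proportional", rng, tol=np.array([5.0, 0.0]))


# ---------------------------------------------------------------- full runs

def test_zero_workload_is_static(small_system):
    system = small_system.with_rho(0.0)
    cfg = SimConfig(system=system, duration=50.0, seed=7, mode="fixed", tolerance=1)
    ts = run_simulation(cfg)
    assert np.all(ts.occupancy == ts.occupancy[0])
    assert np.all(ts.fail_rate == 0.0) and np.all(ts.sys_fail == 0.0)


def test_identical_seeds_identical_output(small_system):
    cfg = dict(system=small_system, duration=150.0, seed=11, mode="adaptive")
    a = run_simulation(SimConfig(**cfg))
    b = run_simulation(SimConfig(**cfg))
    for field in ("t", "occupancy", "fail_rate", "sys_fail", "mean_tol"):
        assert np.array_equal(getattr(a, field), getattr(b, field))
    c = run_simulation(SimConfig(**{**cfg, "seed": 12}))
    assert not np.array_equal(a.occupancy, c.occupancy)


def test_population_conserved_every_sample(small_system):
    cfg = SimConfig(system=small_system, duration=300.0, seed=5, mode="fixed", tolerance=1)
    ts = run_simulation(cfg)
    assert np.all(ts.occupancy.sum(axis=1) == small_system.nu)
    assert np.all((ts.fail_rate >= 0) & (ts.fail_rate <= 1))
    assert np.all((ts.sys_fail >= 0) & (ts.sys_fail <= 1))


def test_adaptive_tolerance_budget_invariant(small_system):
    """Each agent's tolerance budget stays at Ng*T0 with components in [1, 13]."""
    cfg = SimConfig(system=small_system, duration=600.0, seed=13, mode="adaptive", T0=5)
    ts, agents = run_simulation(cfg, return_state=True)
    tols = np.array([a.tol for a in agents])
    assert np.all(tols.sum(axis=1) == 15)
    assert tols.min() >= 1 and tols.max() <= 13
    # population totals per good also sum to Ng*T0 at every sample
    assert np.allclose(ts.mean_tol.sum(axis=1), 15.0, atol=1e-9)
    assert (tols != 5).any(), "learning never moved any tolerance"


def test_pinned_agents_reproduce_queue_analytics(table1_system):
    """With shifting disabled, one server's empirical failure rate matches
    the analytic M/M/1/k value at the pinned load (3 s.e. of the run-to-run
    spread: within one run, queue outcomes are autocorrelated, so the spread
    across independent seeds is the honest error scale)."""
    server = QueueServerSpec(mu=20.0, c=1, k=10, d=0.05)
    other = QueueServerSpec(mu=20.0, c=1, k=10, d=0.05)
    system = SystemSpec(goods=(server, other), nu=60, tau=0.5, lambda_u=0.4)
    vals = []
    for seed in (21, 22, 23, 24):
        cfg = SimConfig(
            system=system, duration=4000.0, seed=seed, mode="fixed",
            tolerance=1e12, initial_assignment=[0] * 60,
        )
        ts = run_simulation(cfg)
        n_att = ts.attempts[:, 0].sum()
        vals.append((ts.fail_rate[:, 0] * ts.attempts[:, 0]).sum() / n_att)
    vals = np.array(vals)
    ana = failure_probability(server, 60.0, system)
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - ana.p_fail) <= 3 * se
    assert ana.p_loss == pytest.approx(loss_probability(server, 60.0, 0.4))


def test_fixed_tolerance_steady_state_matches_equilibrium(small_system):
    """Plain WSLS (tolerance 1) holds the occupancies at the mean-field
    equilibrium once started there."""
    from wsls_commons import solve_equilibrium
    from wsls_commons.ideal import integer_tolerances

    eq = solve_equilibrium(small_system)
    counts = integer_tolerances(eq.n / small_system.nu, total=small_system.nu)
    init = np.repeat(np.arange(3), counts)
    tails = []
    for seed in range(4):
        cfg = SimConfig(system=small_system, duration=2000.0, seed=seed,
                        mode="fixed", tolerance=1, initial_assignment=init)
        ts = run_simulation(cfg)
        tails.append(ts.occupancy[ts.t > 1000].mean(axis=0))
    tails = np.array(tails)
    se = tails.std(axis=0, ddof=1) / np.sqrt(len(tails))
    assert np.all(np.abs(tails.mean(axis=0) - eq.n) <= 3 * se + 1.0)


def test_adaptive_equalizes_failure_better_than_fixed(table1_system):
    """Adaptive tolerance shrinks the cross-server spread of failure
    probabilities relative to a flat fixed tolerance."""
    system = scale_system(table1_system, 0.2)
    runs = {}
    for mode, tol in (("fixed", 5), ("adaptive", None)):
        cfg = SimConfig(system=system, duration=6000.0, seed=3, mode=mode,
                        tolerance=tol if tol else 1)
        runs[mode] = summarize_steady_state(run_simulation(cfg))
    assert runs["adaptive"].fail_range < runs["fixed"].fail_range


def test_workload_schedule_changes_traffic(small_system):
    cfg = SimConfig(
        system=small_system, duration=600.0, seed=9, mode="fixed", tolerance=1,
        schedule=[(200.0, 0.25), (200.0, 1.25), (200.0, 0.25)],
    )
    ts = run_simulation(cfg)
    assert np.all(ts.occupancy.sum(axis=1) == small_system.nu)
    lam = small_system.mu_total / small_system.nu  # per-user rate at rho=1
    att = ts.attempts.sum(axis=1)
    low = att[(ts.t > 50) & (ts.t <= 200)].mean()
    high = att[(ts.t > 250) & (ts.t <= 400)].mean()
    assert high / low == pytest.approx(5.0, rel=0.15)
    # failures concentrate in the overloaded phase
    assert ts.sys_fail[(ts.t > 250) & (ts.t <= 400)].mean() > 10 * max(
        ts.sys_fail[(ts.t > 50) & (ts.t <= 200)].mean(), 1e-6)


# ---------------------------------------------------------------- summaries

def test_summary_constant_series():
    n = 200
    ts = TimeSeries(
        t=np.arange(1.0, n + 1),
        occupancy=np.full((n, 2), 50.0),
        fail_rate=np.full((n, 2), 0.25),
        sys_fail=np.full(n, 0.25),
        mean_tol=np.full((n, 2), 5.0),
        attempts=np.full((n, 2), 100.0),
    )
    assert summarize_steady_state(ts).sys_fail == pytest.approx(0.25)


def test_summary_tail_of_unsmoothed_series_is_global_mean():
    n = 100
    rng = np.random.default_rng(8)
    x = rng.random(n)
    ts = TimeSeries(
        t=np.arange(1.0, n + 1),
        occupancy=np.ones((n, 2)),
        fail_rate=np.zeros((n, 2)),
        sys_fail=x,
        mean_tol=np.ones((n, 2)),
        attempts=np.ones((n, 2)),
    )
    s = summarize_steady_state(ts, tail_fraction=1.0, smooth=1.0)
    assert s.sys_fail == pytest.approx(x.mean())


def test_summary_piecewise_series_hand_computed():
    # 80 samples at 0.2 then 20 at 0.6; unsmoothed last 10% = last 10 samples
    x = np.concatenate([np.full(80, 0.2), np.full(20, 0.6)])
    ts = TimeSeries(
        t=np.arange(1.0, 101),
        occupancy=np.ones((100, 2)),
        fail_rate=np.zeros((100, 2)),
        sys_fail=x,
        mean_tol=np.ones((100, 2)),
        attempts=np.ones((100, 2)),
    )
    s = summarize_steady_state(ts, tail_fraction=0.1, smooth=1.0)
    assert s.sys_fail == pytest.approx(0.6)
    with pytest.raises(ValueError):
        summarize_steady_state(ts, tail_fraction=0.0)
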