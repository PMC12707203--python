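# Methods

## Quality model

Each server is an M/M/c/k loss system: Poisson aggregate arrivals at rate
`n·λ_u` (the superposition of `n` independent per-user Poisson streams),
exponential service at rate `μ` per processor, `c` processors, `k` total
places.  The stationary law of the birth–death chain is evaluated in log
space (via `gammaln`) so extreme offered loads cannot overflow.  The loss
probability is the stationary mass at `k`; the load `n` is allowed to be any
real ≥ 0 so the same formulas serve the continuous mean-field dynamics.

The excessive-delay probability conditions on acceptance via PASTA: an
accepted arrival finds `j ∈ {0,…,k−1}` requests present with probability
`π_j / (1 − π_k)`.  For `c = 1` its sojourn is Erlang(`j+1`, `μ`); for
`c > 1` and `j ≥ c` it is an Erlang(`j−c+1`, `cμ`) wait plus an Exp(`μ`)
service, whose tail has a closed form because `cμ > μ`.  Erlang tails are
evaluated with the regularized incomplete gamma function, never by term
summation.  The return delay charged against the timeout `τ` is
`2d + sojourn` (request travel, queueing wait, service, response travel);
a `latency_mode="one-way"` switch charges `d + sojourn` instead for systems
where the budget covers a single direction.  The two failure channels
compose as `P^F = P^L + (1 − P^L)·P^D`.

Non-queueing commons are supported through a generic monotone load→failure
curve; monotonicity is checked on a grid at construction, and again on
`[0, Nu]` before any equilibrium solve (the solvers rely on it and refuse to
run otherwise).

## Mean-field dynamics and equilibria

Occupancies are continuous; conservation `Σ n_i = Nu` is structural (outflow
is redistributed `1/(Ng−1)` over the other goods).  Trajectories are
integrated with LSODA at `rtol = 1e−8` and renormalized to `Nu` at every
output sample to suppress drift; piecewise-constant workload schedules
restart the integrator at each breakpoint so discontinuities are exact.

The single-type equilibrium equalizes the shift fluxes
`φ = n_i P_i^F(n_i)`.  Since each flux is nondecreasing in `n_i`, the solver
brackets the common value `φ` and inverts each good's flux monotonically on
`[0, Nu]`, bisecting the outer population constraint — a 1-D problem
regardless of `Ng`.  The typed equilibrium uses the closed-form per-type
split `n_ik = Nu(k)·(T_i(k)/P_i^F) / Σ_j (T_j(k)/P_j^F)`; the total
occupancies are found as the root of `n − F(n)` (population constraint
eliminated) with a hybrid Powell method — a plain damped fixed-point
iteration on `F` 2-cycles because the map's slope is large wherever the
failure curves are steep.  Both solvers verify their balance residuals to
`1e−8` (relative) and raise rather than return an unconverged state.

A type with zero tolerance on a good never enters it: the good carries no
flux for that type and is removed from that type's shift destinations (its
inflow is redistributed uniformly over the type's supported goods).  For
types with full support the redistribution is the uniform `1/(Ng−1)`.

## Ideal distribution and tolerance design

The equalized-quality distribution is a water-filling problem: for a
candidate common level `p`, each good contributes the load at which its
failure curve reaches `p` — zero if its vanishing-load failure probability
already exceeds `p` (the exclusion test for unused goods).  The level `p*`
is bisected so the contributions sum to `Nu`.  Tolerance design inverts the
attainability condition `Σ_k Nu(k)·w_i(k) = n_i*` (with `w(k)` the
normalized tolerance row of type `k`).  The condition constrains only the
size-weighted mixture of rows, so the constructive solver returns identical
rows `w_i = n_i*/Nu` — always feasible and the unique answer for one type —
while a verification mode checks arbitrary profiles to `1e−9`.  Hybrid
two-type designs solve `(1−γ)Nu/Ng + γNu·w_i = n_i*`, feasible exactly when
`γ ≥ γ_c = (Nu − Ng·n_min*)/Nu`; at `γ_c` the least-used good gets weight
zero (all tied minima, when there are several).  Simulations need integer
failure counts: normalized weights are scaled to a configurable budget
(default `Ng·T0 = 15`) with largest-remainder rounding, since the dynamics
constrain only ratios.

## Discrete-event simulator

Open-loop traffic: every agent emits a Poisson request stream at `λ_u`
regardless of outstanding requests (several may be in flight), which is what
makes the aggregate arrivals at each server Poisson.  Events — emission,
server arrival after the one-way latency, departure, response after the
return latency — live in one binary heap ordered by time with ties broken by
insertion sequence; all randomness flows from a single seeded PCG64
generator (buffered standard-exponential draws), so identical configurations
produce bit-identical output.  Blocking is decided at the server on arrival;
the agent learns of any outcome only when the response (or loss notice)
returns.  Outcomes of requests sent during an earlier stay still count in
the system metrics but never toward the current failure counter: counters
are per-stay, and cross-stay attribution would corrupt the tolerance
semantics.

Adaptive agents update exactly at shift moments: estimate update for the
good being left from its experienced rate `T_i/R` (with `R` the stay's
attempt count), then the single-unit tolerance transfer toward the
lowest-estimate good (strict improvement required, donor keeps at least one
unit; argmin ties broken uniformly with the run's generator — this matters
at initialization, where every estimate is `x0`), then the destination draw
(uniform over the other goods, or proportional to tolerance with
zero-tolerance goods excluded).  Workload schedules re-derive `λ_u` at each
breakpoint and re-draw every agent's next emission (memorylessness makes the
piecewise process exact); in-flight requests are unaffected, and shifts are
instantaneous.

Metrics are windowed at `sample_dt` (default 1 s): per-good and system
failure fractions per window, occupancies and mean tolerances at window
ends.  Steady-state summaries low-pass filter the system series
(exponential smoothing, default constant 0.01) and average the trailing 10%
of samples; per-good means and coefficients of variation use a trailing
window (default 2000 s).

## Scaling runs

`scale_system(s)` shrinks the population and every capacity by `s` while
dilating the time unit (`d → d/s`, `τ → τ/s`).  All dimensionless products
(`μτ`, `μd`, per-good offered loads at corresponding fractional occupancies,
the workload `ρ`, the per-user rate `λ_u`) are preserved, so scaled runs
sample the same per-request probabilities with `s×` fewer events.  What does
change is the fluctuation scale: with fewer agents the occupancy noise is
relatively larger and nonlinearity couples it into small biases — at scale
0.2 the adaptive steady-state failure probability sits ≈ 10% above its
full-scale value.  Headline quantities are therefore computed at full scale
(1000 agents, 10,000 simulated seconds — stationarity of the smoothed series
was verified out to 30,000 s); scaled runs serve exploration and the fast
tests.

## What the simulator does and does not emulate

It reproduces Poisson request streams, finite-buffer FCFS queues,
deterministic network latencies, timeouts, and fully decentralized WSLS
shifting with fixed or learned tolerances.  It does not model user mobility,
request retries, non-exponential service, heterogeneous per-user rates, or
quality perceived as a continuous signal (shift probability proportional to
negative quality) — so passing tests speak to the congestion-driven
self-organization mechanism, not to radio-level realism.

One deliberate gap between theory and simulation is worth naming: the
mean-field ODE shifts agents the instant an attempt fails, while the
event-driven agent learns of a failure only after the return latency plus,
for late responses, the sojourn itself.  The agent's expected stay is
`1/(λ_u P^F) + D` rather than `1/(λ_u P^F)`, with `D` the expected detection
delay.  The effect is invisible below `ρ = 1` and shifts the overloaded
(`ρ = 1.25`) equilibrium by ~1.3% of occupancy toward the slow server; the
tests compare simulation steady states against the detection-delay-corrected
equilibrium (computed analytically from the stationary queue law) and assert
separately that the correction stays below 1.5%, keeping the plain
flux-balance equilibrium the leading-order description.

## Parameter defaults

| Parameter | Default | Meaning |
|---|---|---|
| `Nu` | 1000 | population size |
| `μ_i` | {100, 200, 400} servs/s | server capacities (`μ = 700`) |
| `c_i`, `k_i` | 1, 10 | processors, total places |
| `d_i` | {10, 20, 30} ms | one-way user↔server latency |
| `τ` | 100 ms | service timeout |
| `ρ` | 0.75 | workload `Nu·λ_u/μ` (so `λ_u = ρμ/Nu`) |
| `T0` | 5 | initial per-good tolerance (budget `Ng·T0`) |
| `x0` | 0 | initial failure-probability estimate |
| `β` | 0.10 | learning rate |
| `sample_dt` | 1 s | metrics window |
| smoothing | 0.01 | steady-state low-pass constant |

## Known limitations

* Tolerance components are confined to `[1, Ng·T0 − (Ng−1)]` by the
  conserved budget, which caps the contrast the learner can express between
  servers; at high workload this leaves small residual failure-probability
  differences (visible as slow, self-correcting oscillations).
* The typed-equilibrium root-finder assumes strictly positive failure
  probabilities on every good (true for queue servers, where an isolated
  request can always be late); generic goods with `failure_fn(0) = 0` can
  make the split degenerate.
* Delay formulas for `c > 1` are implemented (hypoexponential tails) but the
  reference experiments all use `c = 1`; multi-processor delay paths are not
  exercised against a Monte-Carlo oracle.
* The equalized-quality distribution equalizes failure probabilities; it is
  not the minimizer of the population-mean failure probability, and at light
  load (`ρ = 0.5`) the flux-balance equilibrium's mean can be marginally
  lower.  Under congestion (`ρ ≥ 0.75`) equalization also lowers the mean.
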