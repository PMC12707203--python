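# wsls-commons

Self-organized usage of common goods under the **Win-Stay, Lose-Shift (WSLS)**
strategy: analytic quality models for congestible resources, mean-field
population dynamics, the equalized-quality ideal distribution with
tolerance-vector design, and a seeded discrete-event agent simulator with
adaptive tolerance learning.

## The problem

A population of `Nu` users shares `Ng` *common goods* — resources whose
per-user quality degrades with the number of simultaneous users: grazing
patches, transport lines, water sources, or (the reference application here)
servers handling Internet service requests from mobile users.  Each user sees
only its own outcomes: no communication, no coordinator, no load information.
Under WSLS a user keeps using its current good while satisfied and shifts to
another good, chosen at random, once it has accumulated a tolerated number of
failures.

For good `i` with `n_i` concurrent users, quality is `Q_i = 1 − P_i^F(n_i)`
with `P_i^F` nondecreasing in load.  A server is modelled as an M/M/c/k queue:
a request fails by **loss** (arrival to a full buffer, probability `P_i^L`) or
**excessive delay** (return delay — round-trip latency `2 d_i` plus queueing
wait plus service — exceeding the timeout `τ`, probability `P_i^D`), composed
as

```
P_i^F = P_i^L + (1 − P_i^L) · P_i^D .
```

With each user attempting at rate `λ_u`, the occupancies follow the mean-field
dynamics

```
dn_i/dt = −λ_u n_i P_i^F(n_i) + 1/(Ng−1) · Σ_{j≠i} λ_u n_j P_j^F(n_j),
```

whose equilibrium equalizes the shift fluxes `n_i P_i^F(n_i)` across goods.
That equilibrium improves on uniform usage but still overloads weak goods.
The **equalized-quality ideal distribution** `n*` instead equalizes the
failure probability itself (`P_a^F(n_a*) = p*` on all used goods, unused goods
exceeding `p*` even at vanishing load) — the ideal-free-distribution notion
for this setting.  `n*` is attainable by WSLS populations whose per-good
tolerances `T_i(k)` satisfy `Σ_k Nu(k) · T_i(k)/Σ_j T_j(k) = n_i*`; for a
two-type (selective + nonselective) population this is feasible exactly when
the selective fraction reaches `γ_c = (Nu − Ng·min_i n_i*)/Nu`.  Finally, an
**adaptive tolerance** rule lets each agent learn its tolerance vector online:
it estimates per-good failure rates from its own stays
(`x_i ← (1−β)x_i + β·T_i/R`) and moves one tolerance unit from the good it
leaves to the good with the lowest estimate.  A population of such learners
self-organizes onto `n*` without any coordination.

## Worked example

The reference system (defaults of every config): `Nu = 1000` users, three
single-processor servers with capacities `μ = {100, 200, 400}` servs/s,
latencies `d = {10, 20, 30}` ms, `k = 10` places, timeout `τ = 100` ms,
workload `ρ = Nu·λ_u/μ_total = 0.75` (so `λ_u = 0.525` reqs/s).

```bash
$ wsls-commons equilibrium
{
  "rho": 0.75,
  "lambda_u": 0.525,
  "n": [133.61, 291.20, 575.19],
  "p_fail": [0.07577, 0.03476, 0.01760],
  "flux": [10.1234, 10.1234, 10.1234],
  "mean_failure": 0.03037
}
```

The equal fluxes confirm the equilibrium condition; the weakest server keeps
a 7.6% failure probability while the strongest sits at 1.8% — balanced flux,
not balanced quality.  The ideal distribution for the same system
(`wsls-commons ideal`) moves users away from the weak server
(`n* = [106.0, 280.4, 613.6]`) and equalizes failure at `p* = 0.02762`,
with critical selective fraction `γ_c = 0.682`.

A fast, scaled adaptive simulation (population and capacities shrunk 5×, time
unit dilated so every per-request probability is preserved):

```bash
$ wsls-commons preset adaptive --seed 1 --scale 0.2 -o demo
steady-state system failure probability: 0.031881
```

`demo/` then holds the sampled time series (`timeseries.csv`: occupancies,
per-server and system failure rates, mean tolerances) and a `manifest.json`
echoing the full configuration; the steady occupancy mean
`[20.1, 54.6, 125.3]` matches the scaled ideal `n*/5 = [21.2, 56.1, 122.7]`
to within the finite-population fluctuations of 200 agents.  At full scale
(`--scale 1`, ≈ 40 s per 10,000 simulated seconds) the steady-state failure
probability settles at ≈ 0.028, within a few percent of `p*`.

Config files are YAML with five sections (all optional):

```yaml
system:      {nu: 1000, tau_ms: 100, rho: 0.75}   # or lambda_u, not both
servers:
  - {mu: 100, c: 1, k: 10, d_ms: 10}
  - {mu: 200, c: 1, k: 10, d_ms: 20}
  - {mu: 400, c: 1, k: 10, d_ms: 30}
population:  {mode: adaptive, shift_rule: uniform}  # or mode: fixed, tolerance: 1
learning:    {t0: 5, x0: 0.0, beta: 0.10}
run:         {duration: 10000, seed: 1, sample_dt: 1.0,
              schedule: [[3600, 0.75], [3600, 1.25]]}  # optional rho schedule
```

Unknown keys are rejected; omitted keys take the reference defaults above.
Presets: `wsls-basic` (plain WSLS, tolerance 1), `adaptive`, `multi-seed`,
`dynamic-load` (hourly workload sequence 0.75, 1.25, 0.75, 1.25, 0.75, 0.5,
0.25, 0.5, 0.75, 1).

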