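# Methods

## The model

The department is modelled as an M/M/R/N queue: a time-homogeneous Poisson
arrival stream of rate λ, R identical providers with i.i.d. exponential
service times of rate μ, one FIFO waiting line, and a hard capacity of N
patients in the system (N − R waiting places).  An arrival that finds N
patients present is blocked and lost — it does not retry.  The state
(number in system) is a birth–death chain with birth rate λ_n = λ for
n < N (0 at n = N) and death rate μ_n = min(n, R)·μ.

Assumptions worth stating plainly:

- **Stationarity within a window.**  Rates are constant inside each planning
  window; intra-window surges are not modelled.  Window-by-window application
  (`windowed_plan`) is the supported way to handle time variation.
- **Exponential service, no triage classes, no abandonment.**  One patient
  class, memoryless treatment times, and patients never renege from the
  queue.
- **Ergodicity without a stability condition.**  Because capacity is finite,
  the chain has a stationary distribution for *every* λ, μ > 0; system
  utilisation ρ_s = λ/(Rμ) ≥ 1 is a legitimate input (understaffed sweeps
  routinely visit it), not an error.

## Computing the stationary distribution

The textbook two-segment closed form

    P(n) = ρⁿ/n! · P(0)            1 ≤ n ≤ R
    P(n) = ρⁿ/(R!·R^{n−R}) · P(0)  R < n ≤ N,   ρ = λ/μ

is mathematically exact but numerically hostile: the factorials and powers
overflow quickly (ρ = 3.5, N = 15 already produces 3.5¹⁵-sized terms), and
the geometric closed form for the normalising constant has a removable
singularity at ρ_s = 1.  The implementation therefore never forms those
expressions; it builds the detailed-balance coefficients

    c_0 = 1,   c_n = c_{n−1} · λ / (min(n, R)·μ)

and normalises, which is algebraically identical, overflow-safe for the
sizes of interest, and smooth through ρ_s = 1 (verified by a continuity test
at ρ_s = 1 ± 1e−9).  Two published-formula pitfalls are deliberately
avoided: the normalising sum counts each state exactly once (inclusive
writing of both segment sums double-counts the boundary state n = R and
would give P(0) = 0.125 instead of the correct 3/22 ≈ 0.136 in the small
worked example), and no 1/(1 − ρ_s) form is ever evaluated.

An independent oracle, `oracle_stationary`, solves the full (N+1)-state
global-balance system densely (`numpy.linalg.solve` with a normalisation
row).  It shares no code with the recursion and certifies it to 1e−10 over
randomized scenarios spanning ρ_s ∈ (0, 3], including ρ_s = 1 exactly and
the zero-buffer (N = R) stratum; the Erlang-B and M/M/1/N truncated-geometric
special cases are checked against their own closed forms.

## Performance measures and the Little's-law convention

Ls, Lq, E[I], E[B], P_B and P(N) are plain moments/tails of the stationary
vector.  Waits are reported in **two** conventions:

- `Ws = Ls/λ`, `Wq = Lq/λ` — Little's law with the *raw* arrival rate.  This
  is the convention of the reference staffing tables this package
  reproduces, and what the AWT column uses.
- `ws_eff = Ls/λ_eff`, `wq_eff = Lq/λ_eff` with λ_eff = λ·(1 − P(N)) — the
  standard choice for finite-capacity queues, and the wait an *admitted*
  patient actually experiences.  The simulator's per-patient wait estimates
  this quantity, so validation compares simulated Wq against `wq_eff`.

The AWT column of reports is `awt_scale · Lq/λ` with `awt_scale` defaulting
to 100.  The factor reproduces the units of the reference tables (verified
numerically row by row) but is not a documented physical unit, so it is an
explicit configuration knob; set `awt_scale = 1` for waits in natural time
units.  Report formatting follows the tables: cost to 1 decimal, AWT to
2 decimals with values below 0.005 displayed as `0`.

On the small worked example the exact measures are Ls = 43/22 ≈ 1.9545,
E[I] = 46/22 ≈ 2.0909, Ws = 0.9773, Lq = 1/22 ≈ 0.04545; published versions
of these figures (1.949, 2.085, 0.9745, and 0.0453/0.0457 in two places)
carry intermediate rounding of P(0) to 0.136, so exact arithmetic lands
within ±0.006 of them.  The package always computes at full precision and
rounds only in reports.

## The cost function and the decision layer

F(R, N) = Cq·Lq + Cs·(Ls − Lq) + CB·E[B] + CI·E[I], all rates ≥ 0 per unit
time.  The algebraically equivalent arrangement (Cq − Cs)·Lq + Cs·Ls + … is
tested to agree to 1e−9.  N is an input, not a decision variable: the sweep
optimises over R only, by exhaustive evaluation.  The cost curve is unimodal
in R on the worked parameter families, but the optimizer never exploits
that — an argmin over the sweep is cheap (tens of scenarios) and immune to
multimodality.  Ties break toward smaller R (fewer staff at equal cost), in
both the argmin and the smallest-feasible-R search.

The constrained recommendation reports the achieved AWT reduction twice:
`reduction_pct` from full-precision AWTs, and `reduction_pct_display`
recomputed from the 2-dp rounded AWTs, which is how staffing tables quote
it ((6.84 − 2.13)/6.84 → 68.9 %); the two can differ in the first decimal
(68.79 vs 68.86 on the reference curve).  An unsatisfiable constraint
returns an explicit infeasible result rather than raising, so multi-window
plans always complete.

Default sweep range: 1..min(12, N), overridable.

## Simulation protocol

The validating simulator runs the CTMC event by event: exponential holding
times at rate λ + min(n, R)·μ, the event an arrival with probability
λ/(λ + min(n, R)·μ).  Queue-entry timestamps give exact FIFO per-patient
waits (legitimate because exponential services are memoryless).  Departures
conceptually precede arrivals at tied instants — with continuous clocks ties
have probability zero, and the sequential draw realises this ordering.

Protocol defaults (the package's own; chosen once as standard steady-state
practice): warm-up 10 % of the horizon discarded, 20 replications, horizon
2e5 time units, replication k seeded `base_seed + k` so runs are independent
and bit-reproducible.  Per-measure 95 % confidence intervals are t-based
across replication means; the validation report also standardises each error
and flags |z| > 3.  Conservation (arrivals = served + blocked + remaining)
holds exactly per run, and the blocked-arrival fraction is cross-checked
against the time-average P(N) (PASTA).

For broad coverage testing the suite simulates 50 randomized scenarios with
a per-scenario horizon of 1e5/(λ + Rμ) time units — a fixed expected event
budget — at 10 replications each, and checks that analytic values fall in
the simulated 95 % CIs in 88–100 % of (scenario, measure) cases.  In deep
overload some CIs legitimately degenerate to a point (e.g. the all-busy
probability is 1 for the entire horizon), so interval membership is tested
with 1e−9 absolute slack.

What the simulator does *not* emulate: non-Poisson or time-varying arrivals,
non-exponential services, triage priorities, abandonment, or retrials of
blocked patients.  Agreement between simulator and analytics therefore
certifies the implementation of the model, not the model's fidelity to any
particular real department.

## Configuration and I/O

Scenarios are single JSON objects (one `schema_version` field from day one)
validated with pydantic; unknown keys are rejected so typos fail loudly, and
CLI flags override file values.  Cost tables are CSV (`R,cost,awt`) with
locale-independent dot-decimal formatting and deterministic bytes.  Results
go to stdout, logging to stderr.

## Known limitations

- Single patient class and a single service stage; real EDs chain triage,
  treatment and boarding.
- Rates must be supplied (e.g. estimated from historical window data);
  the package does not fit λ or μ from census logs.
- The dense oracle is O(N³) and intended for N up to a few thousand; the
  recursion itself is O(N) and much further-reaching.
- Waiting-cost rates are linear; no overtime, surge premiums or nonlinear
  crowding penalties.
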