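"""Discrete-event simulation of the M/M/R/N queue, for validating the
analytic steady-state measures.

The simulator runs the continuous-time Markov chain directly: in state ``n``
the next event occurs after an exponential holding time of rate
``lam + min(n, R) * mu`` and is an arrival with probability
``lam / (lam + min(n, R) * mu)``, otherwise a departure.  Arrivals finding
the system full are counted as blocked and lost.  Queued patients are served
FIFO; because services are exponential (memoryless), per-patient waiting
times can be tracked exactly from the aggregate state process by recording
queue-entry timestamps.

Protocol: each replication starts empty, discards a warm-up fraction of the
horizon, and contributes one time-average per measure; replications use
independent streams seeded ``base_seed + replication_index`` and are combined
into t-based 95% confidence intervals.

Note on waits: only admitted patients ever wait, so the per-patient mean wait
estimates ``Lq / lam_eff`` (Little's law at the accepted rate), and the
validation report compares it against the analytic ``wq_eff``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .queue_model import QueueParams, performance_measures

__all__ = [
    "SimulationConfig",
    "SimulationEstimates",
    "simulate_mmrn",
    "validate_against_analytic",
    "random_scenarios",
]

_CHUNK = 65536  # random draws generated per batch inside the event loop


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation protocol: horizon per replication (time units), warm-up
    fraction discarded, number of independent replications, base seed."""

    horizon: float = 2e5
    warmup: float = 0.1
    replications: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon!r}")
        if not 0 <= self.warmup < 1:
            raise ValueError(f"warmup must be in [0, 1), got {self.warmup!r}")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


# measures estimated per replication, in output order
_MEASURES = ("Ls", "Lq", "Wq", "PB", "P_block", "EB")


@dataclass(frozen=True)
class SimulationEstimates:
    """Replication-level estimates with 95% confidence intervals.

    ``samples[m]`` holds one time-average (or per-patient average for ``Wq``)
    per replication; ``point(m)`` and ``half_width(m)`` give the replication
    mean and its t-based 95% CI half-width.  Event counts are totals over the
    full horizon of all replications and satisfy
    ``arrivals == served + blocked + remaining``.
    """

    params: QueueParams
    config: SimulationConfig
    samples: dict[str, np.ndarray]
    arrivals: int
    served: int
    blocked: int
    remaining: int
    obs_arrivals: int = 0
    obs_blocked: int = 0

    def point(self, measure: str) -> float:
        return float(self.samples[measure].mean())

    def half_width(self, measure: str) -> float:
        x = self.samples[measure]
        if len(x) < 2:
            return float("nan")
        t = stats.t.ppf(0.975, len(x) - 1)
        return float(t * x.std(ddof=1) / np.sqrt(len(x)))

    def interval(self, measure: str) -> tuple[float, float]:
        p, hw = self.point(measure), self.half_width(measure)
        return p - hw, p + hw

    def summary(self) -> pd.DataFrame:
        rows = [
            {"measure": m, "estimate": self.point(m), "ci_half_width": self.half_width(m)}
            for m in _MEASURES
        ]
        return pd.DataFrame(rows)


def _run_replication(
    params: QueueParams, horizon: float, warmup: float, seed: int
) -> tuple[dict[str, float], dict[str, int]]:
    """One replication; returns per-measure averages and event counts."""
    R, N, lam, mu = params.R, params.N, params.lam, params.mu
    rng = np.random.default_rng(seed)
    w_start = warmup * horizon
    obs_time = horizon - w_start

    t = 0.0
    n = 0
    area_n = area_q = area_busy = area_allbusy = area_full = 0.0
    arrivals = served = blocked = 0
    obs_arrivals = obs_blocked = 0
    wait_sum = 0.0
    wait_count = 0
    queue: deque[float] = deque()  # arrival times of waiting patients, FIFO

    exps = rng.exponential(size=_CHUNK)
    unis = rng.random(size=_CHUNK)
    i = 0
    while True:
        if i >= _CHUNK:
            exps = rng.exponential(size=_CHUNK)
            unis = rng.random(size=_CHUNK)
            i = 0
        busy = n if n < R else R
        rate = lam + busy * mu
        t_next = t + exps[i] / rate
        is_arrival = unis[i] * rate < lam
        i += 1

        lo = t if t > w_start else w_start
        hi = t_next if t_next < horizon else horizon
        if hi > lo:
            w = hi - lo
            area_n += w * n
            area_q += w * (n - busy)
            area_busy += w * busy
            if busy == R:
                area_allbusy += w
            if n == N:
                area_full += w
        if t_next >= horizon:
            break
        t = t_next

        if is_arrival:
            arrivals += 1
            post = t >= w_start
            if post:
                obs_arrivals += 1
            if n == N:
                blocked += 1
                if post:
                    obs_blocked += 1
            else:
                if n >= R:
                    queue.append(t)
                else:
                    if post:  # enters service immediately: zero wait
                        wait_count += 1
                n += 1
        else:
            n -= 1
            served += 1
            if queue:
                entered = queue.popleft()
                if entered >= w_start:
                    wait_sum += t - entered
                    wait_count += 1

    averages = {
        "Ls": area_n / obs_time,
        "Lq": area_q / obs_time,
        "Wq": wait_sum / wait_count if wait_count else 0.0,
        "PB": area_allbusy / obs_time,
        "P_block": area_full / obs_time,
        "EB": area_busy / obs_time,
    }
    counts = {
        "arrivals": arrivals,
        "served": served,
        "blocked": blocked,
        "remaining": n,
        "obs_arrivals": obs_arrivals,
        "obs_blocked": obs_blocked,
    }
    return averages, counts


def simulate_mmrn(
    params: QueueParams, config: SimulationConfig = SimulationConfig()
) -> SimulationEstimates:
    """Simulate the M/M/R/N queue and estimate its steady-state measures.

    Identical ``(params, config)`` always yields identical output: replication
    ``k`` uses the stream seeded ``config.seed + k``.
    """
    if config.horizon * (1.0 - config.warmup) <= 0:
        raise ValueError("no post-warm-up observation window")
    samples: dict[str, list[float]] = {m: [] for m in _MEASURES}
    totals = {"arrivals": 0, "served": 0, "blocked": 0, "remaining": 0,
              "obs_arrivals": 0, "obs_blocked": 0}
    for k in range(config.replications):
        averages, counts = _run_replication(
            params, config.horizon, config.warmup, config.seed + k
        )
        for m in _MEASURES:
            samples[m].append(averages[m])
        for key in totals:
            totals[key] += counts[key]
    return SimulationEstimates(
        params=params,
        config=config,
        samples={m: np.asarray(v) for m, v in samples.items()},
        arrivals=totals["arrivals"],
        served=totals["served"],
        blocked=totals["blocked"],
        remaining=totals["remaining"],
        obs_arrivals=totals["obs_arrivals"],
        obs_blocked=totals["obs_blocked"],
    )


def validate_against_analytic(
    params: QueueParams, config: SimulationConfig = SimulationConfig()
) -> pd.DataFrame:
    """Side-by-side table of analytic vs. simulated measures.

    Columns: measure, analytic, simulated, ci_half_width, z (standardised
    error of the replication mean) and ``flag`` marking ``|z| > 3``.  The
    simulated per-patient wait is compared against the effective-rate wait
    ``wq_eff`` (see module docstring); every other measure against its direct
    analytic counterpart.
    """
    est = simulate_mmrn(params, config)
    analytic = performance_measures(params)
    targets = {
        "Ls": analytic.Ls,
        "Lq": analytic.Lq,
        "Wq": analytic.wq_eff,
        "PB": analytic.PB,
        "P_block": analytic.P_block,
        "EB": analytic.EB,
    }
    rows = []
    for m in _MEASURES:
        x = est.samples[m]
        se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else float("nan")
        z = (est.point(m) - targets[m]) / se if se > 0 else 0.0
        rows.append(
            {
                "measure": m,
                "analytic": targets[m],
                "simulated": est.point(m),
                "ci_half_width": est.half_width(m),
                "z": z,
                "flag": abs(z) > 3,
            }
        )
    return pd.DataFrame(rows)


def random_scenarios(
    seed: int,
    count: int,
    R_bounds: tuple[int, int] = (1, 20),
    N_bounds: tuple[int, int] = (1, 200),
    rho_s_bounds: tuple[float, float] = (0.05, 3.0),
) -> list[QueueParams]:
    """Reproducible random M/M/R/N scenarios for property suites.

    Scenarios span under-, critically- and over-loaded regimes.  The set is
    stratified: when the bounds allow, it always contains at least one
    zero-buffer case (``N == R``) and, when ``rho_s_bounds`` straddles 1, at
    least one scenario with ``rho_s`` exactly 1.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    R_lo, R_hi = R_bounds
    N_lo, N_hi = N_bounds
    s_lo, s_hi = rho_s_bounds
    if R_lo < 1 or R_hi < R_lo or N_hi < N_lo or not (0 < s_lo <= s_hi):
        raise ValueError("impossible bounds")
    if N_hi < R_lo:
        raise ValueError("no admissible N for any admissible R")

    rng = np.random.default_rng(seed)
    scenarios: list[QueueParams] = []
    for idx in range(count):
        R = int(rng.integers(R_lo, min(R_hi, N_hi) + 1))
        if idx == 0:  # stratum: zero waiting buffer
            N = max(R, N_lo)
        else:
            N = int(rng.integers(max(R, N_lo), N_hi + 1))
        if idx == 1 and s_lo <= 1.0 <= s_hi:  # stratum: critical load
            rho_s = 1.0
        else:
            rho_s = float(rng.uniform(s_lo, s_hi))
        mu = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        scenarios.append(QueueParams(R=R, N=N, lam=rho_s * R * mu, mu=mu))
    return scenarios
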