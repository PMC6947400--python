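"""Exact steady-state analysis of the M/M/R/N finite-capacity multi-server queue.

The model: patients arrive in a Poisson stream of rate ``lam``; ``R`` identical
providers each serve one patient at a time with exponential service times of
rate ``mu``; at most ``N`` patients may be present in total (``N - R`` waiting
places), and an arrival finding the system full is blocked and lost.  The
number-in-system process is a birth-death chain on states ``0..N`` with birth
rate ``lam`` below ``N`` and death rate ``min(n, R) * mu``, so it is ergodic
for every positive rate pair -- including overloaded regimes where
``lam > R * mu``.

The stationary distribution is computed by the balance recursion

    c_0 = 1,    c_n = c_{n-1} * lam / mu_n,    P(n) = c_n / sum(c)

which is algebraically identical to the textbook two-segment closed form
``P(n) = rho^n/n! * P(0)`` (``n <= R``) and ``P(n) = rho^n/(R! R^{n-R}) * P(0)``
(``n > R``) but never forms factorials, large powers, or the removable
``1/(1 - rho_s)`` singularity at ``rho_s = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QueueParams",
    "StationaryDistribution",
    "PerformanceMeasures",
    "birth_death_rates",
    "stationary_distribution",
    "performance_measures",
    "oracle_stationary",
]


@dataclass(frozen=True)
class QueueParams:
    """One M/M/R/N scenario.

    Parameters
    ----------
    R : int
        Number of parallel providers (servers), ``R >= 1``.
    N : int
        Total system capacity (patients in service plus waiting), ``N >= R``.
    lam : float
        Mean Poisson arrival rate, per unit time.
    mu : float
        Mean service rate of a single provider, per unit time.

    Notes
    -----
    System utilisation ``rho_s = lam / (R * mu) >= 1`` is permitted: the
    finite capacity keeps the chain ergodic, and overloaded scenarios are a
    normal part of staffing sweeps (small ``R`` against a fixed demand).
    """

    R: int
    N: int
    lam: float
    mu: float

    def __post_init__(self) -> None:
        if int(self.R) != self.R or self.R < 1:
            raise ValueError(f"R must be an integer >= 1, got {self.R!r}")
        if int(self.N) != self.N or self.N < self.R:
            raise ValueError(f"N must be an integer >= R (= {self.R}), got {self.N!r}")
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be finite and > 0, got {self.lam!r}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be finite and > 0, got {self.mu!r}")
        object.__setattr__(self, "R", int(self.R))
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "lam", float(self.lam))
        object.__setattr__(self, "mu", float(self.mu))

    @property
    def rho(self) -> float:
        """Server utilisation lam/mu (offered load in units of one server)."""
        return self.lam / self.mu

    @property
    def rho_s(self) -> float:
        """System utilisation lam/(R*mu)."""
        return self.lam / (self.R * self.mu)


def birth_death_rates(params: QueueParams, n: int) -> tuple[float, float]:
    """Transition rates out of state ``n`` of the number-in-system chain.

    Returns ``(lam_n, mu_n)``: the arrival (birth) rate, which is ``lam``
    except at the full state ``N`` where admissions stop, and the aggregate
    service (death) rate ``min(n, R) * mu``.
    """
    if int(n) != n or n < 0 or n > params.N:
        raise ValueError(f"state index n must be in [0, {params.N}], got {n!r}")
    n = int(n)
    lam_n = params.lam if n < params.N else 0.0
    mu_n = min(n, params.R) * params.mu
    return lam_n, mu_n


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probabilities ``P(0)..P(N)`` of the number-in-system chain."""

    params: QueueParams
    probs: np.ndarray

    @property
    def p0(self) -> float:
        """Probability the system is empty."""
        return float(self.probs[0])

    @property
    def p_full(self) -> float:
        """Blocking probability P(N): the system is at capacity."""
        return float(self.probs[-1])

    def __len__(self) -> int:
        return len(self.probs)


def _unnormalized_coefficients(params: QueueParams) -> np.ndarray:
    # c_n = prod lam/mu_k; exact for the birth-death chain and overflow-safe
    # even for e.g. rho = 3.5, N = 15 where rho^N / R! style terms are huge.
    c = np.empty(params.N + 1)
    c[0] = 1.0
    for n in range(1, params.N + 1):
        c[n] = c[n - 1] * params.lam / (min(n, params.R) * params.mu)
    return c


def stationary_distribution(params: QueueParams) -> StationaryDistribution:
    """Exact stationary distribution of the M/M/R/N queue.

    Each state is counted exactly once in the normalisation (the two-segment
    closed form is prone to double-counting the boundary state ``n = R`` when
    both segment sums are written inclusively).
    """
    c = _unnormalized_coefficients(params)
    probs = c / c.sum()
    return StationaryDistribution(params=params, probs=probs)


@dataclass(frozen=True)
class PerformanceMeasures:
    """Steady-state performance measures of one M/M/R/N scenario.

    Attributes
    ----------
    Ls, Lq : float
        Expected number of patients in the system / in the waiting buffer.
    EI, EB : float
        Expected number of idle / busy providers (``EB + EI = R``).
    PB : float
        Probability all providers are busy (an arrival must wait or is lost).
    P_block : float
        Probability the system is full, P(N); arrivals are then lost.
    Ws, Wq : float
        Mean time in system / in queue by Little's law with the *raw* arrival
        rate: ``Ws = Ls/lam``, ``Wq = Lq/lam``.
    lam_eff : float
        Accepted arrival rate ``lam * (1 - P(N))``.
    ws_eff, wq_eff : float
        Little's-law waits with the effective (accepted) rate, the standard
        choice for finite-capacity queues: ``Ls/lam_eff``, ``Lq/lam_eff``.
        ``wq_eff`` is the mean wait actually experienced by an admitted
        patient.
    """

    params: QueueParams
    distribution: StationaryDistribution
    Ls: float
    Lq: float
    EI: float
    EB: float
    PB: float
    P_block: float
    Ws: float
    Wq: float
    lam_eff: float
    ws_eff: float
    wq_eff: float


def performance_measures(params: QueueParams) -> PerformanceMeasures:
    """All steady-state measures, from the exact stationary distribution.

    ``Ls = sum n P(n)``; ``Lq = sum_{n>=R} (n-R) P(n)``;
    ``EI = sum_{n<R} (R-n) P(n)``; ``EB = R - EI``; ``PB = sum_{n>=R} P(n)``.
    """
    dist = stationary_distribution(params)
    P = dist.probs
    R, N, lam, mu = params.R, params.N, params.lam, params.mu
    n = np.arange(N + 1)

    Ls = float(n @ P)
    Lq = float((n[R:] - R) @ P[R:])
    EI = float((R - n[:R]) @ P[:R])
    EB = R - EI
    PB = float(min(P[R:].sum(), 1.0))  # guard summation roundoff
    P_block = float(P[N])
    lam_eff = lam * (1.0 - P_block)

    return PerformanceMeasures(
        params=params,
        distribution=dist,
        Ls=Ls,
        Lq=Lq,
        EI=EI,
        EB=EB,
        PB=PB,
        P_block=P_block,
        Ws=Ls / lam,
        Wq=Lq / lam,
        lam_eff=lam_eff,
        ws_eff=Ls / lam_eff,
        wq_eff=Lq / lam_eff,
    )


def oracle_stationary(params: QueueParams) -> StationaryDistribution:
    """Stationary distribution by dense linear solve of the global balance
    equations.

    Builds the full (N+1)-state generator matrix and solves ``pi Q = 0`` with
    one balance row replaced by the normalisation ``sum pi = 1``.  Independent
    of the coefficient recursion; intended as a test oracle for small ``N``
    (up to a few thousand states).
    """
    N = params.N
    Q = np.zeros((N + 1, N + 1))
    for n in range(N + 1):
        lam_n, mu_n = birth_death_rates(params, n)
        if n < N:
            Q[n, n + 1] = lam_n
        if n > 0:
            Q[n, n - 1] = mu_n
        Q[n, n] = -(lam_n + mu_n)
    A = Q.T.copy()
    A[-1, :] = 1.0  # normalisation row
    b = np.zeros(N + 1)
    b[-1] = 1.0
    probs = np.linalg.solve(A, b)
    return StationaryDistribution(params=params, probs=probs)
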