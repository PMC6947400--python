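"""Steady-state expected staffing cost per unit time of an M/M/R/N scenario.

The cost function combines four linear cost rates against the steady-state
measures:

    F(R, N) = Cq * Lq + Cs * (Ls - Lq) + CB * E[B] + CI * E[I]

i.e. waiting patients, patients in service, busy providers and idle providers
each accrue cost at their own rate.  An algebraically identical arrangement is
``(Cq - Cs) * Lq + Cs * Ls + CB * E[B] + CI * E[I]``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .queue_model import PerformanceMeasures, QueueParams, performance_measures

__all__ = ["CostRates", "CostEvaluation", "evaluate_cost"]


@dataclass(frozen=True)
class CostRates:
    """Cost per unit time: Cq per waiting patient, Cs per patient in service,
    CB per busy provider, CI per idle provider.  All rates must be >= 0."""

    Cq: float
    Cs: float
    CB: float
    CI: float

    def __post_init__(self) -> None:
        for name in ("Cq", "Cs", "CB", "CI"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(f"cost rate {name} must be >= 0, got {v!r}")
            object.__setattr__(self, name, float(v))


@dataclass(frozen=True)
class CostEvaluation:
    """Cost F at one provider count, with the measures behind it."""

    R: int
    F: float
    measures: PerformanceMeasures


def evaluate_cost(params: QueueParams, rates: CostRates) -> CostEvaluation:
    """Expected cost per unit time F(R, N), from exact (unrounded) measures."""
    m = performance_measures(params)
    F = rates.Cq * m.Lq + rates.Cs * (m.Ls - m.Lq) + rates.CB * m.EB + rates.CI * m.EI
    return CostEvaluation(R=params.R, F=float(F), measures=m)
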