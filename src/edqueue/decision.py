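"""Staffing decision support: cost sweeps over the provider count, the
cost-optimal choice, and waiting-time-constrained recommendations.

A sweep evaluates F(R, N) and the average waiting time (AWT) for every
candidate provider count R.  The optimiser is an exhaustive argmin -- the cost
curve is unimodal on the worked parameter families, but the code never relies
on that.  A constrained recommendation answers "what is the smallest R that
caps AWT at a level, or cuts it by a given percentage relative to the
cost-optimal R*, and what does that cost?".

AWT convention
--------------
The reported AWT is ``awt_scale * Lq / lam`` (Little's law with the raw
arrival rate, times a display scale).  The default ``awt_scale = 100`` matches
the units of the reference staffing tables this module reproduces; set it to 1
for waits in natural time units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cost import CostRates, evaluate_cost
from .queue_model import PerformanceMeasures, QueueParams

__all__ = [
    "CostCurve",
    "CostCurveRow",
    "Recommendation",
    "WindowPlan",
    "AwtConstraint",
    "sweep_cost",
    "optimal_staffing",
    "constrained_staffing",
    "windowed_plan",
]


@dataclass(frozen=True)
class CostCurveRow:
    """One sweep row: provider count, cost, scaled average waiting time."""

    R: int
    F: float
    awt: float
    measures: PerformanceMeasures


@dataclass(frozen=True)
class CostCurve:
    """Ordered (R, F, AWT) table for one scenario, rows strictly increasing in R."""

    rows: tuple[CostCurveRow, ...]
    N: int
    lam: float
    mu: float
    rates: CostRates
    awt_scale: float = 100.0

    def row(self, R: int) -> CostCurveRow:
        for r in self.rows:
            if r.R == R:
                return r
        raise KeyError(f"R={R} not in sweep range {[r.R for r in self.rows]}")


@dataclass(frozen=True)
class AwtConstraint:
    """Either a cap on AWT (``max_level``, in the curve's AWT units) or a
    minimum percent reduction of AWT relative to the cost-optimal R*."""

    max_level: float | None = None
    min_reduction_pct: float | None = None

    def __post_init__(self) -> None:
        if (self.max_level is None) == (self.min_reduction_pct is None):
            raise ValueError(
                "exactly one of max_level and min_reduction_pct must be given"
            )
        if self.max_level is not None and self.max_level < 0:
            raise ValueError("max_level must be >= 0")


@dataclass(frozen=True)
class Recommendation:
    """Decision-support output for one scenario.

    ``R_star`` minimises cost; ``R_constrained`` is the smallest provider
    count meeting the AWT constraint (equal to ``R_star`` when no constraint
    is given).  ``reduction_pct`` is the achieved AWT reduction from R* to the
    constrained choice, in percent, at full precision;
    ``reduction_pct_display`` recomputes it from the AWTs rounded to the 2-dp
    report precision, which is the convention staffing tables quote (the two
    can differ in the first decimal).  ``cost_delta`` is the extra cost
    incurred.  ``feasible`` is False when no R in the sweep satisfies the
    constraint, in which case the constrained fields are None rather than
    raising.
    """

    R_star: int
    F_star: float
    awt_at_star: float
    feasible: bool = True
    R_constrained: int | None = None
    F_constrained: float | None = None
    awt_at_constrained: float | None = None
    reduction_pct: float | None = None
    reduction_pct_display: float | None = None
    cost_delta: float | None = None
    constraint: AwtConstraint | None = None

    def as_dict(self) -> dict:
        d = {
            "R_star": self.R_star,
            "F_star": self.F_star,
            "awt_at_star": self.awt_at_star,
            "feasible": self.feasible,
            "R_constrained": self.R_constrained,
            "F_constrained": self.F_constrained,
            "awt_at_constrained": self.awt_at_constrained,
            "reduction_pct": self.reduction_pct,
            "reduction_pct_display": self.reduction_pct_display,
            "cost_delta": self.cost_delta,
        }
        if self.constraint is not None:
            d["constraint"] = {
                "max_level": self.constraint.max_level,
                "min_reduction_pct": self.constraint.min_reduction_pct,
            }
        return d


def sweep_cost(
    N: int,
    lam: float,
    mu: float,
    rates: CostRates,
    R_range: Sequence[int] | None = None,
    awt_scale: float = 100.0,
) -> CostCurve:
    """Evaluate cost and AWT for every provider count in ``R_range``.

    ``R_range`` is an inclusive ``(R_min, R_max)`` pair (any ascending
    2-element sequence, so ``[3, 3]`` is the singleton sweep at R=3), a
    ``range``, or an explicit ascending list of provider counts of another
    length; the default sweep is ``1..min(12, N)``.
    """
    if R_range is None:
        Rs = list(range(1, min(12, N) + 1))
    else:
        Rs = [int(R) for R in R_range]
        if len(Rs) == 2 and Rs[0] <= Rs[1] and not isinstance(R_range, range):
            Rs = list(range(Rs[0], Rs[1] + 1))
    if not Rs:
        raise ValueError("R_range is empty")
    if any(b <= a for a, b in zip(Rs, Rs[1:])):
        raise ValueError("R_range must be strictly increasing")
    if Rs[0] < 1 or Rs[-1] > N:
        raise ValueError(f"R_range must lie within [1, N={N}], got {Rs[0]}..{Rs[-1]}")

    rows = []
    for R in Rs:
        ev = evaluate_cost(QueueParams(R=R, N=N, lam=lam, mu=mu), rates)
        awt = awt_scale * ev.measures.Lq / lam
        rows.append(CostCurveRow(R=R, F=ev.F, awt=awt, measures=ev.measures))
    return CostCurve(
        rows=tuple(rows), N=N, lam=lam, mu=mu, rates=rates, awt_scale=awt_scale
    )


def optimal_staffing(curve: CostCurve) -> tuple[int, float]:
    """Cost-minimising provider count ``(R*, F*)`` by exhaustive argmin.

    Ties break toward the smaller R (fewer staff at equal cost).
    """
    if not curve.rows:
        raise ValueError("empty cost curve")
    best = min(curve.rows, key=lambda r: (r.F, r.R))
    return best.R, best.F


def constrained_staffing(
    curve: CostCurve, constraint: AwtConstraint | None
) -> Recommendation:
    """Smallest provider count meeting the AWT constraint, with the achieved
    reduction and cost delta relative to the cost-optimal R*.

    An unsatisfiable constraint yields ``feasible=False`` (never an
    exception), so window-by-window plans can report per-window outcomes.
    """
    R_star, F_star = optimal_staffing(curve)
    awt_star = curve.row(R_star).awt
    if constraint is None:
        return Recommendation(
            R_star=R_star,
            F_star=F_star,
            awt_at_star=awt_star,
            R_constrained=R_star,
            F_constrained=F_star,
            awt_at_constrained=awt_star,
            reduction_pct=0.0,
            reduction_pct_display=0.0,
            cost_delta=0.0,
        )

    if constraint.max_level is not None:
        target = constraint.max_level
    else:
        target = awt_star * (1.0 - constraint.min_reduction_pct / 100.0)

    chosen = None
    for row in curve.rows:  # rows increasing in R -> first hit is smallest R
        if row.awt <= target:
            chosen = row
            break
    if chosen is None:
        return Recommendation(
            R_star=R_star,
            F_star=F_star,
            awt_at_star=awt_star,
            feasible=False,
            constraint=constraint,
        )

    reduction = (
        (awt_star - chosen.awt) / awt_star * 100.0 if awt_star > 0 else 0.0
    )
    # the reporting convention: reduction between the 2-dp AWTs as displayed
    awt_star_2dp, awt_chosen_2dp = round(awt_star, 2), round(chosen.awt, 2)
    reduction_display = (
        (awt_star_2dp - awt_chosen_2dp) / awt_star_2dp * 100.0
        if awt_star_2dp > 0
        else 0.0
    )
    return Recommendation(
        R_star=R_star,
        F_star=F_star,
        awt_at_star=awt_star,
        R_constrained=chosen.R,
        F_constrained=chosen.F,
        awt_at_constrained=chosen.awt,
        reduction_pct=reduction,
        reduction_pct_display=reduction_display,
        cost_delta=chosen.F - F_star,
        constraint=constraint,
    )


@dataclass(frozen=True)
class WindowPlan:
    """Per-time-window staffing plan: the window's rates, its cost curve and
    its recommendation."""

    label: str
    lam: float
    mu: float
    curve: CostCurve
    recommendation: Recommendation


def windowed_plan(
    windows: Sequence[tuple[str, float, float]],
    N: int,
    rates: CostRates,
    R_range: Sequence[int] | None = None,
    constraint: AwtConstraint | None = None,
    awt_scale: float = 100.0,
) -> list[WindowPlan]:
    """Apply the sweep + recommendation independently to each time window.

    Each window is ``(label, lam, mu)`` -- e.g. night shift vs. surge hours,
    with rates estimated from that window's history.  Output order preserves
    input order; an invalid window raises a ``ValueError`` naming its label.
    """
    plans: list[WindowPlan] = []
    for label, lam, mu in windows:
        try:
            curve = sweep_cost(N, lam, mu, rates, R_range=R_range, awt_scale=awt_scale)
            rec = constrained_staffing(curve, constraint)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"window {label!r}: {exc}") from exc
        plans.append(
            WindowPlan(label=label, lam=lam, mu=mu, curve=curve, recommendation=rec)
        )
    return plans
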