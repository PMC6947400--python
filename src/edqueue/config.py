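"""Scenario configuration (JSON) and report writers.

A scenario bundles everything one staffing study needs: the queue defaults
(capacity N, service rate mu), a single arrival rate or a list of labelled
time windows each with its own rates, the four cost rates, the sweep range,
an optional waiting-time constraint, and an optional simulation protocol.
Configs are validated on load with field-by-field messages; unknown keys are
rejected outright so typos never silently change a study.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cost import CostRates
from .decision import AwtConstraint, CostCurve
from .simulate import SimulationConfig

__all__ = [
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "scenario_to_dict",
    "write_cost_table",
    "format_awt",
]


class ScenarioError(ValueError):
    """A scenario file or flag set failed validation."""


class _RatesModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Cq: float = Field(ge=0)
    Cs: float = Field(ge=0)
    CB: float = Field(ge=0)
    CI: float = Field(ge=0)


class _WindowModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    lam: float = Field(gt=0)
    mu: float | None = Field(default=None, gt=0)


class _AwtModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_level: float | None = Field(default=None, ge=0)
    reduction_pct: float | None = None

    @model_validator(mode="after")
    def _one_of(self) -> "_AwtModel":
        if (self.max_level is None) == (self.reduction_pct is None):
            raise ValueError(
                "awt constraint needs exactly one of max_level / reduction_pct"
            )
        return self


class _SimModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    horizon: float = Field(default=2e5, gt=0)
    warmup: float = Field(default=0.1, ge=0, lt=1)
    replications: int = Field(default=20, ge=1)
    seed: int = 0


class Scenario(BaseModel):
    """One validated staffing study.

    Either ``lam`` (single window) or ``windows`` (several, each with its own
    ``lam`` and optionally its own ``mu``) must be present for sweep-style
    commands; ``R`` is only needed when evaluating a single provider count.
    """

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    N: int = Field(ge=1)
    mu: float = Field(gt=0)
    lam: float | None = Field(default=None, gt=0)
    R: int | None = Field(default=None, ge=1)
    windows: list[_WindowModel] | None = None
    rates: _RatesModel | None = None
    sweep: tuple[int, int] | None = None
    awt: _AwtModel | None = None
    awt_scale: float = Field(default=100.0, gt=0)
    sim: _SimModel | None = None

    @model_validator(mode="after")
    def _cross_checks(self) -> "Scenario":
        if self.R is not None and self.N < self.R:
            raise ValueError(f"N must satisfy N >= R (N={self.N}, R={self.R})")
        if self.sweep is not None:
            lo, hi = self.sweep
            if not (1 <= lo <= hi <= self.N):
                raise ValueError(
                    f"sweep range [{lo}, {hi}] must satisfy 1 <= lo <= hi <= N={self.N}"
                )
        if self.lam is not None and self.windows:
            raise ValueError("give either a single lam or windows, not both")
        return self

    # -- conversions to the computation-layer types ---------------------------

    def cost_rates(self) -> CostRates:
        if self.rates is None:
            raise ScenarioError("scenario has no cost rates (required for this command)")
        r = self.rates
        return CostRates(Cq=r.Cq, Cs=r.Cs, CB=r.CB, CI=r.CI)

    def sweep_range(self) -> tuple[int, int]:
        return self.sweep if self.sweep is not None else (1, min(12, self.N))

    def awt_constraint(self) -> AwtConstraint | None:
        if self.awt is None:
            return None
        return AwtConstraint(
            max_level=self.awt.max_level, min_reduction_pct=self.awt.reduction_pct
        )

    def sim_config(self) -> SimulationConfig:
        s = self.sim if self.sim is not None else _SimModel()
        return SimulationConfig(
            horizon=s.horizon, warmup=s.warmup,
            replications=s.replications, seed=s.seed,
        )

    def window_list(self) -> list[tuple[str, float, float]]:
        """Windows as (label, lam, mu) triples; a single-lam scenario is one
        window labelled 'all'."""
        if self.windows:
            return [
                (w.label, w.lam, w.mu if w.mu is not None else self.mu)
                for w in self.windows
            ]
        if self.lam is None:
            raise ScenarioError("scenario defines neither lam nor windows")
        return [("all", self.lam, self.mu)]


def load_scenario(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> Scenario:
    """Load and validate a scenario from a JSON file and/or override values.

    ``overrides`` (typically CLI flags) take precedence over file values;
    ``None`` overrides are ignored.  Raises :class:`ScenarioError` naming the
    offending field and the constraint it violated.
    """
    data: dict[str, Any] = {}
    if path is not None:
        p = Path(path)
        try:
            data = json.loads(p.read_text())
        except FileNotFoundError:
            raise ScenarioError(f"scenario file not found: {p}") from None
        except json.JSONDecodeError as exc:
            raise ScenarioError(f"scenario file {p} is not valid JSON: {exc}") from None
        if not isinstance(data, dict):
            raise ScenarioError(f"scenario file {p} must hold a JSON object")
    if overrides:
        for key, value in overrides.items():
            if value is not None:
                data[key] = value
    try:
        return Scenario.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(part) for part in err["loc"]) or "scenario"
            lines.append(f"{loc}: {err['msg']}")
        raise ScenarioError("invalid scenario: " + "; ".join(lines)) from None


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Round-trippable plain-dict form (load_scenario(write(s)) == s)."""
    return scenario.model_dump(exclude_none=True)


def format_awt(awt: float) -> str:
    """AWT display convention: 2 decimals, values below 0.005 shown as 0."""
    return "0" if awt < 0.005 else f"{awt:.2f}"


def write_cost_table(curve: CostCurve, path: str | Path) -> None:
    """Write a cost curve as CSV with header ``R,cost,awt``.

    Cost to 1 decimal, AWT to 2 decimals with the <0.005 -> 0 display rule.
    Byte-deterministic for a fixed curve (dot decimal separator, LF endings).
    """
    if not curve.rows:
        raise ValueError("empty cost curve")
    lines = ["R,cost,awt"]
    for row in curve.rows:
        lines.append(f"{row.R},{row.F:.1f},{format_awt(row.awt)}")
    Path(path).write_text("\n".join(lines) + "\n")
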