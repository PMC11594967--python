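"""Food and temperature forcing scenarios.

A :class:`ForcingScenario` supplies the scaled functional response ``f`` as a
function of time since birth (constant or piecewise linear) together with a
constant rearing temperature.  The embryo never feeds, so ``f`` only matters
from hatching onwards and scenario clocks start at birth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["ForcingScenario", "declining_food_scenario", "load_scenario", "save_scenario"]


@dataclass(frozen=True)
class ForcingScenario:
    """Constant-temperature forcing with constant or piecewise-linear f(t).

    ``f_breakpoints`` is a tuple of ``(t_since_birth_d, f)`` pairs with
    strictly increasing times; ``f`` is held constant outside the breakpoint
    range.  With an empty breakpoint list, ``f_constant`` applies at all
    times.  Values of f above 1 are permitted (rich-diet protocols) but must
    be set explicitly; the Holling map itself is bounded by 1.
    """

    T_celsius: float = 20.0
    f_constant: float = 1.0
    f_breakpoints: tuple[tuple[float, float], ...] = ()
    sex: str = "female"
    horizon_days: float = 200.0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.f_breakpoints:
            times = [t for t, _ in self.f_breakpoints]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("breakpoint times must be strictly increasing")
            if any(fv < 0 for _, fv in self.f_breakpoints):
                raise ValueError("f values must be non-negative")
        elif self.f_constant < 0:
            raise ValueError("f must be non-negative")

    @property
    def T_kelvin(self) -> float:
        return self.T_celsius + 273.15

    @property
    def is_constant(self) -> bool:
        return not self.f_breakpoints

    def f(self, t_since_birth: float) -> float:
        """Scaled functional response at ``t_since_birth`` days after hatching."""
        if self.is_constant:
            return self.f_constant
        times = [t for t, _ in self.f_breakpoints]
        values = [fv for _, fv in self.f_breakpoints]
        return float(np.interp(t_since_birth, times, values))

    def breakpoint_times(self) -> list[float]:
        """Times (since birth) at which f(t) has a kink; integration restarts here."""
        return [t for t, _ in self.f_breakpoints]


def declining_food_scenario(
    fmin: float,
    t_puberty: float,
    decline_duration: float = 7.5,
    T_celsius: float = 21.0,
    sex: str = "female",
) -> ForcingScenario:
    """Ad-libitum food until puberty, then a linear decline to ``fmin``.

    Emulates the rearing protocol inferred for the growth experiments:
    f = 1 from hatching until ``t_puberty`` (days since birth), then a linear
    decrease reaching ``fmin`` after ``decline_duration`` days (7.5 d by
    default), constant thereafter.  ``fmin`` above 1 is rejected here; build
    an explicit piecewise scenario for rich diets.
    """
    if not 0 <= fmin <= 1:
        raise ValueError("fmin must lie in [0, 1] for the declining-food constructor")
    if t_puberty < 0 or decline_duration <= 0:
        raise ValueError("times must be positive")
    points = (
        (0.0, 1.0),
        (t_puberty, 1.0),
        (t_puberty + decline_duration, fmin),
    )
    return ForcingScenario(
        T_celsius=T_celsius, f_breakpoints=points, sex=sex
    )


def load_scenario(path) -> ForcingScenario:
    """Read a scenario from a YAML file.

    Schema: ``{T_celsius, f_mode: constant|piecewise, f_value | breakpoints:
    [[t, f], ...], sex, horizon_days}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mode = raw.get("f_mode", "constant")
    kwargs = dict(
        T_celsius=float(raw.get("T_celsius", 20.0)),
        sex=raw.get("sex", "female"),
        horizon_days=float(raw.get("horizon_days", 200.0)),
    )
    if mode == "constant":
        kwargs["f_constant"] = float(raw.get("f_value", 1.0))
    elif mode == "piecewise":
        pts = tuple((float(t), float(fv)) for t, fv in raw["breakpoints"])
        kwargs["f_breakpoints"] = pts
    else:
        raise ValueError(f"unknown f_mode {mode!r}")
    return ForcingScenario(**kwargs)


def save_scenario(scenario: ForcingScenario, path) -> None:
    raw: dict = {
        "T_celsius": scenario.T_celsius,
        "sex": scenario.sex,
        "horizon_days": scenario.horizon_days,
    }
    if scenario.is_constant:
        raw["f_mode"] = "constant"
        raw["f_value"] = scenario.f_constant
    else:
        raw["f_mode"] = "piecewise"
        raw["breakpoints"] = [[t, fv] for t, fv in scenario.f_breakpoints]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
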