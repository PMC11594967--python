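"""Calibration datasets: schema, model predictions and synthetic generation.

A :class:`CalibrationDataset` is either *zero-variate* (one scalar datum,
e.g. age at pupation) or *uni-variate* (pairs, e.g. length vs age since
hatch), always tied to a forcing scenario.  The synthetic generator samples
the model under a design and applies multiplicative lognormal observation
noise, standing in for raw rearing-experiment data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .forcing import ForcingScenario
from .lifecycle import SimulationResult, simulate_lifecycle
from .observables import append_observables
from .parameters import CompositionParams, CoreParameterSet

__all__ = [
    "CalibrationDataset",
    "predict_dataset",
    "generate_synthetic_datasets",
    "packaged_zero_variate_data",
    "packaged_functional_responses",
]

#: zero-variate quantities the model can predict, mapped to report fields /
#: derived expressions (ages in d, lengths in cm, weights in mg)
ZERO_VARIATE_OBSERVABLES = (
    "age_at_birth",
    "age_at_puberty",
    "age_at_pupation",
    "age_at_emergence",
    "age_at_emergence_since_oviposition",
    "instar1_duration",
    "instar2_duration",
    "instar3_duration",
    "length_at_birth",
    "length_at_pupation",
    "egg_dry_weight",
    "wet_weight_at_pupation",
    "imago_dry_weight",
    "eggs_per_female",
)

UNI_VARIATE_OBSERVABLES = ("length", "wet_weight", "dry_weight", "survival_fraction")


@dataclass
class CalibrationDataset:
    """One dataset in the estimation scheme.

    For uni-variate kinds ``data`` has columns ``x`` (days since hatch) and
    ``y``; for zero-variate kinds ``data`` holds a single row whose ``y`` is
    the datum and whose ``x`` is ignored.  ``shape`` selects the shape
    coefficient for length observables ("alive" or "dead").  ``weight`` is
    the dataset weight coefficient in the loss.
    """

    name: str
    kind: str                      # "zero_variate" | "uni_variate"
    observable: str
    scenario: ForcingScenario
    data: pd.DataFrame
    unit: str = ""
    weight: float = 1.0
    shape: str = "alive"

    def __post_init__(self) -> None:
        if self.kind not in ("zero_variate", "uni_variate"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        allowed = ZERO_VARIATE_OBSERVABLES if self.kind == "zero_variate" \
            else UNI_VARIATE_OBSERVABLES
        if self.observable not in allowed:
            raise ValueError(
                f"observable {self.observable!r} not valid for {self.kind} data"
            )
        if self.weight < 0:
            raise ValueError("dataset weight must be non-negative")
        if not {"x", "y"} <= set(self.data.columns):
            raise ValueError("data table must have columns 'x' and 'y'")

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(dtype=float)


def _delta(params: CoreParameterSet, shape: str) -> float:
    if shape == "alive":
        return params.deltaM1
    if shape == "dead":
        return params.deltaM2
    raise ValueError(f"unknown shape convention {shape!r}")


def _zero_variate_value(
    ds: CalibrationDataset,
    sim: SimulationResult,
    params: CoreParameterSet,
    comp: CompositionParams,
) -> float:
    r = sim.report
    obs = ds.observable
    if obs in ("age_at_birth", "age_at_puberty", "age_at_pupation",
               "age_at_emergence", "age_at_emergence_since_oviposition"):
        return getattr(r, obs) if obs != "age_at_emergence_since_oviposition" \
            else r.age_at_emergence_since_oviposition
    if obs == "instar1_duration":
        return r.age_at_molt1
    if obs == "instar2_duration":
        return r.age_at_molt2 - r.age_at_molt1
    if obs == "instar3_duration":
        return r.age_at_puberty - r.age_at_molt2
    if obs == "length_at_birth":
        return r.Lb / _delta(params, ds.shape)
    if obs == "length_at_pupation":
        return r.Lj / _delta(params, ds.shape)
    if obs == "egg_dry_weight":
        return 1e3 * comp.wE_over_muE * r.E0  # mg; the fresh egg is pure reserve
    if obs == "eggs_per_female":
        return r.Ni
    traj = append_observables(sim.trajectory, params, comp)
    if obs == "wet_weight_at_pupation":
        mask = traj["stage"].isin(["L4_phase1", "L4_phase2"])
        return float(traj.loc[mask, "wet_weight_mg"].iloc[-1])
    if obs == "imago_dry_weight":
        mask = traj["stage"] == "imago"
        if not mask.any():
            return float("nan")
        return float(traj.loc[mask, "dry_weight_mg"].iloc[0])
    raise ValueError(f"unhandled zero-variate observable {obs!r}")


def predict_dataset(
    ds: CalibrationDataset,
    params: CoreParameterSet,
    comp: CompositionParams = CompositionParams(),
    _sim_cache: dict | None = None,
) -> np.ndarray:
    """Model predictions matching a dataset's observation design.

    Uni-variate predictions are interpolated from a trajectory simulated
    under the dataset's scenario (x is days since hatch); zero-variate
    predictions come from the life-history report.  ``_sim_cache`` may be
    shared across datasets with the same scenario to avoid re-simulating.
    """
    cache = _sim_cache if _sim_cache is not None else {}
    needs_imago = ds.observable == "imago_dry_weight"
    sim = cache.get(ds.scenario)
    if sim is None or (needs_imago and not (sim.trajectory["stage"] == "imago").any()
                       and sim.status == "completed"):
        sim = simulate_lifecycle(params, ds.scenario,
                                 stop_after="imago" if needs_imago else "emergence")
        cache[ds.scenario] = sim

    if ds.kind == "zero_variate":
        return np.array([_zero_variate_value(ds, sim, params, comp)])

    traj = append_observables(sim.trajectory, params, comp)
    t_hatch = sim.report.age_at_birth
    ages = traj["t_d"].to_numpy() - t_hatch
    if ds.observable == "length":
        col = "length_cm_alive" if ds.shape == "alive" else "length_cm_dead"
    elif ds.observable == "wet_weight":
        col = "wet_weight_mg"
    elif ds.observable == "dry_weight":
        col = "dry_weight_mg"
    elif ds.observable == "survival_fraction":
        col = "survival"
    else:
        raise ValueError(f"unhandled uni-variate observable {ds.observable!r}")
    post = ages >= 0
    return np.interp(ds.x, ages[post], traj.loc[post, col].to_numpy())


# --------------------------------------------------------------------------
# synthetic data generation
# --------------------------------------------------------------------------

def generate_synthetic_datasets(
    params: CoreParameterSet,
    scenario: ForcingScenario,
    *,
    times: np.ndarray | list,
    cv: float = 0.1,
    seed: int = 0,
    observables: tuple[str, ...] = ("length", "wet_weight"),
    events: tuple[str, ...] = ("age_at_puberty", "age_at_pupation", "eggs_per_female"),
    comp: CompositionParams = CompositionParams(),
) -> list[CalibrationDataset]:
    """Simulate the model and emit noisy datasets in the calibration schema.

    Observation noise is multiplicative lognormal with coefficient of
    variation ``cv`` and unit mean (all observables are positive), so
    ``cv = 0`` reproduces the model predictions exactly and sample means are
    unbiased for the predictions.  Event observables that the scenario does
    not reach (e.g. pupation under severe food limitation) are omitted
    rather than fabricated.  The truth parameters travel with the datasets
    in the ``attrs`` of each data table.
    """
    if cv < 0:
        raise ValueError("noise CV must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    def noisy(values: np.ndarray) -> np.ndarray:
        if cv == 0:
            return values.copy()
        z = rng.standard_normal(values.shape)
        return values * np.exp(sigma * z - 0.5 * sigma**2)

    sim = simulate_lifecycle(params, scenario, stop_after="imago")
    cache = {scenario: sim}
    out: list[CalibrationDataset] = []
    times = np.asarray(times, dtype=float)

    for obs in observables:
        ds = CalibrationDataset(
            name=f"synthetic_{obs}",
            kind="uni_variate",
            observable=obs,
            scenario=scenario,
            data=pd.DataFrame({"x": times, "y": np.nan}),
            unit="cm" if obs == "length" else ("-" if obs == "survival_fraction" else "mg"),
        )
        pred = predict_dataset(ds, params, comp, cache)
        ds.data["y"] = noisy(pred)
        ds.data.attrs["truth"] = params.to_dict()
        ds.data.attrs["cv"] = cv
        out.append(ds)

    for obs in events:
        ds = CalibrationDataset(
            name=f"synthetic_{obs}",
            kind="zero_variate",
            observable=obs,
            scenario=scenario,
            data=pd.DataFrame({"x": [0.0], "y": [np.nan]}),
            unit="d" if obs.startswith(("age", "instar")) else "",
        )
        pred = predict_dataset(ds, params, comp, cache)
        if not np.isfinite(pred[0]):
            continue  # event not reached under this scenario: omit, never fabricate
        ds.data["y"] = noisy(pred)
        ds.data.attrs["truth"] = params.to_dict()
        ds.data.attrs["cv"] = cv
        out.append(ds)
    return out


# --------------------------------------------------------------------------
# packaged fixtures: the printed zero-variate data and per-ration f values
# --------------------------------------------------------------------------

def _read_packaged_csv(name: str) -> pd.DataFrame:
    text = resources.files("chirodeb").joinpath(f"species/{name}").read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def packaged_zero_variate_data() -> list[CalibrationDataset]:
    """The packaged zero-variate observations for *C. riparius*.

    Transcribed single-point observations (ages, lengths, weights at the
    life-history events, and instar durations) with their rearing
    temperatures and measurement conventions, ready for goodness-of-fit
    evaluation or calibration without any hand transcription.
    """
    table = _read_packaged_csv("zero_variate_chironomus.csv")
    out = []
    for _, row in table.iterrows():
        scenario = ForcingScenario(T_celsius=float(row["T_celsius"]), f_constant=1.0)
        out.append(
            CalibrationDataset(
                name=str(row["name"]),
                kind="zero_variate",
                observable=str(row["observable"]),
                scenario=scenario,
                data=pd.DataFrame({"x": [0.0], "y": [float(row["value"])]}),
                unit=str(row["unit"]),
                shape=str(row["shape"]),
            )
        )
    return out


def packaged_functional_responses() -> pd.DataFrame:
    """Estimated scaled functional responses per food ration (mg/larva/d)."""
    return _read_packaged_csv("functional_responses.csv")
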