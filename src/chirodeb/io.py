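"""Dataset file round-tripping: CSV tables with YAML sidecars.

Each dataset is a ``<name>.csv`` with columns ``x,y`` plus a ``<name>.yaml``
sidecar describing kind, observable, unit, weight, shape convention and the
forcing scenario.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datasets import CalibrationDataset
from .forcing import ForcingScenario

__all__ = ["save_dataset", "load_dataset", "load_dataset_dir"]


def save_dataset(ds: CalibrationDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{ds.name}.csv"
    ds.data[["x", "y"]].to_csv(csv_path, index=False)
    sc = ds.scenario
    sidecar = {
        "kind": ds.kind,
        "observable": ds.observable,
        "unit": ds.unit,
        "weight": ds.weight,
        "shape": ds.shape,
        "scenario": {
            "T_celsius": sc.T_celsius,
            "sex": sc.sex,
            "horizon_days": sc.horizon_days,
            "f_mode": "constant" if sc.is_constant else "piecewise",
            **({"f_value": sc.f_constant} if sc.is_constant
               else {"breakpoints": [[t, fv] for t, fv in sc.f_breakpoints]}),
        },
    }
    (directory / f"{ds.name}.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return csv_path


def load_dataset(csv_path: str | Path) -> CalibrationDataset:
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    data = pd.read_csv(csv_path)
    missing = {"x", "y"} - set(data.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing required column(s) {sorted(missing)}")
    sc = meta["scenario"]
    kwargs = dict(T_celsius=float(sc["T_celsius"]), sex=sc.get("sex", "female"),
                  horizon_days=float(sc.get("horizon_days", 200.0)))
    if sc.get("f_mode", "constant") == "constant":
        kwargs["f_constant"] = float(sc.get("f_value", 1.0))
    else:
        kwargs["f_breakpoints"] = tuple(
            (float(t), float(fv)) for t, fv in sc["breakpoints"])
    return CalibrationDataset(
        name=csv_path.stem,
        kind=meta["kind"],
        observable=meta["observable"],
        scenario=ForcingScenario(**kwargs),
        data=data,
        unit=meta.get("unit", ""),
        weight=float(meta.get("weight", 1.0)),
        shape=meta.get("shape", "alive"),
    )


def load_dataset_dir(directory: str | Path) -> list[CalibrationDataset]:
    return [load_dataset(p) for p in sorted(Path(directory).glob("*.csv"))]
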