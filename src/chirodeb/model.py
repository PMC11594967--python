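"""Model / results objects tying simulation and calibration together.

:class:`DEBLifeCycleModel` is built from a collection of calibration
datasets (plus a starting parameter set); its :meth:`~DEBLifeCycleModel.fit`
returns a :class:`DEBLifeCycleResults` carrying the estimates, the loss and
goodness-of-fit metrics, a convergence log and a ``summary()`` table.
Simulation and plotting hang off both objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import (
    FitOutcome,
    FitSpecification,
    LossReport,
    evaluate,
    fit_parameters,
)
from .datasets import CalibrationDataset, predict_dataset
from .forcing import ForcingScenario
from .lifecycle import SimulationResult, simulate_lifecycle
from .parameters import CompositionParams, CoreParameterSet, chironomus_riparius

__all__ = ["DEBLifeCycleModel", "DEBLifeCycleResults"]


class DEBLifeCycleModel:
    """DEB life-cycle model confronted with calibration data.

    Parameters
    ----------
    datasets:
        Zero- and uni-variate observations, each tied to a forcing scenario.
    params:
        Starting parameter set (the packaged *C. riparius* set by default).
    composition:
        Coefficients converting state variables to weights.
    """

    def __init__(
        self,
        datasets: list[CalibrationDataset],
        params: CoreParameterSet | None = None,
        composition: CompositionParams = CompositionParams(),
    ) -> None:
        self.datasets = list(datasets)
        self.params = params if params is not None else chironomus_riparius()
        self.composition = composition

    @classmethod
    def from_tables(
        cls,
        tables: dict[str, pd.DataFrame],
        scenario: ForcingScenario,
        observables: dict[str, str],
        params: CoreParameterSet | None = None,
        **kwargs,
    ) -> "DEBLifeCycleModel":
        """Build a model from plain ``(x, y)`` tables sharing one scenario.

        ``observables`` maps each table name to its observable; tables with
        a single row are treated as zero-variate.
        """
        datasets = []
        for name, table in tables.items():
            kind = "zero_variate" if len(table) == 1 and observables[name] not in (
                "length", "wet_weight", "dry_weight", "survival_fraction"
            ) else "uni_variate"
            datasets.append(CalibrationDataset(
                name=name, kind=kind, observable=observables[name],
                scenario=scenario, data=table.copy(),
            ))
        return cls(datasets, params=params, **kwargs)

    # ------------------------------------------------------------------
    def predict(self, params: CoreParameterSet | None = None) -> dict[str, np.ndarray]:
        """Model predictions for every dataset under ``params``."""
        p = params if params is not None else self.params
        cache: dict = {}
        return {ds.name: predict_dataset(ds, p, self.composition, cache)
                for ds in self.datasets}

    def loss(self, params: CoreParameterSet | None = None) -> LossReport:
        """Goodness of fit of ``params`` (the starting set by default)."""
        return evaluate(params if params is not None else self.params,
                        self.datasets, self.composition)

    def fit(
        self,
        free: tuple[str, ...] = (),
        spec: FitSpecification | None = None,
        **spec_kwargs,
    ) -> "DEBLifeCycleResults":
        """Estimate the free parameters by Nelder-Mead; see FitSpecification.

        With an empty free set the model runs in prediction-only mode and
        the results object reports the starting parameters' fit.
        """
        if spec is None:
            spec = FitSpecification(free=tuple(free), **spec_kwargs)
        outcome = fit_parameters(self.params, self.datasets, spec, self.composition)
        return DEBLifeCycleResults(self, outcome, spec)

    def simulate(self, scenario: ForcingScenario, **kwargs) -> SimulationResult:
        return simulate_lifecycle(self.params, scenario, **kwargs)


class DEBLifeCycleResults:
    """Estimates, uncertainties-by-refit hooks and diagnostics of one fit."""

    def __init__(self, model: DEBLifeCycleModel, outcome: FitOutcome,
                 spec: FitSpecification) -> None:
        self.model = model
        self.spec = spec
        self.params: CoreParameterSet = outcome.params
        self.loss_report: LossReport = outcome.loss_report
        self.converged: bool = outcome.converged
        self.n_evaluations: int = outcome.n_evaluations
        self.history: pd.DataFrame = outcome.history

    # convenient scalars -------------------------------------------------
    @property
    def loss(self) -> float:
        return self.loss_report.loss_value

    @property
    def mre(self) -> float:
        return self.loss_report.MRE

    @property
    def smse(self) -> float:
        return self.loss_report.SMSE

    @property
    def estimates(self) -> dict[str, float]:
        return {name: getattr(self.params, name) for name in self.spec.free}

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "DEB life-cycle model fit",
            "=" * 58,
            f"datasets: {len(self.model.datasets):>4}    "
            f"free parameters: {len(self.spec.free)}",
            f"loss: {self.loss:.6g}    MRE: {self.mre:.4f}    SMSE: {self.smse:.4f}",
            f"converged: {self.converged}    evaluations: {self.n_evaluations}",
            "-" * 58,
        ]
        if self.spec.free:
            start = self.model.params
            lines.append(f"{'parameter':<12}{'start':>14}{'estimate':>14}{'ratio':>10}")
            for name in self.spec.free:
                s, e = getattr(start, name), getattr(self.params, name)
                lines.append(f"{name:<12}{s:>14.6g}{e:>14.6g}{e / s:>10.4f}")
            lines.append("-" * 58)
        lines.append(self.loss_report.per_dataset.to_string(index=False))
        return "\n".join(lines)

    def predict(self) -> dict[str, np.ndarray]:
        return self.model.predict(self.params)

    def simulate(self, scenario: ForcingScenario, **kwargs) -> SimulationResult:
        return simulate_lifecycle(self.params, scenario, **kwargs)

    def plot_fit(self, ax=None):
        """Overlay uni-variate data and fitted predictions (one panel)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        preds = self.predict()
        for ds in self.model.datasets:
            if ds.kind != "uni_variate":
                continue
            pts = ax.plot(ds.x, ds.y, "o", label=f"{ds.name} (data)")
            ax.plot(ds.x, preds[ds.name], "-", color=pts[0].get_color(),
                    label=f"{ds.name} (fit)")
        ax.set_xlabel("time since hatch (d)")
        ax.legend(fontsize="small")
        return ax
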