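"""Multi-dataset parameter estimation and goodness-of-fit metrics.

All parameters are estimated simultaneously by Nelder-Mead minimization of
the symmetric bounded loss

    F = sum_i sum_j w_ij (d_ij - p_ij)^2 / (d_ij^2 + p_ij^2),

whose per-point contributions are scale-invariant, symmetric in data and
prediction, and bounded by the point weight.  Pseudo-data — weakly weighted
prior-like targets, notably the maintenance ratio k = kJ [EG]/[pM] set to 1
— stabilise weakly identified parameters.  Goodness of fit is reported as
the mean relative error (MRE) and the symmetric mean squared error (SMSE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datasets import CalibrationDataset, predict_dataset
from .parameters import CompositionParams, CoreParameterSet

__all__ = [
    "LossReport",
    "FitSpecification",
    "symmetric_bounded_loss",
    "goodness_of_fit",
    "fit_parameters",
    "FitOutcome",
]


def symmetric_bounded_loss(data, predictions, weights=None) -> float:
    """Symmetric bounded loss between matched data and prediction arrays.

    Each point contributes ``w (d - p)^2 / (d^2 + p^2)`` (defined as 0 when
    both d and p vanish), so contributions are invariant under rescaling a
    point and never exceed its weight.
    """
    d = np.asarray(data, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if d.shape != p.shape:
        raise ValueError("data and predictions must have matching shapes")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != d.shape:
        raise ValueError("weights must match the data shape")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    denom = d**2 + p**2
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(denom > 0, (d - p) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return float(np.sum(w * contrib))


@dataclass
class LossReport:
    """Loss and goodness-of-fit summary of one model/data confrontation."""

    loss_value: float
    MRE: float
    SMSE: float
    per_dataset: pd.DataFrame  # name, n, relative_error, smse, weight

    def __str__(self) -> str:
        lines = [
            f"loss = {self.loss_value:.6g}   MRE = {self.MRE:.4f}   SMSE = {self.SMSE:.4f}",
            self.per_dataset.to_string(index=False),
        ]
        return "\n".join(lines)


def goodness_of_fit(
    datasets: list[CalibrationDataset],
    predictions: list[np.ndarray],
) -> LossReport:
    """MRE, SMSE and total loss for matched datasets and predictions.

    Each dataset contributes its within-dataset mean relative deviation
    |p - d| / |d| and mean symmetric squared deviation; MRE and SMSE are the
    dataset-weight-weighted means of these (zero-weight datasets are
    reported but excluded from the aggregates).  Points with a zero datum
    are excluded from the MRE (the relative error is undefined there).
    """
    rows = []
    for ds, pred in zip(datasets, predictions, strict=True):
        d = ds.y
        p = np.asarray(pred, dtype=float)
        ok = np.isfinite(p) & np.isfinite(d)
        d, p = d[ok], p[ok]
        nonzero = d != 0
        rel = float(np.mean(np.abs(p[nonzero] - d[nonzero]) / np.abs(d[nonzero]))) \
            if nonzero.any() else math.nan
        sm = symmetric_bounded_loss(d, p) / max(len(d), 1)
        rows.append((ds.name, len(d), rel, sm, ds.weight))
    table = pd.DataFrame(rows, columns=["name", "n", "relative_error", "smse", "weight"])
    w = table["weight"].to_numpy(dtype=float)
    used = w > 0
    if used.any():
        mre = float(np.average(table.loc[used, "relative_error"].fillna(0.0), weights=w[used]))
        smse = float(np.average(table.loc[used, "smse"], weights=w[used]))
        loss = float(np.sum([
            symmetric_bounded_loss(ds.y, pred) * ds.weight / max(len(ds.y), 1)
            for ds, pred in zip(datasets, predictions)
        ]))
    else:
        mre = smse = loss = 0.0
    return LossReport(loss_value=loss, MRE=mre, SMSE=smse, per_dataset=table)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

#: pseudo-data quantities: name -> (extractor from CoreParameterSet)
_PSEUDO_QUANTITIES = {
    "maintenance_ratio": lambda tp: tp.maintenance_ratio,
    "kappa": lambda tp: tp.kappa,
    "v": lambda tp: tp.v,
    "kJ": lambda tp: tp.kJ,
}


@dataclass
class FitSpecification:
    """What to fit and how.

    ``free`` names the CoreParameterSet fields to estimate (all strictly
    positive, searched in log space).  ``pseudo_data`` maps quantity names
    to ``(target, weight)`` pairs; the default keeps the maintenance ratio
    k near 1 with a small weight.  ``restarts`` jittered Nelder-Mead
    restarts make the search more robust; the whole procedure is
    deterministic given ``seed``.
    """

    free: tuple[str, ...] = ()
    pseudo_data: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"maintenance_ratio": (1.0, 0.1)}
    )
    maxiter: int = 500
    xtol: float = 1e-4
    ftol: float = 1e-8
    restarts: int = 3
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        valid = set(CoreParameterSet().to_dict())
        unknown = set(self.free) - valid
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        for name in self.pseudo_data:
            if name not in _PSEUDO_QUANTITIES:
                raise ValueError(f"unknown pseudo-data quantity {name!r}")


@dataclass
class FitOutcome:
    """Raw result of :func:`fit_parameters`."""

    params: CoreParameterSet
    loss_report: LossReport
    converged: bool
    n_evaluations: int
    history: pd.DataFrame  # accepted-step convergence log


def _total_loss(
    params: CoreParameterSet,
    datasets: list[CalibrationDataset],
    spec: FitSpecification,
    comp: CompositionParams,
) -> float:
    cache: dict = {}
    total = 0.0
    try:
        for ds in datasets:
            if ds.weight == 0:
                continue
            pred = predict_dataset(ds, params, comp, cache)
            ok = np.isfinite(pred)
            if not ok.all():  # unreachable event under these parameters
                total += float(np.sum(~ok)) * ds.weight  # max-loss penalty per point
            total += symmetric_bounded_loss(ds.y[ok], pred[ok]) * ds.weight / max(len(ds.y), 1)
    except (RuntimeError, ValueError):
        return 1e6  # pathological parameter set: integration failed
    for name, (target, weight) in spec.pseudo_data.items():
        value = _PSEUDO_QUANTITIES[name](params)
        total += symmetric_bounded_loss([target], [value], [weight])
    return total


def fit_parameters(
    initial: CoreParameterSet,
    datasets: list[CalibrationDataset],
    spec: FitSpecification,
    comp: CompositionParams = CompositionParams(),
) -> FitOutcome:
    """Simultaneous Nelder-Mead estimation of the free parameters.

    Free parameters are searched as logarithms (positivity by construction).
    With no free parameters the initial set is evaluated and returned.  On
    non-convergence within the iteration budget the best point found is
    returned with ``converged=False``.
    """
    free = list(spec.free)
    log_rows: list[tuple] = []
    if not free:
        report = evaluate(initial, datasets, comp)
        return FitOutcome(initial, report, True, 1, pd.DataFrame(
            columns=["restart", "n_eval", "loss", *free]))

    rng = np.random.default_rng(spec.seed)
    x0 = np.log([getattr(initial, name) for name in free])
    n_eval = 0
    running_best = np.inf
    restart = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval, running_best
        n_eval += 1
        params = initial.replace(**{n: float(v) for n, v in zip(free, np.exp(x))})
        f = _total_loss(params, datasets, spec, comp)
        if f < running_best:  # convergence log: every accepted improvement
            running_best = f
            log_rows.append((restart, n_eval, f, *[float(v) for v in np.exp(x)]))
        return f

    best_x, best_f, converged = None, np.inf, False
    for restart in range(max(spec.restarts, 1)):
        start = x0 if restart == 0 else (
            best_x if best_x is not None else x0
        ) + rng.normal(0.0, spec.jitter, size=len(free))
        res = minimize(
            objective, start, method="Nelder-Mead",
            options=dict(maxiter=spec.maxiter, xatol=spec.xtol, fatol=spec.ftol,
                         adaptive=True),
        )
        if res.fun < best_f:
            best_x, best_f = res.x.copy(), float(res.fun)
            converged = bool(res.success)

    fitted = initial.replace(**{n: float(v) for n, v in zip(free, np.exp(best_x))})
    report = evaluate(fitted, datasets, comp)
    history = pd.DataFrame(log_rows, columns=["restart", "n_eval", "loss", *free])
    return FitOutcome(fitted, report, converged, n_eval, history)


def evaluate(
    params: CoreParameterSet,
    datasets: list[CalibrationDataset],
    comp: CompositionParams = CompositionParams(),
) -> LossReport:
    """Goodness of fit of one parameter set against a dataset collection."""
    cache: dict = {}
    preds = [predict_dataset(ds, params, comp, cache) for ds in datasets]
    return goodness_of_fit(datasets, preds)
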