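"""G-computation on a fitted ensemble.

Counterfactual predictions are formed by overwriting exposure columns with
fixed values (everything else kept at observed levels) and averaging the
ensemble predictions over the sample.  Exposed quantities:

* per-exposure quantile-contrast effects (75th vs 25th percentile by
  default, reported in outcome-SD units per IQR),
* the joint contrast with every exposure of interest moved to its own
  percentile simultaneously,
* sample-average dose-response ("partial dependence") curves over a
  percentile grid, and
* individual conditional expectation (ICE) curves, whose spread in slope
  quantifies departure from additivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mixglearn.preprocess import AnalysisDataset
from mixglearn.superlearner import SuperLearnerFit, sl_predict

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "EffectEstimate",
    "ICEBundle",
    "PartialDependenceCurve",
    "ice",
    "ice_dispersion",
    "joint_nace",
    "nace",
    "partial_dependence",
    "predict_counterfactual",
]

#: Default percentile grid for dose-response and ICE curves: 5..95 by 5.
DEFAULT_GRID: tuple[float, ...] = tuple(range(5, 100, 5))


@dataclass(frozen=True)
class EffectEstimate:
    """A quantile-contrast effect for one exposure or a joint set."""

    target: str
    low_pct: float
    high_pct: float
    estimate: float
    scale_note: str = "SD per IQR"

    def __post_init__(self) -> None:
        if not self.low_pct < self.high_pct:
            raise ValueError("low_pct must be < high_pct")
        if not np.isfinite(self.estimate):
            raise ValueError("estimate must be finite")


@dataclass(frozen=True)
class PartialDependenceCurve:
    exposure: str
    grid: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if list(self.grid) != sorted(set(self.grid)):
            raise ValueError("grid must be strictly increasing")
        if len(self.values) != len(self.grid):
            raise ValueError("values/grid length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")


@dataclass(frozen=True)
class ICEBundle:
    """Per-individual percentile-sweep curves (n rows x G grid points)."""

    exposure: str
    grid: tuple[float, ...]
    curves: np.ndarray
    x_values: np.ndarray = field(default=None)  # counterfactual X at each point

    @property
    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)


def _check_exposures(data: AnalysisDataset, names: Sequence[str]) -> None:
    unknown = [n for n in names if n not in data.X.columns]
    if unknown:
        raise KeyError(f"unknown exposure(s) {unknown}")


def predict_counterfactual(
    fit: SuperLearnerFit,
    data: AnalysisDataset,
    assignments: Mapping[str, float],
) -> np.ndarray:
    """Ensemble predictions with assigned exposures fixed for every row."""
    _check_exposures(data, list(assignments))
    for name, value in assignments.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite assignment for {name!r}")
    design = data.design()
    cols = data.design_columns()
    for name, value in assignments.items():
        design[:, cols.index(name)] = value
    return sl_predict(fit, design)


def nace(
    fit: SuperLearnerFit,
    data: AnalysisDataset,
    exposure: str,
    low_pct: float = 25.0,
    high_pct: float = 75.0,
) -> EffectEstimate:
    """Sample-average prediction contrast: exposure at its ``high_pct`` vs
    ``low_pct`` percentile, all else at observed values."""
    return joint_nace(fit, data, [exposure], low_pct, high_pct)


def joint_nace(
    fit: SuperLearnerFit,
    data: AnalysisDataset,
    exposures: Sequence[str],
    low_pct: float = 25.0,
    high_pct: float = 75.0,
) -> EffectEstimate:
    """Joint contrast: every listed exposure moved to its own percentile
    simultaneously.  A singleton list reduces exactly to :func:`nace`."""
    exposures = list(exposures)
    if not exposures:
        raise ValueError("exposure set must be nonempty")
    _check_exposures(data, exposures)
    if not low_pct < high_pct:
        raise ValueError("low_pct must be < high_pct")
    hi = {e: data.exposure_quantile(e, high_pct) for e in exposures}
    lo = {e: data.exposure_quantile(e, low_pct) for e in exposures}
    if all(hi[e] == lo[e] for e in exposures):
        logger.warning(
            "degenerate contrast for %s: identical quantiles; returning 0",
            exposures,
        )
        estimate = 0.0
    else:
        estimate = float(
            predict_counterfactual(fit, data, hi).mean()
            - predict_counterfactual(fit, data, lo).mean()
        )
    target = exposures[0] if len(exposures) == 1 else "joint:" + "+".join(exposures)
    return EffectEstimate(
        target=target, low_pct=low_pct, high_pct=high_pct, estimate=estimate
    )


def partial_dependence(
    fit: SuperLearnerFit,
    data: AnalysisDataset,
    exposure: str,
    grid: Sequence[float] = DEFAULT_GRID,
) -> PartialDependenceCurve:
    """Sample-average dose-response curve over a percentile grid."""
    bundle = ice(fit, data, exposure, grid)
    return PartialDependenceCurve(
        exposure=exposure, grid=bundle.grid, values=bundle.mean_curve
    )


def ice(
    fit: SuperLearnerFit,
    data: AnalysisDataset,
    exposure: str,
    grid: Sequence[float] = DEFAULT_GRID,
) -> ICEBundle:
    """Individual conditional expectation curves over a percentile grid.

    Row i of the result is individual i's predicted outcome as the
    exposure sweeps the grid percentiles, with their other exposures and
    covariates held at observed values.  The column means equal the
    partial-dependence curve by construction.
    """
    _check_exposures(data, [exposure])
    grid = tuple(float(p) for p in grid)
    if list(grid) != sorted(set(grid)):
        raise ValueError("grid must be strictly increasing")
    if grid and (grid[0] < 0 or grid[-1] > 100):
        raise ValueError("grid percentiles must lie in [0, 100]")
    x_values = np.array([data.exposure_quantile(exposure, p) for p in grid])
    curves = np.empty((data.n, len(grid)))
    for g, xv in enumerate(x_values):
        curves[:, g] = predict_counterfactual(fit, data, {exposure: xv})
    return ICEBundle(exposure=exposure, grid=grid, curves=curves, x_values=x_values)


def ice_dispersion(bundle: ICEBundle) -> float:
    """Spread of individual dose-response slopes.

    Each curve's least-squares slope is taken against the counterfactual
    exposure values at the grid points; the population standard deviation
    (ddof=0) across individuals is returned.  Zero means perfectly
    parallel curves (no interaction signal).
    """
    if len(bundle.grid) < 2:
        raise ValueError("need at least 2 grid points")
    x = np.asarray(
        bundle.x_values
        if bundle.x_values is not None
        else np.asarray(bundle.grid, dtype=float)
    )
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return 0.0
    slopes = (bundle.curves - bundle.curves.mean(axis=1, keepdims=True)) @ xc / denom
    return float(np.std(slopes, ddof=0))
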