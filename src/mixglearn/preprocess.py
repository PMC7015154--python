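"""Raw cohort table -> analysis-ready dataset.

Implements the fixed preprocessing contract: simplified ΣPCB construction,
base-10 log transform with column-mean centering of exposures, outcome
standardization to mean 0 / sd 1 on the analysis sample, strict
complete-case filtering (no imputation), and type-7 quantiles computed on
the transformed exposure scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mixglearn.synthetic import CATEGORICAL_LEVELS, CHEMICALS

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisDataset",
    "MODEL_COVARIATES",
    "build_analysis_dataset",
    "code_covariates",
    "complete_case",
    "inverse_transform_exposures",
    "quantile",
    "standardize_outcome",
    "sum_pcb",
    "transform_exposures",
]

#: Covariate sets per timepoint model.  The age-5 model additionally uses
#: the maternal exposures themselves (log10-centered) as covariates.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "maternal": (
        "age_months",
        "sex",
        "maternal_age",
        "bmi",
        "parity",
        "raven",
        "ses",
        "alcohol",
        "smoking",
    ),
    "age5": (
        "age_months",
        "sex",
        "maternal_age",
        "bmi",
        "parity",
        "raven",
        "ses",
        "alcohol",
        "smoking",
        "breastfeeding_months",
        "birth_weight",
    ),
}


def sum_pcb(cb138, cb153, cb180, lipids=None):
    """Simplified total-PCB summary: 2 * (CB-138 + CB-153 + CB-180).

    When ``lipids`` (total lipid concentration) is supplied the sum is
    expressed per unit lipid.  Accepts scalars or aligned arrays.
    """
    cb138 = np.asarray(cb138, dtype=float)
    cb153 = np.asarray(cb153, dtype=float)
    cb180 = np.asarray(cb180, dtype=float)
    if np.any(cb138 < 0) or np.any(cb153 < 0) or np.any(cb180 < 0):
        raise ValueError("congener concentrations must be >= 0")
    total = 2.0 * (cb138 + cb153 + cb180)
    if lipids is not None:
        lipids = np.asarray(lipids, dtype=float)
        if np.any(lipids <= 0):
            raise ValueError("lipid concentrations must be > 0")
        total = total / lipids
    if total.ndim == 0:
        return float(total)
    return total


def transform_exposures(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """log10-transform and column-mean-center strictly positive exposures.

    Returns the transformed matrix and the centering constants (the
    column means of the log10 values) needed for the inverse map.
    """
    vals = raw.to_numpy(dtype=float)
    bad = ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive exposure at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    logx = np.log10(vals)
    centers = pd.Series(logx.mean(axis=0), index=raw.columns, name="center")
    x = pd.DataFrame(logx - centers.to_numpy(), columns=raw.columns, index=raw.index)
    return x, centers


def inverse_transform_exposures(x: pd.DataFrame, centers: pd.Series) -> pd.DataFrame:
    """Invert :func:`transform_exposures` back to concentrations."""
    return pd.DataFrame(
        np.power(10.0, x.to_numpy(dtype=float) + centers[x.columns].to_numpy()),
        columns=x.columns,
        index=x.index,
    )


def standardize_outcome(y) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, sd 1 using the sample sd (ddof=1).

    Returns ``(y_std, mean, sd)``.  Raises on (near-)zero variance.
    """
    y = np.asarray(y, dtype=float)
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("outcome has zero variance; cannot standardize")
    return (y - mean) / sd, mean, sd


def complete_case(
    table: pd.DataFrame, required_columns: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop rows with any missing required field; order preserved.

    Per-column missingness counts are logged.  Raises if no complete
    cases remain.  Returns the filtered table and the kept row labels.
    """
    missing_cols = [c for c in required_columns if c not in table.columns]
    if missing_cols:
        raise KeyError(f"required columns absent from table: {missing_cols}")
    sub = table[list(required_columns)]
    na = sub.isna()
    for col in required_columns:
        n_missing = int(na[col].sum())
        if n_missing:
            logger.info("complete_case: column %r missing in %d rows", col, n_missing)
    keep = ~na.any(axis=1)
    kept = table.loc[keep]
    logger.info("complete_case: kept %d of %d rows", len(kept), len(table))
    if kept.empty:
        raise ValueError("no complete cases remain after filtering")
    return kept, kept.index.to_numpy()


def quantile(x, p: float) -> float:
    """Type-7 (linear interpolation) quantile at percentile ``p``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot take quantile of empty vector")
    if not 0 <= p <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.quantile(x, p / 100.0, method="linear"))


def code_covariates(
    covariates: pd.DataFrame,
    levels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Numeric coding: binary categoricals to 0/1, multi-level ones to
    reference-coded indicator pairs, continuous passed through as float.

    Level order (reference first) comes from ``levels``; columns not
    listed there are treated as continuous.
    """
    levels = dict(CATEGORICAL_LEVELS if levels is None else levels)
    out: dict[str, np.ndarray] = {}
    for col in covariates.columns:
        if col in levels:
            lv = list(levels[col])
            vals = covariates[col].astype(str)
            unknown = set(vals.unique()) - set(lv)
            if unknown:
                raise ValueError(f"column {col!r} has undeclared levels {unknown}")
            if len(lv) == 2:
                out[col] = (vals == lv[1]).to_numpy(dtype=float)
            else:
                for level in lv[1:]:
                    out[f"{col}_{level}"] = (vals == level).to_numpy(dtype=float)
        else:
            out[col] = covariates[col].to_numpy(dtype=float)
    return pd.DataFrame(out, index=covariates.index)


@dataclass
class AnalysisDataset:
    """Preprocessed complete-case analysis matrix.

    ``Y`` is the standardized outcome, ``X`` the log10-centered exposure
    matrix, ``W`` the numerically coded covariate matrix.  Quantiles are
    taken on the X (transformed) scale; by monotonicity of log10 they
    agree with log10 of the raw-scale quantiles.
    """

    Y: np.ndarray
    X: pd.DataFrame
    W: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.Y) != len(self.X) or len(self.X) != len(self.W):
            raise ValueError("Y, X, W must have equal length")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def exposure_names(self) -> list[str]:
        return list(self.X.columns)

    def design(self) -> np.ndarray:
        """Stacked [X | W] prediction matrix."""
        return np.column_stack(
            [self.X.to_numpy(dtype=float), self.W.to_numpy(dtype=float)]
        )

    def design_columns(self) -> list[str]:
        return list(self.X.columns) + list(self.W.columns)

    def exposure_quantile(self, name: str, p: float) -> float:
        """Type-7 quantile of one exposure on the transformed scale."""
        if name not in self.X.columns:
            raise KeyError(f"unknown exposure {name!r}")
        return quantile(self.X[name].to_numpy(), p)

    def quantile_table(self, grid: Iterable[float]) -> pd.DataFrame:
        """Percentile-by-exposure table on the transformed scale."""
        grid = sorted(grid)
        return pd.DataFrame(
            {
                name: [self.exposure_quantile(name, p) for p in grid]
                for name in self.X.columns
            },
            index=pd.Index(grid, name="percentile"),
        )


def build_analysis_dataset(
    table: pd.DataFrame,
    outcome: str,
    model: str = "maternal",
    exposure_cols: Sequence[str] | None = None,
    covariate_cols: Sequence[str] | None = None,
    id_col: str | None = "child_id",
    levels: Mapping[str, Sequence[str]] | None = None,
) -> AnalysisDataset:
    """Assemble the analysis dataset for one outcome and timepoint model.

    Default column selection follows the simulator's naming: exposures are
    ``<chemical>_<model>`` and covariates come from
    :data:`MODEL_COVARIATES`; the age-5 model also conditions on the
    maternal exposures (log10-centered).  Complete-case filtering happens
    first; centering, standardization and quantiles are computed on the
    retained sample.
    """
    if model not in MODEL_COVARIATES:
        raise ValueError(f"model must be one of {sorted(MODEL_COVARIATES)}")
    if exposure_cols is None:
        exposure_cols = [f"{c}_{model}" for c in CHEMICALS]
    if covariate_cols is None:
        covariate_cols = list(MODEL_COVARIATES[model])
        if model == "age5":
            covariate_cols += [f"{c}_maternal" for c in CHEMICALS]
    exposure_like_covs = [c for c in covariate_cols if c.endswith(tuple(
        f"_{tp}" for tp in ("maternal", "age5")
    ))]
    required = [outcome, *exposure_cols, *covariate_cols]
    kept, row_ids = complete_case(table, required)
    if id_col and id_col in kept.columns:
        row_ids = kept[id_col].to_numpy()

    x, centers = transform_exposures(kept[list(exposure_cols)])
    y, y_mean, y_sd = standardize_outcome(kept[outcome].to_numpy())

    plain_covs = [c for c in covariate_cols if c not in exposure_like_covs]
    w = code_covariates(kept[plain_covs], levels=levels)
    if exposure_like_covs:
        w_exp, cov_centers = transform_exposures(kept[exposure_like_covs])
        w = pd.concat([w, w_exp], axis=1)
    else:
        cov_centers = pd.Series(dtype=float)

    ds = AnalysisDataset(
        Y=y,
        X=x.reset_index(drop=True),
        W=w.reset_index(drop=True),
        meta={
            "outcome": outcome,
            "model": model,
            "row_ids": row_ids,
            "centers": centers,
            "covariate_exposure_centers": cov_centers,
            "y_mean": y_mean,
            "y_sd": y_sd,
        },
    )
    return ds
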