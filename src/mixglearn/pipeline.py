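"""End-to-end driver: preprocess -> ensemble -> G-computation -> bootstrap.

Uncertainty is quantified by a nonparametric bootstrap of the *entire*
pipeline: rows of the raw table are resampled with replacement, and each
replicate redoes complete-case filtering, transformation, quantile
computation, fold assignment, weight solving and refitting before the
effect contrasts are recomputed.  Confidence intervals are the 2.5th and
97.5th percentiles of the replicate distribution (type-7 quantiles).

A single master seed spawns independent substreams for the point-estimate
fit and for every replicate, so runs are reproducible and replicates are
order-independent (they are keyed by replicate index, not execution
order).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from mixglearn import gcomp
from mixglearn.preprocess import AnalysisDataset, build_analysis_dataset, quantile
from mixglearn.superlearner import (
    DEFAULT_LIBRARY,
    FAST_LIBRARY,
    LearnerSpec,
    fit_full,
    fit_superlearner,
    risk_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "PipelineConfig",
    "percentile_ci",
    "resample",
    "run_analysis",
    "run_replicate",
]

_LIBRARY_PRESETS = {
    "default": DEFAULT_LIBRARY,
    "fast": FAST_LIBRARY,
}


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible analysis run."""

    outcome: str = "bnt_cued"
    model: str = "maternal"
    library: str | Sequence = "fast"
    k: int = 10
    grid: tuple[float, ...] = gcomp.DEFAULT_GRID
    low_pct: float = 25.0
    high_pct: float = 75.0
    B: int = 200
    seed: int = 0
    input_path: str | None = None
    out_dir: str | None = None
    include_joint: bool = True
    include_curves: bool = True
    targets: tuple[str, ...] | None = None  # None = every exposure (+ joint)
    refit_weights_in_bootstrap: bool = True
    fixed_quantiles: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not self.low_pct < self.high_pct:
            raise ValueError("low_pct must be < high_pct")

    def resolve_library(self) -> tuple[LearnerSpec, ...]:
        if isinstance(self.library, str):
            try:
                return _LIBRARY_PRESETS[self.library]
            except KeyError:
                raise ValueError(
                    f"unknown library preset {self.library!r}"
                ) from None
        out = []
        for item in self.library:
            if isinstance(item, LearnerSpec):
                out.append(item)
            elif isinstance(item, str):
                out.append(LearnerSpec(item, seed_offset=len(out)))
            else:
                out.append(
                    LearnerSpec(
                        item["id"],
                        dict(item.get("hyperparameters", {})),
                        int(item.get("seed_offset", len(out))),
                    )
                )
        return tuple(out)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        if not isinstance(self.library, str):
            d["library"] = [
                dataclasses.asdict(s) if isinstance(s, LearnerSpec) else s
                for s in self.library
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class BootstrapResult:
    """Point estimate plus its bootstrap percentile interval."""

    target: str
    point: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")


def resample(table: pd.DataFrame, seed) -> pd.DataFrame:
    """Draw n rows with replacement from the raw (pre-preprocessing) table."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n)
    return table.iloc[idx].reset_index(drop=True)


def percentile_ci(
    replicates, levels: tuple[float, float] = (2.5, 97.5)
) -> tuple[float, float]:
    """Type-7 percentile interval of the replicate distribution."""
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size < 2:
        raise ValueError("need at least 2 finite replicates")
    lo, hi = sorted(levels)
    return quantile(reps, lo), quantile(reps, hi)


def _effect_targets(config: PipelineConfig, data: AnalysisDataset) -> list:
    if config.targets is not None:
        return [[e] for e in config.targets]
    targets: list = [[e] for e in data.exposure_names]
    if config.include_joint:
        targets.append(list(data.exposure_names))
    return targets


def _estimate_effects(
    config: PipelineConfig,
    data: AnalysisDataset,
    fit,
    quantile_map: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Effect estimates for every configured target.

    ``quantile_map`` (exposure -> (q_low, q_high) on the X scale) pins the
    counterfactual values instead of recomputing them from ``data`` — used
    by the fixed-quantile bootstrap variant.
    """
    out = {}
    for exposures in _effect_targets(config, data):
        if quantile_map is None:
            est = gcomp.joint_nace(
                fit, data, exposures, config.low_pct, config.high_pct
            )
            out[est.target] = est.estimate
        else:
            hi = {e: quantile_map[e][1] for e in exposures}
            lo = {e: quantile_map[e][0] for e in exposures}
            val = float(
                gcomp.predict_counterfactual(fit, data, hi).mean()
                - gcomp.predict_counterfactual(fit, data, lo).mean()
            )
            key = (exposures[0] if len(exposures) == 1
                   else "joint:" + "+".join(exposures))
            out[key] = val
    return out


def run_replicate(
    config: PipelineConfig,
    table: pd.DataFrame,
    replicate_seed,
    weights: np.ndarray | None = None,
    quantile_map: dict | None = None,
) -> dict[str, float]:
    """Full pipeline on one (possibly resampled) raw table.

    Returns the effect estimates keyed by target.  ``weights`` pins the
    ensemble weights (used when ``refit_weights_in_bootstrap`` is off);
    ``quantile_map`` pins the counterfactual quantile values (used when
    ``fixed_quantiles`` is on).
    """
    data = build_analysis_dataset(table, config.outcome, config.model)
    seed_int = int(np.random.default_rng(replicate_seed).integers(2**31 - 1))
    library = config.resolve_library()
    if weights is None:
        fit = fit_superlearner(library, data, k=config.k, seed=seed_int)
    else:
        # pinned weights make the replicate's CV/weight-solving step moot:
        # just refit the learners on the resampled data
        fit = fit_full(library, data, np.asarray(weights, dtype=float),
                       seed=seed_int)
    return _estimate_effects(config, data, fit, quantile_map=quantile_map)


def _bootstrap(
    config: PipelineConfig,
    table: pd.DataFrame,
    point: dict[str, float],
    seed_seq: np.random.SeedSequence,
    weights: np.ndarray | None,
    quantile_map: dict | None = None,
) -> tuple[list[BootstrapResult], int]:
    reps: dict[str, list[float]] = {t: [] for t in point}
    n_failed = 0
    for b, child in enumerate(seed_seq.spawn(config.B)):
        s_resample, s_fit = child.spawn(2)
        try:
            boot = resample(table, s_resample)
            est = run_replicate(config, boot, s_fit, weights=weights,
                                quantile_map=quantile_map)
        except Exception as exc:  # noqa: BLE001 - replicate failures are counted
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        for t, v in est.items():
            reps[t].append(v)
    results = []
    for t, point_val in point.items():
        r = np.array(reps[t])
        lo, hi = percentile_ci(r)
        results.append(
            BootstrapResult(
                target=t,
                point=point_val,
                replicates=r,
                ci_low=lo,
                ci_high=hi,
                n_failed=n_failed,
            )
        )
    return results, n_failed


def run_analysis(
    config: PipelineConfig,
    table: pd.DataFrame | None = None,
    bootstrap: bool = True,
) -> dict:
    """Point estimates, bootstrap CIs, curves and risk table for one run.

    When ``config.out_dir`` is set, tidy CSVs and a deterministic JSON
    summary (sorted keys, no timestamps) are written there.  The report
    dict is returned either way.
    """
    t0 = time.perf_counter()
    if table is None:
        if not config.input_path:
            raise ValueError("either a table or config.input_path is required")
        table = pd.read_csv(config.input_path)

    master = np.random.SeedSequence(config.seed)
    s_point, s_boot = master.spawn(2)

    data = build_analysis_dataset(table, config.outcome, config.model)
    seed_int = int(np.random.default_rng(s_point).integers(2**31 - 1))
    library = config.resolve_library()
    fit = fit_superlearner(library, data, k=config.k, seed=seed_int)
    point = _estimate_effects(config, data, fit)
    risks = risk_table(fit)

    pd_rows, ice_rows = [], []
    if config.include_curves:
        for exposure in data.exposure_names:
            bundle = gcomp.ice(fit, data, exposure, config.grid)
            for p, v in zip(bundle.grid, bundle.mean_curve):
                pd_rows.append(
                    {"exposure": exposure, "percentile": p, "value": float(v)}
                )
            for i, row_id in enumerate(data.meta.get("row_ids", range(data.n))):
                for g, p in enumerate(bundle.grid):
                    ice_rows.append(
                        {
                            "row_id": row_id,
                            "exposure": exposure,
                            "percentile": p,
                            "value": float(bundle.curves[i, g]),
                        }
                    )

    boot_results: list[BootstrapResult] = []
    n_failed = 0
    if bootstrap:
        weights = None if config.refit_weights_in_bootstrap else fit.weights
        quantile_map = None
        if config.fixed_quantiles:
            quantile_map = {
                e: (data.exposure_quantile(e, config.low_pct),
                    data.exposure_quantile(e, config.high_pct))
                for e in data.exposure_names
            }
        boot_results, n_failed = _bootstrap(config, table, point, s_boot,
                                            weights, quantile_map)

    effects = []
    ci_by_target = {r.target: r for r in boot_results}
    for target, est in point.items():
        row = {
            "target": target,
            "low_pct": config.low_pct,
            "high_pct": config.high_pct,
            "estimate": est,
        }
        if target in ci_by_target:
            row["ci_low"] = ci_by_target[target].ci_low
            row["ci_high"] = ci_by_target[target].ci_high
        effects.append(row)

    # paths are environment-specific; exclude them so equal-seed runs
    # produce byte-identical summaries
    config_dict = config.to_dict()
    config_dict.pop("input_path", None)
    config_dict.pop("out_dir", None)
    report = {
        "config": config_dict,
        "n": data.n,
        "outcome": config.outcome,
        "model": config.model,
        "effects": effects,
        "risk_table": risks.to_dict(orient="records"),
        "bootstrap": {
            "B": config.B if bootstrap else 0,
            "n_failed": n_failed,
        },
    }
    elapsed = time.perf_counter() - t0
    logger.info("run_analysis finished in %.1fs (n=%d, B=%d)", elapsed,
                data.n, config.B if bootstrap else 0)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(effects).to_csv(out / "effects.csv", index=False)
        risks.to_csv(out / "risk_table.csv", index=False)
        if pd_rows:
            pd.DataFrame(pd_rows).to_csv(out / "partial_dependence.csv", index=False)
        if ice_rows:
            pd.DataFrame(ice_rows).to_csv(out / "ice.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
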