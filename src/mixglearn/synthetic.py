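"""Synthetic cohort generation with known ground truth.

Exposure concentrations are drawn from a Gaussian copula with log-normal
margins so that arbitrary rank-correlation targets can be matched without
assuming joint log-normality.  Covariates follow configurable marginals
mimicking a birth-cohort table.  Outcomes are generated from an explicit
data-generating process (DGP) whose per-IQR linear coefficients double as
the analytic truth for recovery tests.

Exposure columns are named ``<chemical>_<timepoint>``, e.g. ``hg_maternal``
or ``pfoa_age5``.  Default marginal locations/scales are plausible
placeholders on the log10 concentration scale, not measured cohort values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHEMICALS",
    "TIMEPOINTS",
    "CopulaSpec",
    "CovariateConfig",
    "ExposureSpec",
    "OutcomeDGP",
    "SyntheticCohort",
    "default_marginals",
    "default_rank_corr",
    "generate_cohort",
    "iqr_units",
    "make_preset",
    "nearest_psd_correlation",
    "repair_correlation",
    "sample_covariates",
    "sample_exposures",
    "spearman_to_pearson",
    "true_nace",
]

CHEMICALS = ("hg", "pcb", "pfos", "pfoa", "pfhxs", "pfna", "pfda")
TIMEPOINTS = ("maternal", "age5")

#: Declared level order for every categorical covariate (first = reference).
CATEGORICAL_LEVELS = {
    "sex": ("boy", "girl"),
    "parity": ("nulliparous", "primipara", "multiparous"),
    "ses": ("low", "intermediate", "high"),
    "alcohol": ("never", "ever"),
    "smoking": ("no", "light", "heavy"),
}

CONTINUOUS_COVARIATES = (
    "age_months",
    "birth_weight",
    "maternal_age",
    "bmi",
    "breastfeeding_months",
    "raven",
)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureSpec:
    """Marginal distribution of one exposure at one timepoint.

    ``log10_mean`` and ``log10_sd`` parameterize the base-10 log-normal
    margin.  ``log10_sd == 0`` is accepted as the degenerate constant
    margin; negative values are rejected.
    """

    name: str
    timepoint: str
    log10_mean: float
    log10_sd: float
    units: str = "ng/mL"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.log10_sd < 0:
            raise ValueError("log10_sd must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.timepoint}"


@dataclass(frozen=True)
class CopulaSpec:
    """Target Spearman rank-correlation structure over labelled exposures."""

    labels: tuple[str, ...]
    rank_corr: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.rank_corr, dtype=float)
        object.__setattr__(self, "rank_corr", mat)
        p = len(self.labels)
        if mat.shape != (p, p):
            raise ValueError(f"rank_corr must be {p}x{p}, got {mat.shape}")
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise ValueError("rank_corr must be symmetric")
        if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
            raise ValueError("rank_corr must have unit diagonal")
        if np.any(np.abs(mat) > 1 + 1e-12):
            raise ValueError("rank correlations must lie in [-1, 1]")
        if len(set(self.labels)) != p:
            raise ValueError("labels must be unique")


@dataclass
class OutcomeDGP:
    """Ground-truth outcome model.

    Linear coefficients are expressed per IQR of the log10-scale exposure
    (one IQR increase in exposure shifts the mean outcome by ``beta``),
    matching the estimand the analysis pipeline reports.  Interactions and
    quadratic terms act on the same IQR-unit scale.

    ``beta_cov`` keys address covariates: a bare name refers to a
    standardized continuous covariate, ``"col=level"`` to a 0/1 level
    indicator of a categorical one.
    """

    intercept: float = 0.0
    beta_per_iqr: dict[str, float] = field(default_factory=dict)
    beta_cov: dict[str, float] = field(default_factory=dict)
    interactions: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    nonlinear: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def is_linear_additive(self) -> bool:
        return not self.interactions and not self.nonlinear

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "beta_per_iqr": dict(self.beta_per_iqr),
            "beta_cov": dict(self.beta_cov),
            "interactions": [[list(pair), coef] for pair, coef in self.interactions],
            "nonlinear": dict(self.nonlinear),
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OutcomeDGP":
        return cls(
            intercept=float(d["intercept"]),
            beta_per_iqr={k: float(v) for k, v in d["beta_per_iqr"].items()},
            beta_cov={k: float(v) for k, v in d["beta_cov"].items()},
            interactions=[((p[0], p[1]), float(c)) for p, c in d["interactions"]],
            nonlinear={k: float(v) for k, v in d["nonlinear"].items()},
            noise_sd=float(d["noise_sd"]),
        )


# ---------------------------------------------------------------------------
# copula machinery
# ---------------------------------------------------------------------------


def spearman_to_pearson(rho: np.ndarray | float) -> np.ndarray | float:
    """Map Spearman rank correlation to the latent Gaussian product-moment
    correlation, r = 2 sin(pi * rho / 6)."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping,
    then rescale to unit diagonal.

    This is the simple one-shot repair (not Higham's alternating
    projections); for the mild indefiniteness produced by entrywise
    rank-to-linear conversion it perturbs entries by well under 0.05.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(mat)
    if w[0] >= 0:
        return mat.copy()
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    d[d == 0] = 1.0
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def repair_correlation(rank_corr: np.ndarray) -> np.ndarray:
    """Convert a Spearman target matrix to the latent Pearson scale and
    repair it to the nearest PSD correlation matrix.

    Returns the matrix used to draw the latent multivariate normal.
    """
    rank_corr = np.asarray(rank_corr, dtype=float)
    if rank_corr.ndim != 2 or rank_corr.shape[0] != rank_corr.shape[1]:
        raise ValueError("rank_corr must be square")
    if not np.allclose(rank_corr, rank_corr.T, atol=1e-10):
        raise ValueError("rank_corr must be symmetric")
    r = spearman_to_pearson(rank_corr)
    np.fill_diagonal(r, 1.0)
    return nearest_psd_correlation(r)


def _latent_factor(corr: np.ndarray) -> np.ndarray:
    # eigh-based factor tolerates exactly-singular repaired matrices
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def sample_exposures(
    n: int,
    copula: CopulaSpec,
    marginals: Sequence[ExposureSpec],
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Draw ``n`` rows of strictly positive exposure concentrations.

    A latent multivariate normal with the repaired correlation is mapped
    through each margin's log-normal quantile function, which for Gaussian
    margins reduces to ``10 ** (mu + sd * z)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = [m.label for m in marginals]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate exposure labels")
    if tuple(labels) != tuple(copula.labels):
        raise ValueError(
            "copula labels do not match marginals: "
            f"{copula.labels} vs {tuple(labels)}"
        )
    corr = repair_correlation(copula.rank_corr)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(labels))) @ _latent_factor(corr).T
    mu = np.array([m.log10_mean for m in marginals])
    sd = np.array([m.log10_sd for m in marginals])
    x = np.power(10.0, mu + sd * z)
    return pd.DataFrame(x, columns=labels)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateConfig:
    """Marginal parameters for the covariate table.

    Categorical probabilities follow the level order in
    :data:`CATEGORICAL_LEVELS`.  Continuous covariates are Gaussian except
    breastfeeding duration (gamma, nonnegative).
    """

    p_boy: float = 0.5
    p_parity: tuple[float, float, float] = (0.25, 0.40, 0.35)
    p_ses: tuple[float, float, float] = (0.25, 0.50, 0.25)
    p_alcohol_ever: float = 0.41
    p_smoking: tuple[float, float, float] = (0.73, 0.17, 0.10)
    age_months: tuple[float, float] = (89.9, 1.2)
    birth_weight: tuple[float, float] = (3600.0, 450.0)
    maternal_age: tuple[float, float] = (29.5, 4.5)
    bmi: tuple[float, float] = (24.5, 4.0)
    raven: tuple[float, float] = (48.6, 6.0)
    breastfeeding_shape: float = 2.0
    breastfeeding_scale: float = 2.4


def sample_covariates(
    n: int,
    seed: int | np.random.SeedSequence,
    config: CovariateConfig | None = None,
) -> pd.DataFrame:
    """Generate the cohort covariate table with configurable marginals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or CovariateConfig()
    rng = np.random.default_rng(seed)

    def cat(levels: Sequence[str], p: Sequence[float]) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if p.shape != (len(levels),) or abs(p.sum() - 1) > 1e-9 or np.any(p < 0):
            raise ValueError(f"invalid probabilities for levels {levels}")
        return rng.choice(levels, size=n, p=p)

    out = pd.DataFrame(
        {
            "age_months": rng.normal(*cfg.age_months, size=n),
            "sex": cat(CATEGORICAL_LEVELS["sex"], (cfg.p_boy, 1 - cfg.p_boy)),
            "birth_weight": rng.normal(*cfg.birth_weight, size=n),
            "maternal_age": rng.normal(*cfg.maternal_age, size=n),
            "bmi": rng.normal(*cfg.bmi, size=n),
            "parity": cat(CATEGORICAL_LEVELS["parity"], cfg.p_parity),
            "breastfeeding_months": rng.gamma(
                cfg.breastfeeding_shape, cfg.breastfeeding_scale, size=n
            ),
            "raven": rng.normal(*cfg.raven, size=n),
            "ses": cat(CATEGORICAL_LEVELS["ses"], cfg.p_ses),
            "alcohol": cat(
                CATEGORICAL_LEVELS["alcohol"],
                (1 - cfg.p_alcohol_ever, cfg.p_alcohol_ever),
            ),
            "smoking": cat(CATEGORICAL_LEVELS["smoking"], cfg.p_smoking),
        }
    )
    return out


def apply_covariate_dependence(
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    coef: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Shift log10 exposures linearly in (standardized) covariates.

    ``coef`` maps exposure label -> {covariate key -> slope on the log10
    scale}; covariate keys follow the :class:`OutcomeDGP.beta_cov`
    convention.  Returns a new exposure table, still strictly positive.
    """
    shifted = np.log10(exposures.to_numpy(dtype=float))
    for j, label in enumerate(exposures.columns):
        terms = coef.get(label)
        if not terms:
            continue
        for key, slope in terms.items():
            shifted[:, j] += slope * _covariate_vector(covariates, key)
    return pd.DataFrame(
        np.power(10.0, shifted), columns=exposures.columns, index=exposures.index
    )


# ---------------------------------------------------------------------------
# outcome DGP
# ---------------------------------------------------------------------------


def iqr_units(exposures: pd.DataFrame) -> pd.DataFrame:
    """Center log10 exposures and rescale so one IQR equals one unit.

    Constant columns map to all-zero columns (their IQR is treated as 1
    to avoid division by zero; the centered values are already 0).
    """
    logx = np.log10(exposures.to_numpy(dtype=float))
    center = logx.mean(axis=0)
    q75 = np.quantile(logx, 0.75, axis=0)
    q25 = np.quantile(logx, 0.25, axis=0)
    iqr = q75 - q25
    iqr[iqr == 0] = 1.0
    return pd.DataFrame(
        (logx - center) / iqr, columns=exposures.columns, index=exposures.index
    )


def _covariate_vector(covariates: pd.DataFrame, key: str) -> np.ndarray:
    """Resolve a ``beta_cov`` key to a numeric column.

    Continuous covariates are z-scored on the sample; ``"col=level"``
    yields the raw 0/1 indicator.
    """
    if "=" in key:
        col, level = key.split("=", 1)
        if col not in covariates.columns:
            raise KeyError(f"unknown covariate {col!r}")
        return (covariates[col].astype(str) == level).to_numpy(dtype=float)
    if key not in covariates.columns:
        raise KeyError(f"unknown covariate {key!r}")
    v = covariates[key].to_numpy(dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _exposure_mean_part(dgp: OutcomeDGP, u: pd.DataFrame) -> np.ndarray:
    """Exposure-dependent part of the DGP mean, on IQR units ``u``."""
    eta = np.zeros(len(u))
    for label, beta in dgp.beta_per_iqr.items():
        if label not in u.columns:
            raise KeyError(f"beta_per_iqr key {label!r} not a generated exposure")
        eta += beta * u[label].to_numpy()
    for (a, b), coef in dgp.interactions:
        for lab in (a, b):
            if lab not in u.columns:
                raise KeyError(f"interaction key {lab!r} not a generated exposure")
        eta += coef * u[a].to_numpy() * u[b].to_numpy()
    for label, coef in dgp.nonlinear.items():
        if label not in u.columns:
            raise KeyError(f"nonlinear key {label!r} not a generated exposure")
        eta += coef * np.square(u[label].to_numpy())
    return eta


def compute_outcome(
    dgp: OutcomeDGP,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    seed: int | np.random.SeedSequence,
    return_linpred: bool = False,
):
    """Generate the outcome vector from the DGP.

    Returns ``y`` or ``(y, linpred)`` where ``linpred`` is the noise-free
    mean.  All DGP keys must resolve to generated columns.
    """
    u = iqr_units(exposures)
    eta = dgp.intercept + _exposure_mean_part(dgp, u)
    for key, beta in dgp.beta_cov.items():
        eta = eta + beta * _covariate_vector(covariates, key)
    rng = np.random.default_rng(seed)
    y = eta + rng.normal(0.0, dgp.noise_sd, size=len(eta))
    if return_linpred:
        return y, eta
    return y


def true_nace(
    dgp: OutcomeDGP,
    exposures: pd.DataFrame,
    target: str | Iterable[str],
    low_pct: float = 25.0,
    high_pct: float = 75.0,
) -> float:
    """Ground-truth quantile-contrast effect implied by the DGP.

    For purely linear additive DGPs with the default 25/75 contrast this
    collapses analytically to the (sum of) per-IQR coefficients.  Otherwise
    the contrast is computed directly from the DGP mean function on the
    supplied exposure sample: set the target column(s) to their own
    ``high_pct`` vs ``low_pct`` quantile and average the difference.
    Covariate terms are additive and cancel in the contrast.
    """
    targets = [target] if isinstance(target, str) else list(target)
    for t in targets:
        if t not in exposures.columns:
            raise KeyError(f"unknown exposure {t!r}")
    default_contrast = (low_pct, high_pct) == (25.0, 75.0)
    if dgp.is_linear_additive and default_contrast:
        return float(sum(dgp.beta_per_iqr.get(t, 0.0) for t in targets))
    u = iqr_units(exposures)
    u_hi, u_lo = u.copy(), u.copy()
    for t in targets:
        col = u[t].to_numpy()
        u_hi[t] = np.quantile(col, high_pct / 100.0)
        u_lo[t] = np.quantile(col, low_pct / 100.0)
    return float(
        _exposure_mean_part(dgp, u_hi).mean() - _exposure_mean_part(dgp, u_lo).mean()
    )


# ---------------------------------------------------------------------------
# whole-cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth manifest."""

    n: int
    exposures: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: dict

    def to_frame(self) -> pd.DataFrame:
        """Single analysis table: id, exposures, covariates, outcomes."""
        df = pd.concat(
            [self.exposures, self.covariates, self.outcomes], axis=1
        ).reset_index(drop=True)
        df.insert(0, "child_id", np.arange(1, self.n + 1))
        return df

    def truth_manifest(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)

    @staticmethod
    def truth_from_manifest(text: str) -> dict:
        return json.loads(text)


def default_marginals(
    timepoints: Sequence[str] = TIMEPOINTS,
) -> list[ExposureSpec]:
    """Plausible placeholder log10 margins for the seven chemicals.

    These locations/scales are chosen to look like serum/blood pollutant
    distributions (right-skewed, positive); they are not cohort estimates.
    """
    base = {
        "hg": (0.30, 0.35, "µg/L"),
        "pcb": (0.00, 0.30, "µg/g lipid"),
        "pfos": (1.20, 0.22, "ng/mL"),
        "pfoa": (0.50, 0.22, "ng/mL"),
        "pfhxs": (-0.10, 0.28, "ng/mL"),
        "pfna": (-0.15, 0.22, "ng/mL"),
        "pfda": (-0.50, 0.24, "ng/mL"),
    }
    out = []
    for tp in timepoints:
        shift = 0.0 if tp == "maternal" else -0.15
        for chem in CHEMICALS:
            mu, sd, units = base[chem]
            out.append(ExposureSpec(chem, tp, mu + shift, sd, units))
    return out


def default_rank_corr(timepoints: Sequence[str] = TIMEPOINTS) -> CopulaSpec:
    """Default Spearman targets echoing the within/between exposure
    correlation structure: strong PFNA-PFDA (0.79), near-zero PFOA-Hg at
    age 5 (-0.04), PCB tracking between timepoints (0.58), weak PFHxS
    tracking (0.09)."""
    within = {
        ("hg", "pcb"): 0.45,
        ("hg", "pfos"): 0.25,
        ("hg", "pfoa"): 0.10,
        ("hg", "pfhxs"): 0.15,
        ("hg", "pfna"): 0.30,
        ("hg", "pfda"): 0.35,
        ("pcb", "pfos"): 0.35,
        ("pcb", "pfoa"): 0.15,
        ("pcb", "pfhxs"): 0.20,
        ("pcb", "pfna"): 0.35,
        ("pcb", "pfda"): 0.40,
        ("pfos", "pfoa"): 0.45,
        ("pfos", "pfhxs"): 0.45,
        ("pfos", "pfna"): 0.50,
        ("pfos", "pfda"): 0.50,
        ("pfoa", "pfhxs"): 0.40,
        ("pfoa", "pfna"): 0.40,
        ("pfoa", "pfda"): 0.30,
        ("pfhxs", "pfna"): 0.35,
        ("pfhxs", "pfda"): 0.35,
        ("pfna", "pfda"): 0.79,
    }
    between_same = {
        "hg": 0.35,
        "pcb": 0.58,
        "pfos": 0.30,
        "pfoa": 0.25,
        "pfhxs": 0.09,
        "pfna": 0.30,
        "pfda": 0.30,
    }
    labels = [f"{c}_{tp}" for tp in timepoints for c in CHEMICALS]
    p = len(labels)
    mat = np.eye(p)

    def set_corr(a: str, b: str, rho: float) -> None:
        i, j = labels.index(a), labels.index(b)
        mat[i, j] = mat[j, i] = rho

    for tp in timepoints:
        for (a, b), rho in within.items():
            set_corr(f"{a}_{tp}", f"{b}_{tp}", rho)
    if "age5" in timepoints:
        set_corr("hg_age5", "pfoa_age5", -0.04)
    if set(("maternal", "age5")).issubset(timepoints):
        for chem, rho in between_same.items():
            set_corr(f"{chem}_maternal", f"{chem}_age5", rho)
        # weak cross-chemical, cross-timepoint background dependence
        for a in CHEMICALS:
            for b in CHEMICALS:
                if a == b:
                    continue
                i, j = labels.index(f"{a}_maternal"), labels.index(f"{b}_age5")
                if mat[i, j] == 0.0:
                    mat[i, j] = mat[j, i] = 0.10
    return CopulaSpec(tuple(labels), mat)


_PRESET_NAMES = ("null", "table3_linear", "interaction", "nonlinear")


def make_preset(
    name: str, timepoints: Sequence[str] = ("maternal",)
) -> tuple[list[ExposureSpec], CopulaSpec, OutcomeDGP]:
    """Bundle (marginals, copula, DGP) for a named scenario.

    ``table3_linear`` places effects of -0.15 SD/IQR on maternal Hg and
    -0.14 on maternal PFOA with all other exposures null; ``interaction``
    adds a +0.1 Hg x PFOS product term; ``nonlinear`` adds a +0.1
    quadratic PCB term; ``null`` has no exposure effects.  Residual sd is
    chosen so the marginal outcome variance is close to 1, keeping the
    per-IQR truth approximately on the standardized-outcome scale.
    """
    if name not in _PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {_PRESET_NAMES}")
    marginals = default_marginals(timepoints)
    copula = default_rank_corr(timepoints)
    # covariates carry substantial linear signal (as maternal cognition and
    # SES do for child neuropsychological scores); residual sd keeps the
    # marginal outcome variance near 1 so per-IQR truth is approximately on
    # the standardized-outcome scale
    beta_cov = {
        "raven": 0.35,
        "ses=high": 0.25,
        "ses=intermediate": 0.10,
        "smoking=heavy": -0.20,
        "maternal_age": 0.10,
        "sex=girl": 0.10,
    }
    if name == "null":
        dgp = OutcomeDGP(beta_cov=dict(beta_cov), noise_sd=0.92)
    else:
        betas = {"hg_maternal": -0.15, "pfoa_maternal": -0.14}
        dgp = OutcomeDGP(
            beta_per_iqr=betas, beta_cov=dict(beta_cov), noise_sd=0.905
        )
        if name == "interaction":
            dgp.interactions = [(("hg_maternal", "pfos_maternal"), 0.1)]
        elif name == "nonlinear":
            dgp.nonlinear = {"pcb_maternal": 0.1}
    return marginals, copula, dgp


def generate_cohort(
    n: int,
    seed: int,
    preset: str = "table3_linear",
    timepoints: Sequence[str] = ("maternal",),
    outcome_name: str = "bnt_cued",
    covariate_config: CovariateConfig | None = None,
    exposure_covariate_coef: Mapping[str, Mapping[str, float]] | None = None,
    dgp: OutcomeDGP | None = None,
) -> SyntheticCohort:
    """Generate a full cohort with truth manifest.

    A single master seed spawns independent substreams for exposures,
    covariates and outcome noise, so identical seeds give bit-identical
    cohorts regardless of which components are consumed.
    """
    marginals, copula, preset_dgp = make_preset(preset, timepoints)
    if dgp is not None:
        preset_dgp = dgp
    ss = np.random.SeedSequence(seed)
    s_exp, s_cov, s_out = ss.spawn(3)
    exposures = sample_exposures(n, copula, marginals, s_exp)
    covariates = sample_covariates(n, s_cov, covariate_config)
    if exposure_covariate_coef:
        exposures = apply_covariate_dependence(
            exposures, covariates, exposure_covariate_coef
        )
    y, linpred = compute_outcome(
        preset_dgp, exposures, covariates, s_out, return_linpred=True
    )
    outcomes = pd.DataFrame({outcome_name: y})
    sd_y = float(np.std(y, ddof=1))
    truth = {
        "preset": preset,
        "outcome": outcome_name,
        "dgp": preset_dgp.to_dict(),
        "sd_y": sd_y,
        "linpred_mean": float(np.mean(linpred)),
        "true_nace": {
            lab: true_nace(preset_dgp, exposures, lab) for lab in exposures.columns
        },
        "true_joint_nace": true_nace(preset_dgp, exposures, list(exposures.columns)),
    }
    truth["true_nace_std"] = {
        k: v / sd_y for k, v in truth["true_nace"].items()
    }
    truth["true_joint_nace_std"] = truth["true_joint_nace"] / sd_y
    return SyntheticCohort(
        n=n, exposures=exposures, covariates=covariates, outcomes=outcomes, truth=truth
    )
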