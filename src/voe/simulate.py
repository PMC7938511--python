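"""Synthetic survival cohorts with correlated mixed-type covariates.

Covariates are generated through a Gaussian copula: latent multivariate
normal rows with a given correlation matrix, where continuous covariates
are the latent values themselves and binary/ordinal covariates are obtained
by thresholding their latent coordinate.  Event times follow a Cox model
with an exponential baseline hazard,

    T_i ~ Exponential(rate = lambda0 * exp(sum_j beta_j x_ij)),

with independent exponential censoring, so every true parameter has a
closed-form oracle for recovery tests.  The bundled example specification
mimics a mortality cohort with one exposure, two baseline adjustments (age,
sex; error-free) and 13 optional adjustments of mixed type including an
error-free ordinal race/ethnicity variable.

``spec_from_cohort`` goes the other way: it estimates the latent
correlation structure and the effect sizes from an existing cohort so that
simulations can adopt the dependence and effects of real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import Cohort, VariableSpec, standardize_continuous
from .exceptions import DegenerateVariableError, SchemaError, VoeError

_COVARIATE_ROLES = ("exposure", "adjustment", "baseline_adjustment")


@dataclass(frozen=True)
class VarDef:
    """Definition of one generated covariate.

    ``thresholds`` are latent-normal cut points: one for a binary variable
    (prevalence = 1 - Phi(threshold)), L-1 strictly increasing values for an
    ordinal variable with L levels, none for continuous.
    """

    name: str
    kind: str
    role: str = "adjustment"
    thresholds: tuple[float, ...] = ()
    error_free: bool = False

    def __post_init__(self):
        if self.role not in _COVARIATE_ROLES:
            raise SchemaError(f"covariate role must be one of {_COVARIATE_ROLES}")
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        n_thr = len(self.thresholds)
        if self.kind == "continuous" and n_thr:
            raise SchemaError("continuous covariates take no thresholds")
        if self.kind == "binary" and n_thr != 1:
            raise SchemaError("binary covariates need exactly 1 threshold")
        if self.kind == "ordinal" and n_thr < 2:
            raise SchemaError("ordinal covariates need >= 2 thresholds (>= 3 levels)")
        if n_thr > 1 and not all(np.diff(self.thresholds) > 0):
            raise SchemaError("thresholds must be strictly increasing")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterisation of the synthetic-cohort generator."""

    n: int
    var_defs: tuple[VarDef, ...]
    corr: np.ndarray
    log_hazards: tuple[float, ...]
    baseline_rate: float
    censor_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "var_defs", tuple(self.var_defs))
        object.__setattr__(self, "log_hazards", tuple(float(b) for b in self.log_hazards))
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "corr", corr)
        p = len(self.var_defs)
        if corr.shape != (p, p):
            raise VoeError(f"corr must be {p}x{p}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise VoeError("corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise VoeError("corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise VoeError("corr must be positive definite")
        if len(self.log_hazards) != p:
            raise VoeError("log_hazards length must match the number of covariates")
        if self.baseline_rate <= 0:
            raise VoeError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise VoeError("censor_rate must be >= 0")
        if sum(v.role == "exposure" for v in self.var_defs) != 1:
            raise SchemaError("exactly one covariate must have role 'exposure'")

    @property
    def p(self) -> int:
        return len(self.var_defs)

    def with_n(self, n: int) -> "GeneratorSpec":
        return dataclasses.replace(self, n=n)


def _covariate_schema(var_defs: Sequence[VarDef]) -> list[VariableSpec]:
    specs = []
    for v in var_defs:
        levels = tuple(range(1, len(v.thresholds) + 2)) if v.kind == "ordinal" else None
        specs.append(
            VariableSpec(
                name=v.name, kind=v.kind, role=v.role,
                error_free=v.error_free, levels=levels,
            )
        )
    return specs


def generate_cohort(spec: GeneratorSpec, seed: int | None = None) -> Cohort:
    """Draw one synthetic cohort from the generator specification.

    ``seed`` overrides ``spec.seed``; omitting both gives fresh entropy.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chol = np.linalg.cholesky(spec.corr)
    latent = rng.standard_normal((spec.n, spec.p)) @ chol.T

    data = {}
    for j, v in enumerate(spec.var_defs):
        z = latent[:, j]
        if v.kind == "continuous":
            data[v.name] = z
        elif v.kind == "binary":
            data[v.name] = (z > v.thresholds[0]).astype(int)
        else:
            data[v.name] = 1 + np.searchsorted(np.asarray(v.thresholds), z)
    x = np.column_stack([data[v.name] for v in spec.var_defs]).astype(float)
    rate = spec.baseline_rate * np.exp(x @ np.asarray(spec.log_hazards))
    t_event = rng.exponential(1.0 / rate)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=spec.n)
    else:
        t_cens = np.full(spec.n, np.inf)
    data["time"] = np.minimum(t_event, t_cens)
    data["event"] = (t_event <= t_cens).astype(int)

    schema = _covariate_schema(spec.var_defs)
    schema.append(VariableSpec(name="time", kind="continuous", role="time"))
    schema.append(VariableSpec(name="event", kind="binary", role="event"))
    cohort = Cohort(data=pd.DataFrame(data), schema=tuple(schema))
    # same convention as load_cohort: a continuous exposure is standardised
    # so hazard ratios are per SD of the observed exposure
    if cohort.spec_of(cohort.exposure).kind == "continuous":
        cohort = standardize_continuous(cohort, [cohort.exposure])
    return cohort


# ---------------------------------------------------------------------------
# estimating a generator spec from data


def _nearest_pd(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eps`` and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() > 0:
        return corr
    repaired = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def _phi_sum(thresholds: tuple[float, ...]) -> float:
    return float(stats.norm.pdf(np.asarray(thresholds)).sum())


def _polyserial(x: np.ndarray, score: np.ndarray, thresholds) -> float:
    """Two-step polyserial correlation: the discrete score is a sum of
    latent-threshold indicators, so Cov(Z_x, score) = rho * sum_j phi(tau_j)."""
    zx = (x - x.mean()) / x.std(ddof=0)
    cov = float(np.mean(zx * (score - score.mean())))
    return cov / _phi_sum(thresholds)


def _polychoric(score_a, thr_a, score_b, thr_b) -> float:
    """Moment-based polychoric correlation for two thresholded latents.

    Solves Cov(score_a, score_b) = sum_jk [P(Z1>tau_j, Z2>ups_k) -
    P(Z1>tau_j) P(Z2>ups_k)] for the latent rho (monotone, bracketed)."""
    cov_obs = float(np.mean((score_a - score_a.mean()) * (score_b - score_b.mean())))
    ta, tb = np.asarray(thr_a), np.asarray(thr_b)
    sa = stats.norm.sf(ta)
    sb = stats.norm.sf(tb)

    def model_cov(rho: float) -> float:
        mvn = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]])
        total = 0.0
        for j, tj in enumerate(ta):
            for k, uk in enumerate(tb):
                upper = 1 - stats.norm.cdf(tj) - stats.norm.cdf(uk) + mvn.cdf([tj, uk])
                total += upper - sa[j] * sb[k]
        return total

    from scipy.optimize import brentq

    lo, hi = -0.999, 0.999
    f_lo, f_hi = model_cov(lo) - cov_obs, model_cov(hi) - cov_obs
    if f_lo > 0:
        return lo
    if f_hi < 0:
        return hi
    return float(brentq(lambda r: model_cov(r) - cov_obs, lo, hi, xtol=1e-5))


def _latent_corr(a, thr_a, b, thr_b) -> float:
    """Pairwise latent correlation: Pearson for continuous pairs, moment-based
    polyserial / polychoric when one or both variables are thresholded."""
    if thr_a is None and thr_b is None:
        return float(np.corrcoef(a, b)[0, 1])
    if thr_a is None:
        return _polyserial(a, b, thr_b)
    if thr_b is None:
        return _polyserial(b, a, thr_a)
    return _polychoric(a, thr_a, b, thr_b)


def spec_from_cohort(cohort: Cohort, design=None) -> GeneratorSpec:
    """Estimate a generator specification adopting a cohort's correlation
    structure and effect sizes.

    Pairwise latent correlations use Pearson for continuous-continuous
    pairs and moment-based polyserial / polychoric estimators when one or
    both variables are thresholded, with a nearest-positive-definite
    eigenvalue repair if needed.  Effect sizes
    come from the all-adjustments Cox fit, the baseline hazard rate from
    the exponential-model likelihood and the censoring rate from the
    censored fraction per unit follow-up.
    """
    from .estimation import DesignInfo  # local import to avoid a cycle
    from lifelines import CoxPHFitter

    cov_specs = [v for v in cohort.schema if v.role in _COVARIATE_ROLES]
    names = [v.name for v in cov_specs]
    df = cohort.data

    var_defs = []
    for v in cov_specs:
        col = df[v.name].to_numpy(float)
        if np.unique(col).size < 2:
            raise DegenerateVariableError(f"covariate {v.name!r} is constant")
        if v.kind == "continuous":
            thresholds: tuple[float, ...] = ()
        elif v.kind == "binary":
            prev = col.mean()
            if prev in (0.0, 1.0):
                raise DegenerateVariableError(f"binary {v.name!r} has one level")
            thresholds = (float(stats.norm.ppf(1 - prev)),)
        else:
            levels = np.asarray(v.levels)
            counts = np.array([(col == lev).sum() for lev in levels], float)
            if (counts == 0).any():
                raise DegenerateVariableError(f"ordinal {v.name!r} has empty levels")
            cum = np.cumsum(counts)[:-1] / counts.sum()
            thresholds = tuple(stats.norm.ppf(cum))
        var_defs.append(
            VarDef(name=v.name, kind=v.kind, role=v.role,
                   thresholds=thresholds, error_free=v.error_free)
        )

    p = len(names)
    thresholds_of = {v.name: (v.thresholds or None) for v in var_defs}
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            corr[i, j] = corr[j, i] = np.clip(
                _latent_corr(
                    df[names[i]].to_numpy(float), thresholds_of[names[i]],
                    df[names[j]].to_numpy(float), thresholds_of[names[j]],
                ),
                -0.999, 0.999,
            )
    corr = _nearest_pd(corr)

    fit_df = df.loc[:, names + [cohort.time_var, cohort.event_var]].astype(float)
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col=cohort.time_var, event_col=cohort.event_var)
    beta = tuple(float(cph.params_[name]) for name in names)

    t = df[cohort.time_var].to_numpy(float)
    ev = df[cohort.event_var].to_numpy(float)
    linpred = fit_df[names].to_numpy() @ np.asarray(beta)
    baseline_rate = float(ev.sum() / (t * np.exp(linpred)).sum())
    censor_rate = float((1 - ev).sum() / t.sum())

    return GeneratorSpec(
        n=cohort.n,
        var_defs=tuple(var_defs),
        corr=corr,
        log_hazards=beta,
        baseline_rate=baseline_rate,
        censor_rate=censor_rate,
    )


# ---------------------------------------------------------------------------
# (de)serialisation and the bundled example


def spec_to_yaml(spec: GeneratorSpec, path: str | Path) -> None:
    doc = {
        "n": spec.n,
        "baseline_rate": spec.baseline_rate,
        "censor_rate": spec.censor_rate,
        "seed": spec.seed,
        "variables": [
            {
                "name": v.name, "kind": v.kind, "role": v.role,
                "error_free": v.error_free,
                "thresholds": list(v.thresholds),
                "log_hazard": spec.log_hazards[i],
            }
            for i, v in enumerate(spec.var_defs)
        ],
        "corr": [[round(float(c), 6) for c in row] for row in spec.corr],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path: str | Path) -> GeneratorSpec:
    doc = yaml.safe_load(Path(path).read_text())
    var_defs = tuple(
        VarDef(
            name=v["name"], kind=v["kind"], role=v.get("role", "adjustment"),
            thresholds=tuple(v.get("thresholds", ())),
            error_free=bool(v.get("error_free", False)),
        )
        for v in doc["variables"]
    )
    return GeneratorSpec(
        n=int(doc["n"]),
        var_defs=var_defs,
        corr=np.asarray(doc["corr"], dtype=float),
        log_hazards=tuple(v["log_hazard"] for v in doc["variables"]),
        baseline_rate=float(doc["baseline_rate"]),
        censor_rate=float(doc.get("censor_rate", 0.0)),
        seed=doc.get("seed"),
    )


def example_spec(n: int = 2000) -> GeneratorSpec:
    """The bundled 16-covariate mortality-cohort-like specification.

    One continuous exposure, baseline age (continuous) and sex (binary,
    both error-free), and 13 optional adjustments of mixed type including
    an error-free ordinal race/ethnicity variable.  Latent correlations
    follow an AR(1) structure with parameter 0.3; effect sizes are modest
    per-SD log hazard ratios.
    """
    data_path = Path(__file__).parent / "data" / "example_cohort_spec.yaml"
    return spec_from_yaml(data_path).with_n(n)


def _build_example_spec() -> GeneratorSpec:
    """Construct the example specification (used to create the bundled file)."""
    q = stats.norm.ppf
    defs_and_betas = [
        (VarDef("exposure", "continuous", "exposure"), 0.25),
        (VarDef("age", "continuous", "baseline_adjustment", error_free=True), 0.40),
        (VarDef("sex", "binary", "baseline_adjustment", (0.0,), True), 0.15),
        (VarDef("race_ethnicity", "ordinal", "adjustment",
                tuple(q([0.45, 0.7, 0.9])), True), 0.05),
        (VarDef("smoking", "binary", "adjustment", (q(0.75),)), 0.20),
        (VarDef("bmi", "continuous"), 0.10),
        (VarDef("systolic_bp", "continuous"), 0.15),
        (VarDef("total_cholesterol", "continuous"), 0.08),
        (VarDef("physical_activity", "ordinal", "adjustment", tuple(q([0.3, 0.7]))), -0.10),
        (VarDef("alcohol", "binary", "adjustment", (q(0.6),)), -0.05),
        (VarDef("education", "ordinal", "adjustment", tuple(q([0.25, 0.55, 0.8]))), -0.08),
        (VarDef("income", "continuous"), -0.10),
        (VarDef("crp", "continuous"), 0.12),
        (VarDef("glucose", "continuous"), 0.10),
        (VarDef("medication_use", "binary", "adjustment", (q(0.65),)), 0.05),
        (VarDef("diet_score", "continuous"), -0.06),
    ]
    p = len(defs_and_betas)
    corr = 0.3 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    return GeneratorSpec(
        n=2000,
        var_defs=tuple(d for d, _ in defs_and_betas),
        corr=corr,
        log_hazards=tuple(b for _, b in defs_and_betas),
        baseline_rate=0.08,
        censor_rate=0.15,
    )
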