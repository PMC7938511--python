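"""Measurement-error generators and per-iteration parameter draws.

Continuous variables follow the classical additive non-differential model
Z = X + U with U ~ N(0, Var(U)) independent of X.  Given a target
correlation rho between true and observed exposure, Var(Z) = Var(X)/rho^2,
so the injected error variance is

    Var(U) = Var(X)/rho^2 - Var(X).

Binary variables are misclassified via sensitivity (P(Z=1|X=1)) and
specificity (P(Z=0|X=0)).  Ordinal variables use a latent-normal scheme:
thresholds are set from the empirical level frequencies via the standard
normal quantile function, each observation is assigned a latent value drawn
from the standard normal truncated to its level's interval, classical noise
for the target latent correlation is added, and the sum is re-discretised
with the same thresholds.

The observed recordings are treated as the "true" values X; the generators
therefore simulate *additional* error on top of whatever error the data
already carry, which is the conservative reading used throughout the
vibration framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort
from .exceptions import DegenerateVariableError, VoeError

SCENARIOS = ("exposure_only", "adjustment_only", "both")

#: default uniform ranges for the per-iteration error-parameter draws
DEFAULT_RHO_RANGE = (0.73, 0.9)
DEFAULT_SENS_RANGE = (0.56, 0.85)
DEFAULT_SPEC_RANGE = (0.73, 0.98)


@dataclass(frozen=True)
class MERanges:
    """Uniform sampling ranges for the measurement-error parameters.

    ``rho`` bounds the correlation between true and observed continuous (or
    latent ordinal) values; ``sens``/``spec`` bound the sensitivity and
    specificity for binary misclassification.  All bounds lie in (0, 1].
    """

    rho_low: float = DEFAULT_RHO_RANGE[0]
    rho_high: float = DEFAULT_RHO_RANGE[1]
    sens_low: float = DEFAULT_SENS_RANGE[0]
    sens_high: float = DEFAULT_SENS_RANGE[1]
    spec_low: float = DEFAULT_SPEC_RANGE[0]
    spec_high: float = DEFAULT_SPEC_RANGE[1]

    def __post_init__(self):
        for lo, hi, label in (
            (self.rho_low, self.rho_high, "rho"),
            (self.sens_low, self.sens_high, "sensitivity"),
            (self.spec_low, self.spec_high, "specificity"),
        ):
            if not (0 < lo <= hi <= 1):
                raise VoeError(f"{label} bounds must satisfy 0 < low <= high <= 1")


@dataclass(frozen=True)
class MEDraw:
    """One realised set of error parameters, shared by all corrupted variables."""

    rho: float
    sensitivity: float
    specificity: float


def variance_of_error(var_x: float, rho: float) -> float:
    """Error variance achieving correlation ``rho`` between X and Z = X + U.

    Var(U) = Var(X)/rho^2 - Var(X); zero when rho = 1 (perfect measurement).
    """
    if var_x <= 0:
        raise DegenerateVariableError("var_x must be > 0")
    if not (0 < rho <= 1):
        raise VoeError("rho must lie in (0, 1]")
    return var_x / rho**2 - var_x


def add_classical_error(
    x: np.ndarray, rho: float, stream: np.random.Generator
) -> np.ndarray:
    """Return Z = X + U with U ~ N(0, Var(U)) targeting correlation ``rho``.

    Var(X) is estimated by the sample variance (ddof=1) of ``x``.
    """
    x = np.asarray(x, dtype=float)
    var_x = x.var(ddof=1)
    if not np.isfinite(var_x) or var_x == 0:
        raise DegenerateVariableError("input column is constant")
    var_u = variance_of_error(var_x, rho)
    if var_u == 0:
        return x.copy()
    return x + stream.normal(0.0, np.sqrt(var_u), size=x.shape)


def misclassify_binary(
    x: np.ndarray,
    sensitivity: float,
    specificity: float,
    stream: np.random.Generator,
) -> np.ndarray:
    """Misclassify a 0/1 column: Z|X=1 ~ Bern(sens), Z|X=0 ~ Bern(1 - spec)."""
    x = np.asarray(x)
    if not np.isin(x, (0, 1)).all():
        raise TypeError("input column must be coded 0/1")
    if not (0 < sensitivity <= 1 and 0 < specificity <= 1):
        raise VoeError("sensitivity and specificity must lie in (0, 1]")
    p_one = np.where(x == 1, sensitivity, 1.0 - specificity)
    return (stream.random(x.shape) < p_one).astype(x.dtype)


def _ordinal_thresholds(x: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Interior latent thresholds tau_1 < ... < tau_{L-1} from level frequencies."""
    counts = np.array([(x == lev).sum() for lev in levels], dtype=float)
    if (counts == 0).any():
        missing = [lev for lev, c in zip(levels, counts) if c == 0]
        raise DegenerateVariableError(f"unobserved ordinal level(s): {missing}")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum)


def perturb_ordinal(
    x: np.ndarray,
    rho: float,
    stream: np.random.Generator,
    levels: np.ndarray | None = None,
) -> np.ndarray:
    """Perturb an ordinal column through its latent-normal representation.

    Thresholds come from the empirical cumulative level frequencies; each
    row's latent value is sampled from the standard normal truncated to its
    level's interval (inverse-CDF sampling), classical noise with variance
    ``variance_of_error(1, rho)`` is added, and the same thresholds
    re-discretise the result.  With rho = 1 the output equals the input.
    """
    x = np.asarray(x)
    if levels is None:
        levels = np.unique(x)
    levels = np.asarray(levels)
    if len(levels) < 3:
        raise TypeError("ordinal variables need >= 3 levels (use the binary path)")
    if not np.isin(x, levels).all():
        raise DegenerateVariableError("values outside the declared ordinal levels")
    tau = _ordinal_thresholds(x, levels)
    var_u = variance_of_error(1.0, rho)
    idx = np.searchsorted(levels, x)  # level index 0..L-1 per row
    lo = stats.norm.cdf(np.concatenate(([-np.inf], tau)))[idx]
    hi = stats.norm.cdf(np.concatenate((tau, [np.inf])))[idx]
    latent = stats.norm.ppf(lo + stream.random(x.shape) * (hi - lo))
    if var_u > 0:
        # rescale so the noisy latent is standard normal again: marginal
        # level frequencies are preserved in distribution and the latent
        # correlation equals rho exactly (1/sqrt(1 + Var(U)) = rho)
        latent = (latent + stream.normal(0.0, np.sqrt(var_u), size=x.shape)) / np.sqrt(
            1.0 + var_u
        )
    # side="right": a latent landing exactly on a threshold belongs upward,
    # so the noise-free path returns the input unchanged
    new_idx = np.searchsorted(tau, latent, side="right")
    return levels[new_idx]


def draw_me_params(ranges: MERanges, stream: np.random.Generator) -> MEDraw:
    """Draw one set of error parameters, each uniform on its range."""
    return MEDraw(
        rho=float(stream.uniform(ranges.rho_low, ranges.rho_high)),
        sensitivity=float(stream.uniform(ranges.sens_low, ranges.sens_high)),
        specificity=float(stream.uniform(ranges.spec_low, ranges.spec_high)),
    )


def _corruption_targets(cohort: Cohort, scenario: str) -> list[str]:
    if scenario not in SCENARIOS:
        raise VoeError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    targets: list[str] = []
    if scenario in ("exposure_only", "both"):
        targets.append(cohort.exposure)
    if scenario in ("adjustment_only", "both"):
        targets.extend(cohort.adjustment_vars)
    return [t for t in targets if not cohort.spec_of(t).error_free]


def corrupt_cohort(
    cohort: Cohort,
    draw: MEDraw,
    scenario: str,
    stream: np.random.Generator,
) -> Cohort:
    """Replace the scenario's non-error-free variables with error-prone versions.

    One parameter draw applies to every corrupted variable, but the noise is
    generated from an independent substream per variable, so errors across
    variables are uncorrelated.  Error-free variables, time, event and the
    survey-design columns pass through unchanged.
    """
    targets = _corruption_targets(cohort, scenario)
    df = cohort.data.copy()
    substreams = stream.spawn(len(targets))
    for name, sub in zip(targets, substreams):
        spec = cohort.spec_of(name)
        col = df[name].to_numpy()
        if spec.kind == "continuous":
            df[name] = add_classical_error(col, draw.rho, sub)
        elif spec.kind == "binary":
            df[name] = misclassify_binary(col, draw.sensitivity, draw.specificity, sub)
        else:
            df[name] = perturb_ordinal(col, draw.rho, sub, np.asarray(spec.levels))
    return cohort.with_data(df)
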