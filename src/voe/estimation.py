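"""Cox proportional-hazards fitting for one model specification.

Fits are delegated to lifelines' ``CoxPHFitter`` (Efron tie handling).  When
a survey design is present — participant weights and/or cluster labels such
as pseudosampling units — the robust sandwich variance estimator is used,
grouped by the cluster variable when one is given; pseudostrata enter as
stratification of the baseline hazard.  P-values come from the normal
approximation to the Wald statistic.

A fit that fails (non-convergence, non-finite coefficients, degenerate
exposure, zero events) is returned as a non-converged
:class:`~voe.cohort.EffectEstimate` rather than raised, so a single bad
subsample or error draw does not abort a vibration run; :func:`fit_all`
aborts only when more than ``max_failure_frac`` of its fits fail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import Cohort, EffectEstimate
from .exceptions import EstimationError
from .model_space import ModelSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignInfo:
    """Optional survey-design columns entering the fit and its variance."""

    weight_var: str | None = None
    stratum_var: str | None = None
    cluster_var: str | None = None

    @property
    def any(self) -> bool:
        return any((self.weight_var, self.stratum_var, self.cluster_var))

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "DesignInfo":
        return cls(
            weight_var=cohort.design_var("weight"),
            stratum_var=cohort.design_var("stratum"),
            cluster_var=cohort.design_var("cluster"),
        )


def _failed(provenance: tuple[str, int]) -> EffectEstimate:
    return EffectEstimate(
        log_hr=float("nan"),
        hr=float("nan"),
        se=None,
        p_value=None,
        converged=False,
        provenance=provenance,
    )


def fit_cox_effect(
    cohort: Cohort,
    spec: ModelSpec,
    design: DesignInfo | None = None,
    provenance: tuple[str, int] | None = None,
    robust: bool | None = None,
) -> EffectEstimate:
    """Fit one Cox model and return the exposure's effect estimate.

    ``robust`` defaults to True when any design column is present (sandwich
    variance, cluster-robust when a cluster variable exists) and False
    otherwise (model-based variance).
    """
    design = design or DesignInfo()
    if provenance is None:
        provenance = ("model", spec.model_id)
    if robust is None:
        robust = design.any

    cols = [spec.exposure, *spec.included_adjustments, cohort.time_var, cohort.event_var]
    for extra in (design.weight_var, design.stratum_var, design.cluster_var):
        if extra is not None:
            cols.append(extra)
    df = cohort.data.loc[:, list(dict.fromkeys(cols))].astype(float)

    if df[spec.exposure].nunique() < 2 or df[cohort.event_var].sum() < 1:
        return _failed(provenance)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col=cohort.time_var,
                event_col=cohort.event_var,
                weights_col=design.weight_var,
                cluster_col=design.cluster_var,
                strata=[design.stratum_var] if design.stratum_var else None,
                robust=robust,
            )
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        logger.debug("fit %s failed: %s", provenance, exc)
        return _failed(provenance)

    row = cph.summary.loc[spec.exposure]
    log_hr = float(row["coef"])
    se = float(row["se(coef)"])
    p = float(row["p"])
    if not (np.isfinite(log_hr) and np.isfinite(se) and np.isfinite(p)):
        return _failed(provenance)
    return EffectEstimate(
        log_hr=log_hr,
        hr=float(np.exp(log_hr)),
        se=se,
        p_value=max(p, np.finfo(float).tiny),
        converged=True,
        provenance=provenance,
    )


def fit_all(
    cohort: Cohort,
    specs: Sequence[ModelSpec],
    design: DesignInfo | None = None,
    max_failure_frac: float = 0.05,
) -> list[EffectEstimate]:
    """Fit every specification on the full cohort, order preserved.

    Raises :class:`EstimationError` when more than ``max_failure_frac`` of
    the fits fail to converge.
    """
    if not specs:
        raise EstimationError("no model specifications to fit")
    estimates = [fit_cox_effect(cohort, spec, design) for spec in specs]
    n_failed = sum(not e.converged for e in estimates)
    if n_failed > max_failure_frac * len(specs):
        raise EstimationError(
            f"{n_failed}/{len(specs)} fits failed to converge "
            f"(> {max_failure_frac:.0%} threshold)"
        )
    if n_failed:
        logger.warning("%d/%d fits failed to converge", n_failed, len(specs))
    return estimates
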