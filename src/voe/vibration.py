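"""Vibration engines: model, sampling and measurement vibration.

Each engine is a model class built from a :class:`~voe.cohort.Cohort` whose
``fit()`` returns a :class:`VibrationResult` — the collection of effect
estimates, the reference fit where applicable, the run settings and the
master seed — with summary statistics, tabulation, plotting and file output
hanging off the result.

* :class:`ModelVibration` fits every adjustment-set specification (2^k
  models, baseline adjustments always included) on the full cohort.
* :class:`SamplingVibration` refits the favourite model on B random
  subsets without replacement of size ``floor(fraction * n)``.
* :class:`MeasurementVibration` repeats B times: draw error parameters
  from their uniform ranges, corrupt the scenario's variables, re-fit the
  favourite model.  A continuous exposure is re-standardised after error
  injection so hazard ratios stay per SD of the observed exposure.

Reproducibility: the master seed feeds a ``numpy.random.SeedSequence``
which spawns one independent substream per iteration, so results are
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    EffectEstimate,
    estimates_to_frame,
    standardize_continuous,
    write_results,
)
from .estimation import DesignInfo, fit_all, fit_cox_effect
from .exceptions import EstimationError, VoeError
from .measurement import MERanges, corrupt_cohort, draw_me_params
from .model_space import ModelSpec, enumerate_models, favourite_model
from .summaries import DEFAULT_ALPHA, DEFAULT_PCT, SummaryStats, summarize

VIBRATION_TYPES = ("model", "sampling", "measurement")


@dataclass
class VibrationResult:
    """Results of one vibration run.

    Carries the per-fit effect estimates and, for sampling and measurement
    vibration, the reference fit of the favourite model on the full,
    uncorrupted cohort (the "no-error" benchmark shown as a distinct marker
    on volcano plots).
    """

    vibration_type: str
    estimates: list[EffectEstimate]
    scenario: str | None = None
    reference: EffectEstimate | None = None
    settings: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.vibration_type not in VIBRATION_TYPES:
            raise VoeError(f"unknown vibration type {self.vibration_type!r}")
        if not self.estimates:
            raise VoeError("a vibration result needs at least one estimate")
        if (self.scenario is not None) != (self.vibration_type == "measurement"):
            raise VoeError("scenario is set iff vibration_type == 'measurement'")

    # -- accessors -------------------------------------------------------
    @property
    def converged_estimates(self) -> list[EffectEstimate]:
        return [e for e in self.estimates if e.converged]

    @property
    def n_failed(self) -> int:
        return len(self.estimates) - len(self.converged_estimates)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per estimate with provenance."""
        return estimates_to_frame(self.estimates)

    # -- summaries -------------------------------------------------------
    def stats(
        self,
        alpha: float = DEFAULT_ALPHA,
        pct_lo: float = DEFAULT_PCT[0],
        pct_hi: float = DEFAULT_PCT[1],
    ) -> SummaryStats:
        return summarize(self, alpha=alpha, pct_lo=pct_lo, pct_hi=pct_hi)

    def summary_dict(
        self,
        alpha: float = DEFAULT_ALPHA,
        pct_lo: float = DEFAULT_PCT[0],
        pct_hi: float = DEFAULT_PCT[1],
    ) -> dict:
        s = self.stats(alpha, pct_lo, pct_hi)
        out = {
            "vibration_type": self.vibration_type,
            "scenario": self.scenario,
            "rhr": s.rhr,
            "rp": s.rp,
            "janus": s.janus,
            "n_neg_sig": s.n_neg_sig,
            "n_nonsig": s.n_nonsig,
            "n_pos_sig": s.n_pos_sig,
            "n_failed": s.n_failed,
            "alpha": s.alpha,
            "pct_lo": s.pct_lo,
            "pct_hi": s.pct_hi,
            "seed": self.seed,
            "settings": self.settings,
        }
        if self.reference is not None and self.reference.converged:
            out["reference"] = {
                "log_hr": self.reference.log_hr,
                "hr": self.reference.hr,
                "se": self.reference.se,
                "p_value": self.reference.p_value,
            }
        return out

    def summary(
        self,
        alpha: float = DEFAULT_ALPHA,
        pct_lo: float = DEFAULT_PCT[0],
        pct_hi: float = DEFAULT_PCT[1],
    ) -> str:
        """Human-readable summary table of the vibration run."""
        s = self.stats(alpha, pct_lo, pct_hi)
        lines = [
            f"Vibration of effects — {self.vibration_type} vibration"
            + (f" (scenario: {self.scenario})" if self.scenario else ""),
            "=" * 60,
            f"{'fits':<28}{len(self.estimates):>12}",
            f"{'non-converged fits':<28}{s.n_failed:>12}",
            f"{'RHR (P' + format(pct_hi, 'g') + '/P' + format(pct_lo, 'g') + ')':<28}"
            f"{s.rhr:>12.4f}",
            f"{'RP (spread of -log10 p)':<28}{s.rp:>12.4f}",
            f"{'Janus pattern':<28}{str(s.janus):>12}",
            f"{'negative significant':<28}{s.n_neg_sig:>12}",
            f"{'non-significant':<28}{s.n_nonsig:>12}",
            f"{'positive significant':<28}{s.n_pos_sig:>12}",
        ]
        if self.reference is not None and self.reference.converged:
            lines.append(
                f"{'reference HR (p)':<28}"
                f"{self.reference.hr:>8.4f} ({self.reference.p_value:.3g})"
            )
        return "\n".join(lines)

    # -- output ----------------------------------------------------------
    def save(self, out_dir) -> dict:
        return write_results(self, out_dir)

    def plot_volcano(self, out_path=None, alpha: float = DEFAULT_ALPHA, ax=None):
        from .plots import render_volcano, volcano_data

        data = volcano_data(self, alpha=alpha)
        if out_path is not None:
            return render_volcano(data, out_path)
        return data


def _resolve_favourite(cohort: Cohort, favourite: ModelSpec | None) -> ModelSpec:
    if favourite is not None:
        return favourite
    return favourite_model(cohort.optional_vars, cohort.baseline_vars, cohort.exposure)


def _resolve_design(cohort: Cohort, design: DesignInfo | None) -> DesignInfo:
    return design if design is not None else DesignInfo.from_cohort(cohort)


class ModelVibration:
    """Vibration over the universe of adjustment-set choices.

    Parameters default to the cohort schema: optional adjustments are the
    ``adjustment``-role variables, baseline adjustments the
    ``baseline_adjustment``-role ones (always included in every model).
    """

    def __init__(
        self,
        cohort: Cohort,
        optional_vars: Sequence[str] | None = None,
        baseline_vars: Sequence[str] | None = None,
        design: DesignInfo | None = None,
        max_k: int = 20,
    ):
        self.cohort = cohort
        self.optional_vars = tuple(
            optional_vars if optional_vars is not None else cohort.optional_vars
        )
        self.baseline_vars = tuple(
            baseline_vars if baseline_vars is not None else cohort.baseline_vars
        )
        self.design = _resolve_design(cohort, design)
        self.specs = enumerate_models(
            self.optional_vars, self.baseline_vars, cohort.exposure, max_k=max_k
        )

    def fit(self) -> VibrationResult:
        estimates = fit_all(self.cohort, self.specs, self.design)
        return VibrationResult(
            vibration_type="model",
            estimates=estimates,
            settings={
                "optional_vars": list(self.optional_vars),
                "baseline_vars": list(self.baseline_vars),
                "exposure": self.cohort.exposure,
                "n_models": len(self.specs),
                "n": self.cohort.n,
            },
        )


class SamplingVibration:
    """Vibration over random subsamples of the cohort.

    Each of the B iterations draws a simple random subset without
    replacement of size ``floor(fraction * n)`` and refits the favourite
    model (all adjustments by default).  Subsets ignore survey strata and
    clusters when drawing rows; the design columns still enter each fit.
    """

    def __init__(
        self,
        cohort: Cohort,
        favourite: ModelSpec | None = None,
        B: int = 1000,
        fraction: float = 0.5,
        design: DesignInfo | None = None,
    ):
        if B < 1:
            raise VoeError("B must be >= 1")
        if not (0 < fraction < 1):
            raise VoeError("fraction must lie in (0, 1)")
        self.cohort = cohort
        self.favourite = _resolve_favourite(cohort, favourite)
        self.B = B
        self.fraction = fraction
        self.design = _resolve_design(cohort, design)

    def fit(self, seed: int | None = None) -> VibrationResult:
        n = self.cohort.n
        size = int(np.floor(self.fraction * n))
        reference = fit_cox_effect(
            self.cohort, self.favourite, self.design, provenance=("reference", -1)
        )
        children = np.random.SeedSequence(seed).spawn(self.B)
        estimates = []
        for b, child in enumerate(children):
            rng = np.random.default_rng(child)
            idx = rng.choice(n, size=size, replace=False)
            sub = self.cohort.with_data(self.cohort.data.iloc[np.sort(idx)])
            estimates.append(
                fit_cox_effect(
                    sub, self.favourite, self.design, provenance=("subsample", b)
                )
            )
        return VibrationResult(
            vibration_type="sampling",
            estimates=estimates,
            reference=reference,
            seed=seed,
            settings={
                "B": self.B,
                "fraction": self.fraction,
                "subset_size": size,
                "favourite": list(self.favourite.included_adjustments),
                "exposure": self.cohort.exposure,
                "n": n,
            },
        )


class MeasurementVibration:
    """Vibration under simulated measurement error / misclassification.

    Per iteration, one parameter draw (correlation, sensitivity,
    specificity — each uniform on its range) applies to all corrupted
    variables; errors across variables are independent.  Scenarios:
    ``exposure_only``, ``adjustment_only`` or ``both``.  Error-free
    variables are never corrupted.
    """

    def __init__(
        self,
        cohort: Cohort,
        scenario: str = "both",
        ranges: MERanges | None = None,
        favourite: ModelSpec | None = None,
        B: int = 1000,
        design: DesignInfo | None = None,
        max_failure_frac: float = 0.05,
    ):
        if B < 1:
            raise VoeError("B must be >= 1")
        self.cohort = cohort
        self.scenario = scenario
        self.ranges = ranges if ranges is not None else MERanges()
        self.favourite = _resolve_favourite(cohort, favourite)
        self.B = B
        self.design = _resolve_design(cohort, design)
        self.max_failure_frac = max_failure_frac

    def fit(self, seed: int | None = None) -> VibrationResult:
        cohort = self.cohort
        exposure_spec = cohort.spec_of(cohort.exposure)
        exposure_corrupted = (
            self.scenario in ("exposure_only", "both")
            and not exposure_spec.error_free
            and exposure_spec.kind == "continuous"
        )
        reference = fit_cox_effect(
            cohort, self.favourite, self.design, provenance=("reference", -1)
        )
        children = np.random.SeedSequence(seed).spawn(self.B)
        estimates = []
        for b, child in enumerate(children):
            rng = np.random.default_rng(child)
            draw = draw_me_params(self.ranges, rng)
            corrupted = corrupt_cohort(cohort, draw, self.scenario, rng)
            if exposure_corrupted and not np.array_equal(
                corrupted.data[cohort.exposure], cohort.data[cohort.exposure]
            ):
                # keep hazard ratios per SD of the observed exposure
                corrupted = standardize_continuous(corrupted, [cohort.exposure])
            estimates.append(
                fit_cox_effect(
                    corrupted, self.favourite, self.design,
                    provenance=("error_draw", b),
                )
            )
        n_failed = sum(not e.converged for e in estimates)
        if n_failed > self.max_failure_frac * self.B:
            raise EstimationError(
                f"{n_failed}/{self.B} error-draw fits failed to converge"
            )
        return VibrationResult(
            vibration_type="measurement",
            scenario=self.scenario,
            estimates=estimates,
            reference=reference,
            seed=seed,
            settings={
                "B": self.B,
                "scenario": self.scenario,
                "rho_range": [self.ranges.rho_low, self.ranges.rho_high],
                "sens_range": [self.ranges.sens_low, self.ranges.sens_high],
                "spec_range": [self.ranges.spec_low, self.ranges.spec_high],
                "favourite": list(self.favourite.included_adjustments),
                "exposure": cohort.exposure,
                "n": cohort.n,
            },
        )


# ---------------------------------------------------------------------------
# functional wrappers


def model_vibration(
    cohort: Cohort,
    optional_vars: Sequence[str] | None = None,
    baseline_vars: Sequence[str] | None = None,
    design: DesignInfo | None = None,
    max_k: int = 20,
) -> VibrationResult:
    return ModelVibration(cohort, optional_vars, baseline_vars, design, max_k).fit()


def sampling_vibration(
    cohort: Cohort,
    favourite: ModelSpec | None = None,
    B: int = 1000,
    fraction: float = 0.5,
    design: DesignInfo | None = None,
    seed: int | None = None,
) -> VibrationResult:
    return SamplingVibration(cohort, favourite, B, fraction, design).fit(seed)


def measurement_vibration(
    cohort: Cohort,
    favourite: ModelSpec | None = None,
    scenario: str = "both",
    ranges: MERanges | None = None,
    B: int = 1000,
    design: DesignInfo | None = None,
    seed: int | None = None,
) -> VibrationResult:
    return MeasurementVibration(cohort, scenario, ranges, favourite, B, design).fit(seed)


def vibration_over_sample_sizes(
    generator_spec,
    sizes: Sequence[int],
    engines: Sequence[str] = VIBRATION_TYPES,
    B: int = 1000,
    fraction: float = 0.5,
    ranges: MERanges | None = None,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the selected engines on synthetic cohorts of increasing size.

    For each n one cohort is generated and each engine summarised; the
    measurement engine uses the ``both`` scenario.  Returns a table with
    one row per (n, vibration type): RHR, RP, Janus flag and significance
    counts.
    """
    from .simulate import generate_cohort

    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise VoeError("sizes must be strictly increasing")
    unknown = set(engines) - set(VIBRATION_TYPES)
    if unknown:
        raise VoeError(f"unknown engines: {unknown}")

    top = np.random.SeedSequence(seed).spawn(len(sizes))
    rows = []
    for n, size_seq in zip(sizes, top):
        gen_seq, samp_seq, meas_seq = size_seq.spawn(3)
        cohort = generate_cohort(
            generator_spec.with_n(n), seed=int(gen_seq.generate_state(1)[0] >> 33)
        )
        results: dict[str, VibrationResult] = {}
        if "model" in engines:
            results["model"] = ModelVibration(cohort).fit()
        if "sampling" in engines:
            results["sampling"] = SamplingVibration(cohort, B=B, fraction=fraction).fit(
                seed=int(samp_seq.generate_state(1)[0] >> 33)
            )
        if "measurement" in engines:
            results["measurement"] = MeasurementVibration(
                cohort, scenario="both", ranges=ranges, B=B
            ).fit(seed=int(meas_seq.generate_state(1)[0] >> 33))
        for vib_type, res in results.items():
            s = res.stats(alpha=alpha)
            rows.append(
                {
                    "n": n,
                    "vibration_type": vib_type,
                    "rhr": s.rhr,
                    "rp": s.rp,
                    "janus": s.janus,
                    "n_neg_sig": s.n_neg_sig,
                    "n_nonsig": s.n_nonsig,
                    "n_pos_sig": s.n_pos_sig,
                    "n_failed": s.n_failed,
                }
            )
    return pd.DataFrame(rows)
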