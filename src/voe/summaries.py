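"""Vibration summary statistics: RHR, RP, Janus pattern, significance counts.

The relative hazard ratio (RHR) is the ratio of the 99th to the 1st
percentile of hazard ratios across a vibration set; the relative P-value
(RP) is the difference between the 99th and 1st percentile of
-log10(p-value).  Quantiles use linear interpolation between order
statistics (numpy's default, Hyndman-Fan type 7).  The Janus pattern is
present when the set contains significant estimates in both the harmful
(HR > 1) and protective (HR < 1) direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import EffectEstimate
from .exceptions import InsufficientDataError, VoeError

DEFAULT_ALPHA = 0.05
DEFAULT_PCT = (1.0, 99.0)


@dataclass(frozen=True)
class SummaryStats:
    rhr: float
    rp: float
    janus: bool
    n_neg_sig: int
    n_nonsig: int
    n_pos_sig: int
    n_failed: int
    alpha: float
    pct_lo: float
    pct_hi: float


def relative_hazard_ratio(
    hrs: Sequence[float], pct_lo: float = DEFAULT_PCT[0], pct_hi: float = DEFAULT_PCT[1]
) -> float:
    """Ratio of the ``pct_hi`` to the ``pct_lo`` percentile of hazard ratios."""
    hrs = np.asarray(hrs, dtype=float)
    if hrs.size < 2:
        raise InsufficientDataError("RHR needs at least 2 hazard ratios")
    if not np.isfinite(hrs).all() or (hrs <= 0).any():
        raise VoeError("hazard ratios must be finite and > 0")
    hi, lo = np.percentile(hrs, [pct_hi, pct_lo])
    return float(hi / lo)


def relative_p(
    pvals: Sequence[float], pct_lo: float = DEFAULT_PCT[0], pct_hi: float = DEFAULT_PCT[1]
) -> float:
    """Spread of -log10(p): ``pct_hi`` minus ``pct_lo`` percentile."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size < 2:
        raise InsufficientDataError("RP needs at least 2 p-values")
    if (pvals <= 0).any() or (pvals > 1).any():
        raise VoeError("p-values must lie in (0, 1]")
    neglog = -np.log10(pvals)
    hi, lo = np.percentile(neglog, [pct_hi, pct_lo])
    return float(hi - lo)


def classify_significance(
    estimates: Sequence[EffectEstimate], alpha: float = DEFAULT_ALPHA
) -> tuple[int, int, int]:
    """Counts of (negative significant, non-significant, positive significant).

    An estimate is significant when p < alpha; the direction is the sign of
    the log hazard ratio, with log HR exactly 0 counted as non-significant.
    """
    n_neg = n_pos = n_non = 0
    for e in estimates:
        if not e.converged:
            raise VoeError("classify_significance expects converged estimates only")
        if e.p_value < alpha and e.log_hr < 0:
            n_neg += 1
        elif e.p_value < alpha and e.log_hr > 0:
            n_pos += 1
        else:
            n_non += 1
    return n_neg, n_non, n_pos


def detect_janus(
    estimates: Sequence[EffectEstimate], alpha: float = DEFAULT_ALPHA
) -> bool:
    """True iff significant estimates occur in both directions."""
    n_neg, _, n_pos = classify_significance(estimates, alpha)
    return n_neg >= 1 and n_pos >= 1


def summarize(
    result,
    alpha: float = DEFAULT_ALPHA,
    pct_lo: float = DEFAULT_PCT[0],
    pct_hi: float = DEFAULT_PCT[1],
) -> SummaryStats:
    """Assemble the summary statistics over a result's converged estimates."""
    converged = [e for e in result.estimates if e.converged]
    n_failed = len(result.estimates) - len(converged)
    if len(converged) < 2:
        raise InsufficientDataError("summary needs >= 2 converged estimates")
    n_neg, n_non, n_pos = classify_significance(converged, alpha)
    return SummaryStats(
        rhr=relative_hazard_ratio([e.hr for e in converged], pct_lo, pct_hi),
        rp=relative_p([e.p_value for e in converged], pct_lo, pct_hi),
        janus=n_neg >= 1 and n_pos >= 1,
        n_neg_sig=n_neg,
        n_nonsig=n_non,
        n_pos_sig=n_pos,
        n_failed=n_failed,
        alpha=alpha,
        pct_lo=pct_lo,
        pct_hi=pct_hi,
    )
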