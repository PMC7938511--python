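"""Enumeration of the adjustment-set model universe.

With k optional adjustment variables there are 2^k Cox specifications,
one per subset, each additionally containing every baseline adjustment
(e.g. age and sex forced into all models).  Enumeration order is the
binary counter over the optional variables, least-significant bit = first
listed optional variable, so ``model_id`` is stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .exceptions import SchemaError

#: guard against accidentally requesting a universe too large to fit
DEFAULT_MAX_K = 20


@dataclass(frozen=True)
class ModelSpec:
    """One Cox specification: the exposure plus a set of adjustments."""

    exposure: str
    included_adjustments: tuple[str, ...]
    model_id: int


def enumerate_models(
    optional_vars: Sequence[str],
    baseline_vars: Sequence[str],
    exposure: str,
    max_k: int = DEFAULT_MAX_K,
) -> list[ModelSpec]:
    """All 2^k adjustment-set specifications in binary-counter order.

    ``model_id`` is the integer whose bit i indicates inclusion of
    ``optional_vars[i]``; every model contains all ``baseline_vars``.
    """
    optional_vars = list(optional_vars)
    baseline_vars = list(baseline_vars)
    overlap = set(optional_vars) & set(baseline_vars)
    if overlap:
        raise SchemaError(f"variables in both optional and baseline sets: {overlap}")
    if exposure in optional_vars or exposure in baseline_vars:
        raise SchemaError("exposure cannot appear among the adjustment variables")
    k = len(optional_vars)
    if k > max_k:
        raise SchemaError(
            f"k={k} optional variables would enumerate 2^{k} models; "
            f"raise max_k explicitly if this is intended"
        )
    return [
        ModelSpec(
            exposure=exposure,
            included_adjustments=tuple(baseline_vars)
            + tuple(v for i, v in enumerate(optional_vars) if mask >> i & 1),
            model_id=mask,
        )
        for mask in range(2**k)
    ]


def favourite_model(
    optional_vars: Sequence[str], baseline_vars: Sequence[str], exposure: str
) -> ModelSpec:
    """The all-adjustments specification used as the favourite model."""
    k = len(optional_vars)
    return ModelSpec(
        exposure=exposure,
        included_adjustments=tuple(baseline_vars) + tuple(optional_vars),
        model_id=2**k - 1,
    )
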