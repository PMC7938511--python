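"""Volcano plots and sample-size trajectory plots.

A volcano plot scatters hazard ratios (x, log scale so reciprocal effects
are symmetric) against -log10 p-values (y), with a horizontal line at the
significance threshold and a distinct cross marker for the reference fit
(the favourite model without injected error).  The sweep plot shows RHR
trajectories against sample size on top and stacked bars of the
significance-class fractions below.

Rendering is deterministic: a fixed style, no timestamps in the output
metadata, and a fixed SVG hash salt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import VoeError
from .summaries import DEFAULT_ALPHA

_SIG_CLASSES = ["n_neg_sig", "n_nonsig", "n_pos_sig"]
_SIG_LABELS = ["negative significant", "non-significant", "positive significant"]
_SIG_COLORS = ["#2166ac", "#bdbdbd", "#b2182b"]


@dataclass(frozen=True)
class VolcanoData:
    """Plot-ready arrays for one vibration run."""

    x: np.ndarray  # hazard ratios
    y: np.ndarray  # -log10 p-values
    reference: tuple[float, float] | None
    alpha_line: float
    title: str = ""

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise VoeError("x and y must have equal length")
        if (np.asarray(self.y) < 0).any():
            raise VoeError("-log10 p-values must be >= 0")


def volcano_data(result, alpha: float = DEFAULT_ALPHA) -> VolcanoData:
    """Extract volcano-plot coordinates from a vibration result."""
    converged = result.converged_estimates
    if not converged:
        raise VoeError("no converged estimates to plot")
    x = np.array([e.hr for e in converged])
    y = -np.log10(np.array([e.p_value for e in converged]))
    ref = None
    if result.reference is not None and result.reference.converged:
        ref = (result.reference.hr, -np.log10(result.reference.p_value))
    title = f"{result.vibration_type} vibration"
    if result.scenario:
        title += f" ({result.scenario})"
    return VolcanoData(
        x=x, y=y, reference=ref, alpha_line=-np.log10(alpha), title=title
    )


def _save(fig, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    metadata = (
        {"Date": None, "Creator": "voe"}
        if out_path.suffix == ".svg"
        else {"Software": "voe"}
    )
    with matplotlib.rc_context({"svg.hashsalt": "voe"}):
        fig.savefig(out_path, dpi=150, metadata=metadata)
    plt.close(fig)
    return out_path


def render_volcano(
    data: VolcanoData,
    out_path: str | Path,
    marker_size: float = 8.0,
    color: str = "#4d4d4d",
) -> Path:
    """Render a volcano plot to PNG or SVG."""
    if len(data.x) == 0:
        raise VoeError("nothing to plot")
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(data.x, data.y, s=marker_size, c=color, alpha=0.6, linewidths=0)
    ax.axhline(data.alpha_line, color="#b2182b", ls="--", lw=1)
    if data.reference is not None:
        ax.scatter(
            *data.reference, marker="x", s=90, c="black", linewidths=2.5, zorder=5
        )
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    if data.title:
        ax.set_title(data.title)
    fig.tight_layout()
    return _save(fig, out_path)


def render_sweep(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Render RHR-vs-n trajectories and significance-class bars.

    Expects the table produced by ``vibration_over_sample_sizes``.
    """
    if table.empty:
        raise VoeError("empty sweep table")
    types = sorted(table["vibration_type"].unique())
    sizes = sorted(table["n"].unique())
    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(6.5, 7), height_ratios=[2, 1.4]
    )
    for vib in types:
        sub = table[table["vibration_type"] == vib].sort_values("n")
        ax_top.plot(sub["n"], sub["rhr"], marker="o", label=vib)
    ax_top.set_xscale("log")
    ax_top.set_xlabel("sample size n")
    ax_top.set_ylabel("RHR")
    ax_top.axhline(1.0, color="grey", lw=0.8)
    ax_top.legend(title="vibration")

    # stacked bars of significance-class fractions per (n, type)
    width = 0.8 / len(types)
    xs = np.arange(len(sizes))
    for t_i, vib in enumerate(types):
        sub = table[table["vibration_type"] == vib].set_index("n").loc[sizes]
        totals = sub[_SIG_CLASSES].sum(axis=1).to_numpy(float)
        bottom = np.zeros(len(sizes))
        for cls, label, color in zip(_SIG_CLASSES, _SIG_LABELS, _SIG_COLORS):
            frac = sub[cls].to_numpy(float) / totals
            ax_bot.bar(
                xs + t_i * width, frac, width=width * 0.95, bottom=bottom,
                color=color, label=label if t_i == 0 else None,
            )
            bottom += frac
    ax_bot.set_xticks(xs + 0.4 - width / 2)
    ax_bot.set_xticklabels([str(s) for s in sizes])
    ax_bot.set_xlabel("sample size n")
    ax_bot.set_ylabel("fraction of fits")
    ax_bot.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    return _save(fig, out_path)
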