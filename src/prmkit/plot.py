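"""Figure export: charge-coded TIC stacks and mirrored sample/reference XICs."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .prm import ReferenceSpectrum, Xic
from .qc import CHARGE_CLASSES, ChargeClassTrace

# +1..+3 in blues/greens (expected peptide range), high charges in warm colors,
# unknown in gray.
_CLASS_COLORS = {
    "+1": "#1f77b4",
    "+2": "#2ca02c",
    "+3": "#17becf",
    "+4": "#bcbd22",
    "+5": "#ff7f0e",
    "+6": "#e377c2",
    "+7": "#d62728",
    ">=+8": "#8c0000",
    "unknown": "#999999",
}


def plot_charge_tic(trace: ChargeClassTrace, path, title: str = "") -> None:
    """Stacked charge-class TIC chromatogram."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(
        trace.time_min,
        [trace.intensity[c] for c in CHARGE_CLASSES],
        labels=CHARGE_CLASSES,
        colors=[_CLASS_COLORS[c] for c in CHARGE_CLASSES],
    )
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mirror_xics(
    sample_xics: Sequence[Xic],
    reference: ReferenceSpectrum,
    path,
    aligned_rt_min: Optional[float] = None,
) -> None:
    """Sample XICs above the axis, reference stick pattern mirrored below."""
    fig, ax = plt.subplots(figsize=(7, 4))
    top = max((x.intensity.max() for x in sample_xics if x.intensity.size), default=1.0)
    top = top or 1.0
    cmap = plt.get_cmap("tab20")
    for i, x in enumerate(sample_xics):
        if x.intensity.size:
            ax.plot(x.time_min, x.intensity / top, color=cmap(i % 20), lw=1,
                    label=x.annotation)
    ref_rel = {a: rel for a, _, rel in reference.transitions}
    if aligned_rt_min is not None:
        for i, x in enumerate(sample_xics):
            rel = ref_rel.get(x.annotation, 0.0)
            ax.vlines(aligned_rt_min, -rel, 0, color=cmap(i % 20), lw=2)
        ax.axvline(aligned_rt_min, color="k", ls=":", lw=0.8)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("relative intensity (sample / reference mirrored)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
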