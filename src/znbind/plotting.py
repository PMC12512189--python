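"""Minimal diagnostic figures for the aligned dose-response channels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .correlate import CHANNELS, DoseResponseSet  # noqa: E402

_LABELS = {
    "occupancy_pct": "occupancy (native MS)",
    "compaction_pct": "compaction (IM-MS)",
    "t50_drop": "t50 reduction (ThT)",
}


def plot_dose_response(drset: DoseResponseSet, path=None,
                       saturation: float | None = None):
    """Overlay of the three normalised channels vs molar equivalents."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for chan, color in zip(CHANNELS, ("tab:red", "tab:blue", "black")):
        ax.plot(drset.equivalents, drset.normalized(chan), "o-",
                color=color, label=_LABELS[chan], ms=4)
    if saturation is not None:
        ax.axvline(saturation, color="gray", alpha=0.5, ls="--",
                   label=f"saturation ~{saturation:.0f}x")
    ax.set_xlabel("molar equivalents (ligand : protein)")
    ax.set_ylabel("normalised response")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
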