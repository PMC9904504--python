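"""Diagnostic plot for a spectral storage result.

One histogram panel per tested scale: the surrogate AIS' distribution,
its median, and the original AIS, with the nominal band in the panel
title.  Matplotlib is imported lazily so the analysis stack has no hard
plotting dependency.
"""

from __future__ import annotations

__all__ = ["plot_result"]


def plot_result(result, bins: int = 30, figsize=None):
    """Per-scale surrogate histograms for a :class:`SpectralAISResult`.

    Returns the matplotlib figure; call ``fig.savefig(...)`` or
    ``matplotlib.pyplot.show()`` to render.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    n = len(result.scales)
    if figsize is None:
        figsize = (6, 1.6 * n)
    fig, axes = plt.subplots(n, 1, figsize=figsize, sharex=True, squeeze=False)
    for ax, j, band, vals, p, delta, sig in zip(
        axes[:, 0],
        result.scales,
        result.bands,
        result.surrogates,
        result.p_values,
        result.deltas,
        result.significant,
    ):
        ax.hist(vals, bins=bins, color="0.85", edgecolor="0.5")
        med = float(np.median(vals))
        ax.axvline(med, color="tab:red", ls="--", label="surrogate median")
        ax.axvline(result.ais_original, color="k", ls="--", label="original AIS")
        star = " *" if sig else ""
        ax.set_title(
            f"scale {j} ({band[0]:.3g}-{band[1]:.3g} Hz): "
            f"delta={delta:+.3f} nats, p={p:.3g}{star}",
            fontsize=9,
        )
        ax.set_ylabel("count")
    axes[-1, 0].set_xlabel("AIS (nats)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    return fig
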