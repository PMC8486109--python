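"""Optional overlay plot: ordinary posterior densities with the BDP band."""

from __future__ import annotations

import numpy as np

from .diagnostics import hdi
from .samplers import PosteriorDraws


def overlay_plot(ordinary: PosteriorDraws, tempered: PosteriorDraws, path,
                 mass: float = 0.95):
    """Histogram of each source's ordinary marginal with the BDP shaded.

    Matplotlib is imported lazily; plotting is never required by the rest of
    the package.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = len(ordinary.source_names)
    ncol = min(K, 2)
    nrow = (K + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 3 * nrow),
                             squeeze=False)
    for k, name in enumerate(ordinary.source_names):
        ax = axes[k // ncol][k % ncol]
        ax.hist(100 * ordinary.p_draws[:, k], bins=60, range=(0, 100),
                density=True, color="steelblue", alpha=0.7,
                label="ordinary posterior")
        lo, hi = hdi(tempered.p_draws[:, k], mass)
        ax.axvspan(100 * lo, 100 * hi, color="firebrick", alpha=0.3,
                   label=f"BDP (beta={tempered.beta:g})")
        ax.set_title(name)
        ax.set_xlabel("contribution (%)")
        if k == 0:
            ax.legend(fontsize=8)
    for k in range(K, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
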