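"""Basic diagnostic figures (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .ibd import IBDFit, PairwiseMatrix
from .reserves import SpacingReport


def ibd_scatter(geo: PairwiseMatrix, gen: PairwiseMatrix, fit: IBDFit, ax=None):
    """Linearized genetic distance against along-shore km with the RMA line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y = geo.offdiag(), gen.offdiag()
    ax.scatter(x, y, s=18, color="0.2")
    xs = np.linspace(0, x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson",
            label=f"RMA slope {fit.slope:.3g}/km")
    ax.set_xlabel("along-shore distance (km)")
    ax.set_ylabel(r"$F_{ST} / (1 - F_{ST})$")
    ax.legend(frameon=False)
    return ax


def spacing_histogram(report: SpacingReport, ax=None, bin_km: float = 25.0):
    """Histogram of nearest-neighbour reserve spacings per network."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    top = max((max(v) for v in report.network_spacings.values() if v), default=0)
    bins = np.arange(0, top + 2 * bin_km, bin_km)
    for net, vals in sorted(report.network_spacings.items()):
        ax.hist(vals, bins=bins, alpha=0.6, label=net)
    ax.set_xlabel("distance to nearest reserve (km)")
    ax.set_ylabel("reserves")
    ax.legend(frameon=False)
    return ax
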