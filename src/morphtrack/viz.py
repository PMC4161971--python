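"""Optional plotting hooks (require matplotlib, installed via the ``plot``
extra).  These mirror the standard presentations of the analysis: the
correlation-matrix pair with its decay curves, and the four-comparison bars.
"""

from __future__ import annotations

import numpy as np

from .correlation import CorrelationMatrix, DecayCurve
from .protrusion import COMPARISONS, ComparisonResult

__all__ = ["plot_correlograms", "plot_decay_curves", "plot_comparison_bars"]


def _mpl():
    import matplotlib.pyplot as plt
    return plt


def plot_correlograms(matrix_1d: CorrelationMatrix, matrix_2d: CorrelationMatrix,
                      ax_pair=None):
    """Side-by-side planar/linear correlation matrices, color = C_ij."""
    plt = _mpl()
    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, m, title in zip(ax_pair, (matrix_2d, matrix_1d),
                            ("planar (2D)", "linear (1D)")):
        im = ax.imshow(m.C, vmin=-1, vmax=1, cmap="jet", origin="lower",
                       extent=(0.5, m.n_sections + 0.5, 0.5, m.n_sections + 0.5))
        ax.set_xlabel("section j")
        ax.set_ylabel("section i")
        ax.set_title(f"{title}: {m.cell_id}")
        plt.colorbar(im, ax=ax, label="C_ij")
    return ax_pair


def plot_decay_curves(curve_1d: DecayCurve, curve_2d: DecayCurve, ax=None):
    """r_d vs d for both frames (1D red, 2D black), SEM error bars."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    for curve, color, label in ((curve_1d, "tab:red", "linear (1D)"),
                                (curve_2d, "black", "planar (2D)")):
        ax.errorbar(curve.d, curve.r, yerr=curve.sem, color=color,
                    marker="o", ms=3, capsize=2, label=label)
    ax.set_xlabel("configuration dissimilarity d")
    ax.set_ylabel(r"$r_d$")
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.legend(frameon=False)
    return ax


def plot_comparison_bars(result: ComparisonResult, ax=None):
    """Mean +/- SEM of the Flip/Distance/Segment/Rescaled correlations."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    means = [result.means[k] for k in COMPARISONS]
    sems = [result.sems[k] for k in COMPARISONS]
    x = np.arange(len(COMPARISONS))
    ax.bar(x, means, yerr=sems, capsize=3, color="tab:blue")
    ax.set_xticks(x, [k.capitalize() for k in COMPARISONS])
    ax.set_ylabel("mean correlation")
    ax.axhline(0.0, lw=0.5, color="gray")
    return ax
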