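"""Plotting helpers: ratio histograms, dose curves and the shape diagram."""

from __future__ import annotations

import numpy as np


def plot_ratio_histogram(stats, ax=None, label=None):
    """Bar plot of an M-m ratio histogram with detected peaks arrowed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (stats.bin_edges[:-1] + stats.bin_edges[1:])
    width = stats.bin_edges[1] - stats.bin_edges[0]
    ax.bar(centers, stats.counts, width=0.9 * width, label=label)
    top = stats.counts.max()
    for peak in stats.peak_locations:
        ax.annotate("", xy=(peak, top * 0.85), xytext=(peak, top * 1.05),
                    arrowprops=dict(arrowstyle="->"))
    ax.set_xlabel("M-m ratio")
    ax.set_ylabel("count")
    return ax


def plot_dose_response(concentrations, means, sds=None, ax=None):
    """Mean M-m ratio (with SD bars) against the dose-like parameter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(concentrations, means, yerr=sds, marker="o", capsize=3)
    ax.set_xlabel("concentration-like parameter")
    ax.set_ylabel("mean M-m ratio")
    return ax


def plot_shape_diagram(library, ax=None):
    """Class map of a shape library over the (da, v) grid."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    from .classify import SHAPE_CLASSES

    if ax is None:
        _, ax = plt.subplots()
    das = library.grid_spec.da_values()
    vs = library.grid_spec.v_values()
    codes = np.full((len(vs), len(das)), np.nan)
    lut = {name: i for i, name in enumerate(SHAPE_CLASSES)}
    for j, v in enumerate(vs):
        for i, da in enumerate(das):
            sol = library.get(da, v)
            if sol.converged and sol.shape_class in lut:
                codes[j, i] = lut[sol.shape_class]
    cmap = ListedColormap(["#cccccc", "#7b3294", "#2c7bb6", "#abd9e9",
                           "#fdae61", "#d7191c"])
    im = ax.imshow(codes, origin="lower", aspect="auto", cmap=cmap,
                   vmin=-0.5, vmax=len(SHAPE_CLASSES) - 0.5,
                   extent=[das[0], das[-1], vs[0], vs[-1]])
    cbar = ax.figure.colorbar(im, ax=ax, ticks=range(len(SHAPE_CLASSES)))
    cbar.ax.set_yticklabels(SHAPE_CLASSES)
    ax.set_xlabel("area difference Δa")
    ax.set_ylabel("reduced volume v")
    return ax


def plot_meridian(solution, ax=None):
    """Cross-section outline of a converged shape solution."""
    import matplotlib.pyplot as plt

    from .classify import meridian_profile

    if ax is None:
        _, ax = plt.subplots()
    p = meridian_profile(solution.shape)
    ax.plot(np.concatenate([p.rho, -p.rho[::-1], p.rho[:1]]),
            np.concatenate([p.z, p.z[::-1], p.z[:1]]))
    ax.set_aspect("equal")
    return ax
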