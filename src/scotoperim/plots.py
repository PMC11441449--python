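"""Optional matplotlib figures: pointwise maps, difference plots,
sentinel-aware histograms, and Bland-Altman scatter."""

from __future__ import annotations

import numpy as np

from .exam import Exam, NON_SEEN
from .indices import DifferenceClass, DifferenceMap

_CLASS_COLORS = {
    DifferenceClass.EQUAL_NORMAL: "0.6",
    DifferenceClass.EQUAL_REDUCED: "black",
    DifferenceClass.ROD_DYSFUNCTION: "tab:red",
    DifferenceClass.CONE_DYSFUNCTION: "tab:blue",
    None: "white",
}


def plot_pointwise(exam: Exam, ax=None):
    """Pointwise sensitivity map; non-seen loci drawn black."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xy = exam.grid.xy
    t = exam.threshold_array
    seen = t != NON_SEEN
    sc = ax.scatter(xy[seen, 0], xy[seen, 1], c=t[seen], vmin=0, vmax=36,
                    cmap="viridis", s=120, edgecolors="k", zorder=3)
    ax.scatter(xy[~seen, 0], xy[~seen, 1], c="black", s=120, zorder=3)
    ax.set_aspect("equal")
    ax.set_xlabel("temporal retina  x (deg)")
    ax.set_ylabel("superior retina  y (deg)")
    ax.figure.colorbar(sc, ax=ax, label="sensitivity (dB)")
    return ax


def plot_difference_map(grid_xy: np.ndarray, diff_map: DifferenceMap, ax=None):
    """Cyan-red difference classification map (remodeled color code)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    classes = diff_map.classes or (None,) * len(diff_map.locus_ids)
    colors = [_CLASS_COLORS[c] for c in classes]
    ax.scatter(grid_xy[:, 0], grid_xy[:, 1], c=colors, s=120, edgecolors="k")
    ax.set_aspect("equal")
    thr = diff_map.threshold_used
    ax.set_title(f"cyan - red, limit ±{thr:g} dB" if thr is not None else "cyan - red")
    return ax


def plot_sensitivity_histogram(thresholds, ax=None):
    """Pointwise histogram with an explicit −1.0 dB non-seen bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bins = [-1.5, -0.5] + list(np.arange(0.0, 37.0, 2.0))
    ax.hist(np.asarray(thresholds, float), bins=bins, edgecolor="k")
    ax.set_xlabel("pointwise sensitivity (dB; -1 = non-seen)")
    ax.set_ylabel("loci")
    return ax


def plot_bland_altman(pairs, result=None, ax=None):
    """Mean-vs-difference scatter with bias and limits of agreement."""
    import matplotlib.pyplot as plt
    import pandas as pd

    if ax is None:
        _, ax = plt.subplots()
    df = pd.DataFrame(pairs)
    mean = (df["value_test1"] + df["value_test2"]) / 2.0
    diff = df["value_test2"] - df["value_test1"]
    ax.scatter(mean, diff, alpha=0.5)
    if result is not None:
        for y, style in ((result.bias, "-"), (result.loa_low, "--"),
                         (result.loa_high, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of test1 and test2")
    ax.set_ylabel("test2 - test1")
    return ax
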