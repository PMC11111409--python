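"""Lineage-through-time curves and slope heatmaps.

For each clade the cumulative lineage count starts at 2 at the clade's crown
node and steps up at every branching age.  Steepness is measured per bin on
a global grid anchored at the present (default 5-Myr bins): the difference
of ``ln(count + 1)`` between consecutive bin edges divided by the bin width,
smoothed with Tukey's running median (the "3R" variant: repeated window-3
medians with the end values copied, iterated to a fixed point).  The ``+1``
inside the logarithm guards the transform at low counts and is exposed as
``log_offset``.  The bin containing a clade's crown node is omitted — the
jump from zero to two lineages would dominate the colour scale — and bins
older than the crown are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree_core import DatedTree, Node, TreeError

__all__ = [
    "LTTCurve",
    "SlopeMatrix",
    "ltt_curve",
    "tukey_running_median",
    "ltt_slope_heatmap",
    "plot_slope_heatmap",
]


@dataclass
class LTTCurve:
    """Branching ages (descending, Ma) and lineage counts of one clade.

    ``count_at(a)`` is right-continuous in decreasing age: a branching node
    at exactly age ``a`` is already counted at ``a``, so the count at the
    crown age is 2 and the count at 0 is the number of extant tips.
    """

    name: str
    branching_ages: np.ndarray  # descending; first entry = crown age
    n_tips: int

    @property
    def crown_age(self) -> float:
        return float(self.branching_ages[0])

    @property
    def counts(self) -> np.ndarray:
        return np.arange(2, 2 + self.branching_ages.size)

    def count_at(self, age) -> np.ndarray:
        ascending = self.branching_ages[::-1]
        at_or_above = self.branching_ages.size - np.searchsorted(
            ascending, np.asarray(age, dtype=float), side="left")
        return 1 + at_or_above


def ltt_curve(tree: DatedTree, clade_root: Node | None = None,
              name: str = "clade") -> LTTCurve:
    """LTT curve of a clade of an extant-only tree, starting at its crown."""
    if not tree.is_ultrametric():
        raise TreeError("LTT curves require an extant-only (ultrametric) tree")
    root = clade_root if clade_root is not None else tree.tree.root
    if root.is_leaf:
        raise TreeError("a single-tip clade has no crown node")
    ages = []
    n_tips = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            n_tips += 1
        else:
            ages.append(tree.age(node))
            stack.extend(node.children)
    return LTTCurve(name=name,
                    branching_ages=np.sort(np.asarray(ages))[::-1],
                    n_tips=n_tips)


def tukey_running_median(series) -> np.ndarray:
    """Tukey's 3R smoother: repeated running medians of window 3 (end values
    copied unchanged) until the sequence stops changing."""
    x = np.asarray(series, dtype=float).copy()
    if x.ndim != 1:
        raise ValueError("need a 1-d sequence")
    if x.size < 3:
        return x
    for _ in range(max(10, 10 * x.size)):
        smoothed = x.copy()
        stacked = np.column_stack((x[:-2], x[1:-1], x[2:]))
        smoothed[1:-1] = np.median(stacked, axis=1)
        if np.array_equal(smoothed, x):
            return smoothed
        x = smoothed
    return x  # pragma: no cover - 3R converges in < n passes


@dataclass
class SlopeMatrix:
    """Smoothed log-LTT slopes (Myr^-1) per clade (rows) and time bin
    (columns, labelled by the bin's older edge, oldest first).  Cells older
    than a clade's crown, and the crown bin itself, are NaN."""

    table: pd.DataFrame
    bin_width: float
    log_offset: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="clade",
                          float_format="%.10g")


def ltt_slope_heatmap(curves: list[LTTCurve], bin_width: float = 5.0,
                      log_offset: float = 1.0) -> SlopeMatrix:
    """Per-clade, per-bin steepness of the log lineage count.

    Bin edges sit on a global grid anchored at age 0 so rows are comparable;
    for each bin fully younger than the clade's crown the slope is
    ``(ln(N(young_edge)+c) - ln(N(old_edge)+c)) / bin_width``, and each
    clade's slope sequence is smoothed with :func:`tukey_running_median`.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not curves:
        raise ValueError("need at least one curve")
    max_crown = max(c.crown_age for c in curves)
    n_bins = int(np.ceil(max_crown / bin_width - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width  # ascending ages
    rows = {}
    for curve in curves:
        counts = curve.count_at(edges).astype(float)
        log_counts = np.log(counts + log_offset)
        raw = (log_counts[:-1] - log_counts[1:]) / bin_width  # per bin, young edge j
        values = np.full(n_bins, np.nan)
        # bin j spans ages [edges[j], edges[j+1]); defined iff fully below crown
        defined = edges[1:] <= curve.crown_age + 1e-12
        # the bin containing the crown is the first undefined one; omit it and
        # everything older by leaving NaN
        idx = np.where(defined)[0]
        if idx.size:
            values[idx] = tukey_running_median(raw[idx])
        rows[curve.name] = values[::-1]  # oldest bin first
    columns = edges[1:][::-1]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return SlopeMatrix(table=table, bin_width=bin_width, log_offset=log_offset)


def plot_slope_heatmap(matrix: SlopeMatrix, path) -> None:
    """Render the slope matrix with a yellow (steep) to blue (shallow)
    colour scale; output format follows the file extension (png/svg)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.table.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.4 * data.shape[1]), max(3.0, 0.3 * data.shape[0])))
    image = ax.imshow(data, aspect="auto", cmap="viridis",
                      interpolation="nearest")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels([f"{c:g}" for c in matrix.table.columns], rotation=90)
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(matrix.table.index)
    ax.set_xlabel("bin older edge (Ma)")
    fig.colorbar(image, ax=ax, label="d ln(lineages+offset) / dt (Myr$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
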