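"""Three-axis visualization of the partial indices.

Each design is drawn as the plane (triangle) through its three axis
intercepts (EM, 0, 0), (0, NM, 0), (0, 0, HM); the reference design's
unit triangle is always shown, so a candidate whose triangle lies outside
it improves on the reference along every dimension.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from mpl_toolkits.mplot3d.art3d import Poly3DCollection

from .compare import ComparisonSet
from .errors import ReefscoreError

_AXIS_LABELS = (
    "EM (substrate, light)",
    "NM (upwelling, circulation)",
    "HM (shelter, nesting)",
)


def plot_index_planes(comparison: ComparisonSet, path: str | Path) -> Path:
    """Render the comparison to an image file (format from the suffix)."""
    if not comparison.reports:
        raise ReefscoreError("nothing to plot: the comparison set is empty")
    for name in comparison.ranking:
        r = comparison.reports[name]
        if any(v is None for v in (r.em, r.nm, r.hm)):
            raise ReefscoreError(
                f"cannot plot {name!r}: all three partial indices are "
                f"required for the three-axis representation"
            )

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")

    def triangle(em, nm, hm, color, label):
        verts = [[(em, 0, 0), (0, nm, 0), (0, 0, hm)]]
        poly = Poly3DCollection(
            verts, alpha=0.35, facecolor=color, edgecolor=color, linewidths=1.5
        )
        ax.add_collection3d(poly)
        ax.plot([em], [0], [0], marker="o", color=color, label=label)
        ax.plot([0], [nm], [0], marker="o", color=color)
        ax.plot([0], [0], [hm], marker="o", color=color)

    triangle(1.0, 1.0, 1.0, "goldenrod", f"reference: {comparison.reference}")
    colors = plt.cm.tab10.colors
    limit = 1.0
    for i, name in enumerate(comparison.ranking):
        r = comparison.reports[name]
        triangle(r.em, r.nm, r.hm, colors[(i + 3) % 10], name)
        limit = max(limit, r.em, r.nm, r.hm)

    ax.set_xlim(0, limit * 1.1)
    ax.set_ylim(0, limit * 1.1)
    ax.set_zlim(0, limit * 1.1)
    ax.set_xlabel(_AXIS_LABELS[0])
    ax.set_ylabel(_AXIS_LABELS[1])
    ax.set_zlabel(_AXIS_LABELS[2])
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()

    path = Path(path)
    try:
        fig.savefig(path, dpi=150)
    finally:
        plt.close(fig)
    return path
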