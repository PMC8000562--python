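"""Three-pane rendering of the acceptability map.

One panel per dimension pair (1-2, 1-3, 2-3): reference evaluations
colored by zone, consolidated centroids, the medicine barycenter and its
90% confidence ellipse.  Purely optional output; all classification is
numeric and lives in :mod:`acceptmap.scoring`.
"""

from __future__ import annotations


from .scoring import DIMENSION_PAIRS, AcceptabilityScore

__all__ = ["plot_map"]

_ZONE_COLORS = {"green": "#2e8b57", "red": "#c0392b"}


def plot_map(framework, scores: list[AcceptabilityScore] | None = None, path=None):
    """Render the 3-pane map; save to ``path`` (SVG/PNG) if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = scores or []
    fig, axes = plt.subplots(1, 3, figsize=(13, 4.2))
    coords = framework.coordinates_
    for ax, pair in zip(axes, DIMENSION_PAIRS):
        if coords is not None:
            zones = framework.assign_zone(coords)
            for zone, color in _ZONE_COLORS.items():
                m = zones == zone
                ax.scatter(
                    coords[m, pair[0]], coords[m, pair[1]], s=4, alpha=0.25,
                    color=color, label=f"{zone} zone",
                )
        for cid, zone in framework.partition_.zone_names.items():
            c = framework.partition_.centroids[cid]
            ax.scatter(c[pair[0]], c[pair[1]], marker="X", s=90,
                       color=_ZONE_COLORS[zone], edgecolor="black", zorder=5)
        for score in scores:
            ell = score.ellipses[pair]
            boundary = ell.boundary(360)
            ax.plot(boundary[:, 0], boundary[:, 1], color="black", lw=1.2)
            ax.scatter(*ell.center, color="black", marker="o", s=25, zorder=6)
            if score.label:
                ax.annotate(score.label, ell.center, fontsize=8,
                            textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel(f"dim {pair[0] + 1}")
        ax.set_ylabel(f"dim {pair[1] + 1}")
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
    axes[0].legend(loc="best", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
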