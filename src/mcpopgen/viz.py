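"""Plot-data transforms and exports: heat maps, de Finetti networks, landscapes.

Every plot has a machine-readable TSV twin; image rendering (matplotlib,
Agg) is a thin optional layer on top, so figures are reproducible from the
exported tables alone.  Transition probabilities are transformed for
display with a negative logarithm or a logit; the infinities these
transforms produce at 0 and 1 are kept as explicit ``inf`` sentinels rather
than dropped, so heat maps can render them in a reserved color.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import TransitionMatrix
from .network import EdgeSelection, most_probable_neighbors
from .statespace import StateSpace

__all__ = ["transform_matrix", "inverse_transform", "LandscapeSurface",
           "landscape_heights", "export_heatmap", "export_network_plot"]

#: kinetic-energy elevation factor: h = d^2 / (2 g) with g approximated by 10
ELEVATION_FACTOR = 0.05


def transform_matrix(m, kind: str, base: float = 10.0) -> np.ndarray:
    """Elementwise display transform of a probability matrix.

    ``neglog``: p -> -log_base(p), mapping [0, 1] to [0, inf];
    ``logit``: p -> log_base(p / (1 - p)), mapping [0, 1] to [-inf, inf].
    Shape-preserving; endpoints become infinite sentinels.
    """
    arr = m.toarray() if isinstance(m, TransitionMatrix) else np.asarray(m, dtype=float)
    if np.min(arr) < 0 or np.max(arr) > 1:
        raise ValueError("entries must lie in [0, 1]")
    lb = np.log(base)
    with np.errstate(divide="ignore"):
        if kind == "neglog":
            return -np.log(arr) / lb
        if kind == "logit":
            out = np.full(arr.shape, np.inf)
            out[arr == 0] = -np.inf
            mid = (arr > 0) & (arr < 1)
            out[mid] = np.log(arr[mid] / (1.0 - arr[mid])) / lb
            return out
    raise ValueError(f"unknown transform {kind!r}; choose 'neglog' or 'logit'")


def inverse_transform(t, kind: str, base: float = 10.0) -> np.ndarray:
    """Inverse of :func:`transform_matrix` (bijective on (0, 1))."""
    t = np.asarray(t, dtype=float)
    if kind == "neglog":
        return base ** (-t)
    if kind == "logit":
        z = base**t
        return z / (1.0 + z)
    raise ValueError(f"unknown transform {kind!r}")


@dataclass
class LandscapeSurface:
    """De Finetti coordinates and elevation per state.

    The elevation h = d^2 * 0.05 converts the one-step expected move of
    length d (Euclidean distance in genotype-frequency space to the most
    probable neighbor) into the height of a gravity-well landscape, taking
    gravitational acceleration as 10.  h = 0 exactly where a state is its
    own most probable neighbor.
    """

    x: np.ndarray
    y: np.ndarray
    h: np.ndarray
    neighbor: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": np.arange(self.h.size), "x": self.x, "y": self.y,
             "h": self.h, "most_probable_neighbor": self.neighbor}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def landscape_heights(m: TransitionMatrix, rescale: float = 1.0) -> LandscapeSurface:
    """Gravity-well elevations over the de Finetti plane.

    Requires a model-bound matrix (states carrying genotype counts).  Ties
    for the most probable neighbor resolve to the smallest state index.
    """
    space = m.space
    if space is None:
        raise ValueError("landscape requires a matrix bound to a StateSpace")
    mpn = most_probable_neighbors(m)
    # smallest-index tie-break: first edge listed per source
    nb = (mpn.edges.groupby("from_state", sort=True)["to_state"].min()
          .to_numpy(dtype=np.intp))
    freq = space.frequencies
    d2 = ((freq - freq[nb]) ** 2).sum(axis=1)
    xy = space.definetti()
    return LandscapeSurface(x=xy[:, 0], y=xy[:, 1],
                            h=d2 * ELEVATION_FACTOR * rescale, neighbor=nb)


def export_heatmap(m, tsv_path=None, png_path=None, transform: str | None = None,
                   base: float = 10.0) -> np.ndarray:
    """Write a (transformed) matrix as a TSV grid and/or rendered heat map.

    Infinite sentinel cells are written as ``inf``/``-inf`` in the TSV and
    shown hatched-grey in the figure.  Returns the exported array.
    """
    arr = m.toarray() if isinstance(m, TransitionMatrix) else np.asarray(m, dtype=float)
    if transform is not None:
        arr = transform_matrix(arr, transform, base)
    if tsv_path is not None:
        np.savetxt(tsv_path, arr, delimiter="\t")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        finite = np.where(np.isfinite(arr), arr, np.nan)
        im = ax.imshow(finite, origin="upper", cmap="viridis")
        ax.set_facecolor("lightgrey")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_xlabel("from state")
        ax.set_ylabel("to state")
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return arr


def export_network_plot(m: TransitionMatrix, space: StateSpace,
                        node_stats: pd.DataFrame, stat: str,
                        edge_selection: EdgeSelection | None = None,
                        png_path=None, tsv_path=None) -> pd.DataFrame:
    """Nodes at de Finetti coordinates, colored by a node statistic, with a
    selected edge subset; writes the TSV twin and optionally a PNG.

    The layout is data, not force-directed: node positions are the ternary
    coordinates of the genotype frequencies.  Unknown ``stat`` names raise,
    listing what is available.
    """
    if stat not in node_stats.columns:
        raise KeyError(
            f"unknown statistic {stat!r}; available: {list(node_stats.columns)}"
        )
    xy = space.definetti()
    nodes = space.to_frame()
    nodes[stat] = np.asarray(node_stats[stat])
    if tsv_path is not None:
        nodes.to_csv(tsv_path, sep="\t", index=False)
        if edge_selection is not None:
            edge_selection.to_tsv(str(tsv_path) + ".edges.tsv")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.collections import LineCollection

        fig, ax = plt.subplots(figsize=(7, 6))
        if edge_selection is not None and len(edge_selection.edges):
            segs = [
                (xy[int(u)], xy[int(v)])
                for u, v in zip(edge_selection.edges["from_state"],
                                edge_selection.edges["to_state"])
                if u != v
            ]
            ax.add_collection(LineCollection(segs, colors="0.6", linewidths=0.5))
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=nodes[stat], s=40, cmap="viridis",
                        zorder=3)
        fig.colorbar(sc, ax=ax, shrink=0.8, label=stat)
        ax.set_aspect("equal")
        ax.set_axis_off()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return nodes
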