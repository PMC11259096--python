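"""Dot-blot array densitometry and protein-interaction graph summaries.

Membrane-based antibody arrays print each analyte as a duplicate spot pair
plus positive- and negative-reference spots. Quantification is the mean
pixel density inside a disk at each spot, duplicates averaged, then

    normalized = (density - mean(neg)) / (mean(pos) - mean(neg)),

which maps the negative controls to 0, the positive controls to 1, and is
exactly invariant to any global affine distortion of the image (detector
gain and offset). A strict ``pos_denominator`` mode divides by the raw positive mean
instead (background subtracted from samples only), for pipelines that
normalized that way.

The interaction-graph summary consumes a user-supplied undirected edge
list (e.g. exported from a protein-association database) and reports node
and edge counts, average degree 2E/N, and the mean local clustering
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .stacks import ImageStack

__all__ = [
    "Spot",
    "ArrayLayout",
    "SpotQuant",
    "GraphSummary",
    "quantify_spots",
    "normalize_spots",
    "interaction_graph_summary",
]


@dataclass(frozen=True)
class Spot:
    target: str
    center: tuple[int, int]  # (row, col) pixel coordinates


@dataclass
class ArrayLayout:
    """Spot grid: targets (with duplicate pairing by shared name) plus
    disjoint positive/negative reference spot sets."""

    spots: list[Spot]
    positive_controls: tuple[str, ...] = ("POS",)
    negative_controls: tuple[str, ...] = ("NEG",)
    measure_radius_px: int = 4

    def __post_init__(self) -> None:
        names = {s.target for s in self.spots}
        pos, neg = set(self.positive_controls), set(self.negative_controls)
        if not pos & names or not neg & names:
            raise ValueError("layout must include positive and negative controls")
        if pos & neg:
            raise ValueError("control sets must be disjoint")

    def targets(self) -> list[str]:
        ctrl = set(self.positive_controls) | set(self.negative_controls)
        seen: list[str] = []
        for s in self.spots:
            if s.target not in ctrl and s.target not in seen:
                seen.append(s.target)
        return seen


@dataclass
class SpotQuant:
    membrane_id: str
    raw: dict[str, list[float]]          # per-spot densities, keyed by target
    per_target: dict[str, float]         # duplicate-averaged density
    normalized: dict[str, float]         # 0 at neg controls, 1 at pos controls
    mode: str = "affine"


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    average_node_degree: float
    average_clustering: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_node_degree": self.average_node_degree,
            "average_clustering": self.average_clustering,
        }


def quantify_spots(
    image: ImageStack | np.ndarray, layout: ArrayLayout
) -> dict[str, list[float]]:
    """Mean pixel density within a disk of the layout radius at every spot.

    Radius 0 reads the single centre pixel. A spot whose disk leaves the
    image raises.
    """
    data = image.voxels if isinstance(image, ImageStack) else np.asarray(image)
    data = np.asarray(data, dtype=float)
    h, w = data.shape
    r = layout.measure_radius_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = yy**2 + xx**2 <= r**2
    raw: dict[str, list[float]] = {}
    for spot in layout.spots:
        cy, cx = spot.center
        if cy - r < 0 or cy + r >= h or cx - r < 0 or cx + r >= w:
            raise ValueError(f"spot {spot.target} at {spot.center} out of bounds")
        patch = data[cy - r : cy + r + 1, cx - r : cx + r + 1]
        raw.setdefault(spot.target, []).append(float(patch[disk].mean()))
    return raw


def normalize_spots(
    raw: dict[str, list[float]],
    layout: ArrayLayout,
    membrane_id: str = "",
    pos_denominator: bool = False,
) -> SpotQuant:
    """Duplicate-average and normalize spot densities against the controls.

    Default mode: ``(d - neg) / (pos - neg)`` (affine-invariant).
    ``pos_denominator``: ``(d - neg) / pos`` — background subtracted from the
    samples and divided by the raw positive-control mean.
    """
    def ctrl_mean(names) -> float:
        vals = [v for n in names if n in raw for v in raw[n]]
        if not vals:
            raise ValueError("control spots missing from quantification")
        return float(np.mean(vals))

    neg = ctrl_mean(layout.negative_controls)
    pos = ctrl_mean(layout.positive_controls)
    if pos <= neg:
        raise ValueError(
            f"positive-control density ({pos:g}) does not exceed "
            f"negative-control density ({neg:g}); membrane saturated or mislaid"
        )
    per_target = {t: float(np.mean(v)) for t, v in raw.items()}
    denom = pos if pos_denominator else (pos - neg)
    normalized = {
        t: (d - neg) / denom
        for t, d in per_target.items()
    }
    return SpotQuant(
        membrane_id=membrane_id,
        raw=raw,
        per_target=per_target,
        normalized=normalized,
        mode="pos_denominator" if pos_denominator else "affine",
    )


def interaction_graph_summary(edges) -> GraphSummary:
    """Summary statistics of a simple undirected interaction graph.

    ``edges`` is an iterable of 2-tuples (or an (n, 2) array of labels).
    Duplicate edges are collapsed after canonicalization; self-loops are
    rejected. Average degree is 2E/N; the clustering coefficient is the
    mean over nodes of the local clustering coefficient, with degree < 2
    nodes contributing 0.
    """
    g = nx.Graph()
    for e in edges:
        u, v = str(e[0]), str(e[1])
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        g.add_edge(u, v)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return GraphSummary(0, 0, 0.0, 0.0)
    return GraphSummary(
        n_nodes=n,
        n_edges=m,
        average_node_degree=2.0 * m / n,
        average_clustering=float(nx.average_clustering(g)),
    )
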