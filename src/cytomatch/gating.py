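"""Hierarchical gating and embedding-guided labeling.

Two labeling routes are modelled:

* the **conventional** route — a tree of bivariate gates (threshold,
  rectangle, polygon) applied sequentially from the root, each terminal node
  naming a population; an event's label is the first terminal (in declaration
  order) whose full ancestor-gate conjunction it satisfies, else
  ``"Unidentified"``.  All gate regions are closed: boundary points are in.

* the **embedding-guided** route — an automated surrogate for an analyst
  drawing gates on a 2-D embedding guided by marker-overlay plots: k-means
  clusters of the embedding coordinates are assigned to template populations
  by matching each cluster's binarised median marker profile against the
  population's discrete-marker signature (normalised Hamming distance);
  clusters matching nothing within a cutoff become ``"Unidentified"``.
  Continuous and unimodal markers carry no reliable binary information and are
  excluded from signatures, which is exactly why populations separated only by
  continuous markers cannot be told apart on the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .matrix import CellMatrix
from .panel import PanelTemplate

UNIDENTIFIED = "Unidentified"


# ---------------------------------------------------------------------------
# Gate geometries


@dataclass(frozen=True)
class Threshold:
    axis: str  # "x" or "y"
    cut: float
    side: str  # "positive" (>= cut) or "negative" (<= cut)

    def __post_init__(self):
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if self.side not in ("positive", "negative"):
            raise ValueError("side must be 'positive' or 'negative'")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        v = x if self.axis == "x" else y
        return v >= self.cut if self.side == "positive" else v <= self.cut


@dataclass(frozen=True)
class Rectangle:
    x_lo: float | None = None
    x_hi: float | None = None
    y_lo: float | None = None
    y_hi: float | None = None

    def __post_init__(self):
        for lo, hi in ((self.x_lo, self.x_hi), (self.y_lo, self.y_hi)):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError("rectangle lo must be <= hi")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ok = np.ones(len(x), dtype=bool)
        if self.x_lo is not None:
            ok &= x >= self.x_lo
        if self.x_hi is not None:
            ok &= x <= self.x_hi
        if self.y_lo is not None:
            ok &= y >= self.y_lo
        if self.y_hi is not None:
            ok &= y <= self.y_hi
        return ok

    @property
    def is_unbounded(self) -> bool:
        return all(v is None for v in (self.x_lo, self.x_hi, self.y_lo, self.y_hi))


@dataclass(frozen=True)
class PolygonGate:
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("polygon is degenerate or self-intersecting")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        poly = _ShapelyPolygon(self.vertices)
        # intersects == covers for points; boundary-inclusive
        return shapely.intersects_xy(poly, x, y)


Geometry = Threshold | Rectangle | PolygonGate


@dataclass(frozen=True)
class Gate:
    name: str
    x_channel: str
    y_channel: str
    geometry: Geometry

    def members(self, m: CellMatrix, parent: np.ndarray) -> np.ndarray:
        """Boolean membership mask over all events, restricted to ``parent``."""
        x = m.channel(self.x_channel)
        y = m.channel(self.y_channel)
        return parent & self.geometry.contains(x, y)


def apply_gate(g: Gate, m: CellMatrix, parent_members: np.ndarray) -> np.ndarray:
    """Events of ``parent_members`` inside the (closed) gate region."""
    parent = np.asarray(parent_members, dtype=bool)
    if parent.shape != (m.n_events,):
        raise ValueError("parent_members must be a boolean mask over all events")
    return g.members(m, parent)


# ---------------------------------------------------------------------------
# Gating tree


@dataclass
class TreeNode:
    name: str
    gate: Gate | None  # None for the root
    parent: str | None
    terminal: bool = False
    level: str | None = None  # "lineage" | "subset" for terminals


@dataclass
class GatingTree:
    nodes: list[TreeNode]

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        known = set()
        for n in self.nodes:
            if n.parent is not None and n.parent not in known:
                raise ValueError(
                    f"node {n.name!r} declared before its parent {n.parent!r}"
                )
            known.add(n.name)
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1 or roots[0].gate is not None:
            raise ValueError("tree needs exactly one gateless root")

    def terminals(self, level: str | None = None) -> list[TreeNode]:
        return [
            n for n in self.nodes
            if n.terminal and (level is None or n.level == level)
        ]

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def geom_d(g: Geometry) -> dict:
            if isinstance(g, Threshold):
                return {"type": "threshold", "axis": g.axis, "cut": g.cut,
                        "side": g.side}
            if isinstance(g, Rectangle):
                return {"type": "rectangle", "x_lo": g.x_lo, "x_hi": g.x_hi,
                        "y_lo": g.y_lo, "y_hi": g.y_hi}
            return {"type": "polygon", "vertices": [list(v) for v in g.vertices]}

        return {
            "nodes": [
                {
                    "name": n.name,
                    "parent": n.parent,
                    "terminal": n.terminal,
                    "level": n.level,
                    "gate": None if n.gate is None else {
                        "x_channel": n.gate.x_channel,
                        "y_channel": n.gate.y_channel,
                        "geometry": geom_d(n.gate.geometry),
                    },
                }
                for n in self.nodes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingTree":
        def geom(gd: dict) -> Geometry:
            t = gd["type"]
            if t == "threshold":
                return Threshold(gd["axis"], gd["cut"], gd["side"])
            if t == "rectangle":
                return Rectangle(gd.get("x_lo"), gd.get("x_hi"),
                                 gd.get("y_lo"), gd.get("y_hi"))
            if t == "polygon":
                return PolygonGate(tuple(tuple(v) for v in gd["vertices"]))
            raise ValueError(f"unknown geometry type {t!r}")

        nodes = [
            TreeNode(
                name=nd["name"],
                parent=nd.get("parent"),
                terminal=bool(nd.get("terminal", False)),
                level=nd.get("level"),
                gate=None if nd.get("gate") is None else Gate(
                    name=nd["name"],
                    x_channel=nd["gate"]["x_channel"],
                    y_channel=nd["gate"]["y_channel"],
                    geometry=geom(nd["gate"]["geometry"]),
                ),
            )
            for nd in d["nodes"]
        ]
        return cls(nodes=nodes)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GatingTree":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Labeling:
    """Per-event population assignment from one analysis route."""

    assignment: np.ndarray  # object array of population names
    level: str  # "lineage" | "subset"
    provenance: str  # "conventional" | "embedding_guided" | "imported"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=object)

    def __len__(self) -> int:
        return len(self.assignment)

    def counts(self) -> pd.Series:
        return pd.Series(self.assignment).value_counts()

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "event": np.arange(len(self.assignment)),
                "label": self.assignment,
                "provenance": self.provenance,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, level: str = "lineage") -> "Labeling":
        df = pd.read_csv(path)
        prov = (
            str(df["provenance"].iloc[0]) if "provenance" in df and len(df)
            else "imported"
        )
        return cls(
            assignment=df["label"].to_numpy(dtype=object), level=level,
            provenance=prov,
        )


def apply_tree(tree: GatingTree, m: CellMatrix, level: str = "lineage") -> Labeling:
    """Label every event by the first matching terminal of the tree."""
    masks: dict[str, np.ndarray] = {}
    for node in tree.nodes:
        if node.parent is None:
            masks[node.name] = np.ones(m.n_events, dtype=bool)
        else:
            masks[node.name] = apply_gate(node.gate, m, masks[node.parent])

    labels = np.full(m.n_events, UNIDENTIFIED, dtype=object)
    assigned = np.zeros(m.n_events, dtype=bool)
    overlap = 0
    covered = np.zeros(m.n_events, dtype=bool)
    for node in tree.terminals(level):
        mask = masks[node.name]
        overlap += int(np.sum(mask & covered))
        labels[mask & ~assigned] = node.name
        assigned |= mask
        covered |= mask
    return Labeling(
        assignment=labels,
        level=level,
        provenance="conventional",
        diagnostics={"overlap_events": overlap},
    )


class GatingTreeClassifier(BaseEstimator):
    """sklearn-style wrapper: ``predict(CellMatrix)`` -> label array."""

    def __init__(self, tree: GatingTree, level: str = "lineage"):
        self.tree = tree
        self.level = level

    def fit(self, X: CellMatrix, y=None):
        for node in self.tree.nodes:
            if node.gate is not None:
                X.channel(node.gate.x_channel)
                X.channel(node.gate.y_channel)
        self.classes_ = np.array(
            [t.name for t in self.tree.terminals(self.level)] + [UNIDENTIFIED],
            dtype=object,
        )
        return self

    def predict(self, X: CellMatrix) -> np.ndarray:
        return apply_tree(self.tree, X, self.level).assignment


# ---------------------------------------------------------------------------
# Automatic tree construction from a template


def build_gating_tree(template: PanelTemplate) -> GatingTree:
    """Sequential threshold-gate tree from the template's gate-marker chains.

    Cuts are the template's global per-marker thresholds (the analyst's one
    positivity boundary per marker); the gate side is the population's
    component for that marker.  Lineage chains end in lineage-level terminals;
    subset chains continue from their lineage's last node to subset-level
    terminals.
    """
    cuts = template.global_thresholds()
    nodes: list[TreeNode] = [TreeNode(name="root", gate=None, parent=None)]

    def chain(pop, start_parent: str, prefix: str) -> str:
        parent = start_parent
        for i, marker in enumerate(pop.gate_markers):
            e = pop.expression[marker]
            side = "positive" if e.positive else "negative"
            node_name = f"{prefix}{pop.name}/{i}:{marker}{'+' if e.positive else '-'}"
            nodes.append(
                TreeNode(
                    name=node_name,
                    parent=parent,
                    gate=Gate(
                        name=node_name,
                        x_channel=marker,
                        y_channel=marker,
                        geometry=Threshold("x", cuts[marker], side),
                    ),
                )
            )
            parent = node_name
        return parent

    lineage_tail: dict[str, str] = {}
    for lin in template.lineages:
        tail = chain(lin, "root", "")
        lineage_tail[lin.name] = tail
        nodes.append(
            TreeNode(
                name=lin.name, parent=tail, gate=Gate(
                    name=lin.name, x_channel=template.markers[0],
                    y_channel=template.markers[0], geometry=Rectangle(),
                ),
                terminal=True, level="lineage",
            )
        )
    for sub in template.subsets:
        extra = sub.gate_markers[len(_parent_chain(template, sub)):]
        tail = lineage_tail[sub.parent]
        pop = sub
        # build only the subset-specific part of the chain under the lineage
        parent = tail
        for i, marker in enumerate(extra):
            e = pop.expression[marker]
            side = "positive" if e.positive else "negative"
            node_name = f"subset:{pop.name}/{i}:{marker}{'+' if e.positive else '-'}"
            nodes.append(
                TreeNode(
                    name=node_name, parent=parent,
                    gate=Gate(
                        name=node_name, x_channel=marker, y_channel=marker,
                        geometry=Threshold("x", cuts[marker], side),
                    ),
                )
            )
            parent = node_name
        terminal_name = sub.name if sub.name not in lineage_tail else f"{sub.name} (subset)"
        nodes.append(
            TreeNode(
                name=terminal_name, parent=parent, gate=Gate(
                    name=terminal_name, x_channel=template.markers[0],
                    y_channel=template.markers[0], geometry=Rectangle(),
                ),
                terminal=True, level="subset",
            )
        )
    return GatingTree(nodes=nodes)


def _parent_chain(template: PanelTemplate, subset) -> tuple[str, ...]:
    for lin in template.lineages:
        if lin.name == subset.parent:
            return lin.gate_markers
    raise ValueError(f"unknown parent {subset.parent!r}")


def conventional_labeling(
    template: PanelTemplate, m: CellMatrix, level: str = "lineage"
) -> Labeling:
    """Conventional-route labeling with auto-threshold gates."""
    lab = apply_tree(build_gating_tree(template), m, level=level)
    if level == "subset":
        # subset terminals may have been renamed to avoid clashing with
        # single-subset lineages; map back to template subset names
        fix = {f"{s.name} (subset)": s.name for s in template.subsets}
        lab.assignment = np.array(
            [fix.get(x, x) for x in lab.assignment], dtype=object
        )
    return lab


# ---------------------------------------------------------------------------
# Embedding-guided labeling surrogate


class EmbeddingGuidedLabeler(ClusterMixin, BaseEstimator):
    """Cluster the embedding, then name clusters by marker signature.

    k-means (k defaulting to six times the population count) partitions the
    2-D map into islands; each non-empty cluster's median marker profile is
    binarised at the template's per-marker cuts and matched to the population
    whose discrete-marker signature it is nearest to (normalised Hamming
    distance).  Ties prefer the most specific (longest) signature, then
    template declaration order.  Clusters farther than ``cutoff`` from every
    signature are left Unidentified.
    """

    def __init__(
        self,
        template: PanelTemplate,
        level: str = "lineage",
        k: int | None = None,
        cutoff: float = 0.25,
        random_state: int = 0,
        signature_modes: tuple[str, ...] = ("discrete_bimodal",),
        cuts: dict | None = None,
    ):
        self.template = template
        self.level = level
        self.k = k
        self.cutoff = cutoff
        self.random_state = random_state
        self.signature_modes = signature_modes
        self.cuts = cuts

    def fit(self, coords: np.ndarray, markers: CellMatrix | np.ndarray = None):
        if markers is None:
            raise ValueError("marker data is required to name clusters")
        coords = np.asarray(coords, dtype=float)
        pops = self.template.populations(self.level)
        # Over-cluster generously: k-means is variance-greedy, so a large
        # island takes many centroids and a 1%-abundance island can get none
        # at small k; merging by signature absorbs the surplus clusters.
        k = 6 * len(pops) if self.k is None else self.k
        if k < len(pops):
            raise ValueError(
                f"k={k} is below the population count ({len(pops)})"
            )
        if isinstance(markers, CellMatrix):
            marker_names = markers.protein_channels
            X = markers.protein_values()
        else:
            marker_names = list(self.template.markers)
            X = np.asarray(markers, dtype=float)

        km = KMeans(n_clusters=k, n_init=10,
                    random_state=self.random_state % (2**31))
        cluster_of = km.fit_predict(coords)

        cuts = dict(self.template.global_thresholds())
        if self.cuts:
            cuts.update(self.cuts)
        signatures = [p.signature(self.signature_modes) for p in pops]

        names = np.full(k, UNIDENTIFIED, dtype=object)
        dropped = 0
        for c in range(k):
            rows = cluster_of == c
            if not rows.any():
                dropped += 1
                continue
            med = np.median(X[rows], axis=0)
            profile = {
                m: med[j] >= cuts[m]
                for j, m in enumerate(marker_names) if m in cuts
            }
            best = None  # (distance, -len, order)
            for order, (p, sig) in enumerate(zip(pops, signatures)):
                usable = [m for m in sig if m in profile]
                if not usable:
                    continue
                dist = sum(profile[m] != sig[m] for m in usable) / len(usable)
                key = (dist, -len(usable), order)
                if best is None or key < best[0]:
                    best = (key, p.name)
            if best is not None and best[0][0] <= self.cutoff:
                names[c] = best[1]

        self.cluster_labels_ = cluster_of
        self.cluster_names_ = names
        self.labels_ = names[cluster_of]
        self.n_empty_clusters_ = dropped
        return self

    def labeling(self) -> Labeling:
        return Labeling(
            assignment=self.labels_,
            level=self.level,
            provenance="embedding_guided",
            diagnostics={"empty_clusters": self.n_empty_clusters_},
        )


def derive_embedding_labeling(
    embedding,
    m: CellMatrix,
    template: PanelTemplate,
    level: str = "lineage",
    k: int | None = None,
    seed: int = 0,
    cutoff: float = 0.25,
    signature_modes: tuple[str, ...] = ("discrete_bimodal",),
    cuts: dict | None = None,
) -> Labeling:
    """Functional wrapper over :class:`EmbeddingGuidedLabeler`."""
    coords = np.asarray(getattr(embedding, "coords", embedding), dtype=float)
    lab = EmbeddingGuidedLabeler(
        template, level=level, k=k, cutoff=cutoff, random_state=seed,
        signature_modes=signature_modes, cuts=cuts,
    )
    lab.fit(coords, m)
    return lab.labeling()
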