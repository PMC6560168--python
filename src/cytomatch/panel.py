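"""Synthetic cytometry panel templates.

A :class:`PanelTemplate` is the stated world of a simulated mass-cytometry
experiment: an ordered marker list, a set of general lineages, and the leaf
subsets nested under them.  Each population carries, for every marker in the
panel, a two-component normal expression model (on the arcsinh scale) plus the
component (positive or negative) that population draws from.

Markers come in three flavours:

``discrete_bimodal``
    clearly resolved negative/positive components (>= 6 sigma apart), the kind
    of lineage marker (CD3, CD19, CD14, ...) an analyst thresholds confidently;
``continuous_bimodal``
    overlapping components (CCR7, CD45RA on memory T cells) whose
    discretisation is an analyst's judgement call;
``unimodal``
    a single component, carrying no population information.

The full template emulates a 38-marker PBMC panel resolving 8 general
lineages into 28 leaf subsets; the mini template is an 11-marker, 8-lineage
panel with purely discrete markers, for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

MODES = ("discrete_bimodal", "continuous_bimodal", "unimodal")


@dataclass(frozen=True)
class MarkerModel:
    """Equal-weight, equal-variance two-component normal expression model."""

    mode: str
    mu_neg: float
    mu_pos: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown marker mode {self.mode!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.mu_pos < self.mu_neg:
            raise ValueError("mu_pos must be >= mu_neg")
        sep = (self.mu_pos - self.mu_neg) * (1 + 1e-9)
        if self.mode == "unimodal" and sep > 2 * self.sigma * (1 + 2e-9):
            # equal-weight two-normal mixtures are unimodal iff dmu <= 2 sigma
            raise ValueError(
                f"unimodal model requires mu_pos - mu_neg <= 2*sigma "
                f"(got {sep:.3g} > {2 * self.sigma:.3g})"
            )
        if self.mode == "discrete_bimodal" and sep < 6 * self.sigma:
            raise ValueError(
                f"discrete_bimodal model requires mu_pos - mu_neg >= 6*sigma "
                f"(got {sep:.3g} < {6 * self.sigma:.3g})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.mu_neg + self.mu_pos)

    def mean(self, positive: bool) -> float:
        return self.mu_pos if positive else self.mu_neg


@dataclass(frozen=True)
class MarkerExpression:
    """One population's expression of one marker: a model plus the component."""

    model: MarkerModel
    positive: bool


@dataclass(frozen=True)
class PopulationSpec:
    """A population (lineage or leaf subset) of the template.

    ``expression`` maps every panel marker to a :class:`MarkerExpression`.
    ``gate_markers`` lists, in gating order, the markers a conventional
    sequential-gating chain uses to define this population; the gate side is
    the population's component for that marker.
    """

    name: str
    prevalence: float
    expression: Mapping[str, MarkerExpression]
    gate_markers: tuple[str, ...]
    parent: str | None = None

    def signature(self, modes: tuple[str, ...] = ("discrete_bimodal",)) -> dict[str, bool]:
        """Binary marker signature over markers whose model mode is in ``modes``."""
        return {
            m: e.positive
            for m, e in self.expression.items()
            if e.model.mode in modes
        }


@dataclass(frozen=True)
class PanelTemplate:
    markers: tuple[str, ...]
    lineages: tuple[PopulationSpec, ...]
    subsets: tuple[PopulationSpec, ...]

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        for pops, what in ((self.lineages, "lineage"), (self.subsets, "subset")):
            names = [p.name for p in pops]
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate {what} names")
        tot = sum(p.prevalence for p in self.lineages)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"lineage prevalences sum to {tot}, expected 1")
        lineage_names = {p.name for p in self.lineages}
        for lin in lineage_names:
            subtot = sum(s.prevalence for s in self.subsets if s.parent == lin)
            if abs(subtot - 1.0) > 1e-9:
                raise ValueError(
                    f"subset prevalences under {lin!r} sum to {subtot}, expected 1"
                )
        for p in (*self.lineages, *self.subsets):
            if p in self.subsets and p.parent not in lineage_names:
                raise ValueError(f"subset {p.name!r} has unknown parent {p.parent!r}")
            for m in p.expression:
                if m not in self.markers:
                    raise ValueError(f"population {p.name!r} references unknown marker {m!r}")
            missing = set(self.markers) - set(p.expression)
            if missing:
                raise ValueError(f"population {p.name!r} missing models for {sorted(missing)}")

    def populations(self, level: str) -> tuple[PopulationSpec, ...]:
        if level == "lineage":
            return self.lineages
        if level == "subset":
            return self.subsets
        raise ValueError(f"unknown level {level!r}")

    def continuously_split_subsets(self) -> tuple[str, ...]:
        """Leaf subsets distinguishable from a sibling only by continuous markers.

        A subset whose discrete-marker signature is identical to another
        subset's carries no binary evidence separating the two; only
        continuous (or unimodal) markers differ.  These are the populations
        an embedding cannot be expected to resolve into distinct islands.
        """
        keys = {
            s.name: tuple(sorted(s.signature().items())) for s in self.subsets
        }
        from collections import Counter

        counts = Counter(keys.values())
        return tuple(n for n, k in keys.items() if counts[k] > 1)

    def lineage_of(self, subset_name: str) -> str:
        for s in self.subsets:
            if s.name == subset_name:
                assert s.parent is not None
                return s.parent
        raise KeyError(subset_name)

    def global_thresholds(self) -> dict[str, float]:
        """Analyst-style positivity cut per marker.

        Midpoint between the largest negative-component mean and the smallest
        positive-component mean across all bimodal models of the marker; one
        cut per marker, shared by conventional auto-gating and the binarisation
        of embedding-guided cluster profiles.  Markers that are unimodal in
        every population fall back to the component-mean midpoint — the
        arbitrary through-the-peak cut an analyst discretising an
        uninformative marker would be forced into.
        """
        cuts: dict[str, float] = {}
        for m in self.markers:
            all_models = [
                s.expression[m].model for s in (*self.subsets, *self.lineages)
            ]
            models = [mod for mod in all_models if mod.mode != "unimodal"]
            if models:
                hi_neg = max(mod.mu_neg for mod in models)
                lo_pos = min(mod.mu_pos for mod in models)
                cuts[m] = 0.5 * (hi_neg + lo_pos)
            else:
                cuts[m] = float(np.mean([mod.midpoint for mod in all_models]))
        return cuts

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def pop_d(p: PopulationSpec) -> dict:
            return {
                "name": p.name,
                "prevalence": p.prevalence,
                "parent": p.parent,
                "gate_markers": list(p.gate_markers),
                "expression": {
                    m: {
                        "mode": e.model.mode,
                        "mu_neg": e.model.mu_neg,
                        "mu_pos": e.model.mu_pos,
                        "sigma": e.model.sigma,
                        "positive": e.positive,
                    }
                    for m, e in p.expression.items()
                },
            }

        return {
            "markers": list(self.markers),
            "lineages": [pop_d(p) for p in self.lineages],
            "subsets": [pop_d(p) for p in self.subsets],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelTemplate":
        def pop(pd: Mapping) -> PopulationSpec:
            expr = {
                m: MarkerExpression(
                    MarkerModel(e["mode"], e["mu_neg"], e["mu_pos"], e["sigma"]),
                    bool(e["positive"]),
                )
                for m, e in pd["expression"].items()
            }
            return PopulationSpec(
                name=pd["name"],
                prevalence=float(pd["prevalence"]),
                expression=expr,
                gate_markers=tuple(pd.get("gate_markers", ())),
                parent=pd.get("parent"),
            )

        return cls(
            markers=tuple(d["markers"]),
            lineages=tuple(pop(p) for p in d["lineages"]),
            subsets=tuple(pop(p) for p in d["subsets"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelTemplate":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default expression models (arcsinh scale).  Chosen once: CyTOF negatives sit
# near 0-0.5 and clean positives near 2-4 after arcsinh(x/5).  The discrete
# separation (8 sigma) keeps midpoint thresholding errors ~3e-5 per gate.
DISCRETE = MarkerModel("discrete_bimodal", 0.4, 3.6, 0.4)
CONTINUOUS = MarkerModel("continuous_bimodal", 0.8, 2.0, 0.5)
FILLER = MarkerModel("unimodal", 0.5, 0.5, 0.4)


def _expression(
    markers: Iterable[str],
    positives: Iterable[str] = (),
    negatives: Iterable[str] = (),
    continuous_pos: Iterable[str] = (),
    continuous_neg: Iterable[str] = (),
) -> dict[str, MarkerExpression]:
    """Build a full expression map: named markers discrete/continuous, rest filler."""
    expr: dict[str, MarkerExpression] = {}
    pos, neg = set(positives), set(negatives)
    cpos, cneg = set(continuous_pos), set(continuous_neg)
    for m in markers:
        if m in pos:
            expr[m] = MarkerExpression(DISCRETE, True)
        elif m in neg:
            expr[m] = MarkerExpression(DISCRETE, False)
        elif m in cpos:
            expr[m] = MarkerExpression(CONTINUOUS, True)
        elif m in cneg:
            expr[m] = MarkerExpression(CONTINUOUS, False)
        else:
            expr[m] = MarkerExpression(FILLER, False)
    return expr


FULL_MARKERS: tuple[str, ...] = (
    "CD45", "CD66", "CD16", "CD49d", "CD3", "CD4", "CD8", "CD25", "CD45RA",
    "CD45RO", "CD161", "Va7.2", "CCR7", "Foxp3", "gdTCR", "CD19", "CD20",
    "CD27", "CD38", "IgD", "CD56", "CD11c", "CD11b", "HLA-DR", "CD14",
    "CD1c", "CD123", "FceRI", "CD141", "CD57", "PD-1", "CD127", "CD28",
    "CXCR3", "CXCR5", "CCR4", "CCR6", "CD24",
)

# Markers every lineage declares discretely (pos or neg) so that lineages are
# mutually exclusive under sequential gating.
_LINEAGE_SET = (
    "CD45", "CD3", "CD19", "CD20", "CD56", "CD14", "CD11c", "HLA-DR",
    "CD66", "CD123", "FceRI",
)


def _lineage(name, prevalence, positives, gate_markers):
    pos = set(positives) | {"CD45"}
    neg = [m for m in _LINEAGE_SET if m not in pos]
    return PopulationSpec(
        name=name,
        prevalence=prevalence,
        expression=_expression(FULL_MARKERS, pos, neg),
        gate_markers=tuple(gate_markers),
    )


def _subset(lineage: PopulationSpec, name, prevalence, gate_markers=(), **kw):
    """Leaf subset: lineage expression overlaid with subset-specific models."""
    base = dict(lineage.expression)
    touched = [m for group in kw.values() for m in group]
    base.update(_expression(touched, **kw))
    return PopulationSpec(
        name=name,
        prevalence=prevalence,
        expression=base,
        gate_markers=tuple((*lineage.gate_markers, *gate_markers)),
        parent=lineage.name,
    )


def _full_template() -> PanelTemplate:
    M = FULL_MARKERS
    t = _lineage("T cells", 0.50, {"CD3"}, ("CD66", "CD3"))
    b = _lineage("B cells", 0.12, {"CD19", "CD20", "HLA-DR"}, ("CD66", "CD3", "CD19"))
    nk = _lineage("NK cells", 0.11, {"CD56"}, ("CD66", "CD3", "CD19", "CD56"))
    mono = _lineage(
        "Monocytes & cDCs", 0.22, {"CD11c", "HLA-DR"},
        ("CD66", "CD3", "CD19", "CD56", "CD11c", "HLA-DR"),
    )
    pdc = _lineage(
        "pDCs", 0.01, {"CD123", "HLA-DR"},
        ("CD66", "CD3", "CD19", "CD11c", "CD123", "HLA-DR"),
    )
    baso = _lineage(
        "Basophils", 0.01, {"CD123", "FceRI"},
        ("CD66", "CD3", "CD19", "FceRI", "CD123"),
    )
    neut = _lineage("Neutrophils", 0.02, {"CD66", "CD16"}, ("CD66", "CD16"))
    eos = _lineage("Eosinophils", 0.01, {"CD66", "CD49d"}, ("CD66", "CD16", "CD49d"))
    # CD16 is intentionally outside _LINEAGE_SET: it differs between subsets
    # of both the NK and the monocyte/cDC lineages.
    lineages = (t, b, nk, mono, pdc, baso, neut, eos)

    subsets = (
        # --- 11 T-cell subsets. Declaration order is gating order: subsets
        # defined by discrete markers outside the CD45RA/CCR7 quadrant logic
        # (Treg, gd, MAIT) come first, so quadrant gates see only the rest.
        _subset(t, "Treg", 0.05, ("CD4", "CD8", "CD25", "Foxp3"),
                positives=("CD4", "CD25", "Foxp3"), negatives=("CD8",),
                continuous_neg=("CCR7", "CD45RA")),
        _subset(t, "gd T cells", 0.04, ("gdTCR",),
                positives=("gdTCR",), negatives=("CD4", "CD8")),
        _subset(t, "MAIT cells", 0.04, ("Va7.2", "CD161"),
                positives=("Va7.2", "CD161", "CD8"), negatives=("CD4",)),
        _subset(t, "CD4 naive T", 0.25, ("CD4", "CD8", "CD45RA", "CCR7"),
                positives=("CD4", "CD45RA", "CCR7", "CD27"), negatives=("CD8",)),
        _subset(t, "CD4 central memory T", 0.15, ("CD4", "CD8", "CD45RA", "CCR7"),
                positives=("CD4",), negatives=("CD8",),
                continuous_pos=("CCR7", "CD27"), continuous_neg=("CD45RA",)),
        _subset(t, "CD4 effector memory T", 0.12, ("CD4", "CD8", "CD45RA", "CCR7"),
                positives=("CD4",), negatives=("CD8",),
                continuous_neg=("CCR7", "CD27", "CD45RA")),
        _subset(t, "CD4 TEMRA", 0.05, ("CD4", "CD8", "CD45RA", "CCR7"),
                positives=("CD4",), negatives=("CD8",),
                continuous_pos=("CD45RA",), continuous_neg=("CCR7", "CD27")),
        _subset(t, "CD8 naive T", 0.10, ("CD8", "CD4", "CD45RA", "CCR7"),
                positives=("CD8", "CD45RA", "CCR7", "CD27"), negatives=("CD4",)),
        _subset(t, "CD8 central memory T", 0.06, ("CD8", "CD4", "CD45RA", "CCR7"),
                positives=("CD8",), negatives=("CD4",),
                continuous_pos=("CCR7", "CD27"), continuous_neg=("CD45RA",)),
        _subset(t, "CD8 effector memory T", 0.08, ("CD8", "CD4", "CD45RA", "CCR7"),
                positives=("CD8",), negatives=("CD4",),
                continuous_neg=("CCR7", "CD27", "CD45RA")),
        _subset(t, "CD8 TEMRA", 0.06, ("CD8", "CD4", "CD45RA", "CCR7"),
                positives=("CD8",), negatives=("CD4",),
                continuous_pos=("CD45RA",), continuous_neg=("CCR7", "CD27")),
        # --- 5 B-cell subsets. CD38-defined subsets are gated first so the
        # shorter IgD/CD27 gates never capture them.
        _subset(b, "Plasmablasts", 0.05, ("CD38", "CD27", "IgD", "CD20"),
                positives=("CD27", "CD38"), negatives=("IgD", "CD20")),
        _subset(b, "Transitional B cells", 0.10, ("CD38", "CD24", "IgD", "CD27"),
                positives=("IgD", "CD38", "CD24"), negatives=("CD27",)),
        _subset(b, "Naive B cells", 0.55, ("IgD", "CD27"),
                positives=("IgD",), negatives=("CD27", "CD38")),
        _subset(b, "Memory B cells", 0.20, ("IgD", "CD27"),
                positives=("CD27",), negatives=("IgD", "CD38")),
        _subset(b, "DN B cells", 0.10, ("IgD", "CD27"),
                negatives=("IgD", "CD27", "CD38")),
        # --- 2 NK subsets ------------------------------------------------
        _subset(nk, "CD56bright NK cells", 0.10, ("CD16",),
                positives=(), negatives=("CD16",)),
        _subset(nk, "CD56dim NK cells", 0.90, ("CD16",),
                positives=("CD16",)),
        # --- 6 monocyte / cDC subsets ------------------------------------
        _subset(mono, "Classical monocytes", 0.50, ("CD14", "CD16"),
                positives=("CD14", "CD11b"), negatives=("CD16",)),
        _subset(mono, "Intermediate monocytes", 0.10, ("CD14", "CD16"),
                positives=("CD14", "CD16", "CD11b")),
        _subset(mono, "Nonclassical monocytes", 0.12, ("CD14", "CD16", "CD11b"),
                positives=("CD16", "CD11b"), negatives=("CD14",)),
        _subset(mono, "CD1c+ mDCs", 0.12, ("CD14", "CD16", "CD1c"),
                positives=("CD1c",), negatives=("CD14", "CD16", "CD11b")),
        _subset(mono, "CD141+ mDCs", 0.06, ("CD14", "CD16", "CD1c", "CD141"),
                positives=("CD141",), negatives=("CD14", "CD16", "CD11b", "CD1c")),
        _subset(mono, "CD16+ mDCs", 0.10, ("CD14", "CD16", "CD11b", "CD1c"),
                positives=("CD16",), negatives=("CD14", "CD11b", "CD1c", "CD141")),
        # --- single-subset lineages --------------------------------------
        _subset(pdc, "pDC", 1.0),
        _subset(baso, "Basophil", 1.0),
        _subset(neut, "Neutrophil", 1.0),
        _subset(eos, "Eosinophil", 1.0),
    )
    return PanelTemplate(markers=M, lineages=lineages, subsets=subsets)


MINI_MARKERS: tuple[str, ...] = (
    "CD45", "CD3", "CD19", "CD14", "CD56", "CD16", "CD11c", "HLA-DR",
    "CD66", "CD123", "FceRI",
)


def _mini_template() -> PanelTemplate:
    spec = {
        "T cells": (0.50, {"CD3"}),
        "B cells": (0.12, {"CD19", "HLA-DR"}),
        "NK cells": (0.11, {"CD56", "CD16"}),
        "Monocytes & cDCs": (0.22, {"CD14", "CD11c", "HLA-DR"}),
        "pDCs": (0.01, {"CD123", "HLA-DR"}),
        "Basophils": (0.01, {"CD123", "FceRI"}),
        "Neutrophils": (0.02, {"CD66", "CD16"}),
        "Eosinophils": (0.01, {"CD66"}),
    }
    lineages = []
    subsets = []
    for name, (prev, pos) in spec.items():
        pos = set(pos) | {"CD45"}
        neg = [m for m in MINI_MARKERS if m not in pos]
        lin = PopulationSpec(
            name=name,
            prevalence=prev,
            expression=_expression(MINI_MARKERS, pos, neg),
            gate_markers=tuple(MINI_MARKERS),
        )
        lineages.append(lin)
        subsets.append(
            PopulationSpec(
                name=name,
                prevalence=1.0,
                expression=lin.expression,
                gate_markers=lin.gate_markers,
                parent=name,
            )
        )
    return PanelTemplate(
        markers=MINI_MARKERS, lineages=tuple(lineages), subsets=tuple(subsets)
    )


def build_panel_template(scale: str = "full") -> PanelTemplate:
    """Return the packaged panel template.

    ``scale="full"``: 38 markers, 8 lineages, 28 leaf subsets (the PBMC
    immunophenotyping panel); ``scale="mini"``: 11 discrete markers, 8
    lineages, for fast tests.
    """
    if scale == "full":
        return _full_template()
    if scale == "mini":
        return _mini_template()
    raise ValueError(f"unknown template scale {scale!r}")
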