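"""Synthetic multi-donor cytometry cohorts with known ground truth.

Cells are drawn population-by-population from a :class:`~cytomatch.panel.PanelTemplate`:
a leaf subset is chosen by prevalence (lineage prevalence x subset prevalence
within the lineage), then every marker is sampled from that subset's normal
component, plus an additive per-donor, per-marker shift emulating inter-donor
staining variability.  Values are generated directly on the transformed
(arcsinh-like) scale; :func:`RawCohort.to_raw_scale` inverts the transform for
pipelines that want to exercise the arcsinh step on ion-count-like data.

The two-marker continuity datasets reproduce the discrete-bimodal /
continuous-bimodal / unimodal mixtures used to probe how marker-distribution
continuity limits embedding-based population separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CellMatrix
from .panel import MarkerModel, PanelTemplate, build_panel_template


@dataclass(frozen=True)
class DonorEffect:
    """Additive Gaussian per-donor, per-marker mean shift."""

    n_donors: int = 10
    mean_shift_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.mean_shift_sd < 0:
            raise ValueError("mean_shift_sd must be >= 0")


@dataclass
class RawCohort:
    """A generated cohort: event matrix plus per-event ground truth."""

    matrix: CellMatrix
    truth: pd.DataFrame  # columns: donor, lineage, subset

    def __post_init__(self) -> None:
        if len(self.truth) != self.matrix.n_events:
            raise ValueError("matrix and truth must align one-to-one")

    def to_raw_scale(self, cofactor: float = 5.0) -> CellMatrix:
        """Export to the raw (pre-arcsinh) intensity scale: sinh(x) * cofactor."""
        out = self.matrix.copy()
        prot = out.protein_indices
        out.values[:, prot] = np.sinh(out.values[:, prot]) * cofactor
        return out

    def per_donor(self) -> list[CellMatrix]:
        """Split the cohort into one CellMatrix per donor."""
        donors = self.truth["donor"].to_numpy()
        return [
            self.matrix.take(np.flatnonzero(donors == d))
            for d in pd.unique(donors)
        ]


def sample_cohort(
    template: PanelTemplate,
    n_donors: int = 10,
    cells_per_donor: int = 50_000,
    effect: DonorEffect | None = None,
    seed: int = 0,
) -> RawCohort:
    """Draw a multi-donor cohort from the template.

    Each cell's subset is drawn by prevalence; each marker from the subset's
    component mean (positive or negative) with the model's sigma, plus the
    donor's shift for that marker.
    """
    if n_donors < 1 or cells_per_donor < 1:
        raise ValueError("n_donors and cells_per_donor must be >= 1")
    if effect is None:
        effect = DonorEffect(n_donors=n_donors)
    rng = np.random.default_rng(seed)
    markers = template.markers
    n_markers = len(markers)

    leaf_prev = np.array(
        [s.prevalence * _lineage_prevalence(template, s.parent) for s in template.subsets]
    )
    leaf_prev = leaf_prev / leaf_prev.sum()
    means = np.array(
        [[s.expression[m].model.mean(s.expression[m].positive) for m in markers]
         for s in template.subsets]
    )
    sigmas = np.array(
        [[s.expression[m].model.sigma for m in markers] for s in template.subsets]
    )
    subset_names = np.array([s.name for s in template.subsets], dtype=object)
    lineage_names = np.array([s.parent for s in template.subsets], dtype=object)

    shifts = rng.normal(0.0, effect.mean_shift_sd, size=(n_donors, n_markers))

    values = np.empty((n_donors * cells_per_donor, n_markers))
    donor_col = np.empty(n_donors * cells_per_donor, dtype=np.int64)
    subset_col = np.empty(n_donors * cells_per_donor, dtype=object)
    for d in range(n_donors):
        sl = slice(d * cells_per_donor, (d + 1) * cells_per_donor)
        which = rng.choice(len(leaf_prev), size=cells_per_donor, p=leaf_prev)
        values[sl] = (
            means[which]
            + rng.standard_normal((cells_per_donor, n_markers)) * sigmas[which]
            + shifts[d]
        )
        donor_col[sl] = d
        subset_col[sl] = subset_names[which]

    truth = pd.DataFrame(
        {
            "donor": donor_col,
            "lineage": pd.Series(subset_col).map(
                dict(zip(subset_names, lineage_names))
            ),
            "subset": subset_col,
        }
    )
    matrix = CellMatrix(
        values=values,
        channel_names=list(markers),
        channel_kinds=["protein"] * n_markers,
        donor_ids=donor_col.copy(),
    )
    return RawCohort(matrix=matrix, truth=truth)


def _lineage_prevalence(template: PanelTemplate, lineage: str | None) -> float:
    for lin in template.lineages:
        if lin.name == lineage:
            return lin.prevalence
    raise ValueError(f"unknown lineage {lineage!r}")


#: Default continuity-study parameters: fixed component means, sigma chosen per
#: mode so the separation is 6 sigma (discrete), 2.4 sigma (continuous) or
#: 1.2 sigma (unimodal) in units of the shared component SD.
CONTINUITY_DEFAULTS = {
    "discrete_bimodal": dict(mu_neg=0.0, mu_pos=1.2, sigma=0.2),
    "continuous_bimodal": dict(mu_neg=0.0, mu_pos=1.2, sigma=0.5),
    "unimodal": dict(mu_neg=0.0, mu_pos=1.2, sigma=1.0),
}


def sample_continuity_dataset(
    mode: str,
    n_cells: int = 5_000,
    mu_neg: float | None = None,
    mu_pos: float | None = None,
    sigma: float | None = None,
    seed: int = 0,
) -> RawCohort:
    """Two-marker (M1, M2) dataset of two equal-prevalence components.

    Component A is M1-positive / M2-negative; component B the reverse.  The
    ``mode`` declares how resolvable the mixture is and is validated against
    the component parameters (see :class:`~cytomatch.panel.MarkerModel`).
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    defaults = CONTINUITY_DEFAULTS[mode]
    mu_neg = defaults["mu_neg"] if mu_neg is None else mu_neg
    mu_pos = defaults["mu_pos"] if mu_pos is None else mu_pos
    sigma = defaults["sigma"] if sigma is None else sigma
    model = MarkerModel(mode, mu_neg, mu_pos, sigma)  # validates the mode

    rng = np.random.default_rng(seed)
    component = rng.integers(0, 2, size=n_cells)  # 0 = A (M1+), 1 = B (M2+)
    m1 = np.where(component == 0, model.mu_pos, model.mu_neg)
    m2 = np.where(component == 0, model.mu_neg, model.mu_pos)
    values = np.column_stack(
        [
            m1 + rng.standard_normal(n_cells) * sigma,
            m2 + rng.standard_normal(n_cells) * sigma,
        ]
    )
    labels = np.where(component == 0, "component A", "component B").astype(object)
    truth = pd.DataFrame(
        {"donor": np.zeros(n_cells, dtype=np.int64), "lineage": labels, "subset": labels}
    )
    matrix = CellMatrix(
        values=values,
        channel_names=["M1", "M2"],
        channel_kinds=["protein", "protein"],
        donor_ids=truth["donor"].to_numpy().copy(),
    )
    return RawCohort(matrix=matrix, truth=truth)


def continuity_template(
    mode: str,
    mu_neg: float | None = None,
    mu_pos: float | None = None,
    sigma: float | None = None,
) -> PanelTemplate:
    """Two-population, two-marker template matching a continuity dataset.

    Component A is M1-positive / M2-negative and component B the reverse, at
    the requested mode's parameters; used to drive the gating and labeling
    machinery on continuity datasets.
    """
    from .panel import MarkerExpression, PopulationSpec

    defaults = CONTINUITY_DEFAULTS[mode]
    model = MarkerModel(
        mode,
        defaults["mu_neg"] if mu_neg is None else mu_neg,
        defaults["mu_pos"] if mu_pos is None else mu_pos,
        defaults["sigma"] if sigma is None else sigma,
    )

    def pop(name, m1_pos):
        expr = {
            "M1": MarkerExpression(model, m1_pos),
            "M2": MarkerExpression(model, not m1_pos),
        }
        return PopulationSpec(
            name=name, prevalence=0.5, expression=expr,
            gate_markers=("M1", "M2"),
        )

    def leaf(p):
        return PopulationSpec(
            name=p.name, prevalence=1.0, expression=p.expression,
            gate_markers=p.gate_markers, parent=p.name,
        )

    a, b = pop("component A", True), pop("component B", False)
    return PanelTemplate(
        markers=("M1", "M2"), lineages=(a, b), subsets=(leaf(a), leaf(b))
    )


def mixture_mode_count(model: MarkerModel, grid_points: int = 20_001) -> int:
    """Count modes of the analytic equal-weight two-normal mixture density.

    Evaluates the density on a fine grid spanning both components and counts
    strict local maxima; used to check that generated mixtures are unimodal or
    bimodal as declared.
    """
    lo = model.mu_neg - 5 * model.sigma
    hi = model.mu_pos + 5 * model.sigma
    x = np.linspace(lo, hi, grid_points)
    dens = 0.5 * (
        np.exp(-0.5 * ((x - model.mu_neg) / model.sigma) ** 2)
        + np.exp(-0.5 * ((x - model.mu_pos) / model.sigma) ** 2)
    )
    d = np.diff(dens)
    return int(np.sum((d[:-1] > 0) & (d[1:] <= 0)))


def write_cohort_csv(cohort: RawCohort, events_path, truth_path) -> None:
    """Write events (header = channel names) and the truth sidecar as CSV."""
    cohort.matrix.to_csv(events_path)
    sidecar = cohort.truth.copy()
    sidecar.insert(0, "event", np.arange(len(sidecar)))
    sidecar.to_csv(truth_path, index=False)


__all__ = [
    "DonorEffect",
    "RawCohort",
    "sample_cohort",
    "sample_continuity_dataset",
    "mixture_mode_count",
    "write_cohort_csv",
    "build_panel_template",
    "CONTINUITY_DEFAULTS",
]
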