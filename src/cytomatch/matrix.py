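"""Event-by-channel matrix container and the data-preparation chain.

Mirrors the standard mass-cytometry preparation for embedding analysis:
technical-channel exclusion, arcsinh transform of protein intensities,
per-donor random subsampling, merge into a single matrix carrying donor
identifiers, and append-back of derived embedding coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: Technical channels removed before embedding analysis.
DEFAULT_EXCLUDE = (
    "beads", "event_length", "intercalator", "viability",
    "center", "offset", "residual", "time",
)

CHANNEL_KINDS = ("protein", "technical", "derived", "donor_id")


@dataclass
class CellMatrix:
    """Events x channels with per-channel kind and optional donor annotation."""

    values: np.ndarray
    channel_names: list[str]
    channel_kinds: list[str]
    donor_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (events x channels)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("values column count != channel count")
        if len(self.channel_kinds) != len(self.channel_names):
            raise ValueError("channel_kinds length != channel count")
        for k in self.channel_kinds:
            if k not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {k!r}")
        if self.donor_ids is not None:
            self.donor_ids = np.asarray(self.donor_ids)
            if len(self.donor_ids) != self.values.shape[0]:
                raise ValueError("donor_ids length != event count")

    # -- basic introspection ---------------------------------------------

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_kinds) == "protein")

    @property
    def protein_channels(self) -> list[str]:
        return [self.channel_names[i] for i in self.protein_indices]

    def protein_values(self) -> np.ndarray:
        return self.values[:, self.protein_indices]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def copy(self) -> "CellMatrix":
        return CellMatrix(
            values=self.values.copy(),
            channel_names=list(self.channel_names),
            channel_kinds=list(self.channel_kinds),
            donor_ids=None if self.donor_ids is None else self.donor_ids.copy(),
        )

    def take(self, rows: np.ndarray) -> "CellMatrix":
        return CellMatrix(
            values=self.values[rows],
            channel_names=list(self.channel_names),
            channel_kinds=list(self.channel_kinds),
            donor_ids=None if self.donor_ids is None else self.donor_ids[rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_names)

    # -- CSV I/O (comma-separated, header row, '.' decimal) ---------------

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, channel_kinds: list[str] | None = None) -> "CellMatrix":
        df = pd.read_csv(path)
        names = list(df.columns)
        if channel_kinds is None:
            channel_kinds = [
                "donor_id" if n == "donor_id"
                else "derived" if n in ("tSNE1", "tSNE2")
                else "protein"
                for n in names
            ]
        donor = None
        if "donor_id" in names:
            donor = df["donor_id"].to_numpy().astype(np.int64)
        return cls(df.to_numpy(dtype=float), names, channel_kinds, donor_ids=donor)


@dataclass(frozen=True)
class TransformSpec:
    """arcsinh(x / cofactor); cofactor 5 is conventional for mass cytometry."""

    cofactor: float = 5.0

    def __post_init__(self) -> None:
        if not self.cofactor > 0:
            raise ValueError("cofactor must be > 0")


def select_channels(
    m: CellMatrix,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    optional: bool | tuple[str, ...] = (),
) -> CellMatrix:
    """Drop the named channels (idempotent).

    ``optional`` marks excluded names that may be absent: a tuple of names, or
    ``True`` to make every name optional.  Excluding an absent, non-optional
    channel raises ``KeyError``.
    """
    optional_set = set(exclude) if optional is True else set(optional or ())
    present = set(m.channel_names)
    for name in exclude:
        if name not in present and name not in optional_set:
            raise KeyError(f"cannot exclude absent channel {name!r}")
    keep = [i for i, n in enumerate(m.channel_names) if n not in set(exclude)]
    return CellMatrix(
        values=m.values[:, keep],
        channel_names=[m.channel_names[i] for i in keep],
        channel_kinds=[m.channel_kinds[i] for i in keep],
        donor_ids=None if m.donor_ids is None else m.donor_ids.copy(),
    )


def arcsinh_transform(m: CellMatrix, spec: TransformSpec = TransformSpec()) -> CellMatrix:
    """Apply x -> arcsinh(x / cofactor) to protein channels only."""
    out = m.copy()
    prot = out.protein_indices
    out.values[:, prot] = np.arcsinh(out.values[:, prot] / spec.cofactor)
    return out


class ArcsinhTransformer(TransformerMixin, BaseEstimator):
    """sklearn-compatible arcsinh(x / cofactor) on plain arrays."""

    def __init__(self, cofactor: float = 5.0):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if not self.cofactor > 0:
            raise ValueError("cofactor must be > 0")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.arcsinh(np.asarray(X, dtype=float) / self.cofactor)

    def inverse_transform(self, X):
        return np.sinh(np.asarray(X, dtype=float)) * self.cofactor


def subsample_and_merge(
    cohort: list[CellMatrix],
    n_per_donor: int,
    seed: int = 0,
    donor_labels: list | None = None,
    return_indices: bool = False,
):
    """Sample ``n_per_donor`` events per donor (without replacement) and merge.

    Donors are concatenated in input order; each donor's sampled rows keep
    their original acquisition order.  The merged matrix carries a numeric
    ``donor_id`` channel so the merged embedding can later be deconvolved
    into per-donor maps.
    """
    if donor_labels is None:
        donor_labels = list(range(len(cohort)))
    rng = np.random.default_rng(seed)
    pieces, donors, picked = [], [], []
    for label, m in zip(donor_labels, cohort):
        if m.n_events < n_per_donor:
            raise ValueError(
                f"donor {label!r} has only {m.n_events} events "
                f"(< n_per_donor={n_per_donor})"
            )
        rows = np.sort(rng.choice(m.n_events, size=n_per_donor, replace=False))
        pieces.append(m.take(rows))
        donors.append(np.full(n_per_donor, label))
        picked.append(rows)
    names = pieces[0].channel_names
    kinds = pieces[0].channel_kinds
    for p in pieces[1:]:
        if p.channel_names != names:
            raise ValueError("donor matrices have mismatched channels")
    donor_col = np.concatenate(donors)
    values = np.column_stack(
        [np.vstack([p.values for p in pieces]), donor_col.astype(float)]
    )
    merged = CellMatrix(
        values=values,
        channel_names=[*names, "donor_id"],
        channel_kinds=[*kinds, "donor_id"],
        donor_ids=donor_col,
    )
    return (merged, picked) if return_indices else merged


def append_derived(m: CellMatrix, coords: np.ndarray,
                   names: tuple[str, str] = ("tSNE1", "tSNE2")) -> CellMatrix:
    """Append embedding coordinates as two derived channels."""
    coords = np.asarray(getattr(coords, "coords", coords), dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n_events, 2)")
    if coords.shape[0] != m.n_events:
        raise ValueError(
            f"coords rows ({coords.shape[0]}) != event count ({m.n_events})"
        )
    return CellMatrix(
        values=np.column_stack([m.values, coords]),
        channel_names=[*m.channel_names, *names],
        channel_kinds=[*m.channel_kinds, "derived", "derived"],
        donor_ids=None if m.donor_ids is None else m.donor_ids.copy(),
    )
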