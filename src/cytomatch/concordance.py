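"""Quantitative comparison of two labeling routes.

The central statistic is the directional *matching fraction*: of the cells a
hand gate captured for a population, the fraction also captured by the
embedding-guided gate (and vice versa) — overlap count divided by one route's
population count.  Population frequencies (percent of a chosen denominator,
per donor and for the pooled aggregate), cross-method frequency correlations,
and cross-run embedding reproducibility complete the comparison layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gating import UNIDENTIFIED, Labeling, derive_embedding_labeling
from .matrix import CellMatrix
from .tsne import EmbeddingParams, run_embedding


@dataclass(frozen=True)
class MatchingResult:
    population: str
    n_hand: int
    n_embed: int
    n_overlap: int
    f_hand_matched: float | None  # n_overlap / n_hand; None when n_hand == 0
    f_embed_matched: float | None  # n_overlap / n_embed; None when n_embed == 0

    def __post_init__(self):
        if self.n_overlap > min(self.n_hand, self.n_embed):
            raise ValueError("overlap exceeds a population count")
        for f in (self.f_hand_matched, self.f_embed_matched):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError("matching fractions must lie in [0, 1]")


def matching_fractions(a: Labeling, b: Labeling, population: str) -> MatchingResult:
    """Bidirectional single-cell matching fractions for one population.

    ``a`` is the hand-gated (reference) route and ``b`` the embedding-guided
    route.  Fractions with an empty denominator are ``None`` (undefined),
    never 0 or 1.
    """
    if len(a) != len(b):
        raise ValueError("labelings must cover the same events")
    in_a = a.assignment == population
    in_b = b.assignment == population
    n_hand = int(in_a.sum())
    n_embed = int(in_b.sum())
    if n_hand == 0 and n_embed == 0:
        raise ValueError(f"population {population!r} absent from both labelings")
    n_overlap = int((in_a & in_b).sum())
    return MatchingResult(
        population=population,
        n_hand=n_hand,
        n_embed=n_embed,
        n_overlap=n_overlap,
        f_hand_matched=None if n_hand == 0 else n_overlap / n_hand,
        f_embed_matched=None if n_embed == 0 else n_overlap / n_embed,
    )


def matching_table(a: Labeling, b: Labeling, populations) -> pd.DataFrame:
    rows = []
    for p in populations:
        r = matching_fractions(a, b, p)
        rows.append(
            {
                "population": p,
                "n_hand": r.n_hand,
                "n_embed": r.n_embed,
                "n_overlap": r.n_overlap,
                "f_hand_matched": np.nan if r.f_hand_matched is None else r.f_hand_matched,
                "f_embed_matched": np.nan if r.f_embed_matched is None else r.f_embed_matched,
            }
        )
    return pd.DataFrame(rows)


def confusion_matrix(a: Labeling, b: Labeling) -> pd.DataFrame:
    """Full population-by-population event count table (rows: a, cols: b)."""
    if len(a) != len(b):
        raise ValueError("labelings must cover the same events")
    return pd.crosstab(
        pd.Series(a.assignment, name="a"), pd.Series(b.assignment, name="b")
    )


@dataclass
class FrequencyTable:
    """Per-unit (donor or "aggregate") population frequencies in percent."""

    table: pd.DataFrame  # index: unit, columns: population
    denominator: str

    @property
    def units(self) -> list:
        return list(self.table.index)

    @property
    def populations(self) -> list:
        return list(self.table.columns)


def population_frequencies(
    l: Labeling,
    m: CellMatrix | None = None,
    denominator: str = "total_events",
    per_donor: bool = False,
    cd45_channel: str = "CD45",
    cd45_threshold: float | None = None,
    include_unidentified: bool = True,
) -> FrequencyTable:
    """Population frequencies as percent of the chosen denominator.

    With ``per_donor`` the table has one row per donor plus an ``aggregate``
    row computed from pooled counts (not a mean of per-donor rows).  The
    ``CD45_positive`` denominator counts events above the CD45 cut.
    """
    labels = l.assignment
    n = len(labels)
    if denominator == "total_events":
        in_denom = np.ones(n, dtype=bool)
    elif denominator == "CD45_positive":
        if m is None or cd45_threshold is None:
            raise ValueError(
                "CD45_positive denominator needs the matrix and a CD45 cut"
            )
        in_denom = m.channel(cd45_channel) >= cd45_threshold
    else:
        raise ValueError(f"unknown denominator {denominator!r}")

    pops = sorted(set(labels) - {UNIDENTIFIED})
    if include_unidentified and UNIDENTIFIED in set(labels):
        pops = pops + [UNIDENTIFIED]

    units: list[tuple[str, np.ndarray]] = []
    if per_donor:
        if m is None or m.donor_ids is None:
            raise ValueError("per_donor requires donor ids on the matrix")
        for d in pd.unique(m.donor_ids):
            units.append((str(d), m.donor_ids == d))
    units.append(("aggregate", np.ones(n, dtype=bool)))

    rows = {}
    for unit, unit_mask in units:
        denom = int((unit_mask & in_denom).sum())
        if denom == 0:
            rows[unit] = {p: np.nan for p in pops}
            continue
        rows[unit] = {
            p: 100.0 * int((unit_mask & in_denom & (labels == p)).sum()) / denom
            for p in pops
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[pops]
    return FrequencyTable(table=table, denominator=denominator)


@dataclass(frozen=True)
class ConcordanceReport:
    per_population: pd.DataFrame  # pearson_r, spearman_r, mean_abs_diff per population
    pooled_pearson_r: float
    pooled_spearman_r: float
    differences: pd.DataFrame  # per-unit absolute differences


def frequency_concordance(fa: FrequencyTable, fb: FrequencyTable) -> ConcordanceReport:
    """Correlate two frequency tables across shared units, per population.

    Emits Pearson and Spearman coefficients (per population and pooled over
    all population-unit pairs) plus per-unit absolute differences.
    Correlations over fewer than 3 units, or against a constant series, are
    NaN (flagged not-computable).
    """
    units = [u for u in fa.units if u in set(fb.units)]
    pops = [p for p in fa.populations if p in set(fb.populations)]
    if not pops:
        raise ValueError("tables share no populations")
    A = fa.table.loc[units, pops]
    B = fb.table.loc[units, pops]

    recs = []
    for p in pops:
        x, y = A[p].to_numpy(), B[p].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            pr = sr = np.nan
        else:
            pr = float(stats.pearsonr(x[ok], y[ok]).statistic)
            sr = float(stats.spearmanr(x[ok], y[ok]).statistic)
        recs.append(
            {
                "population": p,
                "pearson_r": pr,
                "spearman_r": sr,
                "mean_abs_diff": float(np.nanmean(np.abs(x - y))),
            }
        )
    flat_a = A.to_numpy().ravel()
    flat_b = B.to_numpy().ravel()
    ok = np.isfinite(flat_a) & np.isfinite(flat_b)
    if ok.sum() >= 3 and np.std(flat_a[ok]) > 0 and np.std(flat_b[ok]) > 0:
        pooled_p = float(stats.pearsonr(flat_a[ok], flat_b[ok]).statistic)
        pooled_s = float(stats.spearmanr(flat_a[ok], flat_b[ok]).statistic)
    else:
        pooled_p = pooled_s = np.nan
    return ConcordanceReport(
        per_population=pd.DataFrame(recs),
        pooled_pearson_r=pooled_p,
        pooled_spearman_r=pooled_s,
        differences=(A - B).abs(),
    )


def reproducibility_assessment(
    m: CellMatrix,
    template,
    params: EmbeddingParams,
    seeds: list[int],
    level: str = "lineage",
    backend: str = "approximate",
    k: int | None = None,
) -> tuple[list[FrequencyTable], pd.Series]:
    """Frequencies from independent embedding runs, plus per-population spread.

    One embedding and one embedding-guided labeling per seed; the spread is
    the maximum pairwise absolute frequency difference per population across
    runs (aggregate unit).
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds")
    tables = []
    for s in seeds:
        res = run_embedding(m, replace(params, seed=s), backend=backend)
        lab = derive_embedding_labeling(
            res, m, template, level=level, k=k, seed=s
        )
        tables.append(population_frequencies(lab))
    pops = sorted({p for t in tables for p in t.populations})
    spread = {}
    for p in pops:
        vals = np.array(
            [t.table.loc["aggregate", p] if p in t.populations else 0.0 for t in tables]
        )
        spread[p] = float(np.max(vals) - np.min(vals))
    return tables, pd.Series(spread, name="max_abs_spread")
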