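"""End-to-end experiment orchestration.

Four experiments mirror the study design:

* ``general_lineages`` — synthetic cohort -> preprocessing -> embedding ->
  conventional and embedding-guided lineage labelings -> matching fractions,
  per-donor frequencies, cross-method concordance;
* ``deep_subsets`` — the same at leaf-subset level, with naive-like and
  memory-like subsets reported separately;
* ``continuity_study`` — two-marker datasets at decreasing marker
  discreteness, scoring embedding separability and cross-route matching;
* ``parameter_sweep`` — perplexity x iterations x theta grid, scored against
  ground truth.

Every stage's seed is explicit and echoed into the report bundle, so a rerun
with the same config reproduces the numbers exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .concordance import (
    frequency_concordance,
    matching_table,
    population_frequencies,
    reproducibility_assessment,
)
from .datasets import (
    CONTINUITY_DEFAULTS,
    DonorEffect,
    RawCohort,
    continuity_template,
    sample_cohort,
    sample_continuity_dataset,
)
from .fcs import write_fcs
from .gating import (
    UNIDENTIFIED,
    apply_tree,
    build_gating_tree,
    conventional_labeling,
    derive_embedding_labeling,
)
from .matrix import append_derived, arcsinh_transform, select_channels, TransformSpec
from .panel import build_panel_template
from .tsne import (
    EXACT_CAP_DEFAULT,
    EmbeddingParams,
    SweepGrid,
    parameter_sweep,
    run_embedding,
    separability_scores,
)

log = logging.getLogger("cytomatch")

EXPERIMENTS = (
    "general_lineages", "deep_subsets", "continuity_study", "parameter_sweep",
)


@dataclass
class ExperimentConfig:
    experiment: str = "general_lineages"
    # cohort
    template_scale: str = "mini"
    n_donors: int = 10
    cells_per_donor: int = 2000
    mean_shift_sd: float = 0.1
    seed: int = 0
    # preprocessing
    cofactor: float = 5.0
    # embedding
    perplexity: float = 30.0
    n_iter: int = 1000
    theta: float = 0.5
    backend: str = "auto"  # exact when n <= exact_cap, else approximate
    exact_cap: int = EXACT_CAP_DEFAULT
    # labeler
    k: int | None = None
    cutoff: float = 0.25
    # continuity study
    continuity_n_cells: int = 5000
    # sweep
    sweep: dict = field(default_factory=lambda: {
        "perplexities": [5.0, 30.0, 100.0],
        "n_iters": [1000, 10000],
        "thetas": [0.2, 0.5, 0.8],
        "repeats": 1,
    })
    out_dir: str | None = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def embedding_params(self, seed_offset: int = 1) -> EmbeddingParams:
        return EmbeddingParams(
            perplexity=self.perplexity, n_iter=self.n_iter, theta=self.theta,
            seed=(self.seed + seed_offset) % (2**31),
        )


#: "auto" picks the exact reference only below this size: exact t-SNE is
#: O(n^2) per iteration (~0.1 s at n=1000), so anything larger goes to the
#: Barnes-Hut backend even though the hard exact-mode cap is higher.
AUTO_EXACT_MAX = 600


def _resolve_backend(cfg: ExperimentConfig, n: int) -> str:
    if cfg.backend != "auto":
        return cfg.backend
    return "exact" if n <= min(AUTO_EXACT_MAX, cfg.exact_cap) else "approximate"


def _prepared_cohort(cfg: ExperimentConfig) -> RawCohort:
    """Cohort -> raw-scale export -> arcsinh back: exercises the transform
    chain while returning values identical (to fp tolerance) to the stated
    template scale."""
    template = build_panel_template(cfg.template_scale)
    cohort = sample_cohort(
        template,
        n_donors=cfg.n_donors,
        cells_per_donor=cfg.cells_per_donor,
        effect=DonorEffect(n_donors=cfg.n_donors, mean_shift_sd=cfg.mean_shift_sd),
        seed=cfg.seed,
    )
    raw = cohort.to_raw_scale(cfg.cofactor)
    cohort.matrix = arcsinh_transform(raw, TransformSpec(cfg.cofactor))
    return cohort


def _comparison_stages(cfg: ExperimentConfig, level: str) -> dict:
    template = build_panel_template(cfg.template_scale)
    t0 = time.time()
    cohort = _prepared_cohort(cfg)
    log.info("cohort: %d events, seed %d (%.1fs)",
             cohort.matrix.n_events, cfg.seed, time.time() - t0)

    params = cfg.embedding_params()
    backend = _resolve_backend(cfg, cohort.matrix.n_events)
    t0 = time.time()
    emb = run_embedding(cohort.matrix, params, backend=backend)
    log.info("embedding: backend=%s KL=%.3f (%.1fs)",
             backend, emb.final_objective, time.time() - t0)

    conv = conventional_labeling(template, cohort.matrix, level=level)
    guided = derive_embedding_labeling(
        emb, cohort.matrix, template,
        level=level, k=cfg.k, seed=(cfg.seed + 2) % (2**31), cutoff=cfg.cutoff,
    )

    populations = [p.name for p in template.populations(level)]
    matching = matching_table(conv, guided, populations)
    freq_conv = population_frequencies(conv, cohort.matrix, per_donor=True)
    freq_guided = population_frequencies(guided, cohort.matrix, per_donor=True)
    conc = frequency_concordance(freq_conv, freq_guided)
    truth = cohort.truth[level].to_numpy()
    return {
        "template": template,
        "cohort": cohort,
        "embedding": emb,
        "backend": backend,
        "conventional": conv,
        "embedding_guided": guided,
        "matching": matching,
        "freq_conventional": freq_conv,
        "freq_guided": freq_guided,
        "concordance": conc,
        "truth_scores": separability_scores(emb.coords, truth),
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment; returns the report bundle (plain data + tables)."""
    bundle: dict = {"config": asdict(cfg), "experiment": cfg.experiment}
    try:
        if cfg.experiment == "general_lineages":
            st = _comparison_stages(cfg, "lineage")
            bundle.update(_comparison_bundle(st))
        elif cfg.experiment == "deep_subsets":
            st = _comparison_stages(cfg, "subset")
            bundle.update(_comparison_bundle(st))
            m = st["matching"].set_index("population")
            names = list(m.index)
            naive_like = [p for p in names if "naive" in p.lower()]
            memory_like = list(st["template"].continuously_split_subsets())
            bundle["naive_like"] = m.loc[naive_like].reset_index().to_dict("records")
            bundle["memory_like"] = m.loc[memory_like].reset_index().to_dict("records")
        elif cfg.experiment == "continuity_study":
            bundle.update(_continuity_bundle(cfg))
        elif cfg.experiment == "parameter_sweep":
            bundle.update(_sweep_bundle(cfg))
    except Exception as err:
        raise RuntimeError(f"experiment {cfg.experiment!r} failed: {err}") from err
    return bundle


def _comparison_bundle(st: dict) -> dict:
    unid = float(np.mean(st["conventional"].assignment == UNIDENTIFIED))
    return {
        "stages": st,
        "matching": st["matching"],
        "summary": {
            "n_events": int(st["cohort"].matrix.n_events),
            "backend": st["backend"],
            "kl": float(st["embedding"].final_objective),
            "unidentified_fraction_conventional": unid,
            "unidentified_fraction_guided": float(
                np.mean(st["embedding_guided"].assignment == UNIDENTIFIED)
            ),
            "min_f_hand_matched": float(st["matching"]["f_hand_matched"].min()),
            "min_f_embed_matched": float(st["matching"]["f_embed_matched"].min()),
            "pooled_pearson_r": st["concordance"].pooled_pearson_r,
            "pooled_spearman_r": st["concordance"].pooled_spearman_r,
            "truth_scores": st["truth_scores"],
            "seeds": {
                "cohort": int(st["embedding"].params.seed - 1),
                "embedding": int(st["embedding"].params.seed),
                "labeler": int(st["embedding"].params.seed + 1),
            },
        },
    }


def _continuity_bundle(cfg: ExperimentConfig) -> dict:
    per_mode = {}
    for i, mode in enumerate(CONTINUITY_DEFAULTS):
        ds = sample_continuity_dataset(
            mode, n_cells=cfg.continuity_n_cells, seed=(cfg.seed + 10 + i) % (2**31)
        )
        template = continuity_template(mode)
        params = cfg.embedding_params(seed_offset=20 + i)
        backend = _resolve_backend(cfg, ds.matrix.n_events)
        emb = run_embedding(ds.matrix, params, backend=backend)

        conv = apply_tree(build_gating_tree(template), ds.matrix, level="lineage")
        guided = derive_embedding_labeling(
            emb, ds.matrix, template, level="lineage",
            k=cfg.k, seed=(cfg.seed + 30 + i) % (2**31), cutoff=cfg.cutoff,
            signature_modes=("discrete_bimodal", "continuous_bimodal", "unimodal"),
        )
        truth = ds.truth["lineage"].to_numpy()
        matching = matching_table(conv, guided, ["component A", "component B"])
        per_mode[mode] = {
            "backend": backend,
            "seeds": {"data": (cfg.seed + 10 + i) % (2**31),
                      "embedding": params.seed},
            "truth_scores": separability_scores(emb.coords, truth),
            "matching": matching,
            "min_matching": float(
                np.nanmin(matching[["f_hand_matched", "f_embed_matched"]].to_numpy())
            ),
        }
        log.info("continuity %s: silhouette=%.3f min_match=%.3f", mode,
                 per_mode[mode]["truth_scores"]["silhouette"],
                 per_mode[mode]["min_matching"])
    return {"per_mode": per_mode}


def _sweep_bundle(cfg: ExperimentConfig) -> dict:
    cohort = _prepared_cohort(cfg)
    grid = SweepGrid(
        perplexities=tuple(cfg.sweep["perplexities"]),
        n_iters=tuple(cfg.sweep["n_iters"]),
        thetas=tuple(cfg.sweep["thetas"]),
        repeats=int(cfg.sweep.get("repeats", 1)),
    )
    report = parameter_sweep(
        cohort.matrix, grid, cohort.truth["lineage"].to_numpy(),
        backend="approximate",
        base_params=cfg.embedding_params(seed_offset=40),
    )
    return {"sweep_report": report, "stages": {"cohort": cohort}}


# ---------------------------------------------------------------------------
# Report writing


def write_report(bundle: dict, out_dir) -> list[Path]:
    """Write the bundle: JSON summary, CSV tables, appended event files."""
    if not bundle or "experiment" not in bundle:
        raise ValueError("empty or incomplete bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = {"experiment": bundle["experiment"], "config": bundle["config"]}

    if "matching" in bundle:
        p = out / "matching.csv"
        bundle["matching"].to_csv(p, index=False)
        written.append(p)
    if "summary" in bundle:
        summary["summary"] = _plain(bundle["summary"])
    for key in ("naive_like", "memory_like"):
        if key in bundle:
            summary[key] = _plain(bundle[key])
    if "per_mode" in bundle:
        summary["per_mode"] = {
            mode: {
                k: _plain(v) for k, v in d.items() if k != "matching"
            }
            for mode, d in bundle["per_mode"].items()
        }
        for mode, d in bundle["per_mode"].items():
            p = out / f"matching_{mode}.csv"
            d["matching"].to_csv(p, index=False)
            written.append(p)
    if "sweep_report" in bundle:
        p = out / "sweep_report.csv"
        bundle["sweep_report"].to_csv(p, index=False)
        written.append(p)

    st = bundle.get("stages", {})
    if "freq_conventional" in st:
        for name in ("freq_conventional", "freq_guided"):
            p = out / f"{name}.csv"
            st[name].table.to_csv(p)
            written.append(p)
        p = out / "concordance_per_population.csv"
        st["concordance"].per_population.to_csv(p, index=False)
        written.append(p)
    for name in ("conventional", "embedding_guided"):
        if name in st:
            p = out / f"labels_{name}.csv"
            st[name].to_csv(p)
            written.append(p)
    if "embedding" in st:
        appended = append_derived(st["cohort"].matrix, st["embedding"].coords)
        p = out / "events_with_tsne.csv"
        appended.to_csv(p)
        written.append(p)
        p = out / "events_with_tsne.fcs"
        write_fcs(p, appended, extra_keywords={"CYTOMATCH_EXPERIMENT": bundle["experiment"]})
        written.append(p)

    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_plain)
    written.append(p)
    return written


def _plain(x):
    if isinstance(x, dict):
        return {str(k): _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, pd.DataFrame):
        return x.to_dict("records")
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x
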