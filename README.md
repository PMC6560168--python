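# cytomatch

**Does gating on a t-SNE map reproduce conventional hand-gating?**
`cytomatch` is a toolkit for quantifying the concordance between the two
analysis routes used on high-parameter single-cell cytometry data (CyTOF /
mass cytometry):

* the **conventional route** — sequential bivariate gates (thresholds,
  rectangles, polygons) arranged in a hierarchy, the classic
  immunophenotyping workflow;
* the **embedding-guided route** — populations delineated directly on a 2-D
  t-SNE map, informed by per-marker intensity overlays.

It is aimed at cytometrists and computational biologists who want to know
*when* the two routes agree — and, more importantly, when they cannot: a
population that differs from its siblings only in **continuously** distributed
markers (CCR7, CD45RA on memory T cells) carries no discrete boundary for the
embedding to respect, and no choice of t-SNE parameters fixes that.

## What's inside

* `cytomatch.panel` / `cytomatch.datasets` — synthetic multi-donor PBMC
  cohorts with known ground truth: a 38-marker template resolving 8 lineages
  into 28 subsets, an 11-marker fast variant, and two-marker
  discrete/continuous/unimodal mixture datasets.
* `cytomatch.matrix` / `cytomatch.fcs` — events-by-channels container,
  technical-channel exclusion, `arcsinh(x/c)` transform, per-donor
  subsampling and merge, FCS 3.1 and CSV I/O.
* `cytomatch.tsne` — an exact t-SNE reference (perplexity calibration by
  binary search on `2^H`, Student-t kernel, KL gradient descent) plus a
  Barnes-Hut backend (scikit-learn) behind one interface, and a
  perplexity x iterations x theta sweep harness.
* `cytomatch.gating` — gating trees, an sklearn-style
  `GatingTreeClassifier`, and an `EmbeddingGuidedLabeler` that mechanises
  t-SNE-guided gating (k-means islands named by nearest discrete-marker
  signature).
* `cytomatch.concordance` — directional single-cell matching fractions,
  population frequencies per donor and pooled, cross-method correlation, and
  cross-run reproducibility.
* `cytomatch.pipeline` / CLI `cytomatch` — four end-to-end experiments:
  `general_lineages`, `deep_subsets`, `continuity_study`, `parameter_sweep`.

## The core statistic

For a population *p* labelled by the hand route (*H_p* cells) and the
embedding route (*E_p* cells), the **directional matching fractions** are

    f_hand  = |H_p ∩ E_p| / |H_p|      (does the map recover the hand gate?)
    f_embed = |H_p ∩ E_p| / |E_p|      (does the hand gate recover the map?)

Both are reported per population; an empty denominator is flagged undefined
rather than coerced to 0 or 1.  The t-SNE objective is the standard
KL(P||Q) between Gaussian high-dimensional neighbour similarities
(bandwidths set so each point's perplexity `2^H(P_i)` hits the target) and
Student-t map similarities.

## Worked example

```python
from cytomatch import (
    build_panel_template, sample_cohort, run_embedding, EmbeddingParams,
    conventional_labeling, derive_embedding_labeling, matching_table,
)

template = build_panel_template("mini")          # 8 discrete lineages
cohort = sample_cohort(template, n_donors=4, cells_per_donor=1000, seed=7)
emb = run_embedding(cohort.matrix, EmbeddingParams(perplexity=30, n_iter=500,
                                                   seed=8))
hand = conventional_labeling(template, cohort.matrix)
guided = derive_embedding_labeling(emb, cohort.matrix, template, seed=9)
table = matching_table(hand, guided, [p.name for p in template.lineages])
print(table[["population", "n_hand", "f_hand_matched", "f_embed_matched"]])
```

```
         population  n_hand  f_hand_matched  f_embed_matched
0           T cells    2023             1.0         0.999506
1           B cells     479             1.0         1.000000
2          NK cells     412             1.0         1.000000
3  Monocytes & cDCs     881             1.0         0.998866
4              pDCs      44             1.0         1.000000
5         Basophils      39             1.0         1.000000
6       Neutrophils      80             1.0         1.000000
7       Eosinophils      40             1.0         1.000000
```

Every lineage is discrete here, so the two routes agree almost perfectly:
`f_hand_matched = 1.0` means every hand-gated T cell was also captured by the
t-SNE-guided gate; `f_embed_matched = 0.9995` for T cells means one cell of
the embedding-derived island fell outside the hand gate.  Run the same
comparison at subset
level on the full template (`experiment: deep_subsets`) and the memory T
subsets — split only by continuous markers — drop to ~0–40% while the
redundant-marker naive subsets stay above 80%.

A whole experiment from the shell:

```bash
cytomatch run --experiment general_lineages --seed 1 --out report/
# report/: matching.csv, freq_*.csv, labels_*.csv, events_with_tsne.{csv,fcs},
#          summary.json (config and every seed echoed back)
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch (fresh synthetic cohorts, embeddings and both
gating routes at the given seed), the minimum per-lineage matching fractions
of the 20,000-cell general-lineage experiment (both directions, in percent)
and the naive-CD4-subset matching of the 12,000-cell deep-subsets
experiment, writing them as JSON.  Expect roughly 7 minutes on one CPU.

## Layout

```
src/cytomatch/     library (panel, datasets, matrix, fcs, tsne, gating,
                   concordance, pipeline, cli)
tests/             pytest suite incl. acceptance criteria
scripts/           acceptance.py
docs/methods.md    models, defaults, numerical choices, limitations
```
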