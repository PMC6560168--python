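# Methods

`cytomatch` quantifies how well gating performed on a 2-D embedding of
high-parameter cytometry data reproduces conventional hierarchical
("hand") gating, using synthetic cohorts with known ground truth.  This note
records the models, the defaults and why, and what the tests do and do not
establish.

## The synthetic world

### Marker expression model

Every population expresses every marker as one component of an equal-weight,
equal-variance two-normal mixture on the arcsinh scale,
`x ~ N(mu_pos or mu_neg, sigma^2)`, plus an additive per-donor, per-marker
shift `N(0, mean_shift_sd^2)` drawn once per donor.  Three marker flavours are
distinguished by the component separation `d = mu_pos - mu_neg`:

| mode | constraint | default (mu_neg, mu_pos, sigma) | separation |
|---|---|---|---|
| `discrete_bimodal` | d >= 6 sigma | (0.4, 3.6, 0.4) | 8 sigma |
| `continuous_bimodal` | 2 sigma < d < 6 sigma | (0.8, 2.0, 0.5) | 2.4 sigma |
| `unimodal` | d <= 2 sigma | (0.5, 0.5, 0.4) | 0 |

The 2-sigma boundary is the exact unimodality condition for an equal-weight,
equal-variance two-normal mixture.  The discrete default uses 8 sigma rather
than the 6-sigma minimum so that a midpoint threshold across a 10–20 gate
chain misclassifies ~3e-5 per gate, keeping the Unidentified fraction of the
conventional route well under 1% — matching the ~0.24% seen in practice for a
clean PBMC panel.  Values are generated directly on the transformed scale
(that is the scale on which the analysis operates); `RawCohort.to_raw_scale`
inverts the transform (`sinh(x) * cofactor`) so the preprocessing chain's
arcsinh step is exercised on ion-count-like data.

### Panel templates

The **full template** is a 38-marker PBMC immunophenotyping panel resolving
8 general lineages (T, B, NK, monocytes & cDCs, pDCs, basophils, neutrophils,
eosinophils) into 28 leaf subsets (11 T, 5 B, 2 NK, 6 monocyte/cDC, 4
single-subset lineages).  Lineage prevalences loosely follow normal PBMC
composition (T 0.50, B 0.12, NK 0.11, monocytes & cDCs 0.22, rare lineages
0.01–0.02); pDCs are fixed at 1% to keep a genuinely rare island in play.
Naive T subsets carry three redundant *discrete* markers (CD45RA+, CCR7+,
CD27+); central/effector memory and TEMRA subsets are distinguished from one
another **only** by `continuous_bimodal` CCR7/CD45RA (and CD27) models — by
construction they carry no binary evidence separating them, which is the
mechanism behind the memory-subset concordance failure the package measures.
Ten filler markers are unimodal everywhere, contributing realistic
uninformative dimensions.  The **mini template** (11 markers, 8 lineages, all
discrete) is the fast, fully separable counterpart.

Declaration order of subsets is gating order: populations defined by
specific discrete markers (Treg, gd T, MAIT; plasmablasts, transitional B)
are declared before the quadrant-style subsets whose shorter gate chains
would otherwise capture them.

### Continuity datasets

Two markers M1/M2, two equal-prevalence components (A = M1+/M2-,
B = M1-/M2+), fixed means and mode-dependent sigma.  Defaults: n = 5,000
cells, means (0, 1.2), sigma in {0.2, 0.5, 1.0}, i.e. separations of 6, 2.4
and 1.2 sigma for the discrete, continuous and unimodal conditions.  (A
sigma grid applied to a 1.0 separation would make the "discrete" condition
only 5 sigma, violating the discreteness constraint above, so the separation
is 1.2.)

## Preprocessing

`arcsinh(x / cofactor)` with cofactor 5 (the mass-cytometry convention;
configurable) on protein channels only; technical channels (beads, event
length, intercalator, viability, center, offset, residual, time) excluded by
name; per-donor subsampling without replacement; donors concatenated in input
order with a numeric `donor_id` channel and FCS keyword so merged maps can be
deconvolved per donor.  FCS 3.1 files are written single-precision
little-endian; CSV is comma-separated with a header row.

## Embedding

The exact t-SNE reference implements the standard algorithm: per-point
Gaussian bandwidths found by binary search so the conditional distribution's
perplexity `2^H` matches the target within 1e-5; symmetrised joint
similarities `P = (P_c + P_c^T) / 2n`; Student-t (df = 1) kernel in the map;
gradient descent on KL(P||Q) with learning rate 200, momentum 0.5 switching
to 0.8 at iteration 250, adaptive gains, and 12x early exaggeration for the
first 250 iterations (standard practice; only perplexity, iteration count
and theta are scientifically load-bearing here).  Duplicate rows receive
1e-10-scale jitter so conditionals stay defined.  Distances are Euclidean on
the transformed protein channels.

The exact route is O(n^2) per iteration and hard-capped at 5,000 events;
`backend="auto"` switches to the approximate backend above n = 600 (measured
~0.1 s/iteration already at n = 1,000).  The approximate backend is
scikit-learn's Barnes-Hut t-SNE with `angle = theta`; `theta = 0` selects its
exact method.  One integer seed controls initialisation in both backends.

## Gating routes

**Conventional route.**  Threshold-gate chains generated from the template,
with one global cut per marker: the midpoint between the largest
negative-component mean and the smallest positive-component mean across all
of the marker's bimodal models.  A single analyst-style cut per marker is
essential: per-population cuts leave gaps between sibling quadrant gates
(e.g. CD45RA in [1.6, 2.0] would satisfy neither a naive nor a memory gate),
pushing ~10% of memory cells into Unidentified.  Gate regions are closed
(boundary points included); an event's label is the first terminal, in
declaration order, whose full ancestor conjunction it satisfies; overlapping
terminals are reported as a diagnostic count.

**Embedding-guided route.**  An automated, reproducible surrogate for an
analyst drawing polygons on marker-overlay maps: k-means over the 2-D
coordinates, then each cluster's median marker profile is binarised at the
same global cuts and assigned to the population with the nearest
discrete-marker signature (normalised Hamming distance; ties prefer the most
specific — longest — signature, then declaration order; distance > 0.25
leaves the cluster Unidentified).  Continuous and unimodal markers are
excluded from signatures: they cannot be binarised reliably, which is exactly
why island topography cannot resolve populations split only by continuous
markers.  `k` defaults to **6x the population count**: k-means is
variance-greedy, so at 2x a 50%-abundance island absorbs many centroids and a
1%-abundance island can receive none (measured: basophils and eosinophils
vanish at k = 16 on a 20,000-cell cohort, while k = 48 recovers every
lineage at >= 99.9%); merging clusters by signature makes over-clustering
harmless.  Human-drawn polygon gates in embedding coordinates and imported
labelings (CSV) are supported for parity.

## Concordance statistics

Directional matching fractions per population (overlap / hand count and
overlap / embedding count); fractions with an empty denominator are reported
as null, never 0 or 1, to avoid inflating concordance for absent populations.
Frequencies are percentages of a chosen denominator (total events, CD45+
events, per donor and pooled aggregate — the aggregate row is computed from
pooled counts, not a mean of donors).  Cross-method correlation emits both
Pearson and Spearman coefficients; correlations over fewer than 3 units or
against a constant series are flagged not-computable.  Reproducibility across
embedding seeds is summarised as the maximum pairwise absolute frequency
difference per population.

## Scales, runtimes, and what green tests establish

Experiments default to desk scale on one CPU: the general-lineage comparison
runs at 20,000 cells (~4 min, dominated by Barnes-Hut t-SNE), the
deep-subsets comparison at 12,000 cells on the full template (~2 min), the
continuity study at 3 x 5,000 cells, and the reproducibility check at 3,000
cells x 3 seeds.  The 500,000-cell scale of a real 10-donor study is
configuration, not code.

The generator emulates component means, donor shifts and prevalences, but
not spillover, doublets, debris, acquisition drift or bead events; marker
noise is Gaussian and uncorrelated across markers within a population.
Green concordance tests therefore establish that the *analysis machinery*
reproduces the expected relationships (discrete lineages concordant at
>= 97%/93%, redundant-marker naive subsets >= 80%, continuously-split memory
subsets far below both, frequencies stable across embedding seeds) in a
world where ground truth is known — not that any particular real dataset
would meet those bounds.

## Known limitations

- The embedding-guided surrogate mechanises analyst judgement; it cannot
  model idiosyncratic human gate placement, only the marker-boundary logic.
- Exact t-SNE is not practical above a few thousand events; cross-backend
  agreement is checked on separability, not coordinates (t-SNE coordinates
  are only defined up to stochastic rearrangement).
- The FCS writer targets list-mode float data (the subset this package
  produces); it is not a general-purpose FCS library.
- With `theta` at the high end (0.8) rare-island placement degrades before
  aggregate frequencies do; the sweep harness exposes this but the package
  draws no automatic conclusion from it.
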