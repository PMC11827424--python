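# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tlsquant`, in the order the pipeline runs.

## Phenotype gating

Cells arrive with boolean positivity calls for CD20, CD3, CD8, Foxp3 and
Ki-67 (DAPI positivity is implicit in the cell's existence). The gate is
a fixed decision order over the 32 marker combinations:

| gate | definition | note |
|---|---|---|
| CD8 T | CD3⁺ CD8⁺ | Foxp3 ignored (CD3⁺CD8⁺Foxp3⁺ → CD8 T) |
| Foxp3⁺ CD4 | CD3⁺ CD8⁻ Foxp3⁺ | often called Treg, though Foxp3⁺ ≠ suppressive |
| Foxp3⁻ CD4 | CD3⁺ CD8⁻ Foxp3⁻ | CD4 itself is not in the panel; CD3⁺CD8⁻ is read as CD4 |
| B | CD20⁺ CD3⁻ | CD20⁺CD3⁺ double positives fall through to the T gates |
| undefined | everything else | carries no Ki-67 stratum |

The four lymphocyte subsets are each split by Ki-67, giving nine mutually
exclusive, exhaustive classes; the partition property is checked by
enumeration in the tests. The gate order is recorded in the run manifest
because CD20⁺CD3⁺ handling is a genuine design choice: we follow the
B-cell definition's explicit CD3⁻ requirement, so such cells are typed by
their T-cell markers.

## Aggregate detection

Lymphoid aggregates are detected by density clustering (DBSCAN via
scikit-learn) over the positions of **all four lymphocyte subsets
jointly** — a TLS sectioned through its T zone contains few or no B cells,
so B-only detection would miss real domains. Parameters
(`ClusteringParams`, all config-exposed, never hard-coded):

* `neighbour_radius_um = 30` and `min_neighbours = 10` (the cell itself
  counts): a core cell sits in aggregate-level packing. Dense lymphoid
  tissue has ~10 µm nearest-neighbour spacing (0.01 cells/µm²), giving
  ~28 neighbours per 30 µm disc in a follicle interior, while scattered
  background lymphocytes contribute <1 — the threshold separates the two
  regimes with a wide margin.
* Cells are processed in ascending `cell_id` order, so border cells
  attach to the first core cluster reached in that order; the result is
  invariant to input row order.

### Strand merging

Aggregates lying close together and joined by thin strands of lymphocytes
are cross-sections of one multi-lobular structure and are counted as one.
Operationally: build the ε′-graph (`strand_link_radius_um = 40`) over
unclustered (noise) lymphocytes; any noise component of at least
`strand_min_path_cells = 5` cells that lies within ε′ of members of two
or more clusters fuses those clusters. Merging is transitive; merged
membership is the union of the original member sets (strand cells are
*not* added), so the clustered-cell count is conserved. The 5-cell floor
stops two or three stray cells from fusing genuinely separate domains.
Both detection and merging are verified against independently coded
brute-force graph oracles on hundreds of random instances.

### Polygonisation

Each cluster is polygonised with an alpha shape: the union of Delaunay
triangles with circumradius ≤ `hull_alpha_um = 50`. At ~10 µm packing this
closes the hull without bridging concavities, and for convex point sets
with large α it reduces to the convex hull. Any member point left
uncovered (possible only at very small α) is patched in with a 1 µm disc,
so the polygon always covers all members. Fewer than three cells, or a
collinear set, is flagged degenerate with zero area. Merged multi-lobe
clusters may polygonise to a MultiPolygon; all downstream area and
point-in-polygon operations handle that transparently. On 2 000 uniform
points in a 100 µm-radius disc the alpha area lands within a few percent
of the true disc (boundary scalloping biases it slightly low); tests
enforce a 10 % band.

## TLS qualification

An aggregate qualifies as a TLS domain iff it holds **≥250 cells** in
total of which **strictly >50 %** are lymphocytes. Composition counts
every cell whose centroid falls inside or on the aggregate boundary —
including marker-negative (undefined) cells — because the lymphocyte
fraction is read as a fraction of *all* cells in the aggregate; whether
the size threshold counts all cells or lymphocytes only is ambiguous in
general usage, so the all-cells reading is the default and both
thresholds are config-overridable. Strictness is exactly as stated: ≥ for
size, > for the fraction (250 cells at 51.2 % qualifies; 249 cells never
do). Rejections carry machine-readable reasons and are kept in the domain
table.

## Metrics

* **Ki-67 fraction** per subset: Ki-67⁺ count / subset count, NaN when
  the subset is absent (a sentinel, never an exception).
* **Composition fractions**: each of the 8 lymphocyte classes over the
  lymphocyte total; undefined cells are excluded from this denominator.
* **Pooling** (whole-section route): element-wise integer sum of domain
  counts; the pooled Ki-67 fraction therefore equals the count-weighted
  mean of per-domain fractions — an exact identity the tests check to
  1e-12.
* **Per-domain means** are unweighted (one vote per domain), which is the
  canonical ranking measure; the pooled measure weights by cell count.
  The two disagree exactly when domain sizes and activities are coupled.
* **Areas**: total TLS area is the area of the union of domain polygons
  (overlaps counted once), clipped to the tissue union so fractions are
  ≤1 by construction; tumour area is likewise clipped. With no tissue
  annotation, tissue area is estimated by grid occupancy (50 µm tiles
  containing ≥1 cell); this needs a cell density high enough that
  occupied tissue tiles rarely stay empty, so with <100 cells the tissue
  area is reported missing and fractions are NaN. Total TLS area sums
  qualified domains only; sub-threshold aggregates are excluded.

## Statistics

* **Spearman ρ** is computed as the Pearson correlation of average ranks
  (ties handled by mid-ranks) — cross-checked in the tests against an
  independent implementation. ρ is invariant under strictly monotone
  transforms of either axis, so the log10 scaling used for scatterplot
  display never changes ρ; zeros are displayed with a half-minimum offset
  but never dropped.
* **p-values** are two-sided: the t approximation
  t = ρ√((n−2)/(1−ρ²)) for n ≥ 10, exact enumeration of all n!
  permutations below that. The tests compare both regimes against a
  Monte-Carlo permutation oracle.
* **Correlation filter**: domains with fewer than 50 lymphocytes are
  removed from correlation analyses only (never from rankings or areas),
  so each point rests on an adequate denominator. "50 cells of the
  assessed phenotypes" is read as 50 lymphocytes; the threshold is
  config-exposed.
* **Foxp3⁺ presence analysis**: x = (Ki-67⁻ Foxp3⁺ CD4 count)/lymphocyte
  count per domain, correlated against the Ki-67⁺ fraction of B, Foxp3⁻
  CD4 and CD8 T cells.
* **Clustering caveat**: per-domain points are clustered within patients;
  p-values assume independence. A mixed-model treatment is deliberately
  out of scope (it is an off-the-shelf fit, not part of this package);
  every per-domain correlation result carries the caveat string in its
  output metadata.
* **Rankings** are descending in the B-cell Ki-67 measure with ties (and
  undefined measures, placed last) broken by patient id, making them
  deterministic. Concordance reports rank-ρ, the Spearman footrule, and
  top-k overlap (k = 8 by default).

## Synthetic cohort generator

The generator produces the statistical and spatial structure the analysis
assumes, with exact bookkept truth. Defaults describe a 22-patient
colorectal-cancer-like cohort, one 10×10 mm section each:

| parameter | default | rationale |
|---|---|---|
| domains/section | uniform 4–100 | observed spread of per-section TLS counts |
| domain radius | 80–180 µm | typical follicle cross-sections |
| lymphocyte density in domain | 0.01 /µm² | ~10 µm packing |
| undefined fraction in domain | 0.25 | stromal/other cells inside aggregates |
| background cell density | 0.0005 /µm² (20 % lymphocytes) | scattered infiltrate + parenchyma at point-pattern resolution |
| lobularity | 1.6 expected lobes | multi-lobular 3-D structure sectioned |
| strand probability | 0.35 | chance an extra lobe attaches by a strand rather than overlap |
| strand gaps | 200–280 µm, cells every 15 µm | see below |
| inter-domain separation | ≥400 µm | keeps planted domains resolvable and strand corridors unambiguous |
| composition Dirichlet | (8, 4, 5, 2) over B/CD8/CD4conv/Treg | B-dominant follicles with variable T content |
| Ki-67 base logits | B −1.0, CD8 −2.0, CD4conv −1.8, Treg −1.6 | baseline proliferation ordering |
| latent activation SD | 1.0 (logit) | between-patient spread; drives cross-subset correlation |
| GC hotspot | p=0.35, +2.5 logit, 0.45·r | germinal-centre-like proliferating B core |
| suppression coefficient | 0 | no planted Treg suppression under the null |

Per-cell Ki-67 is Bernoulli with
`p = logistic(base[subset] + activation − suppression·treg_presence)`;
B cells inside a GC hotspot get the boost added. Under these settings
per-section TLS area fractions land in the fraction-of-a-percent to
several-percent range and per-domain B Ki-67⁺ fractions span from near 0
to above 0.9 across a cohort.

Geometric consistency is engineered, not hoped for: strand gaps must be
long enough that, after DBSCAN's density-reachability creeps ~50 µm along
each end of a strand (absorbing those cells as cluster members), at least
5 unclustered cells remain to satisfy the merge rule — hence the
200–280 µm gap range; strand corridors are placed to keep ≥60 µm clear of
every other lobe, and inter-domain separation (400 µm) exceeds the
maximum corridor reach plus the link radius, so a strand can never touch
a foreign domain. Background cells falling inside a planted polygon are
credited to that domain's truth; strand cells lie outside all polygons by
construction. A point-in-polygon recount of the emitted cells therefore
reproduces the truth counts exactly, and marker calls are written *from*
the intended labels so the phenotype gate inverts them with zero error.

Randomness: one integer master seed; per-patient activations come from a
stream keyed (seed, 0) and each section from (seed, section index), so
cohorts are reproducible and sections independent.

`sample_cohort_compositions` is a composition-level twin of the spatial
generator: it draws the same per-domain count distributions (Poisson cell
counts on an approximated lobe area, Dirichlet-multinomial composition,
logistic Ki-67 with the GC boost as a binomial mixture) without placing
any cells. It is used for statistical studies needing many replicate
cohorts; it approximates lobe-overlap area with a fixed 0.75 factor and
omits the small contribution of background cells inside domains (~1 % of
domain cells), which is irrelevant to the rank/correlation behaviour it
serves.

### What the generator does not emulate

No pixels, no segmentation error, no marker-thresholding noise or
spillover (marker calls are exact by construction), no spatially
structured stroma or epithelium (undefined cells are uniform), no HEV,
FDC or myeloid populations, no tumour-TLS interaction. Passing tests
demonstrate that the pipeline's algorithms are correct on data satisfying
its stated assumptions — not that those assumptions hold for any given
imaging platform's output.

## Problem sizes used by the tests and the acceptance script

The test suite exercises full study-scale conditions once (a 22-patient
cohort at the defaults above, ~1 100 domains and ~2.5 M cells, streamed
section by section) for parameter-recovery checks; determinism,
pipeline-contract and CLI tests use compact cohorts (3–4 patients, 3–8
domains per 4×4 mm section), and the replicate-heavy statistical checks
(200 null replicates for p-value uniformity; 50 cohorts for ranking
concordance) run on the composition-level twin. `scripts/acceptance.py`
runs the full spatial pipeline on the complete default cohort.

## Known limitations

* Detection parameters are design defaults tied to the generator's
  packing assumptions; real exports with different cell densities need
  them re-tuned (they are all CLI/config exposed and recorded in the
  manifest).
* Alpha-shape areas of sampled regions are biased slightly low at the
  boundary (a sub-percent to few-percent effect at default densities);
  detected compositions are correspondingly a few cells smaller than
  planted truth at domain rims.
* Coordinate units are assumed µm unless `unit_scale` is given; the
  assumption is flagged in the manifest.
* Per-domain correlation p-values ignore within-patient clustering (see
  above); whole-section correlations, with one point per section, do not
  have this problem.
* Tissue-area estimation from cells alone is a coarse occupancy measure;
  supply tissue polygons whenever available.
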