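# Methods

## Overview

`gbstruct` analyzes the spatial architecture of tumors from *typed cell
maps*: tables of cells with µm-scale (x, y) coordinates and categorical
cell-type labels, the standard output of decoded in-situ sequencing after
segmentation and probabilistic cell typing. The pipeline answers four
questions about each cohort: which recurrent cellular niches exist, how
organized each tumor section is (Tumor Structure Score), how vasculature
relates to that organization, and whether a gene signature tied to
organization stratifies survival.

## Neighbor graphs

Two graphs are built per sample and both are exposed:

* a **radius graph** linking cells at Euclidean distance ≤ 40 µm
  (boundary inclusive — deterministic and the common convention);
* a **k-nearest-neighbor graph** with k = 15, symmetrized by union, with
  distance ties broken toward the smaller cell id so gridded synthetic
  data yield reproducible graphs.

By default enrichment runs on the radius graph and niche composition /
refinement on the 15-NN graph. Either pairing can be swapped in the
configuration; results in this package's own analyses use the default.
Graphs are invariant under rigid transforms of the coordinates, a tested
property.

## Neighborhood enrichment and the Tumor Structure Score

For types a, b the observed statistic is the number of undirected edges
with endpoint types {a, b}, each edge counted once. The null permutes the
type labels uniformly over cells (graph fixed, type frequencies
preserved), by default 1000 times, and

    z(a, b) = (observed − mean_perm) / sd_perm,   z := 0 where sd_perm = 0.

The sd = 0 guard covers absent types, single-type samples and tiny
graphs, and keeps degenerate pairs from propagating infinities. 1000
permutations hold the Monte-Carlo error of z near ±0.1 at typical edge
counts; the permutation estimator is checked against exhaustive
enumeration on a 6-node path in the tests.

The **TSS** of a sample is the mean of |z| over unordered type pairs. The
diagonal (self-enrichment) is included by default so self-organization
contributes; `include_diagonal=False` restores the off-diagonal-only
variant. Because this choice — and the annotation level of the labels —
shifts absolute TSS values, TSS is compared *within* a cohort only, never
across studies. Samples are split highly/lowly structured at the cohort
median (strictly above → high; ties go low), a parameter-free rule.

Cohort-level (per-class) enrichment sums observed counts over member
samples and applies the permutation null within each sample before
summing, so pooled z-scores retain the within-sample null. Per-sample
permutation streams are derived by hashing (seed, sample_id), which makes
results independent of sample processing order.

## Niche identification

Each cell's microenvironment is its neighbors' type frequency vector
(focal cell excluded; isolated cells carry a zero row and a flag).
Composition vectors from all samples are pooled, sorted by (sample_id,
cell_id), and clustered jointly by k-means (k = 7 by default, 10 seeded
restarts, best inertia). Pooled fitting — rather than per-sample
clustering plus matching — gives shared niche identities across samples
by construction. Isolated cells inherit the label of the nearest
non-isolated cell in their sample.

Labels are then **spatially refined** by synchronous majority vote over
each cell's 15-NN neighbors, iterated until fewer than 0.1% of labels
change (max 10 iterations). The focal cell's current label votes with
weight 5 (about a third of the neighborhood): plain neighbor majority
acts like curvature flow and erodes thin but genuine structures such as
vessel strands, measurably *decreasing* agreement with planted labels on
ordered synthetic tissue, while the self-weight removes that bias and
still cleans scattered misassignments. The weight is exposed
(`self_weight`). Refinement can only reuse existing labels, never create
new ones.

Niche naming is a post-hoc annotation: observed niche profiles are
matched one-to-one (Hungarian algorithm, cosine similarity) against a
reference profile table; no computation depends on the names.

## Vessels

Vessels are endothelial and mural cells tightly connected in space:
single-linkage connected components at ε = 30 µm (cell-diameter scale)
over the vascular-type cells, keeping components with ≥ 5 cells. Both
thresholds are configuration values, as is the "large vessel" cutoff
(≥ 50 cells) and the definition of percent-vessel (cells in vessel
components over all cells, by default; over vascular cells via a flag).
Because the connectivity rule and size conventions have no canonical
values, absolute vessel counts are validated only on constructed
fixtures, and the high-vs-low-structure contrasts (Welch t-tests) are the
quantities of interest. Distance-to-vessel maps report each cell's
distance to the nearest vessel member, floored to 10 µm bins and capped
at 150 µm; cells whose raw distance exceeds the cap carry the cap value
and an over-cap flag.

## Structure signature and survival

Per-gene sample means are computed after library-size scaling to the
median cell total and log1p (configurable). Pearson r between those
means and the TSS across samples defines the signature: genes with
r strictly above 0.6 are selected; the reporting table additionally lists
genes with r > 0.5 or r < −0.4. Genes constant across samples are flagged
undefined and excluded.

Patients are scored by the mean z-scored expression of signature genes
and median-split (ties low, the same rule as the structure classes).
Survival is compared by Kaplan–Meier curves with plain Greenwood 95%
intervals, the two-group log-rank test, and a Cox proportional-hazards
model with Efron tie handling, adjusted for age, sex and MGMT status
(estimation delegated to lifelines; tests pin the estimates to long-hand
product-limit, per-event-time, and grid-search partial-likelihood
oracles). Non-convergence raises with the optimizer's diagnostics;
complete separation — which genuinely occurs at 13 patients when the
group effect is strong — is surfaced rather than hidden.

## Synthetic cohorts

The generator produces the study conditions every stage is tested under.
One sample is a square canvas (default 1000 µm at 10⁴ cells, ≈10⁴
cells/mm², cell-diameter-scale spacing; section sizes of 10⁴–10⁵ cells
are realistic for targeted in-situ panels) carrying seven planted niche
territories:

* four interior niches (proliferative, non-hypoxia-reliant,
  hypoxia-responsive, immune-interwoven) as Voronoi territories of 2
  seeded centers each;
* a peripheral band (140 µm) along the section border, oligodendrocyte /
  neuron / astrocyte dominated;
* vascular and perivascular bands (30 µm and 80 µm) around 2 curvilinear
  vessel strands, laid as random-walk polylines carrying endothelial
  cells every 20 µm with mural flanks.

Band widths were chosen once so that planted territories are coherent at
the 15-NN neighborhood scale (~25 µm at default density) while keeping
the global endothelial+mural fraction below ~10% — wider endo/mural-rich
bands would let fully shuffled labels percolate into spurious ε = 30 µm
components and destroy the planted vessel–structure contrast.

Cell types are drawn per niche from template composition vectors. The
vectors are illustrative defaults (each niche dominated by its
characteristic types with minority admixture), not estimates of any real
tissue.

**Disorder.** A single parameter λ ∈ [0, 1] resamples each cell's label
from the global type frequency with probability λ. Label resampling —
rather than coordinate jitter — holds cell density constant while
organization varies, isolating exactly what the TSS measures. At λ = 1
labels are spatially iid; at λ = 0 the planted architecture is intact.

**Expression.** Counts are Poisson with per-(type, gene) log-normal
baseline rates (209 genes by default, mirroring a targeted panel). Ten
*structure genes* have a type-independent baseline multiplied by
0.3 + 1.5·(1 − λ), so their expected sample means decrease linearly in
disorder; null genes do not depend on λ (and the global type frequency is
λ-invariant by construction, so they cannot track structure through
composition shifts).

**Survival.** Each sample doubles as a patient whose planted structure
score is the standardized (1 − λ). Event times are exponential with
hazard h₀·exp(β·score + 0.02·(age − 60) − 0.3·MGMT-methylated), h₀ =
ln 2 / 365 per day (median ≈ 1 year at score 0), β = 0.7 by default.
Censoring is independent uniform over a 5-year follow-up window, giving
≈ 20% censoring.

**What the generator does not emulate:** transcript-level in-situ noise
(optical crowding, probe efficiency), segmentation errors, 3D tissue,
realistic niche composition estimates, or inter-patient heterogeneity
beyond the disorder axis. Passing tests therefore demonstrate that the
algorithms recover planted structure under the stated model, not that the
biological conclusions transfer to any particular real dataset.

## Numerical and reproducibility choices

* All randomized stages draw seeds by SHA-256 hashing of
  (master seed, stage, sample_id), below 2³¹, so per-sample streams do
  not depend on processing order and reruns are byte-identical (CSV
  writers use a fixed float format).
* k-means uses 10 restarts with a seeded generator; pooled rows are
  sorted before fitting so clustering is invariant to sample ordering.
* Permutation sd uses the population convention (ddof 0); z is defined 0
  where sd is 0.
* Median splits send exact ties to "low" everywhere (structure classes
  and patient scores).
* Degenerate inputs: single-type samples yield all-zero z with a warning
  (not an error); empty vessel sets yield all-over-cap distance maps;
  empty niches are dropped with renumbering and a warning; an empty
  signature warns and skips the survival stage.

## Problem sizes used in the test and acceptance runs

The shipped analyses and acceptance checks run the default 13-sample ×
10⁴-cell cohort for niche recovery, TSS ordering (10 seeds × 3 disorder
levels) and recovery quality; signature-recovery replicates (20 cohort
seeds) use 1 500-cell sections, which preserve the expression–disorder
coupling the check targets; survival parameter recovery uses 300-patient
cohorts over 50 seeds. These sizes are the package's own choices for its
reference analyses.

## Known limitations

* The TSS is a cohort-relative quantity; no attempt is made to compare
  absolute values across annotation levels or studies.
* Vessel detection has no lumen reconstruction or tracing; a dense
  non-vascular-free region of endothelial-typed cells would be called a
  vessel.
* The refinement fixed point is not unique; synchronous updates with the
  documented tie rule make the output deterministic but order-dependent
  schemes would differ near balanced boundaries.
* At very small cohort sizes (≲ 13 patients) the adjusted hazards model
  can separate completely; the package reports this instead of an
  estimate.
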