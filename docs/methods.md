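# Methods

This note documents the models, numerical choices and open design
decisions behind `metacazprof`, and what the synthetic-data tests do and
do not establish about real data.

## Annotation resolution

Each peptide maps to one or more catalog genes. Its taxonomic class is a
function of the *distinct genera* among those genes: one genus →
`unique`, two or more → `ambiguous` (the full genus set is recorded, not
just a pair), none → `unannotated`. Adding a redundant gene of an
already-present genus never changes the class. Functional (KEGG
ortholog) and CAZy annotations are unions over mapped genes; a peptide
whose genes span several (family, enzyme-name) combinations is counted
once under each.

Per-sample class summaries are computed over *detected* peptides only
(intensity > 0 in that sample), so the three taxon classes partition each
sample's detected peptide count exactly. Peptides detected in no sample
are dropped at load time with a logged count. Genus is the only
taxonomic rank handled; there is no fallback to family or phylum.

## Compositional treatment

MS intensities are relative, so all matrices are treated as per-sample
compositions. The centered log-ratio transform is applied per sample
column over features:

    clr(x)_d = ln(x_d + ε) − (1/D) Σ_k ln(x_k + ε).

Zeros (non-detections) are offset by a pseudocount ε. The default policy
is **half the smallest positive value of the whole matrix**, applied as
one global constant: a per-column ε would break cross-sample
comparability of a feature's log values. ε = 0 is available for strictly
positive data and recovers exact scale invariance (clr(c·x) = clr(x));
with a fixed global ε the transform is scale-invariant only up to the
pseudocount's relative size. Every CLR column sums to zero to 1e-9, and
an all-zero column is an error rather than silently imputed.

Whether per-sample total-intensity normalization is applied *before* CLR
is exposed as an option (`total_intensity_normalize`) and off by
default: CLR is itself per-sample scale-invariant, so the choice only
rescales the pseudocount, but both regimes can be exercised.

## Aggregation to enzyme entities

Peptide intensities are aggregated by **summation** to two layouts: the
enzyme matrix keyed by (taxon state, CAZy family, enzyme name), where the
taxon state is a genus, an explicit `ambiguous:A|B` set label, or
`unannotated`; and the genus–family matrix keyed by (genus, family)
pairs built **only from uniquely annotated peptides** — ambiguous
evidence is kept as separate rows in the first layout but never assigned
to a single genus in the second. A peptide spanning several entities
contributes its full intensity to each (the duplication count is
logged), so summed entity mass can exceed total peptide mass by design.

## Proportionality network

Feature association uses the symmetric proportionality coefficient on
CLR rows, ρ = 1 − var(a−b)/(var(a)+var(b)) = 2·cov(a,b)/(var(a)+var(b)),
with n−1 variances; the two closed forms agree to 1e-9 and are
property-tested. Zero-variance features make ρ undefined and their pairs
are dropped with a logged count. The network retains the **top K = 500
pairs by signed ρ** (most positive; a co-occurrence graph), with ties at
the cutoff broken by canonical node-name order so the result is
deterministic, and reports connected components. An optional permutation
screen (permuting one feature's sample order;
p = (1 + hits)/(1 + n_perm)) is provided but **off by default**: the
rank-based retention rule is the operational definition here, and no
specific significance criterion is claimed for it.

## Differential profiling

Donors are split at the cohort median relative abundance of a focal
genus (16S data, midpoint convention for even n; *high* means strictly
above). Peptide-level CLR values are compared with a moderated two-sample
t statistic: the pooled variance s² is shrunk toward the median peptide
variance s₀² with prior weight d₀ (default 3),

    s²_mod = (d₀·s₀² + d·s²) / (d₀ + d),   d = n₁ + n₂ − 2,

and t = Δmean / sqrt(s²_mod(1/n₁ + 1/n₂)) is referred to t(d₀ + d).
This is the simplest variance moderation consistent with peptide-level
roll-up inference; d₀ = 0 recovers the ordinary pooled t exactly, and the
null calibration of the default is verified empirically (entity-level
type-I error 0.05 ± 0.02 in the acceptance suite). Peptides detected in
fewer than two samples of either group are excluded (variance
undefined).

Peptide p-values are rolled up per enzyme entity through the Beta
order-statistic law of the median of n i.i.d. uniforms: with m the median
peptide p and a = (n+1)/2, the entity p is the Beta(a, a) CDF at m. The
law is exact for odd n, a symmetric-Beta approximation for even n, and
the identity for n = 1. The entity effect size is the median peptide
log-fold-change (robust to a minority of misbehaving peptides). Entity
p-values are adjusted by Benjamini–Hochberg step-up (statsmodels)
with monotonicity enforcement and capping at 1.

Profile discovery restricts the CLR enzyme matrix to entities passing
the FDR gate (0.01 default, 0.05 as the relaxed alternative), clusters
samples by Euclidean distance with complete linkage (configurable:
complete / average / ward; complete is the default of the heatmap tools
this style of analysis typically uses), and cuts the dendrogram at k = 2.
The cohort designs targeted here contrast one enzyme-profile group
against the rest, and no published cut rule exists for the heatmap-frame
alternative, so a two-cluster cut is the declared convention. The
profile-positive cluster is the one with the higher mean CLR over the
gated enzymes.

The shared-family analysis is pure set algebra over uniquely annotated
peptides: families(g) is the set of CAZy families seen in unique-genus
peptides of g; the report gives both repertoire sizes, their
intersection, and — within shared families — enzyme names observed for
both genera (*same*) versus only one (*different*). Ambiguous-genus
evidence is deliberately excluded from these counts.

## Ordination statistics

PCA is the feature-centered eigendecomposition of the sample covariance
(full SVD), with each component's sign fixed by making its
largest-magnitude loading positive; retaining all components reproduces
pairwise Aitchison distances to 1e-6. PERMANOVA uses

    SS_total = (1/N) Σ_{i<j} d²_ij,  SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
    F = (SS_between/(g−1)) / (SS_within/(N−g)),

one grouping factor only, on Euclidean-on-CLR (Aitchison) distances —
the distance consistent with the CLR treatment used everywhere else;
other distances are out of scope. The permutation null is sampled with
the (1 + hits)/(1 + n_perm) convention (999 permutations by default, the
minimum that can report p < 0.001), or enumerated exhaustively whenever
the number of distinct label vectors is ≤ 10,000 (then p is the exact
fraction of labelings, observed included, reaching the observed F).
SS_within = 0 yields an infinite F with p still defined by permutations.
The pseudo-F is cross-checked against scikit-bio's PERMANOVA in the test
suite.

The Mann–Whitney U test reports U = min(U_x, U_y) with midrank ties. For
pooled samples of at most 12 the two-sided p is computed by full
enumeration of group assignments over the midranked pooled values — this
stays exact under ties, which small diet-frequency samples (days/week
values) essentially always contain; larger samples use the normal
approximation with tie and continuity corrections.

## Synthetic cohort generator

The generator produces data with the statistical structure the analysis
assumes, plus the ground truth needed for recovery testing. Defaults
describe a 63-donor cohort.

**Community.** Donors are allocated deterministically (largest-remainder
rounding — stable fixtures) to three archetypes: 40%
*Bacteroides*-dominant, 13% *Prevotella*-high, 47% mixed (63 donors give
25 / 8 / 30), and each donor's genus composition is a Dirichlet draw from
archetype-specific concentrations over ten common gut genera. The
concentrations are set so the cohort-wide *Bacteroides* relative
abundance has median ≈ 0.35 with roughly a 0.05–0.65 range.

**Catalog.** The two focal genera receive CAZy family repertoires of 24
and 16 families with a declared overlap fraction of 21/34 ≈ 0.62
(realized exactly: |shared| = round(overlap × min size) = 10); the eight
other genera receive 12 families each, drawn freely from a realistic
family-name pool. Each family carries 2 enzymes (genes) per genus with
10 peptides per gene, plus 143 background (non-CAZy) genes per genus with
10 peptides each — ≈ 17,000 peptides in total. Of each annotated gene's
peptides, a fixed 70% also map to a homolog gene of a random other genus
(→ ambiguous), and 30% of genes per genus have their genus annotation
blanked (→ unannotated), giving a designed 21 / 49 / 30 unique /
ambiguous / unannotated peptide mix. Enzyme names within shared focal
families reuse a common name for 23% of slots so the same-vs-different
enzyme comparison has both kinds. The focal repertoires are intentionally
*smaller* than a full catalog would give: with the fixed top-500 edge
retention, planted cluster recovery (every planted node inside one
network component) is only structurally possible when the within-cluster
pair sets fit inside the edge budget, so the generator plants clusters
scaled to the network rule it is meant to exercise.

**Intensities.** A detected peptide's log-intensity is
base + coupling·ln(a_gs) + gene effect + boost + N(0, σ): base 20 (natural
log of a typical DIA intensity), coupling 1.0 (protein yield proportional
to organism abundance), per-gene expression effects N(0, 0.8²), noise
σ = 1.0, and a planted boost of 2.0 log units on focal-genus CAZy
peptides in donors of the matching archetype. Detection is Bernoulli with
logistic probability in the true log-intensity (midpoint 15.58, scale
1.5) — intensity-dependent missingness typical of DIA without modeling
the instrument. These defaults were calibrated once so that per-sample
detected peptide counts fall in the 5,415–17,904 range with median near
11,868 and per-sample annotation-class fractions fall inside the
14.6–27.5% / 38.5–59.0% / 13.8–43.2% windows for ≥ 90% of samples.

**Diet.** Each donor gets an index-of-diet-quality score and days-per-week
frequencies for whole grains, vegetables and fruits-and-berries:
Gaussian around per-component locations (σ = 1.5), clipped to [0, 7]
(IDQ to [0, 15]). Per-archetype location shifts default to zero — a null
diet difference — and can be set to produce any planted contrast;
clipping at 7 preserves the median of a location-7 component exactly.

**Determinism.** Every simulation is a pure function of spec + seed; the
single pipeline seed fans out to stage seeds by fixed offsets so stages
rerun in isolation reproduce the chained run. Identical seeds give
byte-identical TSV outputs (floats written with 17 significant digits).

**What the generator does not emulate.** Real peptide sequences and
their physicochemical detectability, chromatographic or spectral
artifacts, shared peptides among more than two genera, phylogenetic
correlation between genera, strain-level variation, and
catalog-incompleteness biases. Passing recovery tests therefore shows
the pipeline correctly extracts the kinds of structure these analyses
assume (abundance-coupled, genus-linked enzyme expression with
compositional and dropout noise) — not that it would recover every
feature of a particular real cohort.

## Numerical conventions and degenerate inputs

* p-values are clipped to (tiny, 1]; zero p is never emitted.
* Median split with all samples tied, CLR of an all-zero column,
  PERMANOVA with one group, PCA of a constant matrix, and fewer than two
  FDR-passing enzymes for clustering are errors with explicit messages,
  not silent fallbacks.
* Tie-breaks (network edge cutoff, dendrogram input order, component
  ordering) are all fixed by canonical sorting, making every pipeline
  output order-invariant and reproducible.
* Scaled-down problem sizes used by the test and acceptance suites (20
  recovery seeds; 1,000-run null calibrations at 199 permutations;
  10,000-replicate roll-up check) were chosen as the smallest sizes at
  which the targeted error bands (± 0.02 around 0.05; KS < 0.05) are
  statistically meaningful.
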