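# metacazprof

Taxonomically resolved profiling of carbohydrate-active enzymes (CAZy) in
gut **metaproteomes**.

Gut bacteria compete for dietary glycans with repertoires of
carbohydrate-active enzymes — glycoside hydrolases (GH), polysaccharide
lyases (PL), carbohydrate esterases (CE) and relatives — and different
genera (notably *Bacteroides* and *Prevotella*) carry partially distinct
repertoires. Mass-spectrometry metaproteomics measures these enzymes as
peptide intensities, but each peptide may map to genes of one genus, of
several genera, or of none. `metacazprof` takes a peptide × sample
intensity table, a peptide → gene multi-map and a pre-annotated protein
catalog (genus, KEGG ortholog, CAZy family, enzyme name per gene), plus a
genus-level 16S relative-abundance table and donor diet records, and
produces taxon-resolved CAZy enzyme matrices, co-occurrence networks,
differential enzyme profiles and ordination statistics. It is aimed at
microbiome researchers analysing DIA metaproteomics of stool samples.

## Methods at the core

* **Annotation resolution.** A peptide is *unique* if its mapped genes
  name exactly one genus, *ambiguous* for two or more, *unannotated* for
  none; KEGG-ortholog and CAZy annotations are resolved as unions over
  mapped genes.
* **Compositional treatment.** Intensity matrices are column-wise
  centered-log-ratio transformed, `clr(x)_d = ln(x_d + ε) − (1/D) Σ_k
  ln(x_k + ε)`, with ε half the smallest positive matrix value by
  default. Sample distances on CLR data are Aitchison distances.
* **Co-occurrence.** Association between (genus, CAZy family) features is
  the symmetric proportionality coefficient
  `ρ = 1 − var(a−b)/(var(a)+var(b)) = 2 cov(a,b)/(var(a)+var(b))` on CLR
  rows; the network keeps the top-500 most positive pairs and reports
  connected components.
* **Differential profiles.** Donors are split at the cohort median
  relative abundance of a focal genus; peptides are tested with a
  variance-moderated t statistic (`s²_mod = (d₀s₀² + ds²)/(d₀+d)`, s₀² the
  median peptide variance); peptide p-values are rolled up to enzymes via
  the Beta order-statistic law of the median of n uniforms,
  `p_enzyme = I_m((n+1)/2, (n+1)/2)` with m the median peptide p; enzymes
  are gated by Benjamini–Hochberg FDR, and samples are clustered
  (Euclidean, complete linkage) into CAZy profiles.
* **Validation statistics.** PCA of CLR matrices; one-way PERMANOVA
  (`F = (SS_B/(g−1))/(SS_W/(N−g))` with a sampled or exhaustive
  permutation null); exact/asymptotic Mann–Whitney U tests for diet
  comparisons.
* **Synthetic cohorts.** A generator simulates Dirichlet community
  archetypes (Bacteroides-dominant, Prevotella-high, mixed), an annotated
  catalog with declared family-repertoire overlap, log-normal peptide
  intensities coupled to source-genus abundance with logistic detection
  dropout, and planted enzyme profiles, returning the ground truth for
  recovery tests.

## Worked example

```python
from metacazprof import (simulate_cohort, annotate_peptides, summarize_annotations,
    aggregate_genus_family, clr_transform, rho_pairs, build_network,
    aitchison_distance, permanova)
from metacazprof.differential import differential_profile_pipeline, shared_family_analysis

cohort = simulate_cohort(seed=1)
ann = annotate_peptides(cohort.table, cohort.catalog)
summ = summarize_annotations(cohort.table, cohort.catalog, ann)

gf_clr = clr_transform(aggregate_genus_family(cohort.table, cohort.catalog, ann))
net = build_network(rho_pairs(gf_clr), 500)

records, profile = differential_profile_pipeline(
    cohort.table, cohort.catalog, ann, cohort.abundance, "Prevotella")
rep = shared_family_analysis(ann, "Bacteroides", "Prevotella")

groups = {s: ("profile" if s in profile.positive else "other")
          for s in cohort.abundance.samples}
res = permanova(aitchison_distance(clr_transform(cohort.abundance.values)),
                groups, n_permutations=999, seed=7)

print(f"peptides/sample: median {int(summ['n_detected'].median())}, "
      f"range {int(summ['n_detected'].min())}-{int(summ['n_detected'].max())}")
print(f"unique-genus fraction: {summ['frac_unique'].mean():.1%} of detected peptides")
print(f"network: {len(net.edges)} edges, {len(net.components)} components, "
      f"largest component {len(net.components[0])} genus-family nodes")
print(f"enzymes at FDR<0.01: {(records['q'] < 0.01).sum()}; "
      f"profile-positive donors: {len(profile.positive)}")
print(f"CAZy families: {rep.n_families_a} Bacteroides, {rep.n_families_b} Prevotella, "
      f"{rep.n_shared} shared")
print(f"PERMANOVA (16S genus composition): pseudo-F {res.f_statistic:.1f}, p = {res.p_value:.3f}")
```

prints:

```
peptides/sample: median 11774, range 10177-12801
unique-genus fraction: 21.0% of detected peptides
network: 500 edges, 10 components, largest component 20 genus-family nodes
enzymes at FDR<0.01: 115; profile-positive donors: 17
CAZy families: 20 Bacteroides, 15 Prevotella, 8 shared
PERMANOVA (16S genus composition): pseudo-F 16.0, p = 0.001
```

Reading: each synthetic donor contributed 10–13 thousand detected
peptides, about a fifth uniquely attributable to one genus. The top-500
proportionality network separates genus-linked CAZy family clusters into
distinct components. Splitting donors at the median *Prevotella*
abundance yields 115 differentially expressed enzymes at FDR < 0.01,
whose expression isolates a profile-positive donor cluster; those donors
also differ significantly in overall 16S genus composition (PERMANOVA
p = 0.001 at 999 permutations).

The same pipeline runs from the shell:

```sh
metacazprof all --seed 1 --outdir results/run1
```

which writes every stage's TSV output plus a `manifest.json`, and the
individual `simulate`, `annotate`, `matrix`, `cooccur`, `diffexp`,
`shared-families`, `ordination`, `permanova` and `diet-test` subcommands
operate on the corresponding TSV files.

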