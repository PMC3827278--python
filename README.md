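# arrayphylo

Phylogenies of closely related species are often built from SNP-array
genotype calls — and the arrays that produce those calls were almost always
designed around variation discovered in a small, unrepresentative panel,
typically dominated by one focal taxon (a crop, a model organism, a
domesticate). That *ascertainment bias* distorts every downstream allele
frequency: the focal taxon shows an excess of intermediate-frequency
alleles, other species look monomorphic at most markers, and
between-species F<sub>ST</sub> values involving the focal taxon collapse
into a narrow intermediate band, misplacing it in distance-based trees.

`arrayphylo` implements, end to end, the comparison between two ways of
turning array data into species trees:

* **the genotype route** — QC filtering of calls (per-call GenCall and
  per-SNP GenTrain scores, missingness, MAF), windowed LD pruning for PCA,
  a codified PCA screen for curation errors, and weighted pairwise
  Weir–Cockerham F<sub>ST</sub>;
* **the intensity route** — the raw two-channel hybridization intensities
  (X for allele A, Y for allele B) used directly as *quantitative
  genotypes*: one of seven summaries (X, Y, X+Y, X/(X+Y), ln(X/(X+Y)),
  ln(Y/(X+Y)), ln(X/Y)) per call, per-species medians per SNP, and
  Euclidean distances between the resulting profiles — with no genotype
  filters, because intensity is informative even where the call is missing
  or monomorphic.

Both matrices feed neighbor joining (Saitou–Nei, deterministic
lexicographic tie-breaking), outgroup rooting, classical MDS, Mantel
permutation tests, and the Penny–Hendy (Robinson–Foulds) topology
distance. A synthetic-data generator reproduces the relevant statistical
structure — discovery-panel ascertainment, Balding–Nichols drift, and
divergence-dependent probe-affinity loss through shared-by-descent
off-target variants — so every claim is testable against a known species
tree without any external dataset.

## The core statistics

For a pair of taxa with per-locus sample sizes n₁, n₂, allele-B frequencies
p₁, p₂ and heterozygote proportions h₁, h₂, the Weir–Cockerham variance
components a (among populations), b (among individuals within populations)
and c (within individuals) are computed per locus, and the weighted
estimate across loci is the ratio of sums

  θ = Σ<sub>l</sub> a<sub>l</sub> / Σ<sub>l</sub> (a<sub>l</sub> + b<sub>l</sub> + c<sub>l</sub>),

with loci monomorphic in both taxa contributing nothing. The intensity
route's default summary is ln(X/Y); the topology distance between two
trees is the size of the symmetric difference of their non-trivial
bipartition sets (twice the number of internal branches resolved
differently, for binary trees).

## Worked example

`examples/two_routes_one_dataset.py` simulates one dataset at the default
study conditions (12 taxa, 20 diploids each, 2000 candidate SNPs
ascertained through an 11-focal + 6-relatives discovery panel, probe
affinity decaying with divergence) and builds both trees:

```
topology distance to the true tree: genotype route = 2, intensity route = 0

focal sister group, genotype route : ['sp02', 'sp03']
focal sister group, intensity route: ['sp01', 'sp02', 'sp03']
focal sister group, truth          : ['sp01', 'sp02', 'sp03']
```

The genotype route resolves one internal branch wrongly — the focal
taxon's attachment — while the intensity route reconstructs the tree
exactly. `examples/replicate_experiment.py` repeats this over 15 fresh
replicates:

```
ascertained regime (focal-dominated panel, affinity decay on):
  mean RF to truth: genotype 2.40, intensity 0.40; sign-test p = 0.0004883
  focal placed correctly: genotype 7%, intensity 100%
```

and `examples/bias_diagnostics.py` prints the bias signatures themselves
(shared-monomorphic counts 42 vs 638 for focal vs other pairs;
focal-involving F<sub>ST</sub> compressed to [0.54, 0.63] against [0.72,
0.94] elsewhere).

There is also a thin CLI (`arrayphylo simulate | qc | gdist | idist |
tree | compare | run | experiment`) for shell use; `arrayphylo run
--outdir out` executes the whole pipeline and writes every artifact
(filter report, both distance matrices in PHYLIP square format, both
rooted newick trees, Mantel result, MDS/PCA coordinates, MAF spectra,
shared-monomorphic table, elevation statistic, topology-distance table,
run manifest).

## Layout

```
src/arrayphylo/
  io.py         final report / manifest / species map / PHYLIP matrices
  sim.py        the ascertained-array generator (trees, drift, panel, intensities)
  qc.py         filter chain, LD pruning, PCA, curation screen
  genotype.py   allele stats, MAF spectra, shared-monomorphic, Weir-Cockerham F_ST
  intensity.py  quantitative-genotype summaries, median profiles, distances
  trees.py      neighbor joining, rooting, bipartitions, topology distance
  compare.py    Mantel test, classical MDS, elevation diagnostic
  pipeline.py   orchestration and the replicate experiment
  cli.py        thin command-line layer
docs/methods.md the model, its parameters and its limitations
examples/       narrative scripts, one per capability
```
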