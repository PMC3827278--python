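# Methods

## What the generator models

The synthetic datasets emulate a genotyping array designed for one focal
taxon and then applied across a genus. Three processes create the
structure the analyses probe:

**Allele-frequency drift.** Each candidate SNP starts from an ancestral
allele-B frequency drawn Uniform(0.05, 0.95) at the root of a known
species tree. Along a branch of length t the child frequency is drawn from
the Balding–Nichols law, Beta(p(1−F)/F, (1−p)(1−F)/F) with fixation index
F = 1 − exp(−t): mean p, variance p(1−p)F, so a zero-length branch copies
its parent and long branches drive frequencies to fixation. Frequencies
within 10⁻⁶ of a bound are absorbed. Branch lengths are therefore drift
units; a lineage with a large effective population size has a *short*
branch per unit of clock time.

**Discovery-panel ascertainment.** The array's SNPs are the candidates
whose minor allele frequency, in genotypes sampled for a 17-individual
panel (11 diploids from the focal taxon plus one from each of its six
closest relatives), reaches 0.10. Ascertainment operates on *sampled*
panel genotypes, not on the true frequencies, so panel size matters. This
single filter produces all three bias signatures at once: intermediate-MAF
excess in the focal taxon (≈63% of array SNPs at MAF ≥ 0.2 versus ≈4–5%
elsewhere at the defaults), a deficit of shared-monomorphic SNPs for
focal-involving pairs, and compression of focal-involving F_ST values into
a narrow band.

**Two-channel intensities.** For true dosage g (copies of allele B),

    X = max(ε₀, α·S·(2−g)/2 + b + N(0, σ²))
    Y = max(ε₀, α·S·g/2     + b + N(0, σ²))

where the probe affinity α = exp(−λ·d_s) decays with the taxon's tree-path
distance d_s from the focal taxon (whose sequence the probes match), and
is multiplied by (1−δ) wherever an off-target variant (OTV) affects that
(taxon, SNP). OTVs are mutations near the probe site: per SNP, each branch
on the focal→taxon path is hit with probability 1 − exp(−μ·t), and a taxon
carries the OTV if any branch on its path is hit. Marginally each taxon's
OTV probability is 1 − exp(−μ·d_s); jointly, OTVs are shared by descent,
which is what makes them phylogenetically informative — two taxa whose
paths from the focal taxon overlap share the same affinity losses. This
inheritance is essential: independent per-(taxon, SNP) events would add
pure noise to the intensity route rather than signal.

GenCall-like per-call scores are exp(−r/τ) with r the distance of the
observed (X, Y) from the nearest noise-free cluster centroid at the
sample's own affinity and τ = σ + ε₀; GenTrain-like per-SNP scores are
gap/(gap + 4σ) for the smallest gap between noise-free cluster centroids
at the cohort-mean affinity. Both live in [0, 1]. The intensity floor ε₀
is kept at 2σ so that a clean call's score almost never falls below the
0.2 masking threshold; a much smaller floor makes the score scale collapse
and the missingness filter then silently discards most SNPs.

## The default species tree

The default tree (`tree_model="radiation"`) mirrors the geometry in which
the genotype route's pathology appears in practice: an outgroup splitting
at the root; a focal lineage nested inside the ingroup on a drift-*short*
pendant (0.2 — a large-population domesticate retains its polymorphism);
and two crown clades whose topology is a pure-birth draw within a 0.9-deep
window, every crown tip extended by a long private stem so wild taxa have
drifted to near-fixation. Total height is 2.8, basal splits are spaced
0.15 apart, and crown internal branches are clamped to ≥ 0.12 so the true
topology is resolvable in principle. A plain pure-birth tree
(`tree_model="yule"`) and user-supplied newick remain available.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| n_species / samples_per_species | 12 / 20 | taxa and diploids per taxon |
| n_candidate_snps | 2000 | pre-ascertainment SNPs (~1100–1250 retained) |
| panel | 11 focal + 1×6 nearest | discovery panel, MAF ≥ 0.10 to retain |
| tree_height / crown_height / basal_gap | 2.8 / 0.9 / 0.15 | drift-unit geometry |
| focal_pendant / min_internal_branch | 0.2 / 0.12 | see above |
| λ (affinity_decay) | 0.5 | per drift unit of divergence from focal |
| μ (otv_rate) / δ (otv_penalty) | 0.15 / 0.9 | OTV mutations per drift unit; affinity loss per OTV |
| S / b / σ / ε₀ | 1.0 / 0.02 / 0.015 / 0.03 | signal, background, channel noise, floor |
| missing_rate | 0.02 | completely-at-random missing calls |
| QC thresholds | GenCall < 0.2 masks; GenTrain < 0.3, missing > 0.20, MAF < 0.05 drop | fixed rule order |

b and σ are small relative to S, as for normalized array channels; λ, μ
and δ were chosen so that probe-affinity loss is strong enough to register
in the intensities (α ranges ≈ 0.2–1 across taxa; OTVs hit ≈ 5–30% of
(taxon, SNP) pairs) without drowning the allelic signal — OTV rates much
above ~0.3 per drift unit make far-taxon OTV status essentially private
noise and degrade the intensity route's focal placement.

## Analysis choices

* **Filter order is fixed** (GenCall masking → GenTrain → missingness →
  MAF) because the order changes survivor counts; MAF is computed over the
  calls that survive masking. The intensity route applies *no* genotype
  filters — all array SNPs, all post-curation samples.
* **F_ST** is the two-level Weir–Cockerham estimator with ratio-of-sums
  weighting across loci; loci monomorphic in both taxa drop out (0/0).
  Negative θ estimates are retained in the reported matrix; before tree
  building, if any entry is negative the whole off-diagonal is shifted up
  by the minimum (logged), preserving order.
* **LD pruning** (window 10, step 3, r² > 0.5 on dosage correlation,
  remove the lower-MAF member, ties to the higher index, sweeps repeated
  to a fixed point) feeds only the PCA/curation screen, matching the
  practice of pruning for PCA but not for F_ST.
* **The curation screen** codifies the by-eye removal of mislabeled
  samples: in top-5 PC space a sample is flagged when the nearest taxon
  centroid is foreign *and* its own leave-one-out centroid is >1.5× as
  far. On planted 5% label swaps this yields recall ≥ 0.8 at a false-flag
  rate ≤ 0.02.
* **Neighbor joining** breaks Q-criterion ties lexicographically on the
  (smallest-leaf-label) pair, clamps negative branch lengths to zero with
  the deficit logged, and is invariant to input label order. On additive
  matrices it reproduces the generating topology and branch lengths
  exactly (checked to 10⁻⁸).
* **Mantel tests** are one-sided toward positive association with the
  add-one estimator p = (#{r_perm ≥ r_obs}+1)/(P+1), so p ≥ 1/(P+1); the
  permutation relabels the second matrix's rows and columns jointly and is
  reproducible from a seed.
* **The elevation diagnostic** rank-transforms both matrices'
  lower-triangle entries to [0, 1] and averages (intensity rank − genotype
  rank) over focal-involving pairs; ranks make the statistic scale-free
  across the two distance types.
* **Replicate experiment**: each replicate draws a fresh seed from the
  master seed, simulates, runs both routes, roots both trees on the taxon
  farthest from the focal taxon, and scores Robinson–Foulds distance to
  the truth; routes are compared by a two-sided paired sign test ignoring
  ties. Focal placement is "correct" when the focal taxon's sister group
  in the rooted tree matches the truth.

Problem sizes throughout (12 taxa, 20 samples/taxon, 2000 candidates, 50
replicates, 10⁴ Mantel permutations) keep a full pipeline run near one
second and the complete replicate experiment under half a minute on one
CPU.

## What the tests do and do not show

The generator reproduces the *statistical structure* of ascertained array
data, not its biology: SNPs are unlinked (LD pruning is exercised on
duplicated-SNP fixtures), there is no gene-tree discordance, hybridization
or introgression, sample sizes are balanced, and Illumina's normalization
and clustering algorithms are replaced by a transparent two-channel model
with model-based quality scores. Passing tests show that the pipeline's
estimators behave as designed under those conditions; they do not certify
behavior on real arrays with batch effects, allele-specific dropout or
unbalanced sampling.

Two honest limitations of the model family surfaced during its design and
are left visible rather than patched:

1. **The genotype route's focal misplacement does not switch off with
   ascertainment.** The ratio-of-sums F_ST estimator compresses the focal
   taxon's distances whenever it is polymorphic while other taxa are
   near-fixed, because same-allele-fixed loci contribute 0/0 and drop out.
   In this model that polymorphism contrast comes from the tree geometry
   (slow focal drift), so the no-bias control — full panel, λ = μ = 0 —
   still misplaces the focal taxon by the genotype route (mean RF ≈ 2.4
   versus ≈ 0.2 for the intensity route), rather than the two routes
   becoming statistically indistinguishable. The bias switches fully
   control the *intensity* route's behavior, and the elevation statistic
   drops from ≈ 0.85 to ≈ 0.3 when they are off, but the residual reflects
   the polymorphism contrast itself, not probe affinity, so it does not
   vanish.
2. **The X+Y summary is genotype-blind by construction.** In the linear
   channel model the total intensity is exactly α·S + 2b regardless of
   dosage, so the X+Y tree rests on affinity characters alone and can
   deviate from the allele-ratio trees by up to ~6 topology-distance
   units. The allele-ratio family — X/(X+Y), ln(X/(X+Y)), ln(Y/(X+Y)),
   ln(X/Y) — produces concordant topologies (pairwise distance ≤ 2 at the
   default conditions), and ln(X/Y) is the default reported statistic.

Relatedly, under the biased defaults the Mantel correlation between the
intensity-route and F_ST matrices is negative (the focal taxon's elevated
intensity distances dominate), so the pipeline reports that Mantel result
without asserting its sign.
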