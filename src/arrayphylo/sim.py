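"""Synthetic SNP-array data with discovery-panel ascertainment bias.

The generator emulates the statistical structure of genotyping-array data
collected across a genus when the array's SNPs were discovered in a small
panel dominated by one focal taxon:

* a known species tree — user newick, a pure-birth draw, or the default
  "radiation" shape (outgroup, a slowly drifting focal lineage nested in
  the crown, and stem-extended crown clades) — along whose branches
  per-SNP allele frequencies drift under the Balding–Nichols model with
  fixation index ``F = 1 - exp(-t)`` for a branch of length t;
* ascertainment: a candidate SNP is kept for the "array" only if its minor
  allele frequency in a sampled discovery panel (by default 11 diploids
  from the focal taxon plus one from each of six others) reaches a
  threshold — this is what produces the focal taxon's excess of
  intermediate-frequency alleles and the deficit of shared-monomorphic
  SNPs in focal-involving pairs;
* two-channel intensities: for true dosage g (count of B alleles),
  X = max(e0, a*S*(2-g)/2 + b + noise) and Y = max(e0, a*S*g/2 + b + noise)
  where the probe affinity a = exp(-lambda * d_s) decays with the taxon's
  tree distance d_s from the focal taxon and is further multiplied by
  (1 - delta) where an off-target variant (OTV) hit that (taxon, SNP).
  OTVs arise on branches of the focal->taxon path and are shared by
  descent, with marginal probability 1 - exp(-mu * d_s) per taxon.
  Divergence therefore leaves a
  signature in the intensities even at SNPs that are monomorphic in the
  genotype calls, which is the signal the intensity route exploits.

Per-call GenCall-like scores decay exponentially with the distance of the
observed (X, Y) point from the nearest noise-free cluster centroid;
per-SNP GenTrain-like scores measure cluster separation relative to the
channel noise.  Both live in [0, 1] like their namesakes, but are model
quantities, not re-derivations of Illumina's algorithms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import io as apio
from .datatypes import GenotypeTable, IntensityTable
from .trees import Tree

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "SimDataset",
    "generate_species_tree",
    "evolve_allele_frequencies",
    "ascertain_snps",
    "simulate_genotypes",
    "simulate_intensities",
    "simulate_dataset",
    "emit_dataset",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic array dataset.

    Defaults describe the standard ascertained regime used throughout the
    package: 12 species, 20 diploid samples each, 2000 candidate SNPs, a
    17-individual discovery panel dominated by the focal taxon, and
    divergence-dependent probe-affinity decay (lambda = 0.5).
    """

    n_species: int = 12
    samples_per_species: int | dict[str, int] = 20
    n_candidate_snps: int = 2000
    tree_newick: str | None = None
    tree_model: str = "radiation"  # "radiation", "yule", or newick via tree_newick
    birth_rate: float = 1.0
    tree_height: float = 2.8  # root-to-tip height (drift + divergence units)
    crown_height: float = 0.9  # window in which crown radiation splits occur
    basal_gap: float = 0.15  # spacing of the outgroup/clade/focal basal splits
    min_internal_branch: float = 0.12  # clamp for crown internal branches
    focal_pendant: float = 0.2  # focal lineage drifts slowly (large population)
    focal_taxon: str | None = None  # default: the tree model's designated focal leaf
    panel_composition: dict[str, int] | None = None  # default: 11 focal + 1 x 6 others
    panel_maf_min: float = 0.10
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    absorb_eps: float = 1e-6
    affinity_decay: float = 0.5  # lambda, per unit tree distance
    otv_rate: float = 0.15  # mu, OTV mutations per unit tree distance
    otv_penalty: float = 0.9  # delta, multiplicative affinity loss at an OTV
    signal: float = 1.0  # S, full-affinity single-channel signal
    background: float = 0.02  # b, channel background
    channel_noise: float = 0.015  # sigma
    intensity_floor: float = 0.03  # e0; ~2x channel_noise so GenCall-like scores are well scaled
    missing_rate: float = 0.02  # genotype-call missingness, completely at random
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("affinity_decay", "otv_rate", "channel_noise", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.otv_penalty <= 1.0):
            raise ValueError("otv_penalty must lie in [0, 1]")
        if self.intensity_floor <= 0 or self.signal <= 0 or self.background <= 0:
            raise ValueError("intensity_floor, signal and background must be positive")
        if not (0.0 <= self.panel_maf_min <= 0.5):
            raise ValueError("panel_maf_min must lie in [0, 0.5]")

    def samples_for(self, taxa: list[str]) -> dict[str, int]:
        if isinstance(self.samples_per_species, dict):
            return dict(self.samples_per_species)
        return {t: int(self.samples_per_species) for t in taxa}

    def panel_for(
        self, taxa: list[str], focal: str, divergence: dict[str, float] | None = None
    ) -> dict[str, int]:
        """Discovery-panel composition: 11 focal diploids plus one diploid
        from each of the six other taxa closest to the focal taxon (label
        order when no divergences are supplied)."""
        if self.panel_composition is not None:
            return dict(self.panel_composition)
        others = [t for t in taxa if t != focal]
        if divergence is not None:
            others.sort(key=lambda t: (divergence[t], t))
        else:
            others.sort()
        panel = {focal: 11}
        panel.update({t: 1 for t in others[:6]})
        return panel

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset."""

    tree: Tree
    species_frequencies: pd.DataFrame  # taxa x ascertained SNP ids, allele-B freq
    candidate_frequencies: pd.DataFrame  # taxa x all candidate SNP ids
    divergence: dict[str, float]  # tree path distance from the focal taxon
    ascertained: np.ndarray  # boolean mask over candidate SNPs
    focal_taxon: str
    otv_events: pd.DataFrame | None = None  # taxa x ascertained SNP ids, 0/1


@dataclass
class SimDataset:
    """A complete simulated dataset plus its ground truth."""

    truth: SimulationTruth
    genotypes: GenotypeTable
    intensities: IntensityTable
    true_dosage: pd.DataFrame
    species_map: dict[str, str]
    manifest: list
    config: SimConfig


def _rngs(cfg: SimConfig) -> dict[str, np.random.Generator]:
    """Named per-stage streams spawned from the master seed."""
    names = ("tree", "frequencies", "panel", "genotypes", "intensities")
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _yule_tree(n: int, birth_rate: float, height: float, rng: np.random.Generator) -> Tree:
    """Pure-birth tree with n leaves, rescaled to the requested root-to-tip height."""
    if n < 2:
        raise ValueError("need at least 2 species")
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root.new_child(), 0.0))
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(k)
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    labels = [f"sp{i + 1:02d}" for i in range(n)]
    for (node, birth), label in zip(active, labels):
        node.edge.length = t_end - birth
        taxon = dendropy.Taxon(label=label)
        taxa.add_taxon(taxon)
        node.taxon = taxon
    scale = height / t_end
    dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Tree(dtree, rooted=False)


def _yule_clade(
    k: int,
    birth_rate: float,
    height: float,
    stem: float,
    min_branch: float,
    rng: np.random.Generator,
) -> dendropy.Node:
    """Root node of a pure-birth clade of k unlabeled tips.

    Internal splits occur within ``height`` of the clade root (internal
    branches clamped up to ``min_branch``); every tip pendant is then
    extended by ``stem``, emulating lineages that radiated quickly and have
    drifted independently since.
    """
    if k == 1:
        leaf = dendropy.Node()
        leaf.edge.length = height + stem
        return leaf
    root = dendropy.Node()
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(root.new_child(), 0.0), (root.new_child(), 0.0)]
    while len(active) < k:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
    t_end = t + rng.exponential(1.0 / (birth_rate * k))
    scale = height / t_end
    for node, birth in active:
        node.edge.length = (t_end - birth) * scale + stem
    for nd in root.preorder_iter():
        if nd is root or nd.is_leaf():
            continue
        nd.edge.length = max(nd.edge.length * scale, min_branch)
    return root


def _radiation_tree(cfg: SimConfig, rng: np.random.Generator) -> Tree:
    """Default study-shaped tree: outgroup + deeply nested focal + crown clades.

    Shape (root at depth 0, tips near depth H = tree_height, g = basal_gap):

    * the outgroup splits at the root (pendant H);
    * the focal taxon splits at depth 2g and sits on a long pendant —
      an old lineage nested inside the radiation, sister to crown clade A;
    * crown clades A and B radiate within ``crown_height`` starting at
      depth 4g, and every crown tip is extended by a stem so crown taxa
      have drifted to near-fixation at most loci.

    The designated leaf labels are "outgroup", "focal" and "sp01"... .
    """
    n = cfg.n_species
    if n < 5:
        raise ValueError("the radiation tree model needs at least 5 species")
    g, H, hc = cfg.basal_gap, cfg.tree_height, cfg.crown_height
    stem = H - 4 * g - hc
    if stem <= 0:
        raise ValueError("tree_height too small for basal_gap and crown_height")
    n_crown = n - 2
    k_a = max(2, n_crown // 3)
    k_b = n_crown - k_a

    root = dendropy.Node()
    outgroup = root.new_child()
    outgroup.edge.length = H
    n1 = root.new_child()
    n1.edge.length = g
    n2 = n1.new_child()
    n2.edge.length = g
    clade_b = _yule_clade(k_b, cfg.birth_rate, hc, stem, cfg.min_internal_branch, rng)
    n1.add_child(clade_b)
    clade_b.edge.length = 3 * g
    focal = n2.new_child()
    focal.edge.length = cfg.focal_pendant
    clade_a = _yule_clade(k_a, cfg.birth_rate, hc, stem, cfg.min_internal_branch, rng)
    n2.add_child(clade_a)
    clade_a.edge.length = 2 * g

    taxa = dendropy.TaxonNamespace()
    outgroup.taxon = dendropy.Taxon(label="outgroup")
    focal.taxon = dendropy.Taxon(label="focal")
    crown_leaves = [nd for nd in clade_a.leaf_iter()] + [nd for nd in clade_b.leaf_iter()]
    for i, leaf in enumerate(crown_leaves):
        leaf.taxon = dendropy.Taxon(label=f"sp{i + 1:02d}")
    for leaf in (outgroup, focal, *crown_leaves):
        taxa.add_taxon(leaf.taxon)
    dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    return Tree(dtree, rooted=False)


def generate_species_tree(cfg: SimConfig) -> Tree:
    """The true species tree: user newick, the radiation model, or pure birth."""
    if cfg.tree_newick is not None:
        tree = Tree.from_newick(cfg.tree_newick)
        for edge in tree.dendropy_tree.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue
            if edge.length is None:
                raise ValueError("species tree newick must carry branch lengths on every edge")
            if edge.length <= 0:
                raise ValueError("species tree branch lengths must be positive")
        return tree
    if cfg.tree_model == "radiation":
        return _radiation_tree(cfg, _rngs(cfg)["tree"])
    if cfg.tree_model == "yule":
        return _yule_tree(cfg.n_species, cfg.birth_rate, cfg.tree_height, _rngs(cfg)["tree"])
    raise ValueError(f"unknown tree_model {cfg.tree_model!r}")


def unbiased_variant(cfg: SimConfig) -> SimConfig:
    """The no-bias control for ``cfg``: every taxon in the discovery panel,
    no probe-affinity decay and no off-target variants.  The tree, drift and
    sampling conditions are unchanged."""
    taxa = generate_species_tree(cfg).leaf_labels
    return dataclasses.replace(
        cfg,
        affinity_decay=0.0,
        otv_rate=0.0,
        panel_composition={t: 1 for t in taxa},
    )


def default_focal_taxon(cfg: SimConfig, taxa: list[str]) -> str:
    """The focal taxon: explicit config, the designated 'focal' leaf, else first leaf."""
    if cfg.focal_taxon:
        return cfg.focal_taxon
    if "focal" in taxa:
        return "focal"
    return taxa[0]


def evolve_allele_frequencies(
    tree: Tree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Drift per-SNP allele-B frequencies down the tree (Balding–Nichols).

    The root frequency of each SNP is Uniform(ancestral_low, ancestral_high).
    Along a branch of length t the child frequency is Beta(p(1-F)/F,
    (1-p)(1-F)/F) with F = 1 - exp(-t): mean p, variance p(1-p)F.  A zero-
    length branch copies the parent exactly; frequencies within absorb_eps
    of 0 or 1 are absorbed and stay fixed below that node.
    """
    if rng is None:
        rng = _rngs(cfg)["frequencies"]
    n_snps = cfg.n_candidate_snps
    eps = cfg.absorb_eps
    dtree = tree.dendropy_tree
    freqs: dict[int, np.ndarray] = {}
    root = dtree.seed_node
    freqs[id(root)] = rng.uniform(cfg.ancestral_low, cfg.ancestral_high, size=n_snps)
    out: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length
            if t is None or t <= 0:
                raise ValueError("every branch must have positive length for drift simulation")
            parent_p = freqs[id(node.parent_node)]
            F = 1.0 - np.exp(-t)
            p = parent_p.copy()
            seg = (p > eps) & (p < 1.0 - eps)
            if seg.any():
                ps = p[seg]
                shape = (1.0 - F) / F
                child = rng.beta(ps * shape, (1.0 - ps) * shape)
                child[child <= eps] = 0.0
                child[child >= 1.0 - eps] = 1.0
                p[seg] = child
            p[p <= eps] = 0.0
            p[p >= 1.0 - eps] = 1.0
            freqs[id(node)] = p
        if node.is_leaf():
            out[node.taxon.label] = freqs[id(node)]
    snp_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    return pd.DataFrame(out, index=snp_ids).T


def ascertain_snps(
    frequencies: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    divergence: dict[str, float] | None = None,
) -> np.ndarray:
    """Discovery-panel ascertainment mask over candidate SNPs.

    Panel genotypes are sampled (2 binomial draws per diploid) from the true
    taxon frequencies according to the panel composition; a SNP is retained
    iff the panel minor allele frequency reaches ``panel_maf_min``.
    """
    if rng is None:
        rng = _rngs(cfg)["panel"]
    taxa = list(frequencies.index)
    focal = default_focal_taxon(cfg, taxa)
    panel = cfg.panel_for(taxa, focal, divergence)
    unknown = set(panel) - set(taxa)
    if unknown:
        raise ValueError(f"panel taxa absent from the tree: {sorted(unknown)}")
    n_snps = frequencies.shape[1]
    b_count = np.zeros(n_snps, dtype=np.int64)
    n_alleles = 0
    for taxon in sorted(panel):
        count = panel[taxon]
        p = frequencies.loc[taxon].to_numpy(float)
        b_count += rng.binomial(2 * count, p)
        n_alleles += 2 * count
    maf = np.minimum(b_count, n_alleles - b_count) / n_alleles
    mask = maf >= cfg.panel_maf_min
    if not mask.any():
        raise ValueError(
            "no SNPs survived panel ascertainment; increase n_candidate_snps or panel size"
        )
    return mask


def simulate_genotypes(
    truth: SimulationTruth, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, pd.DataFrame, dict[str, str]]:
    """Sample diploid dosages at the ascertained SNPs.

    Returns the genotype table (missingness applied completely at random,
    GenCall scores provisionally 1.0 until intensities are simulated), the
    underlying true dosages (missing calls still have a true dosage, which
    drives their intensities), and the sample-to-taxon map.
    """
    if rng is None:
        rng = _rngs(cfg)["genotypes"]
    freqs = truth.species_frequencies
    taxa = list(freqs.index)
    per = cfg.samples_for(taxa)
    sample_ids: list[str] = []
    species_map: dict[str, str] = {}
    rows = []
    for taxon in taxa:
        p = freqs.loc[taxon].to_numpy(float)
        for k in range(per[taxon]):
            sid = f"{taxon}_s{k + 1:02d}"
            sample_ids.append(sid)
            species_map[sid] = taxon
            rows.append(rng.binomial(2, p))
    true_dosage = pd.DataFrame(
        np.array(rows, float), index=sample_ids, columns=freqs.columns
    )
    observed = true_dosage.to_numpy(float).copy()
    if cfg.missing_rate > 0:
        miss = rng.random(observed.shape) < cfg.missing_rate
        observed[miss] = np.nan
    dosage = pd.DataFrame(observed, index=sample_ids, columns=freqs.columns)
    gencall = pd.DataFrame(1.0, index=sample_ids, columns=freqs.columns)
    return GenotypeTable(dosage, gencall), true_dosage, species_map


def simulate_intensities(
    truth: SimulationTruth,
    true_dosage: pd.DataFrame,
    species_map: dict[str, str],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTable, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Two-channel intensities plus GenCall-like and GenTrain-like scores.

    Returns (intensities, per-call gencall scores, per-SNP gentrain scores,
    per-(taxon, SNP) OTV indicator).
    """
    if cfg.channel_noise < 0:
        raise ValueError("channel_noise must be nonnegative")
    if rng is None:
        rng = _rngs(cfg)["intensities"]
    S, b, sig, e0 = cfg.signal, cfg.background, cfg.channel_noise, cfg.intensity_floor
    taxa = list(truth.species_frequencies.index)
    snp_ids = list(true_dosage.columns)
    n_snps = len(snp_ids)

    d_s = np.array([truth.divergence[t] for t in taxa])
    # Off-target variants are mutations that arise on tree branches between
    # the probe's design taxon (the focal taxon) and each assayed taxon, so
    # they are shared by descent: each edge on a focal->taxon path is hit
    # with probability 1 - exp(-mu * t_edge) per SNP, and a taxon carries
    # the OTV if any edge on its path is hit.  Marginally this gives the
    # per-taxon probability 1 - exp(-mu * d_s).
    edge_lengths, edge_paths = truth.tree.edge_paths_from(truth.focal_taxon)
    p_edge = 1.0 - np.exp(-cfg.otv_rate * np.asarray(edge_lengths))
    hits = rng.random((len(edge_lengths), n_snps)) < p_edge[:, None]
    otv = np.zeros((len(taxa), n_snps))
    for ti, taxon in enumerate(taxa):
        path = edge_paths[taxon]
        if path:
            otv[ti] = hits[path].any(axis=0)
    alpha_taxon = np.exp(-cfg.affinity_decay * d_s)[:, None] * (1.0 - cfg.otv_penalty) ** otv

    taxon_index = {t: i for i, t in enumerate(taxa)}
    sample_taxon = np.array([taxon_index[species_map[s]] for s in true_dosage.index])
    alpha = alpha_taxon[sample_taxon, :]  # samples x snps
    g = true_dosage.to_numpy(float)

    mean_x = alpha * S * (2.0 - g) / 2.0 + b
    mean_y = alpha * S * g / 2.0 + b
    x = np.maximum(e0, mean_x + rng.normal(0.0, sig, size=g.shape))
    y = np.maximum(e0, mean_y + rng.normal(0.0, sig, size=g.shape))

    # GenCall-like: distance of (x, y) to the nearest noise-free centroid
    # (under the sample's own affinity), mapped through exp(-dist / tau).
    tau = sig + e0
    best = np.full(g.shape, np.inf)
    for gp in (0.0, 1.0, 2.0):
        cx = alpha * S * (2.0 - gp) / 2.0 + b
        cy = alpha * S * gp / 2.0 + b
        dist = np.hypot(x - cx, y - cy)
        best = np.minimum(best, dist)
    gencall = np.exp(-best / tau)

    # GenTrain-like: separation of the noise-free dosage clusters at the
    # sample-weighted mean affinity; adjacent clusters sit S*abar/sqrt(2)
    # apart, so the score is gap / (gap + 4 sigma) for the smallest gap.
    abar = alpha.mean(axis=0)
    gaps = np.stack(
        [
            np.hypot(abar * S / 2.0, abar * S / 2.0),  # 0 vs 1 and 1 vs 2
            np.hypot(abar * S, abar * S),  # 0 vs 2
        ]
    )
    gentrain = (gaps / (gaps + 4.0 * sig)).min(axis=0)

    intensities = IntensityTable(
        pd.DataFrame(x, index=true_dosage.index, columns=snp_ids),
        pd.DataFrame(y, index=true_dosage.index, columns=snp_ids),
    )
    gencall_df = pd.DataFrame(gencall, index=true_dosage.index, columns=snp_ids)
    gentrain_s = pd.Series(gentrain, index=snp_ids)
    otv_df = pd.DataFrame(otv, index=taxa, columns=snp_ids)
    return intensities, gencall_df, gentrain_s, otv_df


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Run the full generator: tree, drift, ascertainment, genotypes, intensities."""
    rngs = _rngs(cfg)
    tree = generate_species_tree(cfg)
    candidate = evolve_allele_frequencies(tree, cfg, rngs["frequencies"])
    taxa = list(candidate.index)
    focal = default_focal_taxon(cfg, taxa)
    if focal not in taxa:
        raise ValueError(f"focal taxon {focal!r} is not a leaf of the tree")
    divergence = tree.path_distances_from(focal)
    mask = ascertain_snps(candidate, cfg, rngs["panel"], divergence)
    truth = SimulationTruth(
        tree=tree,
        species_frequencies=candidate.loc[:, mask],
        candidate_frequencies=candidate,
        divergence=divergence,
        ascertained=mask,
        focal_taxon=focal,
    )
    genotypes, true_dosage, species_map = simulate_genotypes(truth, cfg, rngs["genotypes"])
    intensities, gencall, gentrain, otv = simulate_intensities(
        truth, true_dosage, species_map, cfg, rngs["intensities"]
    )
    truth.otv_events = otv
    genotypes = GenotypeTable(genotypes.dosage, gencall)
    manifest = [
        apio.SnpManifestRecord(
            snp_id=snp, gentrain=float(np.clip(gentrain[snp], 0.0, 1.0)), chrom="1",
            pos=1000 * (k + 1),
        )
        for k, snp in enumerate(truth.species_frequencies.columns)
    ]
    return SimDataset(
        truth=truth,
        genotypes=genotypes,
        intensities=intensities,
        true_dosage=true_dosage,
        species_map=species_map,
        manifest=manifest,
        config=cfg,
    )


def emit_dataset(ds: SimDataset, outdir, force: bool = False) -> dict[str, Path]:
    """Write the dataset to disk in the pipeline's on-disk formats.

    Emits the final report, SNP manifest, species map, the true tree as
    newick, a JSON truth record and the config as YAML.  Refuses to write
    into an existing non-empty directory unless ``force`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "final_report": outdir / "final_report.tsv",
        "manifest": outdir / "manifest.tsv",
        "species_map": outdir / "species_map.tsv",
        "true_tree": outdir / "true_tree.nwk",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    apio.write_final_report(ds.genotypes, ds.intensities, paths["final_report"])
    apio.write_snp_manifest(ds.manifest, paths["manifest"])
    apio.write_species_map(ds.species_map, paths["species_map"])
    paths["true_tree"].write_text(ds.truth.tree.to_newick() + "\n", encoding="utf-8")
    truth_record = {
        "focal_taxon": ds.truth.focal_taxon,
        "divergence": {k: float(v) for k, v in ds.truth.divergence.items()},
        "n_candidate_snps": int(ds.truth.ascertained.size),
        "n_ascertained": int(ds.truth.ascertained.sum()),
        "ascertained_ids": list(ds.truth.species_frequencies.columns),
        "species_frequencies": {
            t: [round(float(v), 6) for v in ds.truth.species_frequencies.loc[t]]
            for t in ds.truth.species_frequencies.index
        },
        "otv_events": {
            t: [int(v) for v in ds.truth.otv_events.loc[t]] for t in ds.truth.otv_events.index
        },
    }
    paths["truth"].write_text(json.dumps(truth_record, sort_keys=True), encoding="utf-8")
    ds.config.to_yaml(paths["config"])
    return paths
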