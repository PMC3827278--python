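"""End-to-end orchestration: simulate or load data, run both distance
routes, build trees, and compare them.

The two routes deliberately see different SNP sets: the genotype route
applies the QC filter chain (and, for PCA only, LD pruning), while the
intensity route uses every array SNP with no genotype filters — intensity
is informative even at SNPs whose calls are monomorphic or missing.

``run_replicate_experiment`` embodies the package's headline comparison:
over many simulated replicates of the ascertained regime, the tree built
from intensity distances is closer (Robinson–Foulds) to the true species
tree than the tree built from genotype-call F_ST distances.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from skbio import DistanceMatrix

from . import io as apio
from .compare import (
    classical_mds,
    focal_elevation_statistic,
    mantel_test,
    topology_distance_table,
)
from .datatypes import GenotypeTable, IntensityTable
from .genotype import (
    count_shared_monomorphic,
    maf_spectrum,
    pairwise_fst_matrix,
    shift_nonnegative,
    species_allele_stats,
)
from .intensity import SummaryStatKind, euclidean_species_distance, species_median_profiles
from .qc import apply_genotype_filters, flag_curation_errors, genotype_pca, ld_prune
from .sim import SimConfig, simulate_dataset
from .trees import Tree, neighbor_joining, root_with_outgroup, tree_topology_distance

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentResult",
    "genotype_route",
    "intensity_route",
    "run_pipeline",
    "run_replicate_experiment",
]


@dataclass
class ExperimentResult:
    """Per-replicate tree accuracies for both routes plus summary statistics."""

    replicates: pd.DataFrame  # seed, rf_genotype, rf_intensity, focal flags
    mean_rf_genotype: float
    mean_rf_intensity: float
    sign_test_p: float
    n_reps: int

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "mean_rf_genotype": self.mean_rf_genotype,
            "mean_rf_intensity": self.mean_rf_intensity,
            "sign_test_p": self.sign_test_p,
            "replicates": self.replicates.to_dict(orient="records"),
        }


def genotype_route(
    genotypes: GenotypeTable,
    manifest,
    species_map: dict[str, str],
    thresholds: dict | None = None,
) -> tuple[DistanceMatrix, "pd.DataFrame"]:
    """QC filters, per-species allele stats, weighted pairwise F_ST matrix.

    Returns the (possibly shifted-nonnegative) F_ST matrix ready for tree
    building and the raw matrix as a DataFrame for reporting.
    """
    filtered, _report = apply_genotype_filters(genotypes, manifest, thresholds)
    stats = species_allele_stats(filtered, species_map)
    raw = pairwise_fst_matrix(stats)
    ready = shift_nonnegative(raw)
    raw_df = pd.DataFrame(np.asarray(raw.data), index=list(raw.ids), columns=list(raw.ids))
    return ready, raw_df


def intensity_route(
    intensities: IntensityTable,
    species_map: dict[str, str],
    kind: SummaryStatKind = SummaryStatKind.LN_XY,
) -> DistanceMatrix:
    """Median quantitative-genotype profiles and Euclidean distances (all SNPs)."""
    profiles = species_median_profiles(intensities, species_map, kind)
    return euclidean_species_distance(profiles)


def _default_outgroup(divergence: dict[str, float], focal: str) -> str:
    """The taxon farthest from the focal taxon (deterministic tie-break)."""
    return max(sorted(divergence), key=lambda t: (divergence[t], t))


def run_pipeline(
    config,
    outdir,
    force: bool = False,
) -> dict[str, Path]:
    """Run simulate/load -> QC -> both routes -> trees -> comparisons.

    ``config`` is a mapping with either a ``simulation`` section (SimConfig
    fields) or a ``data`` section (paths: final_report, manifest,
    species_map; plus a required ``outgroup``).  Optional top-level keys:
    ``outgroup``, ``thresholds``, ``summary_stat`` (default LN_XY),
    ``mantel_permutations`` (default 10000), ``seed``.

    Writes all artifacts into ``outdir`` and returns their paths.  On a
    stage failure, partial outputs are kept and a FAILED marker names the
    stage.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "configure"
    try:
        seed = int(config.get("seed", 0))
        thresholds = config.get("thresholds")
        kind = SummaryStatKind(config.get("summary_stat", "LN_XY"))
        permutations = int(config.get("mantel_permutations", 10000))

        stage = "acquire-data"
        focal_taxa: set[str] = set()
        if "simulation" in config:
            sim_kwargs = dict(config["simulation"] or {})
            sim_kwargs.setdefault("seed", seed)
            cfg = SimConfig(**sim_kwargs)
            ds = simulate_dataset(cfg)
            genotypes, intensities = ds.genotypes, ds.intensities
            species_map, manifest = ds.species_map, ds.manifest
            outgroup = config.get("outgroup") or _default_outgroup(
                ds.truth.divergence, ds.truth.focal_taxon
            )
            focal_taxa = {ds.truth.focal_taxon}
            truth_tree = ds.truth.tree
        elif "data" in config:
            data = config["data"]
            genotypes, intensities = apio.read_final_report(data["final_report"])
            manifest = apio.read_snp_manifest(data["manifest"])
            species_map = apio.read_species_map(data["species_map"])
            outgroup = config.get("outgroup")
            if not outgroup:
                raise ValueError("real-data mode requires an 'outgroup' taxon")
            focal_taxa = set(config.get("focal_taxa", []))
            truth_tree = None
        else:
            raise ValueError("config needs a 'simulation' or 'data' section")

        stage = "qc-filters"
        filtered, report = apply_genotype_filters(genotypes, manifest, thresholds)
        paths["filter_report"] = outdir / "filter_report.json"
        paths["filter_report"].write_text(json.dumps(report.to_dict(), indent=2))

        stage = "ld-prune"
        kept, _removed = ld_prune(filtered)
        pruned = filtered.subset_snps(kept)

        stage = "pca-curation"
        k = min(5, pruned.n_samples, pruned.n_snps)
        pca = genotype_pca(pruned, k)
        paths["pca_samples"] = outdir / "pca_samples.tsv"
        pca.coordinates.to_csv(paths["pca_samples"], sep="\t")
        flagged = flag_curation_errors(pca, species_map)
        paths["flagged_samples"] = outdir / "flagged_samples.tsv"
        paths["flagged_samples"].write_text("".join(f"{s}\n" for s in flagged))
        keep_samples = [s for s in genotypes.sample_ids if s not in set(flagged)]
        genotypes = genotypes.subset_samples(keep_samples)
        intensities = intensities.subset_samples(keep_samples)

        stage = "genotype-route"
        fst_ready, fst_raw = genotype_route(genotypes, manifest, species_map, thresholds)
        paths["fst_distances"] = outdir / "fst_distances.phylip"
        apio.write_distance_matrix(fst_ready, paths["fst_distances"])

        stage = "bias-diagnostics"
        refiltered, _ = apply_genotype_filters(genotypes, manifest, thresholds)
        stats = species_allele_stats(refiltered, species_map)
        edges = np.linspace(0.0, 0.5, 11)
        spectra = {
            taxon: maf_spectrum(stats, taxon, edges)[0] for taxon in stats.taxa
        }
        spec_df = pd.DataFrame(
            spectra, index=[f"[{a:.2f},{b:.2f})" for a, b in zip(edges[:-1], edges[1:])]
        ).T
        paths["maf_spectra"] = outdir / "maf_spectra.tsv"
        spec_df.to_csv(paths["maf_spectra"], sep="\t")
        taxa = stats.taxa
        mono = pd.DataFrame(0, index=taxa, columns=taxa)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                v = count_shared_monomorphic(stats, a, b)
                mono.loc[a, b] = mono.loc[b, a] = v
        paths["shared_monomorphic"] = outdir / "shared_monomorphic.tsv"
        mono.to_csv(paths["shared_monomorphic"], sep="\t")

        stage = "intensity-route"
        int_dm = intensity_route(intensities, species_map, kind)
        paths["intensity_distances"] = outdir / "intensity_distances.phylip"
        apio.write_distance_matrix(int_dm, paths["intensity_distances"])

        stage = "trees"
        tree_g = root_with_outgroup(neighbor_joining(fst_ready), outgroup)
        tree_i = root_with_outgroup(neighbor_joining(int_dm), outgroup)
        paths["tree_genotype"] = outdir / "tree_genotype.nwk"
        paths["tree_genotype"].write_text(tree_g.to_newick() + "\n")
        paths["tree_intensity"] = outdir / "tree_intensity.nwk"
        paths["tree_intensity"].write_text(tree_i.to_newick() + "\n")

        stage = "mds"
        for name, dm in (("genotype", fst_ready), ("intensity", int_dm)):
            mds = classical_mds(dm, k=2)
            paths[f"mds_{name}"] = outdir / f"mds_{name}.tsv"
            mds.coordinates.to_csv(paths[f"mds_{name}"], sep="\t")

        stage = "comparisons"
        mantel = mantel_test(int_dm, fst_ready, permutations=permutations, seed=seed)
        paths["mantel"] = outdir / "mantel.json"
        paths["mantel"].write_text(
            json.dumps(dataclasses.asdict(mantel), indent=2)
        )
        comparison: dict = {}
        if focal_taxa:
            comparison["focal_elevation"] = focal_elevation_statistic(
                int_dm, fst_ready, focal_taxa
            )
            comparison["focal_taxa"] = sorted(focal_taxa)
        if truth_tree is not None:
            comparison["rf_genotype_vs_truth"] = tree_topology_distance(tree_g, truth_tree)
            comparison["rf_intensity_vs_truth"] = tree_topology_distance(tree_i, truth_tree)
        paths["elevation"] = outdir / "elevation.json"
        paths["elevation"].write_text(json.dumps(comparison, indent=2))

        stage = "summary-statistic-sweep"
        trees = {}
        for stat_kind in SummaryStatKind:
            dm = intensity_route(intensities, species_map, stat_kind)
            trees[stat_kind.value] = neighbor_joining(dm)
        table = topology_distance_table(trees)
        paths["topology_distances"] = outdir / "topology_distances.tsv"
        table.to_csv(paths["topology_distances"], sep="\t")

        stage = "manifest"
        run_manifest = {
            "seed": seed,
            "outgroup": outgroup,
            "summary_stat": kind.value,
            "mantel_permutations": permutations,
            "n_samples": len(genotypes.sample_ids),
            "n_snps_genotype_route": int(
                json.loads(paths["filter_report"].read_text())["n_snps_out"]
            ),
            "n_snps_intensity_route": len(intensities.snp_ids),
            "artifacts": {k: str(v) for k, v in paths.items()},
        }
        paths["run_manifest"] = outdir / "run_manifest.json"
        paths["run_manifest"].write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths


def _replicate_once(cfg: SimConfig, kind: SummaryStatKind, thresholds: dict | None):
    """One simulated replicate: both routes, RF to truth, focal placement."""
    ds = simulate_dataset(cfg)
    truth = ds.truth
    outgroup = _default_outgroup(truth.divergence, truth.focal_taxon)
    fst_ready, _ = genotype_route(ds.genotypes, ds.manifest, ds.species_map, thresholds)
    int_dm = intensity_route(ds.intensities, ds.species_map, kind)
    tree_g = root_with_outgroup(neighbor_joining(fst_ready), outgroup)
    tree_i = root_with_outgroup(neighbor_joining(int_dm), outgroup)
    true_rooted = root_with_outgroup(truth.tree, outgroup)
    rf_g = tree_topology_distance(tree_g, truth.tree)
    rf_i = tree_topology_distance(tree_i, truth.tree)
    true_sister = true_rooted.sister_group(truth.focal_taxon)
    return {
        "seed": cfg.seed,
        "rf_genotype": rf_g,
        "rf_intensity": rf_i,
        "focal_correct_genotype": tree_g.sister_group(truth.focal_taxon) == true_sister,
        "focal_correct_intensity": tree_i.sister_group(truth.focal_taxon) == true_sister,
    }


def run_replicate_experiment(
    cfg: SimConfig,
    n_reps: int = 50,
    kind: SummaryStatKind = SummaryStatKind.LN_XY,
    thresholds: dict | None = None,
) -> ExperimentResult:
    """Paired comparison of the two routes over fresh simulated replicates.

    Each replicate draws its own seed from the master seed in ``cfg.seed``,
    simulates a dataset, runs both routes, and scores each inferred tree by
    Robinson–Foulds distance to the true tree (both rooted on the taxon
    farthest from the focal taxon).  The paired sign test is two-sided on
    the per-replicate RF differences, ignoring ties.
    """
    if n_reps < 5:
        raise ValueError("need at least 5 replicates for a meaningful summary")
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(n_reps) % (2**31)
    rows = []
    for rep_seed in child_seeds:
        rep_cfg = dataclasses.replace(cfg, seed=int(rep_seed))
        rows.append(_replicate_once(rep_cfg, kind, thresholds))
    frame = pd.DataFrame(rows)
    diff = frame["rf_genotype"] - frame["rf_intensity"]
    wins_i = int((diff > 0).sum())
    wins_g = int((diff < 0).sum())
    n_eff = wins_i + wins_g
    p = binomtest(wins_i, n_eff, 0.5).pvalue if n_eff > 0 else 1.0
    return ExperimentResult(
        replicates=frame,
        mean_rf_genotype=float(frame["rf_genotype"].mean()),
        mean_rf_intensity=float(frame["rf_intensity"].mean()),
        sign_test_p=float(p),
        n_reps=n_reps,
    )
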