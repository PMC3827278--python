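"""The synthetic-array generator: trees, drift, ascertainment, intensities."""

import dataclasses

import numpy as np
import pytest

from arrayphylo.sim import (
    SimConfig,
    SimulationTruth,
    ascertain_snps,
    emit_dataset,
    evolve_allele_frequencies,
    generate_species_tree,
    simulate_dataset,
    simulate_genotypes,
    simulate_intensities,
)
from arrayphylo.trees import parse_newick, tree_topology_distance


class TestSpeciesTree:
    def test_newick_input(self):
        cfg = SimConfig(tree_newick="((A:1,B:1):1,(C:1,D:1):1);")
        t = generate_species_tree(cfg)
        assert sorted(t.leaf_labels) == ["A", "B", "C", "D"]
        assert len(t.bipartitions()) == 1

    def test_newick_without_lengths_rejected(self):
        cfg = SimConfig(tree_newick="((A,B),(C,D));")
        with pytest.raises(ValueError, match="branch lengths"):
            generate_species_tree(cfg)

    def test_pure_birth_deterministic(self):
        cfg = SimConfig(tree_model="yule", seed=7)
        t1 = generate_species_tree(cfg)
        t2 = generate_species_tree(cfg)
        assert t1.to_newick() == t2.to_newick()

    def test_pure_birth_edge_count(self):
        cfg = SimConfig(tree_model="yule", n_species=12, seed=1)
        t = generate_species_tree(cfg)
        assert len(t.leaf_labels) == 12
        edges = sum(
            1
            for e in t.dendropy_tree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )
        # rooted representation has 2n-2 edges; the two root-adjacent edges
        # form one unrooted edge, giving 2n-3
        assert edges - 1 == 2 * 12 - 3

    def test_radiation_tree_designated_leaves(self):
        t = generate_species_tree(SimConfig(seed=4))
        labels = t.leaf_labels
        assert "focal" in labels and "outgroup" in labels
        assert len(labels) == 12
        for edge in t.dendropy_tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0


class TestDrift:
    def test_near_zero_branch_nearly_copies_parent(self):
        cfg = SimConfig(tree_newick="(A:1e-9,B:1.0);", n_candidate_snps=200, seed=0)
        tree = generate_species_tree(cfg)
        freqs = evolve_allele_frequencies(tree, cfg, np.random.default_rng(0))
        root_like = freqs.loc["A"].to_numpy()
        assert np.all((root_like > 0) & (root_like < 1))

    def test_absorbed_frequencies_stay_fixed(self):
        cfg = SimConfig(
            tree_newick="((A:0.5,B:0.5):3.0,C:3.5);",
            n_candidate_snps=500,
            ancestral_low=0.001,
            ancestral_high=0.002,
            seed=0,
        )
        tree = generate_species_tree(cfg)
        freqs = evolve_allele_frequencies(tree, cfg, np.random.default_rng(1))
        # ancestral frequencies this small are absorbed at 0 almost surely
        assert (freqs.to_numpy() == 0.0).mean() > 0.95

    def test_balding_nichols_variance_moment(self):
        # one branch with F = 1 - exp(-t) = 0.2, root p = 0.5
        t = -np.log(1.0 - 0.2)
        cfg = SimConfig(
            tree_newick=f"(A:{t:.12f},B:{t:.12f});",
            n_candidate_snps=100_000,
            ancestral_low=0.5,
            ancestral_high=0.5,
            seed=0,
        )
        tree = generate_species_tree(cfg)
        freqs = evolve_allele_frequencies(tree, cfg, np.random.default_rng(2))
        child = freqs.loc["A"].to_numpy()
        assert abs(child.mean() - 0.5) < 0.01
        expected_var = 0.5 * 0.5 * 0.2
        assert abs(child.var() - expected_var) / expected_var < 0.05


class TestAscertainment:
    def test_monomorphic_panel_excluded_and_arithmetic(self):
        import pandas as pd

        # two taxa; first SNP fixed everywhere, second with known panel MAF
        freqs = pd.DataFrame(
            {"snp1": [1.0, 1.0], "snp2": [0.5, 0.5]}, index=["focal", "other"]
        ).astype(float)
        cfg = SimConfig(
            focal_taxon="focal",
            panel_composition={"focal": 11, "other": 6},
            panel_maf_min=0.10,
            seed=0,
        )
        mask = ascertain_snps(freqs, cfg, np.random.default_rng(3))
        assert not mask[0]  # fixed in every panel taxon -> excluded

    def test_panel_maf_threshold_arithmetic(self):
        # 17 diploids, 5 B alleles -> MAF 5/34 ~ 0.147 >= 0.10 -> retained
        assert min(5, 34 - 5) / 34 >= 0.10

    def test_retention_replay_oracle(self):
        cfg = SimConfig(seed=5, n_candidate_snps=400)
        tree = generate_species_tree(cfg)
        freqs = evolve_allele_frequencies(tree, cfg, np.random.default_rng(50))
        divergence = tree.path_distances_from("focal")
        mask = ascertain_snps(freqs, cfg, np.random.default_rng(51), divergence)
        # brute-force replay with the same stream
        rng = np.random.default_rng(51)
        panel = cfg.panel_for(list(freqs.index), "focal", divergence)
        b = np.zeros(freqs.shape[1], dtype=np.int64)
        n_alleles = 0
        for taxon in sorted(panel):
            b += rng.binomial(2 * panel[taxon], freqs.loc[taxon].to_numpy())
            n_alleles += 2 * panel[taxon]
        expected = np.minimum(b, n_alleles - b) / n_alleles >= cfg.panel_maf_min
        assert np.array_equal(mask, expected)

    def test_no_retained_snps_is_an_error(self):
        import pandas as pd

        freqs = pd.DataFrame({"snp1": [1.0, 1.0]}, index=["focal", "o"]).astype(float)
        cfg = SimConfig(panel_composition={"focal": 11, "o": 6}, focal_taxon="focal")
        with pytest.raises(ValueError, match="no SNPs survived"):
            ascertain_snps(freqs, cfg, np.random.default_rng(0))


def make_truth(freqs_dict, cfg):
    import pandas as pd

    tree = generate_species_tree(cfg)
    freqs = pd.DataFrame(freqs_dict, index=tree.leaf_labels[:2]).astype(float)
    return SimulationTruth(
        tree=tree,
        species_frequencies=freqs,
        candidate_frequencies=freqs,
        divergence=tree.path_distances_from(tree.leaf_labels[0]),
        ascertained=np.ones(freqs.shape[1], bool),
        focal_taxon=tree.leaf_labels[0],
    )


class TestGenotypes:
    @pytest.mark.parametrize("p,expected", [(1.0, 2.0), (0.0, 0.0)])
    def test_fixed_frequency_dosages(self, p, expected):
        cfg = SimConfig(
            tree_newick="(A:1,B:1);",
            samples_per_species=10,
            missing_rate=0.0,
            focal_taxon="A",
        )
        truth = make_truth({"snp1": [p, p], "snp2": [p, p]}, cfg)
        g, true_dosage, smap = simulate_genotypes(truth, cfg, np.random.default_rng(1))
        assert (g.dosage.to_numpy() == expected).all()

    def test_binomial_moment(self):
        cfg = SimConfig(
            tree_newick="(A:1,B:1);",
            samples_per_species=10_000,
            missing_rate=0.0,
            focal_taxon="A",
        )
        truth = make_truth({"snp1": [0.3, 0.3]}, cfg)
        g, _, smap = simulate_genotypes(truth, cfg, np.random.default_rng(2))
        vals = g.dosage.to_numpy().ravel()
        se = np.sqrt(2 * 0.3 * 0.7 / vals.size)
        assert abs(vals.mean() - 0.6) < 3 * se


class TestIntensities:
    def base_cfg(self, **kw):
        kw.setdefault("tree_newick", "(A:1,B:1);")
        kw.setdefault("samples_per_species", 4)
        kw.setdefault("focal_taxon", "A")
        kw.setdefault("missing_rate", 0.0)
        return SimConfig(**kw)

    def test_symmetric_heterozygote_channels(self):
        cfg = self.base_cfg(
            affinity_decay=0.0, channel_noise=0.0, otv_rate=0.0, otv_penalty=0.0,
            signal=1.0, background=0.05, intensity_floor=1e-3,
        )
        truth = make_truth({"snp1": [0.5, 0.5]}, cfg)
        import pandas as pd

        td = pd.DataFrame(1.0, index=["A_s01", "B_s01"], columns=["snp1"])
        smap = {"A_s01": "A", "B_s01": "B"}
        i, gc, gt, otv = simulate_intensities(truth, td, smap, cfg, np.random.default_rng(0))
        assert np.allclose(i.x.to_numpy(), 0.55)
        assert np.allclose(i.y.to_numpy(), 0.55)

    def test_homozygote_channels(self):
        cfg = self.base_cfg(
            affinity_decay=0.0, channel_noise=0.0, otv_rate=0.0, otv_penalty=0.0,
            signal=1.0, background=0.05, intensity_floor=1e-3,
        )
        truth = make_truth({"snp1": [1.0, 1.0]}, cfg)
        import pandas as pd

        td = pd.DataFrame(2.0, index=["A_s01", "B_s01"], columns=["snp1"])
        smap = {"A_s01": "A", "B_s01": "B"}
        i, *_ = simulate_intensities(truth, td, smap, cfg, np.random.default_rng(0))
        assert np.allclose(i.x.to_numpy(), 0.05)  # X = b
        assert np.allclose(i.y.to_numpy(), 1.05)  # Y = S + b

    def test_affinity_moment_for_heterozygotes(self):
        # taxon at path distance 2 with lambda = 0.5: mean(X+Y) ~ e^-1 S + 2b
        cfg = self.base_cfg(
            tree_newick="(A:1.0,B:1.0);",
            samples_per_species=10_000,
            affinity_decay=0.5,
            otv_rate=0.0,
            channel_noise=0.015,
            background=0.02,
            intensity_floor=1e-6,
        )
        truth = make_truth({"snp1": [0.5, 0.5]}, cfg)
        import pandas as pd

        samples = [f"B_s{k}" for k in range(10_000)]
        td = pd.DataFrame(1.0, index=samples, columns=["snp1"])
        smap = {s: "B" for s in samples}
        i, *_ = simulate_intensities(truth, td, smap, cfg, np.random.default_rng(4))
        total = (i.x.to_numpy() + i.y.to_numpy()).mean()
        expected = np.exp(-1.0) * cfg.signal + 2 * cfg.background
        assert abs(total - expected) < 4 * (cfg.channel_noise * np.sqrt(2) / 100)

    def test_otv_marginal_rate_matches_path_length(self):
        cfg = SimConfig(seed=8, otv_rate=0.3)
        ds = simulate_dataset(cfg)
        otv = ds.truth.otv_events
        for taxon in otv.index:
            d = ds.truth.divergence[taxon]
            expected = 1.0 - np.exp(-cfg.otv_rate * d)
            observed = otv.loc[taxon].mean()
            se = np.sqrt(max(expected * (1 - expected), 1e-9) / otv.shape[1])
            assert abs(observed - expected) < 5 * se + 1e-9

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(channel_noise=-0.1)

    def test_scores_within_unit_interval(self, small_dataset):
        gc = small_dataset.genotypes.gencall.to_numpy()
        assert gc.min() >= 0.0 and gc.max() <= 1.0
        gts = [m.gentrain for m in small_dataset.manifest]
        assert min(gts) > 0.0 and max(gts) <= 1.0


class TestEmit:
    def test_round_trip_and_truth_newick(self, tmp_path, small_dataset):
        paths = emit_dataset(small_dataset, tmp_path / "d")
        reparsed = parse_newick(paths["true_tree"].read_text())
        assert tree_topology_distance(reparsed, small_dataset.truth.tree) == 0

    def test_existing_nonempty_outdir_rejected(self, tmp_path, small_dataset):
        out = tmp_path / "d"
        out.mkdir()
        (out / "junk").write_text("x")
        with pytest.raises(FileExistsError):
            emit_dataset(small_dataset, out)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_species=5, samples_per_species=4, n_candidate_snps=150, seed=3)
        p1 = emit_dataset(simulate_dataset(cfg), tmp_path / "a")
        p2 = emit_dataset(simulate_dataset(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestBiasStructure:
    """The generator reproduces the ascertainment-bias signatures it targets."""

    def test_focal_intermediate_maf_excess(self, default_dataset):
        # ascertained SNPs show an intermediate-MAF excess in the focal taxon
        # relative to every taxon absent from the discovery panel
        truth = default_dataset.truth
        freqs = truth.species_frequencies
        assert freqs.shape[1] >= 1000
        maf = np.minimum(freqs, 1.0 - freqs)
        inter = ((maf >= 0.2) & (maf <= 0.5)).mean(axis=1)
        cfg = default_dataset.config
        panel = cfg.panel_for(list(freqs.index), truth.focal_taxon, truth.divergence)
        for taxon in freqs.index:
            if taxon not in panel:
                assert inter[truth.focal_taxon] > inter[taxon]

    def test_focal_pairs_share_fewer_monomorphic_snps(self, default_dataset):
        import itertools

        from arrayphylo.genotype import count_shared_monomorphic, species_allele_stats

        stats = species_allele_stats(
            default_dataset.genotypes, default_dataset.species_map
        )
        focal = default_dataset.truth.focal_taxon
        focal_counts, other_counts = [], []
        for a, b in itertools.combinations(stats.taxa, 2):
            c = count_shared_monomorphic(stats, a, b)
            (focal_counts if focal in (a, b) else other_counts).append(c)
        assert np.mean(focal_counts) < np.mean(other_counts)

    def test_unbiased_variant_removes_elevation(self):
        from arrayphylo.compare import focal_elevation_statistic
        from arrayphylo.pipeline import genotype_route, intensity_route
        from arrayphylo.sim import unbiased_variant

        cfg = SimConfig(seed=2)
        biased = simulate_dataset(cfg)
        fst_b, _ = genotype_route(biased.genotypes, biased.manifest, biased.species_map)
        int_b = intensity_route(biased.intensities, biased.species_map)
        elev_b = focal_elevation_statistic(int_b, fst_b, {biased.truth.focal_taxon})

        clean = simulate_dataset(unbiased_variant(cfg))
        fst_c, _ = genotype_route(clean.genotypes, clean.manifest, clean.species_map)
        int_c = intensity_route(clean.intensities, clean.species_map)
        elev_c = focal_elevation_statistic(int_c, fst_c, {clean.truth.focal_taxon})

        # switching the affinity machinery off removes most of the elevation;
        # a residual reflects the focal taxon's polymorphism contrast
        assert elev_b > 0.5
        assert elev_c < elev_b - 0.3
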