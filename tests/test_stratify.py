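"""Signature-site selection, ward.D clustering, INO labels, NMDS."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from inosinome import (
    EditingMatrix,
    assign_ino_labels,
    build_editing_matrix,
    cut_tree,
    discover_subtype_differential_sites,
    euclidean_distance_matrix,
    nmds_ordination,
    select_stratification_sites,
    stratify_inosinome,
    ward_hierarchical_clustering,
)
from inosinome.simulate import SimulationConfig, simulate_cohort
from inosinome.stratify import impute_site_median, merge_tree_to_newick

from conftest import toy_matrix


class TestSiteSelection:
    def make(self):
        freq = np.full((5, 4), 0.2)
        freq[0, 1] = np.nan      # site1 detected in 4/5
        freq[:3, 2] = np.nan     # site2 detected in 2/5
        matrix = toy_matrix(freq, np.full((5, 4), 50.0))
        # vary features: site0 UTR, site1 exon, site2 intron, site3 intergenic
        from dataclasses import replace
        feats = ["UTR", "exon", "intron", "intergenic"]
        matrix.sites = [replace(s, feature=f) for s, f in zip(matrix.sites, feats)]
        return matrix

    def test_detection_and_feature_gates(self):
        matrix = self.make()
        kept = select_stratification_sites(matrix, min_detected=5)
        assert [s.feature for s in kept] == ["UTR"]  # site3 fails feature gate
        kept4 = select_stratification_sites(matrix, min_detected=4)
        assert {s.feature for s in kept4} == {"UTR", "exon"}

    def test_fractional_threshold_scales_with_cohort(self):
        matrix = self.make()
        # 140/145 of 5 samples rounds up to 5
        kept = select_stratification_sites(matrix, min_detected=140 / 145)
        assert len(kept) == 1

    def test_threshold_above_cohort_size_is_fatal(self):
        with pytest.raises(ValueError):
            select_stratification_sites(self.make(), min_detected=6)

    def test_matches_exhaustive_gate_oracle(self, rng):
        from dataclasses import replace
        freq = rng.uniform(0, 0.5, size=(8, 20))
        freq[rng.random(size=freq.shape) < 0.3] = np.nan
        matrix = toy_matrix(np.round(freq, 2), np.full((8, 20), 40.0))
        feats = rng.choice(["exon", "intron", "UTR", "intergenic"], size=20)
        matrix.sites = [replace(s, feature=f) for s, f in zip(matrix.sites, feats)]
        kept = {s.label for s in select_stratification_sites(matrix, 6)}
        for s in matrix.sites:
            expected = (matrix.freq[s.label].notna().sum() >= 6
                        and s.feature in ("exon", "intron", "UTR"))
            assert (s.label in kept) == expected


class TestDistances:
    def test_identical_samples_have_zero_distance(self):
        freq = pd.DataFrame([[0.1, 0.2], [0.1, 0.2]], index=["a", "b"])
        d = euclidean_distance_matrix(freq)
        assert d.loc["a", "b"] == 0.0

    def test_single_coordinate_difference(self):
        freq = pd.DataFrame([[0.1, 0.5], [0.1, 0.2]], index=["a", "b"])
        assert euclidean_distance_matrix(freq).loc["a", "b"] == pytest.approx(0.3)

    def test_matches_direct_formula(self, rng):
        X = rng.uniform(size=(6, 9))
        d = euclidean_distance_matrix(pd.DataFrame(X)).to_numpy()
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((X[i] - X[j]) ** 2).sum()), abs=1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_missing_cells_are_rejected_and_imputation_fills_them(self):
        freq = pd.DataFrame([[0.1, np.nan], [0.3, 0.2], [0.5, 0.4]])
        with pytest.raises(ValueError):
            euclidean_distance_matrix(freq)
        filled, n = impute_site_median(freq)
        assert n == 1
        assert filled.iloc[0, 1] == pytest.approx(0.3)  # per-site median


class TestWardD:
    def test_well_separated_pairs(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        d = squareform(pdist(x))
        labels = cut_tree(ward_hierarchical_clustering(d), k=2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_cut_at_n_is_singletons_and_cut_is_partition(self, rng):
        d = squareform(pdist(rng.normal(size=(7, 3))))
        Z = ward_hierarchical_clustering(d)
        assert len(set(cut_tree(Z, 7))) == 7
        for k in range(1, 8):
            labels = cut_tree(Z, k)
            assert len(set(labels)) == k
        with pytest.raises(ValueError):
            cut_tree(Z, 8)

    def test_frozen_reference_case(self):
        # heights verified against R hclust(method="ward.D") on this matrix
        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.normal(size=(6, 3))))
        Z = ward_hierarchical_clustering(d)
        assert Z[:, 2] == pytest.approx(
            [0.4909613, 0.6468332, 2.1456589, 3.1884666, 3.5140313], abs=1e-6)

    def test_merge_heights_match_independent_reference(self, rng):
        # ward.D on d == Ward-D2 on sqrt(d) with squared heights; SciPy's
        # nn-chain implementation is an independent route to the same tree
        for _ in range(100):
            n = int(rng.integers(3, 7))
            d = squareform(pdist(rng.normal(size=(n, 3))))
            Z = ward_hierarchical_clustering(d)
            Zs = linkage(np.sqrt(squareform(d)), method="ward")
            assert np.allclose(np.sort(Z[:, 2]), np.sort(Zs[:, 2] ** 2),
                               atol=1e-9)
            for k in (2, 3):
                if k < n:
                    a = cut_tree(Z, k)
                    from scipy.cluster.hierarchy import fcluster
                    b = fcluster(Zs, k, criterion="maxclust")
                    assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_newick_rendering_contains_all_leaves(self, rng):
        d = squareform(pdist(rng.normal(size=(5, 2))))
        Z = ward_hierarchical_clustering(d)
        nwk = merge_tree_to_newick(Z, [f"s{i}" for i in range(5)])
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(5))


class TestInoLabels:
    def test_higher_editing_cluster_is_ino1(self):
        freq = np.array([[0.30, 0.32], [0.28, 0.31], [0.10, 0.12], [0.09, 0.11]])
        matrix = toy_matrix(freq, np.full((4, 2), 100.0))
        res = assign_ino_labels(np.array([0, 0, 1, 1]), matrix, matrix.sites)
        assert list(res.labels) == ["INO-1", "INO-1", "INO-2", "INO-2"]
        assert res.cluster_means["INO-1"] >= res.cluster_means["INO-2"]

    def test_assignment_invariant_to_cluster_input_order(self):
        freq = np.array([[0.30, 0.32], [0.28, 0.31], [0.10, 0.12], [0.09, 0.11]])
        matrix = toy_matrix(freq, np.full((4, 2), 100.0))
        a = assign_ino_labels(np.array([0, 0, 1, 1]), matrix, matrix.sites)
        b = assign_ino_labels(np.array([1, 1, 0, 0]), matrix, matrix.sites)
        assert list(a.labels) == list(b.labels)

    def test_tie_falls_back_to_smallest_sample_id(self):
        freq = np.full((4, 2), 0.2)
        matrix = toy_matrix(freq, np.full((4, 2), 100.0))
        with pytest.warns(UserWarning, match="tied"):
            res = assign_ino_labels(np.array([1, 1, 0, 0]), matrix, matrix.sites)
        assert res.labels["S0"] == "INO-1"

    def test_non_binary_clustering_rejected(self):
        matrix = toy_matrix(np.full((3, 2), 0.2), np.full((3, 2), 100.0))
        with pytest.raises(ValueError):
            assign_ino_labels(np.array([0, 1, 2]), matrix, matrix.sites)

    def test_planted_two_cluster_cohort_recovered(self):
        config = SimulationConfig(seed=3, n_tumor=60, n_normal=4,
                                  n_alu_sites=80, n_rep_sites=10,
                                  n_nonrep_sites=60, ino_n_sites=50,
                                  ino_delta=0.15)
        cohort = simulate_cohort(config)
        tumors = {s: t for s, t in cohort.tables.items() if s.startswith("T")}
        matrix = build_editing_matrix(tumors, cohort.catalog)
        res = stratify_inosinome(matrix)
        truth = [cohort.truth.ino_labels[s] for s in matrix.samples]
        assert adjusted_rand_score(truth, list(res.labels)) >= 0.9
        assert res.cluster_means["INO-1"] >= res.cluster_means["INO-2"]


class TestSubtypeDiscovery:
    def test_planted_subtype_effect_is_discovered(self, rng):
        n = 24
        freq = np.clip(rng.normal(0.25, 0.02, size=(n, 10)), 0.05, 0.9)
        subtypes = pd.Series(["PN"] * 6 + ["CL"] * 6 + ["M"] * 6 + ["N"] * 6,
                             index=[f"S{i}" for i in range(n)])
        freq[:6, 0] -= 0.18  # PN-specific under-editing at site 0
        matrix = toy_matrix(np.round(freq * 100) / 100, np.full((n, 10), 100.0))
        sites = discover_subtype_differential_sites(matrix, subtypes)
        assert matrix.sites[0].label in {s.label for s in sites}

    def test_identical_subtypes_rarely_selected(self, rng):
        n = 24
        freq = np.clip(rng.normal(0.25, 0.02, size=(n, 40)), 0.05, 0.9)
        subtypes = pd.Series(rng.permutation(["PN", "CL", "M", "N"] * 6),
                             index=[f"S{i}" for i in range(n)])
        matrix = toy_matrix(np.round(freq * 100) / 100, np.full((n, 40), 100.0))
        sites = discover_subtype_differential_sites(matrix, subtypes)
        assert len(sites) <= 6  # BH holds the null selection rate down

    def test_small_subtype_is_skipped_with_warning(self, rng):
        n = 13
        freq = np.clip(rng.normal(0.25, 0.05, size=(n, 5)), 0.05, 0.9)
        subtypes = pd.Series(["PN"] * 6 + ["CL"] * 6 + ["M"],
                             index=[f"S{i}" for i in range(n)])
        matrix = toy_matrix(np.round(freq * 100) / 100, np.full((n, 5), 100.0))
        with pytest.warns(UserWarning, match="skipped"):
            discover_subtype_differential_sites(matrix, subtypes)


class TestNmds:
    def planar_dissimilarity(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [2, 2.0]])
        d = squareform(pdist(pts))
        return pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))

    def test_embeddable_configuration_reaches_near_zero_stress(self):
        res = nmds_ordination(self.planar_dissimilarity(), seed=1, n_restarts=5)
        assert res.stress < 1e-3

    def test_stress_non_increasing_within_run(self):
        res = nmds_ordination(self.planar_dissimilarity(), seed=1, n_restarts=5)
        assert all(b <= a + 1e-10 for a, b in
                   zip(res.stress_trace, res.stress_trace[1:]))

    def test_deterministic_under_seed(self):
        d = self.planar_dissimilarity()
        r1 = nmds_ordination(d, seed=4, n_restarts=3)
        r2 = nmds_ordination(d, seed=4, n_restarts=3)
        assert np.allclose(r1.coords, r2.coords)
        r3 = nmds_ordination(d, seed=9, n_restarts=3)
        assert abs(r1.stress - r3.stress) < 1e-6  # both reach the optimum

    def test_coords_are_centered(self):
        res = nmds_ordination(self.planar_dissimilarity(), seed=0, n_restarts=2)
        assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-9)

    def test_planted_groups_separate_in_ordination(self, small_cohort,
                                                   small_matrix):
        detected = small_matrix.freq.notna().mean(axis=0) >= 0.9
        sub = small_matrix.restrict(
            [s for s in small_matrix.sites if detected[s.label]])
        res = nmds_ordination(sub, seed=0, n_restarts=4)
        coords = res.coords
        tumors = [s for s in coords.index if s.startswith("T")]
        normals = [s for s in coords.index if s.startswith("N")]
        d = squareform(pdist(coords.to_numpy()))
        df = pd.DataFrame(d, index=coords.index, columns=coords.index)
        within = np.mean([df.loc[a, b] for g in (tumors, normals)
                          for a in g for b in g if a < b])
        between = np.mean([df.loc[a, b] for a in tumors for b in normals])
        assert within < between

    def test_constant_profile_is_fatal(self):
        matrix = toy_matrix(np.array([[0.2, 0.2, 0.2], [0.1, 0.5, 0.3]]),
                            np.full((2, 3), 100.0))
        with pytest.raises(ValueError, match="constant"):
            nmds_ordination(matrix, seed=0)
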