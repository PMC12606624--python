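import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from saxsens import analysis
from saxsens.analysis import (build_network, contact_analysis,
                              free_energy_profile, logistic_size,
                              partition_by_rg, qt_cluster, weighted_pca)
from saxsens.ensemble import AtomEnsemble
from saxsens.maxent import KT_300K


class TestFreeEnergyProfile:
    def test_uniform_sample_flat_profile(self):
        rg = (np.arange(100) + 0.5) / 100  # 10 per bin, exactly
        w = np.full(100, 0.01)
        _, f = free_energy_profile(rg, w, bins=10, range_=(0, 1))
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_minimum_at_mode(self):
        rng = np.random.default_rng(0)
        rg = np.concatenate([rng.normal(10, 0.5, 900), rng.normal(20, 0.5, 100)])
        w = np.full(1000, 1e-3)
        centers, f = free_energy_profile(rg, w, bins=25)
        assert abs(centers[np.nanargmin(f)] - 10) < 1.0

    def test_two_state_depth_matches_analytic_masses(self):
        # well depth difference = -kT ln(p1/p2) from the analytic bin masses
        rng = np.random.default_rng(1)
        n = 40_000
        is_b = rng.random(n) < 0.3
        rg = np.where(is_b, rng.normal(20, 0.4, n), rng.normal(10, 0.4, n))
        w = np.full(n, 1 / n)
        centers, f = free_energy_profile(rg, w, bins=40, range_=(7, 23))
        a_bin = np.nanargmin(np.where(centers < 15, f, np.nan))
        b_bin = np.nanargmin(np.where(centers > 15, f, np.nan))
        depth = f[b_bin] - f[a_bin]
        from scipy.stats import norm
        width = (23 - 7) / 40

        def mass(mu, frac, c):
            return frac * (norm.cdf(c + width / 2, mu, 0.4)
                           - norm.cdf(c - width / 2, mu, 0.4))

        expected = -KT_300K * np.log(mass(20, 0.3, centers[b_bin])
                                     / mass(10, 0.7, centers[a_bin]))
        assert depth == pytest.approx(expected, abs=3 * KT_300K * 0.05)

    def test_empty_bins_are_nan(self):
        rg = np.array([1.0, 1.1, 9.0])
        w = np.array([0.4, 0.4, 0.2])
        _, f = free_energy_profile(rg, w, bins=8, range_=(0, 10))
        assert np.isnan(f).any()
        assert np.nanmin(f) == pytest.approx(0.0)


class TestPartition:
    def test_all_below_threshold(self):
        assert partition_by_rg(np.array([1.0, 2.0]), np.array([0.5, 0.5]), 2.0) \
            == (1.0, 0.0)

    def test_two_frame_split(self):
        frac = partition_by_rg(np.array([1.0, 5.0]), np.array([0.35, 0.65]), 3.0)
        assert frac == pytest.approx((0.35, 0.65))

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        rg = rng.uniform(5, 30, 50)
        w = rng.uniform(0, 1, 50)
        assert partition_by_rg(rg, w, 15.0) == \
            pytest.approx(partition_by_rg(rg, 7.7 * w, 15.0))

    def test_threshold_outside_range_warns(self):
        with pytest.warns(UserWarning, match="units"):
            partition_by_rg(np.array([10.0, 12.0]), np.array([0.5, 0.5]), 2.47)


class TestWeightedPca:
    def test_single_direction_one_component(self):
        t = np.linspace(-1, 1, 10)
        coords = np.zeros((10, 4, 3))
        coords[:, 0, 0] = t
        comps, proj, explained, k = weighted_pca(coords, None, 0.93)
        assert k == 1
        assert explained[0] == pytest.approx(1.0)

    def test_uniform_weights_match_sklearn(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 2, (30, 6, 3))
        _, proj, explained, _ = weighted_pca(coords, None, 0.93)
        X = coords.reshape(30, -1)
        ref = PCA().fit(X)
        # sklearn uses the n-1 normalization; compare normalized spectra
        ref_explained = ref.explained_variance_ratio_
        assert np.allclose(explained[:len(ref_explained)], ref_explained,
                           atol=1e-8)

    def test_explained_normalized(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 1, (20, 5, 3))
        w = rng.uniform(0, 1, 20)
        _, _, explained, _ = weighted_pca(coords, w, 0.9)
        assert (explained >= 0).all()
        assert explained.sum() == pytest.approx(1.0)


def qt_oracle(dist, weights, cutoff):
    """Brute-force QT: each round, enumerate every subset with diameter
    <= cutoff and take the one with the largest summed weight."""
    n = len(weights)
    remaining = list(range(n))
    clusters = []
    while remaining:
        best, best_w = None, -1.0
        for r in range(len(remaining), 0, -1):
            for sub in itertools.combinations(remaining, r):
                idx = np.array(sub)
                if len(idx) > 1 and dist[np.ix_(idx, idx)].max() > cutoff:
                    continue
                w = weights[idx].sum()
                if w > best_w:
                    best, best_w = list(sub), w
        clusters.append(best)
        remaining = [i for i in remaining if i not in set(best)]
    return clusters


class TestQtClustering:
    def test_all_close_single_cluster(self):
        d = np.full((5, 5), 0.5)
        np.fill_diagonal(d, 0)
        cs = qt_cluster(d, np.ones(5), cutoff=1.0)
        assert cs.n_clusters == 1
        assert (cs.labels == 0).all()

    def test_all_far_singletons(self):
        d = np.full((4, 4), 9.0)
        np.fill_diagonal(d, 0)
        cs = qt_cluster(d, np.ones(4), cutoff=1.0)
        assert cs.n_clusters == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 4, (7, 2))
        w = rng.uniform(0.1, 1.0, 7)
        d = squareform(pdist(pts))
        cutoff = 2.0
        cs = qt_cluster(d, w, cutoff)
        mine = {frozenset(np.nonzero(cs.labels == c)[0].tolist())
                for c in range(cs.n_clusters)}
        oracle = {frozenset(c) for c in qt_oracle(d, w, cutoff)}
        assert mine == oracle

    def test_partition_and_representatives(self):
        rng = np.random.default_rng(9)
        d = squareform(pdist(rng.uniform(0, 10, (20, 3))))
        w = rng.uniform(0, 1, 20)
        cs = qt_cluster(d, w, cutoff=4.0)
        assert (cs.labels >= 0).all()
        assert sorted(np.unique(cs.labels)) == list(range(cs.n_clusters))
        for c in range(cs.n_clusters):
            assert cs.labels[cs.representatives[c]] == c
        assert cs.cluster_weights.sum() == pytest.approx(w.sum())

    def test_subsets_never_mix(self):
        rng = np.random.default_rng(10)
        d = squareform(pdist(rng.uniform(0, 3, (15, 2))))
        w = rng.uniform(0, 1, 15)
        subset = np.where(rng.random(15) < 0.5, "compact", "extended")
        cs = qt_cluster(d, w, cutoff=5.0, subset=subset)
        for c in range(cs.n_clusters):
            tags = subset[cs.labels == c]
            assert len(set(tags)) == 1
            assert tags[0] == cs.subset_tag[c]


class TestNetwork:
    def _clusters(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        d = squareform(pdist(rng.uniform(0, 10, (n, 2))))
        w = rng.uniform(0, 1, n)
        return qt_cluster(d, w, cutoff=0.5), d

    def test_edges_match_threshold_scan(self):
        cs, d = self._clusters()
        reps = cs.representatives
        rep_d = d[np.ix_(reps, reps)]
        g = build_network(cs, rep_d, edge_cutoff=5.0)
        expected = {(a, b) for a in range(len(reps)) for b in range(a + 1, len(reps))
                    if rep_d[a, b] <= 5.0}
        assert {tuple(sorted(e)) for e in g.edges} == expected
        assert all(a != b for a, b in g.edges)

    def test_distant_representatives_no_edges(self):
        cs, d = self._clusters()
        rep_d = np.full((cs.n_clusters, cs.n_clusters), 99.0)
        np.fill_diagonal(rep_d, 0)
        g = build_network(cs, rep_d, edge_cutoff=5.0)
        assert g.number_of_edges() == 0

    def test_node_sizes_monotone_in_weight(self):
        w = np.array([0.1, 0.2, 0.5, 0.9])
        s = logistic_size(w)
        assert (np.diff(s) > 0).all()


def _contact_ensemble(gap, n_frames=4):
    """Two single-atom residues on different chains at a fixed distance."""
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, 0] = gap
    return AtomEnsemble(
        coords=coords, elements=np.array(["C", "C"]),
        atom_names=np.array(["CA", "CA"]), residue_ids=np.array([1, 1]),
        residue_names=np.array(["ALA", "ALA"]),
        chain_ids=np.array(["A", "B"]), masses=np.array([12.0, 12.0]))


class TestContacts:
    def test_contact_below_cutoff(self):
        ens = _contact_ensemble(4.9)
        out = contact_analysis(ens, np.full(4, 0.25), [("A", 1)], [("B", 1)])
        assert out["pairs"][0][2] == pytest.approx(1.0)
        assert out["pairs"][0][3] is True

    def test_no_contact_above_cutoff(self):
        ens = _contact_ensemble(5.1)
        out = contact_analysis(ens, np.full(4, 0.25), [("A", 1)], [("B", 1)])
        assert out["pairs"][0][2] == pytest.approx(0.0)

    def test_weighted_fraction_and_persistence(self):
        ens = _contact_ensemble(4.0, n_frames=5)
        ens.coords[2:, 1, 0] = 8.0  # contact only in frames 0-1
        w = np.array([0.2, 0.1, 0.3, 0.2, 0.2])
        out = contact_analysis(ens, w, [("A", 1)], [("B", 1)],
                               persistence=0.025)
        assert out["pairs"][0][2] == pytest.approx(0.30)
        assert out["pairs"][0][3] is True

    def test_overlapping_groups_raise(self):
        ens = _contact_ensemble(4.0)
        with pytest.raises(ValueError, match="disjoint"):
            contact_analysis(ens, np.full(4, 0.25), [("A", 1)], [("A", 1)])

    def test_matches_mdtraj_closest_heavy(self, tmp_path, small_ensemble):
        import mdtraj

        from saxsens.ensemble import write_pdb
        ens, _ = small_ensemble
        sub_a = [("A", int(r)) for r in range(1, 6)]
        sub_b = [("B", int(r)) for r in range(1, 6)]
        w = np.full(ens.n_frames, 1.0 / ens.n_frames)
        ours = contact_analysis(ens, w, sub_a, sub_b, cutoff=8.0)
        path = tmp_path / "ens.pdb"
        write_pdb(ens, path)
        traj = mdtraj.load(str(path))
        n_a = len({(c, int(r)) for c, r in zip(ens.chain_ids, ens.residue_ids)
                   if c == "A"})
        pairs = [(i, n_a + j) for i in range(5) for j in range(5)]
        d, _ = mdtraj.compute_contacts(traj, contacts=pairs,
                                       scheme="closest-heavy")
        probs_md = (d * 10.0 < 8.0).mean(axis=0)  # nm -> A
        probs_ours = [p[2] for p in ours["pairs"]]
        assert np.allclose(probs_ours, probs_md, atol=1e-12)
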