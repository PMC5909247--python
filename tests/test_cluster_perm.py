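"""Electrode adjacency, spatio-temporal clustering, cluster-mass permutation test.

Oracles: an O(n^2) pairwise-distance scan for adjacency, a recursive
flood-fill for clustering, and full 2^n sign-pattern enumeration (with the
flood-fill re-run per pattern) for cluster p-values.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from oddball_stda.cluster_perm import (
    ClusterTestConfig,
    build_adjacency,
    cluster_mass_test,
    find_clusters,
)


def floodfill_clusters(tmap, thr, neighbor_matrix):
    """Independent oracle: recursive flood fill over (channel, sample) nodes."""
    n_ch, n_s = tmap.shape
    out = []
    for sign in (1, -1):
        supra = (sign * tmap) >= thr
        seen = np.zeros_like(supra)
        for c0 in range(n_ch):
            for s0 in range(n_s):
                if not supra[c0, s0] or seen[c0, s0]:
                    continue
                stack = [(c0, s0)]
                members = []
                seen[c0, s0] = True
                while stack:
                    c, s = stack.pop()
                    members.append((c, s))
                    for s2 in (s - 1, s + 1):
                        if 0 <= s2 < n_s and supra[c, s2] and not seen[c, s2]:
                            seen[c, s2] = True
                            stack.append((c, s2))
                    for c2 in range(n_ch):
                        if (neighbor_matrix[c, c2] and supra[c2, s]
                                and not seen[c2, s]):
                            seen[c2, s] = True
                            stack.append((c2, s))
                mass = sum(tmap[c, s] for c, s in members)
                out.append((frozenset(members), mass, sign))
    return out


def small_adjacency(montage, channels, threshold):
    return build_adjacency(montage, threshold_cm=threshold, channels=channels)


class TestAdjacency:
    def test_threshold_zero_gives_no_neighbors(self, montage):
        g = build_adjacency(montage, threshold_cm=0.0)
        assert not g.matrix.any()

    def test_huge_threshold_gives_complete_graph_over_62(self, montage):
        g = build_adjacency(montage, threshold_cm=100.0)
        assert len(g.labels) == 62
        expected = np.ones((62, 62), bool)
        np.fill_diagonal(expected, False)
        assert np.array_equal(g.matrix, expected)

    def test_default_graph_matches_bruteforce_scan(self, montage):
        """Neighbor sets at 5.44 cm equal an independent O(n^2) scan."""
        g = build_adjacency(montage)
        labels = g.labels
        for i, li in enumerate(labels):
            expected = set()
            for j, lj in enumerate(labels):
                if i == j:
                    continue
                d = np.linalg.norm(montage.position(li) - montage.position(lj))
                if d <= 5.44:
                    expected.add(lj)
            assert set(g.neighbors(li)) == expected

    def test_symmetric_and_irreflexive(self, montage):
        g = build_adjacency(montage)
        assert np.array_equal(g.matrix, g.matrix.T)
        assert not g.matrix.diagonal().any()

    def test_mastoids_excluded_by_default(self, montage):
        g = build_adjacency(montage)
        assert "M1" not in g.labels and "M2" not in g.labels


class TestFindClusters:
    def _graph(self, montage):
        # 6 fronto-central channels, threshold keeping a sparse graph
        chans = ["F3", "Fz", "F4", "C3", "Cz", "C4"]
        return small_adjacency(montage, chans, 6.0)

    def test_single_suprathreshold_point_is_singleton(self, montage):
        g = self._graph(montage)
        t = np.zeros((6, 5))
        t[2, 3] = 4.0
        clusters = find_clusters(t, 3.0, g)
        assert len(clusters) == 1
        assert clusters[0].size == 1
        assert clusters[0].mass == 4.0

    def test_temporal_neighbors_merge(self, montage):
        g = self._graph(montage)
        t = np.zeros((6, 5))
        t[1, 2] = t[1, 3] = 5.0
        (c,) = find_clusters(t, 3.0, g)
        assert c.size == 2 and c.mass == 10.0

    def test_opposite_signs_never_merge(self, montage):
        g = self._graph(montage)
        t = np.zeros((6, 5))
        t[1, 2], t[1, 3] = 5.0, -5.0
        clusters = find_clusters(t, 3.0, g)
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_random_maps_match_floodfill_oracle(self, montage, rng):
        g = self._graph(montage)
        for _ in range(10):
            t = 3.0 * rng.standard_normal((6, 20))
            ours = {(frozenset(map(tuple, c.members)), c.sign)
                    for c in find_clusters(t, 2.5, g)}
            oracle = {(m, s) for m, mass, s in floodfill_clusters(t, 2.5,
                                                                  g.matrix)}
            assert ours == oracle
            # masses agree too
            mass_ours = {frozenset(map(tuple, c.members)): c.mass
                         for c in find_clusters(t, 2.5, g)}
            for m, mass, s in floodfill_clusters(t, 2.5, g.matrix):
                assert mass_ours[m] == pytest.approx(mass)


class TestClusterMassTest:
    def _graph(self, montage):
        chans = ["F3", "Fz", "F4", "C3", "Cz", "C4"]
        return small_adjacency(montage, chans, 6.0)

    def test_points_outside_clusters_have_p_one(self, montage, rng):
        g = self._graph(montage)
        diffs = rng.standard_normal((6, 6, 10))
        res = cluster_mass_test(diffs, ClusterTestConfig(n_perm=100, seed=0), g)
        in_cluster = np.zeros_like(res.p_map, bool)
        for c in res.clusters:
            in_cluster[c.members[:, 0], c.members[:, 1]] = True
        assert np.all(res.p_map[~in_cluster] == 1.0)

    def test_exhaustive_p_matches_full_recompute_oracle(self, montage, rng):
        """n=5 subjects: cluster p-values under 2^5 enumeration equal an
        oracle that re-runs thresholding+flood-fill for every sign pattern."""
        g = self._graph(montage)
        diffs = rng.standard_normal((5, 6, 8)) + 0.8
        cfg = ClusterTestConfig(n_perm=32, seed=0)
        res = cluster_mass_test(diffs, cfg, g)
        assert res.exhaustive

        thr = float(sps.t.ppf(1 - cfg.inclusion_alpha / 2, df=4))
        max_masses = []
        for signs in itertools.product([1.0, -1.0], repeat=5):
            flipped = np.array(signs)[:, None, None] * diffs
            n = 5
            mean = flipped.mean(0)
            sd = flipped.std(0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / (sd / np.sqrt(n))
            masses = [abs(m) for _, m, _ in floodfill_clusters(t, thr, g.matrix)]
            max_masses.append(max(masses) if masses else 0.0)
        max_masses = np.array(max_masses)
        for c in res.clusters:
            expected = np.mean(max_masses >= abs(c.mass) - 1e-12)
            assert c.p_value == pytest.approx(expected, abs=1e-12)

    def test_stronger_effect_never_raises_cluster_p(self, montage, rng):
        g = self._graph(montage)
        noise = rng.standard_normal((8, 6, 10))
        effect = np.zeros((6, 10))
        effect[1:4, 3:7] = 1.0
        p_prev = 1.1
        for amp in (1.0, 2.0, 4.0):
            diffs = noise + amp * effect
            res = cluster_mass_test(diffs, ClusterTestConfig(n_perm=256, seed=3),
                                    g)
            pos = [c for c in res.clusters if c.sign > 0]
            p = min(c.p_value for c in pos)
            assert p <= p_prev + 1e-12
            p_prev = p

    def test_null_distribution_symmetric_under_data_negation(self, montage,
                                                             rng):
        """Sign-flip null: the max-mass distribution for -X mirrors that
        for +X (the symmetric-null assumption holds by construction)."""
        g = self._graph(montage)
        diffs = rng.standard_normal((5, 6, 8))
        cfg = ClusterTestConfig(n_perm=32, seed=0)
        r1 = cluster_mass_test(diffs, cfg, g)
        r2 = cluster_mass_test(-diffs, cfg, g)
        np.testing.assert_allclose(np.sort(r1.max_mass_distribution),
                                   np.sort(r2.max_mass_distribution),
                                   atol=1e-10)

    def test_fewer_than_two_subjects_rejected(self, montage):
        with pytest.raises(ValueError):
            cluster_mass_test(np.zeros((1, 6, 4)),
                              ClusterTestConfig(n_perm=10),
                              self._graph(montage))
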