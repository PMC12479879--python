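from itertools import combinations

import numpy as np
import pytest

import eodsort as es
from eodsort.errors import ConfigError, DomainError
from eodsort.separation import SeparationConfig, TSNEPairSeparator


def brute_force_average_linkage_2(points):
    """Recompute all inter-cluster mean distances at every merge."""
    clusters = [[i] for i in range(len(points))]
    while len(clusters) > 2:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = np.mean([
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a] for j in clusters[b]
            ])
            if best is None or d < best[0]:
                best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


def brute_force_silhouette(points, labels):
    points = np.asarray(points)
    scores = []
    for i, p in enumerate(points):
        same = [j for j in range(len(points))
                if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(p - points[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(p - points[j])
                     for j in range(len(points)) if labels[j] == other])
            for other in set(labels) if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestHCluster2:
    def test_well_separated_pairs(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = es.hcluster2(pts)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(4, 11), 2))
        assert np.array_equal(es.hcluster2(pts),
                              brute_force_average_linkage_2(pts))

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            es.hcluster2(np.zeros((1, 2)))

    def test_label_zero_is_larger_cluster(self):
        pts = np.vstack([np.zeros((7, 2)),
                         np.full((3, 2), 10.0) + np.arange(3)[:, None] * 0.01])
        labels = es.hcluster2(pts)
        assert np.sum(labels == 0) == 7


class TestSilhouette:
    def test_tight_far_blobs_score_high(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)),
                         rng.normal(20, 0.05, (10, 2))])
        labels = np.repeat([0, 1], 10)
        assert es.silhouette(pts, labels) > 0.9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(15, 2))
        labels = rng.integers(0, 2, 15)
        if np.unique(labels).size < 2:
            labels[0] = 1 - labels[0]
        assert es.silhouette(pts, labels) == pytest.approx(
            brute_force_silhouette(pts, labels), abs=1e-10
        )

    def test_random_split_of_one_blob_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(40, 2))
            labels = rng.integers(0, 2, 40)
            if np.unique(labels).size < 2:
                labels[0] = 1 - labels[0]
            vals.append(es.silhouette(pts, labels))
        assert all(abs(v) < 0.2 for v in vals)

    def test_bounds_and_single_cluster(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        labels = rng.integers(0, 2, 12)
        labels[:2] = [0, 1]
        assert -1.0 <= es.silhouette(pts, labels) <= 1.0
        with pytest.raises(DomainError):
            es.silhouette(pts, np.zeros(12, dtype=int))


class TestCDbw:
    def _blobs(self, seed, n=40, sep=12.0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1.0, (n, 2)),
                         rng.normal(sep, 1.0, (n, 2))])
        return pts, np.repeat([0, 1], n)

    def test_true_labels_beat_random_in_9_of_10(self):
        wins = 0
        for seed in range(10):
            pts, labels = self._blobs(seed)
            rng = np.random.default_rng(100 + seed)
            random_labels = rng.permutation(labels)
            if es.cdbw(pts, labels) > es.cdbw(pts, random_labels):
                wins += 1
        assert wins >= 9

    def test_positive_for_valid_input(self):
        pts, labels = self._blobs(0)
        assert es.cdbw(pts, labels) > 0

    def test_scaling_preserves_ranking(self):
        pts, labels = self._blobs(1)
        rng = np.random.default_rng(42)
        alt = labels.copy()
        flip = rng.choice(len(alt), 10, replace=False)
        alt[flip] = 1 - alt[flip]
        order = es.cdbw(pts, labels) > es.cdbw(pts, alt)
        order_scaled = es.cdbw(pts * 2, labels) > es.cdbw(pts * 2, alt)
        assert order == order_scaled

    def test_n_reps_guard(self):
        pts, labels = self._blobs(0, n=5)
        with pytest.raises(ConfigError):
            es.cdbw(pts, labels, n_reps=10)


class TestTSNEEmbed:
    def _features(self, two_fish_waveforms, n_per=100):
        rows = np.vstack([two_fish_waveforms["A"][:n_per],
                          two_fish_waveforms["B"][:n_per]])
        return es.feature_matrix(list(rows), "timefreq"), \
            np.repeat(["A", "B"], n_per)

    def test_nearest_neighbor_purity(self, two_fish_waveforms):
        X, truth = self._features(two_fish_waveforms)
        emb = es.tsne_embed(X, SeparationConfig(perplexity=30, seed=0))
        from scipy.spatial.distance import squareform, pdist
        d = squareform(pdist(emb))
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        purity = np.mean(truth[nn] == truth)
        assert purity >= 0.99

    def test_deterministic_per_seed(self, two_fish_waveforms):
        X, _ = self._features(two_fish_waveforms, n_per=60)
        cfg = SeparationConfig(perplexity=20, seed=7)
        emb1 = es.tsne_embed(X, cfg)
        emb2 = es.tsne_embed(X, cfg)
        assert np.array_equal(emb1, emb2)

    def test_duplicated_rows_embed_together(self, two_fish_waveforms):
        X, _ = self._features(two_fish_waveforms, n_per=40)
        X2 = np.vstack([X, X])
        emb = es.tsne_embed(X2, SeparationConfig(perplexity=20, seed=1))
        n = X.shape[0]
        dists = np.linalg.norm(emb[:n] - emb[n:], axis=1)
        spread = np.linalg.norm(emb.max(axis=0) - emb.min(axis=0))
        assert np.median(dists) < 0.05 * spread

    def test_perplexity_too_large(self):
        with pytest.raises(ConfigError):
            es.tsne_embed(np.random.default_rng(0).normal(size=(30, 4)),
                          SeparationConfig(perplexity=50))


class TestIdentityAssignment:
    def _events(self, amps_ch0_a, amps_ch1_b):
        events = []
        for i, a in enumerate(amps_ch0_a):
            events.append(es.EODEvent(t_s=i * 0.01, channel=0, peak_amp_V=a))
        for i, a in enumerate(amps_ch1_b):
            events.append(es.EODEvent(t_s=1 + i * 0.01, channel=1,
                                      peak_amp_V=a))
        return events

    def test_dominant_channel_polarity_maps_to_a(self):
        events = self._events([0.02, 0.03], [-0.02, -0.03])
        labels = np.array([0, 0, 1, 1])
        id_map, ambiguous = es.assign_cluster_identity(events, labels)
        assert not ambiguous
        assert id_map[0] == "A"  # positive channel-0 cluster sorts first

    def test_identical_signatures_flagged(self):
        events = self._events([0.02, 0.02], [0.0, 0.0])
        events[2] = es.EODEvent(t_s=1.0, channel=0, peak_amp_V=0.02)
        events[3] = es.EODEvent(t_s=1.01, channel=0, peak_amp_V=0.02)
        _, ambiguous = es.assign_cluster_identity(events,
                                                  np.array([0, 0, 1, 1]))
        assert ambiguous

    def test_relabeling_invariance(self):
        events = self._events([0.02, 0.03], [-0.02, -0.03])
        labels = np.array([0, 0, 1, 1])
        map1, _ = es.assign_cluster_identity(events, labels)
        map2, _ = es.assign_cluster_identity(events, 1 - labels)
        assert map1[0] == map2[1] and map1[1] == map2[0]


class TestSelectPerplexity:
    def test_singleton_grid(self, two_fish_waveforms):
        rows = np.vstack([two_fish_waveforms["A"], two_fish_waveforms["B"]])
        X = es.feature_matrix(list(rows), "timefreq")
        truth = np.repeat(["A", "B"], 150)
        best, table = es.select_perplexity([(X, truth)], [50])
        assert best == 50
        assert table.shape == (1, 4)

    def test_returned_value_attains_max_median_mcc(self, two_fish_waveforms):
        rows = np.vstack([two_fish_waveforms["A"], two_fish_waveforms["B"]])
        X = es.feature_matrix(list(rows), "timefreq")
        truth = np.repeat(["A", "B"], 150)
        best, table = es.select_perplexity([(X, truth)], [30, 50])
        best_row = table[table[:, 0] == best][0]
        assert best_row[2] == table[:, 2].max()

    def test_out_of_range_grid(self):
        with pytest.raises(ConfigError):
            es.select_perplexity([], [10])


class TestEndToEnd:
    def test_separate_recovers_truth(self, short_dyad):
        rec, truth = short_dyad
        result, events = es.separate(
            rec, config=SeparationConfig(perplexity=30, seed=0))
        scores = es.evaluate_run(events, truth, 1.0, tol_s=1.0 / rec.fs)
        assert scores.acc >= 0.99
        assert set(result.identity_map.values()) == {"A", "B"}
        assert -1 <= result.ss <= 1
        assert result.cdbw > 0

    def test_same_seed_identical_labels(self, short_dyad):
        rec, _ = short_dyad
        cfg = SeparationConfig(perplexity=30, seed=4)
        r1, _ = es.separate(rec, config=cfg)
        r2, _ = es.separate(rec, config=cfg)
        assert np.array_equal(r1.labels, r2.labels)

    def test_single_fish_still_two_clusters_with_warning(self):
        fish = es.make_fish(8, 0.8, ipi_mean_s=0.1)
        from eodsort.synthetic_fish import DyadSimConfig
        rec, _ = es.simulate_dyad(
            fish, es.make_fish(8, 0.8, ipi_mean_s=0.1),
            DyadSimConfig(duration_s=30.0, seed=8))
        result, _ = es.separate(rec,
                                config=SeparationConfig(perplexity=30,
                                                        seed=0))
        assert np.unique(result.labels).size == 2

    def test_too_few_eods_raises_perplexity_hint(self):
        fish = es.make_fish(1, 0.5, ipi_mean_s=0.5)
        from eodsort.synthetic_fish import DyadSimConfig
        rec, _ = es.simulate_dyad(fish, fish,
                                  DyadSimConfig(duration_s=5.0, seed=1))
        with pytest.raises(ConfigError, match="perplexity"):
            es.separate(rec, config=SeparationConfig(perplexity=50, seed=0))


def test_estimator_fit_predict(two_fish_waveforms):
    rows = np.vstack([two_fish_waveforms["A"][:80],
                      two_fish_waveforms["B"][:80]])
    X = es.feature_matrix(list(rows), "timefreq")
    est = TSNEPairSeparator(perplexity=25, seed=0)
    labels = est.fit_predict(X)
    truth = np.repeat([0, 1], 80)
    aligned, _ = es.align_labels(labels, truth)
    assert np.mean(aligned == truth) >= 0.99
    assert est.embedding_.shape == (160, 2)
    assert np.isfinite(est.silhouette_)
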