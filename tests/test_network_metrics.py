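import numpy as np
import pytest

from comanet.connectivity import ConnectivityMatrix
from comanet.eeg_io import Montage
from comanet.network_metrics import (
    Partition,
    ThresholdedGraph,
    clustering_coefficients,
    density_averaged_metrics,
    detect_communities,
    extract_features,
    modular_span,
    modularity,
    participation_coefficients,
    threshold_by_density,
    FEATURE_KEYS,
)
from comanet.preprocess import EpochedRecording, preprocess
from comanet.spectral import BANDS
from comanet.synthetic_data import Coupling, EEGSimSpec, simulate_eeg
from oracles import (
    clustering_brute,
    modular_span_brute,
    modularity_brute,
    participation_brute,
    threshold_brute,
)


def _cm(values, labels=None):
    n = values.shape[0]
    labels = labels or [f"C{i}" for i in range(n)]
    return ConnectivityMatrix(values, BANDS["alpha"], labels, 10)


def _random_cm(rng, n=8):
    v = rng.uniform(-0.2, 1.0, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return _cm(v)


def _graph(W, labels=None):
    return ThresholdedGraph(W, 1.0, labels or [f"C{i}" for i in range(W.shape[0])])


def _two_cliques(k=5):
    n = 2 * k
    W = np.zeros((n, n))
    W[:k, :k] = 1.0
    W[k:, k:] = 1.0
    np.fill_diagonal(W, 0)
    return W


class TestThresholdByDensity:
    def test_full_density_keeps_everything_nonnegative(self):
        rng = np.random.default_rng(0)
        cm = _random_cm(rng, 5)
        g = threshold_by_density(cm, 1.0)
        np.testing.assert_allclose(g.weights, np.clip(cm.values, 0, None))

    def test_half_density_counts(self):
        rng = np.random.default_rng(1)
        cm = _random_cm(rng, 4)
        g = threshold_by_density(cm, 0.5)
        assert (np.triu(g.weights, 1) > 0).sum() <= 3
        kept = set(map(tuple, np.argwhere(np.triu(g.weights, 1) > 0)))
        top3 = sorted(
            [(i, j) for i in range(4) for j in range(i + 1, 4)],
            key=lambda p: -max(cm.values[p], 0),
        )[:3]
        assert kept <= set(top3)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("density", [0.9, 0.5, 0.2])
    def test_matches_brute_force(self, seed, density):
        rng = np.random.default_rng(seed)
        cm = _random_cm(rng, 7)
        g = threshold_by_density(cm, density)
        expected = threshold_brute(cm.values, density)
        # brute force may retain zero-weight pairs; compare weight placement
        for (i, j) in expected:
            w = max(cm.values[i, j], 0.0)
            assert g.weights[i, j] == pytest.approx(w)
        iu = np.triu_indices(7, k=1)
        n_retained = len(expected)
        n_positive = sum(
            1 for (i, j) in expected if cm.values[i, j] > 0
        )
        assert (g.weights[iu] > 0).sum() == n_positive

    def test_zero_edges_error(self):
        rng = np.random.default_rng(2)
        cm = _random_cm(rng, 3)
        with pytest.raises(ValueError, match="zero edges"):
            threshold_by_density(cm, 0.01)


class TestDetectCommunities:
    def test_disconnected_cliques_recovered(self):
        g = _graph(_two_cliques(5))
        p = detect_communities(g, seed=0)
        assert p.n_modules == 2
        assert len(set(p.assignment[:5])) == 1
        assert len(set(p.assignment[5:])) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        cm = _random_cm(rng, 10)
        g = threshold_by_density(cm, 0.5)
        p1 = detect_communities(g, seed=42, n_runs=20)
        p2 = detect_communities(g, seed=42, n_runs=20)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        assert p1.q == p2.q

    def test_no_edges_error(self):
        g = _graph(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="edge"):
            detect_communities(g, seed=0)


class TestModularity:
    def test_two_cliques_half(self):
        g = _graph(_two_cliques(5))
        p = Partition(np.array([0] * 5 + [1] * 5), 0.0)
        assert modularity(g, p) == pytest.approx(0.5)

    def test_single_module_zero(self):
        rng = np.random.default_rng(4)
        g = _graph(np.clip(_random_cm(rng, 6).values, 0, None))
        p = Partition(np.zeros(6, dtype=int), 0.0)
        assert modularity(g, p) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        W = np.clip(_random_cm(rng, 8).values, 0, None)
        memb = rng.integers(0, 3, 8)
        g = _graph(W)
        p = Partition(memb, 0.0)
        assert modularity(g, p) == pytest.approx(
            modularity_brute(W, memb), abs=1e-12
        )


class TestParticipation:
    def test_single_module_all_zero(self):
        rng = np.random.default_rng(5)
        g = _graph(np.clip(_random_cm(rng, 6).values, 0, None))
        pc, sd = participation_coefficients(g, Partition(np.zeros(6, int), 0.0))
        np.testing.assert_allclose(pc, 0.0, atol=1e-12)
        assert sd == 0.0

    def test_equal_split_gives_half(self):
        # node 0 connects equally into two modules
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[0, 2] = W[2, 0] = 1.0
        g = _graph(W)
        pc, _ = participation_coefficients(g, Partition(np.array([0, 0, 1]), 0.0))
        assert pc[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        W = np.clip(_random_cm(rng, 8).values, 0, None)
        memb = rng.integers(0, 3, 8)
        pc, sd = participation_coefficients(_graph(W), Partition(memb, 0.0))
        np.testing.assert_allclose(pc, participation_brute(W, memb), atol=1e-12)
        assert 0 <= sd < 1


class TestClustering:
    def test_triangle_and_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[0, 2] = W[2, 0] = W[1, 2] = W[2, 1] = 1.0
        c, mean = clustering_coefficients(_graph(W))
        np.testing.assert_allclose(c, 1.0)
        path = np.zeros((3, 3))
        path[0, 1] = path[1, 0] = path[1, 2] = path[2, 1] = 1.0
        c, _ = clustering_coefficients(_graph(path))
        assert c[1] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_networkx(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        W = np.clip(_random_cm(rng, 8).values - 0.3, 0, None)
        c, mean = clustering_coefficients(_graph(W))
        np.testing.assert_allclose(c, clustering_brute(W), atol=1e-12)
        G = nx.from_numpy_array(W)
        nx_c = nx.clustering(G, weight="weight")
        np.testing.assert_allclose(c, [nx_c[i] for i in range(8)], atol=1e-10)


class TestModularSpan:
    def _montage(self, coords, labels):
        return Montage("test", labels, coords)

    def test_identical_coordinates_zero(self):
        W = _two_cliques(2)
        labels = [f"C{i}" for i in range(4)]
        m = self._montage(np.tile([1.0, 0, 0], (4, 1)), labels)
        p = Partition(np.array([0, 0, 1, 1]), 0.0)
        assert modular_span(_graph(W, labels), p, m) == 0.0

    def test_single_edge_distance_one(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.7
        labels = ["a", "b"]
        coords = np.array([[1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])  # 60 deg apart
        m = self._montage(coords, labels)
        p = Partition(np.array([0, 0]), 0.0)
        assert modular_span(_graph(W, labels), p, m) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        W = np.clip(_random_cm(rng, n).values - 0.2, 0, None)
        memb = rng.integers(0, 3, n)
        theta = rng.uniform(0, 2 * np.pi, n)
        coords = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
        labels = [f"C{i}" for i in range(n)]
        m = self._montage(coords, labels)
        got = modular_span(_graph(W, labels), Partition(memb, 0.0), m)
        assert got == pytest.approx(
            modular_span_brute(W, memb, coords), abs=1e-12
        )


class TestDensityAveragedMetrics:
    def test_average_is_mean_of_per_density(self, ring8):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 1, (8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        cm = _cm(v, list(ring8.labels))
        gm = density_averaged_metrics(cm, ring8, seed=0, n_runs=10)
        for name, avg in gm.averaged.items():
            per = [gm.per_density[d][name] for d in gm.per_density]
            assert avg == pytest.approx(np.mean(per))

    def test_metric_ranges_on_random_graphs(self, ring8):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cm = _random_cm(rng, 8)
            cm.channel_labels = list(ring8.labels)
            gm = density_averaged_metrics(cm, ring8, seed=seed, n_runs=10)
            for d, metrics in gm.per_density.items():
                assert -0.5 <= metrics["modularity"] <= 1.0
                assert 0.0 <= metrics["clustering_mean"] <= 1.0
                assert 0.0 <= metrics["participation_sd"] < 1.0
                assert metrics["modular_span"] >= 0.0


@pytest.fixture(scope="module")
def epoched(ring8):
    spec = EEGSimSpec(
        duration_s=120.0, sampling_rate=128, montage_ref="ring8",
        band_profiles={"delta": 0.2, "theta": 0.1, "alpha": 0.5},
        couplings={"alpha": Coupling({f"S{i}": i // 4 for i in range(8)},
                                     c=0.8, lag_deg=45.0)},
        mixing=0.1,
    )
    rec = simulate_eeg(spec, montage=ring8)
    return preprocess(rec)


class TestExtractFeatures:
    def test_eight_finite_features(self, epoched, ring8):
        feats = extract_features(epoched, ring8, seed=0, n_runs=20)
        assert list(feats) == FEATURE_KEYS
        assert all(np.isfinite(v) for v in feats.values())

    def test_alpha_dominant_ordering(self, epoched, ring8):
        feats = extract_features(epoched, ring8, seed=0, n_runs=20)
        assert feats["alpha_rel_power"] > feats["delta_rel_power"]

    def test_channel_order_invariance(self, epoched, ring8):
        feats = extract_features(epoched, ring8, seed=0, n_runs=20)
        perm = np.random.default_rng(1).permutation(epoched.n_channels)
        shuffled = EpochedRecording(
            epochs=epoched.epochs[:, perm, :],
            sampling_rate=epoched.sampling_rate,
            channel_labels=[epoched.channel_labels[i] for i in perm],
        )
        feats2 = extract_features(shuffled, ring8, seed=0, n_runs=20)
        for k in FEATURE_KEYS:
            assert abs(feats[k] - feats2[k]) <= 1e-9
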