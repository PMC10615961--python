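"""EEG network features: connectivity layers, strength, search
information, multilayer partitions, flexibility, allegiance."""

import itertools

import networkx as nx
import numpy as np
import pytest

from surgilearn.eegnet import (
    CortexMap,
    EEGRecording,
    LayerStack,
    PartitionEnsemble,
    allegiance,
    build_layers,
    cortex_from_label,
    default_cortex_map,
    extract_eeg_features,
    flexibility,
    multilayer_partition,
    node_strength,
    preprocess,
    recruitment_integration,
    search_information,
    synthetic_channel_names,
)
from surgilearn.names import EEG_FEATURES


def brute_force_si(W):
    """Oracle: enumerate shortest paths with networkx and accumulate the
    walker's step probabilities along the lexicographically smallest one."""
    n = W.shape[0]
    s = W.sum(axis=1)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                G.add_edge(i, j, length=1.0 / W[i, j])
    SI = np.full((n, n), np.inf)
    np.fill_diagonal(SI, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            try:
                paths = list(nx.all_shortest_paths(G, i, j, weight="length"))
            except nx.NetworkXNoPath:
                continue
            path = min(tuple(p) for p in paths)
            SI[i, j] = sum(
                np.log2(s[u]) - np.log2(W[u, v]) for u, v in zip(path[:-1], path[1:])
            )
    return SI


def random_weighted_graph(rng, n, p_edge=0.6):
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0)
    return W


class TestPreprocess:
    def test_passband_signal_preserved(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)[None, :]
        out = preprocess(EEGRecording(sig, fs))
        z = (sig[0] - sig[0].mean()) / sig[0].std()
        r = np.corrcoef(out.signal[0], z)[0, 1]
        assert r > 0.99

    def test_stopband_signal_attenuated(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        sig = np.sin(2 * np.pi * 60.0 * t)[None, :]
        sos_out = preprocess(EEGRecording(sig, fs))
        # z-scoring would re-inflate a pure tone, so check pre-z RMS via
        # the filter alone: a 60 Hz tone in a 4-30 Hz band must lose >95%
        import scipy.signal

        sos = scipy.signal.butter(4, [4, 30], btype="bandpass", fs=fs, output="sos")
        filt = scipy.signal.sosfiltfilt(sos, sig[0])
        core = slice(int(0.5 * fs), -int(0.5 * fs))  # skip filtfilt edge transients
        assert np.sqrt(np.mean(filt[core] ** 2)) < 0.05 * np.sqrt(np.mean(sig[0, core] ** 2))
        assert np.all(np.isfinite(sos_out.signal))

    def test_flat_channel_becomes_zero(self):
        fs = 500.0
        sig = np.vstack([np.full(2000, 7.0), np.random.default_rng(0).normal(size=2000)])
        out = preprocess(EEGRecording(sig, fs))
        assert np.all(out.signal[0] == 0.0)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            preprocess(EEGRecording(np.zeros((2, 100)), 100.0), band=(4.0, 60.0))


class TestLayers:
    def test_identical_channels_fully_connected(self, rng):
        base = rng.normal(size=2000)
        sig = np.vstack([base, base, base])
        stack = build_layers(EEGRecording(sig, 500.0), 2.0, 2.0)
        for A in stack.layers:
            off = A[~np.eye(3, dtype=bool)]
            np.testing.assert_allclose(off, 1.0)
            np.testing.assert_allclose(np.diag(A), 0.0)

    def test_orthogonal_sinusoids_unconnected(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        sig = np.vstack([np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)])
        stack = build_layers(EEGRecording(sig, fs), 2.0, 2.0)
        for A in stack.layers:
            assert A[0, 1] < 1e-10

    def test_independent_noise_weakly_connected(self, rng):
        sig = rng.normal(size=(4, 2000))
        stack = build_layers(EEGRecording(sig, 500.0), 2.0, 2.0)
        mean_w = np.mean([A[~np.eye(4, dtype=bool)].mean() for A in stack.layers])
        assert mean_w < 0.1

    def test_single_window_rejected(self, rng):
        sig = rng.normal(size=(3, 900))
        with pytest.raises(ValueError):
            build_layers(EEGRecording(sig, 500.0), 2.0, 2.0)


class TestStrength:
    def test_complete_graph(self):
        A = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(node_strength(A), 4.0)

    def test_zero_matrix(self):
        np.testing.assert_allclose(node_strength(np.zeros((4, 4))), 0.0)

    def test_weighted_triangle(self):
        A = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
        np.testing.assert_allclose(node_strength(A), 1.0)

    def test_asymmetric_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1.0
        with pytest.raises(ValueError):
            node_strength(A)


class TestSearchInformation:
    def test_two_node_graph_zero_bits(self):
        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        np.testing.assert_allclose(search_information(W), 0.0, atol=1e-12)

    def test_complete_k4_log2_three(self):
        W = np.ones((4, 4)) - np.eye(4)
        SI = search_information(W)
        off = SI[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, np.log2(3.0))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            W = random_weighted_graph(rng, n)
            mine = search_information(W, warn_disconnected=False)
            oracle = brute_force_si(W)
            finite = np.isfinite(oracle)
            assert np.array_equal(np.isfinite(mine), finite)
            np.testing.assert_allclose(mine[finite], oracle[finite], atol=1e-9)

    def test_disconnected_pairs_infinite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.warns(UserWarning, match="disconnected"):
            SI = search_information(W)
        assert np.isinf(SI[0, 2]) and np.isfinite(SI[0, 1])

    def test_nonnegative(self, rng):
        W = random_weighted_graph(rng, 8, 0.9)
        SI = search_information(W, warn_disconnected=False)
        assert np.all(SI[np.isfinite(SI)] >= -1e-12)


def planted_two_block_stack(n=12, n_layers=4):
    A = np.zeros((n, n))
    h = n // 2
    A[:h, :h] = 1.0
    A[h:, h:] = 1.0
    np.fill_diagonal(A, 0.0)
    return LayerStack([A.copy() for _ in range(n_layers)], 2.0, 2.0)


class TestMultilayerPartition:
    def test_planted_bipartition_recovered_exactly(self):
        stack = planted_two_block_stack()
        ens = multilayer_partition(stack, n_runs=10, seed=3)
        h = stack.n_nodes // 2
        for r in range(ens.n_runs):
            for l in range(ens.n_layers):
                g = ens.labels[r, l]
                assert len(set(g[:h])) == 1
                assert len(set(g[h:])) == 1
                assert g[0] != g[-1]

    def test_strong_coupling_freezes_communities(self, rng):
        layers = []
        for _ in range(4):
            M = rng.random((10, 10))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            layers.append(M)
        ens = multilayer_partition(LayerStack(layers, 2, 2), omega=100.0, n_runs=5, seed=1)
        assert flexibility(ens).max() == 0.0

    def test_same_seed_same_ensemble(self):
        stack = planted_two_block_stack()
        a = multilayer_partition(stack, n_runs=5, seed=9).labels
        b = multilayer_partition(stack, n_runs=5, seed=9).labels
        assert np.array_equal(a, b)

    def test_identical_layers_give_zero_flexibility(self):
        """Modal partitions on identical layers with omega>0 should not
        change across layers at zero noise."""
        stack = planted_two_block_stack(n=10, n_layers=5)
        ens = multilayer_partition(stack, n_runs=8, seed=2)
        assert flexibility(ens).max() == 0.0

    def test_invalid_run_count_rejected(self):
        with pytest.raises(ValueError):
            multilayer_partition(planted_two_block_stack(), n_runs=0)


class TestFlexibility:
    def test_constant_labels_zero(self):
        labels = np.ones((2, 5, 4), dtype=int)
        np.testing.assert_allclose(flexibility(PartitionEnsemble(labels)), 0.0)

    def test_alternating_labels_one(self):
        labels = np.zeros((1, 6, 3), dtype=int)
        labels[0, 1::2] = 1
        np.testing.assert_allclose(flexibility(PartitionEnsemble(labels)), 1.0)

    def test_one_change_in_four_transitions(self):
        labels = np.zeros((1, 5, 1), dtype=int)
        labels[0, 3:, 0] = 1  # change at transition 2->3 only
        assert flexibility(PartitionEnsemble(labels))[0] == pytest.approx(0.25)

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            flexibility(PartitionEnsemble(np.zeros((1, 1, 3), dtype=int)))


class TestAllegiance:
    def test_single_community_all_ones(self):
        P = allegiance(PartitionEnsemble(np.zeros((1, 1, 4), dtype=int)))
        np.testing.assert_allclose(P, 1.0)

    def test_never_coassigned_zero(self):
        labels = np.array([[[0, 1]]])
        P = allegiance(PartitionEnsemble(labels))
        assert P[0, 1] == 0.0 and P[0, 0] == 1.0

    def test_three_of_four_slices(self):
        labels = np.array([[[0, 0], [0, 0]], [[0, 0], [0, 1]]])  # 2 runs x 2 layers
        P = allegiance(PartitionEnsemble(labels))
        assert P[0, 1] == pytest.approx(0.75)

    def test_symmetric_unit_diagonal(self, rng):
        labels = rng.integers(0, 3, size=(4, 5, 8))
        P = allegiance(PartitionEnsemble(labels))
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(np.diag(P), 1.0)
        assert np.all((P >= 0) & (P <= 1))


class TestRecruitmentIntegration:
    cortices = np.array(["frontal"] * 3 + ["parietal"] * 3, dtype=object)

    def test_all_ones_allegiance(self):
        P = np.ones((6, 6))
        rec, integ = recruitment_integration(P, self.cortices)
        np.testing.assert_allclose(rec, 1.0)
        np.testing.assert_allclose(integ, 1.0)

    def test_block_diagonal_allegiance(self):
        P = np.zeros((6, 6))
        P[:3, :3] = 1.0
        P[3:, 3:] = 1.0
        rec, integ = recruitment_integration(P, self.cortices)
        np.testing.assert_allclose(rec, 1.0)
        np.testing.assert_allclose(integ, 0.0)

    def test_uniform_half_allegiance(self):
        P = np.full((6, 6), 0.5)
        np.fill_diagonal(P, 1.0)
        rec, integ = recruitment_integration(P, self.cortices)
        np.testing.assert_allclose(rec, 0.5)
        np.testing.assert_allclose(integ, 0.5)

    def test_singleton_cortex_recruitment_nan(self):
        cort = np.array(["frontal", "parietal", "parietal"], dtype=object)
        P = np.ones((3, 3))
        rec, _ = recruitment_integration(P, cort)
        assert np.isnan(rec[0]) and rec[1] == 1.0


class TestExtraction:
    def make_recording(self, rng, n_ch=16, duration=8.0, switch=0.0):
        from surgilearn.simulate import (
            SimulationConfig,
            generate_eeg_recording,
            make_module_schedule,
        )

        cfg = SimulationConfig(n_participants=1, eeg_channels=n_ch, duration=duration)
        sched = make_module_schedule(n_ch, cfg.n_layers, 2, switch_fraction=switch, rng=rng)
        rec, sched = generate_eeg_recording(sched, cfg, rng)
        return rec, sched

    def test_exactly_twenty_features(self, rng):
        rec, _ = self.make_recording(rng)
        feats = extract_eeg_features(rec, default_cortex_map(rec.channel_names), n_runs=5, seed=0)
        assert tuple(feats) == EEG_FEATURES
        assert len(feats) == 20

    def test_static_structure_gives_low_flexibility(self, rng):
        rec, _ = self.make_recording(rng, switch=0.0)
        feats = extract_eeg_features(rec, default_cortex_map(rec.channel_names), n_runs=5, seed=0)
        for cortex in ("frontal", "parietal", "occipital", "temporal"):
            assert feats[f"flexibility_{cortex}"] < 0.1

    def test_switching_channels_are_more_flexible(self, rng):
        """Channels planted to switch communities every layer show higher
        flexibility than channels that never switch."""
        from surgilearn.simulate import SimulationConfig, generate_eeg_recording

        n_ch, n_layers = 16, 5
        cfg = SimulationConfig(n_participants=1, eeg_channels=n_ch, duration=10.0)
        sched = np.zeros((n_layers, n_ch), dtype=int)
        sched[:, 8:] = 1                      # static split
        sched[1::2, :4] = 1                   # first 4 channels flip every layer
        rec, _ = generate_eeg_recording(sched, cfg, rng, noise_sd=0.1)
        stack = build_layers(preprocess(rec), 2.0, 2.0)
        ens = multilayer_partition(stack, omega=0.5, n_runs=8, seed=4)
        flex = flexibility(ens)
        assert flex[:4].mean() > flex[8:].mean() + 0.3

    def test_missing_cortex_named_in_error(self, rng):
        rec, _ = self.make_recording(rng)
        cmap = CortexMap({name: "frontal" for name in rec.channel_names})
        with pytest.raises(ValueError, match="parietal"):
            extract_eeg_features(rec, cmap, n_runs=3, seed=0)

    def test_channel_permutation_leaves_cortex_averages(self, rng):
        rec, _ = self.make_recording(rng)
        cmap = default_cortex_map(rec.channel_names)
        f1 = extract_eeg_features(rec, cmap, n_runs=5, seed=0)
        perm = rng.permutation(rec.n_channels)
        rec2 = EEGRecording(
            rec.signal[perm], rec.sampling_rate, [rec.channel_names[i] for i in perm]
        )
        f2 = extract_eeg_features(rec2, cmap, n_runs=5, seed=0)
        for name in ("strength_frontal", "search_information_parietal"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9)

    def test_feature_ranges(self, rng):
        rec, _ = self.make_recording(rng, switch=0.3)
        feats = extract_eeg_features(rec, default_cortex_map(rec.channel_names), n_runs=5, seed=0)
        for cortex in ("frontal", "parietal", "occipital", "temporal"):
            assert 0.0 <= feats[f"flexibility_{cortex}"] <= 1.0
            assert 0.0 <= feats[f"recruitment_{cortex}"] <= 1.0
            assert 0.0 <= feats[f"integration_{cortex}"] <= 1.0
            assert feats[f"search_information_{cortex}"] >= 0.0
            assert feats[f"strength_{cortex}"] >= 0.0


@pytest.mark.parametrize(
    "label,cortex",
    [
        ("Fp1", "frontal"), ("AF7", "frontal"), ("F3", "frontal"), ("FC5", "frontal"),
        ("P7", "parietal"), ("CP3", "parietal"),
        ("O1", "occipital"), ("PO8", "occipital"),
        ("T7", "temporal"), ("FT9", "temporal"), ("TP10", "temporal"),
        ("Cz", None), ("C3", None),
    ],
)
def test_ten_five_prefix_mapping(label, cortex):
    assert cortex_from_label(label) == cortex


def test_synthetic_montage_covers_all_cortices():
    names = synthetic_channel_names(124)
    cmap = default_cortex_map(names)
    idx = cmap.indices(names)
    assert len(names) == 124
    assert all(v.size >= 25 for v in idx.values())
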