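"""Motif statistics, filter analysis, attributions and in silico evolution."""

import numpy as np
import pytest

from flipkit import interpret
from flipkit.interpret import (
    cluster_attributions,
    filter_correlations,
    in_silico_evolve,
    integrated_gradients,
    motif_effect,
    mutation_neighbors,
    start_codon_effect,
)


def _random_seqs(n, seed=0, length=17):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]


class TestMotifEffect:
    def test_hand_countable_group(self):
        seqs = ["AGGAGGCCCCCCCCCCC", "AGGAGGCCCCCCCCCCT",
                "CCCCCCCCCCCCCCCCC", "TTTTTTTTTTTTTTTTT"]
        vals = [0.8, 0.6, 0.1, 0.2]
        rep = motif_effect(seqs, vals, "AGGAGG", -17)
        assert rep.group_size == 2
        assert rep.median == pytest.approx(0.7)
        assert rep.overall_median == pytest.approx(np.median(vals))

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            motif_effect(["A" * 17], [0.5], "AGGAGG", -3)

    def test_empty_group_returns_none(self):
        assert motif_effect(["C" * 17], [0.5], "AGGAGG", -17) is None

    def test_sequences_with_stray_start_codons_excluded(self):
        carrier = "AGGAGG" + "ATG" + "C" * 8     # stray ATG at -11
        clean = "AGGAGG" + "C" * 11
        rep = motif_effect([carrier, clean], [0.9, 0.4], "AGGAGG", -17)
        assert rep.group_size == 1
        assert rep.median == pytest.approx(0.4)

    def test_planted_offset_recovered(self):
        rng = np.random.default_rng(1)
        seqs = _random_seqs(3000, seed=1)
        motif, pos = "AGGA", -10
        idx = 17 + pos
        has = np.array([
            s[idx:idx + 4] == motif
            and not interpret._has_other_start(s, None)
            for s in seqs
        ])
        clean = np.array([
            not interpret._has_other_start(s, None) for s in seqs
        ])
        vals = rng.normal(0.3, 0.02, len(seqs))
        vals[has] += 0.25
        vals = np.clip(vals, 0, 1)
        rep = motif_effect(seqs, vals, motif, pos)
        background = np.median(vals[clean & ~has])
        assert rep.group_size == has.sum()
        assert rep.median - background == pytest.approx(0.25, abs=0.03)


class TestStartCodonEffect:
    def test_frame_annotation(self):
        seqs = ["C" * 14 + "ATG", "C" * 13 + "ATGC"]
        rep3 = start_codon_effect(seqs, [0.5, 0.5], "ATG", -3)
        rep4 = start_codon_effect(seqs, [0.5, 0.5], "ATG", -4)
        assert rep3.in_frame is True
        assert rep4.in_frame is False

    def test_overlapping_native_start_rejected(self):
        with pytest.raises(ValueError):
            start_codon_effect(["A" * 17], [0.5], "ATG", -2)

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            start_codon_effect(["A" * 17], [0.5], "AAA", -6)


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(2)
        w = rng.normal(0, 1, (17, 4))

        def vg(batch):
            batch = np.asarray(batch, dtype=float)
            vals = (batch * w).sum(axis=(1, 2))
            grads = np.tile(w, (batch.shape[0], 1, 1))
            return vals, grads

        x = np.eye(4)[np.random.default_rng(3).integers(0, 4, 17)]
        for steps in (16, 64):
            attr = integrated_gradients(vg, x, steps=steps)
            assert np.allclose(attr.scores, w * x, atol=1e-12)
            assert attr.completeness_residual < 1e-10

    def test_baseline_input_gives_zero_attributions(self):
        def vg(batch):
            batch = np.asarray(batch, dtype=float)
            return batch.sum(axis=(1, 2)), np.ones_like(batch)

        attr = integrated_gradients(vg, np.zeros((17, 4)))
        assert np.all(attr.scores == 0.0)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            integrated_gradients(lambda b: (None, None),
                                 np.zeros((17, 4)), steps=8)

    def test_completeness_on_trained_model(self, tiny_ensemble,
                                           activity_dataset):
        vg = interpret.ensemble_value_and_grad(tiny_ensemble)
        x = activity_dataset["X"][7]
        attr = integrated_gradients(vg, x, steps=256)
        gap = abs(attr.prediction - attr.baseline_prediction)
        assert attr.completeness_residual < 0.01 * max(gap, 1e-9)


class TestAttributionClustering:
    def test_single_cluster_medoid_nearest_pool_mean(self):
        rng = np.random.default_rng(4)
        A = rng.normal(0, 1, (10, 17, 4))
        out = cluster_attributions(A, [f"s{i}" for i in range(10)], k=1)
        flat = A.reshape(10, -1)
        d = np.linalg.norm(flat - flat.mean(axis=0), axis=1)
        assert out[0]["medoid_index"] == np.argmin(d)

    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(5)
        protos = [rng.normal(0, 1, 68) for _ in range(3)]
        A = np.array(
            [protos[i // 8] + rng.normal(0, 0.05, 68) for i in range(24)]
        ).reshape(24, 17, 4)
        out = cluster_attributions(A, [f"s{i}" for i in range(24)], k=3,
                                   seed=1)
        medoid_groups = sorted(o["medoid_index"] // 8 for o in out)
        assert medoid_groups == [0, 1, 2]

    def test_pool_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_attributions(np.zeros((3, 17, 4)), ["a", "b", "c"], k=5)


class TestFilterCorrelations:
    def test_g_detector_filter_correlates(self, activity_dataset):
        """A hand-built filter that responds to G correlates positively
        with a G-count phenotype."""
        from flipkit.predictor import NetConfig, TrainedNet
        from flipkit.nn import BetaResNet

        net = BetaResNet(n_blocks=1, filters=4, kernels=(1, 1), seed=0)
        conv = net.blocks[0].conv_a
        conv.W.value[:] = 0.0
        conv.W.value[2, 0] = 1.0        # channel G -> filter 0
        conv.b.value[:] = 0.0
        wrapped = TrainedNet(net, NetConfig(n_blocks=1, filters=4,
                                            kernel_sizes=(1, 1)))
        X = activity_dataset["X"][:400]
        y = X[:, :, 2].sum(axis=1)      # number of G bases
        out = filter_correlations(wrapped, X, y, n_clusters=2)
        assert np.all(out["correlations"][0] > 0.1)

    def test_random_network_near_zero_correlation(self, tiny_net,
                                                  activity_dataset):
        from flipkit.predictor import NetConfig, TrainedNet
        from flipkit.nn import BetaResNet

        net = TrainedNet(BetaResNet(n_blocks=2, filters=12, seed=9),
                         NetConfig())
        d = activity_dataset
        rng = np.random.default_rng(6)
        y_rand = rng.random(300)
        out = filter_correlations(net, d["X"][:300], y_rand, n_clusters=4)
        assert np.mean(np.abs(out["correlations"])) < 0.12

    def test_twelve_filters_twelve_singletons(self, activity_dataset):
        from flipkit.predictor import NetConfig, TrainedNet
        from flipkit.nn import BetaResNet

        net = TrainedNet(BetaResNet(n_blocks=1, filters=12, seed=2),
                         NetConfig())
        d = activity_dataset
        out = filter_correlations(net, d["X"][:200], d["y"][:200],
                                  n_clusters=12)
        assert len(out["clusters"]) == 12
        assert all(len(c["members"]) == 1 for c in out["clusters"].values())
        assert out["clusters"][1]["medoid_logo"].shape == (9, 4)


class TestEvolution:
    def test_neighbor_count_is_1275(self):
        neigh = mutation_neighbors("A" * 17)
        assert len(neigh) == 17 * 3 + (17 * 16 // 2) * 9 == 1275
        assert len(set(neigh)) == 1275

    def test_g_count_toy_converges_in_nine_rounds(self):
        def scorer(seqs):
            return np.array([s.count("G") for s in seqs], float)

        trace = in_silico_evolve(scorer, "A" * 17, "maximize")
        assert trace.sequences[-1] == "G" * 17
        # 17 positions, 2 fixed per round -> ceil(17/2) = 9 rounds
        assert len(trace.rounds) - 1 == 9
        assert np.all(np.diff(trace.scores) > 0)

    def test_local_optimum_terminates_immediately(self):
        def scorer(seqs):
            return np.array([s.count("G") for s in seqs], float)

        trace = in_silico_evolve(scorer, "G" * 17, "maximize")
        assert len(trace.rounds) == 1

    def test_minimize_direction_monotone_decreasing(self, tiny_net):
        from flipkit.predictor import encode_batch

        def scorer(seqs):
            return tiny_net.predict_mean(encode_batch(seqs))

        trace = in_silico_evolve(scorer, "A" * 17, "minimize", max_rounds=3)
        assert np.all(np.diff(trace.scores) < 0) or len(trace.rounds) == 1
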