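"""Relevance propagation: conservation, fixtures, region statistics, ablation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eci._nn import Conv2D, Flatten, MaxPool2D, ReLU, Sequential
from eci.explain import (
    RegionScores,
    RelevanceMap,
    drop_electrodes,
    electrode_ablation,
    lrp,
    region_scores,
    region_stats,
)
from eci.model import CNNSpec, TrainSpec
from eci.workflows import lopo_indicator


def _positive_net(depth, seed=0):
    """Published architecture with positive weights and zero biases, float64:
    all pre-activations are strictly positive for positive inputs."""
    net = CNNSpec().build(depth, np.random.default_rng(seed), dtype=np.float64)
    for obj, name in net.params():
        if name == "W":
            setattr(obj, name, np.abs(getattr(obj, name)) + 1e-3)
    return net


def _target_relevance(net, x, cls=1):
    logits = net.forward(x)
    R = np.zeros_like(logits)
    R[np.arange(len(x)), cls] = logits[:, cls]
    return logits[:, cls], R


class TestConservation:
    def test_epsilon_zero_conserves_on_positive_fixture_nets(self):
        rng = np.random.default_rng(1)
        for depth in (5, 72):
            net = _positive_net(depth)
            x = rng.uniform(0.1, 1.0, size=(50, 10, 11, depth))
            f, R0 = _target_relevance(net, x)
            rel = net.relevance(R0, eps=0.0)
            err = np.abs(rel.reshape(50, -1).sum(axis=1) - f) / np.abs(f)
            assert err.max() <= 1e-6

    def test_leakage_grows_smoothly_with_epsilon(self):
        net = _positive_net(5)
        x = np.random.default_rng(3).uniform(0.1, 1.0, size=(8, 10, 11, 5))
        f, R0 = _target_relevance(net, x)
        errs = []
        for eps in (0.0, 1e-3, 1e-2, 1e-1):
            rel = net.relevance(R0, eps=eps)
            errs.append(np.abs(rel.reshape(8, -1).sum(axis=1) - f).mean())
        assert errs == sorted(errs)

    def test_single_linear_layer_reproduces_w_times_x_exactly(self):
        w = np.array([0.5, -1.25, 2.0])
        conv = Conv2D(1, 1, 3, 1, (1, 1), np.random.default_rng(0), dtype=np.float64)
        conv.W = w.reshape(1, 1, 3, 1)
        conv.b[:] = 0.0
        net = Sequential([conv, Flatten()])
        x = np.array([[[[1.5, 2.0, -0.5]]]])
        out = net.forward(x)
        assert out[0, 0] == np.dot(w, x.ravel())
        rel = net.relevance(out.copy(), eps=0.0)
        assert np.array_equal(rel.ravel(), w * x.ravel())

    def test_max_pool_routing_preserves_total_relevance(self):
        rng = np.random.default_rng(5)
        pool = MaxPool2D(2, 2, (1, 2))
        x = rng.normal(size=(4, 6, 8, 3))
        out = pool.forward(x)
        routed = pool.relevance(out.copy(), eps=0.0)
        assert routed.sum() == pytest.approx(out.sum(), rel=1e-12)

    def test_zero_input_on_bias_free_net_gives_zero_relevance(self):
        net = _positive_net(5)
        x = np.zeros((2, 10, 11, 5))
        _f, R0 = _target_relevance(net, x)
        rel = net.relevance(R0, eps=0.0)
        assert np.all(rel == 0.0)


class TestLrpInterface:
    def test_map_matches_input_shape_and_null_cells_are_zero(
            self, trained_awareness, small_tensor, layout60):
        rmap = lrp(trained_awareness, small_tensor)
        assert rmap.values.shape == small_tensor.values.shape
        for r, c in layout60.null_cells:
            assert np.all(rmap.values[:, r, c, :] == 0.0)

    def test_target_class_variants(self, trained_awareness, small_tensor):
        few = small_tensor.select_trials(np.arange(4))
        for target in ("high", "low", "predicted"):
            rmap = lrp(trained_awareness, few, target_class=target)
            assert np.all(np.isfinite(rmap.values))
        with pytest.raises(ValueError, match="target_class"):
            lrp(trained_awareness, few, target_class="middle")

    def test_depth_mismatch_rejected(self, trained_awareness, small_clean, layout60):
        from eci.features import to_spatiospectral
        from eci.preprocess import window

        spect = to_spatiospectral(window(small_clean, 200.0, 400.0), layout60)
        with pytest.raises(ValueError, match="depth"):
            lrp(trained_awareness, spect)


def test_relevance_container_round_trip(tmp_path, trained_awareness, small_tensor):
    from eci.explain import read_relevance, write_relevance

    rmap = lrp(trained_awareness, small_tensor.select_trials(np.arange(5)))
    write_relevance(tmp_path / "r.h5", rmap)
    back = read_relevance(tmp_path / "r.h5")
    assert np.array_equal(back.values, rmap.values)
    assert np.array_equal(back.f_x, rmap.f_x)
    assert back.layout.mapping == rmap.layout.mapping
    assert back.target_class == rmap.target_class


def _manual_map(values, layout60, pids):
    meta = pd.DataFrame({
        "participant_id": pids, "session_id": "s", "domain": "sleep",
        "state": "wake", "modality": "tms",
    })
    return RelevanceMap(values=values, target_class="high",
                        f_x=values.reshape(len(values), -1).sum(axis=1),
                        layout=layout60, trial_meta=meta)


class TestRegionScores:
    def test_relevance_on_pz_only_scores_parietal_only(self, layout60):
        values = np.zeros((3, 10, 11, 72))
        r, c = layout60.mapping["Pz"]
        values[:, r, c, 0] = 2.0
        scores = region_scores(_manual_map(values, layout60, ["p1"] * 3))
        row = scores.table.iloc[0]
        assert row["parietal"] > 0
        assert row["frontal"] == 0 and row["temporal"] == 0

    def test_uniform_relevance_gives_equal_region_means(self, layout60):
        values = np.zeros((2, 10, 11, 72))
        for (r, c) in layout60.mapping.values():
            values[:, r, c, 0] = 1.0
        scores = region_scores(_manual_map(values, layout60, ["p1", "p1"]))
        row = scores.table.iloc[0]
        assert row["frontal"] == pytest.approx(row["temporal"], abs=1e-12)
        assert row["temporal"] == pytest.approx(row["parietal"], abs=1e-12)

    def test_trial_order_invariance_and_linearity(self, layout60, rng):
        values = rng.normal(size=(6, 10, 11, 72))
        pids = ["p1"] * 3 + ["p2"] * 3
        base = region_scores(_manual_map(values, layout60, pids))
        perm = np.array([2, 0, 1, 5, 4, 3])    # permute within participants
        shuffled = region_scores(_manual_map(values[perm], layout60,
                                             [pids[i] for i in perm]))
        pd.testing.assert_frame_equal(base.table, shuffled.table)
        doubled = region_scores(_manual_map(2 * values, layout60, pids))
        assert np.allclose(doubled.table[["frontal", "temporal", "parietal"]],
                           2 * base.table[["frontal", "temporal", "parietal"]])

    def test_positive_part_variant_differs_for_signed_maps(self, layout60, rng):
        values = rng.normal(size=(4, 10, 11, 72))
        signed = region_scores(_manual_map(values, layout60, ["p1"] * 4), signed=True)
        pos = region_scores(_manual_map(values, layout60, ["p1"] * 4), signed=False)
        assert not np.allclose(signed.table["parietal"], pos.table["parietal"])


class TestRegionStats:
    def _scores(self, frontal, temporal, parietal):
        return RegionScores(table=pd.DataFrame({
            "participant": [f"p{i}" for i in range(len(frontal))],
            "frontal": frontal, "temporal": temporal, "parietal": parietal,
        }), signed=True, skipped_electrodes={})

    def test_identical_columns_give_h_zero_p_one(self):
        st = region_stats(self._scores([1.0, 1.0], [1.0, 1.0], [1.0, 1.0]))
        assert st.h == 0.0 and st.p == 1.0
        assert not st.pairwise["significant"].any()

    def test_fully_separated_ranks_reach_the_hand_computed_maximum(self):
        # groups (1,1,1),(2,2,2),(3,3,3): midranks 2, 5, 8 of N=9
        # H_raw = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2 = 12/90 * 54 = 7.2
        # tie correction C = 1 - 3(3^3-3)/(9^3-9) = 0.9 -> H = 7.2/0.9 = 8.0
        st = region_stats(self._scores([1.0] * 3, [2.0] * 3, [3.0] * 3))
        assert st.h == pytest.approx(8.0, abs=1e-9)

    def test_lsd_pairwise_equals_plain_t_tests(self, rng):
        cols = {r: rng.normal(size=6) for r in ("frontal", "temporal", "parietal")}
        st = region_stats(self._scores(cols["frontal"], cols["temporal"], cols["parietal"]))
        for _, row in st.pairwise.iterrows():
            _t, p = sps.ttest_ind(cols[row["region_a"]], cols[row["region_b"]])
            assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_needs_two_participants(self):
        with pytest.raises(ValueError, match="2 participants"):
            region_stats(self._scores([1.0], [2.0], [3.0]))


class TestAblation:
    def test_drop_nothing_reproduces_the_baseline(self, small_tensor):
        spec = TrainSpec(seed=2, budget_multiplier=1)
        base = lopo_indicator(small_tensor, "awareness", spec, keep_models=False)
        abl = electrode_ablation(small_tensor, "awareness", (), spec)
        assert abl.roc.auc == pytest.approx(base.roc.auc, abs=1e-12)
        assert abl.trial_auc == pytest.approx(base.trial_auc, abs=1e-12)

    def test_drop_electrodes_zeroes_only_their_cells(self, small_tensor, layout60):
        dropped = drop_electrodes(small_tensor, layout60.region_sets["parietal"])
        for ch in layout60.region_sets["parietal"]:
            r, c = layout60.mapping[ch]
            assert np.all(dropped.values[:, r, c, :] == 0)
        others = [ch for ch in layout60.mapping if ch not in layout60.region_sets["parietal"]]
        r, c = layout60.mapping[others[0]]
        assert np.array_equal(dropped.values[:, r, c, :], small_tensor.values[:, r, c, :])

    def test_dropping_every_electrode_rejected(self, small_tensor, layout60):
        with pytest.raises(ValueError, match="every mapped electrode"):
            electrode_ablation(small_tensor, "awareness", tuple(layout60.mapping))
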