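"""Domain pooling, training regimen, and cross-validation harness contracts."""

import numpy as np
import pytest

from eci.model import (
    DomainProfile,
    TrainSpec,
    TrainedModel,
    domain_distance,
    domain_profile,
    holdout_evaluate,
    lopo_evaluate,
    pool_sources,
    predict_proba,
    train_component,
)
from eci.preprocess import standard_chain, window
from eci.features import build_layout, to_spatiotemporal
from eci.synthetic import SimConfig, generate_cohort


def _profile(v, domain="sleep"):
    return DomainProfile(domain=domain, f=np.asarray(v, dtype=float))


class TestDomainDistance:
    def test_identical_profiles_have_zero_distance(self):
        f = _profile([1.0, 2.0, -3.0])
        assert domain_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_have_distance_one(self):
        assert domain_distance(_profile([1, 0]), _profile([0, 2])) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_profiles_have_distance_two(self):
        a = _profile([1.0, -2.0, 0.5])
        b = _profile(-np.asarray(a.f))
        assert domain_distance(a, b) == pytest.approx(2.0, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = _profile(rng.normal(size=8)), _profile(rng.normal(size=8))
        assert domain_distance(a, b) == pytest.approx(domain_distance(b, a), abs=1e-12)

    def test_zero_norm_profile_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            domain_distance(_profile([0.0, 0.0]), _profile([1.0, 0.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            domain_distance(_profile([1.0]), _profile([1.0, 2.0]))

    def test_profile_from_cohort_averages_domain_trials(self, small_cohort):
        prof = domain_profile(small_cohort, "sleep")
        assert prof.f.shape == (small_cohort.n_channels * small_cohort.n_samples,)


class TestPoolSources:
    def test_default_pools_follow_the_fixed_policy(self):
        avail = ["sleep", "anesthesia", "doc"]
        assert pool_sources("doc", avail, "paper_default", "tms") == ["doc", "anesthesia"]
        assert set(pool_sources("sleep", avail, "paper_default", "tms")) == {"sleep", "anesthesia"}
        assert pool_sources("anesthesia", avail, "paper_default", "resting") == ["anesthesia"]
        assert pool_sources("doc", avail, "paper_default", "resting") == ["doc", "anesthesia"]

    def test_arousal_on_doc_only_pool_is_untrainable(self):
        with pytest.raises(ValueError, match="untrainable"):
            pool_sources("doc", ["doc"], "explicit", component="arousal")

    def test_awareness_on_doc_only_pool_is_trainable(self):
        assert pool_sources("doc", ["doc"], "explicit", component="awareness") == ["doc"]

    def test_distance_rank_orders_by_cosine_and_breaks_ties_by_declaration(self):
        profs = {
            "sleep": _profile([1.0, 0.0], "sleep"),
            "anesthesia": _profile([1.0, 0.0], "anesthesia"),
            "doc": _profile([0.0, 1.0], "doc"),
        }
        out = pool_sources("sleep", ["sleep", "anesthesia", "doc"], "distance_rank",
                           profiles=profs)
        assert out == ["sleep", "anesthesia", "doc"]
        # tie case: identical profiles keep declaration order
        profs["doc"] = _profile([1.0, 0.0], "doc")
        out = pool_sources("sleep", ["sleep", "doc", "anesthesia"], "distance_rank",
                           profiles=profs)
        assert out == ["sleep", "doc", "anesthesia"]

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            pool_sources("sleep", ["sleep"], "bogus")


class TestTraining:
    def test_single_class_pool_rejected(self, small_tensor):
        wake_only = small_tensor.select_trials(
            (small_tensor.trial_meta["state"] == "wake").to_numpy())
        with pytest.raises(ValueError, match="single-class"):
            train_component(wake_only, "awareness")

    def test_validation_accuracy_recovers_strong_effect(self, trained_awareness):
        assert trained_awareness.log["val_accuracy"].max() > 0.8

    def test_loss_decreases_on_separable_data(self, trained_awareness):
        log = trained_awareness.log
        assert log["mean_loss"].iloc[-1] < log["mean_loss"].iloc[0]

    def test_learning_rate_decays_sublinearly(self, trained_awareness):
        lr = trained_awareness.log["lr"].to_numpy()
        assert np.all(np.diff(lr) < 0)
        assert lr[1] == pytest.approx(0.005 / np.sqrt(2), rel=1e-6)

    def test_identical_seeds_identical_weights(self, small_tensor):
        sub = small_tensor.select_trials(np.arange(40))
        spec = TrainSpec(seed=11, budget_multiplier=1)
        a = train_component(sub, "awareness", spec)
        b = train_component(sub, "awareness", spec)
        for wa, wb in zip(a.net.state(), b.net.state()):
            assert np.array_equal(wa, wb)

    def test_null_effect_validation_accuracy_within_chance_band(self):
        cohort = generate_cohort(SimConfig(
            n_participants_per_domain=2, trials_per_session=24,
            states=("nrem", "wake"), effect_size=0.0, seed=23,
        ))
        clean, _ = standard_chain(cohort)
        tensor = to_spatiotemporal(window(clean, 200.0, 400.0),
                                   build_layout(clean.channel_labels))
        model = train_component(tensor, "awareness", TrainSpec(seed=5))
        n_val = int(round(0.2 * tensor.n_trials))
        half_width = 1.96 * np.sqrt(0.25 / n_val)
        acc = model.log["val_accuracy"].iloc[-1]
        assert abs(acc - 0.5) <= half_width + 1e-9

    def test_checkpoint_save_load_round_trip(self, tmp_path, trained_awareness, small_tensor):
        trained_awareness.save(tmp_path / "m")
        back = TrainedModel.load(tmp_path / "m")
        p0 = predict_proba(trained_awareness, small_tensor)
        p1 = predict_proba(back, small_tensor)
        assert np.allclose(p0, p1, atol=1e-7)


class TestPredictProba:
    def test_rows_are_probabilities(self, trained_awareness, small_tensor):
        p = predict_proba(trained_awareness, small_tensor)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_all_zero_input_is_still_a_valid_pair(self, trained_awareness, small_tensor):
        zeros = small_tensor.select_trials(np.arange(2))
        zeros.values[:] = 0.0
        p = predict_proba(trained_awareness, zeros)
        assert np.all(np.isfinite(p))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_trial_gets_identical_probabilities(self, trained_awareness, small_tensor):
        dup = small_tensor.select_trials(np.array([0, 0]))
        p = predict_proba(trained_awareness, dup)
        assert np.array_equal(p[0], p[1])

    def test_trial_order_invariance(self, trained_awareness, small_tensor):
        perm = np.random.default_rng(0).permutation(small_tensor.n_trials)
        p = predict_proba(trained_awareness, small_tensor)
        pp = predict_proba(trained_awareness, small_tensor.select_trials(perm))
        assert np.allclose(p[perm], pp, atol=1e-7)

    def test_depth_mismatch_rejected(self, trained_awareness, small_clean, layout60):
        from eci.features import to_spatiospectral

        spect = to_spatiospectral(window(small_clean, 200.0, 400.0), layout60)
        with pytest.raises(ValueError, match="depth"):
            predict_proba(trained_awareness, spect)


class TestHarnesses:
    def test_lopo_folds_partition_participants(self, small_tensor):
        res = lopo_evaluate(small_tensor, "awareness",
                            TrainSpec(seed=2, budget_multiplier=1), keep_models=False)
        assert len(res.accuracy_table) == 3
        assert not np.any(np.isnan(res.trial_p_high))
        assert set(res.accuracy_table["participant"]) == set(
            small_tensor.trial_meta["participant_id"].unique())

    def test_lopo_needs_two_participants(self, small_tensor):
        solo = small_tensor.select_trials(
            (small_tensor.trial_meta["participant_id"] == "sleep01").to_numpy())
        with pytest.raises(ValueError, match="2 participants"):
            lopo_evaluate(solo, "awareness")

    def test_rem_gets_opposite_labels_across_components(self, small_tensor):
        # the same tensors train both models; REM is low arousal yet high awareness
        rem = (small_tensor.trial_meta["state"] == "rem").to_numpy()
        aro = small_tensor.component_labels("arousal")
        awa = small_tensor.component_labels("awareness")
        assert np.all(aro[rem] == 0)
        assert np.all(awa[rem] == 1)

    def test_holdout_split_is_by_participant_and_seeded(self, small_tensor):
        spec = TrainSpec(seed=4, budget_multiplier=1)
        a = holdout_evaluate(small_tensor, "awareness", 0.75, spec)
        b = holdout_evaluate(small_tensor, "awareness", 0.75, spec)
        assert a.train_participants == b.train_participants
        assert len(a.train_participants) == 2 and len(a.test_participants) == 1
        assert set(a.train_participants).isdisjoint(a.test_participants)
        held_pids = set(small_tensor.trial_meta["participant_id"].to_numpy()[a.test_index])
        assert held_pids == set(a.test_participants)

    def test_holdout_fraction_validated(self, small_tensor):
        with pytest.raises(ValueError, match="train_frac"):
            holdout_evaluate(small_tensor, "awareness", 1.5)
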