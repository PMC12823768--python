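"""GMM-HMM core: emissions, forward/Viterbi vs enumeration, Baum-Welch."""

import numpy as np
import pytest

from bruxhmm.hmm import (
    ClassHMM,
    GaussianMixture,
    baum_welch,
    batch_scores,
    forward_loglik,
    init_hmm,
    load_hmm,
    log_emission,
    sample,
    save_hmm,
    viterbi,
)
from oracles import enum_forward, enum_viterbi, random_lr_hmm


def build_hmm(trans, streams, **kw):
    n_states = trans.shape[0] - 1
    emissions = {
        name: [GaussianMixture(w, m, v) for (w, m, v) in per_state]
        for name, per_state in streams.items()
    }
    return ClassHMM("test", n_states, trans, emissions, **kw)


def random_instance(rng, n_states=None, T=None, n_mix=None, n_streams=1, dim=2):
    n_states = n_states or int(rng.integers(1, 4))
    T = T or int(rng.integers(n_states, 7))
    n_mix = n_mix or int(rng.integers(1, 3))
    trans, streams = random_lr_hmm(rng, n_states, n_mix, dim, n_streams)
    hmm = build_hmm(trans, streams)
    obs = {name: rng.normal(0, 1.5, (T, dim)) for name in streams}
    return hmm, obs, trans


def frame_matrix(hmm, obs):
    T = len(next(iter(obs.values())))
    return np.array(
        [[log_emission(hmm, s, obs, t) for s in range(hmm.n_states)] for t in range(T)]
    )


class TestLogEmission:
    def test_standard_normal_at_mode(self):
        g = GaussianMixture(np.ones(1), np.zeros((1, 1)), np.ones((1, 1)))
        trans = np.array([[1.0, 0.0], [0.0, 1.0]])
        hmm = build_hmm(trans, {"a": [(np.ones(1), np.zeros((1, 1)), np.ones((1, 1)))]})
        val = log_emission(hmm, 0, {"a": np.zeros((1, 1))}, 0)
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_duplicate_components_collapse_to_single(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(1, 3))
        var = rng.uniform(0.5, 2, (1, 3))
        single = GaussianMixture(np.ones(1), mu, var)
        double = GaussianMixture(
            np.array([0.5, 0.5]), np.vstack([mu, mu]), np.vstack([var, var])
        )
        X = rng.normal(size=(10, 3))
        np.testing.assert_allclose(single.log_density(X), double.log_density(X), rtol=1e-12)

    def test_two_identical_streams_double_the_score(self):
        rng = np.random.default_rng(1)
        trans, streams = random_lr_hmm(rng, 2, 2, 3, n_streams=1)
        per_state = streams["s0"]
        hmm2 = build_hmm(trans, {"s0": per_state, "s1": per_state})
        hmm1 = build_hmm(trans, {"s0": per_state})
        X = rng.normal(size=(4, 3))
        one = log_emission(hmm1, 1, {"s0": X}, 2)
        two = log_emission(hmm2, 1, {"s0": X, "s1": X}, 2)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_unknown_stream_raises(self):
        rng = np.random.default_rng(2)
        hmm, obs, _ = random_instance(rng)
        bad = dict(obs)
        bad["ghost"] = np.zeros((len(next(iter(obs.values()))), 2))
        with pytest.raises(KeyError, match="ghost"):
            log_emission(hmm, 0, bad, 0)


class TestForwardViterbiOracle:
    def test_forward_and_viterbi_match_enumeration(self):
        """Scores equal exhaustive monotone-path enumeration on random
        small instances, with and without a forced exit."""
        rng = np.random.default_rng(42)
        for trial in range(80):
            require_exit = trial % 4 == 0
            hmm, obs, trans = random_instance(rng)
            hmm.require_exit = require_exit
            logB = frame_matrix(hmm, obs)
            want_f = enum_forward(trans, logB, hmm.n_states, require_exit)
            want_path, want_v = enum_viterbi(trans, logB, hmm.n_states, require_exit)
            assert forward_loglik(hmm, obs) == pytest.approx(want_f, abs=1e-8)
            path, score = viterbi(hmm, obs)
            assert score == pytest.approx(want_v, abs=1e-8)
            assert list(path) == list(want_path)

    def test_viterbi_never_exceeds_forward(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            hmm, obs, _ = random_instance(rng)
            _, v = viterbi(hmm, obs)
            assert v <= forward_loglik(hmm, obs) + 1e-10

    def test_single_state_forward_is_emission_sum(self):
        rng = np.random.default_rng(3)
        trans = np.array([[1.0, 0.0], [0.0, 1.0]])
        _, streams = random_lr_hmm(rng, 1, 2, 2)
        hmm = build_hmm(trans, streams)
        obs = {"s0": rng.normal(size=(5, 2))}
        total = sum(log_emission(hmm, 0, obs, t) for t in range(5))
        assert forward_loglik(hmm, obs) == pytest.approx(total, rel=1e-12)

    def test_deterministic_chain_forces_unique_path(self):
        trans = np.zeros((4, 4))
        trans[0, 1] = trans[1, 2] = trans[2, 2] = 1.0
        trans[3, 3] = 1.0
        rng = np.random.default_rng(4)
        _, streams = random_lr_hmm(rng, 3, 1, 2)
        hmm = build_hmm(trans, streams)
        obs = {"s0": rng.normal(size=(6, 2))}
        path, _ = viterbi(hmm, obs)
        assert list(path) == [0, 1, 2, 2, 2, 2]

    def test_identical_emission_states_permutation_invariant(self):
        rng = np.random.default_rng(5)
        per_state = [(np.ones(1), np.zeros((1, 2)), np.ones((1, 2)))] * 3
        trans = np.zeros((4, 4))
        for i in range(3):
            trans[i, i] = 0.5
            trans[i, i + 1] = 0.5
        trans[3, 3] = 1.0
        hmm = build_hmm(trans, {"a": per_state})
        obs = {"a": rng.normal(size=(5, 2))}
        f1 = forward_loglik(hmm, obs)
        # identical emissions: swapping state parameters changes nothing
        hmm2 = build_hmm(trans, {"a": [per_state[1], per_state[0], per_state[2]]})
        assert forward_loglik(hmm2, obs) == pytest.approx(f1, rel=1e-12)

    def test_empty_observation_rejected(self):
        rng = np.random.default_rng(6)
        hmm, obs, _ = random_instance(rng)
        empty = {k: v[:0] for k, v in obs.items()}
        with pytest.raises(ValueError, match="empty"):
            forward_loglik(hmm, empty)

    def test_batch_scores_agree_with_scalar_api(self):
        rng = np.random.default_rng(8)
        hmm, _, _ = random_instance(rng, n_states=3, T=6)
        seqs = [{"s0": rng.normal(0, 1.5, (6, 2))} for _ in range(9)]
        vit = batch_scores(hmm, seqs, statistic="viterbi")
        fwd = batch_scores(hmm, seqs, statistic="forward")
        for i, seq in enumerate(seqs):
            assert vit[i] == pytest.approx(viterbi(hmm, seq)[1], rel=1e-12)
            assert fwd[i] == pytest.approx(forward_loglik(hmm, seq), rel=1e-12)

    def test_cross_check_against_hmmlearn_forward(self):
        """Forward log-likelihood agrees with an independent HMM library
        on a single-stream single-Gaussian left-to-right model."""
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        S, D = 3, 4
        self_p = rng.uniform(0.3, 0.8, S)
        trans = np.zeros((S + 1, S + 1))
        for i in range(S - 1):
            trans[i, i] = self_p[i]
            trans[i, i + 1] = 1 - self_p[i]
        trans[S - 1, S - 1] = 1.0
        trans[S, S] = 1.0
        means = rng.normal(0, 2, (S, D))
        variances = rng.uniform(0.5, 2, (S, D))
        mine = build_hmm(
            trans,
            {"x": [(np.ones(1), means[i : i + 1], variances[i : i + 1]) for i in range(S)]},
        )
        ref = hmmlearn_hmm.GaussianHMM(n_components=S, covariance_type="diag", init_params="")
        ref.startprob_ = np.array([1.0, 0.0, 0.0])
        ref.transmat_ = trans[:S, :S]
        ref.means_ = means
        ref.covars_ = variances
        X = rng.normal(0, 1.5, (20, D))
        assert forward_loglik(mine, {"x": X}) == pytest.approx(ref.score(X), abs=1e-8)


class TestInit:
    def make_seqs(self, rng, n=6, T=12, d=3):
        return [{"a": rng.normal(0, 1, (T, d)) + np.linspace(0, 4, T)[:, None]} for _ in range(n)]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        seqs = self.make_seqs(rng)
        a = init_hmm(seqs, "c", n_states=3, n_mix=2, seed=5)
        b = init_hmm(seqs, "c", n_states=3, n_mix=2, seed=5)
        for st in range(3):
            np.testing.assert_array_equal(
                a.emissions["a"][st].means, b.emissions["a"][st].means
            )

    def test_single_mixture_means_are_block_means(self):
        rng = np.random.default_rng(1)
        seqs = self.make_seqs(rng, n=4, T=9)
        model = init_hmm(seqs, "c", n_states=3, n_mix=1, seed=0)
        for b in range(3):
            block = np.vstack([seq["a"][3 * b : 3 * (b + 1)] for seq in seqs])
            np.testing.assert_allclose(
                model.emissions["a"][b].means[0], block.mean(axis=0), rtol=1e-12
            )

    def test_constant_sequence_variance_at_floor(self):
        seqs = [{"a": np.ones((9, 2))}]
        model = init_hmm(seqs, "c", n_states=3, n_mix=1, seed=0)
        for b in range(3):
            np.testing.assert_array_equal(
                model.emissions["a"][b].variances, model.var_floor["a"][None, :]
            )

    def test_mixture_count_reduced_with_warning_when_data_scarce(self):
        rng = np.random.default_rng(2)
        seqs = [{"a": rng.normal(size=(6, 2))}]
        with pytest.warns(UserWarning, match="reducing"):
            model = init_hmm(seqs, "c", n_states=3, n_mix=10, seed=0)
        assert model.emissions["a"][0].n_mix <= 2

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="n_states"):
            init_hmm([{"a": np.zeros((2, 2))}], "c", n_states=3, n_mix=1, seed=0)


class TestBaumWelch:
    def test_loglik_trace_non_decreasing_on_random_draws(self):
        """EM monotonicity over 20 random (model, data) draws."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            S = int(rng.integers(1, 4))
            T = int(rng.integers(max(S, 4), 12))
            seqs = [
                {"a": rng.normal(0, 1, (T, 3)) + rng.normal(0, 1, (1, 3))}
                for _ in range(int(rng.integers(2, 6)))
            ]
            model = init_hmm(seqs, "c", n_states=S, n_mix=2, seed=int(rng.integers(100)))
            _, trace = baum_welch(model, seqs, max_iter=8)
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-6), trace

    def test_sampled_data_one_iteration_improves(self):
        rng = np.random.default_rng(12)
        gen, _, _ = random_instance(rng, n_states=2, T=20, n_mix=1)
        gen.transition[1, 1] = 1.0
        gen.transition[1, 2] = 0.0
        seqs = [sample(gen, 20, rng)[0] for _ in range(10)]
        model = init_hmm(seqs, "c", n_states=2, n_mix=1, seed=0)
        _, trace = baum_welch(model, seqs, max_iter=1)
        assert trace[-1] >= trace[0] - 1e-6

    def test_left_to_right_zero_pattern_preserved(self):
        rng = np.random.default_rng(13)
        seqs = [{"a": rng.normal(size=(12, 2))} for _ in range(5)]
        model = init_hmm(seqs, "c", n_states=3, n_mix=2, seed=1)
        trained, _ = baum_welch(model, seqs, max_iter=5)
        A = trained.transition
        assert np.all(np.tril(A, -1) == 0)
        assert np.all(np.triu(A, 2) == 0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-9)

    def test_training_order_invariant(self):
        rng = np.random.default_rng(14)
        seqs = [{"a": rng.normal(size=(12, 2)) + i * 0.3} for i in range(8)]
        m1 = init_hmm(seqs, "c", n_states=3, n_mix=2, seed=3)
        t1, _ = baum_welch(m1, seqs, max_iter=4)
        perm = [seqs[i] for i in [5, 2, 7, 0, 3, 6, 1, 4]]
        m2 = init_hmm(perm, "c", n_states=3, n_mix=2, seed=3)
        t2, _ = baum_welch(m2, perm, max_iter=4)
        for st in range(3):
            np.testing.assert_allclose(
                t1.emissions["a"][st].means, t2.emissions["a"][st].means, atol=1e-9
            )
        np.testing.assert_allclose(t1.transition, t2.transition, atol=1e-12)

    def test_transition_recovery_from_known_model(self):
        """Training on data sampled from a well-separated 3-state,
        2-mixture model recovers its transition matrix."""
        rng = np.random.default_rng(2024)
        S, D = 3, 4
        trans = np.zeros((S + 1, S + 1))
        # dwell times roughly a third of T=99 each, so every state is
        # well represented in every sequence
        self_p = [0.96, 0.94, 1.0]
        for i in range(S):
            trans[i, i] = self_p[i]
            if i + 1 <= S:
                trans[i, i + 1] = 1.0 - self_p[i]
        trans[S, S] = 1.0
        streams = {"a": []}
        for i in range(S):
            mu = np.full((2, D), 10.0 * i, dtype=float)
            mu[1] += 3.0
            streams["a"].append((np.array([0.6, 0.4]), mu, np.full((2, D), 0.5)))
        gen = build_hmm(trans, streams)
        seqs = [sample(gen, 99, rng)[0] for _ in range(50)]
        assert all(len(s["a"]) == 99 for s in seqs)
        model = init_hmm(seqs, "c", n_states=S, n_mix=2, seed=1)
        trained, _ = baum_welch(model, seqs, max_iter=20)
        np.testing.assert_allclose(
            trained.transition[:S, : S + 1], trans[:S, : S + 1], atol=0.05
        )


class TestSample:
    def test_no_self_loop_chain_walks_straight(self):
        trans = np.zeros((4, 4))
        trans[0, 1] = trans[1, 2] = 1.0
        trans[2, 2] = 0.5
        trans[2, 3] = 0.5
        trans[3, 3] = 1.0
        rng = np.random.default_rng(0)
        _, streams = random_lr_hmm(rng, 3, 1, 2)
        hmm = build_hmm(trans, streams)
        _, path = sample(hmm, 10, np.random.default_rng(1))
        assert list(path[:3]) == [0, 1, 2]

    def test_sample_mean_matches_model_mean(self):
        mu = np.array([[1.5, -2.0]])
        var = np.array([[0.8, 1.2]])
        trans = np.array([[1.0, 0.0], [0.0, 1.0]])
        hmm = build_hmm(trans, {"a": [(np.ones(1), mu, var)]})
        obs, _ = sample(hmm, 10_000, np.random.default_rng(3))
        est = obs["a"].mean(axis=0)
        tol = 3.0 * np.sqrt(var[0]) / 100.0
        assert np.all(np.abs(est - mu[0]) < tol)

    def test_fixed_rng_reproducible(self):
        rng = np.random.default_rng(9)
        hmm, _, _ = random_instance(rng, n_states=2, T=5)
        a, pa = sample(hmm, 8, np.random.default_rng(5))
        b, pb = sample(hmm, 8, np.random.default_rng(5))
        np.testing.assert_array_equal(pa, pb)
        np.testing.assert_array_equal(a["s0"], b["s0"])


class TestFusionAndInvariances:
    def test_zero_weight_duplicate_stream_reproduces_single_stream(self):
        """Weights (1, 0) on duplicated streams give exactly the
        single-stream scores."""
        rng = np.random.default_rng(21)
        trans, streams = random_lr_hmm(rng, 3, 2, 3)
        per_state = streams["s0"]
        single = build_hmm(trans, {"s0": per_state})
        fused = build_hmm(
            trans,
            {"s0": per_state, "copy": per_state},
            stream_weights={"s0": 1.0, "copy": 0.0},
        )
        for _ in range(10):
            X = rng.normal(0, 1.5, (6, 3))
            assert viterbi(fused, {"s0": X, "copy": X})[1] == pytest.approx(
                viterbi(single, {"s0": X})[1], abs=1e-12
            )
            assert forward_loglik(fused, {"s0": X, "copy": X}) == pytest.approx(
                forward_loglik(single, {"s0": X}), abs=1e-12
            )

    def test_translation_invariance_of_score_differences(self):
        """Shifting features and means by a constant leaves likelihood
        differences between matched-variance models unchanged."""
        rng = np.random.default_rng(22)
        var = rng.uniform(0.5, 2.0, (2, 3))

        def model(mu_shift):
            trans, streams = random_lr_hmm(rng, 2, 2, 3)
            per = [
                (w, m + mu_shift, var.copy()) for (w, m, _v) in streams["s0"]
            ]
            return trans, per

        t1, p1 = model(0.0)
        t2, p2 = model(1.0)
        h1, h2 = build_hmm(t1, {"a": p1}), build_hmm(t2, {"a": p2})
        c = 7.3
        h1s = build_hmm(t1, {"a": [(w, m + c, v) for w, m, v in p1]})
        h2s = build_hmm(t2, {"a": [(w, m + c, v) for w, m, v in p2]})
        X = rng.normal(0, 1, (6, 3))
        d0 = forward_loglik(h1, {"a": X}) - forward_loglik(h2, {"a": X})
        d1 = forward_loglik(h1s, {"a": X + c}) - forward_loglik(h2s, {"a": X + c})
        assert d1 == pytest.approx(d0, abs=1e-8)


class TestSerialization:
    def test_round_trip_scores_bit_stable(self, tmp_path):
        rng = np.random.default_rng(30)
        hmm, obs, _ = random_instance(rng, n_states=3, T=6, n_mix=2, n_streams=2)
        p = tmp_path / "model.json"
        save_hmm(hmm, p)
        loaded = load_hmm(p)
        assert loaded.class_label == hmm.class_label
        assert abs(forward_loglik(loaded, obs) - forward_loglik(hmm, obs)) < 1e-12
        assert abs(viterbi(loaded, obs)[1] - viterbi(hmm, obs)[1]) < 1e-12

    def test_unsupported_version_rejected(self, tmp_path):
        rng = np.random.default_rng(31)
        hmm, _, _ = random_instance(rng)
        from bruxhmm.hmm import hmm_to_dict, hmm_from_dict

        doc = hmm_to_dict(hmm)
        doc["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            hmm_from_dict(doc)
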