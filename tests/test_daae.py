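"""Dual-layer attention core: each stage against brute-force arithmetic,
normalization and permutation invariants, adaptive-M behaviour, training."""

import math

import numpy as np
import pytest

from daaemil.backbone import BackboneConfig, build_backbone
from daaemil.daae import (AttentionParams, MController, MilModel,
                          ProjectionParams, TrainConfig, attention_pool,
                          bag_embed, distance_weights, extract_deep_features,
                          forward_bag, project_qv, top_m_select, train_stage1,
                          update_m)
from daaemil.exceptions import DomainError
from conftest import smoke_backbone_config


def make_attention(d, L=4, seed=0):
    return AttentionParams(d, L, np.random.default_rng(seed))


def make_projection(d, dp, seed=0, heads=1):
    return ProjectionParams(d, dp, np.random.default_rng(seed), heads=heads)


def zero_controller(k_in=8):
    c = MController(np.random.default_rng(0), zero_init=True)
    return c


def brute_attention(H, w, V):
    scores = np.array([w.T @ np.tanh(V @ h) for h in H]).ravel()
    e = np.exp(scores - scores.max())
    a = e / e.sum()
    Z = sum(a_k * h for a_k, h in zip(a, H))
    return a, Z


def brute_distance(Q, critical, normalizer="bag"):
    k = len(Q)
    D = np.zeros(k)
    for kk in range(k):
        for c in critical:
            sims = np.array([Q[n] @ Q[c] for n in range(k)])
            e = np.exp(sims - sims.max())
            D[kk] += e[kk] / e.sum()
    return D / (k if normalizer == "bag" else len(critical))


class TestAttentionPool:
    def test_singleton_bag(self):
        params = make_attention(3)
        h = np.array([[0.3, -0.2, 1.0]])
        a, Z = attention_pool(h, params)
        assert np.allclose(a, [1.0])
        assert np.allclose(Z, h[0])

    def test_identical_instances_share_weight(self):
        params = make_attention(2)
        h = np.array([[0.5, -1.0], [0.5, -1.0]])
        a, _ = attention_pool(h, params)
        assert np.allclose(a, [0.5, 0.5], atol=1e-12)

    def test_matches_elementwise_evaluation(self):
        w = np.array([[0.2], [-0.4]])
        V = np.array([[0.3, -0.1], [0.5, 0.7]])
        params = make_attention(2, L=2)
        params.w.data, params.V.data = w, V
        H = np.array([[1.0, 0.5], [-0.3, 0.8], [0.1, -0.2]])
        a, Z = attention_pool(H, params)
        a_ref, Z_ref = brute_attention(H, w, V)
        assert np.allclose(a, a_ref, atol=1e-12)
        assert np.allclose(Z, Z_ref, atol=1e-12)

    def test_weights_normalize_on_random_bags(self):
        rng = np.random.default_rng(1)
        params = make_attention(4)
        for _ in range(200):
            H = rng.normal(size=(rng.integers(1, 9), 4))
            a, _ = attention_pool(H, params)
            assert (a >= 0).all()
            assert a.sum() == pytest.approx(1.0, abs=1e-9)


class TestTopMSelect:
    def test_direct_ranking(self):
        assert top_m_select([0.1, 0.5, 0.4], 2) == [1, 2]

    def test_ties_break_by_index(self):
        assert top_m_select([0.25, 0.25, 0.25, 0.25], 2) == [0, 1]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.random(rng.integers(2, 12))
            M = max(1, len(a) // 2)
            ref = sorted(range(len(a)), key=lambda j: (-a[j], j))[:M]
            assert top_m_select(a, M) == ref

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            top_m_select([0.5, 0.5], 3)
        with pytest.raises(DomainError):
            top_m_select([0.5, 0.5], 0)


class TestUpdateM:
    def test_zero_network_gives_half_bag(self):
        assert update_m([0.7, 0.3], 10, zero_controller()) == 5

    def test_lower_clamp(self):
        c = zero_controller()
        c.fc2.bias.data[:] = -20.0
        assert update_m([1.0], 8, c) == 1

    def test_upper_clamp(self):
        c = zero_controller()
        c.fc2.bias.data[:] = 20.0
        assert update_m([1.0, 0.5], 8, c) == 8

    def test_matches_hand_arithmetic(self):
        c = zero_controller()
        rng = np.random.default_rng(3)
        c.fc1.weight.data = rng.normal(size=c.fc1.weight.data.shape)
        c.fc1.bias.data = rng.normal(size=c.fc1.bias.data.shape)
        c.fc2.weight.data = rng.normal(size=c.fc2.weight.data.shape)
        top = np.array([0.7, 0.3])
        e = np.exp(top - top.max())
        p = np.concatenate([e / e.sum(), np.zeros(6)])
        logit = float((c.fc2.weight.data @ np.tanh(
            c.fc1.weight.data @ p + c.fc1.bias.data) + c.fc2.bias.data)[0])
        k = 9
        expected = min(max(int(math.floor(k / (1 + math.exp(-logit)) + 0.5)),
                           1), k)
        assert update_m(top, k, c) == expected

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            update_m([0.5], 0, zero_controller())
        with pytest.raises(DomainError):
            update_m([], 4, zero_controller())


class TestProjectQV:
    def test_identity_query_map(self):
        params = make_projection(3, 3)
        params.Wq[0].data = np.eye(3)
        H = np.random.default_rng(4).normal(size=(5, 3))
        Q, _ = project_qv(H, params)
        assert np.allclose(Q, H)

    def test_zero_value_map(self):
        params = make_projection(3, 2)
        params.Wv[0].data[:] = 0.0
        H = np.random.default_rng(5).normal(size=(4, 3))
        _, Vv = project_qv(H, params)
        assert np.array_equal(Vv, np.zeros((4, 2)))

    def test_matches_matrix_product(self):
        params = make_projection(4, 3, seed=6)
        H = np.random.default_rng(7).normal(size=(6, 4))
        Q, Vv = project_qv(H, params)
        assert np.allclose(Q, H @ params.Wq[0].data.T, atol=1e-12)
        assert np.allclose(Vv, H @ params.Wv[0].data.T, atol=1e-12)


class TestDistanceWeights:
    def test_singleton(self):
        assert np.allclose(distance_weights(np.array([[2.0, 1.0]]), [0]), [1.0])

    def test_identical_queries_uniform(self):
        Q = np.tile([0.5, -0.5], (4, 1))
        D = distance_weights(Q, [0, 1])
        assert np.allclose(D, 0.125)
        assert D.sum() == pytest.approx(0.5)   # M/k = 2/4

    def test_matches_direct_arithmetic(self):
        Q = np.array([[1.0, 0.0], [0.2, 0.8], [-0.5, 0.3]])
        D = distance_weights(Q, [0])
        assert np.allclose(D, brute_distance(Q, [0]), atol=1e-12)

    @pytest.mark.parametrize("normalizer,total", [("bag", None),
                                                  ("critical", 1.0)])
    def test_normalizer_sums_on_random_bags(self, normalizer, total):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            k = int(rng.integers(1, 9))
            M = int(rng.integers(1, k + 1))
            Q = rng.normal(size=(k, 3))
            crit = top_m_select(rng.random(k), M)
            D = distance_weights(Q, crit, normalizer=normalizer)
            expected = M / k if total is None else total
            assert (D >= 0).all()
            assert D.sum() == pytest.approx(expected, abs=1e-9)

    def test_empty_critical_rejected(self):
        with pytest.raises(DomainError):
            distance_weights(np.zeros((3, 2)), [])


class TestBagEmbed:
    def test_singleton_identity(self):
        out = bag_embed([1.0], np.array([[3.0, -1.0]]))
        assert np.allclose(out.flattened, [3.0, -1.0])

    def test_convexity_at_unit_mass(self):
        v = np.array([0.4, 1.2])
        out = bag_embed([0.5, 0.5], np.vstack([v, v]))
        assert np.allclose(out.flattened, v)

    def test_weighted_sum_arithmetic(self):
        out = bag_embed([0.25, 0.75], np.array([[1.0, 0.0], [0.0, 2.0]]))
        assert np.allclose(out.flattened, [0.25, 1.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            bag_embed([0.5], np.zeros((2, 3)))


class TestStageOracleEquivalence:
    def test_all_stages_match_brute_force_on_random_bags(self):
        """Pipeline stages vs independent brute-force arithmetic, 100 bags."""
        rng = np.random.default_rng(9)
        att = make_attention(4, L=3, seed=10)
        proj = make_projection(4, 3, seed=11)
        for _ in range(100):
            k = int(rng.integers(1, 7))
            d = 4
            H = rng.normal(size=(k, d))
            a, Z = attention_pool(H, att)
            a_ref, Z_ref = brute_attention(H, att.w.data, att.V.data)
            assert np.allclose(a, a_ref, atol=1e-10)
            assert np.allclose(Z, Z_ref, atol=1e-10)
            M = int(rng.integers(1, k + 1))
            crit = top_m_select(a, M)
            assert crit == sorted(range(k), key=lambda j: (-a[j], j))[:M]
            Q, Vv = project_qv(H, proj)
            D = distance_weights(Q, crit)
            assert np.allclose(D, brute_distance(Q, crit), atol=1e-10)
            B = bag_embed(D, Vv)
            assert np.allclose(B.flattened, D @ Vv, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_model():
    cfg = BackboneConfig(widths=(4,), pools=((2, 2, 1),), feature_dim=5, seed=0)
    extractor = build_backbone(cfg, input_shape=(8, 8, 6))
    return MilModel(extractor, pooling="daae", attention_dim=4, proj_dim=3,
                    seed=0)


class TestForwardBag:
    def test_degenerate_single_instance_bag(self, tiny_model):
        feats = np.random.default_rng(12).normal(size=(1, 5))
        emb, state, score = forward_bag(feats, tiny_model)
        assert state.m == 1
        assert np.allclose(state.D, [1.0])
        _, Vv = project_qv(feats, tiny_model.projection)
        assert np.allclose(emb.flattened, Vv[0])
        assert 0.0 < score < 1.0

    def test_permutation_equivariance_and_invariant_embedding(self, tiny_model):
        rng = np.random.default_rng(13)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            feats = rng.normal(size=(k, 5))
            tiny_model.m_inference = max(1, k // 2)
            emb, state, score = forward_bag(feats, tiny_model)
            perm = rng.permutation(k)
            emb_p, state_p, score_p = forward_bag(feats[perm], tiny_model)
            assert np.allclose(state_p.a, state.a[perm], atol=1e-12)
            assert np.allclose(state_p.D, state.D[perm], atol=1e-12)
            assert np.allclose(emb_p.flattened, emb.flattened, atol=1e-12)
            assert score_p == pytest.approx(score, abs=1e-12)

    def test_bit_identical_reruns(self, tiny_model):
        feats = np.random.default_rng(14).normal(size=(4, 5))
        out1 = forward_bag(feats, tiny_model)
        out2 = forward_bag(feats, tiny_model)
        assert np.array_equal(out1[0].flattened, out2[0].flattened)
        assert out1[2] == out2[2]


class TestTrainStage1:
    def test_loss_decreases_on_separable_bags(self, trained_smoke_model):
        _, log = trained_smoke_model
        assert log["train_loss"][-1] < log["train_loss"][0]

    def test_same_seed_gives_identical_validation_loss(self, smoke_cohort):
        volumes, _, _, truth = smoke_cohort

        def run():
            ex = build_backbone(smoke_backbone_config(),
                                input_shape=volumes.shape[1:])
            model = MilModel(ex, pooling="daae", attention_dim=8, proj_dim=8,
                             seed=0)
            _, log = train_stage1(volumes, truth.bag_labels, model,
                                  TrainConfig(lr=3e-3, max_epochs=2,
                                              patience=2, seed=0))
            return log["val_loss"]

        assert run() == run()

    def test_patience_halts_training(self, smoke_cohort):
        volumes, _, _, truth = smoke_cohort
        ex = build_backbone(smoke_backbone_config(),
                            input_shape=volumes.shape[1:])
        model = MilModel(ex, pooling="daae", attention_dim=8, proj_dim=8, seed=0)
        # zero learning rate: validation loss can never improve
        _, log = train_stage1(volumes, truth.bag_labels, model,
                              TrainConfig(lr=0.0, max_epochs=100, patience=3,
                                          seed=0))
        assert log["stopped_epoch"] == 4      # 1 best epoch + 3 flat epochs
        assert len(log["val_loss"]) == 4

    def test_empty_cohort_rejected(self):
        ex = build_backbone(smoke_backbone_config(), input_shape=(12, 12, 6))
        model = MilModel(ex, seed=0)
        with pytest.raises(DomainError):
            train_stage1(np.empty((0, 12, 12, 6)), np.empty(0), model)


class TestExtractDeepFeatures:
    def test_shape_and_determinism(self, trained_smoke_model, smoke_cohort):
        model, _ = trained_smoke_model
        volumes = smoke_cohort[0]
        table = extract_deep_features(model, volumes)
        assert table.values.shape == (len(volumes), model.embed_dim)
        again = extract_deep_features(model, volumes)
        assert np.array_equal(table.values, again.values)
        dup = extract_deep_features(model, np.stack([volumes[0], volumes[0]]))
        assert np.array_equal(dup.values[0], dup.values[1])

    def test_untrained_model_warns_but_proceeds(self, smoke_cohort):
        volumes = smoke_cohort[0][:2]
        ex = build_backbone(smoke_backbone_config(),
                            input_shape=volumes.shape[1:])
        model = MilModel(ex, seed=0)
        with pytest.warns(UserWarning, match="untrained"):
            table = extract_deep_features(model, volumes)
        assert table.values.shape[0] == 2

    def test_classes_separate_after_training(self, trained_smoke_model,
                                             smoke_cohort):
        model, _ = trained_smoke_model
        volumes, _, _, truth = smoke_cohort
        X = extract_deep_features(model, volumes).values
        y = truth.bag_labels
        between = np.linalg.norm(X[y == 1].mean(0) - X[y == 0].mean(0))
        within = 0.5 * (np.linalg.norm(X[y == 1] - X[y == 1].mean(0), axis=1).mean()
                        + np.linalg.norm(X[y == 0] - X[y == 0].mean(0), axis=1).mean())
        assert between > 0.3 * within


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                min_size=1, max_size=12),
       st.integers(min_value=1, max_value=12))
def test_top_m_selection_agrees_with_sorting_for_any_weights(a, m):
    """Hard selection equals a stable descending sort, for any finite a."""
    m = min(m, len(a))
    ref = sorted(range(len(a)), key=lambda j: (-a[j], j))[:m]
    assert top_m_select(a, m) == ref


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(min_value=-10, max_value=10, allow_nan=False),
                min_size=2, max_size=30))
def test_minmax_preserves_order_and_bounds(values):
    """Rescaling is monotone and lands exactly on [0, 1]."""
    from daaemil.backbone import minmax_normalize
    from daaemil.exceptions import DomainError
    vol = np.array(values).reshape(1, 1, -1)
    if vol.max() == vol.min():
        with pytest.raises(DomainError):
            minmax_normalize(vol)
        return
    out = minmax_normalize(vol).data.ravel()
    assert out.min() == 0.0 and out.max() == 1.0
    x = np.array(values)
    for i in range(len(x)):          # monotone: never inverts a comparison
        for j in range(len(x)):
            if x[i] < x[j]:
                assert out[i] <= out[j]
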