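"""Loss stack, reference distribution, KL confidence, distillation
masks, optimizer determinism and gradient correctness."""

import numpy as np
import pytest

from cgrna.geometry import BinSpec, GeometryLabels
from cgrna.network import (GeometryPrediction, ModelConfig, forward,
                           init_parameters)
from cgrna.synthetic import OracleConfig, make_dataset, oracle_prediction
from cgrna.training import (Adam, ConfidenceMap, TrainingSchedule,
                            build_reference, kl_confidence, losses,
                            make_distillation_labels, total_loss, train)

NBINS = BinSpec().n_dist_classes   # 39


def _uniform_prediction(L, seed=0):
    rng = np.random.default_rng(seed)
    dist = np.full((5, L, L, 39), 1 / 39)
    ori2d = [np.full((L, L, 25), 1 / 25) for _ in range(3)] + \
            [np.full((L, L, 13), 1 / 13) for _ in range(2)]
    ori1d = np.full((4, L, 25), 1 / 25)
    return GeometryPrediction(dist=dist, ori2d=ori2d, ori1d=ori1d,
                              contact=np.full((L, L), 0.5))


def _labels_from_prediction(pred):
    """One-hot labels at each argmax class (all elements unmasked)."""
    L = pred.L
    mask2d = ~np.eye(L, dtype=bool)
    return GeometryLabels(
        dist=pred.dist.argmax(-1),
        ori2d=[a.argmax(-1) for a in pred.ori2d],
        ori1d=pred.ori1d.argmax(-1),
        contact=(pred.contact > 0.5).astype(int),
        mask2d=mask2d,
        mask1d=np.ones((4, L), bool))


class TestLosses:
    def test_perfect_prediction_zero_loss(self, hairpin):
        pred = oracle_prediction(hairpin,
                                 OracleConfig(sigma_dist=1e-3,
                                              sigma_ang=1e-3, seed=0))
        labels = _labels_from_prediction(pred)
        labels.contact = (pred.contact > 0.5).astype(int)
        br = losses(pred, labels)
        assert br.l2d < 1e-3 and br.l1d < 1e-3

    def test_contact_weight_five(self):
        """l2d = l1d = 0 and lcont = 1 gives total 5 — and the combiner
        reproduces it."""
        L = 6
        pred = _uniform_prediction(L)
        # one-hot everywhere -> l2d = l1d = 0 via exact match
        pred.dist = np.zeros((5, L, L, 39))
        pred.dist[..., 3] = 1.0
        pred.ori2d = [np.eye(a.shape[-1])[np.zeros((L, L), int)]
                      for a in pred.ori2d]
        pred.ori1d = np.eye(25)[np.zeros((4, L), int)]
        pred.contact = np.full((L, L), np.exp(-1.0))   # BCE vs y=1 is 1
        labels = _labels_from_prediction(pred)
        labels.contact = np.ones((L, L), int)
        labels.mask2d = np.ones((L, L), bool)          # include diagonal
        br = losses(pred, labels)
        assert br.lcont == pytest.approx(1.0, abs=1e-9)
        assert br.l2d == pytest.approx(0.0, abs=1e-6)
        assert br.total == pytest.approx(5.0, abs=1e-6)
        assert total_loss(0.0, 0.0, 1.0) == pytest.approx(5.0)

    def test_uniform_39_class_prediction_ln39(self, hairpin):
        """Uniform distance predictions against one-hot labels: the 2D
        term contributes ln 39 per distance channel element."""
        L = len(hairpin)
        pred = _uniform_prediction(L)
        labels = _labels_from_prediction(pred)
        labels.mask2d = np.ones((L, L), bool)
        br = losses(pred, labels)
        # 5 channels at ln39 + 3 dihedrals at ln25 + 2 angles at ln13,
        # averaged over the 10 channels of the 2D term
        expect = (5 * np.log(39) + 3 * np.log(25) + 2 * np.log(13)) / 10
        assert br.l2d == pytest.approx(expect, rel=1e-6)

    def test_decomposition_identity_random(self, rng):
        for _ in range(100):
            l2d, l1d, lcont = rng.uniform(0, 4, size=3)
            assert total_loss(l2d, l1d, lcont) == pytest.approx(
                l2d + l1d + 5 * lcont, abs=1e-6)

    def test_masks_zero_contribution_fixed_normalizer(self, hairpin):
        L = len(hairpin)
        pred = _uniform_prediction(L)
        labels = _labels_from_prediction(pred)
        full = losses(pred, labels)
        half = labels.mask2d.copy()
        half[:, : L // 2] = False
        half[: L // 2, :] = False
        labels2 = _labels_from_prediction(pred)
        labels2.mask2d = half
        part = losses(pred, labels2)
        ratio = half.sum() / labels.mask2d.sum()
        assert part.l2d == pytest.approx(full.l2d * ratio, rel=1e-9)

    def test_class_count_mismatch(self, hairpin):
        L = len(hairpin)
        pred = _uniform_prediction(L)
        soft = make_distillation_labels(
            pred, ConfidenceMap(np.ones((L, L)), np.ones(L)))
        soft.dist = soft.dist[..., :20]
        with pytest.raises(ValueError, match="class count"):
            losses(pred, soft)

    def test_gradient_matches_finite_differences(self, hairpin_spec,
                                                 hairpin_labels, rng):
        from cgrna.features import Alignment, build_features
        from cgrna.synthetic import synthetic_msa
        from cgrna.evalio import pairs_to_matrix
        msa = Alignment(synthetic_msa(hairpin_spec.sequence,
                                      hairpin_spec.dotbracket, 4, seed=0))
        fb = build_features(msa, pairs_to_matrix(hairpin_spec.pairs,
                                                 msa.L))
        cfg = ModelConfig(n_blocks=1)
        params = init_parameters(cfg, seed=5)

        def loss_value():
            return losses(forward(fb, params, cfg),
                          hairpin_labels).total

        br = losses(forward(fb, params, cfg, train=True), hairpin_labels)
        for p in params.values():
            p.grad = None
        br.graph.backward()
        keys = [k for k, p in params.items() if p.grad is not None
                and p.v.size > 4]
        for k in list(rng.choice(keys, size=10, replace=False)):
            p = params[k]
            idx = tuple(rng.integers(0, s) for s in p.v.shape)
            eps = 1e-5
            orig = p.v[idx]
            p.v[idx] = orig + eps
            fp = loss_value()
            p.v[idx] = orig - eps
            fm = loss_value()
            p.v[idx] = orig
            num = (fp - fm) / (2 * eps)
            ana = p.grad[idx]
            assert abs(num - ana) <= 1e-3 * max(abs(num), abs(ana), 1e-4)


class TestReference:
    def test_single_sample_identical_rows(self):
        L = 12
        pred = _uniform_prediction(L)
        row = np.zeros(39)
        row[5] = 0.6
        row[6] = 0.4
        pred.dist = np.broadcast_to(row, (5, L, L, 39)).copy()
        ref = build_reference([pred])
        for s in range(1, L):
            np.testing.assert_allclose(ref.probs[s - 1], row, atol=1e-12)

    def test_rows_sum_to_one_and_match_bruteforce(self, hairpin, rng):
        preds = [oracle_prediction(hairpin,
                                   OracleConfig(sigma_dist=2.0,
                                                sigma_ang=20.0, seed=s))
                 for s in range(2)]
        ref = build_reference(preds)
        L = preds[0].L
        present = ref.present
        assert np.allclose(ref.probs[present].sum(1), 1.0, atol=1e-5)
        # brute-force accumulation for separation 3
        acc = np.zeros(39)
        cnt = 0
        for p in preds:
            for i in range(L - 3):
                acc += p.dist[0][i, i + 3]
                cnt += 1
        np.testing.assert_allclose(ref.probs[2], acc / cnt, atol=1e-12)

    def test_absent_separations_flagged(self):
        pred = _uniform_prediction(6)
        ref = build_reference([pred])
        assert ref.present[:5].all()
        assert not ref.present[6:].any()


class TestKLConfidence:
    def test_zero_when_prediction_equals_reference(self):
        pred = _uniform_prediction(10)
        ref = build_reference([pred])
        conf = kl_confidence(pred, ref)
        np.testing.assert_allclose(conf.c_pair, 0.0, atol=1e-9)
        np.testing.assert_allclose(conf.c_nt, 0.0, atol=1e-9)

    def test_delta_vs_uniform_is_ln39(self):
        L = 8
        pred = _uniform_prediction(L)
        delta = np.zeros((5, L, L, 39))
        delta[..., 7] = 1.0
        dpred = GeometryPrediction(dist=delta, ori2d=pred.ori2d,
                                   ori1d=pred.ori1d, contact=pred.contact)
        ref = build_reference([pred])    # uniform reference
        conf = kl_confidence(dpred, ref)
        assert conf.c_pair[0, 3] == pytest.approx(np.log(39), rel=1e-4)

    def test_matches_bruteforce_and_nonnegative(self, hairpin, rng):
        pred = oracle_prediction(hairpin, OracleConfig(sigma_dist=2.0,
                                                       sigma_ang=20.0,
                                                       seed=3))
        ref = build_reference([oracle_prediction(
            hairpin, OracleConfig(sigma_dist=4.0, sigma_ang=30.0,
                                  seed=4))])
        conf = kl_confidence(pred, ref)
        assert (conf.c_pair >= -1e-9).all()
        assert (conf.c_nt >= -1e-9).all()
        i, j = 2, 9
        p = pred.dist[0][i, j]
        r = ref.probs[j - i - 1]
        r = np.where(r > 0, r, 1e-8)
        expect = float((p * np.log(p / r)).sum())
        assert conf.c_pair[i, j] == pytest.approx(expect, rel=1e-9)
        # c_i: fixed 1/128 normalizer over the one-sided window
        L = pred.L
        expect_ci = sum(conf.c_pair[2, j] for j in range(3, L)) / 128.0
        assert conf.c_nt[2] == pytest.approx(expect_ci, rel=1e-9)


class TestDistillation:
    def test_threshold_masks(self, hairpin):
        L = len(hairpin)
        pred = oracle_prediction(hairpin, OracleConfig(sigma_dist=2.0,
                                                       sigma_ang=20.0,
                                                       seed=0))
        hi = ConfidenceMap(np.ones((L, L)), np.ones(L))
        soft = make_distillation_labels(pred, hi)
        assert soft.mask2d.sum() == L * L - L    # all but the diagonal
        assert soft.mask1d.all()
        lo = ConfidenceMap(np.zeros((L, L)), np.zeros(L))
        soft = make_distillation_labels(pred, lo)
        assert not soft.mask2d.any() and not soft.mask1d.any()
        br = losses(pred, soft)
        assert br.total == pytest.approx(0.0, abs=1e-12)

    def test_mixed_counts_match_bruteforce(self, hairpin, rng):
        L = len(hairpin)
        pred = oracle_prediction(hairpin, OracleConfig(sigma_dist=2.0,
                                                       sigma_ang=20.0,
                                                       seed=0))
        c_pair = rng.uniform(0, 1, size=(L, L))
        c_pair = 0.5 * (c_pair + c_pair.T)
        c_nt = rng.uniform(0, 1, size=L)
        soft = make_distillation_labels(pred,
                                        ConfidenceMap(c_pair, c_nt))
        expect = (c_pair >= 0.5) & ~np.eye(L, dtype=bool)
        assert soft.mask2d.sum() == expect.sum()
        assert soft.mask1d[0].sum() == (c_nt >= 0.5).sum()


class TestTrain:
    @pytest.fixture(scope="class")
    def tiny_set(self):
        return make_dataset(3, seed=2, min_len=16, max_len=24,
                            msa_rows=4)

    def test_zero_epochs_unchanged(self, tiny_set):
        cfg = ModelConfig(n_blocks=1)
        params = init_parameters(cfg, seed=0)
        before = {k: p.v.copy() for k, p in params.items()}
        train(params, cfg, tiny_set,
              schedule=TrainingSchedule(phase1_epochs=0))
        for k, p in params.items():
            np.testing.assert_array_equal(p.v, before[k])

    def test_seeded_trajectory_reproducible(self, tiny_set):
        cfg = ModelConfig(n_blocks=1)
        logs = []
        for _ in range(2):
            params = init_parameters(cfg, seed=0)
            _, log = train(params, cfg, tiny_set,
                           schedule=TrainingSchedule(phase1_epochs=2,
                                                     lr=1e-3, seed=7))
            logs.append([row[2] for row in log])
        np.testing.assert_array_equal(logs[0], logs[1])

    def test_loss_decreases(self, tiny_set):
        cfg = ModelConfig(n_blocks=1)
        params = init_parameters(cfg, seed=0)
        _, log = train(params, cfg, tiny_set,
                       schedule=TrainingSchedule(phase1_epochs=10,
                                                 lr=3e-3, seed=1,
                                                 batch_size=3))
        first = np.mean([r[2] for r in log[:3]])
        last = np.mean([r[2] for r in log[-3:]])
        assert last < first

    def test_empty_dataset_error(self):
        cfg = ModelConfig(n_blocks=1)
        with pytest.raises(ValueError):
            train(init_parameters(cfg), cfg, [])
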