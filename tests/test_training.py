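import numpy as np
import pytest
from scipy.stats import chisquare

from banvep import (
    ModelConfig,
    TrainingConfig,
    build_model,
    compute_gap_mask,
    compute_sequence_weights,
    conditional_log_probs,
    encode,
    label_loss,
    lr_at,
    sample_minibatch,
    sequence_log_likelihood,
    teacher_loss,
    tempered_softmax,
    train_student,
    train_teacher,
)
from banvep.alignment import Msa, SequenceWeights
from banvep.model import ConfigurationError


def _encoded(rows):
    msa = Msa(ids=[str(i) for i in range(len(rows))], rows=rows, focus_index=0)
    mask = compute_gap_mask(msa)
    return encode(msa, mask)


@pytest.fixture
def degenerate_family():
    enc = _encoded(["ACDEFGHA"] * 20)
    return enc, compute_sequence_weights(enc)


class TestMinibatch:
    def test_uniform_weights_sample_uniformly(self):
        enc = _encoded(["AAAA", "CCCC", "DDDD", "EEEE"])
        w = SequenceWeights(w=np.ones(4), identity_threshold=0.8)
        rng = np.random.default_rng(0)
        draws = sample_minibatch(enc, w, 100_000, rng)
        observed = np.bincount(draws[:, 0], minlength=22)
        observed = observed[observed > 0]
        assert chisquare(observed).pvalue > 1e-4

    def test_weight_proportional_sampling(self):
        enc = _encoded(["AAAA", "CCCC"])
        eps = 0.01
        w = SequenceWeights(w=np.array([1.0, eps]), identity_threshold=0.8)
        rng = np.random.default_rng(1)
        draws = sample_minibatch(enc, w, 200_000, rng)
        freq = (draws[:, 0] == enc.matrix[1, 0]).mean()
        expected = eps / (1 + eps)
        assert freq == pytest.approx(expected, rel=0.15)

    def test_seed_reproducibility(self):
        enc = _encoded(["AAAA", "CCCC", "DDDD"])
        w = SequenceWeights(w=np.ones(3), identity_threshold=0.8)
        a = sample_minibatch(enc, w, 64, np.random.default_rng(7))
        b = sample_minibatch(enc, w, 64, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_rejects_empty_batch(self):
        enc = _encoded(["AAAA"])
        w = SequenceWeights(w=np.ones(1), identity_threshold=0.8)
        with pytest.raises(ValueError):
            sample_minibatch(enc, w, 0, np.random.default_rng(0))


class TestLosses:
    def test_label_loss_zero_at_certainty(self, tiny_model_factory):
        model = tiny_model_factory(seq_length=6)
        x = np.random.default_rng(0).integers(0, 20, size=6)
        dists = conditional_log_probs(model, x)
        dists.log_probs[:] = -100.0
        dists.log_probs[np.arange(6), x] = 0.0
        assert label_loss(dists, x) == 0.0

    def test_label_loss_uniform_closed_form(self, tiny_model_factory):
        model = tiny_model_factory(seq_length=6)
        model.params["out_w"][:] = 0
        model.params["out_b"][:] = 0
        x = np.zeros(6, dtype=int)
        dists = conditional_log_probs(model, x)
        assert label_loss(dists, x) == pytest.approx(np.log(21), abs=1e-6)

    def test_label_loss_is_mean_negative_log_likelihood(self, tiny_model_factory):
        model = tiny_model_factory(seq_length=9, seed=4)
        x = np.random.default_rng(5).integers(0, 20, size=9)
        dists = conditional_log_probs(model, x)
        assert label_loss(dists, x) == pytest.approx(
            -sequence_log_likelihood(model, x) / 9
        )

    def test_teacher_loss_self_distillation_floor(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 8))
        p = tempered_softmax(logits, 4.0)
        entropy = float(-(p * np.log(p)).sum(axis=1).mean())
        assert teacher_loss(logits, logits, T=4.0) == pytest.approx(entropy)

    def test_teacher_loss_uniform_teacher(self):
        teacher = np.zeros((3, 5))
        student = np.zeros((3, 5))
        assert teacher_loss(student, teacher, T=2.0) == pytest.approx(np.log(5))
        worse = teacher_loss(np.eye(5)[:3] * 4, teacher, T=2.0)
        assert worse > np.log(5)

    def test_teacher_loss_two_class_hand_computed(self):
        t_logits = np.array([[2.0, 0.0]])
        s_logits = np.array([[1.0, -1.0]])
        p = tempered_softmax(t_logits, 4.0)[0]
        np.testing.assert_allclose(p, [0.6225, 0.3775], atol=1e-4)
        q = tempered_softmax(s_logits, 4.0)[0]
        expected = -(p * np.log(q)).sum()
        assert teacher_loss(s_logits, t_logits, T=4.0) == pytest.approx(expected)

    def test_temperature_validation(self):
        z = np.zeros((2, 3))
        with pytest.raises(ValueError):
            teacher_loss(z, z, T=-1.0)


class TestSchedule:
    def test_rate_switch(self):
        cfg = TrainingConfig()
        assert lr_at(cfg, 0) == 0.001
        assert lr_at(cfg, 2999) == 0.001
        assert lr_at(cfg, 3000) == 0.0001
        assert lr_at(cfg, 400_000) == 0.0001

    def test_logged_rates_follow_schedule(self, degenerate_family):
        enc, w = degenerate_family
        cfg = ModelConfig(
            seq_length=enc.seq_length, embedding_dim=4, conv_channels=4,
            dilation_schedule=(1,), attention_dim=4,
        )
        tc = TrainingConfig(
            iterations_teacher=3002, batch_size=2, seed=0, log_every=1
        )
        model = build_model(cfg, rng_seed=0)
        _, log = train_teacher(model, enc, w, tc)
        assert log.at_iteration(2999)["lr"] == 0.001
        assert log.at_iteration(3000)["lr"] == 0.0001
        iters = log.column("iteration")
        assert iters == sorted(iters)
        assert all(
            r["lr"] == lr_at(tc, r["iteration"]) for r in log.records
        )


class TestTeacherTraining:
    def test_converges_on_degenerate_family(self, degenerate_family):
        enc, w = degenerate_family
        cfg = ModelConfig(
            seq_length=enc.seq_length, embedding_dim=8, conv_channels=8,
            dilation_schedule=(1, 2), attention_dim=4,
        )
        tc = TrainingConfig(iterations_teacher=600, batch_size=16, seed=1)
        model = build_model(cfg, rng_seed=1)
        _, log = train_teacher(model, enc, w, tc)
        assert log.records[-1]["label_loss"] < log.records[0]["label_loss"]
        assert log.records[-1]["label_loss"] < 0.5

    def test_fixed_seed_reproducibility(self, degenerate_family):
        enc, w = degenerate_family
        cfg = ModelConfig(
            seq_length=enc.seq_length, embedding_dim=4, conv_channels=4,
            dilation_schedule=(1,), attention_dim=4,
        )
        tc = TrainingConfig(iterations_teacher=50, batch_size=4, seed=3)
        runs = []
        for _ in range(2):
            m = build_model(cfg, rng_seed=3)
            m, log = train_teacher(m, enc, w, tc)
            runs.append((m, log))
        (m1, l1), (m2, l2) = runs
        assert all((m1.params[k] == m2.params[k]).all() for k in m1.params)
        assert l1.records == l2.records


class TestStudentTraining:
    @pytest.fixture
    def ban_pair(self, degenerate_family):
        enc, w = degenerate_family
        cfg = ModelConfig(
            seq_length=enc.seq_length, embedding_dim=6, conv_channels=6,
            dilation_schedule=(1, 2), attention_dim=4,
        )
        tc = TrainingConfig(
            iterations_teacher=200, iterations_student=200, batch_size=8, seed=2
        )
        teacher = build_model(cfg, rng_seed=2)
        teacher, _ = train_teacher(teacher, enc, w, tc)
        return enc, w, cfg, tc, teacher

    def test_teacher_frozen(self, ban_pair):
        enc, w, cfg, tc, teacher = ban_pair
        before = teacher.params_hash()
        student = build_model(cfg, rng_seed=20)
        train_student(student, teacher, enc, w, tc)
        assert teacher.params_hash() == before

    def test_capacity_equality(self, ban_pair):
        enc, w, cfg, tc, teacher = ban_pair
        student = build_model(cfg, rng_seed=21)
        assert student.n_parameters() == teacher.n_parameters()

    def test_config_mismatch_rejected(self, ban_pair):
        enc, w, cfg, tc, teacher = ban_pair
        import dataclasses

        other = dataclasses.replace(cfg, conv_channels=8)
        student = build_model(other, rng_seed=0)
        with pytest.raises(ConfigurationError):
            train_student(student, teacher, enc, w, tc)

    def test_loss_components_logged(self, ban_pair):
        enc, w, cfg, tc, teacher = ban_pair
        student = build_model(cfg, rng_seed=22)
        _, log = train_student(student, teacher, enc, w, tc)
        for rec in log.records:
            assert rec["label_loss"] >= 0
            assert rec["teacher_loss"] >= 0
        assert log.records[-1]["label_loss"] < log.records[0]["label_loss"]
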