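import math

import numpy as np
import pytest

from tumortag import AnnotationTable
from tumortag.model import ModelSpec, init_model
from tumortag.training import (
    RiskVector,
    TrainConfig,
    average_risk,
    cross_entropy,
    domain_risk,
    rex_loss,
    rex_loss_and_grad,
    train,
    variance_risk,
)


class TestRisks:
    def test_uniform_scores_give_ln2(self, rng):
        m = init_model(ModelSpec(input_dim=4, bottleneck_dim=2), seed=0)
        for k in m.params:
            m.params[k][:] = 0.0
        risk = domain_risk(m, rng.normal(size=(7, 4)), rng.integers(0, 2, 7))
        assert risk == pytest.approx(math.log(2.0), abs=1e-12)

    def test_perfect_scores_drive_risk_to_zero(self):
        scores = np.array([[50.0, -50.0], [-50.0, 50.0]])
        assert cross_entropy(scores, np.array([0, 1])) < 1e-12

    def test_cross_entropy_matches_per_cell_loop_oracle(self, rng):
        scores = rng.normal(size=(20, 2))
        labels = rng.integers(0, 2, 20)
        total = 0.0
        for g, y in zip(scores, labels):
            p = math.exp(g[y]) / (math.exp(g[0]) + math.exp(g[1]))
            total += -math.log(p)
        assert cross_entropy(scores, labels) == pytest.approx(total / 20, abs=1e-10)

    def test_empty_batch_rejected(self, rng):
        m = init_model(ModelSpec(input_dim=3, bottleneck_dim=2), seed=0)
        with pytest.raises(ValueError):
            domain_risk(m, np.empty((0, 3)), np.empty(0, dtype=int))


class TestObjective:
    def test_average_risk_hand_values(self):
        assert average_risk(RiskVector([0.2, 0.4])) == pytest.approx(0.3)
        assert average_risk(RiskVector([0.7])) == pytest.approx(0.7)
        assert average_risk(RiskVector([0.0, 0.0])) == 0.0

    def test_variance_risk_hand_values(self):
        assert variance_risk(RiskVector([0.2, 0.4])) == pytest.approx(0.01, abs=1e-15)
        assert variance_risk(RiskVector([0.3, 0.3, 0.3])) == 0.0
        assert variance_risk(RiskVector([0.9])) == 0.0  # single domain

    def test_variance_matches_two_pass_oracle(self, rng):
        for _ in range(200):
            v = rng.uniform(0, 5, size=rng.integers(1, 8))
            mu = sum(v) / len(v)
            oracle = sum((x - mu) ** 2 for x in v) / len(v)
            assert abs(variance_risk(RiskVector(v)) - oracle) < 1e-12

    def test_rex_loss_hand_value_and_erm_limit(self, rng):
        assert rex_loss(RiskVector([0.2, 0.4]), beta=1.0) == pytest.approx(0.31)
        for _ in range(50):
            rv = RiskVector(rng.uniform(0, 3, size=rng.integers(1, 6)))
            assert rex_loss(rv, 0.0) == average_risk(rv)
            beta = rng.uniform(0, 10)
            assert rex_loss(rv, beta) >= average_risk(rv)

    def test_equal_risks_reduce_to_average(self):
        rv = RiskVector([0.5, 0.5, 0.5])
        assert rex_loss(rv, beta=42.0) == pytest.approx(0.5)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            rex_loss(RiskVector([0.1]), beta=-0.1)


class TestGradient:
    def test_finite_difference_check(self, rng):
        """Analytic gradient of L = beta*R_var + R_avg vs central differences."""
        spec = ModelSpec(input_dim=2, hidden1_dim=2, bottleneck_dim=2, dropout_p=0.0)
        model = init_model(spec, seed=1)
        batches = [
            (rng.normal(size=(6, 2)), rng.integers(0, 2, 6)) for _ in range(3)
        ]
        beta = 1.5
        _, grads, _ = rex_loss_and_grad(model.params, spec, batches, beta)
        eps = 1e-6
        for k in model.params:
            flat = model.params[k].reshape(-1)
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + eps
                up, _, _ = rex_loss_and_grad(model.params, spec, batches, beta)
                flat[idx] = orig - eps
                down, _, _ = rex_loss_and_grad(model.params, spec, batches, beta)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                analytic = grads[k].reshape(-1)[idx]
                assert abs(analytic - fd) <= 1e-4 * max(1.0, abs(fd))


def make_training_problem(rng, n_per_domain=40, n_features=6, m=3):
    """Linearly separable toy: label 1 iff feature 0 is shifted up."""
    X, labels, domains, ids = [], [], [], []
    for d in range(m):
        for y in (0, 1):
            block = rng.normal(size=(n_per_domain // 2, n_features))
            block[:, 0] += 5.0 * y
            X.append(block)
            labels += [y] * (n_per_domain // 2)
            domains += [f"d{d}"] * (n_per_domain // 2)
    X = np.vstack(X)
    ids = [f"c{i}" for i in range(len(labels))]
    ann = AnnotationTable(ids, np.array(labels), domains)
    partition = {
        d: np.array([i for i, dd in enumerate(domains) if dd == d])
        for d in dict.fromkeys(domains)
    }
    extra = rng.normal(size=(30, n_features))
    y_extra = rng.integers(0, 2, 30)
    extra[:, 0] += 5.0 * y_extra
    return X, ann, partition, extra, y_extra


class TestTrainLoop:
    def _cfg(self, **kw):
        base = dict(beta=1.0, learning_rate=1e-2, batch_per_domain=10, max_epochs=8,
                    seed=0)
        base.update(kw)
        return TrainConfig(**base)

    def _model(self, n_features=6):
        spec = ModelSpec(input_dim=n_features, hidden1_dim=4, bottleneck_dim=3,
                         dropout_p=0.5)
        return init_model(spec, seed=0)

    def test_checkpoint_is_first_maximizer(self, rng):
        X, ann, partition, extra, y_extra = make_training_problem(rng)
        model, trace = train(self._model(), (X, ann, partition), (extra, y_extra),
                             self._cfg())
        acc = trace.extra_accuracy
        assert trace.checkpoint_epoch == int(np.argmax(acc))
        assert acc[trace.checkpoint_epoch] == max(acc)
        assert trace.to_frame()["checkpoint"].sum() == 1

    def test_identical_seed_identical_trace(self, rng):
        X, ann, partition, extra, y_extra = make_training_problem(rng)
        _, t1 = train(self._model(), (X, ann, partition), (extra, y_extra), self._cfg())
        _, t2 = train(self._model(), (X, ann, partition), (extra, y_extra), self._cfg())
        np.testing.assert_allclose(t1.loss, t2.loss, atol=1e-10)
        np.testing.assert_allclose(t1.extra_accuracy, t2.extra_accuracy, atol=0)

    def test_learns_separable_problem(self, rng):
        X, ann, partition, extra, y_extra = make_training_problem(rng)
        model, trace = train(self._model(), (X, ann, partition), (extra, y_extra),
                             self._cfg(max_epochs=25))
        assert max(trace.extra_accuracy) >= 0.9

    def test_single_domain_beta_warns(self, rng):
        X, ann, partition, extra, y_extra = make_training_problem(rng, m=1)
        with pytest.warns(UserWarning, match="variance risk"):
            train(self._model(), (X, ann, partition), (extra, y_extra),
                  self._cfg(max_epochs=1))

    def test_trace_tsv_round_trip(self, rng, tmp_path):
        import pandas as pd

        X, ann, partition, extra, y_extra = make_training_problem(rng)
        _, trace = train(self._model(), (X, ann, partition), (extra, y_extra),
                         self._cfg(max_epochs=3))
        trace.to_tsv(tmp_path / "trace.tsv")
        back = pd.read_csv(tmp_path / "trace.tsv", sep="\t")
        assert len(back) == 3
        assert {"epoch", "R_avg", "R_var", "loss", "extra_domain_accuracy",
                "checkpoint"} <= set(back.columns)
        np.testing.assert_allclose(back["loss"], trace.loss)
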