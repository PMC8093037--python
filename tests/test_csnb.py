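"""Cost matrix, Gaussian naive Bayes posteriors and the minimum-risk rule."""

import numpy as np
import pytest
from scipy.stats import norm

from csnbstack import (
    CostMatrix,
    LabeledDataset,
    expected_risk,
    fit_csnb,
    model_from_json,
    model_to_json,
    posterior,
    predict_cs,
)
from csnbstack.csnb import CSNBModel, decide_from_posteriors


def make_model(priors=(0.5, 0.5), means=((0.0,), (1.0,)), variances=((1.0,), (1.0,)),
               cost=CostMatrix(c01=1.0, c10=1.0)):
    return CSNBModel(
        log_priors=np.log(np.asarray(priors, dtype=float)),
        means=np.asarray(means, dtype=float),
        variances=np.asarray(variances, dtype=float),
        cost=cost,
        eps=1e-9,
        class_labels=("min", "maj"),
    )


class TestCostMatrix:
    def test_auto_ratio(self):
        c = CostMatrix.auto(n_minority=10, n_majority=40)
        assert c.c01 == pytest.approx(4.0)
        assert c.c10 == pytest.approx(1.0)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            CostMatrix(c01=2.0, c10=1.0, c00=0.5)

    def test_inverted_costs_rejected(self):
        with pytest.raises(ValueError):
            CostMatrix(c01=1.0, c10=2.0)


class TestFit:
    def test_hand_moments_single_feature(self):
        d = LabeledDataset(
            np.array([[-1.0], [1.0], [1.0], [3.0]]),
            np.array(["c0", "c0", "c1", "c1"]),
        )
        m = fit_csnb(d, cost=CostMatrix.uniform())
        i0 = list(m.class_labels).index("c0")
        i1 = 1 - i0
        assert m.means[i0, 0] == pytest.approx(0.0)
        assert m.means[i1, 0] == pytest.approx(2.0)
        assert m.variances[i0, 0] == pytest.approx(2.0)
        assert m.variances[i1, 0] == pytest.approx(2.0)

    def test_auto_cost_from_frequencies(self):
        y = np.array(["m"] * 10 + ["M"] * 40)
        d = LabeledDataset(np.random.default_rng(0).normal(size=(50, 3)), y)
        m = fit_csnb(d, cost="auto")
        assert m.cost.c01 == pytest.approx(4.0)

    def test_single_class_sample_rejected(self):
        d = LabeledDataset(
            np.zeros((5, 2)), np.array(["a", "a", "a", "a", "b"])
        )
        with pytest.raises(ValueError, match="at least 2"):
            fit_csnb(d)


class TestPosterior:
    def test_identical_conditionals_return_priors(self):
        m = make_model(priors=(0.3, 0.7), means=((0.0,), (0.0,)))
        p = posterior(m, np.array([1.7]))
        assert p == pytest.approx([0.3, 0.7])

    def test_symmetric_point(self):
        m = make_model()
        assert posterior(m, np.array([0.5])) == pytest.approx([0.5, 0.5])

    def test_derived_logistic_value(self):
        # priors 1/2, N(0,1) vs N(1,1), x=0 -> P(c0|x) = 1/(1+e^-0.5)
        m = make_model()
        p = posterior(m, np.array([0.0]))
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-0.5)), abs=1e-12)

    def test_matches_direct_density_computation(self, rng):
        m = make_model(
            priors=(0.25, 0.75),
            means=((0.0, 1.0, -1.0), (0.5, 0.0, 2.0)),
            variances=((1.0, 2.0, 0.5), (1.5, 1.0, 3.0)),
        )
        for _ in range(20):
            x = rng.normal(size=3)
            lik = [
                np.prod(norm.pdf(x, m.means[c], np.sqrt(m.variances[c])))
                * np.exp(m.log_priors[c])
                for c in (0, 1)
            ]
            want = lik[0] / (lik[0] + lik[1])
            assert posterior(m, x)[0] == pytest.approx(want, rel=1e-10)

    def test_sums_to_one_and_in_range(self, rng):
        m = make_model(means=((0.0, 0.0), (1.0, -1.0)), variances=((1.0, 1.0), (2.0, 0.5)))
        P = posterior(m, rng.normal(size=(50, 2)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert ((P >= 0) & (P <= 1)).all()

    def test_no_underflow_at_p500(self, rng):
        p = 500
        m = make_model(
            means=(tuple(np.zeros(p)), tuple(np.ones(p))),
            variances=(tuple(np.ones(p)), tuple(np.ones(p))),
        )
        P = posterior(m, rng.normal(size=(10, p)))
        assert np.isfinite(P).all()
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="features"):
            posterior(make_model(), np.zeros(3))


class TestRiskAndDecision:
    def test_risk_direct_evaluation(self):
        # posteriors (0.3, 0.7), c01=5, c10=1 -> (r0, r1) = (0.7, 1.5)
        m = make_model(priors=(0.3, 0.7), means=((0.0,), (0.0,)),
                       cost=CostMatrix(c01=5.0, c10=1.0))
        rv = expected_risk(m, np.array([0.0]))
        assert rv.r0 == pytest.approx(0.7)
        assert rv.r1 == pytest.approx(1.5)

    def test_uniform_costs_reduce_to_posteriors(self):
        m = make_model(priors=(0.4, 0.6), means=((0.0,), (0.0,)))
        rv = expected_risk(m, np.array([0.0]))
        assert rv.r0 == pytest.approx(0.6)
        assert rv.r1 == pytest.approx(0.4)

    def test_cost_flips_map_decision(self):
        m = make_model(priors=(0.3, 0.7), means=((0.0,), (0.0,)),
                       cost=CostMatrix(c01=5.0, c10=1.0))
        assert predict_cs(m, np.array([0.0])) == "min"

    def test_uniform_cost_is_map(self):
        m = make_model(priors=(0.3, 0.7), means=((0.0,), (0.0,)))
        assert predict_cs(m, np.array([0.0])) == "maj"

    def test_tie_goes_to_minority(self):
        assert decide_from_posteriors(0.5, 0.5, CostMatrix.uniform()) == 0

    def test_monotone_in_cost_ratio(self, small_imbalanced, rng):
        data, _ = small_imbalanced
        counts = []
        Xtest = rng.normal(size=(200, data.n_features))
        for ratio in (1, 2, 4, 8, 16):
            m = fit_csnb(data, cost=CostMatrix(c01=float(ratio), c10=1.0))
            pred = predict_cs(m, Xtest)
            counts.append(int(np.sum(pred == data.minority_class)))
        assert counts == sorted(counts)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, small_imbalanced, rng):
        data, _ = small_imbalanced
        m = fit_csnb(data, cost="auto")
        back = model_from_json(model_to_json(m))
        X = rng.normal(size=(30, data.n_features))
        assert predict_cs(m, X).tolist() == predict_cs(back, X).tolist()


class TestCategoricalVariant:
    def test_categorical_event_model_fits_and_predicts(self):
        rng = np.random.default_rng(5)
        y = np.array([0] * 20 + [1] * 60)
        codes = np.where(
            y[:, None] == 1,
            rng.integers(0, 2, size=(80, 3)),
            rng.integers(1, 3, size=(80, 3)),
        ).astype(float)
        d = LabeledDataset(codes, np.where(y == 1, "maj", "min"))
        m = fit_csnb(d, cost="auto", event_model="categorical")
        pred = predict_cs(m, codes)
        assert (np.asarray(pred) == d.labels).mean() > 0.7
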