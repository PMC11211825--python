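"""Fusion gate, prediction heads, end-to-end model and atom attribution."""

import numpy as np
import pytest

from dtafusion._autodiff import Tensor
from dtafusion.encoders import MLP
from dtafusion.fusion_predict import (
    DTAModel,
    FusionBlock,
    FusionParams,
    ModelConfig,
    UnsupportedAttributionError,
    featurize_drug,
    featurize_protein,
    fuse,
    fusion_gate,
    grad_aam,
    predict_affinity,
    predict_interaction,
)


def make_params(rng, width, hidden):
    from dtafusion.encoders import Linear

    return FusionParams(
        proj_d=Linear(width, width, rng),
        proj_p=Linear(width, width, rng),
        W1=Tensor(rng.standard_normal((width, hidden)), requires_grad=True),
        b1=Tensor(rng.standard_normal(hidden), requires_grad=True),
        W2=Tensor(rng.standard_normal((hidden, width)), requires_grad=True),
        b2=Tensor(rng.standard_normal(width), requires_grad=True),
    )


class TestFusionGate:
    def test_zero_params_give_half(self):
        rng = np.random.default_rng(0)
        params = make_params(rng, 4, 3)
        for t in (params.W1, params.b1, params.W2, params.b2):
            t.data = np.zeros_like(t.data)
        w = fusion_gate(np.ones(4), np.ones(4), params)
        assert np.allclose(w.data, 0.5)

    def test_large_bias_saturates_toward_one(self):
        rng = np.random.default_rng(0)
        params = make_params(rng, 4, 3)
        params.b2.data = np.full(4, 20.0)
        w = fusion_gate(np.zeros(4), np.zeros(4), params)
        assert np.all(w.data > 1 - 1e-6)
        assert np.all(w.data < 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        params = make_params(rng, 6, 4)
        d, p = rng.standard_normal(6), rng.standard_normal(6)
        w = fusion_gate(d, p, params).data
        x = d + p
        att = np.maximum(x @ params.W1.data + params.b1.data, 0) @ params.W2.data + params.b2.data
        assert np.allclose(w, 1 / (1 + np.exp(-att)), atol=1e-6)


class TestFuse:
    def test_half_weight_is_mean(self):
        d, p = np.array([1.0, 3.0]), np.array([5.0, 7.0])
        out = fuse(d, p, np.full(2, 0.5))
        assert np.allclose(out.data, [3.0, 5.0])

    def test_equal_inputs_fixed_point(self):
        v = np.array([2.0, -1.0, 0.5])
        out = fuse(v, v, np.array([0.2, 0.9, 0.6]))
        assert np.allclose(out.data, v)

    def test_output_bounded_by_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            d, p = rng.standard_normal(4), rng.standard_normal(4)
            w = rng.random(4)
            out = fuse(d, p, w).data
            lo, hi = np.minimum(d, p), np.maximum(d, p)
            assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            fuse(np.ones(3), np.ones(4), np.ones(3))


class TestHeads:
    def test_zero_weight_head_outputs_bias(self):
        rng = np.random.default_rng(0)
        head = MLP([4, 3, 1], rng).eval()
        for layer in head.layers:
            layer.weight.data = np.zeros_like(layer.weight.data)
        head.layers[-1].bias.data = np.array([0.7])
        assert np.allclose(predict_affinity(np.ones(4), head).data, 0.7)
        assert np.allclose(predict_interaction(np.ones(4), head).data, 1 / (1 + np.exp(-0.7)))

    def test_interaction_is_sigmoid_of_affinity_logit(self):
        rng = np.random.default_rng(1)
        head = MLP([4, 3, 1], rng).eval()
        x = rng.standard_normal(4)
        logit = predict_affinity(x, head).data
        prob = predict_interaction(x, head).data
        assert np.allclose(prob, 1 / (1 + np.exp(-logit)))
        assert 0 < float(prob[0]) < 1

    def test_two_layer_head_hand_computation(self):
        rng = np.random.default_rng(2)
        head = MLP([3, 2, 1], rng).eval()
        x = np.array([0.3, -0.2, 1.1])
        w0, b0 = head.layers[0].weight.data, head.layers[0].bias.data
        w1, b1 = head.layers[1].weight.data, head.layers[1].bias.data
        oracle = np.maximum(x @ w0 + b0, 0) @ w1 + b1
        assert np.allclose(predict_affinity(x, head).data, oracle, atol=1e-10)


@pytest.fixture(scope="module")
def pair(small_config):
    drug = featurize_drug("Cc1ccncc1CC", small_config)
    protein = featurize_protein("ACDEFGHIKLMNPQRSTVWY", small_config)
    return drug, protein


class TestModel:
    def test_forward_finite_and_deterministic_in_eval(self, small_config, pair):
        model = DTAModel(small_config).eval()
        drug, protein = pair
        a = float(model.forward_pair(drug, protein).data)
        b = float(model.forward_pair(drug, protein).data)
        assert np.isfinite(a)
        assert a == b

    def test_dpi_output_in_unit_interval(self, small_config, pair):
        config = ModelConfig(**{**small_config.to_dict(), "task": "dpi"})
        model = DTAModel(config).eval()
        out = float(model.forward_pair(*pair).data)
        assert 0 < out < 1

    def test_gate_weight_strictly_inside_unit_interval(self, small_config, pair):
        model = DTAModel(small_config).eval()
        ctx = model.context(*pair)
        assert ctx.weight is not None
        assert np.all(ctx.weight > 0) and np.all(ctx.weight < 1)
        assert ctx.embedding.shape == (small_config.fusion_width,)

    def test_gradient_check_end_to_end(self, small_config):
        # central differences through the whole model w.r.t. a fusion
        # parameter, on a 5-atom molecule
        model = DTAModel(small_config).eval()
        drug = featurize_drug("CCOCC", small_config)
        protein = featurize_protein("ACDEFGHIKL", small_config)
        out = model.forward_pair(drug, protein)
        model.zero_grad()
        out.backward()
        target = model.fusion.params.W1
        analytic = target.grad.copy()
        eps = 1e-5
        num = np.zeros_like(analytic)
        for idx in [(0, 0), (1, 2), (3, 1)]:
            orig = target.data[idx]
            target.data[idx] = orig + eps
            hi = float(model.forward_pair(drug, protein).data)
            target.data[idx] = orig - eps
            lo = float(model.forward_pair(drug, protein).data)
            target.data[idx] = orig
            num[idx] = (hi - lo) / (2 * eps)
            assert abs(num[idx] - analytic[idx]) < 1e-4

    def test_batch_forward_matches_single_pairs(self, small_config, pair):
        model = DTAModel(small_config).eval()
        drug, protein = pair
        drug2 = featurize_drug("c1ccccc1O", small_config)
        batch = model.forward_batch([drug, drug2], [protein], [(0, 0), (1, 0)])
        singles = [float(model.forward_pair(d, protein).data) for d in (drug, drug2)]
        assert np.allclose(batch.data, singles, atol=1e-10)

    def test_ablation_ladder_structure(self, small_config, pair):
        base = {k: v for k, v in small_config.to_dict().items()
                if k not in ("use_pharm", "use_providers", "use_fusion")}
        expectations = {1: (False, False, False), 2: (True, False, False),
                        3: (True, True, False), 4: (True, True, True)}
        for level, (ph, pr, fu) in expectations.items():
            config = ModelConfig.ablation(level, **base)
            assert (config.use_pharm, config.use_providers, config.use_fusion) == (ph, pr, fu)
            drug = featurize_drug("Cc1ccncc1CC", config)
            protein = featurize_protein("ACDEFGHIKLMNPQRSTVWY", config)
            model = DTAModel(config).eval()
            assert np.isfinite(float(model.forward_pair(drug, protein).data))
            assert (model.pharm_encoder is not None) == ph
            assert (model.fusion is not None) == fu

    def test_state_dict_roundtrip(self, small_config, pair):
        model = DTAModel(small_config).eval()
        state = model.state_dict()
        clone = DTAModel(small_config).eval()
        clone.load_state_dict(state)
        assert np.allclose(
            float(model.forward_pair(*pair).data), float(clone.forward_pair(*pair).data)
        )


class TestGradAAM:
    def test_scores_per_atom_normalized(self, small_config, pair):
        model = DTAModel(small_config)
        drug, protein = pair
        scores = grad_aam(model, drug, protein)
        assert scores.shape == (drug.molecule.num_atoms,)
        assert np.all((scores >= 0) & (scores <= 1))
        if scores.max() > 0:
            assert scores.max() == pytest.approx(1.0)

    def test_unsupported_view_raises(self, small_config, pair):
        model = DTAModel(small_config)
        with pytest.raises(UnsupportedAttributionError):
            grad_aam(model, *pair, view="pharmacophore")
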