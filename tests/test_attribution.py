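import numpy as np
import pytest

from noisyvision import attribution as at
from noisyvision.attribution import LRPRuleSchedule, RelevanceMap
from noisyvision.network import Dense, SmallCNN, softmax


def _basic_schedule(model):
    return LRPRuleSchedule({n: ("basic", {}) for n, _ in model.parameterized_layers})


def _propagate_unrescaled(model, image, target, schedule):
    """Run LRP but return raw (pre-rescaling, signed) input relevance."""
    from noisyvision.attribution import _linear_lrp
    from noisyvision.network import Conv2D, MaxPool2D, _col2im

    x = model.preprocess(image)
    caches = []
    probs = model.forward(x, caches)
    R = np.zeros_like(probs)
    R[0, target] = probs[0, target]
    for name, layer, cache in reversed(caches):
        if isinstance(layer, Dense):
            R = _linear_lrp(cache["x"], layer.w, layer.b, R, *schedule.rule_for(name))
            if "flattened_from" in cache:
                R = R.reshape(cache["flattened_from"])
        elif isinstance(layer, MaxPool2D):
            R = layer.unpool(cache, R)
        else:
            n, co, h, w = R.shape
            Rf = R.transpose(0, 2, 3, 1).reshape(n, h * w, co)
            Rp = np.stack(
                [_linear_lrp(cache["patches"][i], layer.w, layer.b, Rf[i], *schedule.rule_for(name)) for i in range(n)]
            )
            R = _col2im(Rp, cache["x_shape"], layer.ksize, layer.ksize)
    return probs, R[0, 0]


class TestLinearRule:
    def test_hand_computed_single_layer(self):
        # x = (1, 2), weights (1, 1) to a single unit, seed relevance 3
        from noisyvision.attribution import _linear_lrp

        x = np.array([[1.0, 2.0]])
        w = np.array([[1.0, 1.0]])
        R = _linear_lrp(x, w, np.zeros(1), np.array([[3.0]]), "basic", {})
        assert np.allclose(R, [[1.0, 2.0]])

    def test_epsilon_zero_equals_basic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 6))
        w = rng.normal(size=(4, 6))
        R_out = rng.uniform(0, 1, size=(1, 4))
        from noisyvision.attribution import _linear_lrp

        basic = _linear_lrp(x, w, np.zeros(4), R_out, "basic", {})
        eps0 = _linear_lrp(x, w, np.zeros(4), R_out, "epsilon", {"epsilon": 0.0})
        assert np.max(np.abs(basic - eps0)) < 1e-12

    def test_epsilon_infinity_kills_relevance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 6))
        w = rng.normal(size=(4, 6))
        R_out = rng.uniform(0, 1, size=(1, 4))
        from noisyvision.attribution import _linear_lrp

        big = _linear_lrp(x, w, np.zeros(4), R_out, "epsilon", {"epsilon": 1e9})
        assert np.max(np.abs(big)) < 1e-6


class TestNetworkLRP:
    def test_conservation_on_bias_free_network(self, tiny_model):
        model = tiny_model.copy()
        for _, layer in model.parameterized_layers:
            layer.b[:] = 0.0
        img = np.random.default_rng(3).uniform(0, 255, (32, 32))
        probs, raw = _propagate_unrescaled(model, img, 2, _basic_schedule(model))
        assert abs(raw.sum() - probs[0, 2]) < 1e-5

    def test_epsilon_zero_equals_basic_on_network(self, tiny_model):
        img = np.random.default_rng(4).uniform(0, 255, (32, 32))
        basic = _basic_schedule(tiny_model)
        eps = LRPRuleSchedule({n: ("epsilon", {"epsilon": 0.0}) for n, _ in tiny_model.parameterized_layers})
        a = at.lrp(tiny_model, img, 1, basic).pixels
        b = at.lrp(tiny_model, img, 1, eps).pixels
        assert np.max(np.abs(a - b)) < 1e-8

    def test_vectorized_matches_double_loop_oracle(self):
        # 3-layer toy MLP checked against an explicit per-unit double loop
        rng = np.random.default_rng(5)
        sizes = [6, 5, 4, 3]
        Ws = [rng.normal(size=(sizes[i + 1], sizes[i])) for i in range(3)]
        x0 = rng.uniform(0.1, 1.0, sizes[0])

        # forward
        acts = [x0]
        for i, W in enumerate(Ws):
            z = W @ acts[-1]
            acts.append(np.maximum(z, 0) if i < 2 else z)
        probs = softmax(acts[-1][None])[0]
        target = 0

        # double-loop oracle (basic rule)
        R = np.zeros(sizes[-1])
        R[target] = probs[target]
        for li in reversed(range(3)):
            x, W = acts[li], Ws[li]
            R_in = np.zeros(len(x))
            for j in range(W.shape[0]):
                zj = sum(x[i] * W[j, i] for i in range(len(x)))
                if zj == 0:
                    continue
                for i in range(len(x)):
                    R_in[i] += x[i] * W[j, i] / zj * R[j]
            R = R_in

        from noisyvision.attribution import _linear_lrp

        Rv = np.zeros((1, sizes[-1]))
        Rv[0, target] = probs[target]
        for li in reversed(range(3)):
            Rv = _linear_lrp(acts[li][None], Ws[li], np.zeros(Ws[li].shape[0]), Rv, "basic", {})
        assert np.max(np.abs(Rv[0] - R)) < 1e-6

    def test_map_invariant_to_seed_rescaling(self, tiny_model):
        # final [0, 1] rescaling cancels any positive scaling of the seed
        img = np.random.default_rng(6).uniform(0, 255, (32, 32))
        m1 = at.lrp(tiny_model, img, 0).pixels

        # scale all fc2 outgoing weights: softmax prob changes, map must not
        probs = tiny_model.predict_proba(img[None])[0]
        assert m1.min() == 0.0 and m1.max() == 1.0
        m2 = at.lrp(tiny_model, img, 0).pixels
        assert np.array_equal(m1, m2)

    def test_schedule_matches_published_indices_at_depth_19(self):
        class _FakeModel:
            input_mean, input_sd = 127.5, 64.0
            parameterized_layers = [(f"layer{i}", None) for i in range(1, 20)]

        sch = at.default_schedule(_FakeModel(), zbeta_bounds=(-1.99, 2.44))
        rules = {k: v[0] for k, v in sch.rules.items()}
        assert rules["layer1"] == "zbeta"
        assert all(rules[f"layer{i}"] == "gamma" for i in range(2, 9))
        assert all(rules[f"layer{i}"] == "epsilon" for i in range(9, 15))
        assert all(rules[f"layer{i}"] == "basic" for i in range(15, 20))

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            LRPRuleSchedule({"a": ("epsilon", {"epsilon": -1.0})})
        with pytest.raises(ValueError):
            LRPRuleSchedule({"a": ("zbeta", {"low": 2.0, "high": -2.0})})
        with pytest.raises(ValueError):
            LRPRuleSchedule({"a": ("mystery", {})})


class TestMapOperations:
    def test_smooth_delta_peaks_at_origin(self):
        m = np.zeros((21, 21))
        m[10, 10] = 1.0
        out = at.smooth_map(m, sigma=2.0)
        assert out.pixels[10, 10] == 1.0
        assert out.pixels[0, 0] < 0.01

    def test_smooth_preserves_mass_and_constants(self):
        from scipy import ndimage

        m = np.random.default_rng(0).uniform(0, 1, (32, 32))
        blurred = ndimage.gaussian_filter(m, sigma=3, mode="reflect")
        assert abs(blurred.sum() - m.sum()) < 1e-6 * m.sum()
        const = at.smooth_map(np.full((16, 16), 0.7), sigma=3.0)
        assert np.allclose(const.pixels, 1.0)  # constant map renormalises to 1

    def test_binarize_cases(self):
        assert np.all(at.binarize(np.ones((4, 4)), 0.5) == 1)
        assert np.all(at.binarize(np.zeros((4, 4)), 0.5) == 0)
        ramp = np.tile(np.linspace(0, 1, 10), (10, 1))
        mask = at.binarize(ramp, 0.5)
        assert mask[:, :4].sum() == 0 and mask[:, -4:].sum() == 40

    def test_overlap_ratio_cases(self):
        a = np.zeros((20, 20), bool)
        a[:10, :10] = True
        assert at.overlap_ratio(a, a) == 1.0
        b = np.zeros((20, 20), bool)
        b[10:, 10:] = True
        assert at.overlap_ratio(a, b) == 0.0
        # two 10x10 squares offset by 5 pixels: 50 / 150 = 1/3
        c = np.zeros((20, 20), bool)
        c[:10, 5:15] = True
        assert np.isclose(at.overlap_ratio(a, c), 1.0 / 3.0)
        assert at.overlap_ratio(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            at.overlap_ratio(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDiagnosticComparison:
    def _maps(self, rng, n=8, size=24):
        maps = {}
        for i in range(n):
            m = np.zeros((size, size))
            r0, c0 = rng.integers(4, size - 10, 2)
            m[r0 : r0 + 8, c0 : c0 + 8] = 1.0
            maps[i] = m
        return maps

    def test_identical_maps_give_perfect_agreement(self):
        rng = np.random.default_rng(0)
        human = self._maps(rng)
        labels = {i: i % 4 for i in human}
        levels = [0.3, 0.6]
        model = {(i, w): human[i] for i in human for w in levels}
        out = at.diagnostic_comparison(human, model, levels, labels, n_bins=2, seed=0, smooth_sigma=0)
        assert np.allclose(out["mean_r"], 1.0)
        assert np.allclose(out["mean_overlap"], 1.0)

    def test_shuffled_maps_give_zero_correlation(self):
        rng = np.random.default_rng(1)
        human = self._maps(rng, n=16, size=32)
        labels = {i: i % 4 for i in human}
        levels = [0.5]
        model = {}
        for i in human:
            flat = human[i].ravel().copy()
            rng.shuffle(flat)
            model[(i, 0.5)] = flat.reshape(human[i].shape)
        out = at.diagnostic_comparison(human, model, levels, labels, n_bins=20, seed=0, smooth_sigma=0)
        assert abs(out["mean_r"].iloc[0]) < 0.1

    def test_degenerate_bins_equal_single_sample_values(self):
        rng = np.random.default_rng(2)
        human = self._maps(rng, n=4)
        labels = {i: i for i in human}  # 4 categories, 1 image each
        model = {(i, 0.4): np.roll(human[i], 3, axis=0) for i in human}
        out = at.diagnostic_comparison(human, model, [0.4], labels, n_bins=2, seed=0, smooth_sigma=0)
        rs = [np.corrcoef(human[i].ravel(), model[(i, 0.4)].ravel())[0, 1] for i in human]
        ovs = [at.overlap_ratio(human[i] >= 0.5, model[(i, 0.4)] >= 0.2) for i in human]
        assert np.isclose(out["mean_r"].iloc[0], np.mean(rs))
        assert np.isclose(out["mean_overlap"].iloc[0], np.mean(ovs))
        assert out["sd_r"].iloc[0] < 1e-12  # both bins see the same 4 images
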