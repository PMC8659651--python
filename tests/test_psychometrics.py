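import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from noisyvision import psychometrics as psy
from noisyvision.psychometrics import PsychometricCurve, logistic4


TRUTH = dict(lower=0.0625, upper=1.0, midpoint=0.3, slope=20.0)


class TestLogisticFit:
    def test_exact_data_recovers_parameters(self):
        levels = np.linspace(0.05, 0.95, 10)
        y = logistic4(levels, **TRUTH)
        fit = psy.fit_logistic4(PsychometricCurve(levels, y), guess_rate=0.0625)
        assert fit.converged
        assert abs(fit.lower - TRUTH["lower"]) < 0.01 * max(TRUTH["lower"], 1)
        assert abs(fit.upper - TRUTH["upper"]) < 0.01
        assert abs(fit.midpoint - TRUTH["midpoint"]) < 0.003
        assert abs(fit.slope - TRUTH["slope"]) / TRUTH["slope"] < 0.01

    def test_binomial_recovery_median_error(self):
        # 100 simulated experiments, binomial n=50 per level
        levels = np.linspace(0.05, 0.95, 10)
        p = logistic4(levels, **TRUTH)
        true_thr = psy.threshold_at(
            psy.LogisticFit(**TRUTH, residual=0, converged=True), 0.5
        ).threshold
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            y = rng.binomial(50, p) / 50.0
            fit = psy.fit_logistic4(PsychometricCurve(levels, y), guess_rate=0.0625)
            est = psy.threshold_at(fit, 0.5)
            if est.valid:
                errs.append(abs(est.threshold - true_thr))
        assert len(errs) > 90
        assert np.median(errs) < 0.03

    def test_constant_curve_flags_failure(self):
        levels = np.linspace(0.1, 0.9, 6)
        fit = psy.fit_logistic4(PsychometricCurve(levels, np.full(6, 0.0625)))
        assert not fit.converged

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            psy.fit_logistic4(PsychometricCurve([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]))

    def test_threshold_shifts_with_curve(self):
        # shifting the curve rightward by delta shifts the threshold by delta
        levels = np.linspace(0.02, 0.98, 14)
        for delta in (0.0, 0.1, 0.2):
            y = logistic4(levels, 0.0625, 1.0, 0.3 + delta, 20.0)
            fit = psy.fit_logistic4(PsychometricCurve(levels, y), guess_rate=0.0625)
            t = psy.threshold_at(fit, 0.5).threshold
            base = 0.3 - np.log((1 - 0.0625) / (0.5 - 0.0625) - 1) / 20.0
            assert abs(t - (base + delta)) < 2e-3


class TestThresholdAt:
    def test_midpoint_symmetry(self):
        fit = psy.LogisticFit(0.0, 1.0, 0.3, 12.0, 0.0, True)
        est = psy.threshold_at(fit, 0.5)
        assert est.valid and np.isclose(est.threshold, 0.3)

    def test_unreachable_criterion_flagged(self):
        fit = psy.LogisticFit(0.0625, 0.85, 0.3, 20.0, 0.0, True)
        assert not psy.threshold_at(fit, 0.9).valid
        assert not psy.threshold_at(fit, 1.1).valid

    def test_closed_form_matches_bisection(self):
        fit = psy.LogisticFit(0.0625, 1.0, 0.3, 20.0, 0.0, True)
        est = psy.threshold_at(fit, 0.9)
        f = lambda w: logistic4(w, 0.0625, 1.0, 0.3, 20.0) - 0.9
        ref = optimize.bisect(f, 0.0, 1.0, xtol=1e-12)
        assert abs(est.threshold - ref) < 1e-9


class _CorrelationModel:
    """Toy recognizer with engineered per-image SSNR thresholds.

    Holds the clean images; a blended input is matched to the most
    correlated clean image and recognised iff that correlation exceeds the
    image's criterion.  Errors go to the next category, so pure noise
    produces a stable response bias.
    """

    def __init__(self, images, labels, criteria, canvas=32, n_classes=4):
        self.images = images
        self.labels = labels
        self.criteria = criteria
        self.canvas = canvas
        self.n_classes = n_classes

    def predict(self, batch):
        out = []
        flat = self.images.reshape(len(self.images), -1)
        for x in np.atleast_3d(batch):
            r = np.array([np.corrcoef(x.ravel(), f)[0, 1] for f in flat])
            i = int(np.argmax(r))
            if r[i] >= self.criteria[i]:
                out.append(self.labels[i])
            else:
                out.append((self.labels[i] + 1) % self.n_classes)
        return np.array(out)


class TestPerImageThresholds:
    def test_recovers_engineered_ordering(self):
        rng = np.random.default_rng(4)
        n = 12
        images = rng.normal(127.5, 40.0, (n, 32, 32))
        labels = np.arange(n) % 4
        criteria = np.linspace(0.25, 0.8, n)
        model = _CorrelationModel(images, labels, criteria)
        table = psy.per_image_thresholds(
            model, images, labels, np.linspace(0.05, 1.0, 20), n_noise=8, criterion=0.5, seed=0
        )
        ok = table[~table["excluded"]]
        assert len(ok) >= 8
        rho = pd.Series(ok["threshold"].to_numpy()).corr(
            pd.Series(criteria[ok["image_id"].to_numpy()]), method="spearman"
        )
        assert rho > 0.9

    def test_bias_category_is_excluded(self):
        rng = np.random.default_rng(1)
        images = rng.normal(127.5, 40.0, (4, 32, 32))
        labels = np.arange(4)
        model = _CorrelationModel(images, labels, np.full(4, 0.5))
        table = psy.per_image_thresholds(
            model, images, labels, np.linspace(0.05, 1.0, 12), n_noise=6, criterion=0.5, seed=0
        )
        bias = psy.noise_bias_category(model, n_noise=6, seed=0)
        assert (table.loc[table["label"] == bias, "reason"] == "bias").all()


class TestConfusionMatrix:
    def test_all_correct_gives_identity(self):
        t = pd.DataFrame({"true_label": [0, 1, 2, 0, 1, 2], "response": [0, 1, 2, 0, 1, 2]})
        assert np.allclose(psy.confusion_matrix(t, 3), np.eye(3))

    def test_hand_tallied_table(self):
        t = pd.DataFrame(
            {"true_label": [0, 0, 0, 1, 1, 2], "response": [0, 0, 1, 1, 0, 2]}
        )
        expected = np.array([[2 / 3, 1 / 3, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(psy.confusion_matrix(t, 3), expected)

    def test_uniform_responses_and_empty_rows(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(
            {"true_label": np.repeat([0, 1], 4000), "response": rng.integers(0, 4, 8000)}
        )
        M = psy.confusion_matrix(t, 4)
        assert np.allclose(M[:2], 0.25, atol=0.03)
        assert np.isnan(M[2]).all() and np.isnan(M[3]).all()  # no trials: flagged


class TestSplitHalfReliability:
    def test_identical_observers_give_unit_r(self):
        base = np.random.default_rng(0).uniform(0.2, 0.6, 50)
        T = np.tile(base, (6, 1))
        mean_r, sd_r = psy.split_half_reliability(T, n_splits=50, seed=0)
        assert np.isclose(mean_r, 1.0)
        assert sd_r < 1e-12

    def test_matches_spearman_brown_prediction(self):
        # thresholds = shared per-image signal + iid observer noise
        rng = np.random.default_rng(2)
        n_obs, n_img = 20, 300
        sig_sd, noise_sd = 0.08, 0.08
        signal = rng.normal(0.4, sig_sd, n_img)
        T = signal + rng.normal(0.0, noise_sd, (n_obs, n_img))
        mean_r, _ = psy.split_half_reliability(T, n_splits=2000, seed=1)
        half = n_obs // 2
        predicted = sig_sd**2 / (sig_sd**2 + noise_sd**2 / half)
        assert abs(mean_r - predicted) < 0.02

    def test_two_observers_degenerate_split(self):
        rng = np.random.default_rng(3)
        T = rng.uniform(0.2, 0.6, (2, 40))
        mean_r, sd_r = psy.split_half_reliability(T, n_splits=100, seed=0)
        expected = np.corrcoef(T[0], T[1])[0, 1]
        assert np.isclose(mean_r, expected)
        assert sd_r < 1e-12  # only one split exists


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = psy.compare_correlations_fisher(0.4, 100, 0.4, 80)
        assert z == 0.0 and np.isclose(p, 1.0)

    def test_published_worked_example(self):
        # r = 0.53 (n=716) vs r = 0.24 (n=723) -> z reported as 6.55
        z, p = psy.compare_correlations_fisher(0.53, 716, 0.24, 723)
        assert round(z, 1) == 6.5
        assert p < 1e-9

    def test_antisymmetry(self):
        z1, _ = psy.compare_correlations_fisher(0.6, 50, 0.2, 70)
        z2, _ = psy.compare_correlations_fisher(0.2, 70, 0.6, 50)
        assert np.isclose(z1, -z2)

    def test_type_i_error_calibration(self):
        # both samples from the same bivariate normal (rho = 0.3, n = 100)
        rng = np.random.default_rng(0)
        n, reps, rho = 100, 10_000, 0.3
        cov = np.array([[1.0, rho], [rho, 1.0]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            a = rng.standard_normal((n, 2)) @ L.T
            b = rng.standard_normal((n, 2)) @ L.T
            r1 = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
            r2 = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
            _, p = psy.compare_correlations_fisher(r1, n, r2, n)
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            psy.compare_correlations_fisher(1.0, 50, 0.2, 50)
        with pytest.raises(ValueError):
            psy.compare_correlations_fisher(0.5, 3, 0.2, 50)
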