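"""Layer-wise noise susceptibility and weight-change analyses.

Two complementary per-layer SSNR thresholds quantify how noise degrades a
network's internal representations:

* correlation-based -- the Pearson correlation between a layer's response
  to a clean image and to the same image at SSNR ``w`` rises monotonically
  with ``w``; the SSNR at which the (logistic-fitted) correlation curve
  crosses 0.5 is the layer's threshold.  If the curve is still positive at
  SSNR 0 it is first linearly rescaled to span [0, 1].
* classification-based -- a linear multiclass SVM trained on clean-image
  activations is tested at each SSNR level; the threshold is the SSNR at
  which accuracy crosses 50%.

How much training changed a layer's weights is measured by canonical
correlation analysis between the two weight matrices, treating units as the
canonical variables and their flattened incoming weights as observations --
so the measure is invariant to any invertible (e.g. orthogonal) mixing of
the unit axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .psychometrics import PsychometricCurve, fit_logistic4, threshold_at
from .stimulus import blend_ssnr, make_gaussian_noise, make_phase_scrambled_noise

__all__ = [
    "LayerThresholdProfile",
    "capture_activations",
    "corr_susceptibility",
    "clf_susceptibility",
    "threshold_slope",
    "weight_cca",
]

MAX_UNITS = 50_000  # layers above this are randomly subsampled (fixed seed)


@dataclass
class LayerThresholdProfile:
    layers: list
    thresholds: np.ndarray
    valid: np.ndarray
    kind: str                       # 'correlation' | 'classification'
    noise_type: str
    curves: pd.DataFrame            # level x layer mean values
    clean_accuracy: dict | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"layer": self.layers, "threshold": self.thresholds, "valid": self.valid,
             "kind": self.kind, "noise_type": self.noise_type}
        )


def capture_activations(model, image: np.ndarray) -> dict:
    """Per-layer flattened activation vectors for one image (deterministic)."""
    return model.forward_activations(image)


def _noise(noise_type, canvas, rng, spectrum):
    if noise_type == "gaussian":
        return make_gaussian_noise(canvas, canvas, rng.integers(2**31))
    if noise_type == "phase":
        if spectrum is None:
            raise ValueError("phase-scrambled noise requires an amplitude spectrum")
        return make_phase_scrambled_noise(spectrum, rng.integers(2**31))
    raise ValueError(f"unknown noise type {noise_type!r}")


def _subsample_indices(n_units: int, seed: int = 12345) -> np.ndarray | None:
    if n_units <= MAX_UNITS:
        return None
    return np.random.default_rng(seed).choice(n_units, MAX_UNITS, replace=False)


def _safe_corr(a, b) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def corr_susceptibility(
    model, images, noise_type: str, levels, n_noise: int = 3, seed: int = 0,
    spectrum=None, clip: bool = True,
) -> LayerThresholdProfile:
    """Correlation-based SSNR threshold per layer.

    Per level, the mean over images and noise draws of the correlation
    between clean and noisy activation patterns is computed per layer; each
    layer's curve is rescaled to span [0, 1] if its floor is above zero,
    fitted with a logistic, and inverted at r = 0.5.  Layers with constant
    activations are flagged invalid.
    """
    images = np.asarray(images, dtype=float)
    levels = np.asarray(list(levels), dtype=float)
    rng = np.random.default_rng(seed)
    clean_acts = [capture_activations(model, im) for im in images]
    layer_names = list(clean_acts[0])
    sub = {name: _subsample_indices(len(clean_acts[0][name])) for name in layer_names}

    sums = {name: np.zeros(len(levels)) for name in layer_names}
    counts = {name: np.zeros(len(levels)) for name in layer_names}
    for ii, im in enumerate(images):
        for _ in range(n_noise):
            noise = _noise(noise_type, model.canvas, rng, spectrum)
            for li, w in enumerate(levels):
                acts = capture_activations(model, blend_ssnr(im, noise, w, clip=clip))
                for name in layer_names:
                    a = clean_acts[ii][name]
                    b = acts[name]
                    if sub[name] is not None:
                        a, b = a[sub[name]], b[sub[name]]
                    r = _safe_corr(a, b)
                    if np.isfinite(r):
                        sums[name][li] += r
                        counts[name][li] += 1

    thresholds, valid = [], []
    curve_cols = {}
    for name in layer_names:
        with np.errstate(invalid="ignore"):
            curve = sums[name] / counts[name]
        curve_cols[name] = curve
        if not np.all(np.isfinite(curve)):
            thresholds.append(np.nan)
            valid.append(False)
            continue
        fitted_curve = curve
        if curve[0] > 0:  # floor above zero: linearly rescale to span [0, 1]
            span = curve.max() - curve.min()
            if span > 0:
                fitted_curve = (curve - curve.min()) / span
        fit = fit_logistic4(PsychometricCurve(levels, np.clip(fitted_curve, 0, 1)))
        est = threshold_at(fit, 0.5)
        thresholds.append(est.threshold)
        valid.append(est.valid)
    return LayerThresholdProfile(
        layers=layer_names, thresholds=np.array(thresholds), valid=np.array(valid),
        kind="correlation", noise_type=noise_type,
        curves=pd.DataFrame(curve_cols, index=levels),
    )


def clf_susceptibility(
    model, train_images, train_labels, test_images, test_labels,
    noise_type: str, levels, n_noise: int = 1, seed: int = 0, spectrum=None,
) -> LayerThresholdProfile:
    """Classification-based SSNR threshold per layer.

    A linear one-vs-one SVM (C=1, default settings) is trained per layer on
    clean training-image activations, standardized by the clean-training
    statistics, then tested on noisy held-out images at each SSNR level.
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("need at least 2 categories")
    if set(map(tuple, np.asarray(train_images).reshape(len(train_images), -1))) & set(
        map(tuple, np.asarray(test_images).reshape(len(test_images), -1))
    ):
        raise ValueError("train and test images must be disjoint")
    levels = np.asarray(list(levels), dtype=float)
    rng = np.random.default_rng(seed)

    train_acts = [capture_activations(model, im) for im in np.asarray(train_images, dtype=float)]
    layer_names = list(train_acts[0])
    sub = {name: _subsample_indices(len(train_acts[0][name])) for name in layer_names}

    classifiers, scalers = {}, {}
    for name in layer_names:
        X = np.stack([(a[name] if sub[name] is None else a[name][sub[name]]) for a in train_acts])
        scalers[name] = StandardScaler().fit(X)
        classifiers[name] = SVC(kernel="linear", C=1.0).fit(scalers[name].transform(X), train_labels)

    acc = {name: np.zeros(len(levels)) for name in layer_names}
    test_images = np.asarray(test_images, dtype=float)
    for li, w in enumerate(levels):
        draws = 1 if w == 1.0 else n_noise
        for _ in range(draws):
            feats = {name: [] for name in layer_names}
            for im in test_images:
                blended = blend_ssnr(im, _noise(noise_type, model.canvas, rng, spectrum), w) if w < 1.0 else np.clip(im, 0, 255)
                a = capture_activations(model, blended)
                for name in layer_names:
                    feats[name].append(a[name] if sub[name] is None else a[name][sub[name]])
            for name in layer_names:
                X = scalers[name].transform(np.stack(feats[name]))
                acc[name][li] += float(np.mean(classifiers[name].predict(X) == test_labels))
        for name in layer_names:
            acc[name][li] /= draws

    K = len(np.unique(train_labels))
    thresholds, valid, clean_acc = [], [], {}
    for name in layer_names:
        clean_acc[name] = acc[name][levels == 1.0][0] if np.any(levels == 1.0) else np.nan
        fit = fit_logistic4(PsychometricCurve(levels, acc[name]), guess_rate=1.0 / K)
        est = threshold_at(fit, 0.5)
        thresholds.append(est.threshold)
        valid.append(est.valid)
    return LayerThresholdProfile(
        layers=layer_names, thresholds=np.array(thresholds), valid=np.array(valid),
        kind="classification", noise_type=noise_type,
        curves=pd.DataFrame(acc, index=levels), clean_accuracy=clean_acc,
    )


def threshold_slope(profile: LayerThresholdProfile) -> tuple[float, float]:
    """OLS slope of threshold against 1-based layer index, with two-sided p.

    Layers with invalid thresholds are dropped; a flat profile returns
    slope 0 with p = 1 (zero-variance flag).
    """
    idx = np.arange(1, len(profile.layers) + 1, dtype=float)
    ok = profile.valid & np.isfinite(profile.thresholds)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid layers for a slope")
    x, y = idx[ok], profile.thresholds[ok]
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def weight_cca(model_a, model_b, layer: str, rcond: float = 1e-8) -> tuple[float, np.ndarray]:
    """Mean canonical correlation between two models' weights at ``layer``.

    Weights are reshaped to (units, flattened incoming weights); CCA treats
    the units as the canonical variables and the incoming-weight coordinates
    as observations, so the similarity is invariant to invertible linear
    mixing of the unit axis.  Whitening is performed in the SVD basis with
    singular values below ``rcond * max`` discarded, which handles
    rank-deficient weight matrices and is exact (no ridge bias) otherwise;
    the number of components is min(rank_a, rank_b).  Returns
    ``(mean canonical correlation, full spectrum)``.
    """
    Wa = np.asarray(model_a.get_layer(layer).weight_matrix, dtype=float)
    Wb = np.asarray(model_b.get_layer(layer).weight_matrix, dtype=float)
    if Wa.shape != Wb.shape:
        raise ValueError(f"layer {layer!r} shapes differ: {Wa.shape} vs {Wb.shape}")
    # observations = incoming-weight coordinates, variables = units
    X = Wa.T - Wa.T.mean(axis=0)
    Y = Wb.T - Wb.T.mean(axis=0)
    Ux, sx, _ = linalg.svd(X, full_matrices=False)
    Uy, sy, _ = linalg.svd(Y, full_matrices=False)
    Ux = Ux[:, sx > rcond * sx.max()]
    Uy = Uy[:, sy > rcond * sy.max()]
    sv = linalg.svdvals(Ux.T @ Uy)
    sv = np.clip(sv, 0.0, 1.0)
    return float(sv.mean()), sv
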