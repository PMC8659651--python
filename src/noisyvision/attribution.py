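"""Composite layer-wise relevance propagation and diagnostic-map comparison.

Relevance propagation distributes a network's output score for the target
class backward through the layers.  For a linear step z_j = sum_i x_i w_ij
(+ b_j), the basic (LRP-0) rule assigns

    R_i = sum_j  x_i w_ij / z_j * R_j,

and the composite variants stabilise or constrain the redistribution:
LRP-eps adds a sign-matched stabiliser eps*sign(z_j) to the denominator,
LRP-gamma boosts positive weights (w + gamma*max(w, 0)) in numerator and
denominator, and LRP-zbeta (input layer only) uses the feasible input range
[l, h] so that relevance respects the pixel bounds.  Through max-pooling
relevance follows the pooling winner; rectification is pass-through.  Biases
enter the denominator but receive no back-distributed relevance, so
conservation is exact only on bias-free networks.

The rule schedule mirrors the composite assignment used on 19-layer
networks (input layer z-beta; first ~40% of remaining layers gamma; next
~35% epsilon; final ~25% basic); at depth 19 the exact published indices
(zbeta 1, gamma 2-8, eps 9-14, basic 15-19) are reproduced.

The resulting pixel map (negatives zeroed, rescaled to [0, 1]) plays the
same role as a human observer's annotated diagnostic region and is compared
to it by spatial correlation and intersection-over-union overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .network import Conv2D, Dense, MaxPool2D, _col2im, _im2col

__all__ = [
    "LRPRuleSchedule",
    "RelevanceMap",
    "default_schedule",
    "lrp",
    "smooth_map",
    "binarize",
    "overlap_ratio",
    "diagnostic_comparison",
]

_RULES = ("basic", "epsilon", "gamma", "zbeta")


@dataclass
class LRPRuleSchedule:
    """Assignment of one relevance rule per parameterized layer."""

    rules: dict                      # layer name -> (rule, params dict)

    def __post_init__(self):
        for name, (rule, params) in self.rules.items():
            if rule not in _RULES:
                raise ValueError(f"unknown rule {rule!r} for layer {name!r}")
            if rule == "epsilon" and params.get("epsilon", 0.0) < 0:
                raise ValueError("epsilon must be nonnegative")
            if rule == "gamma" and params.get("gamma", 0.0) < 0:
                raise ValueError("gamma must be nonnegative")
            if rule == "zbeta":
                if params["low"] >= params["high"]:
                    raise ValueError("zbeta requires low < high")

    def rule_for(self, name: str):
        return self.rules[name]


def default_schedule(
    model, epsilon: float = 0.25, gamma: float = 0.05, zbeta_bounds: tuple | None = None
) -> LRPRuleSchedule:
    """Fractional-depth composite schedule for an arbitrary-depth model.

    ``zbeta_bounds`` defaults to the model's actual standardized input range
    ((0 - mean)/sd, (255 - mean)/sd); fixed published bounds such as
    (-1.99, 2.44) may be supplied instead.
    """
    names = [n for n, _ in model.parameterized_layers]
    if zbeta_bounds is None:
        zbeta_bounds = ((0.0 - model.input_mean) / model.input_sd, (255.0 - model.input_mean) / model.input_sd)
    rules = {names[0]: ("zbeta", {"low": float(zbeta_bounds[0]), "high": float(zbeta_bounds[1])})}
    rest = names[1:]
    n = len(rest)
    n_gamma = int(round(n * 7 / 18))
    n_eps = int(round(n * 6 / 18))
    for i, name in enumerate(rest):
        if i < n_gamma:
            rules[name] = ("gamma", {"gamma": gamma})
        elif i < n_gamma + n_eps:
            rules[name] = ("epsilon", {"epsilon": epsilon})
        else:
            rules[name] = ("basic", {})
    return LRPRuleSchedule(rules)


@dataclass
class RelevanceMap:
    """Pixel-wise nonnegative relevance, rescaled to [0, 1]."""

    pixels: np.ndarray
    target_class: int
    image_id: object = None
    all_zero: bool = False
    schedule: LRPRuleSchedule | None = field(default=None, repr=False)


def _stabilize(z, epsilon):
    s = np.where(z >= 0, 1.0, -1.0)
    d = z + epsilon * s
    return np.where(d == 0, s * 1e-12, d)


def _linear_lrp(x, w, b, R_out, rule, params):
    """Relevance through one linear map (x: (..., F), w: (O, F), R_out: (..., O))."""
    if rule == "gamma":
        g = params.get("gamma", 0.05)
        w = w + g * np.maximum(w, 0.0)
        b = b + g * np.maximum(b, 0.0)
    if rule == "zbeta":
        low, high = params["low"], params["high"]
        wp, wm = np.maximum(w, 0.0), np.minimum(w, 0.0)
        z = x @ w.T - low * np.sum(wp, axis=1) - high * np.sum(wm, axis=1) + b
        s = R_out / _stabilize(z, 0.0)
        return x * (s @ w) - low * (s @ wp) - high * (s @ wm)
    z = x @ w.T + b
    eps = params.get("epsilon", 0.0) if rule == "epsilon" else 0.0
    s = R_out / _stabilize(z, eps)
    return x * (s @ w)


def lrp(model, image: np.ndarray, target_class: int, schedule: LRPRuleSchedule | None = None) -> RelevanceMap:
    """Relevance map of ``model``'s response to ``target_class`` for ``image``.

    Relevance is seeded at the softmax unit of the target class and
    propagated backward with the per-layer rule; negatives are zeroed and
    the map rescaled to [0, 1] only at the end.  A dead path yields a
    flagged all-zero map rather than an exception.
    """
    if not (0 <= target_class < model.n_classes):
        raise ValueError(f"target class {target_class} out of range")
    schedule = schedule or default_schedule(model)
    x = model.preprocess(np.asarray(image, dtype=float))
    caches = []
    probs = model.forward(x, caches)

    # seed: relevance of the target softmax unit
    R = np.zeros_like(probs)
    R[0, target_class] = probs[0, target_class]

    for name, layer, cache in reversed(caches):
        if isinstance(layer, Dense):
            rule, params = schedule.rule_for(name)
            xin = cache["x"]
            R = _linear_lrp(xin, layer.w, layer.b, R, rule, params)
            if "flattened_from" in cache:
                R = R.reshape(cache["flattened_from"])
        elif isinstance(layer, MaxPool2D):
            R = layer.unpool(cache, R)
        elif isinstance(layer, Conv2D):
            rule, params = schedule.rule_for(name)
            n, co, h, w = R.shape if R.ndim == 4 else (1, *R.shape)
            R_flat = R.transpose(0, 2, 3, 1).reshape(n, h * w, co)
            patches = cache["patches"]
            R_patches = np.stack(
                [_linear_lrp(patches[i], layer.w, layer.b, R_flat[i], rule, params) for i in range(n)]
            )
            R = _col2im(R_patches, cache["x_shape"], layer.ksize, layer.ksize)
        else:  # pragma: no cover
            raise TypeError(f"no relevance rule for layer {name!r}")

    pix = R[0, 0]
    pix = np.maximum(pix, 0.0)
    top = pix.max()
    if top <= 0:
        return RelevanceMap(np.zeros_like(pix), target_class, all_zero=True, schedule=schedule)
    return RelevanceMap(pix / top, target_class, schedule=schedule)


def smooth_map(rmap: RelevanceMap | np.ndarray, sigma: float = 3.0) -> RelevanceMap:
    """Gaussian blur (reflective boundary) followed by [0, 1] renormalization."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pix = rmap.pixels if isinstance(rmap, RelevanceMap) else np.asarray(rmap, dtype=float)
    out = ndimage.gaussian_filter(pix, sigma=sigma, mode="reflect")
    top = out.max()
    if top > 0:
        out = out / top
    if isinstance(rmap, RelevanceMap):
        return RelevanceMap(out, rmap.target_class, rmap.image_id, all_zero=top <= 0, schedule=rmap.schedule)
    return RelevanceMap(out, -1, all_zero=top <= 0)


def binarize(rmap, threshold: float) -> np.ndarray:
    """Pixels at or above ``threshold`` -> 1, else 0."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    pix = rmap.pixels if isinstance(rmap, RelevanceMap) else np.asarray(rmap, dtype=float)
    return (pix >= threshold).astype(int)


def overlap_ratio(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (both empty -> 0)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask dimension mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


HUMAN_BINARIZE_THRESHOLD = 0.5
MODEL_BINARIZE_THRESHOLD = 0.2


def diagnostic_comparison(
    human_maps: dict,
    model_maps_by_ssnr: dict,
    levels,
    labels: dict,
    n_bins: int = 50,
    seed: int = 0,
    smooth_sigma: float = 3.0,
) -> pd.DataFrame:
    """Binned comparison of human and model diagnostic maps per SSNR level.

    ``human_maps`` maps image id -> map; ``model_maps_by_ssnr`` maps
    ``(image id, level)`` -> map (RelevanceMap or array); ``labels`` maps
    image id -> category.  Per bin, one image per category is sampled
    (without replacement across bins while images last); per level, the mean
    spatial Pearson correlation and the overlap ratio (human maps binarized
    at 0.5, model maps smoothed then binarized at 0.2) are averaged across
    the bin's images.  Returns per-level means and SDs over bins.
    """
    levels = list(levels)
    rng = np.random.default_rng(seed)
    by_cat = {}
    for img, cat in labels.items():
        if img in human_maps:
            by_cat.setdefault(cat, []).append(img)
    pools = {cat: rng.permutation(imgs).tolist() for cat, imgs in by_cat.items()}

    def _pix(m):
        return m.pixels if isinstance(m, RelevanceMap) else np.asarray(m, dtype=float)

    bin_r = {w: [] for w in levels}
    bin_ov = {w: [] for w in levels}
    for b in range(n_bins):
        chosen = []
        for cat, pool in pools.items():
            if not pool:  # pool exhausted: refill (sampling with replacement across refills)
                pool.extend(rng.permutation(by_cat[cat]).tolist())
            chosen.append(pool.pop())
        for w in levels:
            rs, ovs = [], []
            for img in chosen:
                if (img, w) not in model_maps_by_ssnr:
                    continue  # missing pair skipped
                hm = _pix(human_maps[img])
                mm = _pix(model_maps_by_ssnr[(img, w)])
                if smooth_sigma > 0:  # pen-thickness compensation, model side only
                    mm = smooth_map(mm, smooth_sigma).pixels
                if hm.std() > 0 and mm.std() > 0:
                    rs.append(float(np.corrcoef(hm.ravel(), mm.ravel())[0, 1]))
                ovs.append(
                    overlap_ratio(
                        hm >= HUMAN_BINARIZE_THRESHOLD, mm >= MODEL_BINARIZE_THRESHOLD
                    )
                )
            if rs:
                bin_r[w].append(np.mean(rs))
            if ovs:
                bin_ov[w].append(np.mean(ovs))
    rows = []
    for w in levels:
        rows.append(
            {
                "level": w,
                "mean_r": float(np.mean(bin_r[w])) if bin_r[w] else np.nan,
                "sd_r": float(np.std(bin_r[w])) if bin_r[w] else np.nan,
                "mean_overlap": float(np.mean(bin_ov[w])) if bin_ov[w] else np.nan,
                "sd_overlap": float(np.std(bin_ov[w])) if bin_ov[w] else np.nan,
            }
        )
    return pd.DataFrame(rows)
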