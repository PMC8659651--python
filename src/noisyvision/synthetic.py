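"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: procedural object
images organised into visually distinct shape categories, simulated
observers for the two behavioural designs (fixed-SSNR single presentations
and ascending-SSNR stopping trials, with diagnostic-region maps), and
run-structured voxel response patterns that are noisy linear readouts of a
chosen network layer.  All generators are pure functions of their seed and
parameters, so recovery tests can compare pipeline output against the
generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import neural

__all__ = [
    "ImageDataset",
    "ObserverModel",
    "VoxelPatternSet",
    "generate_image_dataset",
    "simulate_observer_fixed",
    "simulate_observer_ascending",
    "simulate_voxel_patterns",
    "psychometric_probability",
]

_FAMILIES = ("blob", "bars", "ring", "cross", "wedge", "checker")


@dataclass
class ImageDataset:
    """Procedural grayscale object images with category labels and masks."""

    images: np.ndarray          # (N, canvas, canvas) float in [0, 255]
    labels: np.ndarray          # (N,) int in [0, K-1]
    split: np.ndarray           # (N,) 'train' | 'test'
    masks: np.ndarray           # (N, canvas, canvas) bool foreground masks
    category_names: list
    params: dict

    @property
    def n_classes(self) -> int:
        return len(self.category_names)

    def subset(self, split: str):
        sel = self.split == split
        return self.images[sel], self.labels[sel], self.masks[sel]


def _draw_shape(family: str, canvas: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """One jittered instance of a shape family: (image, foreground mask)."""
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
    cx = canvas / 2 + rng.uniform(-0.05, 0.05) * canvas
    cy = canvas / 2 + rng.uniform(-0.05, 0.05) * canvas
    r = canvas * rng.uniform(0.22, 0.30)
    theta = rng.uniform(0, np.pi / 6)  # modest pose jitter keeps raw pixels informative
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)

    if family == "blob":
        a, b = r, r * rng.uniform(0.5, 0.75)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    elif family == "bars":
        period = r * rng.uniform(0.55, 0.75)
        stripes = (np.mod(u, period) < period / 2)
        mask = stripes & (np.abs(u) <= r) & (np.abs(v) <= r * 0.8)
    elif family == "ring":
        rad = np.sqrt(u ** 2 + v ** 2)
        mask = (rad <= r) & (rad >= r * rng.uniform(0.55, 0.65))
    elif family == "cross":
        t = r * rng.uniform(0.25, 0.35)
        mask = ((np.abs(u) <= t) & (np.abs(v) <= r)) | ((np.abs(v) <= t) & (np.abs(u) <= r))
    elif family == "wedge":
        ang = np.arctan2(v, u)
        rad = np.sqrt(u ** 2 + v ** 2)
        mask = (rad <= r * 1.1) & (np.abs(ang) <= np.pi / 4)
    elif family == "checker":
        period = r * rng.uniform(0.6, 0.8)
        mask = (np.mod(u, period) < period / 2) ^ (np.mod(v, period) < period / 2)
        mask &= (np.abs(u) <= r) & (np.abs(v) <= r)
    else:  # pragma: no cover - guarded by generate_image_dataset
        raise ValueError(f"unknown shape family {family!r}")

    fg = rng.uniform(175, 205)
    bg = rng.uniform(80, 100)
    img = np.full((canvas, canvas), bg)
    img[mask] = fg
    img += rng.normal(0.0, 4.0, size=img.shape)  # mild pixel texture
    return np.clip(img, 0, 255), mask


def generate_image_dataset(
    K: int, n_train: int, n_test: int, canvas: int = 64, seed: int = 0
) -> ImageDataset:
    """K shape families, ``n_train``/``n_test`` jittered instances per family."""
    if K < 2:
        raise ValueError("need at least 2 categories")
    if K > len(_FAMILIES):
        raise ValueError(f"at most {len(_FAMILIES)} shape families available")
    if n_train < 1 or n_test < 1:
        raise ValueError("counts must be positive")
    if canvas < 16:
        raise ValueError("canvas too small for the shape families")
    rng = np.random.default_rng(seed)
    images, labels, split, masks = [], [], [], []
    for k in range(K):
        for i in range(n_train + n_test):
            img, mask = _draw_shape(_FAMILIES[k], canvas, rng)
            images.append(img)
            labels.append(k)
            masks.append(mask)
            split.append("train" if i < n_train else "test")
    return ImageDataset(
        images=np.array(images),
        labels=np.array(labels),
        split=np.array(split),
        masks=np.array(masks),
        category_names=list(_FAMILIES[:K]),
        params={"K": K, "n_train": n_train, "n_test": n_test, "canvas": canvas, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Simulated observers


def _default_confusability(K: int, strength: float = 0.5) -> np.ndarray:
    """Error-response distribution with two superordinate clusters.

    Rows are true categories, columns the distribution of *incorrect*
    responses.  Categories are split into two clusters (animate/inanimate
    analogue); within-cluster confusions receive ``1 + strength`` times the
    weight of between-cluster confusions.
    """
    half = K // 2
    C = np.ones((K, K))
    np.fill_diagonal(C, 0.0)
    for a in range(K):
        for b in range(K):
            if a != b and (a < half) == (b < half):
                C[a, b] *= 1.0 + strength
    return C / C.sum(axis=1, keepdims=True)


@dataclass
class ObserverModel:
    """Observer whose accuracy follows a 4-parameter psychometric law.

    P(correct | w) = g + (1 - g - lapse) / (1 + exp(-slope * (w - t_img)))

    with guess rate ``g = 1/K`` and a per-image midpoint ``t_img``.  Errors
    are drawn from a confusability matrix over the wrong categories.  In the
    ascending design the observer stops when the SSNR ramp passes
    ``t_img`` plus Gaussian decision noise.
    """

    thresholds: np.ndarray               # (n_images,) per-image t_img in (0, 1)
    slope: float = 20.0
    lapse: float = 0.02
    n_classes: int = 4
    confusability: np.ndarray | None = None
    decision_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any((self.thresholds <= 0) | (self.thresholds >= 1)):
            raise ValueError("per-image thresholds must lie in (0, 1)")
        if self.confusability is None:
            self.confusability = _default_confusability(self.n_classes)
        rows = self.confusability.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("confusability rows must sum to 1")

    @property
    def guess_rate(self) -> float:
        return 1.0 / self.n_classes


def psychometric_probability(w, threshold, slope, lapse, guess_rate):
    """The generating psychometric law (shared by observers and oracles)."""
    from scipy.special import expit

    return guess_rate + (1.0 - guess_rate - lapse) * expit(slope * (np.asarray(w, dtype=float) - threshold))


def _respond(true_label, p_correct, model: ObserverModel, rng) -> int:
    if rng.random() < p_correct:
        return int(true_label)
    return int(rng.choice(model.n_classes, p=model.confusability[true_label]))


def simulate_observer_fixed(labels, levels, model: ObserverModel, observer_id: int = 0) -> pd.DataFrame:
    """Fixed-SSNR design: each image is shown once at its assigned level.

    Images are assigned to SSNR levels cyclically within the image list
    (the experimental counterbalancing is irrelevant to a simulated
    observer).  Returns a trial table with one row per image.
    """
    levels = np.asarray(list(levels), dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("SSNR levels must lie in [0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng((model.seed, observer_id))
    rows = []
    for i, lab in enumerate(labels):
        w = levels[i % len(levels)]
        p = psychometric_probability(w, model.thresholds[i], model.slope, model.lapse, model.guess_rate)
        resp = _respond(lab, p, model, rng)
        rows.append((i, int(lab), float(w), resp, resp == lab, np.nan, observer_id))
    return pd.DataFrame(
        rows, columns=["image_id", "true_label", "ssnr", "response", "correct", "stop_ssnr", "observer_id"]
    )


def simulate_observer_ascending(
    labels, masks, step: float, model: ObserverModel, observer_id: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Ascending-SSNR design: the ramp stops at the observer's threshold.

    The stop SSNR is the per-image threshold plus Gaussian decision noise,
    quantized *up* to the step grid (the observer responds at the first ramp
    step whose SSNR exceeds their internal criterion), clipped to [0, 1].
    The categorization response then follows the psychometric law evaluated
    at the stop level.  Also returns ground-truth diagnostic maps: the shape
    mask eroded to its core and smoothed with a 15-pixel-diameter disc
    (emulating thick-penned human annotations).
    """
    if not (0 < step < 1):
        raise ValueError("step must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng((model.seed, 1000 + observer_id))
    rows = []
    for i, lab in enumerate(labels):
        criterion = model.thresholds[i] + (
            rng.normal(0.0, model.decision_noise_sd) if model.decision_noise_sd > 0 else 0.0
        )
        stop = np.ceil(max(criterion, 0.0) / step) * step
        stop = float(min(stop, 1.0))
        p = psychometric_probability(stop, model.thresholds[i], model.slope, model.lapse, model.guess_rate)
        resp = _respond(lab, p, model, rng)
        rows.append((i, int(lab), stop, resp, resp == lab, stop, observer_id))
    trials = pd.DataFrame(
        rows, columns=["image_id", "true_label", "ssnr", "response", "correct", "stop_ssnr", "observer_id"]
    )
    maps = {i: diagnostic_map_truth(masks[i]) for i in range(len(labels))}
    return trials, maps


def diagnostic_map_truth(mask: np.ndarray, pen_diameter: int = 15) -> np.ndarray:
    """Ground-truth diagnostic map: eroded shape core, disc-smoothed, in [0, 1]."""
    core = ndimage.binary_erosion(mask, iterations=2)
    if not core.any():
        core = mask
    r = pen_diameter // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = (yy ** 2 + xx ** 2 <= r ** 2).astype(float)
    out = ndimage.convolve(core.astype(float), disc / disc.sum(), mode="constant")
    return out / out.max() if out.max() > 0 else out


# ---------------------------------------------------------------------------
# Synthetic voxel patterns


@dataclass
class VoxelPatternSet:
    """Run-structured voxel responses generated from a model layer."""

    data: "neural.ResponseAmplitudeSet"
    ground_truth_layer: str | None
    snr: float
    seed: int
    timeseries: list | None = None   # per-run dicts understood by amplitudes_from_timeseries


def simulate_voxel_patterns(
    layer_features: np.ndarray,
    n_voxels: int,
    n_runs: int,
    snr: float,
    seed: int,
    conditions=None,
    categories=None,
    ground_truth_layer: str | None = None,
    emit_timeseries: bool = False,
) -> VoxelPatternSet:
    """Voxel responses = fixed random linear readout of layer features + run noise.

    Each of ``n_runs`` runs contains every stimulus (row of
    ``layer_features``) exactly once.  The readout is standardized across
    stimuli and scaled by ``snr`` relative to unit-SD run noise, so
    ``snr = 0`` carries no stimulus information and large ``snr`` makes
    stimuli linearly separable.  With ``emit_timeseries`` a synthetic
    percent-signal-change time series (boxcar over the response window on a
    baseline of 100) is emitted per run so the amplitude-extraction path can
    be validated against the direct path.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out analyses")
    F = np.asarray(layer_features, dtype=float)
    n_stim = F.shape[0]
    rng = np.random.default_rng(seed)
    readout = rng.normal(size=(F.shape[1], n_voxels)) / np.sqrt(F.shape[1])
    signal = F @ readout
    # responses are deviations from each voxel's baseline: center per voxel,
    # then scale to unit SD overall (also keeps the percent-signal-change
    # baseline of the emitted time series free of stimulus-mean leakage)
    signal = signal - signal.mean(axis=0)
    sd = signal.std()
    if sd > 0:
        signal = signal / sd
    conditions = np.asarray(conditions) if conditions is not None else np.array(["clean"] * n_stim)
    categories = np.asarray(categories) if categories is not None else np.arange(n_stim)

    responses, run_l, stim_l, cond_l, cat_l = [], [], [], [], []
    timeseries = [] if emit_timeseries else None
    for run in range(n_runs):
        order = rng.permutation(n_stim)
        amps = snr * signal + rng.normal(size=(n_stim, n_voxels))
        responses.append(amps[order])
        run_l.append(np.full(n_stim, run))
        stim_l.append(order)
        cond_l.append(conditions[order])
        cat_l.append(categories[order])
        if emit_timeseries:
            trial_len = 5                      # 4 s stimulus + 6 s rest at TR 2 s
            T = n_stim * trial_len + 6
            base = 100.0
            series = np.full((T, n_voxels), base)
            series += rng.normal(0.0, 0.05, size=series.shape)
            onsets = []
            for t_i, s in enumerate(order):
                t0 = t_i * trial_len
                # amplitude expressed in percent signal change over TRs 3-5
                series[t0 + 2 : t0 + 5] += base * amps[s] / 100.0
                onsets.append((t0, int(s), str(conditions[s]), int(categories[s])))
            timeseries.append({"series": series, "onsets": onsets})
    data = neural.ResponseAmplitudeSet(
        responses=np.concatenate(responses),
        run=np.concatenate(run_l),
        stimulus=np.concatenate(stim_l),
        condition=np.concatenate(cond_l),
        category=np.concatenate(cat_l),
    )
    data = neural.normalize_by_run(data)
    return VoxelPatternSet(
        data=data, ground_truth_layer=ground_truth_layer, snr=snr, seed=seed,
        timeseries=timeseries,
    )
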