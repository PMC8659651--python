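"""Psychometric function fitting and threshold statistics.

Accuracy (or pattern-correlation) as a function of SSNR is summarised by a
4-parameter logistic

    f(w) = L + (U - L) / (1 + exp(-k (w - m)))

with lower/upper asymptotes L, U, midpoint m, and slope k.  The SSNR
threshold is the level at which the fitted curve crosses a stated criterion
(50% accuracy for aggregate curves, 90% for per-image model thresholds,
r = 0.5 for layer susceptibility), obtained by analytic inversion.  The
module also provides confusion matrices, split-half reliability of
per-image thresholds, and the Fisher z test for comparing two correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimulus import blend_ssnr, make_gaussian_noise, make_phase_scrambled_noise

__all__ = [
    "PsychometricCurve",
    "LogisticFit",
    "ThresholdEstimate",
    "logistic4",
    "fit_logistic4",
    "threshold_at",
    "per_image_thresholds",
    "confusion_matrix",
    "split_half_reliability",
    "compare_correlations_fisher",
]


@dataclass
class PsychometricCurve:
    """Accuracy (or correlation) per SSNR level."""

    levels: np.ndarray
    values: np.ndarray
    n: np.ndarray | None = None

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if self.n is not None:
            self.n = np.asarray(self.n)


@dataclass
class LogisticFit:
    lower: float
    upper: float
    midpoint: float
    slope: float
    residual: float
    converged: bool


@dataclass
class ThresholdEstimate:
    threshold: float
    criterion: float
    valid: bool


def logistic4(w, lower, upper, midpoint, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (np.asarray(w, dtype=float) - midpoint)))


def fit_logistic4(
    curve: PsychometricCurve,
    guess_rate: float | None = None,
    n_restarts: int = 5,
    restart_seed: int = 0,
) -> LogisticFit:
    """Least-squares 4PL fit with multi-start initialization.

    The lower asymptote is bounded to [0, guess_rate + 0.2] when a guess
    rate (1/K) is supplied -- the guessing floor of a K-alternative task --
    and to [0, 1] otherwise.  A curve with no variation yields
    ``converged=False`` rather than an exception.
    """
    w, y = curve.levels, curve.values
    if len(w) < 4:
        raise ValueError("need at least 4 distinct levels for a 4-parameter fit")
    if np.ptp(y) < 1e-12:
        return LogisticFit(float(y[0]), float(y[0]), np.nan, np.nan, 0.0, converged=False)

    l_hi = min(1.0, guess_rate + 0.2) if guess_rate is not None else 1.0
    lo = np.array([0.0, 0.0, -0.5, 1e-3])
    hi = np.array([l_hi, 1.0, 1.5, 500.0])

    def resid(p):
        return logistic4(w, *p) - y

    rng = np.random.default_rng(restart_seed)
    # midpoint guess: level closest to the half-way accuracy
    half = (y.min() + y.max()) / 2.0
    m0 = w[np.argmin(np.abs(y - half))]
    starts = [np.array([max(y.min(), 0.0), min(y.max(), 1.0), m0, 15.0])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(0, l_hi),
                    rng.uniform(0.5, 1.0),
                    rng.uniform(0.0, 1.0),
                    10 ** rng.uniform(0.5, 2.3),
                ]
            )
        )
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.inf, converged=False)
    L, U, m, k = best.x
    return LogisticFit(float(L), float(U), float(m), float(k), float(np.sqrt(2 * best.cost)), converged=bool(best.success))


def threshold_at(fit: LogisticFit, criterion: float) -> ThresholdEstimate:
    """Analytic inversion of the fitted logistic at ``criterion``.

    Invalid when the criterion lies outside the open asymptote interval
    (L, U) -- e.g. a model that never reaches 90% accuracy even at SSNR 1 --
    or when the crossing falls outside the [0, 1] SSNR range.
    """
    if not fit.converged or not (fit.lower < criterion < fit.upper):
        return ThresholdEstimate(np.nan, criterion, valid=False)
    t = fit.midpoint - np.log((fit.upper - fit.lower) / (criterion - fit.lower) - 1.0) / fit.slope
    valid = bool(0.0 <= t <= 1.0)
    return ThresholdEstimate(float(t) if valid else np.nan, criterion, valid=valid)


def _noise_field(noise_type, shape, seed, spectrum=None):
    if noise_type == "gaussian":
        return make_gaussian_noise(shape[0], shape[1], seed)
    if noise_type == "phase":
        if spectrum is None:
            raise ValueError("phase-scrambled noise requires an amplitude spectrum")
        return make_phase_scrambled_noise(spectrum, seed)
    raise ValueError(f"unknown noise type {noise_type!r}")


def noise_bias_category(model, n_noise: int = 50, seed: int = 0, noise_type: str = "gaussian", spectrum=None):
    """The model's modal response to pure-noise (SSNR 0) images."""
    resp = []
    for i in range(n_noise):
        field = np.clip(_noise_field(noise_type, (model.canvas, model.canvas), (seed, 7, i), spectrum), 0, 255)
        resp.append(int(model.predict(field[None])[0]))
    return int(np.bincount(resp, minlength=model.n_classes).argmax())


def per_image_thresholds(
    model,
    images,
    labels,
    levels,
    n_noise: int = 50,
    criterion: float = 0.9,
    seed: int = 0,
    noise_type: str = "gaussian",
    spectrum=None,
) -> pd.DataFrame:
    """Per-image SSNR thresholds of a model, with the two exclusion rules.

    Each image is shown with ``n_noise`` freshly generated noise fields at
    every level; the per-image accuracy curve is fitted and inverted at
    ``criterion``.  Images are excluded when (a) the model's modal response
    to pure noise equals the image's category ("bias") or (b) the criterion
    is unreachable ("unreachable"), mirroring the exclusions applied before
    correlating model and human thresholds.
    """
    levels = np.asarray(list(levels), dtype=float)
    images = np.asarray(images)
    labels = np.asarray(labels)
    bias_cat = noise_bias_category(model, n_noise=n_noise, seed=seed, noise_type=noise_type, spectrum=spectrum)
    rows = []
    for i in range(len(images)):
        acc = np.zeros(len(levels))
        for j in range(n_noise):
            noise = _noise_field(noise_type, images[i].shape, (seed, i, j), spectrum)
            stack = np.stack([blend_ssnr(images[i], noise, w) for w in levels])
            acc += model.predict(stack) == labels[i]
        acc /= n_noise
        fit = fit_logistic4(PsychometricCurve(levels, acc), guess_rate=1.0 / model.n_classes)
        est = threshold_at(fit, criterion)
        if labels[i] == bias_cat:
            excluded, reason = True, "bias"
        elif not est.valid:
            excluded, reason = True, "unreachable"
        else:
            excluded, reason = False, ""
        rows.append(
            {
                "image_id": i, "label": int(labels[i]),
                "threshold": est.threshold, "valid": est.valid,
                "excluded": excluded, "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def confusion_matrix(trials: pd.DataFrame, K: int) -> np.ndarray:
    """Row-stochastic K x K confusion matrix (rows true, columns response).

    Rows with no trials are returned as NaN (flagged rather than raising).
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    if "true_label" not in trials:
        raise ValueError("trial table must carry a 'true_label' column")
    M = np.zeros((K, K))
    np.add.at(M, (trials["true_label"].to_numpy().astype(int), trials["response"].to_numpy().astype(int)), 1.0)
    rowsum = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = M / rowsum
    out[rowsum[:, 0] == 0, :] = np.nan
    return out


def split_half_reliability(
    per_observer_thresholds: np.ndarray, n_splits: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Split-half reliability of per-image thresholds across observers.

    Observers are randomly split into two halves ``n_splits`` times; each
    half's per-image mean threshold (NaN-aware: correct trials only enter
    the table upstream) is correlated between halves.  Returns the mean and
    SD of the split correlations.
    """
    T = np.asarray(per_observer_thresholds, dtype=float)
    n_obs = T.shape[0]
    if n_obs < 2:
        raise ValueError("need at least 2 observers")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_splits)
    half = n_obs // 2
    for s in range(n_splits):
        perm = rng.permutation(n_obs)
        a = np.nanmean(T[perm[:half]], axis=0)
        b = np.nanmean(T[perm[half:]], axis=0)
        ok = np.isfinite(a) & np.isfinite(b)
        rs[s] = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(rs.mean()), float(rs.std())


def compare_correlations_fisher(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided z test for the difference between independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
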