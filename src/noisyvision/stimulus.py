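"""SSNR-controlled noise stimuli.

Object images are degraded by blending them with a noise field under the
signal-to-signal-plus-noise ratio (SSNR) rule

    T = w * S + (1 - w) * N,        0 <= w <= 1,

where ``S`` is the source image, ``N`` a noise image, and ``w`` the SSNR
level (0 = pure noise, 1 = pure signal; unlike conventional SNR, SSNR is
bounded).  Two noise families are provided:

* pixelated Gaussian noise -- every pixel drawn i.i.d. from a Gaussian
  centred at 127.5 whose SD is 255/6, so the 0-255 intensity range spans
  +/- 3 standard deviations ("white" noise);
* Fourier phase-scrambled noise -- noise sharing a target amplitude
  spectrum (typically the mean spectrum of the image set, close to 1/f)
  with phases randomised under Hermitian symmetry, giving spatially
  correlated, cloud-like structure.

Noise fields are generated *unclipped*; clipping into [0, 255] happens once,
after blending.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

GAUSSIAN_NOISE_MEAN = 127.5
GAUSSIAN_NOISE_SD = 255.0 / 6.0

__all__ = [
    "GAUSSIAN_NOISE_MEAN",
    "GAUSSIAN_NOISE_SD",
    "make_gaussian_noise",
    "mean_amplitude_spectrum",
    "make_phase_scrambled_noise",
    "blend_ssnr",
    "ssnr_series",
    "load_png",
    "save_png",
]


def _as_image(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def make_gaussian_noise(height: int, width: int, seed: int) -> np.ndarray:
    """Pixelated Gaussian noise field, mean 127.5 and SD 255/6, unclipped.

    The field is intentionally left unclipped; intensities are clipped into
    [0, 255] only after SSNR blending (see :func:`blend_ssnr`).
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(GAUSSIAN_NOISE_MEAN, GAUSSIAN_NOISE_SD, size=(height, width))


def mean_amplitude_spectrum(images) -> np.ndarray:
    """Element-wise mean of the 2-D Fourier magnitude over a set of images."""
    images = [_as_image(im) for im in images]
    if not images:
        raise ValueError("need at least one image")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("all images must share the same dimensions")
    acc = np.zeros(shape, dtype=float)
    for im in images:
        acc += np.abs(np.fft.fft2(im))
    return acc / len(images)


def make_phase_scrambled_noise(spectrum: np.ndarray, seed: int) -> np.ndarray:
    """Noise field with the supplied amplitude spectrum and random phases.

    Random phases are drawn with Hermitian (conjugate) symmetry so the
    inverse transform is real: we take the Fourier phases of a real white
    noise field, which are uniform on (-pi, pi] with the required symmetry
    (Nyquist bins real-valued automatically).  The DC phase is fixed at 0.
    The real part of the inverse transform is shifted to mean 127.5; no
    variance rescaling is applied, so the off-DC amplitude spectrum of the
    output matches the input exactly.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 2:
        raise ValueError("spectrum must be 2-D")
    if not np.all(np.isfinite(spectrum)) or np.any(spectrum < 0):
        raise ValueError("spectrum must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    carrier = np.fft.fft2(rng.standard_normal(spectrum.shape))
    mag = np.abs(carrier)
    phase = np.where(mag > 0, carrier / np.where(mag > 0, mag, 1.0), 1.0)
    field = spectrum * phase
    field[0, 0] = spectrum[0, 0]  # DC phase fixed at 0
    out = np.fft.ifft2(field)
    out = np.real(out)
    return out + (GAUSSIAN_NOISE_MEAN - out.mean())


def blend_ssnr(signal, noise, w: float, clip: bool = True) -> np.ndarray:
    """Blend signal and noise at SSNR level ``w``: ``clip(w*S + (1-w)*N)``.

    ``clip=False`` skips the final clipping into [0, 255]; useful for
    analyses that rely on the exact linear-blend statistics.
    """
    s = _as_image(signal)
    n = _as_image(noise)
    if s.shape != n.shape:
        raise ValueError(f"dimension mismatch: {s.shape} vs {n.shape}")
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"SSNR level must lie in [0, 1], got {w}")
    t = w * s + (1.0 - w) * n
    if clip:
        t = np.clip(t, 0.0, 255.0)
    return t


def ssnr_series(signal, noise, levels, clip: bool = True) -> list[np.ndarray]:
    """Blend ``signal`` with one *fixed* noise field at each SSNR level.

    Mirrors the ascending-SSNR trial design in which a single noise image is
    generated and the target gradually increases in SSNR.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    return [blend_ssnr(signal, noise, w, clip=clip) for w in levels]


def load_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float image in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def save_png(path, image) -> None:
    """Write a float image, clipped into [0, 255], as 8-bit grayscale PNG."""
    a = np.clip(_as_image(image), 0, 255).round().astype(np.uint8)
    Image.fromarray(a, mode="L").save(path)
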