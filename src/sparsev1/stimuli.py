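"""Stimulus generation and the retina/LGN front-end.

Natural-image statistics are emulated by Gaussian random fields with an
approximately 1/f^2 spatial power spectrum (the dominant second-order statistic
of natural scenes, and the statistic the center-surround whitening filter is
matched to).  Images are filtered with a divisively normalized
difference-of-Gaussians, normalized to unit standard deviation, cut into
patches, and converted to ON/OFF LGN Poisson rates by rectification:

    on  = min(cr * max(v, 0),  rate_cap)
    off = min(cr * max(-v, 0), rate_cap)

so at every pixel at most one of the two channels is active.  Gaussian white
noise stimuli for spike-triggered averaging go through the same filter but are
scaled by 2*cr and are not variance-normalized per stimulus (a flat noise field
must map to zero drive, not to an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "LgnConfig", "StimulusBatch", "SpikeRaster",
    "generate_synthetic_images", "dog_filter", "normalize_filtered",
    "sample_patches", "encode_on_off", "poisson_spikes", "white_noise_batch",
]

#: Gaussian kernels are truncated at 4 standard deviations (the scipy sampled
#: Gaussian, renormalized to unit sum); truncation error is below 1e-4.
GAUSS_TRUNCATE = 4.0


@dataclass
class LgnConfig:
    """Retina/LGN front-end parameters (center-surround filter + rectification)."""

    sigma_c: float = 1.0
    sigma_s: float = 1.5
    sigma_d: float = 1.5
    cr: float = 70.0
    rate_cap: float = 100.0
    patch_size: int = 16
    mean_target_rate: float = 20.0  # diagnostic only

    def __post_init__(self):
        if not (self.sigma_c < self.sigma_s):
            raise ConfigurationError("sigma_c must be < sigma_s")
        if self.cr <= 0 or self.rate_cap <= 0:
            raise ConfigurationError("cr and rate_cap must be > 0")
        if self.patch_size < 2:
            raise ConfigurationError("patch_size must be >= 2")

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "LgnConfig":
        return cls(cfg.sigma_c, cfg.sigma_s, cfg.sigma_d, cfg.cr,
                   cfg.rate_cap, cfg.patch_size, cfg.mean_target_rate)


@dataclass
class StimulusBatch:
    """Filtered image patches together with their ON/OFF LGN rate vectors.

    ``patches`` has shape (n, p, p); ``on_rates`` / ``off_rates`` have shape
    (n, p*p) in Hz.  ``noise`` optionally carries the raw white-noise fields
    that generated the patches (needed for spike-triggered averaging).
    """

    patches: np.ndarray
    on_rates: np.ndarray | None = None
    off_rates: np.ndarray | None = None
    noise: np.ndarray | None = None

    def __len__(self):
        return self.patches.shape[0]

    @property
    def rates(self) -> np.ndarray:
        """Concatenated [ON, OFF] rate matrix, shape (n, 2*p*p)."""
        return np.concatenate([self.on_rates, self.off_rates], axis=1)


@dataclass
class SpikeRaster:
    """Discrete-time spike events: parallel arrays of neuron index and time."""

    neuron_index: np.ndarray  # uint32
    time_ms: np.ndarray       # float64, multiples of dt
    duration_ms: float
    n_neurons: int

    def __post_init__(self):
        self.neuron_index = np.asarray(self.neuron_index, dtype=np.uint32)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)

    def counts(self) -> np.ndarray:
        return np.bincount(self.neuron_index, minlength=self.n_neurons)

    def __len__(self):
        return self.neuron_index.size


def generate_synthetic_images(n_images: int, size: int, seed: int,
                              patch_size: int = 16) -> np.ndarray:
    """Grayscale images in [0, 1] with an approximately 1/f^2 power spectrum.

    Spectral synthesis: white Gaussian Fourier coefficients are shaped by a
    1/f amplitude envelope (zero DC) and inverse-transformed; each image is
    then min-max rescaled to [0, 1].  This reproduces the second-order
    statistic of natural scenes the whitening front-end is designed for; it is
    a synthetic stand-in, not a claim of equivalence to photographic data.
    """
    if n_images < 1:
        raise ConfigurationError("n_images must be >= 1")
    if size < patch_size:
        raise ConfigurationError(
            f"image size {size} is smaller than patch_size {patch_size}")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(size)
    f = np.hypot(fx[:, None], fx[None, :])
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = 1.0 / f[nonzero]
    images = np.empty((n_images, size, size))
    for k in range(n_images):
        coeff = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
        img = np.fft.ifft2(amp * coeff).real
        lo, hi = img.min(), img.max()
        if hi - lo < 1e-12:  # pathologically flat draw; keep mid-gray
            images[k] = 0.5
        else:
            images[k] = (img - lo) / (hi - lo)
    return images


def _gauss(image: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(image, sigma, mode="reflect",
                                   truncate=GAUSS_TRUNCATE)


def dog_filter(image: np.ndarray, config: LgnConfig) -> np.ndarray:
    """Divisively normalized difference-of-Gaussians center-surround filter.

    Returns (G_c * I - G_s * I) / (G_d * I) elementwise, with reflect-padded,
    unit-sum, isotropic Gaussian kernels.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise DegenerateInputError("image contains non-finite values")
    center = _gauss(image, config.sigma_c)
    surround = _gauss(image, config.sigma_s)
    divisive = _gauss(image, config.sigma_d)
    if np.any(divisive <= 0):
        raise DegenerateInputError(
            "divisive normalization field is non-positive (all-dark region?)")
    return (center - surround) / divisive


def normalize_filtered(filtered: np.ndarray) -> np.ndarray:
    """Scale a filtered image to unit standard deviation (mean untouched)."""
    filtered = np.asarray(filtered, dtype=float)
    sd = filtered.std()
    if sd < 1e-12:
        raise DegenerateInputError("cannot normalize a zero-variance image")
    return filtered / sd


def sample_patches(images: np.ndarray, n_patches: int, patch_size: int,
                   seed: int, return_corners: bool = False):
    """Sample patches uniformly over images and valid top-left corners."""
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    n_img, h, w = images.shape
    if h < patch_size or w < patch_size:
        raise ConfigurationError(
            f"images of shape {(h, w)} are smaller than patch_size {patch_size}")
    rng = np.random.default_rng(seed)
    img_idx = rng.integers(0, n_img, size=n_patches)
    rows = rng.integers(0, h - patch_size + 1, size=n_patches)
    cols = rng.integers(0, w - patch_size + 1, size=n_patches)
    patches = np.empty((n_patches, patch_size, patch_size))
    for k in range(n_patches):
        r, c = rows[k], cols[k]
        patches[k] = images[img_idx[k], r:r + patch_size, c:c + patch_size]
    if return_corners:
        return patches, np.stack([img_idx, rows, cols], axis=1)
    return patches


def encode_on_off(patches: np.ndarray, config: LgnConfig,
                  rate_scale: float | None = None) -> StimulusBatch:
    """Rectify filtered patches into capped ON/OFF Poisson rates (Hz).

    ``rate_scale`` overrides the scaling constant (white-noise stimuli use
    2*cr); by default ``config.cr`` is used.
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    scale = config.cr if rate_scale is None else rate_scale
    flat = patches.reshape(patches.shape[0], -1)
    on = np.minimum(scale * np.maximum(flat, 0.0), config.rate_cap)
    off = np.minimum(scale * np.maximum(-flat, 0.0), config.rate_cap)
    return StimulusBatch(patches=patches, on_rates=on, off_rates=off)


def poisson_spikes(rates: np.ndarray, duration_ms: float, dt: float,
                   seed: int) -> SpikeRaster:
    """Bernoulli-per-step Poisson spike generation.

    Each neuron spikes independently per step with probability rate*dt; valid
    because rate*dt <= 0.1 under the 100 Hz cap and 1 ms step.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ConfigurationError("rates must be non-negative")
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    p = rates * dt / 1000.0
    if np.any(p > 1):
        raise ConfigurationError("rate * dt exceeds one spike per step")
    n_steps = int(round(duration_ms / dt))
    rng = np.random.default_rng(seed)
    hits = rng.random((n_steps, rates.size)) < p
    step_idx, neuron_idx = np.nonzero(hits)
    return SpikeRaster(neuron_index=neuron_idx, time_ms=step_idx * dt,
                       duration_ms=duration_ms, n_neurons=rates.size)


def white_noise_batch(n_stimuli: int, config: LgnConfig, seed: int) -> StimulusBatch:
    """Gaussian white-noise stimuli for spike-triggered averaging.

    Unit-variance spatial noise ``n`` is mapped to pixel values via
    50*n + 100 clipped to [0, 255], rescaled to the [0, 1] luminance
    convention, pushed through the same center-surround filtering and
    unit-SD normalization as natural images, and rectified into ON/OFF rates
    scaled by 2*cr.  A flat noise field (zero filter output) yields zero
    rates rather than a degenerate-input error.  The raw noise fields are
    kept on the returned batch for reverse correlation.
    """
    if n_stimuli < 1:
        raise ConfigurationError("n_stimuli must be >= 1")
    rng = np.random.default_rng(seed)
    p = config.patch_size
    noise = rng.standard_normal((n_stimuli, p, p))
    pixels = np.clip(50.0 * noise + 100.0, 0.0, 255.0)
    lum = pixels / 255.0
    filtered = np.empty_like(lum)
    for k in range(n_stimuli):
        f = dog_filter(lum[k], config)
        sd = f.std()
        if sd > 1e-12:  # flat fields stay zero instead of erroring
            f = f / sd
        filtered[k] = f
    batch = encode_on_off(filtered, config, rate_scale=2.0 * config.cr)
    batch.noise = noise
    return batch
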