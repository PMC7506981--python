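"""Signal-level augmentations: Gaussian noise, magnitude warping, wavelet
detail scaling.

All three transforms are label-preserving deformations of an RMS-envelope
sEMG record: they change amplitude texture, not gesture identity, and they
preserve the ``(n_samples, n_channels)`` shape exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from . import wavelets
from .errors import ParameterError
from .signal_model import MultichannelSignal

__all__ = [
    "GNParams",
    "MWParams",
    "WDParams",
    "gaussian_noise",
    "magnitude_warp",
    "wavelet_perturb",
]


@dataclass(frozen=True)
class GNParams:
    """Additive Gaussian noise at a target signal-to-noise ratio.

    ``snr`` is a *linear* power ratio: the noise variance on each channel
    is ``mean(x_c^2) / snr``.  Set ``snr_is_db=True`` to pass the ratio in
    decibels instead.  ``pool_channels=True`` uses one pooled signal power
    for all channels; the default keeps per-channel noise floors, because
    channel activations in a gesture differ by an order of magnitude and a
    pooled floor would drown quiet channels.

    The grid-search winner for Ninapro-DB1-style envelopes is ``snr=30``
    (35 for the noisier putEMG-style data).
    """

    snr: float = 30.0
    rng_seed: int = 0
    snr_is_db: bool = False
    pool_channels: bool = False

    def __post_init__(self):
        if not self.snr > 0:
            raise ParameterError(f"snr must be positive, got {self.snr}")

    @property
    def snr_linear(self) -> float:
        return 10.0 ** (self.snr / 10.0) if self.snr_is_db else self.snr


@dataclass(frozen=True)
class MWParams:
    """Magnitude warping: multiply by a random smooth curve around 1.

    ``knot_count`` equidistant knots spanning the record get values drawn
    from N(1, sigma^2); a natural cubic spline through them is evaluated
    at every sample and multiplies the signal.  ``sigma=0.1`` is the
    selected deformation strength; larger values risk warping one gesture
    into another.  One shared curve is applied to all channels so the
    inter-channel amplitude ratios — the gesture's spatial signature —
    are preserved; ``per_channel=True`` draws an independent curve per
    channel instead.
    """

    knot_count: int = 4
    sigma: float = 0.1
    rng_seed: int = 0
    per_channel: bool = False

    def __post_init__(self):
        if self.knot_count < 2:
            raise ParameterError("cubic-spline warp needs at least 2 knots")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")


@dataclass(frozen=True)
class WDParams:
    """Wavelet-decomposition perturbation.

    An ``level``-deep DWT splits each channel into one approximation band
    and ``level`` detail bands; every detail coefficient at every level is
    multiplied by ``detail_factor`` (b) and the signal is re-synthesized.
    ``b=1`` is the identity, ``b=0`` keeps only the smooth approximation,
    ``b>1`` exaggerates fine texture.  Selected configurations:
    ``sym4, level=5, b=3`` (Ninapro-DB1) and ``db7, level=5, b=0``
    (putEMG).
    """

    wavelet: str = "sym4"
    level: int = 5
    detail_factor: float = 3.0
    mode: str = "symmetric"

    def __post_init__(self):
        if self.level < 1:
            raise ParameterError("decomposition level must be >= 1")
        if self.detail_factor < 0:
            raise ParameterError("detail_factor must be >= 0")
        wavelets.Wavelet(self.wavelet)  # validate the name eagerly


def gaussian_noise(x: MultichannelSignal, p: GNParams) -> MultichannelSignal:
    """Add zero-mean Gaussian noise with variance ``signal_power / snr``."""
    rng = np.random.default_rng(p.rng_seed)
    power = np.mean(x.samples**2, axis=0)  # per channel
    if p.pool_channels:
        power = np.full_like(power, power.mean())
    sigma = np.sqrt(power / p.snr_linear)
    noise = rng.standard_normal(x.samples.shape) * sigma
    return x.with_samples(x.samples + noise)


def magnitude_warp(x: MultichannelSignal, p: MWParams) -> MultichannelSignal:
    """Multiply the record by a cubic-spline curve through Gaussian knots."""
    n = x.n_samples
    if p.knot_count > n:
        raise ParameterError(
            f"knot_count {p.knot_count} exceeds signal length {n}"
        )
    rng = np.random.default_rng(p.rng_seed)
    knots_t = np.linspace(0.0, n - 1.0, p.knot_count)
    t = np.arange(n)
    if p.per_channel:
        curves = np.empty((n, x.channel_count))
        for c in range(x.channel_count):
            r = 1.0 + p.sigma * rng.standard_normal(p.knot_count)
            curves[:, c] = CubicSpline(knots_t, r, bc_type="natural")(t)
        return x.with_samples(x.samples * curves)
    r = 1.0 + p.sigma * rng.standard_normal(p.knot_count)
    curve = CubicSpline(knots_t, r, bc_type="natural")(t)
    return x.with_samples(x.samples * curve[:, None])


def warp_curve(n: int, p: MWParams) -> np.ndarray:
    """The spline curve magnitude_warp would apply (shared-curve mode).

    Exposed for auditing: the curve interpolates its drawn knot values
    exactly, so ``warp_curve(n, p)[knot] == r(knot)``.
    """
    if p.knot_count > n:
        raise ParameterError(f"knot_count {p.knot_count} exceeds signal length {n}")
    rng = np.random.default_rng(p.rng_seed)
    knots_t = np.linspace(0.0, n - 1.0, p.knot_count)
    r = 1.0 + p.sigma * rng.standard_normal(p.knot_count)
    return CubicSpline(knots_t, r, bc_type="natural")(np.arange(n))


def wavelet_perturb(x: MultichannelSignal, p: WDParams) -> MultichannelSignal:
    """Scale all DWT detail bands by ``detail_factor`` and re-synthesize.

    Raises :class:`ParameterError` when ``level`` exceeds the maximum
    decomposition depth for the record length (no silent level reduction).
    """
    n = x.n_samples
    out = np.empty_like(x.samples)
    for c in range(x.channel_count):
        coeffs = wavelets.wavedec(x.samples[:, c], p.wavelet, p.level, mode=p.mode)
        scaled = [coeffs[0]] + [p.detail_factor * d for d in coeffs[1:]]
        rec = wavelets.waverec(scaled, p.wavelet, n, mode=p.mode)
        if len(rec) < n:  # pad defensively; trimming is handled by waverec
            rec = np.pad(rec, (0, n - len(rec)), mode="edge")
        out[:, c] = rec[:n]
    return x.with_samples(out)
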