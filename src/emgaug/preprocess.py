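"""Signal conditioning: RMS envelope, Butterworth filtering, subsampling.

The conditioning chain mirrors standard sEMG gesture-recognition practice.
Ninapro-DB1-style recordings arrive as RMS envelopes and only need a 1st
order 1 Hz Butterworth low-pass; putEMG-style raw sEMG first gets a 50 Hz
notch and a 5th order 20-700 Hz band-pass, then a 100 ms RMS, the same
low-pass, and subsampling to the common 100 Hz rate.

All filters are applied forward-backward (zero phase): augmentation cares
about envelope shape, not causal latency, and zero-phase filtering keeps
the envelope aligned with the gesture it encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .signal_model import MultichannelSignal

__all__ = [
    "PreprocessConfig",
    "ninapro_config",
    "putemg_config",
    "rms_envelope",
    "envelope_ma",
    "butterworth_filter",
    "resample_to",
    "preprocess_signal",
]

NOTCH_Q = 30.0  # quality factor of the second-order IIR power-line notch


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning chain.

    ``notch_hz`` / ``bandpass`` are ``None`` for envelope-style inputs
    that skip the raw-signal stages.
    """

    rms_window_ms: float = 100.0
    lowpass_order: int = 1
    lowpass_fc_hz: float = 1.0
    notch_hz: float | None = None
    bandpass: tuple[float, float, int] | None = None
    target_fs_hz: float = 100.0

    def __post_init__(self):
        if self.lowpass_order < 1:
            raise ParameterError("lowpass_order must be >= 1")
        if self.bandpass is not None and self.bandpass[2] < 1:
            raise ParameterError("bandpass order must be >= 1")


def ninapro_config() -> PreprocessConfig:
    """Chain for RMS-envelope inputs (Ninapro-DB1 style)."""
    return PreprocessConfig()


def putemg_config() -> PreprocessConfig:
    """Chain for raw high-rate sEMG (putEMG style)."""
    return PreprocessConfig(notch_hz=50.0, bandpass=(20.0, 700.0, 5))


def _window_samples(window_ms: float, fs: float, n: int) -> int:
    w = int(round(window_ms * fs / 1000.0))
    if w < 1:
        raise ParameterError(
            f"window of {window_ms} ms is shorter than one sample at {fs} Hz"
        )
    if w > n:
        raise ParameterError(f"window of {w} samples exceeds signal length {n}")
    return w


def _sliding_mean(arr: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average over axis 0 with truncated edge windows."""
    n = arr.shape[0]
    half_lo = (w - 1) // 2
    half_hi = w // 2
    cum = np.zeros((n + 1,) + arr.shape[1:])
    np.cumsum(arr, axis=0, out=cum[1:])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    counts = (hi - lo).reshape((-1,) + (1,) * (arr.ndim - 1))
    return (cum[hi] - cum[lo]) / counts


def rms_envelope(x: MultichannelSignal, window_ms: float = 100.0) -> MultichannelSignal:
    """Per-channel sliding root-mean-square with a centered window.

    Edge windows are truncated (divide by the actual sample count) so the
    output keeps the input length, which keeps all downstream windowing
    arithmetic stable.
    """
    w = _window_samples(window_ms, x.fs, x.n_samples)
    return x.with_samples(np.sqrt(_sliding_mean(x.samples**2, w)))


def envelope_ma(x: MultichannelSignal, window_ms: float = 15.0) -> MultichannelSignal:
    """Centered moving-average amplitude envelope (same-length output)."""
    w = _window_samples(window_ms, x.fs, x.n_samples)
    return x.with_samples(_sliding_mean(x.samples, w))


def butterworth_filter(x: MultichannelSignal, kind: str, **params) -> MultichannelSignal:
    """Zero-phase Butterworth (or IIR-notch) filtering per channel.

    ``kind`` is one of ``'lowpass'`` (params ``fc_hz``, ``order``),
    ``'bandpass'`` (``low_hz``, ``high_hz``, ``order``) or ``'notch'``
    (``freq_hz``, optional ``q``).
    """
    nyq = x.fs / 2.0
    if kind == "lowpass":
        fc = params["fc_hz"]
        order = int(params.get("order", 1))
        if not 0 < fc < nyq:
            raise ParameterError(f"cutoff {fc} Hz must lie in (0, {nyq}) Hz")
        sos = sps.butter(order, fc, btype="low", fs=x.fs, output="sos")
        filtered = sps.sosfiltfilt(sos, x.samples, axis=0)
    elif kind == "bandpass":
        lo, hi = params["low_hz"], params["high_hz"]
        order = int(params.get("order", 5))
        if not 0 < lo < hi < nyq:
            raise ParameterError(
                f"band edges ({lo}, {hi}) Hz must satisfy 0 < low < high < {nyq}"
            )
        sos = sps.butter(order, (lo, hi), btype="band", fs=x.fs, output="sos")
        filtered = sps.sosfiltfilt(sos, x.samples, axis=0)
    elif kind == "notch":
        f0 = params["freq_hz"]
        q = float(params.get("q", NOTCH_Q))
        if not 0 < f0 < nyq:
            raise ParameterError(f"notch frequency {f0} Hz must lie in (0, {nyq}) Hz")
        b, a = sps.iirnotch(f0, q, fs=x.fs)
        filtered = sps.filtfilt(b, a, x.samples, axis=0)
    else:
        raise ParameterError(f"unknown filter kind {kind!r}")
    return x.with_samples(filtered)


def resample_to(x: MultichannelSignal, target_fs_hz: float) -> MultichannelSignal:
    """Anti-aliased subsampling to ``target_fs_hz`` (upsampling is refused).

    Integer decimation factors and rational ones both go through a
    polyphase FIR resampler; the output has ``floor(n * target / fs)``
    samples.
    """
    if target_fs_hz > x.fs:
        raise ParameterError(
            f"target rate {target_fs_hz} Hz exceeds signal rate {x.fs} Hz; "
            "upsampling is out of scope"
        )
    if target_fs_hz == x.fs:
        return x.with_samples(x.samples.copy())
    frac = Fraction(target_fs_hz / x.fs).limit_denominator(10_000)
    out = sps.resample_poly(x.samples, frac.numerator, frac.denominator, axis=0)
    n_out = int(np.floor(x.n_samples * target_fs_hz / x.fs))
    return MultichannelSignal(out[:n_out], target_fs_hz)


def preprocess_signal(x: MultichannelSignal, cfg: PreprocessConfig) -> MultichannelSignal:
    """Run the full conditioning chain described by ``cfg``.

    Order: notch -> band-pass (raw-signal stages, when configured) ->
    RMS envelope -> low-pass -> subsample to the target rate.
    """
    y = x
    if cfg.notch_hz is not None:
        y = butterworth_filter(y, "notch", freq_hz=cfg.notch_hz)
    if cfg.bandpass is not None:
        lo, hi, order = cfg.bandpass
        y = butterworth_filter(y, "bandpass", low_hz=lo, high_hz=hi, order=order)
    y = rms_envelope(y, cfg.rms_window_ms)
    y = butterworth_filter(y, "lowpass", fc_hz=cfg.lowpass_fc_hz, order=cfg.lowpass_order)
    if cfg.target_fs_hz < y.fs:
        y = resample_to(y, cfg.target_fs_hz)
    return y
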