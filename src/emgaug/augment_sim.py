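"""Generative sEMG simulation augmentations (SS1, SS2).

Both methods synthesize a new record from a stochastic model fitted to a
real one.  A band-shaped Gaussian carrier is produced by convolving white
noise with a *shaping filter* g whose power spectral density is

    PSD_g(f) = fh^2 f^2 / ((f^2 + fl^2) (f^2 + fh^2)^2),

the classical two-corner sEMG spectrum model (zero at DC, peak between
``fl`` and ``fh``).  SS1 modulates the carrier with the real record's
moving-average amplitude envelope and matches the inter-electrode
covariance of the real channels.  SS2 instead models the sEMG variance as
inverse-gamma distributed, fits IG(alpha, beta) to each real channel by
expectation-maximization, and modulates a unit-variance carrier with a
random variance envelope drawn from the fitted distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps
from scipy.special import digamma, gammaln
from scipy.stats import invgamma

from .errors import ParameterError
from .preprocess import _sliding_mean, envelope_ma
from .signal_model import MultichannelSignal

__all__ = [
    "ShapingFilter",
    "SS1Params",
    "SS2Params",
    "IGFit",
    "IDENTITY_FILTER",
    "shaping_psd",
    "shaping_filter_response",
    "default_shaping_filter",
    "envelope_ma",
    "ss1_carrier",
    "simulate_ss1",
    "fit_inverse_gamma_em",
    "simulate_ss2",
]

#: Sentinel: skip the shaping filter entirely (g = delta impulse).
IDENTITY_FILTER = "identity"


def shaping_psd(f, fl: float, fh: float):
    """Analytic (unnormalized) shaping-filter power spectral density."""
    f = np.asarray(f, dtype=float)
    f2 = f**2
    return fh**2 * f2 / ((f2 + fl**2) * (f2 + fh**2) ** 2)


@dataclass(frozen=True)
class ShapingFilter:
    """Linear-phase FIR realization of the shaping filter g.

    The corner frequencies are not dictated by the PSD formula itself;
    the defaults ``fl=2, fh=20`` Hz suit 100 Hz RMS-envelope inputs
    (the band is scaled into the Nyquist interval), while raw 2 kHz sEMG
    would use the literature preset ``fl=60, fh=120``.
    """

    fl: float = 2.0
    fh: float = 20.0
    fs: float = 100.0
    n_taps: int = 129

    def __post_init__(self):
        if not 0 < self.fl < self.fh < self.fs / 2:
            raise ParameterError(
                f"corner frequencies must satisfy 0 < fl < fh < fs/2, got "
                f"fl={self.fl}, fh={self.fh}, fs={self.fs}"
            )
        if self.n_taps < 9 or self.n_taps % 2 == 0:
            raise ParameterError("n_taps must be an odd integer >= 9")


def shaping_filter_response(filt: ShapingFilter) -> np.ndarray:
    """Impulse response of g: a linear-phase FIR sampled from sqrt(PSD_g).

    Designed by frequency sampling on a dense grid with the target
    amplitude peak-normalized.  A mild Kaiser taper (beta = 1) keeps the
    squared magnitude within a few percent of the analytic PSD over the
    passband at the default 129 taps; heavier windows over-smooth the
    steep low-frequency edge.  Very low corners relative to the rate
    (fl < fs/100) need more taps.
    """
    nyq = filt.fs / 2.0
    freqs = np.linspace(0.0, nyq, 4097)
    amp = np.sqrt(shaping_psd(freqs, filt.fl, filt.fh))
    amp /= amp.max()
    amp[-1] = 0.0  # force zero gain at Nyquist for an even-symmetric design
    return sps.firwin2(filt.n_taps, freqs, amp, fs=filt.fs, window=("kaiser", 1.0))


def default_shaping_filter(fs: float) -> ShapingFilter:
    """Default corners scaled to the sampling rate: fl = fs/50, fh = fs/5.

    At the 100 Hz envelope rate this is the shipped fl=2 Hz, fh=20 Hz
    preset; the ratios keep the spectral peak inside the Nyquist band for
    any rate.
    """
    return ShapingFilter(fl=0.02 * fs, fh=0.2 * fs, fs=fs)


@dataclass(frozen=True)
class SS1Params:
    """Covariance-matched simulation parameters.

    ``noise_sigma`` is the std of the additive sensor-noise term (the
    model states sigma = 0.1); the amplitude envelope is a 15 ms moving
    average of the real record.  ``filter=None`` selects
    :func:`default_shaping_filter` for the record's rate;
    ``filter=IDENTITY_FILTER`` bypasses g (auditing only).
    """

    filter: "ShapingFilter | str | None" = None
    noise_sigma: float = 0.1
    envelope_window_ms: float = 15.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class SS2Params:
    """Inverse-gamma-variance simulation parameters.

    The variance envelope drawn from the fitted IG(alpha, beta) is
    smoothed with the same 15 ms moving average SS1 uses for its
    amplitude envelope (the model states no temporal structure for the
    variance sequence).  ``variance_consistent=True`` (default)
    multiplies the unit-variance carrier by sqrt(variance) so the
    instantaneous output variance equals the drawn value; ``False``
    multiplies by the variance itself (the literal reading).
    """

    filter: "ShapingFilter | str | None" = None
    noise_sigma: float = 0.1
    envelope_window_ms: float = 15.0
    variance_consistent: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


COV_REG_EPS = 1e-8  # diagonal loading: eps * trace/C tolerates rank deficiency


def _channel_covariance(samples: np.ndarray) -> np.ndarray:
    c = samples.shape[1]
    cov = np.cov(samples, rowvar=False, bias=True).reshape(c, c)
    if not np.all(np.isfinite(cov)):
        raise ParameterError("non-finite channel covariance")
    tr = np.trace(cov)
    if tr > 0:
        cov = cov + COV_REG_EPS * (tr / c) * np.eye(c)
    return cov


def _resolve_filter(filt, fs: float):
    if filt is None:
        return default_shaping_filter(fs)
    if isinstance(filt, str):
        if filt == IDENTITY_FILTER:
            return None
        raise ParameterError(f"unknown filter spec {filt!r}")
    return filt


def _convolve_same(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    # centered "same" that keeps len(x) even when the filter is longer
    full = np.convolve(x, g, mode="full")
    off = (len(g) - 1) // 2
    return full[off : off + len(x)]


def _apply_filter(carrier: np.ndarray, filt: ShapingFilter | None) -> np.ndarray:
    if filt is None:  # identity filter (g = delta), used mainly for auditing
        return carrier
    g = shaping_filter_response(filt)
    if carrier.ndim == 1:
        return _convolve_same(carrier, g)
    out = np.empty_like(carrier)
    for c in range(carrier.shape[1]):
        out[:, c] = _convolve_same(carrier[:, c], g)
    return out


def _carrier_ss1(x: MultichannelSignal, p: SS1Params, rng) -> np.ndarray:
    filt = _resolve_filter(p.filter, x.fs)
    cov = _channel_covariance(x.samples)
    if np.trace(cov) == 0.0:
        chol = np.zeros_like(cov)
    else:
        chol = np.linalg.cholesky(cov)
    w = rng.standard_normal(x.samples.shape) @ chol.T
    return _apply_filter(w, filt)


def ss1_carrier(x: MultichannelSignal, p: SS1Params) -> np.ndarray:
    """The covariance-matched, shaping-filtered carrier (w * g) of SS1.

    Exposed for auditing: before envelope modulation the carrier's
    inter-channel correlation matches the real record's, because each
    time step is a Cholesky transform of white noise and all channels
    share the same filter g.
    """
    return _carrier_ss1(x, p, np.random.default_rng(p.rng_seed))


def simulate_ss1(x: MultichannelSignal, p: SS1Params) -> MultichannelSignal:
    """Simulate a record: (correlated noise * g) x envelope + sensor noise.

    The white carrier is drawn per time step from a multivariate Gaussian
    whose covariance matches the real record's channel covariance
    (Cholesky of the diagonally-loaded matrix), so the synthetic channels
    keep the real inter-electrode correlation structure.
    """
    rng = np.random.default_rng(p.rng_seed)
    carrier = _carrier_ss1(x, p, rng)
    env = envelope_ma(x, p.envelope_window_ms).samples
    out = carrier * env
    if p.noise_sigma > 0:
        out = out + p.noise_sigma * rng.standard_normal(out.shape)
    return x.with_samples(out)


@dataclass
class IGFit:
    """Result of the inverse-gamma variance fit.

    ``loglik_trace`` is the marginal log-likelihood after each EM
    iteration; EM theory guarantees it is non-decreasing (up to 1e-8
    numerical slack per step).
    """

    alpha: float
    beta: float
    loglik_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _ig_marginal_loglik(x2_half: np.ndarray, alpha: float, beta: float) -> float:
    # x ~ N(0, s2), s2 ~ IG(alpha, beta)  =>  marginal is a scaled Student-t:
    # log p(x) = lgamma(a+1/2) - lgamma(a) + a log b - (a+1/2) log(b + x^2/2)
    #            - log(2 pi)/2
    n = x2_half.size
    return float(
        n * (gammaln(alpha + 0.5) - gammaln(alpha) + alpha * np.log(beta))
        - (alpha + 0.5) * np.sum(np.log(beta + x2_half))
        - 0.5 * n * np.log(2.0 * np.pi)
    )


def fit_inverse_gamma_em(
    samples, max_iter: int = 200, tol: float = 1e-8
) -> IGFit:
    """Fit ``sample_t ~ N(0, s2_t), s2_t ~ IG(alpha, beta)`` by EM.

    E-step: the conjugate posterior ``s2_t | sample_t ~ IG(alpha + 1/2,
    beta + sample_t^2 / 2)`` gives ``E[1/s2_t]`` and ``E[log s2_t]`` in
    closed form.  M-step: ``beta = alpha / mean(E[1/s2])`` and alpha
    solves ``log(alpha) - digamma(alpha) = mean(E[log s2]) + log
    mean(E[1/s2])`` (1-D root-find; the left side is strictly decreasing
    and the right side is non-negative by Jensen, so a root exists).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 10:
        raise ParameterError("need at least 10 samples to fit the variance model")
    if np.var(x) == 0.0:
        raise ParameterError("degenerate input: zero variance")
    x2_half = 0.5 * x**2

    alpha = 2.5
    beta = max((alpha - 1.0) * np.var(x), np.finfo(float).tiny)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        post_a = alpha + 0.5
        post_b = beta + x2_half
        e_inv = post_a / post_b
        e_log = np.log(post_b) - digamma(post_a)
        B = float(np.mean(e_inv))
        A = float(np.mean(e_log))
        # M-step
        rhs = A + np.log(B)
        if rhs <= 0:
            rhs = np.finfo(float).tiny

        def f(a):
            return np.log(a) - digamma(a) - rhs

        try:
            alpha = optimize.brentq(f, 1e-8, 1e8, xtol=1e-12, rtol=1e-12)
        except ValueError as exc:
            err = RuntimeError(
                f"alpha root-find failed at iteration {it} (rhs={rhs:.3e})"
            )
            err.loglik_trace = trace  # attach partial trace for diagnosis
            raise err from exc
        beta = alpha / B
        trace.append(_ig_marginal_loglik(x2_half, alpha, beta))
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    return IGFit(
        alpha=float(alpha),
        beta=float(beta),
        loglik_trace=trace,
        iterations=it,
        converged=converged,
    )


def simulate_ss2(
    x: MultichannelSignal, p: SS2Params, return_details: bool = False
):
    """Simulate a record from the fitted inverse-gamma variance model.

    Per channel: fit IG(alpha, beta) to the real samples, draw an i.i.d.
    variance sequence from the fit, smooth it with the moving average,
    modulate a standard-normal carrier convolved with g, add sensor
    noise.  Fit errors (e.g. a constant channel) propagate.

    With ``return_details=True`` also returns a dict holding the
    per-channel ``fits`` and smoothed ``variance_envelopes`` (columns),
    so the modulation can be audited.
    """
    rng = np.random.default_rng(p.rng_seed)
    filt = _resolve_filter(p.filter, x.fs)
    n, n_ch = x.samples.shape
    w = int(round(p.envelope_window_ms * x.fs / 1000.0))
    w = max(w, 1)
    out = np.empty_like(x.samples)
    fits = []
    var_envs = np.empty_like(x.samples)
    for c in range(n_ch):
        fit = fit_inverse_gamma_em(x.samples[:, c])
        fits.append(fit)
        var_seq = invgamma.rvs(
            fit.alpha, scale=fit.beta, size=n, random_state=rng
        )
        var_seq = _sliding_mean(var_seq, min(w, n))
        var_envs[:, c] = var_seq
        carrier = _apply_filter(rng.standard_normal(n), filt)
        mult = np.sqrt(var_seq) if p.variance_consistent else var_seq
        out[:, c] = carrier * mult
    if p.noise_sigma > 0:
        out = out + p.noise_sigma * rng.standard_normal(out.shape)
    result = x.with_samples(out)
    if return_details:
        return result, {"fits": fits, "variance_envelopes": var_envs}
    return result
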