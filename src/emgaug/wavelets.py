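"""Orthogonal discrete wavelet transform with Daubechies and Symlet filters.

Filter banks are constructed numerically rather than read from tables:
Daubechies scaling filters come from spectral factorization of the binomial
half-band polynomial (all factor-polynomial roots taken inside the unit
circle, i.e. minimum phase), and Symlets from the same factorization with
the inside/outside choice per conjugate root group that makes the phase
closest to linear — the standard "least-asymmetric" selection.  Both
families are orthonormal to machine precision, so multi-level analysis /
synthesis is a perfect-reconstruction pair.

Two boundary policies are supported:

``symmetric``
    Half-point symmetric extension with redundant boundary coefficients
    (coefficient length ``(n + filter_len - 1) // 2`` per band).  Perfect
    reconstruction, but the transform is over-complete at the boundaries,
    so coefficient energy slightly exceeds signal energy.
``periodization``
    Circular (periodized) transform, ``ceil(n / 2)`` coefficients per
    band.  This is an orthogonal matrix: signal energy equals total
    coefficient energy exactly (Parseval), which is what energy-accounting
    checks should use.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb, floor, log2

import numpy as np

from .errors import ParameterError

__all__ = [
    "Wavelet",
    "wavelist",
    "dwt",
    "idwt",
    "wavedec",
    "waverec",
    "dwt_max_level",
]

_MAX_DB = 20
_MAX_SYM = 10


def wavelist() -> list[str]:
    """Names of the supported wavelets (``db1``..``db20``, ``sym2``..``sym10``)."""
    return [f"db{n}" for n in range(1, _MAX_DB + 1)] + [
        f"sym{n}" for n in range(2, _MAX_SYM + 1)
    ]


def _binomial_roots(order: int) -> np.ndarray:
    """Roots of P(y) = sum_k C(order-1+k, k) y^k, the Daubechies polynomial."""
    p = [comb(order - 1 + k, k) for k in range(order)]
    return np.roots(p[::-1]) if order > 1 else np.array([])


def _z_pair(y: complex) -> np.ndarray:
    # y = (2 - z - 1/z) / 4  <=>  z^2 + (4y - 2) z + 1 = 0; roots come in
    # reciprocal pairs, sorted by modulus (inside first).
    zr = np.roots([1.0, 4.0 * y - 2.0, 1.0])
    return zr[np.argsort(np.abs(zr))]


def _normalize(h: np.ndarray) -> np.ndarray:
    h = np.real(h)
    return h * (np.sqrt(2.0) / h.sum())


def _db_scaling_filter(order: int) -> np.ndarray:
    zin = [_z_pair(y)[0] for y in _binomial_roots(order)]
    return _normalize(np.poly([-1.0] * order + zin))


def _phase_nonlinearity(h: np.ndarray) -> float:
    H = np.fft.rfft(h, 1024)
    mag = np.abs(H)
    sel = mag > 1e-3 * mag.max()
    w = np.linspace(0.0, np.pi, len(H))[sel]
    ph = np.unwrap(np.angle(H[sel]))
    A = np.column_stack([w, np.ones_like(w)])
    resid = ph - A @ np.linalg.lstsq(A, ph, rcond=None)[0]
    return float(np.max(np.abs(resid)))


def _sym_scaling_filter(order: int) -> np.ndarray:
    yroots = _binomial_roots(order)
    used = np.zeros(len(yroots), bool)
    groups: list[tuple[complex, ...]] = []
    for i, y in enumerate(yroots):
        if used[i]:
            continue
        used[i] = True
        if abs(y.imag) > 1e-12:
            j = int(np.argmin(np.abs(yroots - np.conj(y)) + used * 1e9))
            used[j] = True
            groups.append((y, yroots[j]))
        else:
            groups.append((y,))
    best_h, best_obj = None, np.inf
    for mask in range(1 << len(groups)):
        zsel = []
        for g, grp in enumerate(groups):
            pick = (mask >> g) & 1
            zsel.extend(_z_pair(y)[pick] for y in grp)
        h = _normalize(np.poly([-1.0] * order + zsel))
        obj = _phase_nonlinearity(h)
        if obj < best_obj:
            best_h, best_obj = h, obj
    return best_h


class Wavelet:
    """An orthonormal wavelet identified by name, e.g. ``'db7'`` or ``'sym4'``.

    Exposes the four-filter bank in the usual analysis/synthesis layout:
    ``dec_lo``/``dec_hi`` are the (time-reversed) analysis filters,
    ``rec_lo``/``rec_hi`` the synthesis ones.
    """

    def __init__(self, name: str):
        h = _scaling_filter(name)
        self.name = name
        self.rec_lo = h
        self.dec_lo = h[::-1].copy()
        L = len(h)
        n = np.arange(L)
        self.rec_hi = (-1.0) ** n * h[::-1]
        self.dec_hi = self.rec_hi[::-1].copy()

    @property
    def filter_len(self) -> int:
        return len(self.rec_lo)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Wavelet({self.name!r}, filter_len={self.filter_len})"


@lru_cache(maxsize=None)
def _scaling_filter(name: str) -> np.ndarray:
    if name.startswith("db"):
        order = _parse_order(name, 2, 1, _MAX_DB)
        h = _db_scaling_filter(order)
    elif name.startswith("sym"):
        order = _parse_order(name, 3, 2, _MAX_SYM)
        h = _sym_scaling_filter(order)
    elif name.startswith("coif"):
        raise ParameterError(
            "coiflets are not supported by this build; "
            f"choose one of {wavelist()!r}"
        )
    else:
        raise ParameterError(f"unknown wavelet {name!r}; supported: {wavelist()!r}")
    h.setflags(write=False)
    return h


def _parse_order(name: str, prefix_len: int, lo: int, hi: int) -> int:
    try:
        order = int(name[prefix_len:])
    except ValueError:
        raise ParameterError(f"unknown wavelet {name!r}") from None
    if not lo <= order <= hi:
        raise ParameterError(
            f"wavelet {name!r} outside supported order range [{lo}, {hi}]"
        )
    return order


def _as_wavelet(wavelet: "str | Wavelet") -> Wavelet:
    return wavelet if isinstance(wavelet, Wavelet) else Wavelet(wavelet)


def dwt_max_level(n: int, wavelet: "str | Wavelet") -> int:
    """Deepest level whose filters still fit the (sub-sampled) signal."""
    w = _as_wavelet(wavelet)
    if w.filter_len <= 2:
        return max(0, floor(log2(n))) if n >= 1 else 0
    if n < w.filter_len - 1:
        return 0
    return floor(log2(n / (w.filter_len - 1)))


def dwt(x, wavelet, mode: str = "symmetric"):
    """One analysis step: return ``(cA, cD)`` for a 1-D signal."""
    w = _as_wavelet(wavelet)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("dwt expects a 1-D signal")
    if mode == "symmetric":
        L = w.filter_len
        ext = np.pad(x, (L - 1, L - 1), mode="symmetric")
        cA = np.convolve(ext, w.dec_lo, "valid")[1::2]
        cD = np.convolve(ext, w.dec_hi, "valid")[1::2]
        return cA, cD
    if mode == "periodization":
        return _dwt_per(x, w)
    raise ParameterError(f"unknown extension mode {mode!r}")


def _dwt_per(x: np.ndarray, w: Wavelet):
    n = len(x)
    if n % 2:
        x = np.concatenate([x, x[-1:]])
        n += 1
    k2 = 2 * np.arange(n // 2)
    cA = np.zeros(n // 2)
    cD = np.zeros(n // 2)
    # Analysis row k is the circular shift-by-2k of the synthesis filters,
    # which makes the transform matrix exactly orthogonal for even n.
    for m in range(w.filter_len):
        xm = x[(k2 + m) % n]
        cA += w.rec_lo[m] * xm
        cD += w.rec_hi[m] * xm
    return cA, cD


def idwt(cA, cD, wavelet, n_out: int, mode: str = "symmetric"):
    """One synthesis step, trimmed to ``n_out`` samples."""
    w = _as_wavelet(wavelet)
    cA = np.asarray(cA, dtype=float)
    cD = np.asarray(cD, dtype=float)
    if len(cA) != len(cD):
        raise ParameterError("cA and cD must have equal length")
    if mode == "symmetric":
        up_a = np.zeros(2 * len(cA))
        up_a[::2] = cA
        up_d = np.zeros(2 * len(cD))
        up_d[::2] = cD
        rec = np.convolve(up_a, w.rec_lo) + np.convolve(up_d, w.rec_hi)
        L = w.filter_len
        if L > 2:
            rec = rec[L - 2 : len(rec) - (L - 2)]
        return rec[:n_out]
    if mode == "periodization":
        n = 2 * len(cA)
        out = np.zeros(n)
        k2 = 2 * np.arange(len(cA))
        for m in range(w.filter_len):
            np.add.at(out, (k2 + m) % n, w.rec_lo[m] * cA + w.rec_hi[m] * cD)
        return out[:n_out]
    raise ParameterError(f"unknown extension mode {mode!r}")


def wavedec(x, wavelet, level: int, mode: str = "symmetric"):
    """Multi-level analysis: ``[cA_l, cD_l, cD_{l-1}, ..., cD_1]``."""
    w = _as_wavelet(wavelet)
    x = np.asarray(x, dtype=float)
    if level < 1:
        raise ParameterError("decomposition level must be >= 1")
    max_level = dwt_max_level(len(x), w)
    if level > max_level:
        raise ParameterError(
            f"level {level} exceeds max level {max_level} for length {len(x)} "
            f"and wavelet {w.name!r}"
        )
    coeffs = []
    approx = x
    for _ in range(level):
        approx, detail = dwt(approx, w, mode=mode)
        coeffs.append(detail)
    coeffs.append(approx)
    return coeffs[::-1]


def waverec(coeffs, wavelet, n_out: int, mode: str = "symmetric"):
    """Inverse of :func:`wavedec`; output trimmed to ``n_out`` samples."""
    w = _as_wavelet(wavelet)
    # Replay the forward length bookkeeping so each synthesis step trims to
    # the length the matching analysis step actually consumed.
    lengths = [n_out]
    for _ in range(len(coeffs) - 1):
        n = lengths[-1]
        if mode == "symmetric":
            lengths.append((n + w.filter_len - 1) // 2)
        else:
            lengths.append((n + 1) // 2)
    approx = np.asarray(coeffs[0], dtype=float)
    for i, detail in enumerate(coeffs[1:]):
        target = lengths[len(coeffs) - 2 - i]
        approx = idwt(approx, np.asarray(detail, float), w, target, mode=mode)
    return approx
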