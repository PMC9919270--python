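"""Spectral preprocessing: edge trimming, smoothing, fractional derivatives.

The fractional-order derivative (FOD) generalises the familiar first and
second backward differences of a spectrum to non-integer orders v via the
Grünwald–Letnikov expansion.  On a unit wavelength grid the order-v
derivative at band x is

    d^v f(x) ≈ Σ_k  w_k · f(x − k),   w_0 = 1,  w_k = w_{k−1} · (k−1−v) / k,

i.e. the weights are the alternating generalised binomial coefficients
(−1)^k · C(v, k).  v = 0 is the identity, v = 1 the backward first
difference, v = 2 the backward second difference; intermediate orders trade
off the baseline-removal of differencing against its noise amplification.
The weights are computed by the multiplicative recursion (numerically stable
for any m); the Γ-function closed form is equivalent.

Bands near the start of the spectrum have too little left-history for the
sum and are flagged invalid in the result mask instead of being zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, savgol_filter

from .containers import SpectraSet

__all__ = [
    "FODConfig",
    "FODResult",
    "trim_edges",
    "savgol_smooth",
    "gl_coefficients",
    "fod_transform",
    "fod_sweep",
    "DEFAULT_ORDERS",
]

#: the standard order sweep: 0, 0.2, …, 2.0 (11 orders)
DEFAULT_ORDERS = tuple(np.round(np.arange(0.0, 2.01, 0.2), 10))


@dataclass(frozen=True)
class FODConfig:
    """Fractional-derivative settings.

    ``memory`` is the number of history terms in the Grünwald–Letnikov sum
    (``None`` = all bands to the left of the evaluation point); bands with
    fewer than ``min_history`` available points are masked invalid.
    """

    order: float = 0.0
    memory: int | None = None
    min_history: int = 2

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be nonnegative")
        if self.memory is not None and self.memory < 1:
            raise ValueError("memory must be at least 1")


@dataclass
class FODResult:
    """A derivative spectrum tagged with its order and validity mask."""

    spectra: SpectraSet
    order: float
    valid_mask: np.ndarray  # bool per band; False where history was truncated

    def valid_spectra(self) -> SpectraSet:
        """The derivative restricted to bands with full-enough history."""
        return self.spectra.select_bands(self.valid_mask)


def trim_edges(s: SpectraSet, low: int = 400, high: int = 2400) -> SpectraSet:
    """Drop noisy edge bands, keeping the closed interval [low, high] nm."""
    keep = (s.wavelengths >= low) & (s.wavelengths <= high)
    if not keep.any():
        raise ValueError(f"trim window [{low}, {high}] does not intersect the grid")
    return s.select_bands(keep)


def savgol_smooth(s: SpectraSet, window: int = 9, polyorder: int = 2) -> SpectraSet:
    """Per-sample Savitzky–Golay smoothing along the wavelength axis.

    Edge bands are handled by one-sided polynomial fits (``mode='interp'``).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > s.n_bands:
        raise ValueError("window exceeds band count")
    smoothed = savgol_filter(s.reflectance, window, polyorder, axis=1, mode="interp")
    return SpectraSet(list(s.sample_ids), s.wavelengths.copy(), smoothed)


def gl_coefficients(v: float, m: int) -> np.ndarray:
    """Grünwald–Letnikov weights w_0 … w_m for order ``v``.

    w_0 = 1 and w_k = w_{k−1}·(k−1−v)/k, equal to (−1)^k·C(v, k).  At
    integer v the sequence terminates in the familiar difference stencils
    ([1, −1, 0, …] and [1, −2, 1, 0, …]).
    """
    if v < 0:
        raise ValueError("order must be nonnegative")
    if m < 0:
        raise ValueError("m must be nonnegative")
    w = np.empty(m + 1)
    w[0] = 1.0
    if m > 0:
        k = np.arange(1, m + 1, dtype=float)
        w[1:] = np.cumprod((k - 1.0 - v) / k)
    return w


def _unit_step(s: SpectraSet) -> None:
    if s.n_bands > 1 and np.any(np.diff(s.wavelengths) != 1):
        raise ValueError(
            "fractional derivative requires a unit (1 nm) wavelength step; "
            "resample the spectra first"
        )


def fod_transform(
    s: SpectraSet, order: float, cfg: FODConfig | None = None
) -> FODResult:
    """Grünwald–Letnikov derivative of every spectrum at a single order.

    For each band x the output is Σ_k w_k·f(x−k) over the available history
    (up to ``cfg.memory`` terms).  Order 0 returns the input unchanged with a
    fully valid mask; for positive orders the leading bands with fewer than
    ``cfg.min_history`` points are masked invalid.
    """
    cfg = cfg or FODConfig()
    if order < 0:
        raise ValueError("order must be nonnegative")
    _unit_step(s)
    p = s.n_bands
    if order == 0:
        out = s.reflectance.copy()
        mask = np.ones(p, dtype=bool)
    else:
        m = p - 1 if cfg.memory is None else min(cfg.memory, p - 1)
        w = gl_coefficients(order, m)
        if p * (m + 1) <= 1_000_000:
            # exact direct summation for small problems
            out = np.empty_like(s.reflectance)
            R = s.reflectance
            for j in range(p):
                kmax = min(j, m)
                out[:, j] = R[:, j - kmax : j + 1] @ w[: kmax + 1][::-1]
        else:
            out = fftconvolve(s.reflectance, w[None, :], axes=1)[:, :p]
        mask = np.arange(p) + 1 >= cfg.min_history
    derived = SpectraSet(list(s.sample_ids), s.wavelengths.copy(), out)
    return FODResult(spectra=derived, order=float(order), valid_mask=mask)


def fod_sweep(
    s: SpectraSet,
    orders=DEFAULT_ORDERS,
    cfg: FODConfig | None = None,
) -> list[FODResult]:
    """Derivatives at every order of the sweep (default 0…2 by 0.2, 11 results)."""
    return [fod_transform(s, v, cfg) for v in orders]
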