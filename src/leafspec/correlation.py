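"""Band-wise Pearson screening of derivative spectra against chlorophyll.

For each band, the product-moment correlation r between reflectance (or its
fractional derivative) and leaf chlorophyll content is computed, and
significance at level α is judged against the two-sided critical value from
the t-distribution with n−2 degrees of freedom,

    r_crit = t_{1−α/2, n−2} / sqrt(n − 2 + t²).

The per-order summary counts the total (Tb), positively (Pb) and negatively
(Nb) correlated significant bands and records the maximum |r| with its
wavelength — the screening table that motivates restricting wavelength
selection to the visible/near-infrared region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpectraSet, TraitVector
from .preprocess import FODResult

__all__ = ["CorrelationProfile", "pearson_profile", "critical_r", "summarize_profile"]


@dataclass
class CorrelationProfile:
    """Per-band correlation against the trait at one derivative order."""

    order: float
    wavelengths: np.ndarray
    r: np.ndarray  # NaN on masked/constant bands
    r_crit: float
    tb: int  # significant bands
    pb: int  # of which positive
    nb: int  # of which negative
    r_max: float  # max |r|
    r_max_wavelength: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "r": self.r,
                "significant": np.abs(self.r) > self.r_crit,
            }
        )

    def summary_dict(self) -> dict:
        return {
            "order": self.order,
            "r_crit": self.r_crit,
            "Tb": self.tb,
            "Pb": self.pb,
            "Nb": self.nb,
            "r_max": self.r_max,
            "r_max_wavelength_nm": int(self.r_max_wavelength),
        }


def pearson_profile(X: FODResult | SpectraSet, y: TraitVector | np.ndarray) -> np.ndarray:
    """Product-moment r of every band against the trait.

    Masked bands (truncated derivative history) and constant bands yield NaN.
    Requires at least 3 samples.
    """
    if isinstance(X, FODResult):
        mask = X.valid_mask
        M = X.spectra.reflectance
    else:
        mask = np.ones(X.n_bands, dtype=bool)
        M = X.reflectance
    yv = y.lcc if isinstance(y, TraitVector) else np.asarray(y, dtype=float)
    n = M.shape[0]
    if yv.size != n:
        raise ValueError("trait length does not match sample count")
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation profile")
    Xc = M - M.mean(axis=0)
    yc = yv - yv.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~mask] = np.nan
    r[sx == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Two-sided significance threshold on r for a sample of size ``n``."""
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t * t))


def summarize_profile(
    r: np.ndarray,
    r_crit: float,
    wavelengths: np.ndarray,
    order: float = 0.0,
) -> CorrelationProfile:
    """Fill the Tb/Pb/Nb counts and the (|r|max, wavelength) record.

    NaN bands are never counted; ties on |r| resolve to the lowest wavelength.
    """
    r = np.asarray(r, dtype=float)
    wavelengths = np.asarray(wavelengths)
    if r.shape != wavelengths.shape:
        raise ValueError("r and wavelengths must align")
    finite = np.isfinite(r)
    pb = int(np.sum(finite & (r > r_crit)))
    nb = int(np.sum(finite & (r < -r_crit)))
    if finite.any():
        absr = np.where(finite, np.abs(r), -np.inf)
        imax = int(np.argmax(absr))  # first occurrence = lowest wavelength
        r_max = float(absr[imax])
        wl_max = int(wavelengths[imax])
    else:
        r_max, wl_max = float("nan"), -1
    return CorrelationProfile(
        order=order,
        wavelengths=wavelengths,
        r=r,
        r_crit=float(r_crit),
        tb=pb + nb,
        pb=pb,
        nb=nb,
        r_max=r_max,
        r_max_wavelength=wl_max,
    )
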