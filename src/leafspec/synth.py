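"""Synthetic leaf reflectance and chlorophyll generator.

Field spectra of healthy broadleaf canopies share a stereotyped shape: a green
reflection peak near 550 nm, chlorophyll absorption valleys near 450 nm
(blue) and 670 nm (red), a steep red-edge rise between ~670 and 750 nm whose
inflection moves to longer wavelengths as pigment content increases, a broad
near-infrared plateau, and two water absorption valleys at 1450 and 1950 nm
that do not depend on pigment content.  The generator reproduces exactly this
qualitative structure on the standard 350–2500 nm, 1-nm field-spectrometer
grid, so that every downstream stage (derivatives, band screening, wavelength
selection, regression) can be exercised and validated against known ground
truth.

The construction is deliberately phenomenological rather than a
radiative-transfer model: a near-infrared plateau, Gaussian absorption
valleys (chlorophyll valleys with LCC-proportional depth, water valleys with
fixed depth), a Gaussian green-peak modulation that shrinks as LCC rises, and
a logistic red edge whose centre shifts linearly with LCC.  Each monotone
dependence on LCC is therefore analytic and testable.

SPAD meter readings are related to absolute chlorophyll content
(Cab, μg·cm⁻²) by the exponential calibration

    Cab = 6.34299 · exp(0.04379 · SPAD) − 6.10629

and simulated SPAD values are obtained by inverting this exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import SpectraSet, TraitVector

__all__ = [
    "ConversionParams",
    "SpectrumModelParams",
    "spad_to_cab",
    "cab_to_spad",
    "generate_trait_vector",
    "generate_spectrum",
    "generate_dataset",
    "make_planted_bands",
    "WAVELENGTH_GRID",
    "LCC_MIN",
    "LCC_MAX",
]

#: full field-spectrometer grid, 350…2500 nm at 1 nm
WAVELENGTH_GRID = np.arange(350, 2501, dtype=np.int64)

#: default chlorophyll range of the emulated field campaign, μg·cm⁻²
LCC_MIN = 12.44
LCC_MAX = 73.95


@dataclass(frozen=True)
class ConversionParams:
    """Constants of the exponential SPAD → Cab calibration."""

    scale: float = 6.34299  # μg·cm⁻²
    rate: float = 0.04379  # per SPAD unit
    offset: float = -6.10629  # μg·cm⁻²

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.rate > 0):
            raise ValueError("scale and rate must be positive")


DEFAULT_CONVERSION = ConversionParams()


def spad_to_cab(spad, params: ConversionParams = DEFAULT_CONVERSION):
    """Convert SPAD meter readings to chlorophyll content (μg·cm⁻²).

    Strictly increasing in SPAD.  Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(spad, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("spad must be finite")
    out = params.scale * np.exp(arr * params.rate) + params.offset
    return float(out) if np.isscalar(spad) or arr.ndim == 0 else out


def cab_to_spad(lcc, params: ConversionParams = DEFAULT_CONVERSION):
    """Analytic inverse of :func:`spad_to_cab`.

    Defined for ``lcc > offset`` (i.e. lcc + 6.10629 > 0 at the defaults).
    """
    arr = np.asarray(lcc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("lcc must be finite")
    if np.any(arr <= params.offset):
        raise ValueError(
            f"lcc must exceed {params.offset:.5f} μg·cm⁻² for the inverse to exist"
        )
    out = np.log((arr - params.offset) / params.scale) / params.rate
    return float(out) if np.isscalar(lcc) or arr.ndim == 0 else out


@dataclass(frozen=True)
class SpectrumModelParams:
    """Shape parameters of the phenomenological leaf-spectrum model.

    All reflectance quantities are dimensionless in [0, 1]; centres, widths in
    nm; LCC sensitivities are expressed per unit of the normalised chlorophyll
    ``lcc / lcc_scale``.
    """

    # near-infrared plateau and its (weak, positive) LCC dependence
    nir_plateau: float = 0.45
    nir_lcc_gain: float = 0.05
    # visible baseline and green peak (amplitude shrinks with LCC: more
    # chlorophyll -> more green absorption -> lower 550 nm reflectance)
    vis_base: float = 0.12
    green_center: float = 550.0
    green_sigma: float = 40.0
    green_amp: float = 0.28
    green_lcc_loss: float = 0.75
    # chlorophyll absorption valleys, depth grows with LCC
    blue_center: float = 450.0
    blue_sigma: float = 25.0
    blue_depth0: float = 0.04
    blue_depth_lcc: float = 0.05
    red_center: float = 670.0
    red_sigma: float = 30.0
    red_depth0: float = 0.05
    red_depth_lcc: float = 0.05
    # logistic red edge; centre shifts to longer wavelengths with LCC
    red_edge_center0: float = 700.0
    red_edge_shift: float = 15.0
    red_edge_width: float = 8.0
    # water absorption valleys, independent of LCC
    water_centers: tuple[float, float] = (1450.0, 1950.0)
    water_sigmas: tuple[float, float] = (30.0, 45.0)
    water_depths: tuple[float, float] = (0.18, 0.28)
    # i.i.d. additive Gaussian noise per band (reflectance units)
    noise_sd: float = 0.005
    # normalisation constant for LCC sensitivities
    lcc_scale: float = 70.0

    def __post_init__(self) -> None:
        if not 0 <= self.nir_plateau <= 1:
            raise ValueError("nir_plateau must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


DEFAULT_SPECTRUM = SpectrumModelParams()


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def generate_spectrum(
    lcc: float,
    params: SpectrumModelParams = DEFAULT_SPECTRUM,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
) -> np.ndarray:
    """Deterministic leaf spectrum for one LCC value, plus optional noise.

    Returns reflectance in [0, 1] on ``wavelengths`` (default 350…2500 nm).
    Reflectance at 550 nm decreases strictly with ``lcc``; the red-edge
    inflection moves to longer wavelengths; the 1450/1950 nm water valleys are
    LCC-independent.
    """
    if lcc < 0:
        raise ValueError("lcc must be nonnegative")
    wl = np.asarray(wavelengths, dtype=float)
    z = lcc / params.lcc_scale

    vis = (
        params.vis_base
        + (params.green_amp * (1.0 - params.green_lcc_loss * z))
        * _gauss(wl, params.green_center, params.green_sigma)
        - (params.blue_depth0 + params.blue_depth_lcc * z)
        * _gauss(wl, params.blue_center, params.blue_sigma)
        - (params.red_depth0 + params.red_depth_lcc * z)
        * _gauss(wl, params.red_center, params.red_sigma)
    )
    plateau = params.nir_plateau + params.nir_lcc_gain * z
    edge_center = params.red_edge_center0 + params.red_edge_shift * z
    s = 1.0 / (1.0 + np.exp(-(wl - edge_center) / params.red_edge_width))
    refl = vis * (1.0 - s) + plateau * s
    for c, w, d in zip(params.water_centers, params.water_sigmas, params.water_depths):
        refl = refl - d * _gauss(wl, c, w)
    if rng is not None and params.noise_sd > 0:
        refl = refl + rng.normal(0.0, params.noise_sd, size=refl.shape)
    return np.clip(refl, 0.0, 1.0)


def generate_trait_vector(
    n: int,
    lcc_min: float = LCC_MIN,
    lcc_max: float = LCC_MAX,
    seed: int | np.random.Generator | None = 0,
    distribution: str = "uniform",
    mean: float | None = None,
    sd: float | None = None,
    conversion: ConversionParams = DEFAULT_CONVERSION,
    spad_noise_sd: float = 0.0,
) -> TraitVector:
    """Draw ``n`` LCC values within ``[lcc_min, lcc_max]`` and derive SPAD.

    ``distribution`` is ``"uniform"`` (default) or ``"truncnorm"`` (a normal
    with the given ``mean``/``sd``, re-drawn into the bounds).  SPAD readings
    are the exact analytic inverse of the exponential calibration, with
    optional additive meter noise (off by default).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not lcc_min < lcc_max:
        raise ValueError("lcc_min must be below lcc_max")
    if lcc_min < 0:
        raise ValueError("lcc bounds must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distribution == "uniform":
        lcc = rng.uniform(lcc_min, lcc_max, size=n)
    elif distribution == "truncnorm":
        mu = mean if mean is not None else 0.5 * (lcc_min + lcc_max)
        s = sd if sd is not None else (lcc_max - lcc_min) / 4.0
        lcc = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mu, s, size=n - filled)
            keep = draw[(draw >= lcc_min) & (draw <= lcc_max)]
            lcc[filled : filled + keep.size] = keep
            filled += keep.size
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    spad = cab_to_spad(lcc, conversion)
    if spad_noise_sd > 0:
        spad = spad + rng.normal(0.0, spad_noise_sd, size=n)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return TraitVector(sample_ids=ids, lcc=lcc, spad=spad)


def generate_dataset(
    n: int = 293,
    params: SpectrumModelParams = DEFAULT_SPECTRUM,
    seed: int = 0,
    lcc_min: float = LCC_MIN,
    lcc_max: float = LCC_MAX,
    distribution: str = "uniform",
) -> tuple[SpectraSet, TraitVector]:
    """Paired (spectra, traits) emulating a leaf-level field campaign.

    Defaults mirror the emulated campaign: 293 samples, LCC uniform over
    12.44–73.95 μg·cm⁻², 350–2500 nm grid, additive noise sd 0.005.
    """
    if n < 20:
        warnings.warn(
            f"n={n} is small for the downstream calibration/validation splits",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    traits = generate_trait_vector(
        n, lcc_min=lcc_min, lcc_max=lcc_max, seed=rng, distribution=distribution
    )
    refl = np.empty((n, WAVELENGTH_GRID.size))
    for i, lcc in enumerate(traits.lcc):
        refl[i] = generate_spectrum(lcc, params, rng=rng)
    spectra = SpectraSet(
        sample_ids=list(traits.sample_ids),
        wavelengths=WAVELENGTH_GRID.copy(),
        reflectance=refl,
    )
    return spectra, traits


def make_planted_bands(
    n: int = 200,
    p: int = 501,
    n_informative: int = 6,
    noise_sd: float = 0.5,
    seed: int = 0,
    wavelength_start: int = 400,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-signal band matrix for selection benchmarks.

    An i.i.d. standard-normal band matrix ``X`` (n × p) with a response that
    depends on exactly ``n_informative`` randomly placed bands,
    ``y = Σ X[:, planted] + ε`` with ``ε ~ N(0, noise_sd²)``.  Returns
    ``(X, y, planted)`` where ``planted`` is sorted band indices — ground
    truth for recovery tests.  Columns correspond to a nominal wavelength
    grid starting at ``wavelength_start`` (1-nm step).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    planted = np.sort(rng.choice(p, size=n_informative, replace=False))
    y = X[:, planted].sum(axis=1) + rng.normal(0.0, noise_sd, size=n)
    return X, y, planted
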