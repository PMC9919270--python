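"""In-memory carriers for leaf spectra and paired trait values.

A :class:`SpectraSet` is the universal data carrier of the pipeline: a set of
leaf samples measured on a common integer wavelength grid (nanometres), with
one reflectance row per sample.  A :class:`TraitVector` holds the paired leaf
chlorophyll content (LCC, μg·cm⁻²) and optionally the raw SPAD meter reading
for the same samples, in the same order.

Both round-trip losslessly through plain CSV files:

* spectra:  header ``sample_id,350,351,…,2500``, one row per sample;
* traits:   header ``sample_id,lcc_ug_cm2[,spad]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "TraitVector",
    "read_spectra",
    "write_spectra",
    "read_traits",
    "write_traits",
]


class SpectraParseError(ValueError):
    """Raised when a spectra/trait file violates the expected dialect."""


@dataclass
class SpectraSet:
    """Reflectance matrix on a shared wavelength grid.

    Parameters
    ----------
    sample_ids : list of str
        Unique per-sample identifiers, one per matrix row.
    wavelengths : ndarray of int
        Strictly increasing wavelength grid in nm.
    reflectance : ndarray, shape (n_samples, n_bands)
        Reflectance values; must be finite.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.int64)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if len(np.unique(self.wavelengths)) != self.wavelengths.size:
            raise ValueError("duplicate wavelengths in grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} bands"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def band_index(self, nm: int) -> int:
        """Index of the band at wavelength ``nm`` (exact match)."""
        idx = np.searchsorted(self.wavelengths, nm)
        if idx >= self.n_bands or self.wavelengths[idx] != nm:
            raise KeyError(f"wavelength {nm} nm not on grid")
        return int(idx)

    def select_bands(self, index: np.ndarray) -> "SpectraSet":
        """Sub-spectra keeping the bands given by ``index`` (ints or bool mask)."""
        index = np.asarray(index)
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            wavelengths=self.wavelengths[index],
            reflectance=self.reflectance[:, index],
        )

    def select_samples(self, index: np.ndarray) -> "SpectraSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in index],
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[index],
        )

    # -- conversion -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance, columns=self.wavelengths)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraSet":
        if "sample_id" not in df.columns:
            raise SpectraParseError("missing 'sample_id' column")
        wl_cols = [c for c in df.columns if c != "sample_id"]
        try:
            wavelengths = np.array([int(c) for c in wl_cols], dtype=np.int64)
        except (TypeError, ValueError) as exc:
            raise SpectraParseError(f"non-integer wavelength column: {exc}") from exc
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            wavelengths=wavelengths,
            reflectance=df[wl_cols].to_numpy(dtype=float),
        )


@dataclass
class TraitVector:
    """Per-sample leaf chlorophyll content, optionally with SPAD readings."""

    sample_ids: list[str]
    lcc: np.ndarray  # μg·cm⁻²
    spad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.lcc = np.asarray(self.lcc, dtype=float).ravel()
        if self.lcc.size != len(self.sample_ids):
            raise ValueError("lcc length does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.lcc)):
            raise ValueError("lcc contains non-finite values")
        if np.any(self.lcc < 0):
            raise ValueError("lcc must be nonnegative")
        if self.spad is not None:
            self.spad = np.asarray(self.spad, dtype=float).ravel()
            if self.spad.size != self.lcc.size:
                raise ValueError("spad length does not match lcc")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids, "lcc_ug_cm2": self.lcc}
        if self.spad is not None:
            data["spad"] = self.spad
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        # round_trip parsing keeps the read exactly inverse to the %.17g write
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraParseError(f"{path}: malformed CSV ({exc})") from exc


def read_spectra(path) -> SpectraSet:
    """Read a spectra CSV (``sample_id,350,351,…``) into a :class:`SpectraSet`."""
    df = _read_csv(path)
    # pandas mangles duplicate headers into '550.1' etc.; detect and reject
    for col in df.columns:
        if col != "sample_id" and "." in str(col):
            raise SpectraParseError(
                f"{path}: duplicate or non-integer wavelength column {col!r}"
            )
    wl_cols = [c for c in df.columns if c != "sample_id"]
    bad = df[wl_cols].apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise SpectraParseError(
            f"{path}: non-numeric cell at data row {r}, column {wl_cols[c]!r}"
        )
    try:
        return SpectraSet.from_dataframe(df)
    except ValueError as exc:
        raise SpectraParseError(f"{path}: {exc}") from exc


def write_spectra(spectra: SpectraSet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g is the shortest format guaranteed to round-trip float64 exactly
    spectra.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_traits(path) -> TraitVector:
    df = _read_csv(path)
    if "sample_id" not in df.columns or "lcc_ug_cm2" not in df.columns:
        raise SpectraParseError(f"{path}: expected columns sample_id,lcc_ug_cm2[,spad]")
    spad = df["spad"].to_numpy(dtype=float) if "spad" in df.columns else None
    try:
        return TraitVector(
            sample_ids=df["sample_id"].astype(str).tolist(),
            lcc=df["lcc_ug_cm2"].to_numpy(dtype=float),
            spad=spad,
        )
    except ValueError as exc:
        raise SpectraParseError(f"{path}: {exc}") from exc


def write_traits(traits: TraitVector, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    traits.to_dataframe().to_csv(path, index=False, float_format="%.17g")
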