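"""Shared data model for fluorescence titration and lifetime analyses.

All concentrations are stored in molar (M), wavelengths in nm, times in ns,
absorbances dimensionless per the stated path length. Constructors validate
their invariants eagerly: no partially-valid value ever escapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "EmissionSpectrum",
    "AbsorbancePair",
    "CuvetteGeometry",
    "TitrationSeries",
    "DecayHistogram",
    "EllipticityRecord",
]


class ValidationError(ValueError):
    """Raised when a domain type's invariants are violated."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan: intensity vs wavelength at one titration point.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing wavelength grid in nm.
    intensities : array-like
        Non-negative fluorescence intensities (arbitrary units), same length.
    excitation_wavelength : float
        Excitation wavelength in nm.
    temperature : float
        Sample temperature in K.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float
    temperature: float

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        it = _as_float_array(self.intensities, "intensities")
        if wl.size != it.size:
            raise ValidationError("wavelengths and intensities differ in length")
        if wl.size < 1:
            raise ValidationError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if np.any(it < 0):
            raise ValidationError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def intensity_at(self, wavelength: float) -> float:
        """Linearly interpolated intensity at `wavelength` (nm)."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValidationError(
                f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.intensities))


@dataclass(frozen=True)
class AbsorbancePair:
    """Sample absorbance (per 1 cm) at the excitation and emission wavelengths."""

    a_ex: float
    a_em: float

    def __post_init__(self):
        if self.a_ex < 0 or self.a_em < 0:
            raise ValidationError("absorbances must be non-negative")


@dataclass(frozen=True)
class CuvetteGeometry:
    """Optical path lengths (cm) along the excitation and emission directions.

    The default is a 10 x 2 mm microcuvette: 1.0 cm excitation path,
    0.2 cm emission path.
    """

    path_ex: float = 1.0
    path_em: float = 0.2

    def __post_init__(self):
        if self.path_ex <= 0 or self.path_em <= 0:
            raise ValidationError("path lengths must be positive")


@dataclass(frozen=True)
class TitrationSeries:
    """One temperature's ligand-into-protein titration.

    The first titration point must be ligand-free: it defines F0 for every
    ratio-based analysis downstream.
    """

    protein_conc: float
    ligand_concs: np.ndarray
    spectra: tuple
    absorbances: tuple
    temperature: float

    def __post_init__(self):
        lc = _as_float_array(self.ligand_concs, "ligand_concs")
        if self.protein_conc <= 0:
            raise ValidationError("protein_conc must be positive")
        if lc.size == 0:
            raise ValidationError("empty titration")
        if lc[0] != 0.0:
            raise ValidationError("first titration point must be ligand-free")
        if np.any(np.diff(lc) < 0):
            raise ValidationError("ligand_concs must be non-decreasing")
        spectra = tuple(self.spectra)
        absorbances = tuple(self.absorbances)
        if len(spectra) != lc.size or len(absorbances) != lc.size:
            raise ValidationError(
                "ligand_concs, spectra and absorbances must have equal lengths"
            )
        for s in spectra:
            if not isinstance(s, EmissionSpectrum):
                raise ValidationError("spectra must be EmissionSpectrum instances")
        for a in absorbances:
            if not isinstance(a, AbsorbancePair):
                raise ValidationError("absorbances must be AbsorbancePair instances")
        object.__setattr__(self, "ligand_concs", lc)
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "absorbances", absorbances)

    def __len__(self) -> int:
        return self.ligand_concs.size


@dataclass(frozen=True)
class DecayHistogram:
    """TCSPC photon-count decay histogram at one ligand concentration."""

    times: np.ndarray
    counts: np.ndarray
    ligand_conc: float = 0.0

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        c = _as_float_array(self.counts, "counts")
        if t.size != c.size:
            raise ValidationError("times and counts differ in length")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        if self.ligand_conc < 0:
            raise ValidationError("ligand_conc must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class EllipticityRecord:
    """Raw circular-dichroism scan in millidegrees, with the quantities
    needed to convert to mean residue ellipticity."""

    wavelengths: np.ndarray
    theta_mdeg: np.ndarray
    molar_conc: float
    path_cm: float
    n_residues: int

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths, "wavelengths")
        th = _as_float_array(self.theta_mdeg, "theta_mdeg")
        if wl.size != th.size:
            raise ValidationError("wavelengths and theta_mdeg differ in length")
        if self.molar_conc <= 0 or self.path_cm <= 0 or self.n_residues <= 0:
            raise ValidationError("molar_conc, path_cm and n_residues must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "theta_mdeg", th)
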