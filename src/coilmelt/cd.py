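"""Circular-dichroism spectrum metrics for helical and coiled-coil proteins.

Raw far-UV CD signals (ellipticity theta, in millidegrees) are normalized to
mean residue molar ellipticity

    [Theta] = theta / (10 * C * l * N)      [deg cm^2 dmol^-1]

with C the molar concentration (mol/L), l the cuvette path length (cm) and N
the residue count. Two secondary-structure summaries are provided:

* the [Theta]222/[Theta]208 ratio, an empirical index separating isolated
  alpha-helices (~0.83) from two-stranded coiled coils (~1.03);
* the helix fraction, either from the chain-length-corrected limiting
  ellipticity [Theta]222 = -40000*(1 - 4.6/n), or by non-negative
  least-squares deconvolution against reference basis spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CDSpectrum",
    "MRESpectrum",
    "HelixEstimate",
    "CoiledCoilIndex",
    "Classification",
    "to_mre",
    "ratio_222_208",
    "helix_fraction_chain_length",
    "helix_fraction_basis",
    "reference_basis",
    "DEFAULT_ANCHORS",
]

#: (helix_like, coiled_coil_like) literature anchors for [Theta]222/[Theta]208.
DEFAULT_ANCHORS = (0.83, 1.03)
#: Ratios within this distance of an anchor midpoint stay "intermediate".
DEFAULT_DEAD_BAND = (0.88, 0.98)


class Classification(str, Enum):
    helix_like = "helix_like"
    intermediate = "intermediate"
    coiled_coil_like = "coiled_coil_like"


@dataclass(frozen=True)
class CDSpectrum:
    """Raw far-UV CD spectrum with the metadata needed for normalization."""

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    concentration_molar: float
    path_cm: float
    n_residues: int
    temperature_K: float = 278.0

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        el = np.asarray(self.ellipticity_mdeg, dtype=float)
        if wl.ndim != 1 or wl.shape != el.shape or wl.size < 2:
            raise ValueError("wavelength and ellipticity must be equal-length 1-D "
                             "arrays with at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.min() < 185.0 or wl.max() > 300.0:
            raise ValueError("wavelengths must lie within [185, 300] nm")
        if self.concentration_molar <= 0 or self.path_cm <= 0 or self.n_residues <= 0:
            raise ValueError("concentration, path length and residue count must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "ellipticity_mdeg", el)

    @classmethod
    def from_csv(cls, path, concentration_molar, path_cm, n_residues,
                 temperature_K=278.0) -> "CDSpectrum":
        df = pd.read_csv(path, sep=None, engine="python")
        df.columns = [c.strip().lower() for c in df.columns]
        df = df.sort_values("wavelength_nm")
        return cls(df["wavelength_nm"].to_numpy(), df["ellipticity_mdeg"].to_numpy(),
                   concentration_molar, path_cm, n_residues, temperature_K)


@dataclass(frozen=True)
class MRESpectrum:
    """Mean residue molar ellipticity spectrum, deg cm^2 dmol^-1."""

    wavelength_nm: np.ndarray
    mre_deg_cm2_dmol: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        m = np.asarray(self.mre_deg_cm2_dmol, dtype=float)
        if wl.shape != m.shape:
            raise ValueError("arrays must have the same length")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "mre_deg_cm2_dmol", m)

    def at(self, wavelength_nm: float) -> float:
        """Value at a wavelength, linearly interpolated on the grid."""
        wl = self.wavelength_nm
        if not wl[0] <= wavelength_nm <= wl[-1]:
            raise ValueError(f"{wavelength_nm} nm outside the measured range "
                             f"[{wl[0]}, {wl[-1]}] nm")
        return float(np.interp(wavelength_nm, wl, self.mre_deg_cm2_dmol))


@dataclass(frozen=True)
class HelixEstimate:
    fraction: float
    method: str  # "chain_length_formula" | "basis_deconvolution"


@dataclass(frozen=True)
class CoiledCoilIndex:
    ratio_222_208: float
    classification: Classification


def to_mre(spectrum: CDSpectrum) -> MRESpectrum:
    """Normalize raw ellipticity to mean residue molar ellipticity."""
    scale = 10.0 * spectrum.concentration_molar * spectrum.path_cm * spectrum.n_residues
    return MRESpectrum(spectrum.wavelength_nm, spectrum.ellipticity_mdeg / scale)


def ratio_222_208(mre: MRESpectrum, anchors=DEFAULT_ANCHORS,
                  dead_band=DEFAULT_DEAD_BAND) -> CoiledCoilIndex:
    """[Theta]222/[Theta]208 with a qualitative coiled-coil classification.

    Ratios at or above ``dead_band[1]`` classify as coiled-coil-like, at or
    below ``dead_band[0]`` as helix-like, in between as intermediate. The
    anchors themselves (defaults 0.83 and 1.03) sit outside the dead band so
    a spectrum matching an anchor classifies with that anchor.
    """
    m208, m222 = mre.at(208.0), mre.at(222.0)
    if abs(m208) < 1e-12:
        raise ZeroDivisionError("[Theta]208 is ~0; the 222/208 ratio is undefined")
    ratio = m222 / m208
    if ratio >= dead_band[1]:
        cls = Classification.coiled_coil_like
    elif ratio <= dead_band[0]:
        cls = Classification.helix_like
    else:
        cls = Classification.intermediate
    return CoiledCoilIndex(ratio, cls)


def helix_fraction_chain_length(mre222: float, n_residues: int) -> HelixEstimate:
    """Helix fraction from the chain-length-corrected limiting ellipticity.

    fraction = [Theta]222_obs / (-40000*(1 - 4.6/n)), clipped to [0, 1].
    """
    if n_residues <= 5:
        raise ValueError("chain-length formula requires n_residues > 5")
    if mre222 > 0:
        warnings.warn("positive [Theta]222: no helix signal; fraction set to 0")
        return HelixEstimate(0.0, "chain_length_formula")
    limiting = -40000.0 * (1.0 - 4.6 / n_residues)
    frac = float(np.clip(mre222 / limiting, 0.0, 1.0))
    return HelixEstimate(frac, "chain_length_formula")


def reference_basis(wavelength_nm) -> dict[str, np.ndarray]:
    """Generic helix/sheet/coil reference spectra on an arbitrary grid.

    Synthetic basis built from Gaussian bands at the canonical far-UV band
    positions (helix: pi-pi* exciton couplet near 192/208 nm and n-pi* at
    222 nm; sheet: 195/218 nm; coil: strong negative band near 198 nm).
    Amplitudes approximate literature limiting mean residue ellipticities.
    These shapes are for testing and rough deconvolution only; quantitative
    work should supply a measured basis set.
    """
    wl = np.asarray(wavelength_nm, dtype=float)

    def band(center, width, amp):
        return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)

    helix = band(191.0, 5.5, 76000.0) + band(208.0, 6.0, -33000.0) \
        + band(222.0, 8.0, -35000.0)
    sheet = band(196.0, 6.0, 32000.0) + band(218.0, 8.0, -18000.0)
    coil = band(197.0, 7.0, -42000.0) + band(221.0, 11.0, 2500.0)
    return {"helix": helix, "sheet": sheet, "coil": coil}


def helix_fraction_basis(mre: MRESpectrum, basis: dict | None = None) -> HelixEstimate:
    """Helix fraction by non-negative least-squares basis deconvolution.

    The spectrum is modelled as a non-negative mixture of the basis spectra
    (interpolated onto the query grid if supplied on their own grid as
    ``(wavelengths, values)`` tuples); coefficients are normalized to sum to
    one and the helix coefficient is reported.
    """
    wl = mre.wavelength_nm
    if basis is None:
        basis = reference_basis(wl)
    if len(basis) < 2:
        raise ValueError("basis deconvolution needs at least 2 reference spectra")
    names, columns = [], []
    for name, spec in basis.items():
        if isinstance(spec, tuple):
            bwl, bval = (np.asarray(a, dtype=float) for a in spec)
            spec = np.interp(wl, bwl, bval)
        else:
            spec = np.asarray(spec, dtype=float)
            if spec.shape != wl.shape:
                raise ValueError(f"basis spectrum {name!r} not on the query grid; "
                                 "pass (wavelengths, values) to interpolate")
        names.append(name)
        columns.append(spec)
    if "helix" not in names:
        raise ValueError("basis must include a 'helix' component")
    A = np.column_stack(columns)
    coef, _ = nnls(A, mre.mre_deg_cm2_dmol)
    total = coef.sum()
    if total <= 0:
        return HelixEstimate(0.0, "basis_deconvolution")
    frac = float(np.clip(coef[names.index("helix")] / total, 0.0, 1.0))
    return HelixEstimate(frac, "basis_deconvolution")


def spectrum_report(spectrum: CDSpectrum, basis: dict | None = None,
                    anchors=DEFAULT_ANCHORS, dead_band=DEFAULT_DEAD_BAND) -> dict:
    """JSON-ready summary: MRE landmarks, ratio classification, helix fractions."""
    mre = to_mre(spectrum)
    idx = ratio_222_208(mre, anchors=anchors, dead_band=dead_band)
    m222 = mre.at(222.0)
    return {
        "mre222": m222,
        "mre208": mre.at(208.0),
        "ratio_222_208": idx.ratio_222_208,
        "classification": idx.classification.value,
        "helix_fraction_by_method": {
            "chain_length_formula": helix_fraction_chain_length(
                m222, spectrum.n_residues).fraction,
            "basis_deconvolution": helix_fraction_basis(mre, basis).fraction,
        },
    }
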