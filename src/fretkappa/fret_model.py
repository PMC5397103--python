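"""Forster theory: efficiency, Forster radius, overlap integral, inverse map.

The transfer efficiency for a donor-acceptor pair at distance R_DA is

    E = 1 / (1 + (R_DA / R0)^6)

with the Forster radius R0 set by the photophysics,

    R0^6 = 9000 ln(10) kappa^2 Q_D J / (128 pi^5 N_A n^4)

where Q_D is the donor fluorescence quantum yield, n the refractive index
of the medium, J = integral of f_D(lambda) eps_A(lambda) lambda^4 dlambda
the spectral overlap (donor emission area-normalized to 1; acceptor molar
extinction in M^-1 cm^-1), and N_A Avogadro's number.  With J expressed in
M^-1 cm^-1 nm^4 the reduction to Angstrom is

    R0^6 [A^6] = C * kappa^2 * n^-4 * Q_D * J,   C ~ 8.785e-5,

where C is derived below from the constants and unit conversions rather
than quoted.  Per-frame ("instantaneous") efficiencies rescale R0 with the
frame's orientation factor, R0(t)^6 = R0_ref^6 * kappa^2(t) / kappa2_ref,
holding Q_D, n and J fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.constants import Avogadro

# Unit reduction of the R0^6 prefactor:
#   9000 ln(10) / (128 pi^5 N_A)  [the 9000 = 9 * 1000 already carries the
#   M^-1 (liter/mol) -> cm^3/mol conversion, so J is taken numerically in
#   M^-1 cm^-1 cm^4]; then nm^4 -> cm^4 (1e-28) and cm^6 -> A^6 (1e48).
FORSTER_PREFACTOR_A6 = (
    9000.0 * math.log(10.0) / (128.0 * math.pi**5 * Avogadro) * 1e-28 * 1e48
)


@dataclass(frozen=True)
class FretParameters:
    """Photophysical constants of a donor-acceptor pair.

    Attributes
    ----------
    r0_ref : float
        Forster radius (Angstrom) at the reference orientation factor.
    kappa2_ref : float
        Orientation factor to which ``r0_ref`` refers; 2/3 is the isotropic
        dynamic-averaging convention, but an ensemble average (e.g. 0.69
        measured on a specific trajectory) can be used instead.
    quantum_yield_donor : float
        Donor fluorescence quantum yield Q_D, in (0, 1].
    refractive_index : float
        Medium refractive index n (>= 1).
    overlap_integral : float, optional
        J in M^-1 cm^-1 nm^4, when known.
    """

    r0_ref: float
    kappa2_ref: float = 2.0 / 3.0
    quantum_yield_donor: float = 0.4
    refractive_index: float = 1.4
    overlap_integral: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r0_ref <= 0:
            raise ValueError("r0_ref must be positive")
        if not (0 < self.kappa2_ref <= 4):
            raise ValueError("kappa2_ref must lie in (0, 4]")
        if not (0 < self.quantum_yield_donor <= 1):
            raise ValueError("quantum_yield_donor must lie in (0, 1]")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum on a strictly ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("spectrum needs at least two points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")

    @classmethod
    def from_file(cls, path) -> "Spectrum":
        """Load a two-column text spectrum (wavelength_nm value; '#' comments)."""
        data = np.loadtxt(Path(path), comments="#")
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (wavelength_nm value)")
        return cls(data[:, 0], data[:, 1])


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_excitation: Spectrum,
    epsilon_peak: float,
    peak_wavelength: float,
) -> float:
    """Spectral overlap J in M^-1 cm^-1 nm^4.

    The donor emission is area-normalized to 1 over its own grid.  The
    acceptor spectrum is rescaled so its (interpolated) value at
    ``peak_wavelength`` equals ``epsilon_peak`` (M^-1 cm^-1).  J is then
    the trapezoidal integral of f_D(l) eps_A(l) l^4 over the union grid of
    the overlapping range, with linear interpolation of both spectra.
    """
    if epsilon_peak <= 0:
        raise ValueError("epsilon_peak must be positive")
    a_wl = acceptor_excitation.wavelengths
    if not (a_wl[0] <= peak_wavelength <= a_wl[-1]):
        raise ValueError("peak_wavelength lies outside the acceptor grid")

    d_wl, d_val = donor_emission.wavelengths, donor_emission.values
    area = np.trapezoid(d_val, d_wl)
    if area <= 0:
        raise ValueError("donor emission spectrum has zero area")
    d_val = d_val / area

    ref = np.interp(peak_wavelength, a_wl, acceptor_excitation.values)
    if ref <= 0:
        raise ValueError("acceptor spectrum is zero at peak_wavelength")
    a_val = acceptor_excitation.values * (epsilon_peak / ref)

    lo = max(d_wl[0], a_wl[0])
    hi = min(d_wl[-1], a_wl[-1])
    if lo >= hi:
        raise ValueError("donor and acceptor spectra do not overlap in wavelength")
    grid = np.union1d(d_wl, a_wl)
    grid = grid[(grid >= lo) & (grid <= hi)]
    f_d = np.interp(grid, d_wl, d_val)
    eps_a = np.interp(grid, a_wl, a_val)
    return float(np.trapezoid(f_d * eps_a * grid**4, grid))


def forster_radius(
    kappa2: float,
    quantum_yield_donor: float,
    refractive_index: float,
    overlap: float,
) -> float:
    """Forster radius R0 in Angstrom (J in M^-1 cm^-1 nm^4)."""
    if kappa2 < 0 or quantum_yield_donor <= 0 or refractive_index < 1 or overlap <= 0:
        raise ValueError("kappa2 must be >= 0 and Q_D, n, J positive")
    r0_6 = (
        FORSTER_PREFACTOR_A6
        * kappa2
        * quantum_yield_donor
        * overlap
        / refractive_index**4
    )
    return float(r0_6 ** (1.0 / 6.0))


def overlap_for_forster_radius(
    r0: float,
    kappa2: float,
    quantum_yield_donor: float,
    refractive_index: float,
) -> float:
    """Invert the R0 formula for J (M^-1 cm^-1 nm^4) given a known R0 (Angstrom)."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    return float(
        r0**6
        * refractive_index**4
        / (FORSTER_PREFACTOR_A6 * kappa2 * quantum_yield_donor)
    )


def fret_efficiency(r_da, r0: float):
    """Transfer efficiency E = 1/(1 + (R_DA/R0)^6); scalar or elementwise."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    r = np.asarray(r_da, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_da must be non-negative")
    e = 1.0 / (1.0 + (r / r0) ** 6)
    return float(e) if np.isscalar(r_da) else e


def instantaneous_efficiency(r_da, kappa2, params: FretParameters):
    """Per-frame efficiency with the Forster radius rescaled by kappa^2(t).

    R0(t)^6 = r0_ref^6 * kappa2 / kappa2_ref; kappa2 = 0 gives E = 0
    (transfer forbidden by orientation).  Scalar or elementwise.
    """
    k2 = np.asarray(kappa2, dtype=float)
    if np.any(k2 < 0):
        raise ValueError("kappa2 must be non-negative")
    r = np.asarray(r_da, dtype=float)
    r0_6 = params.r0_ref**6 * k2 / params.kappa2_ref
    e = r0_6 / (r0_6 + r**6)
    if np.isscalar(r_da) and np.isscalar(kappa2):
        return float(e)
    return e


def apparent_distance(efficiency, r0: float):
    """Distance inferred from an efficiency under a unique Forster radius.

    R_app = R0 * (1/E - 1)^(1/6), the inverse of :func:`fret_efficiency`;
    defined only for E strictly inside (0, 1).
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    e = np.asarray(efficiency, dtype=float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("efficiency must lie strictly inside (0, 1)")
    r = r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)
    return float(r) if np.isscalar(efficiency) else r
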