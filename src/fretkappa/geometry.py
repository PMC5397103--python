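"""Inter-dipole geometry and the FRET orientation factor kappa^2.

For a donor dipole mu_D, acceptor dipole mu_A and unit separation vector
R_hat (donor -> acceptor):

* theta_D, theta_A are the angles each dipole makes with R_hat;
* phi is the angle between the (mu_D, R_hat) and (mu_A, R_hat) planes;
* kappa = sin(theta_D) sin(theta_A) cos(phi) - 2 cos(theta_D) cos(theta_A),
  equivalently kappa = mu_D . mu_A - 3 (mu_D . R_hat)(mu_A . R_hat);
* kappa^2 in [0, 4] modulates the Forster radius (R0^6 proportional to
  kappa^2); isotropic dynamic averaging gives <kappa^2> = 2/3.

The vector form is the primary computation path: it has no trigonometric
degeneracies.  The angle form exists for reporting theta_D/theta_A/phi and
as an independent cross-check; phi is undefined (flagged as NaN) whenever a
dipole is collinear with the separation vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedDihedralError
from .frames import DipoleFrame, as_trajectory

#: sin(theta) below which the dihedral plane is considered degenerate.
DEGENERATE_SIN_THETA = 1e-9


@dataclass(frozen=True)
class AngleSet:
    """theta_D, theta_A, phi (radians) and scalar R_DA (Angstrom) of one frame.

    ``phi`` is NaN when either dipole is (anti)parallel to the separation
    vector, in which case the dihedral plane is undefined.
    """

    theta_d: float
    theta_a: float
    phi: float
    r_da: float

    @property
    def phi_defined(self) -> bool:
        return not math.isnan(self.phi)


def frame_angles(frame: DipoleFrame) -> AngleSet:
    """Compute the angular geometry (theta_D, theta_A, phi, R_DA) of a frame."""
    sep = frame.separation
    r = float(np.linalg.norm(sep))
    if r <= 0:
        raise ValueError("zero donor-acceptor separation")
    r_hat = sep / r
    mu_d, mu_a = frame.donor_dipole, frame.acceptor_dipole

    cos_d = float(np.clip(np.dot(mu_d, r_hat), -1.0, 1.0))
    cos_a = float(np.clip(np.dot(mu_a, r_hat), -1.0, 1.0))
    theta_d = math.acos(cos_d)
    theta_a = math.acos(cos_a)

    # Plane normals; degenerate when sin(theta) ~ 0.
    n_d = np.cross(mu_d, r_hat)
    n_a = np.cross(mu_a, r_hat)
    nd_norm = float(np.linalg.norm(n_d))
    na_norm = float(np.linalg.norm(n_a))
    if nd_norm < DEGENERATE_SIN_THETA or na_norm < DEGENERATE_SIN_THETA:
        phi = math.nan
    else:
        cos_phi = float(np.clip(np.dot(n_d, n_a) / (nd_norm * na_norm), -1.0, 1.0))
        phi = math.acos(cos_phi)  # unsigned dihedral in [0, pi]
    return AngleSet(theta_d=theta_d, theta_a=theta_a, phi=phi, r_da=r)


def kappa_squared_from_angles(angles: AngleSet) -> float:
    """kappa^2 from the angular definition; requires a defined phi."""
    if not angles.phi_defined:
        raise UndefinedDihedralError(
            "phi is undefined (dipole collinear with separation); "
            "use kappa_squared_from_vectors"
        )
    kappa = (
        math.sin(angles.theta_d) * math.sin(angles.theta_a) * math.cos(angles.phi)
        - 2.0 * math.cos(angles.theta_d) * math.cos(angles.theta_a)
    )
    return kappa * kappa


def kappa_squared_from_vectors(frame: DipoleFrame) -> float:
    """kappa^2 from the vector form; defined for every valid frame."""
    sep = frame.separation
    r = float(np.linalg.norm(sep))
    if r <= 0:
        raise ValueError("zero donor-acceptor separation")
    r_hat = sep / r
    kappa = float(
        np.dot(frame.donor_dipole, frame.acceptor_dipole)
        - 3.0 * np.dot(frame.donor_dipole, r_hat) * np.dot(frame.acceptor_dipole, r_hat)
    )
    return kappa * kappa


def kappa_squared_array(mu_d: np.ndarray, mu_a: np.ndarray, separation: np.ndarray) -> np.ndarray:
    """Vectorized kappa^2 for stacked ``(n, 3)`` dipoles and separations."""
    r = np.linalg.norm(separation, axis=-1, keepdims=True)
    if np.any(r <= 0):
        raise ValueError("zero donor-acceptor separation")
    r_hat = separation / r
    kappa = (
        np.einsum("...i,...i->...", mu_d, mu_a)
        - 3.0 * np.einsum("...i,...i->...", mu_d, r_hat) * np.einsum("...i,...i->...", mu_a, r_hat)
    )
    return kappa**2


def kappa_squared_series(frames) -> pd.DataFrame:
    """Per-frame kappa^2 and R_DA, order preserved.

    Returns a DataFrame with columns ``frame``, ``kappa2``, ``r_da``
    (exportable directly as a TSV series).
    """
    traj = as_trajectory(frames)
    k2 = kappa_squared_array(traj.donor_dipoles, traj.acceptor_dipoles, traj.separations)
    return pd.DataFrame({"frame": traj.indices, "kappa2": k2, "r_da": traj.r_da})
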