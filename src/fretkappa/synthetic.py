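"""Synthetic donor-acceptor trajectories with controlled statistics.

The generator emulates the statistical structure an equilibrated flexible
two-fluorophore construct presents to the FRET analysis: a stationary
donor-acceptor distance distribution (fixed or Gaussian around a plateau
value) and transition dipoles that re-orient independently from frame to
frame, either fully isotropically or restricted to a cone.  Frames are
independent draws — the generator reproduces ensemble statistics, not
temporal autocorrelation.

The "paper-like" preset places the distance distribution at 44 +/- 1.5 A
with isotropic orientations, a stationary stand-in for a flexibly linked
CFP/YFP pair whose distance has plateaued in the low-to-mid-40-Angstrom
range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .frames import DipoleTrajectory
from .geometry import kappa_squared_array


@dataclass(frozen=True)
class LinkerModelParams:
    """Generative parameters for a synthetic dipole trajectory.

    Attributes
    ----------
    n_frames : int
        Number of independent frames to draw.
    distance_model : {"fixed", "gaussian"}
        Fixed R_DA = mean_A, or Gaussian(mean_A, sd_A) with negative draws
        rejected and redrawn.
    mean_A, sd_A : float
        Distance distribution parameters, Angstrom.
    orientation_model : {"isotropic", "cone"}
        Dipole orientations: uniform on the sphere, or uniform within a
        cone of semi-angle ``cone_semiangle`` about an axis.
    cone_semiangle : float
        Cone semi-angle in radians (0 = dipoles pinned to the axis;
        pi = full sphere).
    cone_axis_mode : {"along_separation", "fixed_lab_axis"}
        Cone axis per frame: the donor->acceptor direction, or the lab +x
        axis (in which case the separation is also placed along +x).
    relaxation_tau_frames, start_A : optional
        Only used by :func:`simulate_relaxing_distance_series`.
    seed : int
        Seed for the random generator; identical parameters and seed give
        a bitwise-identical trajectory.
    """

    n_frames: int
    distance_model: str = "gaussian"
    mean_A: float = 44.0
    sd_A: float = 1.5
    orientation_model: str = "isotropic"
    cone_semiangle: float = np.pi
    cone_axis_mode: str = "along_separation"
    relaxation_tau_frames: Optional[int] = None
    start_A: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.distance_model not in ("fixed", "gaussian"):
            raise ValueError(f"unknown distance_model {self.distance_model!r}")
        if self.orientation_model not in ("isotropic", "cone"):
            raise ValueError(f"unknown orientation_model {self.orientation_model!r}")
        if self.cone_axis_mode not in ("along_separation", "fixed_lab_axis"):
            raise ValueError(f"unknown cone_axis_mode {self.cone_axis_mode!r}")
        if self.mean_A <= 0:
            raise ValueError("mean_A must be positive")
        if self.sd_A < 0:
            raise ValueError("sd_A must be non-negative")
        if not (0 <= self.cone_semiangle <= np.pi):
            raise ValueError("cone_semiangle must lie in [0, pi]")


def paper_like_preset(n_frames: int, seed: int = 0) -> LinkerModelParams:
    """Gaussian distances 44 +/- 1.5 A, isotropic orientations."""
    return LinkerModelParams(
        n_frames=n_frames,
        distance_model="gaussian",
        mean_A=44.0,
        sd_A=1.5,
        orientation_model="isotropic",
        seed=seed,
    )


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform directions via normalized standard-normal triples."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    # a 3-D standard normal is never numerically zero in practice, but redraw defensively
    while np.any(norms < 1e-12):
        bad = norms < 1e-12
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


def _cone_vectors(rng: np.random.Generator, axes: np.ndarray, semiangle: float) -> np.ndarray:
    """Uniform directions within a cone of given semi-angle about each axis."""
    n = axes.shape[0]
    cos_t = rng.uniform(np.cos(semiangle), 1.0, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # orthonormal frame (e1, e2, axis) per row; helper chosen away from the axis
    helper = np.where(np.abs(axes[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e1 = np.cross(helper, axes)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)
    return (
        sin_t[:, None] * np.cos(phi)[:, None] * e1
        + sin_t[:, None] * np.sin(phi)[:, None] * e2
        + cos_t[:, None] * axes
    )


def _draw_distances(rng: np.random.Generator, params: LinkerModelParams) -> np.ndarray:
    if params.distance_model == "fixed":
        return np.full(params.n_frames, params.mean_A)
    r = rng.normal(params.mean_A, params.sd_A, size=params.n_frames)
    while np.any(r <= 0):  # reject non-physical negative distances
        bad = r <= 0
        r[bad] = rng.normal(params.mean_A, params.sd_A, size=int(bad.sum()))
    return r


def simulate_trajectory(params: LinkerModelParams) -> DipoleTrajectory:
    """Draw a synthetic trajectory of independent dipole frames.

    The donor center sits at the origin; the acceptor center lies at the
    drawn distance along a uniformly random direction (along +x when
    ``cone_axis_mode='fixed_lab_axis'``).  Dipoles are drawn per frame and
    per fluorophore according to the orientation model.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    r = _draw_distances(rng, params)
    if params.cone_axis_mode == "fixed_lab_axis":
        directions = np.tile([1.0, 0.0, 0.0], (n, 1))
    else:
        directions = _random_unit_vectors(rng, n)
    acceptor_centers = r[:, None] * directions
    donor_centers = np.zeros((n, 3))

    if params.orientation_model == "isotropic":
        mu_d = _random_unit_vectors(rng, n)
        mu_a = _random_unit_vectors(rng, n)
    else:
        if params.cone_axis_mode == "along_separation":
            axes = directions
        else:
            axes = np.tile([1.0, 0.0, 0.0], (n, 1))
        mu_d = _cone_vectors(rng, axes, params.cone_semiangle)
        mu_a = _cone_vectors(rng, axes, params.cone_semiangle)
    # renormalize to absorb rounding from the cone construction
    mu_d /= np.linalg.norm(mu_d, axis=1, keepdims=True)
    mu_a /= np.linalg.norm(mu_a, axis=1, keepdims=True)

    return DipoleTrajectory(np.arange(n), donor_centers, acceptor_centers, mu_d, mu_a)


def simulate_isotropic_kappa2(n: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo kappa^2 samples for isotropic, independent dipoles.

    Each sample uses two independent uniform unit dipoles and a uniform
    separation direction through the vector form of kappa; the sample mean
    converges to the isotropic limit 2/3.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu_d = _random_unit_vectors(rng, n)
    mu_a = _random_unit_vectors(rng, n)
    r_hat = _random_unit_vectors(rng, n)
    return kappa_squared_array(mu_d, mu_a, r_hat)


def simulate_relaxing_distance_series(params: LinkerModelParams) -> pd.DataFrame:
    """Exponential approach of R_DA from start_A to mean_A plus Gaussian noise.

    A convergence fixture mimicking a trajectory started far from
    equilibrium (e.g. an extended linker at ~90 A relaxing to a plateau in
    the mid-40s): r(t) = mean_A + (start_A - mean_A) exp(-t / tau) + noise.
    Returns a DataFrame with columns ``frame`` and ``r_da``.
    """
    if params.relaxation_tau_frames is None or params.start_A is None:
        raise ValueError("relaxation_tau_frames and start_A must be set")
    if params.relaxation_tau_frames < 1:
        raise ValueError("relaxation_tau_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames, dtype=float)
    base = params.mean_A + (params.start_A - params.mean_A) * np.exp(
        -t / params.relaxation_tau_frames
    )
    noise = rng.normal(0.0, params.sd_A, size=params.n_frames) if params.sd_A > 0 else 0.0
    return pd.DataFrame({"frame": np.arange(params.n_frames), "r_da": base + noise})


def with_seed(params: LinkerModelParams, seed: int) -> LinkerModelParams:
    """Copy of the parameters with a different seed."""
    return replace(params, seed=seed)
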