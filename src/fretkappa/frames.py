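"""Per-frame donor/acceptor dipole records and their array-backed trajectory container.

A :class:`DipoleFrame` holds one conformation's geometry: the donor and
acceptor chromophore centers (Angstrom) and the unit transition-dipole
vectors mu_D and mu_A.  A :class:`DipoleTrajectory` stores many frames as
contiguous ``(n, 3)`` arrays so that million-frame orientation-factor series
stay vectorized, while still behaving as an ordered sequence of
:class:`DipoleFrame` objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

UNIT_NORM_TOL = 1e-12


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} has non-finite components: {v}")
    return v


@dataclass(frozen=True)
class DipoleFrame:
    """One conformation's dipole geometry.

    Attributes
    ----------
    index : int
        Frame identifier (model number or simulation step).
    donor_center, acceptor_center : (3,) ndarray
        Chromophore reference points, Angstrom.
    donor_dipole, acceptor_dipole : (3,) ndarray
        Unit transition-dipole vectors mu_D, mu_A.
    """

    index: int
    donor_center: np.ndarray
    acceptor_center: np.ndarray
    donor_dipole: np.ndarray
    acceptor_dipole: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "donor_center", _as_vec3(self.donor_center, "donor_center"))
        object.__setattr__(self, "acceptor_center", _as_vec3(self.acceptor_center, "acceptor_center"))
        object.__setattr__(self, "donor_dipole", _as_vec3(self.donor_dipole, "donor_dipole"))
        object.__setattr__(self, "acceptor_dipole", _as_vec3(self.acceptor_dipole, "acceptor_dipole"))
        for name in ("donor_dipole", "acceptor_dipole"):
            norm = float(np.linalg.norm(getattr(self, name)))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a unit vector (|v| = {norm:.3g})")
        if np.allclose(self.donor_center, self.acceptor_center):
            raise ValueError("donor and acceptor centers coincide (zero separation)")

    @property
    def separation(self) -> np.ndarray:
        """Vector R_DA from donor center to acceptor center, Angstrom."""
        return self.acceptor_center - self.donor_center

    @property
    def r_da(self) -> float:
        """Scalar donor-acceptor distance |R_DA|, Angstrom."""
        return float(np.linalg.norm(self.separation))


class DipoleTrajectory(Sequence):
    """Ordered collection of dipole frames stored as ``(n, 3)`` arrays.

    Supports ``len``, indexing (returning :class:`DipoleFrame`) and
    iteration, so any API documented to accept an ordered collection of
    frames accepts either this container or a plain list of frames.
    """

    def __init__(
        self,
        indices,
        donor_centers,
        acceptor_centers,
        donor_dipoles,
        acceptor_dipoles,
        *,
        renormalize: bool = False,
    ) -> None:
        self.indices = np.asarray(indices, dtype=int)
        self.donor_centers = np.asarray(donor_centers, dtype=float)
        self.acceptor_centers = np.asarray(acceptor_centers, dtype=float)
        self.donor_dipoles = np.asarray(donor_dipoles, dtype=float)
        self.acceptor_dipoles = np.asarray(acceptor_dipoles, dtype=float)

        n = len(self.indices)
        for name in ("donor_centers", "acceptor_centers", "donor_dipoles", "acceptor_dipoles"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if n == 0:
            raise ValueError("trajectory must contain at least one frame")

        if renormalize:
            for name in ("donor_dipoles", "acceptor_dipoles"):
                arr = getattr(self, name)
                norms = np.linalg.norm(arr, axis=1)
                bad = np.flatnonzero(norms < 1e-300)
                if bad.size:
                    raise ValueError(f"zero-length dipole vector at row {bad[0]}")
                setattr(self, name, arr / norms[:, None])
        else:
            for name in ("donor_dipoles", "acceptor_dipoles"):
                norms = np.linalg.norm(getattr(self, name), axis=1)
                if np.any(np.abs(norms - 1.0) > 1e-6):
                    raise ValueError(f"{name} must contain unit vectors")

        sep = self.acceptor_centers - self.donor_centers
        r = np.linalg.norm(sep, axis=1)
        zero = np.flatnonzero(r <= 0.0)
        if zero.size:
            raise ValueError(f"zero donor-acceptor separation at frame index {self.indices[zero[0]]}")
        self._r_da = r

    @classmethod
    def from_frames(cls, frames: Iterable[DipoleFrame]) -> "DipoleTrajectory":
        frames = list(frames)
        if not frames:
            raise ValueError("empty frame collection")
        return cls(
            [f.index for f in frames],
            [f.donor_center for f in frames],
            [f.acceptor_center for f in frames],
            [f.donor_dipole for f in frames],
            [f.acceptor_dipole for f in frames],
        )

    @property
    def separations(self) -> np.ndarray:
        return self.acceptor_centers - self.donor_centers

    @property
    def r_da(self) -> np.ndarray:
        """Scalar distances |R_DA| per frame, Angstrom."""
        return self._r_da

    def __len__(self) -> int:
        return len(self.indices)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return DipoleTrajectory(
                self.indices[i],
                self.donor_centers[i],
                self.acceptor_centers[i],
                self.donor_dipoles[i],
                self.acceptor_dipoles[i],
            )
        return DipoleFrame(
            int(self.indices[i]),
            self.donor_centers[i],
            self.acceptor_centers[i],
            self.donor_dipoles[i],
            self.acceptor_dipoles[i],
        )

    def __iter__(self) -> Iterator[DipoleFrame]:
        for i in range(len(self)):
            yield self[i]


def as_trajectory(frames) -> DipoleTrajectory:
    """Coerce a DipoleTrajectory or iterable of DipoleFrame to a trajectory."""
    if isinstance(frames, DipoleTrajectory):
        return frames
    return DipoleTrajectory.from_frames(frames)
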