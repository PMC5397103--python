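"""Shared fixtures: programmatically built PDB text and handcrafted frames."""

from __future__ import annotations

import numpy as np
import pytest

from fretkappa import DipoleFrame, DipoleTrajectory


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    hetatm: bool = False,
    element: str = "C",
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name_field = f" {name:<3}" if len(name) < 4 else f"{name:<4}"
    return (
        f"{record}{serial:>5} {name_field} {resname:<3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


def make_multimodel_pdb(n_models: int, n_atoms: int = 10) -> str:
    """Simple poly-ALA multi-model PDB text."""
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:>4}")
        for i in range(n_atoms):
            lines.append(
                pdb_atom_line(i + 1, "CA", "ALA", "A", i + 1, float(i) + 0.1 * m, 0.0, 0.0)
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_chromophore_pdb(n_models: int = 2) -> str:
    """Models containing CRF (donor) and CRO (acceptor) heteroatom chromophores.

    Donor dipole atoms CA2 -> CZ2 span (0,0,0) -> (2,0,0); acceptor
    CA2 -> CZ span (40,0,0) -> (40,2,0), so the donor center sits at
    (1,0,0) and the acceptor center at (40,1,0).
    """
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:>4}")
        lines.append(pdb_atom_line(1, "CA", "ALA", "A", 1, -5.0, 0.0, 0.0))
        lines.append(pdb_atom_line(2, "CA2", "CRF", "A", 10, 0.0, 0.0, 0.0, hetatm=True))
        lines.append(pdb_atom_line(3, "CZ2", "CRF", "A", 10, 2.0, 0.0, 0.0, hetatm=True))
        lines.append(pdb_atom_line(4, "CA2", "CRO", "B", 10, 40.0, 0.0, 0.0, hetatm=True))
        lines.append(pdb_atom_line(5, "CZ", "CRO", "B", 10, 40.0, 2.0, 0.0, hetatm=True))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def frame_from_vectors(mu_d, mu_a, separation, index: int = 0) -> DipoleFrame:
    """Frame with donor at the origin and the given separation vector."""
    return DipoleFrame(
        index=index,
        donor_center=np.zeros(3),
        acceptor_center=np.asarray(separation, dtype=float),
        donor_dipole=np.asarray(mu_d, dtype=float),
        acceptor_dipole=np.asarray(mu_a, dtype=float),
    )


def random_trajectory(n: int, seed: int, r: float = 40.0) -> DipoleTrajectory:
    """Random unit dipoles and separation directions at fixed distance r."""
    rng = np.random.default_rng(seed)

    def units(k):
        v = rng.standard_normal((k, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    return DipoleTrajectory(
        np.arange(n),
        np.zeros((n, 3)),
        r * units(n),
        units(n),
        units(n),
    )


@pytest.fixture
def orthogonal_frames():
    """Three handcrafted frames with kappa^2 exactly 4, 1 and 0."""
    return [
        frame_from_vectors([1, 0, 0], [1, 0, 0], [40, 0, 0], index=0),  # collinear -> 4
        frame_from_vectors([0, 0, 1], [0, 0, 1], [40, 0, 0], index=1),  # parallel, perp -> 1
        frame_from_vectors([0, 0, 1], [0, 1, 0], [40, 0, 0], index=2),  # orthogonal -> 0
    ]
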