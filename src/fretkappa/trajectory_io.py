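"""Reading conformational frames and dipole vector tables.

Two ingestion paths feed the analysis:

* multi-model PDB files (one MODEL/ENDMDL block per conformation; ATOM and
  HETATM records are both kept, so fluorescent-protein chromophores stored
  as heteroatoms — e.g. the CRO and CRF residues of EYFP and ECFP — are
  available), plus a :class:`ChromophoreSpec` describing which atom pair
  spans each transition dipole;
* plain tab-separated vector tables carrying precomputed per-frame centers
  and dipole unit vectors, the format the synthetic-trajectory generator
  writes.

The transition-dipole *direction* of a chromophore is approximated by the
axis between two named atoms of the chromophore residue.  This is a
configurable approximation: the true S0->S1 transition dipole comes from
quantum chemistry and is not derivable from coordinates alone, but the
orientation factor depends only on the dipole axis (it is invariant under a
sign flip), so a long-axis atom pair across the conjugated ring system is a
reasonable default and users can substitute better axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import ChromophoreLookupError, PDBParseError, SchemaError
from .frames import DipoleTrajectory

#: Exact column order of the vector-table format.
VECTOR_TABLE_COLUMNS = [
    "frame",
    "dx", "dy", "dz",          # donor center, Angstrom
    "ax", "ay", "az",          # acceptor center, Angstrom
    "mux_d", "muy_d", "muz_d",  # donor dipole unit vector
    "mux_a", "muy_a", "muz_a",  # acceptor dipole unit vector
]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record of a PDB conformation."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} has invalid position {pos}")
        if not self.name.strip():
            raise ValueError(f"atom {self.serial} has an empty name")


@dataclass(frozen=True)
class ConformationFrame:
    """All atoms of one MODEL block."""

    model_index: int
    atoms: Sequence[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"model {self.model_index} contains no atoms")


@dataclass(frozen=True)
class ChromophoreSpec:
    """Which residue and atom pair define a chromophore's dipole and center.

    ``dipole_atom_tail -> dipole_atom_head`` spans the transition-dipole
    axis.  The chromophore reference point is either the midpoint of that
    atom pair (``center_mode='dipole_midpoint'``, the default, which keeps
    the distance and the dipole referenced to the same moiety) or a named
    atom (``center_mode='named_atom'`` with ``center_atom`` set).
    """

    residue_name: str
    dipole_atom_tail: str
    dipole_atom_head: str
    chain_id: Optional[str] = None
    center_mode: str = "dipole_midpoint"
    center_atom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dipole_atom_tail == self.dipole_atom_head:
            raise ValueError("dipole tail and head atoms must differ")
        if self.center_mode not in ("dipole_midpoint", "named_atom"):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")
        if self.center_mode == "named_atom" and not self.center_atom:
            raise ValueError("center_mode='named_atom' requires center_atom")


# Default dipole axes: a long-axis pair across each chromophore's conjugated
# ring system (imidazolinone CA2 to the phenol/indole-side CZ of the
# p-hydroxybenzylidene / tryptophan-derived moiety).  These are geometric
# approximations to the quantum-chemical transition dipoles, not their
# computed directions; override them when better axes are known.
EYFP_CHROMOPHORE = ChromophoreSpec(residue_name="CRO", dipole_atom_tail="CA2", dipole_atom_head="CZ")
ECFP_CHROMOPHORE = ChromophoreSpec(residue_name="CRF", dipole_atom_tail="CA2", dipole_atom_head="CZ2")


def read_multimodel_pdb(path) -> List[ConformationFrame]:
    """Parse a (possibly multi-model) PDB file into conformational frames.

    One frame per MODEL/ENDMDL block; a file without MODEL records yields a
    single frame with ``model_index`` 1.  ATOM and HETATM records are both
    kept; for atoms with alternate locations only the blank/'A' location is
    used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBParseError(f"{path}: {exc}") from exc

    frames: List[ConformationFrame] = []
    for pos, model in enumerate(structure):
        atoms: List[AtomRecord] = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.is_disordered():
                        chosen = None
                        for alt in atom.disordered_get_list():
                            if alt.get_altloc() in (" ", "", "A"):
                                chosen = alt
                                break
                        if chosen is None:
                            continue
                        atom = chosen
                    elif atom.get_altloc() not in (" ", "", "A"):
                        continue
                    atoms.append(
                        AtomRecord(
                            serial=int(atom.get_serial_number()),
                            name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            chain_id=chain.get_id(),
                            residue_number=int(residue.get_id()[1]),
                            position=atom.get_coord(),
                        )
                    )
        model_index = int(model.serial_num) if model.serial_num and model.serial_num >= 1 else pos + 1
        if atoms:
            frames.append(ConformationFrame(model_index=model_index, atoms=atoms))
    if not frames:
        raise PDBParseError(f"{path}: no conformational frames parsed")
    return frames


def _locate_atom(frame: ConformationFrame, spec: ChromophoreSpec, atom_name: str, frame_pos: int) -> np.ndarray:
    for atom in frame.atoms:
        if atom.residue_name != spec.residue_name:
            continue
        if spec.chain_id is not None and atom.chain_id != spec.chain_id:
            continue
        if atom.name == atom_name:
            return atom.position
    raise ChromophoreLookupError(
        f"frame {frame_pos} (model {frame.model_index}): atom {atom_name!r} of "
        f"chromophore residue {spec.residue_name!r} not found"
    )


def extract_dipole_frames(
    frames: Sequence[ConformationFrame],
    donor: ChromophoreSpec,
    acceptor: ChromophoreSpec,
) -> DipoleTrajectory:
    """Reduce conformational frames to per-frame dipole/center records.

    For each chromophore the dipole is the unit vector from its tail atom to
    its head atom and the center follows the spec's ``center_mode``.  Frame
    order is preserved and the frame count is unchanged.
    """
    if not frames:
        raise ValueError("empty frame collection")
    indices, d_cen, a_cen, d_dip, a_dip = [], [], [], [], []
    for pos, frame in enumerate(frames):
        row = []
        for spec in (donor, acceptor):
            tail = _locate_atom(frame, spec, spec.dipole_atom_tail, pos)
            head = _locate_atom(frame, spec, spec.dipole_atom_head, pos)
            axis = head - tail
            norm = float(np.linalg.norm(axis))
            if norm <= 0:
                raise ChromophoreLookupError(
                    f"frame {pos}: coincident dipole atoms for residue {spec.residue_name!r}"
                )
            if spec.center_mode == "named_atom":
                center = _locate_atom(frame, spec, spec.center_atom, pos)
            else:
                center = 0.5 * (tail + head)
            row.append((axis / norm, center))
        indices.append(frame.model_index)
        d_dip.append(row[0][0])
        d_cen.append(row[0][1])
        a_dip.append(row[1][0])
        a_cen.append(row[1][1])
    return DipoleTrajectory(indices, d_cen, a_cen, d_dip, a_dip)


def write_vector_table(frames, path) -> None:
    """Write frames as a tab-separated vector table (full float precision)."""
    traj = frames if isinstance(frames, DipoleTrajectory) else DipoleTrajectory.from_frames(frames)
    df = pd.DataFrame(
        np.column_stack(
            [
                traj.indices,
                traj.donor_centers,
                traj.acceptor_centers,
                traj.donor_dipoles,
                traj.acceptor_dipoles,
            ]
        ),
        columns=VECTOR_TABLE_COLUMNS,
    )
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_vector_table(path) -> DipoleTrajectory:
    """Read a tab-separated vector table written by :func:`write_vector_table`.

    Dipole columns are renormalized to unit length on read, so the
    write/read round trip is stable at the written precision.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = [c for c in VECTOR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: table contains no data rows")
    try:
        return DipoleTrajectory(
            df["frame"].to_numpy(),
            df[["dx", "dy", "dz"]].to_numpy(),
            df[["ax", "ay", "az"]].to_numpy(),
            df[["mux_d", "muy_d", "muz_d"]].to_numpy(),
            df[["mux_a", "muy_a", "muz_a"]].to_numpy(),
            renormalize=True,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
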