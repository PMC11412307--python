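"""Conformational data model and structure I/O.

A :class:`ConformationSet` holds an ordered stack of frames (conformations) of
one molecule: per-frame, per-atom coordinates plus static atom/residue
metadata and a frame time axis.  Internal units are nm and ps throughout the
package; PDB files (Å) are converted on read/write.

Multi-model PDB is the canonical on-disk format (one MODEL per frame); binary
trajectory formats (XTC/DCD) are supported through a thin mdtraj adapter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "ConformationSet",
    "AtomSelection",
    "FormatError",
    "read_multimodel_pdb",
    "write_ensemble_pdb",
    "read_trajectory",
]

ANGSTROM_PER_NM = 10.0

# Standard atomic masses (amu) for elements that occur in protein frames.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}


class FormatError(ValueError):
    """Raised when an input file violates the expected structure."""


@dataclass
class ConformationSet:
    """Frames of atomic coordinates with shared atom/residue metadata.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in nm.
    atom_names : ndarray of str, shape (n_atoms,)
        PDB-style atom names (``N``, ``CA``, ``C``, ``HN`` ...).
    elements : ndarray of str, shape (n_atoms,)
        Element symbols; empty string marks an unknown element (mass 0).
    residue_index : ndarray of int, shape (n_atoms,)
        0-based residue index per atom, non-decreasing along the atom axis.
    residue_name : ndarray of str, shape (n_atoms,)
        3-letter residue codes (including SEP/TPO/PTR for phosphorylated
        serine/threonine/tyrosine).
    frame_times : ndarray, shape (n_frames,)
        Time of each frame in ps, strictly increasing.
    masses : ndarray, shape (n_atoms,)
        Atomic masses in amu (0 for unknown elements).
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    frame_times: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        for name, arr in (
            ("atom_names", self.atom_names), ("elements", self.elements),
            ("residue_index", self.residue_index),
            ("residue_name", self.residue_name), ("masses", self.masses),
        ):
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have one entry per atom")
        if self.frame_times.shape != (self.n_frames,):
            raise ValueError("frame_times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must be non-decreasing over atoms")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.residue_index[-1]) + 1 if self.n_atoms else 0

    def subset(self, frames: Sequence[int]) -> "ConformationSet":
        """A new set containing ``frames`` in the given order."""
        frames = np.asarray(frames, dtype=int)
        times = self.frame_times[frames]
        # Re-time to keep the strictly-increasing invariant for arbitrary order.
        if len(frames) > 1 and not np.all(np.diff(times) > 0):
            times = np.arange(len(frames), dtype=float)
        return ConformationSet(
            coords=self.coords[frames].copy(),
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            residue_index=self.residue_index.copy(),
            residue_name=self.residue_name.copy(),
            frame_times=times,
            masses=self.masses.copy(),
        )

    def atom_indices(self, predicate: Callable[[str, str, int], bool]) -> np.ndarray:
        out = [
            i for i in range(self.n_atoms)
            if predicate(str(self.atom_names[i]), str(self.elements[i]),
                         int(self.residue_index[i]))
        ]
        return np.asarray(out, dtype=int)


@dataclass
class AtomSelection:
    """A predicate over (atom_name, element, residue_index).

    ``resolve`` turns the predicate into a sorted, unique index list for a
    specific :class:`ConformationSet`.
    """

    predicate: Callable[[str, str, int], bool]
    label: str = "custom"

    def resolve(self, cset: ConformationSet) -> np.ndarray:
        idx = cset.atom_indices(self.predicate)
        return np.unique(idx)

    @staticmethod
    def all_atoms() -> "AtomSelection":
        return AtomSelection(lambda name, el, res: True, label="all")

    @staticmethod
    def by_name(*names: str) -> "AtomSelection":
        wanted = {n.upper() for n in names}
        return AtomSelection(
            lambda name, el, res: name.upper() in wanted,
            label="name:" + ",".join(sorted(wanted)),
        )

    @staticmethod
    def calpha() -> "AtomSelection":
        return AtomSelection.by_name("CA")

    @staticmethod
    def heavy_atoms() -> "AtomSelection":
        return AtomSelection(
            lambda name, el, res: el.upper() not in ("H", ""),
            label="heavy",
        )

    @staticmethod
    def polar_atoms() -> "AtomSelection":
        """O and S atoms: the SASA contributors that dominate solvent contrast."""
        return AtomSelection(
            lambda name, el, res: el.upper() in ("O", "S"), label="polar"
        )


# ---------------------------------------------------------------------------
# PDB I/O (via mdtraj, with a pre-scan for a precise format diagnosis)
# ---------------------------------------------------------------------------

def _scan_model_atom_counts(path: str) -> list[int]:
    """ATOM/HETATM record count per MODEL block (single block if no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not saw_model:
        return [current] if current else []
    if in_model:  # unterminated trailing MODEL
        counts.append(current)
    return counts


def read_multimodel_pdb(path: str) -> ConformationSet:
    """Read a (multi-model) PDB file into a :class:`ConformationSet`.

    Coordinates are converted Å→nm.  All models must contain the same atoms
    in the same order; masses are assigned from the element, with a warning
    and mass 0 for unknown elements.  Frame times are synthesized as
    0, 1, 2, ... ps (PDB carries no time axis).
    """
    import mdtraj as md

    counts = _scan_model_atom_counts(path)
    if not counts:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise FormatError(
            f"{path}: MODEL {bad + 1} has {counts[bad]} atoms, "
            f"expected {counts[0]} (all models must match)"
        )

    traj = md.load_pdb(path, standard_names=False, no_boxchk=True)
    top = traj.topology
    n_atoms = top.n_atoms
    atom_names = np.empty(n_atoms, dtype=object)
    elements = np.empty(n_atoms, dtype=object)
    residue_index = np.empty(n_atoms, dtype=int)
    residue_name = np.empty(n_atoms, dtype=object)
    masses = np.zeros(n_atoms)
    unknown = []
    for i, atom in enumerate(top.atoms):
        atom_names[i] = atom.name
        residue_index[i] = atom.residue.index
        residue_name[i] = atom.residue.name
        symbol = atom.element.symbol if atom.element is not None else ""
        if symbol.upper() in ATOMIC_MASSES:
            elements[i] = symbol
            masses[i] = ATOMIC_MASSES[symbol.upper()]
        else:
            elements[i] = ""
            unknown.append(atom.name)
    if unknown:
        warnings.warn(
            f"{path}: unknown element for atoms {unknown}; mass set to 0",
            stacklevel=2,
        )
    return ConformationSet(
        coords=np.asarray(traj.xyz, dtype=float),
        atom_names=atom_names,
        elements=elements,
        residue_index=residue_index,
        residue_name=residue_name,
        frame_times=np.arange(traj.n_frames, dtype=float),
        masses=masses,
    )


def to_mdtraj(cset: ConformationSet):
    """Bridge to an mdtraj.Trajectory (used for PDB output and SASA)."""
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    residues = {}
    for i in range(cset.n_atoms):
        ri = int(cset.residue_index[i])
        if ri not in residues:
            residues[ri] = top.add_residue(str(cset.residue_name[i]), chain,
                                           resSeq=ri + 1)
        symbol = str(cset.elements[i])
        try:
            element = md.element.get_by_symbol(symbol) if symbol else md.element.virtual
        except KeyError:
            element = md.element.virtual
        top.add_atom(str(cset.atom_names[i]), element, residues[ri])
    return md.Trajectory(
        xyz=np.asarray(cset.coords, dtype=np.float32),
        topology=top,
        time=cset.frame_times,
    )


def write_ensemble_pdb(cset: ConformationSet, frames: Sequence[int],
                       path: str) -> None:
    """Write selected frames as a multi-model PDB, one MODEL per frame.

    Models appear in the order requested in ``frames``; coordinates are
    written in Å at standard PDB precision (0.001 Å).
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        raise ValueError("frames must contain at least one index")
    if frames.min() < 0 or frames.max() >= cset.n_frames:
        raise IndexError(
            f"frame indices out of range [0, {cset.n_frames})"
        )
    traj = to_mdtraj(cset.subset(frames))
    traj.save_pdb(path)


def read_trajectory(path: str, top: str | None = None) -> ConformationSet:
    """Adapter for binary trajectory formats (XTC/DCD) via mdtraj.

    ``top`` is a PDB file supplying the topology; plain PDB input is routed
    through :func:`read_multimodel_pdb`.
    """
    import mdtraj as md

    if str(path).lower().endswith(".pdb"):
        return read_multimodel_pdb(path)
    if top is None:
        raise ValueError("binary trajectory formats require a topology PDB (top=...)")
    template = read_multimodel_pdb(top)
    traj = md.load(path, top=md.load_pdb(top, standard_names=False).topology)
    times = np.asarray(traj.time, dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(traj.n_frames, dtype=float)
    return ConformationSet(
        coords=np.asarray(traj.xyz, dtype=float),
        atom_names=template.atom_names,
        elements=template.elements,
        residue_index=template.residue_index,
        residue_name=template.residue_name,
        frame_times=times,
        masses=template.masses,
    )
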