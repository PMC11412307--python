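"""Per-frame conformational fingerprints fed to dimensionality reduction.

Three feature families characterize each frame of a trajectory:

* ``PHI_PSI`` — backbone ϕ/ψ torsions, encoded as (sin, cos) pairs so the
  ±180° wrap does not create an artificial discontinuity;
* ``CALPHA``  — internal Cα geometry: consecutive Cα–Cα distances,
  pseudo-bond angles and pseudo-dihedrals (sin/cos);
* ``SASA``    — per-atom solvent-accessible surface area over a selection.

All fingerprints are deterministic functions of the conformations and are
invariant under rigid-body motion of every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import shrake_rupley_sasa
from .traj import AtomSelection, ConformationSet

__all__ = [
    "FeatureMatrix",
    "dihedral_angle",
    "phi_psi_features",
    "calpha_features",
    "sasa_features",
]


@dataclass
class FeatureMatrix:
    """frames × features numeric table with a fingerprint kind tag."""

    values: np.ndarray
    kind: str  # PHI_PSI | CALPHA | SASA
    column_labels: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.column_labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if len(set(self.column_labels)) != len(self.column_labels):
            raise ValueError("column labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _dihedral_batch(p1, p2, p3, p4):
    """Signed torsion (degrees, atan2 convention) for stacked point arrays."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle about p2–p3 in degrees, in (−180, 180].

    Positive angles follow the IUPAC (right-hand, clockwise looking from
    p2 to p3) convention.  Raises if any three consecutive points are
    collinear (the torsion is then undefined).
    """
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    for a, b, c in ((pts[0], pts[1], pts[2]), (pts[1], pts[2], pts[3])):
        cross = np.cross(b - a, c - b)
        if np.linalg.norm(cross) < 1e-10:
            raise ValueError("collinear points: torsion undefined")
    ang = float(_dihedral_batch(*pts))
    return 180.0 if np.isclose(ang, -180.0) else ang


def _backbone_index(cset: ConformationSet, name: str) -> np.ndarray:
    """Index of backbone atom ``name`` for every residue, in residue order."""
    idx = np.full(cset.n_residues, -1, dtype=int)
    for i in range(cset.n_atoms):
        if str(cset.atom_names[i]).upper() == name:
            idx[int(cset.residue_index[i])] = i
    missing = np.nonzero(idx < 0)[0]
    if missing.size:
        raise ValueError(f"residue {int(missing[0])} lacks backbone atom {name}")
    return idx


def backbone_dihedrals(cset: ConformationSet) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) arrays in degrees.

    phi has shape (n_frames, n_residues − 1) for residues 1..n−1 (0-based),
    psi has shape (n_frames, n_residues − 1) for residues 0..n−2.
    """
    n_idx = _backbone_index(cset, "N")
    ca_idx = _backbone_index(cset, "CA")
    c_idx = _backbone_index(cset, "C")
    X = cset.coords
    phi = _dihedral_batch(X[:, c_idx[:-1]], X[:, n_idx[1:]],
                          X[:, ca_idx[1:]], X[:, c_idx[1:]])
    psi = _dihedral_batch(X[:, n_idx[:-1]], X[:, ca_idx[:-1]],
                          X[:, c_idx[:-1]], X[:, n_idx[1:]])
    return phi, psi


def phi_psi_features(cset: ConformationSet) -> FeatureMatrix:
    """ϕ/ψ torsion fingerprint: 4(n−1) columns for n residues.

    ϕ exists for residues 2..n and ψ for residues 1..n−1 (2n−2 angles);
    each angle contributes a (sin, cos) pair.
    """
    if cset.n_residues < 2:
        raise ValueError("phi/psi features require at least 2 residues")
    phi, psi = backbone_dihedrals(cset)
    rad_phi, rad_psi = np.radians(phi), np.radians(psi)
    cols, labels = [], []
    for r in range(cset.n_residues - 1):
        cols += [np.sin(rad_phi[:, r]), np.cos(rad_phi[:, r])]
        labels += [f"sin_phi_{r + 1}", f"cos_phi_{r + 1}"]
    for r in range(cset.n_residues - 1):
        cols += [np.sin(rad_psi[:, r]), np.cos(rad_psi[:, r])]
        labels += [f"sin_psi_{r}", f"cos_psi_{r}"]
    return FeatureMatrix(np.column_stack(cols), "PHI_PSI", labels)


def calpha_features(cset: ConformationSet,
                    all_pairs: bool = False) -> FeatureMatrix:
    """Cα internal-geometry fingerprint.

    Default columns for n Cα atoms: n−1 consecutive distances (nm), n−2
    pseudo-bond angles (degrees) and 2(n−3) sin/cos pseudo-dihedrals.
    With ``all_pairs=True`` the distance block instead holds all n(n−1)/2
    pairwise Cα distances.
    """
    ca = AtomSelection.calpha().resolve(cset)
    n = ca.size
    if n < 4:
        raise ValueError("Cα fingerprint requires at least 4 Cα atoms")
    X = cset.coords[:, ca]  # (F, n, 3)
    cols, labels = [], []
    if all_pairs:
        iu, ju = np.triu_indices(n, k=1)
        d = np.linalg.norm(X[:, iu] - X[:, ju], axis=2)
        for c, (i, j) in enumerate(zip(iu, ju)):
            cols.append(d[:, c])
            labels.append(f"dist_{i}_{j}")
    else:
        d = np.linalg.norm(X[:, 1:] - X[:, :-1], axis=2)
        for i in range(n - 1):
            cols.append(d[:, i])
            labels.append(f"dist_{i}_{i + 1}")
    v1 = X[:, :-2] - X[:, 1:-1]
    v2 = X[:, 2:] - X[:, 1:-1]
    cosang = np.sum(v1 * v2, axis=2) / (
        np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    for i in range(n - 2):
        cols.append(ang[:, i])
        labels.append(f"angle_{i}_{i + 1}_{i + 2}")
    tor = _dihedral_batch(X[:, :-3], X[:, 1:-2], X[:, 2:-1], X[:, 3:])
    rad = np.radians(tor)
    for i in range(n - 3):
        cols += [np.sin(rad[:, i]), np.cos(rad[:, i])]
        labels += [f"sin_tor_{i}", f"cos_tor_{i}"]
    return FeatureMatrix(np.column_stack(cols), "CALPHA", labels)


def sasa_features(cset: ConformationSet,
                  selection: AtomSelection | None = None,
                  **sasa_kwargs) -> FeatureMatrix:
    """Per-atom SASA fingerprint over a selection (default: heavy atoms)."""
    selection = selection or AtomSelection.heavy_atoms()
    sel = selection.resolve(cset)
    if sel.size == 0:
        raise ValueError("SASA fingerprint selection is empty")
    area = shrake_rupley_sasa(cset, **sasa_kwargs)[:, sel]
    # atom index in the label guarantees uniqueness even for repeated names
    labels = [
        f"sasa_{i}_{cset.atom_names[i]}_{cset.residue_index[i]}" for i in sel
    ]
    return FeatureMatrix(area, "SASA", labels)
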