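"""Global conformational descriptors of a trajectory.

Per-frame scalar series — radius of gyration (R_G), Cα end-to-end distance
(EE_DIST), total solvent-accessible surface area (SASA) and superposed RMSD —
plus per-atom RMSF and the moment statistics (mean, σ, skew, excess kurtosis,
variance) used to summarize their distributions.

Units: nm for lengths, nm² for areas, everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .traj import AtomSelection, ConformationSet

__all__ = [
    "ScalarSeries",
    "MomentSummary",
    "radius_of_gyration",
    "end_to_end_distance",
    "superpose_rmsd",
    "rmsf",
    "shrake_rupley_sasa",
    "sasa_total",
    "moment_summary",
    "BONDI_RADII",
]

# Bondi van der Waals radii (nm) for the elements seen in protein frames.
BONDI_RADII = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "SE": 0.190,
}

DEFAULT_PROBE_RADIUS = 0.14   # nm, water-sized probe
DEFAULT_SPHERE_POINTS = 960


@dataclass
class ScalarSeries:
    """One real value per frame, with a label and units ('nm' or 'nm^2')."""

    values: np.ndarray
    label: str
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.label}: non-finite values in series")


@dataclass
class MomentSummary:
    mean: float
    sd: float
    kurtosis: float  # excess: Gaussian -> 0
    skew: float
    variance: float
    degenerate: bool = False


def radius_of_gyration(cset: ConformationSet,
                       mass_weighted: bool = True) -> ScalarSeries:
    """Per-frame radius of gyration in nm.

    R_G = sqrt( Σ w_i |r_i − r̄|² / Σ w_i ) with w_i the atomic masses
    (default) or 1 for the geometric variant.
    """
    if cset.n_atoms < 1:
        raise ValueError("radius_of_gyration requires at least one atom")
    if mass_weighted:
        w = cset.masses
        if w.sum() <= 0:
            raise ValueError("total mass is zero; use mass_weighted=False")
    else:
        w = np.ones(cset.n_atoms)
    w = w / w.sum()
    center = np.einsum("a,fax->fx", w, cset.coords)
    d2 = np.sum((cset.coords - center[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("a,fa->f", w, d2))
    return ScalarSeries(rg, "RG", "nm")


def end_to_end_distance(cset: ConformationSet) -> ScalarSeries:
    """Per-frame Euclidean distance between the first and last residue Cα."""
    ca = AtomSelection.calpha().resolve(cset)
    if ca.size == 0:
        raise ValueError("no Cα atoms found")
    first_res, last_res = cset.residue_index[ca[0]], cset.residue_index[ca[-1]]
    if first_res == last_res:
        raise ValueError("end-to-end distance needs Cα in at least 2 residues")
    if first_res != cset.residue_index.min() or last_res != cset.residue_index.max():
        raise ValueError("terminal residue lacks a Cα atom")
    d = np.linalg.norm(cset.coords[:, ca[-1]] - cset.coords[:, ca[0]], axis=1)
    return ScalarSeries(d, "EE_DIST", "nm")


def _kabsch_rmsd(ref: np.ndarray, mobile: np.ndarray) -> float:
    """Minimum RMSD of mobile onto ref over translation + proper rotation."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref_c, mob_c)
    return float(rssd / np.sqrt(len(ref)))


def superpose_frames(coords: np.ndarray, reference: np.ndarray,
                     sel: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the selected atoms.

    The rotation/translation is fit on ``sel`` and applied to all atoms.
    """
    ref_sel = reference[sel]
    ref_center = ref_sel.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        mob_sel = coords[f, sel]
        mob_center = mob_sel.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_sel - ref_center, mob_sel - mob_center)
        out[f] = rot.apply(coords[f] - mob_center) + ref_center
    return out


def superpose_rmsd(cset: ConformationSet, reference_frame: int = 0,
                   selection: AtomSelection | None = None) -> ScalarSeries:
    """Per-frame Kabsch RMSD (nm) to a reference frame over a selection.

    Optimal translation + proper rotation (reflections disallowed); needs at
    least 3 non-collinear selected atoms for a unique rotation.
    """
    selection = selection or AtomSelection.calpha()
    sel = selection.resolve(cset)
    if sel.size < 3:
        raise ValueError("superposition requires at least 3 selected atoms")
    ref = cset.coords[reference_frame, sel]
    vals = np.array([_kabsch_rmsd(ref, cset.coords[f, sel])
                     for f in range(cset.n_frames)])
    return ScalarSeries(vals, "RMSD_REF", "nm")


def rmsf(cset: ConformationSet,
         selection: AtomSelection | None = None) -> np.ndarray:
    """Per-selected-atom root-mean-square fluctuation (nm).

    Frames are superposed onto the mean structure (two iterations of
    superpose → recompute mean), then the RMS deviation of each selected
    atom from its time-average position is returned.
    """
    if cset.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    selection = selection or AtomSelection.calpha()
    sel = selection.resolve(cset)
    if sel.size < 3:
        raise ValueError("RMSF superposition requires at least 3 selected atoms")
    coords = cset.coords
    reference = coords[0]
    for _ in range(2):
        coords = superpose_frames(cset.coords, reference, sel)
        reference = coords.mean(axis=0)
    fluct = coords[:, sel] - reference[None, sel]
    return np.sqrt(np.mean(np.sum(fluct ** 2, axis=2), axis=0))


def shrake_rupley_sasa(cset: ConformationSet,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_sphere_points: int = DEFAULT_SPHERE_POINTS,
                       radii: dict[str, float] | None = None) -> np.ndarray:
    """Shrake–Rupley per-frame, per-atom SASA in nm².

    Quasi-uniform test points are placed on each atom's expanded sphere
    (r_vdw + probe); the accessible fraction times the sphere area is that
    atom's SASA.  Radii default to the Bondi set.

    Returns an array of shape (n_frames, n_atoms).
    """
    from . import traj as _traj  # local import to avoid cycle at module load
    import mdtraj as md

    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    radii = radii or BONDI_RADII
    unknown = [
        f"{cset.atom_names[i]} (residue {cset.residue_index[i]})"
        for i in range(cset.n_atoms)
        if str(cset.elements[i]).upper() not in radii
    ]
    if unknown:
        raise ValueError(f"no van der Waals radius for atoms: {unknown}")
    traj = _traj.to_mdtraj(cset)
    change = {str(el): radii[str(el).upper()]
              for el in set(map(str, cset.elements))}
    area = md.shrake_rupley(traj, probe_radius=probe_radius,
                            n_sphere_points=n_sphere_points, mode="atom",
                            change_radii=change)
    return np.asarray(area, dtype=float)


def sasa_total(cset: ConformationSet, **kwargs) -> ScalarSeries:
    """Per-frame total SASA (nm²): per-atom Shrake–Rupley summed over atoms."""
    per_atom = shrake_rupley_sasa(cset, **kwargs)
    return ScalarSeries(per_atom.sum(axis=1), "SASA_TOTAL", "nm^2")


def moment_summary(series: ScalarSeries | np.ndarray) -> MomentSummary:
    """Population moments of a scalar series.

    skew = m₃/m₂^1.5 and kurtosis = m₄/m₂² − 3 (excess convention: a Gaussian
    scores 0).  A zero-variance series is flagged degenerate with skew and
    kurtosis reported as 0.
    """
    x = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("moment_summary requires at least 2 values")
    mean = float(np.mean(x))
    var = float(np.var(x))  # population
    if var == 0.0:
        return MomentSummary(mean, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    d = x - mean
    m2, m3, m4 = (float(np.mean(d ** k)) for k in (2, 3, 4))
    return MomentSummary(
        mean=mean, sd=float(np.sqrt(var)),
        kurtosis=m4 / m2 ** 2 - 3.0, skew=m3 / m2 ** 1.5, variance=var,
    )
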