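"""Seeded generator of multi-state disordered-polymer trajectories.

A disordered protein hopping between conformational basins is emulated by a
Markov chain over states, each state defined by per-residue (ϕ, ψ) targets
drawn from named Ramachandran basins (α-helix, polyproline II, extended).
Frames are built with ideal peptide geometry at the state's torsions plus
wrapped-Gaussian angular noise; matching per-frame chemical shifts are state
means plus Gaussian noise, and the reference table is the exact
stationary-weighted state mean — the infinite-time ensemble average a
converged experiment would see.

Everything is deterministic under the spec's seed, so every pipeline stage
(fingerprints, DR, clustering, ensemble design, shift validation) is
testable without MD or experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traj import ConformationSet

__all__ = [
    "BASINS",
    "SyntheticSpec",
    "three_state_spec",
    "stationary_distribution",
    "sample_state_path",
    "build_backbone",
    "generate_trajectory",
    "generate_shifts",
]

# Named Ramachandran basins: (phi, psi) in degrees.
BASINS = {
    "helix": (-60.0, -45.0),
    "ppii": (-75.0, 150.0),
    "extended": (-120.0, 120.0),
}

SHIFT_ATOMS = ("HN", "HA", "CA", "CB", "C", "N")

# Random-coil base shifts (ppm) per nucleus and the scale of per-state,
# per-residue deviations around them.
_BASE_SHIFT = {"HN": 8.30, "HA": 4.35, "CA": 56.0, "CB": 32.0,
               "C": 176.0, "N": 119.0}
_STATE_SHIFT_SD = {"HN": 0.25, "HA": 0.15, "CA": 1.5, "CB": 1.0,
                   "C": 1.2, "N": 2.5}

# Ideal backbone geometry: bond lengths (nm) and angles (degrees).
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_B_N_H, _B_CA_CB = 0.1010, 0.1521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_C_N_H, _A_C_CA_CB = 119.0, 110.1
_OMEGA = 180.0
_CHI_CB = 122.6  # torsion N-C-CA-CB placing CB at L-amino-acid geometry


@dataclass
class SyntheticSpec:
    """Parameters of the multi-state polymer generator.

    ``states`` holds per-residue (ϕ, ψ) targets per state, shape
    (n_states, n_residues, 2) in degrees; ``shift_means`` holds per
    (state, residue, atom) mean shifts in ppm, atoms ordered as
    ``SHIFT_ATOMS``.
    """

    n_residues: int
    states: np.ndarray
    transition_matrix: np.ndarray
    n_frames: int
    angular_noise_sd: float = 8.0  # degrees
    shift_noise_sd: float = 0.05   # ppm, scaled per nucleus
    shift_means: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        ns = self.states.shape[0]
        if ns < 1:
            raise ValueError("at least one state is required")
        if self.states.shape != (ns, self.n_residues, 2):
            raise ValueError("states must have shape (n_states, n_residues, 2)")
        T = self.transition_matrix
        if T.shape != (ns, ns):
            raise ValueError("transition matrix shape must match n_states")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be stochastic")
        if self.angular_noise_sd < 0 or self.shift_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.shift_means is None:
            self.shift_means = _default_shift_means(ns, self.n_residues)
        self.shift_means = np.asarray(self.shift_means, dtype=float)
        if self.shift_means.shape != (ns, self.n_residues, len(SHIFT_ATOMS)):
            raise ValueError(
                "shift_means must have shape (n_states, n_residues, n_atoms)")

    @property
    def n_states(self) -> int:
        return self.states.shape[0]


def _default_shift_means(n_states: int, n_residues: int,
                         shift_seed: int = 1729) -> np.ndarray:
    """Random-coil base + deterministic per-(state, residue) deviations.

    The deviation pattern varies along the sequence within each state, so a
    wrong state mixture in an ensemble perturbs the *profile* of shifts
    across residues (visible to r²), not just their overall offset.  The
    pattern seed is independent of the trajectory seed: replicate
    trajectories share one shift model.
    """
    rng = np.random.default_rng(shift_seed)
    means = np.empty((n_states, n_residues, len(SHIFT_ATOMS)))
    for a, atom in enumerate(SHIFT_ATOMS):
        base = _BASE_SHIFT[atom] + rng.normal(
            0.0, 0.3 * _STATE_SHIFT_SD[atom], size=n_residues)
        means[:, :, a] = base[None, :] + rng.normal(
            0.0, _STATE_SHIFT_SD[atom], size=(n_states, n_residues))
    return means


def _persistent_transition_matrix(pi: np.ndarray, mixing: float) -> np.ndarray:
    """Reversible chain with stationary ``pi``: T = (1−ε)I + ε·1πᵀ."""
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    n = pi.size
    T = mixing * np.tile(pi, (n, 1))
    T[np.diag_indices(n)] += 1.0 - mixing
    return T


def three_state_spec(n_residues: int = 12, n_frames: int = 2000,
                     occupancy: tuple[float, float, float] = (1/3, 1/3, 1/3),
                     mixing: float = 0.05, angular_noise_sd: float = 8.0,
                     shift_noise_sd: float = 0.05,
                     seed: int = 0) -> SyntheticSpec:
    """Three-basin polymer: all-helix, all-PPII and all-extended states.

    ``occupancy`` sets the stationary distribution of the Markov chain and
    ``mixing`` its switching rate (expected dwell ≈ 1/(mixing·(1−π_s))
    frames).  A small ``occupancy`` entry produces the sparse-state regime
    in which evenly strided ensembles under-sample the rare basin.
    """
    states = np.stack([
        np.tile(BASINS["helix"], (n_residues, 1)),
        np.tile(BASINS["ppii"], (n_residues, 1)),
        np.tile(BASINS["extended"], (n_residues, 1)),
    ])
    T = _persistent_transition_matrix(np.asarray(occupancy), mixing)
    return SyntheticSpec(
        n_residues=n_residues, states=states, transition_matrix=T,
        n_frames=n_frames, angular_noise_sd=angular_noise_sd,
        shift_noise_sd=shift_noise_sd, seed=seed,
    )


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_state_path(spec: SyntheticSpec,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Markov-chain state labels per frame, from a uniform initial state."""
    rng = rng or np.random.default_rng(spec.seed)
    T = spec.transition_matrix
    cum = np.cumsum(T, axis=1)
    path = np.empty(spec.n_frames, dtype=int)
    state = int(rng.integers(spec.n_states))
    for f in range(spec.n_frames):
        path[f] = state
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    return path


# ---------------------------------------------------------------------------
# Backbone construction (NeRF internal-to-Cartesian conversion)
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond: float, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom d bonded to c with |dc|=bond, angle(b,c,d) and
    torsion(a,b,c,d) as requested.  Broadcasts over leading axes."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(np.asarray(angle_deg, dtype=float))
    chi = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n_hat = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m_hat = np.cross(n_hat, bc_hat)
    d2 = (
        -np.cos(theta)[..., None] * bc_hat
        + (np.sin(theta) * np.cos(chi))[..., None] * m_hat
        - (np.sin(theta) * np.sin(chi))[..., None] * n_hat
    )
    return c + bond * d2


# atoms per residue, in order
_RES_ATOMS = ("N", "H", "CA", "CB", "C")
_RES_ELEMENTS = ("N", "H", "C", "C", "C")


def _build_frames(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Vectorized backbone builder.

    phi, psi: (n_frames, n_residues) degrees.  phi[:, 0] and psi[:, -1] do
    not influence the geometry (their torsions are undefined at the chain
    ends).  Returns coords (n_frames, 5·n_residues, 3) in nm with atoms
    ordered N, H, CA, CB, C per residue.
    """
    F, n_res = phi.shape
    coords = np.zeros((F, 5 * n_res, 3))

    def slot(res: int, name: str) -> int:
        return 5 * res + _RES_ATOMS.index(name)

    # seed residue 0 in the xy-plane
    N0 = np.zeros((F, 3))
    CA0 = np.tile([_B_N_CA, 0.0, 0.0], (F, 1))
    ang = np.radians(180.0 - _A_N_CA_C)
    C0 = CA0 + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    coords[:, slot(0, "N")] = N0
    coords[:, slot(0, "CA")] = CA0
    coords[:, slot(0, "C")] = C0
    coords[:, slot(0, "H")] = _nerf(C0, CA0, N0, _B_N_H, 118.0, 180.0)
    coords[:, slot(0, "CB")] = _nerf(
        coords[:, slot(0, "N")], C0, CA0, _B_CA_CB, _A_C_CA_CB, _CHI_CB)

    prev_N, prev_CA, prev_C = N0, CA0, C0
    for r in range(1, n_res):
        N = _nerf(prev_N, prev_CA, prev_C, _B_C_N, _A_CA_C_N, psi[:, r - 1])
        CA = _nerf(prev_CA, prev_C, N, _B_N_CA, _A_C_N_CA, _OMEGA)
        C = _nerf(prev_C, N, CA, _B_CA_C, _A_N_CA_C, phi[:, r])
        H = _nerf(prev_CA, prev_C, N, _B_N_H, _A_C_N_H, 180.0)
        CB = _nerf(N, C, CA, _B_CA_CB, _A_C_CA_CB, _CHI_CB)
        coords[:, slot(r, "N")] = N
        coords[:, slot(r, "H")] = H
        coords[:, slot(r, "CA")] = CA
        coords[:, slot(r, "CB")] = CB
        coords[:, slot(r, "C")] = C
        prev_N, prev_CA, prev_C = N, CA, C
    return coords


def _metadata(n_res: int):
    from .traj import ATOMIC_MASSES

    atom_names = np.array([nm for _ in range(n_res) for nm in _RES_ATOMS],
                          dtype=object)
    elements = np.array([el for _ in range(n_res) for el in _RES_ELEMENTS],
                        dtype=object)
    residue_index = np.repeat(np.arange(n_res), len(_RES_ATOMS))
    residue_name = np.array(["ALA"] * (5 * n_res), dtype=object)
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    return atom_names, elements, residue_index, residue_name, masses


def build_backbone(phi, psi) -> ConformationSet:
    """Single-frame backbone (N, H, CA, CB, C per residue) at given torsions.

    ``phi`` and ``psi`` are equal-length degree lists, one entry per
    residue; ϕ of the first and ψ of the last residue are undefined at the
    chain ends and ignored.  Measured torsions reproduce the inputs to
    better than 1e-6°.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be equal-length 1-D lists")
    n_res = phi.size
    coords = _build_frames(phi[None, :], psi[None, :])
    names, elements, res_idx, res_name, masses = _metadata(n_res)
    return ConformationSet(
        coords=coords, atom_names=names, elements=elements,
        residue_index=res_idx, residue_name=res_name,
        frame_times=np.array([0.0]), masses=masses,
    )


def _wrap_degrees(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


def generate_trajectory(spec: SyntheticSpec):
    """Seeded trajectory of the multi-state polymer.

    Returns (ConformationSet, state_labels).  Per frame the active state's
    (ϕ, ψ) targets receive independent wrapped-Gaussian noise before the
    backbone is rebuilt, so basins are clouds, not points.
    """
    rng = np.random.default_rng(spec.seed)
    path = sample_state_path(spec, rng)
    targets = spec.states[path]  # (F, n_res, 2)
    noise = rng.normal(0.0, spec.angular_noise_sd, size=targets.shape)
    angles = _wrap_degrees(targets + noise)
    coords = _build_frames(angles[:, :, 0], angles[:, :, 1])
    names, elements, res_idx, res_name, masses = _metadata(spec.n_residues)
    cset = ConformationSet(
        coords=coords, atom_names=names, elements=elements,
        residue_index=res_idx, residue_name=res_name,
        frame_times=np.arange(spec.n_frames, dtype=float), masses=masses,
    )
    return cset, path


def generate_shifts(spec: SyntheticSpec, labels: np.ndarray):
    """Per-frame predicted shifts and the exact reference table.

    Per-frame shift = active-state mean + Gaussian noise (the noise sd is
    ``shift_noise_sd`` scaled by each nucleus' natural spread); the
    reference is the stationary-distribution-weighted state mean with no
    noise — the converged ensemble average.

    Returns (per_frame_table, reference_table) as ShiftTables.
    """
    from .shifts import ShiftTable

    labels = np.asarray(labels, dtype=int)
    means = spec.shift_means  # (S, R, A)
    # seed offset decorrelates shift noise from the trajectory stream while
    # keeping full determinism under spec.seed
    rng = np.random.default_rng((spec.seed + 991) % (2 ** 31))
    scale = np.array([
        spec.shift_noise_sd * _STATE_SHIFT_SD[a] / _STATE_SHIFT_SD["HN"]
        for a in SHIFT_ATOMS
    ])
    F, R, A = labels.size, spec.n_residues, len(SHIFT_ATOMS)
    values = means[labels] + rng.normal(0.0, 1.0, size=(F, R, A)) * scale
    frame_col = np.repeat(np.arange(F), R * A)
    res_col = np.tile(np.repeat(np.arange(R), A), F)
    atom_col = np.tile(list(SHIFT_ATOMS), F * R)
    per_frame = ShiftTable(pd.DataFrame({
        "frame": frame_col, "res_index": res_col,
        "res_name": "ALA", "atom": atom_col,
        "shift_ppm": values.ravel(),
    }))
    pi = stationary_distribution(spec.transition_matrix)
    ref_vals = np.einsum("s,sra->ra", pi, means)
    reference = ShiftTable(pd.DataFrame({
        "frame": pd.NA, "res_index": np.repeat(np.arange(R), A),
        "res_name": "ALA", "atom": np.tile(list(SHIFT_ATOMS), R),
        "shift_ppm": ref_vals.ravel(),
    }))
    return per_frame, reference
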