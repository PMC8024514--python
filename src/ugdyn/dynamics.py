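"""Essential dynamics: superposition, Calpha covariance PCA, projections.

The PCA here is the classical essential-dynamics recipe: rigid-body
superpose every frame (iterative mean reference by default), build the
3N x 3N positional covariance of the selected atoms about the ensemble
mean (population divisor, no mass weighting), and diagonalise it.  The
leading eigenvectors are the collective modes; projecting frames or
single crystal structures onto them places conformers on a common
low-dimensional landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, SelectionError
from .structures import Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "PrincipalComponents",
    "kabsch_superpose",
    "rmsd_matched",
    "align_trajectory",
    "fuse_trajectories",
    "common_calpha_selection",
    "compute_pca",
    "project",
]


@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition: ``rotation @ x + translation``
    maps mobile coordinates onto the reference frame."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile_coords: np.ndarray, reference_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal proper rotation + translation (Kabsch, via SVD) minimising
    the weighted RMSD of mobile onto reference."""
    X = np.asarray(mobile_coords, float)
    Y = np.asarray(reference_coords, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"superposition needs >=3 atoms, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    xm = (w[:, None] * X).sum(axis=0)
    ym = (w[:, None] * Y).sum(axis=0)
    X0 = X - xm
    Y0 = Y - ym
    H = (w[:, None] * X0).T @ Y0
    if np.linalg.matrix_rank(np.cov(X0.T)) < 2:
        raise DegenerateGeometryError("collinear atom set: rotation ill-defined")
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ym - R @ xm
    moved = X @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - Y) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def rmsd_matched(
    structure_a: Structure, structure_b: Structure,
    chain_a: str | None = None, chain_b: str | None = None,
    atom_mode: str = "calpha",
) -> tuple[float, int]:
    """Superpose the residues common to both chains (matched by author
    residue number) and return (RMSD in Angstrom, number matched)."""
    if chain_a is None:
        chain_a = structure_a.first_protein_chain
    if chain_b is None:
        chain_b = structure_b.first_protein_chain
    name = {"CA"} if atom_mode == "calpha" else None

    def ca_map(st: Structure, chain: str) -> dict[int, np.ndarray]:
        out = {}
        for a in st.select(chain=chain, atom_names=name, include_het=False):
            out.setdefault(a.residue_number, a.coords)
        return out

    ma, mb = ca_map(structure_a, chain_a), ca_map(structure_b, chain_b)
    common = sorted(set(ma) & set(mb))
    if len(common) < 3:
        raise SelectionError(
            f"only {len(common)} residues in common between chains "
            f"{chain_a!r} and {chain_b!r}"
        )
    A = np.array([ma[r] for r in common])
    B = np.array([mb[r] for r in common])
    res = kabsch_superpose(A, B)
    return res.rmsd, len(common)


def _selection_indices(topology: Structure, atom_mode: str) -> np.ndarray:
    if atom_mode == "calpha":
        idx = [i for i, a in enumerate(topology.atoms)
               if a.name == "CA" and not a.is_heteroatom]
    elif atom_mode == "heavy":
        idx = [i for i, a in enumerate(topology.atoms)
               if not a.is_heteroatom and a.element.upper() != "H"]
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    if not idx:
        raise SelectionError(f"no atoms match atom_mode={atom_mode!r}")
    return np.array(idx, dtype=int)


def align_trajectory(
    trajectory: Trajectory, atom_mode: str = "calpha",
    reference: str = "iterative_mean",
    tol: float = 1e-6, max_iter: int = 20,
) -> Trajectory:
    """Rigid-body superpose every frame onto a common reference.

    ``iterative_mean`` (the covariance-analysis standard) alternates
    aligning to the running mean and re-averaging until the mean shifts by
    less than ``tol`` Angstrom; ``first_frame`` aligns once onto frame 0.
    The fit is computed on the selected atoms and applied to all atoms.
    """
    if trajectory.n_frames < 2:
        raise ValueError("alignment needs at least 2 frames")
    if reference not in ("first_frame", "iterative_mean"):
        raise ValueError(f"unknown reference {reference!r}")
    sel = _selection_indices(trajectory.topology, atom_mode)
    frames = [np.array(f, dtype=float) for f in trajectory.frames]

    def align_to(ref_sel: np.ndarray) -> list[np.ndarray]:
        out = []
        for f in frames:
            fit = kabsch_superpose(f[sel], ref_sel)
            out.append(fit.transform(f))
        return out

    if reference == "first_frame":
        aligned = align_to(frames[0][sel])
    else:
        ref = frames[0][sel]
        aligned = frames
        for _ in range(max_iter):
            aligned = [np.asarray(f) for f in align_to(ref)]
            new_ref = np.mean([f[sel] for f in aligned], axis=0)
            shift = float(np.sqrt(((new_ref - ref) ** 2).sum(axis=1).mean()))
            ref = new_ref
            frames = aligned
            if shift < tol:
                break
    return Trajectory(trajectory.topology, aligned,
                      frame_times=trajectory.frame_times,
                      source_labels=trajectory.source_labels)


AtomKey = tuple[str, int, str]  # (chain, residue number, atom name)


def common_calpha_selection(trajectories: list[Trajectory]) -> list[AtomKey]:
    """Calpha atom keys present in every topology, ordered as in the first."""
    keysets = []
    for traj in trajectories:
        keys = [(a.chain_id, a.residue_number, a.name)
                for a in traj.topology.atoms
                if a.name == "CA" and not a.is_heteroatom]
        keysets.append(keys)
    common = set(keysets[0])
    for ks in keysets[1:]:
        common &= set(ks)
    return [k for k in keysets[0] if k in common]


def _key_indices(topology: Structure, selection: list[AtomKey]) -> np.ndarray:
    lookup: dict[AtomKey, int] = {}
    for i, a in enumerate(topology.atoms):
        lookup.setdefault((a.chain_id, a.residue_number, a.name), i)
    idx = []
    for key in selection:
        if key not in lookup:
            raise SelectionError(
                f"atom {key} absent from topology of "
                f"{topology.entry_id or 'trajectory'}"
            )
        idx.append(lookup[key])
    return np.array(idx, dtype=int)


def fuse_trajectories(
    trajectories: list[Trajectory],
    common_atom_selection: list[AtomKey] | None = None,
) -> Trajectory:
    """Concatenate trajectories restricted to a common atom selection.
    Frames keep per-source labels (trajectory entry_id or its index)."""
    if not trajectories:
        raise ValueError("nothing to fuse")
    if common_atom_selection is None:
        common_atom_selection = common_calpha_selection(trajectories)
    if not common_atom_selection:
        raise SelectionError("common atom selection is empty")

    base_idx = _key_indices(trajectories[0].topology, common_atom_selection)
    base_atoms = [trajectories[0].topology.atoms[i] for i in base_idx]
    topo = Structure(base_atoms,
                     entry_id=trajectories[0].topology.entry_id or "fused")

    frames: list[np.ndarray] = []
    labels: list[str] = []
    for k, traj in enumerate(trajectories):
        idx = _key_indices(traj.topology, common_atom_selection)
        label = traj.topology.entry_id or f"traj{k}"
        for f in traj.frames:
            frames.append(f[idx])
            labels.append(label)
    return Trajectory(topo, frames, source_labels=labels)


@dataclass
class PrincipalComponents:
    """Eigendecomposition of the positional covariance of an aligned
    ensemble.  ``eigenvectors`` rows are orthonormal 3N vectors sorted by
    descending eigenvalue (Angstrom^2); ``atom_keys`` records which atoms
    the 3N layout refers to so other structures can be projected."""

    mean_coords: np.ndarray          # (3N,)
    eigenvalues: np.ndarray          # (k,), descending
    eigenvectors: np.ndarray         # (k, 3N)
    n_frames: int
    atom_selection: str
    atom_keys: list[AtomKey]

    @property
    def n_atoms(self) -> int:
        return len(self.mean_coords) // 3


def compute_pca(
    trajectory: Trajectory, atom_mode: str = "calpha",
    n_components: int | None = None, drift_warn: float = 1.0,
) -> PrincipalComponents:
    """Covariance PCA of the selected atoms over all frames.

    The input should already be aligned (``align_trajectory``); a net
    drift of the selection centroid beyond ``drift_warn`` Angstrom
    triggers a warning.  Components with numerically zero variance are
    dropped, so the returned count can be lower than requested.  Each
    eigenvector's sign is fixed so its largest-magnitude entry is
    positive.
    """
    sel = _selection_indices(trajectory.topology, atom_mode)
    F = trajectory.n_frames
    if F < 2:
        raise ValueError("PCA needs at least 2 frames")
    X = np.array([f[sel].ravel() for f in trajectory.frames])  # (F, 3N)

    centroids = X.reshape(F, -1, 3).mean(axis=1)
    drift = np.linalg.norm(centroids - centroids.mean(axis=0), axis=1).max()
    if drift > drift_warn:
        warnings.warn(
            f"selection centroid drifts {drift:.2f} A across frames; "
            "did you align the trajectory first?", stacklevel=2)

    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data; population covariance eigenvalues = s^2 / F
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s ** 2 / F
    keep = evals > max(1e-12, evals[0] * 1e-12) if evals.size else slice(0)
    evals = evals[keep]
    evecs = Vt[keep]
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:n_components]
    # deterministic sign: largest-magnitude coefficient positive
    for row in evecs:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0

    keys = [(a.chain_id, a.residue_number, a.name)
            for a in (trajectory.topology.atoms[i] for i in sel)]
    return PrincipalComponents(
        mean_coords=mean, eigenvalues=evals, eigenvectors=evecs,
        n_frames=F, atom_selection=atom_mode, atom_keys=keys,
    )


def project(
    pcs: PrincipalComponents,
    coords_or_trajectory: Trajectory | Structure | np.ndarray,
    components: list[int] = (1, 2),
) -> np.ndarray:
    """Project frames or a single structure onto the chosen components
    (1-based).  Returns an (n_frames, n_components) array; a single
    structure gives one row.

    A crystal structure with unresolved residues is projected on the
    atoms it shares with the PCA selection: the mean and eigenvectors are
    restricted pairwise to those atoms (an approximation — the restricted
    eigenvectors are no longer exactly orthonormal).
    """
    comp_idx = [c - 1 for c in components]
    if any(c < 0 or c >= len(pcs.eigenvalues) for c in comp_idx):
        raise ValueError(f"components {list(components)} out of range "
                         f"(have {len(pcs.eigenvalues)})")

    if isinstance(coords_or_trajectory, Trajectory):
        idx = _key_indices(coords_or_trajectory.topology, pcs.atom_keys)
        X = np.array([f[idx].ravel() for f in coords_or_trajectory.frames])
        return (X - pcs.mean_coords) @ pcs.eigenvectors[comp_idx].T

    if isinstance(coords_or_trajectory, Structure):
        st = coords_or_trajectory
        lookup: dict[AtomKey, np.ndarray] = {}
        for a in st.atoms:
            lookup.setdefault((a.chain_id, a.residue_number, a.name), a.coords)
        present = [i for i, k in enumerate(pcs.atom_keys) if k in lookup]
        if len(present) < 3:
            raise SelectionError("structure shares <3 atoms with the PCA selection")
        flat_idx = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in present])
        x = np.concatenate([lookup[pcs.atom_keys[i]] for i in present])
        diff = x - pcs.mean_coords[flat_idx]
        return (diff @ pcs.eigenvectors[np.ix_(comp_idx, flat_idx)].T)[None, :]

    X = np.asarray(coords_or_trajectory, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(pcs.mean_coords):
        raise SelectionError(
            f"coordinate length {X.shape[1]} does not match PCA layout "
            f"{len(pcs.mean_coords)}"
        )
    return (X - pcs.mean_coords) @ pcs.eigenvectors[comp_idx].T
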