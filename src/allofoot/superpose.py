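"""Rigid-body superposition and steric-clash assessment.

Receptor-HLA complexes (TCR, KIR, CD8) are brought into the frame of the
Fab-HLA complex by least-squares superposition (Kabsch) of the shared HLA
alpha chain, fit on CA atoms of common numbered positions (alpha1-alpha2
domain, positions 1-180, by default). Steric compatibility of the Fab with
each superposed receptor is then scored as the number of heavy-atom pairs
whose van der Waals spheres interpenetrate beyond a tolerance (0.4 A, the
common steric-clash convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _chem
from .structure import Structure, atom_table


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float = 0.0
    n_fit_atoms: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (determinant +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares proper rotation + translation mapping points P onto Q.

    Reflections are corrected by sign-flipping the smallest singular
    direction, so the result is always a proper rotation.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    # degenerate (collinear) configurations leave the rotation underdetermined
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd, len(P))


def transform_structure(structure: Structure, tf: RigidTransform) -> Structure:
    out = structure.copy()
    for residues in out.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.coord = tf.apply(atom.coord[None, :])[0]
    return out


def superpose_by_shared_chain(
    target: Structure,
    mobile: Structure,
    shared_role: str = "hla_alpha",
    fit_positions: Sequence[int] | range = range(1, 181),
) -> tuple[Structure, RigidTransform]:
    """Superpose ``mobile`` onto ``target`` via CA atoms of the chain both
    structures assign to ``shared_role`` at common numbered positions."""
    ct = target.chain_for_role(shared_role)
    cm = mobile.chain_for_role(shared_role)
    ca_t = {r.seq_position: r.ca.coord for r in target.chains[ct] if r.ca is not None}
    ca_m = {r.seq_position: r.ca.coord for r in mobile.chains[cm] if r.ca is not None}
    common = [p for p in fit_positions if p in ca_t and p in ca_m]
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 common CA positions in the fit range, got {len(common)}")
    tf = kabsch(np.array([ca_m[p] for p in common]), np.array([ca_t[p] for p in common]))
    return transform_structure(mobile, tf), tf


@dataclass
class ClashReport:
    clash_pairs: list[tuple[tuple[str, int, str], tuple[str, int, str], float, float]]
    min_distance: float
    n_clashes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_clashes = len(self.clash_pairs)


def detect_clashes(
    fixed: Structure,
    fixed_chains: Iterable[str],
    moved: Structure,
    moved_chains: Iterable[str],
    overlap_tolerance: float = 0.4,
    radii: dict[str, float] | None = None,
) -> ClashReport:
    """Heavy-atom van der Waals clashes between two chain sets in one frame.

    A pair clashes when r_vdw(a) + r_vdw(b) - distance > overlap_tolerance.
    ``clash_pairs`` entries are ((chain, pos, atom), (chain, pos, atom),
    distance, overlap).
    """
    radii = radii or _chem.VDW_RADII
    ta = atom_table(fixed, list(fixed_chains))
    tb = atom_table(moved, list(moved_chains))
    ra = np.array([_chem.vdw_radius(e, radii) for e in ta.elements])
    rb = np.array([_chem.vdw_radius(e, radii) for e in tb.elements])
    reach = float(ra.max() + rb.max()) - overlap_tolerance
    tree_b = cKDTree(tb.coords)
    pairs = []
    min_d = np.inf
    for i, hits in enumerate(cKDTree(ta.coords).query_ball_tree(tree_b, r=max(reach, 0.1))):
        for j in hits:
            d = float(np.linalg.norm(ta.coords[i] - tb.coords[j]))
            min_d = min(min_d, d)
            overlap = ra[i] + rb[j] - d
            if overlap > overlap_tolerance:
                pairs.append((
                    (ta.chain_ids[i], int(ta.res_positions[i]), ta.atom_names[i]),
                    (tb.chain_ids[j], int(tb.res_positions[j]), tb.atom_names[j]),
                    d, float(overlap),
                ))
    if not np.isfinite(min_d):
        # no pair within clash reach; report the true global minimum
        d, _ = tree_b.query(ta.coords, k=1)
        min_d = float(np.min(d))
    return ClashReport(sorted(pairs, key=lambda p: -p[3]), float(min_d))
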