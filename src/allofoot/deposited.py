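"""Role detection and analysis entry points for deposited crystal structures.

Crystal asymmetric units may hold several copies of a Fab-HLA complex and
give no machine-readable chain roles, so this module classifies chains by
polymer length (HLA alpha ~275, beta-2-microglobulin ~99, peptide <= 15,
Fab chains 150-250 residues), groups them into complex copies by spatial
proximity, and disambiguates the Fab heavy from the light chain by which
of the two touches beta-2-microglobulin (the heavy chain carries the
beta-2-microglobulin patch in the lateral binding mode analysed here).
Analyses run on one copy (the first complete one by default).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .interface import HbondCriteria, InterfaceReport, SasaParams, analyze_interface
from .structure import Structure, StructureError, parse_structure
from .superpose import ClashReport, detect_clashes, superpose_by_shared_chain


def _centroid(structure: Structure, chain_id: str) -> np.ndarray:
    coords = [a.coord for r in structure.chains[chain_id] for a in r.atoms]
    return np.mean(coords, axis=0)


def _min_distance(structure: Structure, c1: str, c2: str) -> float:
    from scipy.spatial import cKDTree

    a = np.array([a.coord for r in structure.chains[c1] for a in r.atoms])
    b = np.array([a.coord for r in structure.chains[c2] for a in r.atoms])
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.min(d))


def classify_chains(structure: Structure) -> dict[str, list[str]]:
    """Bucket chains by polymer length."""
    buckets: dict[str, list[str]] = {"hla_alpha": [], "b2m": [], "peptide": [], "fab": [], "other": []}
    for cid, residues in structure.chains.items():
        n = len(residues)
        if n <= 15:
            buckets["peptide"].append(cid)
        elif 60 <= n <= 130:
            buckets["b2m"].append(cid)
        elif 250 <= n <= 320:
            buckets["hla_alpha"].append(cid)
        elif 150 <= n < 250:
            buckets["fab"].append(cid)
        else:
            buckets["other"].append(cid)
    return buckets


def select_fab_hla_copy(structure: Structure, copy_index: int = 0) -> Structure:
    """Assign roles for one Fab-HLA complex copy in the asymmetric unit.

    Copies are formed around each HLA alpha chain by nearest-partner
    matching; the Fab chain in contact with beta-2-microglobulin is the
    heavy chain.
    """
    buckets = classify_chains(structure)
    if not buckets["hla_alpha"]:
        raise StructureError("no HLA-alpha-sized chain (250-320 residues) found")
    alphas = sorted(buckets["hla_alpha"], key=lambda c: _centroid(structure, c)[0])
    if copy_index >= len(alphas):
        raise StructureError(f"copy {copy_index} requested but only {len(alphas)} copies present")
    alpha = alphas[copy_index]

    def nearest(candidates: list[str]) -> str | None:
        if not candidates:
            return None
        return min(candidates, key=lambda c: _min_distance(structure, alpha, c))

    b2m = nearest(buckets["b2m"])
    peptide = nearest(buckets["peptide"])
    fab_near = sorted(buckets["fab"], key=lambda c: _min_distance(structure, alpha, c))[:2]
    if len(fab_near) < 2:
        raise StructureError("could not locate two Fab-sized chains near the alpha chain")
    if b2m is None:
        raise StructureError("no beta-2-microglobulin-sized chain found")
    heavy = min(fab_near, key=lambda c: _min_distance(structure, b2m, c))
    light = next(c for c in fab_near if c != heavy)
    role_map = {alpha: "hla_alpha", b2m: "b2m", heavy: "fab_heavy", light: "fab_light"}
    if peptide is not None:
        role_map[peptide] = "peptide"
    out = structure.copy()
    out.role_map = role_map
    return out


def select_receptor_hla_copy(structure: Structure, copy_index: int = 0) -> Structure:
    """Assign roles for a receptor-HLA complex: alpha/b2m/peptide by length,
    every other polymer chain of the copy as 'receptor'."""
    buckets = classify_chains(structure)
    if not buckets["hla_alpha"]:
        raise StructureError("no HLA-alpha-sized chain found")
    alphas = sorted(buckets["hla_alpha"], key=lambda c: _centroid(structure, c)[0])
    if copy_index >= len(alphas):
        raise StructureError(f"copy {copy_index} requested but only {len(alphas)} copies present")
    alpha = alphas[copy_index]
    role_map = {alpha: "hla_alpha"}
    if buckets["b2m"]:
        role_map[min(buckets["b2m"], key=lambda c: _min_distance(structure, alpha, c))] = "b2m"
    if buckets["peptide"]:
        role_map[min(buckets["peptide"], key=lambda c: _min_distance(structure, alpha, c))] = "peptide"
    # receptor chains: anything Fab/other-sized in contact with this copy
    core = set(role_map)
    for cid in buckets["fab"] + buckets["other"]:
        if cid in core:
            continue
        if min(_min_distance(structure, cid, c) for c in core) < 6.0:
            role_map[cid] = "receptor"
    if "receptor" not in role_map.values():
        raise StructureError("no receptor chain in contact with the HLA copy")
    out = structure.copy()
    out.role_map = role_map
    return out


def analyze_deposited_fab_hla(
    path: str | Path,
    copy_index: int = 0,
    sasa_params: SasaParams | None = None,
    hbond_criteria: HbondCriteria | None = None,
    contact_cutoff: float = 4.0,
    gap_tolerance: int = 3,
) -> tuple[Structure, InterfaceReport]:
    """Parse a deposited Fab-HLA complex, pick one copy, analyze its interface."""
    st = select_fab_hla_copy(parse_structure(path), copy_index)
    return st, analyze_interface(st, sasa_params, hbond_criteria, contact_cutoff, gap_tolerance)


def coengagement_clashes(
    fab_complex: Structure,
    receptor_path: str | Path,
    fit_positions: range = range(1, 181),
    overlap_tolerance: float = 0.4,
) -> tuple[ClashReport, float]:
    """Superpose a deposited receptor-HLA complex onto the Fab-HLA complex
    via the shared alpha chain and count Fab-receptor clashes."""
    mobile = select_receptor_hla_copy(parse_structure(receptor_path))
    moved, tf = superpose_by_shared_chain(fab_complex, mobile, "hla_alpha", fit_positions)
    fab_chains = [fab_complex.chain_for_role(r) for r in ("fab_heavy", "fab_light")]
    receptor_chains = [c for c, r in moved.role_map.items() if r == "receptor"]
    report = detect_clashes(fab_complex, fab_chains, moved, receptor_chains, overlap_tolerance)
    return report, tf.rmsd
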