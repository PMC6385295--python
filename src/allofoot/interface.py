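"""Antibody-antigen interface analysis.

Quantifies how a Fab engages a class-I HLA molecule: solvent-accessible
surface area (SASA) by the Shrake-Rupley method, the buried footprint on
the HLA side decomposed per Fab chain, residue-residue contacts, geometric
hydrogen bonds, the epitope residue set with its discontinuous segments
along the alpha chain, and binding-induced backbone displacement relative
to an unbound reference structure.

Area conventions
----------------
The footprint is the one-sided loss of SASA on the HLA side (alpha chain +
beta-2-microglobulin by default; the presented peptide is excluded unless
requested). The per-Fab-chain decomposition attributes every surface
sample point that the Fab newly occludes to the occluding Fab atom's chain
(nearest occluding surface on ties), which makes the decomposition sum to
the total footprint exactly, by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _chem
from .structure import AtomTable, Structure, atom_table

HLA_SIDE_ROLES = ("hla_alpha", "b2m")
FAB_SIDE_ROLES = ("fab_heavy", "fab_light")


# ---------------------------------------------------------------------------
# parameters


@dataclass
class SasaParams:
    """Parameters of the Shrake-Rupley surface calculation.

    probe_radius is the water-probe radius in Angstrom; n_sphere_points
    controls the deterministic golden-spiral lattice on each atomic sphere.
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_set: Mapping[str, float] = field(default_factory=lambda: dict(_chem.VDW_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 100:
            raise ValueError("n_sphere_points must be at least 100")


@dataclass
class HbondCriteria:
    """Heavy-atom geometric hydrogen-bond criteria (no modeled hydrogens).

    A donor-acceptor pair counts if the donor-acceptor distance is at most
    ``max_donor_acceptor_distance`` and the angle at each end between the
    bonded antecedent, the end atom and the partner atom is at least
    ``min_donor_angle`` (an antecedent-angle proxy for near-linear D-H...A
    geometry that needs no hydrogen positions).
    """

    max_donor_acceptor_distance: float = 3.5
    min_donor_angle: float = 90.0

    def __post_init__(self) -> None:
        if not 2.2 < self.max_donor_acceptor_distance <= 4.0:
            raise ValueError("max_donor_acceptor_distance must be in (2.2, 4.0]")
        if not 0.0 <= self.min_donor_angle <= 180.0:
            raise ValueError("min_donor_angle must be in [0, 180]")


@dataclass(frozen=True)
class ResidueRef:
    chain_id: str
    position: int
    aa: str

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.aa}{self.position}"


@dataclass
class ContactRecord:
    residue_a: ResidueRef            # antigen (HLA) side
    residue_b: ResidueRef            # antibody (Fab) side
    min_heavy_atom_distance: float
    kind: str = "nonbonded"          # nonbonded | hbond | salt_bridge
    atom_a: str | None = None
    atom_b: str | None = None


@dataclass
class InterfaceReport:
    pair_bsa: dict[tuple[str, str], float]
    total_footprint: float
    epitope_residues: set[tuple[str, int]]
    segments: list[list[int]]
    contacts: list[ContactRecord]
    hbonds: list[ContactRecord]

    def hbonded_positions(self, chain_role_chain_id: str) -> set[int]:
        """Alpha-chain positions whose residue takes part in any H-bond."""
        return {hb.residue_a.position for hb in self.hbonds
                if hb.residue_a.chain_id == chain_role_chain_id}

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "pair_bsa": {f"{a}:{b}": round(v, 2) for (a, b), v in self.pair_bsa.items()},
            "total_footprint": round(self.total_footprint, 2),
            "epitope_residues": sorted([c, p] for c, p in self.epitope_residues),
            "segments": self.segments,
            "contacts": [asdict(c) for c in self.contacts],
            "hbonds": [asdict(h) for h in self.hbonds],
        }
        return json.dumps(payload, indent=indent, default=str)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _radii_for(table: AtomTable, params: SasaParams) -> np.ndarray:
    radii = np.empty(len(table))
    for i, el in enumerate(table.elements):
        key = el.upper()
        if key not in params.radii_set:
            raise KeyError(
                f"no van der Waals radius for element {el!r} "
                f"(atom {table.atom_names[i]} in {table.chain_ids[i]}/{table.res_positions[i]})"
            )
        radii[i] = params.radii_set[key]
    return radii


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (A^2) on the golden-spiral lattice; bit-reproducible."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    pts = golden_spiral_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    pairs = tree.query_ball_tree(tree, r=2.0 * float(np.max(expanded)))
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        ri = expanded[i]
        neigh = [j for j in pairs[i]
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        sample = coords[i] + ri * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", sample - coords[j], sample - coords[j])
            accessible &= d2 >= expanded[j] ** 2
        areas[i] = 4.0 * np.pi * ri * ri * np.count_nonzero(accessible) / n_points
    return areas


def compute_sasa(
    structure: Structure,
    params: SasaParams | None = None,
    subset: Iterable[str] | None = None,
) -> tuple[AtomTable, np.ndarray]:
    """SASA of the atoms of ``subset`` chains (default: all), in isolation
    from every chain outside the subset."""
    params = params or SasaParams()
    table = atom_table(structure, subset)
    radii = _radii_for(table, params)
    return table, shrake_rupley(table.coords, radii, params.probe_radius, params.n_sphere_points)


def buried_surface_area(
    structure: Structure,
    side_a: Iterable[str],
    side_b: Iterable[str],
    params: SasaParams | None = None,
) -> float:
    """One-sided buried area: SASA lost by ``side_a`` on adding ``side_b``."""
    params = params or SasaParams()
    side_a, side_b = list(side_a), list(side_b)
    if not side_a or not side_b:
        raise ValueError("both sides must name at least one chain")
    if set(side_a) & set(side_b):
        raise ValueError("sides must be disjoint")
    _, alone = compute_sasa(structure, params, side_a)
    table_all, together = compute_sasa(structure, params, side_a + side_b)
    in_a = np.array([c in set(side_a) for c in table_all.chain_ids])
    return float(np.sum(alone) - np.sum(together[in_a]))


def pairwise_bsa_decomposition(
    structure: Structure,
    params: SasaParams | None = None,
    include_peptide: bool = False,
) -> dict[tuple[str, str], float]:
    """Footprint on each HLA-side chain decomposed by occluding Fab chain.

    Every golden-spiral sample point of an HLA-side atom that is solvent
    accessible with the Fab absent but occluded with the Fab present is
    attributed to the Fab chain whose atom buries it most deeply (largest
    van der Waals overlap with the sample point); the per-pair sums are
    therefore an exact partition of the one-sided footprint. Keys are
    (HLA-side role, Fab-side role).
    """
    params = params or SasaParams()
    present = set(structure.role_map.values())
    if "hla_alpha" not in present:
        raise ValueError("role map incomplete: missing 'hla_alpha'")
    fab_roles = [r for r in FAB_SIDE_ROLES if r in present]
    if not fab_roles:
        raise ValueError("role map incomplete: no Fab chain assigned")
    hla_roles = [r for r in HLA_SIDE_ROLES if r in present]
    if include_peptide and "peptide" in present:
        hla_roles.append("peptide")
    hla_chains = [structure.chain_for_role(r) for r in hla_roles]
    fab_chains = {structure.chain_for_role(r): r for r in fab_roles}

    table_h = atom_table(structure, hla_chains)
    radii_h = _radii_for(table_h, params) + params.probe_radius
    table_f = atom_table(structure, list(fab_chains))
    radii_f = _radii_for(table_f, params) + params.probe_radius
    pts = golden_spiral_points(params.n_sphere_points)

    tree_h = cKDTree(table_h.coords)
    tree_f = cKDTree(table_f.coords)
    rmax = float(max(radii_h.max(), radii_f.max()))
    neigh_h = tree_h.query_ball_tree(tree_h, r=2.0 * rmax)
    neigh_f = tree_h.query_ball_tree(tree_f, r=2.0 * rmax)

    role_of_hla_chain = {structure.chain_for_role(r): r for r in hla_roles}
    pair_bsa: dict[tuple[str, str], float] = {
        (hr, fr): 0.0 for hr in hla_roles for fr in fab_roles
    }

    per_point = 4.0 * np.pi / params.n_sphere_points
    for i in range(len(table_h)):
        ri = radii_h[i]
        ci = table_h.coords[i]
        sample = ci + ri * pts
        free = np.ones(params.n_sphere_points, dtype=bool)
        for j in neigh_h[i]:
            if j == i or np.linalg.norm(table_h.coords[j] - ci) >= ri + radii_h[j]:
                continue
            d2 = np.einsum("ij,ij->i", sample - table_h.coords[j], sample - table_h.coords[j])
            free &= d2 >= radii_h[j] ** 2
        if not free.any():
            continue
        fneigh = [j for j in neigh_f[i]
                  if np.linalg.norm(table_f.coords[j] - ci) < ri + radii_f[j]]
        if not fneigh:
            continue
        # depth of burial of each free point inside each nearby Fab sphere
        best_depth = np.full(params.n_sphere_points, -np.inf)
        best_chain = np.full(params.n_sphere_points, -1, dtype=int)
        fab_chain_list = list(fab_chains)
        for j in fneigh:
            d = np.linalg.norm(sample - table_f.coords[j], axis=1)
            depth = radii_f[j] - d
            covered = free & (depth > 0)
            better = covered & (depth > best_depth)
            best_depth[better] = depth[better]
            best_chain[better] = fab_chain_list.index(table_f.chain_ids[j])
        hr = role_of_hla_chain[table_h.chain_ids[i]]
        area_point = per_point * ri * ri
        for k, fc in enumerate(fab_chain_list):
            n_pts = int(np.count_nonzero(best_chain == k))
            if n_pts:
                pair_bsa[(hr, fab_chains[fc])] += n_pts * area_point
    return pair_bsa


# ---------------------------------------------------------------------------
# contacts and hydrogen bonds


def _cross_side_tables(
    structure: Structure,
    side_a_chains: Sequence[str] | None,
    side_b_chains: Sequence[str] | None,
    include_peptide: bool,
) -> tuple[AtomTable, AtomTable]:
    if side_a_chains is None:
        roles = list(HLA_SIDE_ROLES) + (["peptide"] if include_peptide else [])
        side_a_chains = [structure.chain_for_role(r) for r in roles
                         if r in structure.role_map.values()]
    if side_b_chains is None:
        side_b_chains = [structure.chain_for_role(r) for r in FAB_SIDE_ROLES
                         if r in structure.role_map.values()]
    if not side_a_chains or not side_b_chains:
        raise ValueError("role map does not define both interface sides")
    return atom_table(structure, side_a_chains), atom_table(structure, side_b_chains)


def find_contacts(
    structure: Structure,
    cutoff: float = 4.0,
    side_a_chains: Sequence[str] | None = None,
    side_b_chains: Sequence[str] | None = None,
    hbond_criteria: HbondCriteria | None = None,
    include_peptide: bool = False,
) -> list[ContactRecord]:
    """Cross-side residue pairs whose closest heavy atoms are within ``cutoff``.

    Pairs are annotated as hydrogen bonds (geometric criteria), salt bridges
    (opposite formal charges with charged-group atoms within 4.0 A) or plain
    nonbonded contacts. Sides default to HLA vs Fab from the role map.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ta, tb = _cross_side_tables(structure, side_a_chains, side_b_chains, include_peptide)
    pairs = cKDTree(ta.coords).query_ball_tree(cKDTree(tb.coords), r=cutoff)
    best: dict[tuple, tuple[float, str, str]] = {}
    for i, hits in enumerate(pairs):
        for j in hits:
            d = float(np.linalg.norm(ta.coords[i] - tb.coords[j]))
            if d > cutoff:
                continue
            key = (ta.chain_ids[i], int(ta.res_positions[i]), ta.res_codes[i],
                   tb.chain_ids[j], int(tb.res_positions[j]), tb.res_codes[j])
            if key not in best or d < best[key][0]:
                best[key] = (d, ta.atom_names[i], tb.atom_names[j])

    hb = detect_hbonds(structure, hbond_criteria or HbondCriteria(),
                       side_a_chains=list(dict.fromkeys(ta.chain_ids)),
                       side_b_chains=list(dict.fromkeys(tb.chain_ids)))
    hb_pairs = {(h.residue_a.chain_id, h.residue_a.position,
                 h.residue_b.chain_id, h.residue_b.position) for h in hb}
    salt = _salt_bridge_pairs(ta, tb)

    out = []
    for (ca, pa, aa, cb, pb, ab), (d, na, nb) in sorted(best.items()):
        kind = "nonbonded"
        if (ca, pa, cb, pb) in hb_pairs:
            kind = "hbond"
        elif (ca, pa, cb, pb) in salt:
            kind = "salt_bridge"
        out.append(ContactRecord(ResidueRef(ca, pa, aa), ResidueRef(cb, pb, ab), d, kind, na, nb))
    return out


def _salt_bridge_pairs(ta: AtomTable, tb: AtomTable, cutoff: float = 4.0) -> set[tuple]:
    def charged(table: AtomTable, sign: int) -> list[int]:
        src = _chem.POSITIVE_ATOMS if sign > 0 else _chem.NEGATIVE_ATOMS
        return [i for i in range(len(table))
                if table.atom_names[i] in src.get(table.res_names3[i], ())]

    found: set[tuple] = set()
    for sa, sb in ((1, -1), (-1, 1)):
        ia, ib = charged(ta, sa), charged(tb, sb)
        if not ia or not ib:
            continue
        tree = cKDTree(tb.coords[ib])
        for i in ia:
            for k in tree.query_ball_point(ta.coords[i], r=cutoff):
                j = ib[k]
                found.add((ta.chain_ids[i], int(ta.res_positions[i]),
                           tb.chain_ids[j], int(tb.res_positions[j])))
    return found


def _donors_acceptors(table: AtomTable) -> tuple[list[tuple[int, list[int]]], list[tuple[int, list[int]]]]:
    """Indices of donor/acceptor atoms with indices of their antecedents."""
    # index atoms by (chain, pos, name) for antecedent lookup
    by_key = {(table.chain_ids[i], int(table.res_positions[i]), table.atom_names[i]): i
              for i in range(len(table))}

    def resolve(i: int, names: tuple[str, ...]) -> list[int]:
        key_base = (table.chain_ids[i], int(table.res_positions[i]))
        return [by_key[key_base + (n,)] for n in names if key_base + (n,) in by_key]

    donors, acceptors = [], []
    for i in range(len(table)):
        res3, name = table.res_names3[i], table.atom_names[i]
        if name in _chem.BACKBONE_DONOR and res3 != "PRO":
            donors.append((i, resolve(i, _chem.BACKBONE_DONOR[name])))
        if name in _chem.BACKBONE_ACCEPTOR:
            acceptors.append((i, resolve(i, _chem.BACKBONE_ACCEPTOR[name])))
        if name in _chem.SIDECHAIN_DONORS.get(res3, {}):
            donors.append((i, resolve(i, _chem.SIDECHAIN_DONORS[res3][name])))
        if name in _chem.SIDECHAIN_ACCEPTORS.get(res3, {}):
            acceptors.append((i, resolve(i, _chem.SIDECHAIN_ACCEPTORS[res3][name])))
    return donors, acceptors


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-300)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    structure: Structure,
    criteria: HbondCriteria | None = None,
    side_a_chains: Sequence[str] | None = None,
    side_b_chains: Sequence[str] | None = None,
    include_peptide: bool = False,
) -> list[ContactRecord]:
    """Geometric hydrogen bonds across the interface (heavy atoms only).

    Both donor-on-side-a/acceptor-on-side-b and the reverse are searched;
    records are deduplicated per donor-acceptor atom pair and reported with
    residue_a on side a.
    """
    criteria = criteria or HbondCriteria()
    ta, tb = _cross_side_tables(structure, side_a_chains, side_b_chains, include_peptide)
    bonds: dict[tuple, ContactRecord] = {}

    def scan(t_from: AtomTable, t_to: AtomTable, flip: bool) -> None:
        donors, _ = _donors_acceptors(t_from)
        _, acceptors = _donors_acceptors(t_to)
        if not donors or not acceptors:
            return
        acc_idx = [i for i, _ in acceptors]
        acc_ante = {i: a for i, a in acceptors}
        tree = cKDTree(t_to.coords[acc_idx])
        for di, d_ante in donors:
            for k in tree.query_ball_point(t_from.coords[di], r=criteria.max_donor_acceptor_distance):
                ai = acc_idx[k]
                d = float(np.linalg.norm(t_from.coords[di] - t_to.coords[ai]))
                if d > criteria.max_donor_acceptor_distance:
                    continue
                ok_d = (not d_ante) or any(
                    _angle(t_from.coords[x], t_from.coords[di], t_to.coords[ai]) >= criteria.min_donor_angle
                    for x in d_ante)
                ok_a = (not acc_ante[ai]) or any(
                    _angle(t_from.coords[di], t_to.coords[ai], t_to.coords[x]) >= criteria.min_donor_angle
                    for x in acc_ante[ai])
                if not (ok_d and ok_a):
                    continue
                ra = ResidueRef(t_from.chain_ids[di], int(t_from.res_positions[di]), t_from.res_codes[di])
                rb = ResidueRef(t_to.chain_ids[ai], int(t_to.res_positions[ai]), t_to.res_codes[ai])
                na, nb = t_from.atom_names[di], t_to.atom_names[ai]
                if flip:
                    ra, rb, na, nb = rb, ra, nb, na
                key = (ra.chain_id, ra.position, na, rb.chain_id, rb.position, nb)
                rec = ContactRecord(ra, rb, d, "hbond", na, nb)
                if key not in bonds or d < bonds[key].min_heavy_atom_distance:
                    bonds[key] = rec

    scan(ta, tb, flip=False)
    scan(tb, ta, flip=True)
    return sorted(bonds.values(),
                  key=lambda h: (h.residue_a.chain_id, h.residue_a.position, h.atom_a or "",
                                 h.residue_b.chain_id, h.residue_b.position, h.atom_b or ""))


# ---------------------------------------------------------------------------
# epitope footprint and segments


def epitope_segments(positions: Iterable[int], gap_tolerance: int = 3) -> list[list[int]]:
    """Partition sorted epitope positions into maximal runs where consecutive
    members differ by at most ``gap_tolerance``."""
    pos = sorted(set(positions))
    if not pos:
        return []
    segments: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - segments[-1][-1] <= gap_tolerance:
            segments[-1].append(p)
        else:
            segments.append([p])
    return segments


def epitope_footprint(
    contacts: Sequence[ContactRecord],
    alpha_chain_id: str,
    gap_tolerance: int = 3,
) -> tuple[set[tuple[str, int]], list[list[int]]]:
    """Epitope residue set (antigen side of each contact) and the maximal
    runs of alpha-chain epitope positions."""
    residues = {(c.residue_a.chain_id, c.residue_a.position) for c in contacts}
    alpha_positions = [p for c, p in residues if c == alpha_chain_id]
    return residues, epitope_segments(alpha_positions, gap_tolerance)


# ---------------------------------------------------------------------------
# conformational change vs unbound reference


def per_residue_displacement(
    bound: Structure,
    unbound: Structure,
    align_on: Sequence[int] | range,
    chain_role: str = "hla_alpha",
) -> dict[int, float]:
    """CA displacement per shared position after rigid superposition of the
    unbound chain onto the bound one, fit on CA atoms of ``align_on``."""
    from .superpose import kabsch

    cb = bound.chain_for_role(chain_role)
    cu = unbound.chain_for_role(chain_role)
    ca_b = {r.seq_position: r.ca.coord for r in bound.chains[cb] if r.ca is not None}
    ca_u = {r.seq_position: r.ca.coord for r in unbound.chains[cu] if r.ca is not None}
    fit = [p for p in align_on if p in ca_b and p in ca_u]
    if len(fit) < 3:
        raise ValueError(f"need at least 3 shared alignment positions, got {len(fit)}")
    tf = kabsch(np.array([ca_u[p] for p in fit]), np.array([ca_b[p] for p in fit]))
    shared = sorted(set(ca_b) & set(ca_u))
    moved = tf.apply(np.array([ca_u[p] for p in shared]))
    ref = np.array([ca_b[p] for p in shared])
    return {p: float(np.linalg.norm(moved[i] - ref[i])) for i, p in enumerate(shared)}


# ---------------------------------------------------------------------------
# one-call report


def analyze_interface(
    structure: Structure,
    sasa_params: SasaParams | None = None,
    hbond_criteria: HbondCriteria | None = None,
    contact_cutoff: float = 4.0,
    gap_tolerance: int = 3,
    include_peptide: bool = False,
) -> InterfaceReport:
    """Full interface report for a role-assigned Fab-HLA complex."""
    sasa_params = sasa_params or SasaParams()
    hbond_criteria = hbond_criteria or HbondCriteria()
    pair_bsa = pairwise_bsa_decomposition(structure, sasa_params, include_peptide)
    contacts = find_contacts(structure, contact_cutoff,
                             hbond_criteria=hbond_criteria, include_peptide=include_peptide)
    hbonds = [c for c in contacts if c.kind == "hbond"]
    hbond_records = detect_hbonds(structure, hbond_criteria, include_peptide=include_peptide)
    alpha = structure.chain_for_role("hla_alpha")
    residues, segments = epitope_footprint(contacts, alpha, gap_tolerance)
    return InterfaceReport(
        pair_bsa=pair_bsa,
        total_footprint=float(sum(pair_bsa.values())),
        epitope_residues=residues,
        segments=segments,
        contacts=contacts,
        hbonds=hbond_records,
    )
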