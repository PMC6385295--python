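"""Synthetic inputs with known ground truth for every pipeline stage.

Toy complexes are built from idealized residue templates (fixed internal
geometry, side chains extended along one axis), so every planted contact,
hydrogen bond and buried patch is known by construction; ground truth is
recomputed here with plain all-pairs arithmetic, independent of the
neighbor-search production code, and buried areas come from the
Gauss-Legendre quadrature oracle. Allele panels, single-cycle sensorgrams
and cytotoxicity replicate tables are generated with seeded randomness and
carry their truth labels/parameters.

The geometry emulated by the flagship toy complex mirrors the topology of
an alloantibody Fab engaging a class-I HLA laterally: an alpha chain
contacted in three spatially separated position runs ({14,16..19}, {39},
{90}), a hydrogen bond from a light-chain asparagine to the aspartate at
position 90, four hydrogen bonds from the heavy chain to the arginine at
position 17, and a modest heavy-chain patch on beta-2-microglobulin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _chem
from .gridsasa import grid_sasa
from .interface import HbondCriteria, SasaParams
from .kinetics import InjectionSchedule, KineticParams, Sensorgram, simulate_sck
from .cytotox import CytotoxicityTable
from .specificity import AllelePanel
from .structure import Structure, structure_from_arrays

# ---------------------------------------------------------------------------
# idealized residue templates: (atom, element, (x, y, z)) with the backbone
# near the origin and the side chain extended along -y

_RING = {
    "CG": (1.46, -2.9, 0.0), "CD1": (2.67, -3.6, 0.0), "CD2": (0.25, -3.6, 0.0),
    "CE1": (2.67, -5.0, 0.0), "CE2": (0.25, -5.0, 0.0), "CZ": (1.46, -5.7, 0.0),
}

_BACKBONE = [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
             ("C", "C", (2.2, 1.2, 0.0)), ("O", "O", (2.2, 2.44, 0.0))]

_SIDE: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "G": [],
    "A": [("CB", "C", (1.46, -1.53, 0.0))],
    "S": [("CB", "C", (1.46, -1.53, 0.0)), ("OG", "O", (1.46, -2.9, 0.0))],
    "V": [("CB", "C", (1.46, -1.53, 0.0)), ("CG1", "C", (0.36, -2.3, 0.0)),
          ("CG2", "C", (2.56, -2.3, 0.0))],
    "D": [("CB", "C", (1.46, -1.53, 0.0)), ("CG", "C", (1.46, -3.0, 0.0)),
          ("OD1", "O", (0.36, -3.7, 0.0)), ("OD2", "O", (2.56, -3.7, 0.0))],
    "N": [("CB", "C", (1.46, -1.53, 0.0)), ("CG", "C", (1.46, -3.0, 0.0)),
          ("OD1", "O", (0.36, -3.7, 0.0)), ("ND2", "N", (2.56, -3.7, 0.0))],
    "E": [("CB", "C", (1.46, -1.53, 0.0)), ("CG", "C", (1.46, -2.9, 0.0)),
          ("CD", "C", (1.46, -4.4, 0.0)), ("OE1", "O", (0.36, -5.1, 0.0)),
          ("OE2", "O", (2.56, -5.1, 0.0))],
    "Q": [("CB", "C", (1.46, -1.53, 0.0)), ("CG", "C", (1.46, -2.9, 0.0)),
          ("CD", "C", (1.46, -4.4, 0.0)), ("OE1", "O", (0.36, -5.1, 0.0)),
          ("NE2", "N", (2.56, -5.1, 0.0))],
    "K": [("CB", "C", (1.46, -1.53, 0.0)), ("CG", "C", (1.46, -2.9, 0.0)),
          ("CD", "C", (1.46, -4.3, 0.0)), ("CE", "C", (1.46, -5.8, 0.0)),
          ("NZ", "N", (1.46, -7.2, 0.0))],
    "R": [("CB", "C", (1.46, -1.53, 0.0)), ("CG", "C", (1.46, -2.9, 0.0)),
          ("CD", "C", (1.46, -4.3, 0.0)), ("NE", "N", (1.46, -5.7, 0.0)),
          ("CZ", "C", (1.46, -7.0, 0.0)), ("NH1", "N", (0.36, -7.7, 0.0)),
          ("NH2", "N", (2.56, -7.7, 0.0))],
    "F": [("CB", "C", (1.46, -1.53, 0.0))] + [(n, "C", xyz) for n, xyz in _RING.items()],
    "Y": [("CB", "C", (1.46, -1.53, 0.0))] + [(n, "C", xyz) for n, xyz in _RING.items()]
         + [("OH", "O", (1.46, -7.1, 0.0))],
}


@dataclass
class ResiduePlacement:
    chain_id: str
    position: int
    aa: str
    translation: tuple[float, float, float]
    flipped: bool = False        # rotate 180 deg about x: side chain points +y


@dataclass
class ToyComplexSpec:
    """Explicit geometry plan: each residue is placed rigidly; ``flipped``
    residues present their side chain toward +y (binder chains approaching
    an antigen whose side chains point -y)."""

    placements: list[ResiduePlacement]
    role_map: Mapping[str, str] = field(default_factory=dict)
    identifier: str = "TOY"
    min_atom_separation: float = 0.5    # feasibility guard between residues


def _residue_atoms(aa: str, translation: Sequence[float], flipped: bool):
    if aa not in _SIDE:
        raise ValueError(f"no idealized template for residue type {aa!r}")
    out = []
    t = np.asarray(translation, dtype=float)
    for name, element, xyz in _BACKBONE + _SIDE[aa]:
        v = np.array(xyz, dtype=float)
        if flipped:
            v = v * np.array([1.0, -1.0, -1.0])
        out.append((name, element, tuple(v + t)))
    return out


def make_toy_complex(spec: ToyComplexSpec) -> Structure:
    rows = []
    for p in spec.placements:
        rows.append((p.chain_id, p.position, p.aa, _residue_atoms(p.aa, p.translation, p.flipped)))
    st = structure_from_arrays(spec.identifier, rows, spec.role_map)
    # feasibility: no two atoms of different residues may (nearly) coincide
    coords, keys = [], []
    for cid, residues in st.chains.items():
        for r in residues:
            for a in r.atoms:
                coords.append(a.coord)
                keys.append((cid, r.seq_position))
    coords = np.asarray(coords)
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(r=spec.min_atom_separation):
        if keys[i] != keys[j]:
            raise ValueError(
                f"infeasible geometry plan: atoms of residues {keys[i]} and {keys[j]} "
                f"closer than {spec.min_atom_separation} A")
    return st


# ---------------------------------------------------------------------------
# brute-force ground-truth calculators (independent of the production
# neighbor-search code paths; plain all-pairs loops)


def brute_force_contacts(
    structure: Structure,
    side_a_chains: Sequence[str],
    side_b_chains: Sequence[str],
    cutoff: float = 4.0,
) -> set[tuple[str, int, str, int]]:
    """All cross-side residue pairs with min heavy-atom distance <= cutoff."""
    found = set()
    for ca in side_a_chains:
        for ra in structure.chains[ca]:
            for cb in side_b_chains:
                for rb in structure.chains[cb]:
                    d = min(
                        float(np.linalg.norm(a.coord - b.coord))
                        for a in ra.atoms for b in rb.atoms)
                    if d <= cutoff:
                        found.add((ca, ra.seq_position, cb, rb.seq_position))
    return found


def brute_force_hbonds(
    structure: Structure,
    side_a_chains: Sequence[str],
    side_b_chains: Sequence[str],
    criteria: HbondCriteria | None = None,
) -> set[tuple[str, int, str, str, int, str]]:
    """Donor/acceptor atom pairs across sides meeting the geometric
    criteria, as (chain_a, pos_a, atom_a, chain_b, pos_b, atom_b) with the
    side-a member first."""
    criteria = criteria or HbondCriteria()

    def polar_atoms(res, which):
        res3 = res.name3
        table: dict[str, tuple[str, ...]] = {}
        if which == "donor":
            if res3 != "PRO":
                table.update(_chem.BACKBONE_DONOR)
            table.update(_chem.SIDECHAIN_DONORS.get(res3, {}))
        else:
            table.update(_chem.BACKBONE_ACCEPTOR)
            table.update(_chem.SIDECHAIN_ACCEPTORS.get(res3, {}))
        out = []
        for atom in res.atoms:
            if atom.name in table:
                ante = [res.atom(n) for n in table[atom.name]]
                out.append((atom, [a for a in ante if a is not None]))
        return out

    def angle_ok(end_atom, antecedents, partner):
        if not antecedents:
            return True
        for ante in antecedents:
            v1 = ante.coord - end_atom.coord
            v2 = partner.coord - end_atom.coord
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= criteria.min_donor_angle:
                return True
        return False

    found = set()
    for ca in side_a_chains:
        for ra in structure.chains[ca]:
            for cb in side_b_chains:
                for rb in structure.chains[cb]:
                    for da, db in (("donor", "acceptor"), ("acceptor", "donor")):
                        for atom_a, ante_a in polar_atoms(ra, da):
                            for atom_b, ante_b in polar_atoms(rb, db):
                                d = float(np.linalg.norm(atom_a.coord - atom_b.coord))
                                if d > criteria.max_donor_acceptor_distance:
                                    continue
                                if angle_ok(atom_a, ante_a, atom_b) and angle_ok(atom_b, ante_b, atom_a):
                                    found.add((ca, ra.seq_position, atom_a.name,
                                               cb, rb.seq_position, atom_b.name))
    return found


def oracle_bsa(
    structure: Structure,
    side_a: Sequence[str],
    side_b: Sequence[str],
    params: SasaParams | None = None,
    n_lat: int = 30,
    n_lon: int = 48,
) -> float:
    """One-sided buried area of ``side_a`` from the quadrature oracle."""
    params = params or SasaParams()
    from .structure import atom_table

    ta = atom_table(structure, list(side_a))
    tab = atom_table(structure, list(side_a) + list(side_b))
    radii_a = np.array([_chem.vdw_radius(e, params.radii_set) for e in ta.elements])
    radii_ab = np.array([_chem.vdw_radius(e, params.radii_set) for e in tab.elements])
    alone = grid_sasa(ta.coords, radii_a, params.probe_radius, n_lat, n_lon)
    together = grid_sasa(tab.coords, radii_ab, params.probe_radius, n_lat, n_lon)
    in_a = np.array([c in set(side_a) for c in tab.chain_ids])
    return float(np.sum(alone) - np.sum(together[in_a]))


# ---------------------------------------------------------------------------
# named toy complexes


def hbond_pair_complex(distance: float = 2.9) -> tuple[Structure, dict]:
    """Two 5-residue chains with exactly one planted N...O hydrogen bond
    (chain B ASN ND2 donating to chain A ASP OD1 at ``distance``)."""
    a_places = [ResiduePlacement("A", i + 1, aa, ((i) * 3.8, 0.0, 0.0), flipped=True)
                for i, aa in enumerate("GADAG")]
    # chain B above, side chains pointing down (-y): unflipped template
    b_places = [ResiduePlacement("B", i + 1, aa, ((i) * 3.8, 0.0, 0.0))
                for i, aa in enumerate("GANAG")]
    spec = ToyComplexSpec(a_places + b_places, {"A": "hla_alpha", "B": "fab_heavy"},
                          identifier="TOY-HB")
    # place B so that B3/ND2 sits `distance` above A3/OD1 along +y
    st = make_toy_complex(ToyComplexSpec(a_places, {}, "TMP"))
    od1 = st.chains["A"][2].atom("OD1").coord
    stb = make_toy_complex(ToyComplexSpec(b_places, {}, "TMP"))
    nd2 = stb.chains["B"][2].atom("ND2").coord
    shift = od1 + np.array([0.0, distance, 0.0]) - nd2
    b_places = [ResiduePlacement("B", p.position, p.aa, tuple(np.array(p.translation) + shift))
                for p in b_places]
    spec = ToyComplexSpec(a_places + b_places, {"A": "hla_alpha", "B": "fab_heavy"},
                          identifier="TOY-HB")
    structure = make_toy_complex(spec)
    truth = {
        "contacts": brute_force_contacts(structure, ["A"], ["B"]),
        "hbonds": brute_force_hbonds(structure, ["A"], ["B"]),
        "planted_hbond": ("A", 3, "OD1", "B", 3, "ND2"),
    }
    return structure, truth


def separated_complex(gap: float = 100.0) -> tuple[Structure, dict]:
    """Two short chains ``gap`` Angstrom apart: no contacts, zero BSA."""
    a = [ResiduePlacement("A", i + 1, aa, (i * 3.8, 0.0, 0.0)) for i, aa in enumerate("GAG")]
    b = [ResiduePlacement("B", i + 1, aa, (gap + i * 3.8, 0.0, 0.0)) for i, aa in enumerate("GAG")]
    st = make_toy_complex(ToyComplexSpec(a + b, {"A": "hla_alpha", "B": "fab_heavy"}, "TOY-APART"))
    return st, {"contacts": set(), "hbonds": set(), "bsa": 0.0}


def fab_hla_toy() -> tuple[Structure, dict]:
    """Four-chain toy emulating the lateral Fab-HLA engagement topology.

    Chain A (alpha) presents three spatially separated epitope rows; chain
    B (beta-2-microglobulin stand-in) carries one heavy-chain contact; H
    and L are the Fab heavy/light stand-ins. Planted truth: alpha epitope
    positions {14, 16, 17, 18, 19, 39, 90} (three segments at gap
    tolerance 3), one light-chain N...O bond to Asp90, exactly four
    heavy-chain hydrogen bonds to Arg17, and a nonbonded light-chain
    tyrosine contact to Asp90.
    """
    P = ResiduePlacement
    x = lambda p, base: (p - base) * 3.8

    placements: list[ResiduePlacement] = []
    # alpha row 1: positions 10-22 at z=0; R14, R17, E19
    row1 = {p: "A" for p in range(10, 23)}
    row1.update({10: "G", 14: "R", 15: "G", 17: "R", 19: "E", 22: "G"})
    placements += [P("A", p, aa, (x(p, 10), 0.0, 0.0)) for p, aa in sorted(row1.items())]
    # alpha row 2: positions 36-42 at z=20; D39
    row2 = {36: "G", 37: "A", 38: "A", 39: "D", 40: "A", 41: "A", 42: "G"}
    placements += [P("A", p, aa, (x(p, 36), 0.0, 20.0)) for p, aa in sorted(row2.items())]
    # alpha row 3: positions 86-94 at z=40; D90
    row3 = {86: "G", 87: "A", 88: "A", 89: "A", 90: "D", 91: "A", 92: "A", 93: "A", 94: "G"}
    placements += [P("A", p, aa, (x(p, 86), 0.0, 40.0)) for p, aa in sorted(row3.items())]
    # beta-2-microglobulin stand-in: positions 1-6 at z=60
    placements += [P("B", p, aa, (x(p, 1), 0.0, 60.0))
                   for p, aa in enumerate("GAAAAG", start=1)]

    # heavy chain probes (flipped: side chains point +y, toward the antigen)
    heavy = [
        # nonbonded ring contact under Arg14 NH1 (NH1 at (15.56, -7.7, 0))
        P("H", 50, "F", (14.10, -16.90, 0.0), flipped=True),
        # nonbonded ring contact near Ala16 CB, dodged in -z
        P("H", 52, "F", (22.80, -9.68, -2.5), flipped=True),
        # glutamate: OE1/OE2 2.9 A below Arg17 NH1/NH2
        P("H", 53, "E", (26.62, -15.70, 0.0), flipped=True),
        # glutamine: OE1 2.9 A from Arg17 NH1, displaced in -z
        P("H", 54, "Q", (26.60, -14.30, -2.4), flipped=True),
        # asparagine: OD1 2.9 A from Arg17 NH2, displaced in +z
        P("H", 55, "N", (28.80, -12.90, 2.4), flipped=True),
        # nonbonded ring contact near Ala18 CB, dodged in -z
        P("H", 56, "F", (30.40, -9.68, -2.5), flipped=True),
        # nonbonded ring contact under Glu19 OE1
        P("H", 57, "F", (33.10, -14.30, 0.0), flipped=True),
        # row 2: nonbonded ring contact under Asp39 OD1
        P("H", 58, "F", (10.30, -12.90, 20.0), flipped=True),
        # beta-2-microglobulin patch: ring contact under B3 CB
        P("H", 60, "F", (7.60, -10.73, 60.0), flipped=True),
    ]
    light = [
        # tyrosine ring near Asp90 (nonbonded; OH kept out of bond range)
        P("L", 30, "Y", (15.09, -9.90, 43.6), flipped=True),
        # asparagine ND2 2.9 A below Asp90 OD1 (OD1 at (15.56, -3.7, 40))
        P("L", 31, "N", (13.00, -10.30, 40.0), flipped=True),
        # spacers keeping the chain >=2 residues long but out of range
        P("L", 28, "G", (5.0, -18.0, 40.0), flipped=True),
        P("L", 33, "G", (25.0, -18.0, 40.0), flipped=True),
    ]
    placements += heavy + light
    role_map = {"A": "hla_alpha", "B": "b2m", "H": "fab_heavy", "L": "fab_light"}
    structure = make_toy_complex(ToyComplexSpec(placements, role_map, "TOY-FABHLA"))

    contacts = brute_force_contacts(structure, ["A", "B"], ["H", "L"])
    hbonds = brute_force_hbonds(structure, ["A", "B"], ["H", "L"])
    truth = {
        "contacts": contacts,
        "hbonds": hbonds,
        "alpha_epitope": {14, 16, 17, 18, 19, 39, 90},
        "segments": [[14, 16, 17, 18, 19], [39], [90]],
        "eplet_hbond": ("A", 90, "OD1", "L", 31, "ND2"),
        "n_arg17_heavy_hbonds": 4,
        "zero_pairs": [("b2m", "fab_light")],
    }
    return structure, truth


def receptor_complex_pair(seed: int = 0, clashing: bool = False):
    """A Fab-HLA target and a receptor-HLA mobile complex built in
    different frames; after superposition on the shared alpha chain the
    receptor sits opposite the Fab (no clashes) unless ``clashing``."""
    P = ResiduePlacement
    # slight zig-zag keeps the CA trace non-collinear for the least-squares fit
    alpha = [P("A", p, "A" if p % 3 else "G",
               ((p - 1) * 3.8, 1.2 * (p % 2), 0.8 * (p % 3))) for p in range(1, 13)]
    fab = [P("F", p, "A", ((p - 1) * 3.8 + 1.0, -8.0, 0.0)) for p in range(1, 9)]
    target = make_toy_complex(ToyComplexSpec(alpha + fab, {"A": "hla_alpha", "F": "fab_heavy"},
                                             "TOY-TARGET"))
    y_rec = -8.0 if clashing else 8.0
    rec = [P("R", p, "A", ((p - 1) * 3.8 + 1.0, y_rec, 0.0)) for p in range(1, 9)]
    mobile = make_toy_complex(ToyComplexSpec(alpha + rec, {"A": "hla_alpha", "R": "receptor"},
                                             "TOY-MOBILE"))
    # move the mobile complex into an arbitrary frame
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    for residues in mobile.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.coord = R @ atom.coord + t
    return target, mobile


# ---------------------------------------------------------------------------
# allele panels


ABROGATING_SUBSTITUTIONS = ((90, "D", "A"), (14, "R", "W"), (17, "R", "S"))
WEAKENING_SUBSTITUTIONS = ((19, "E", "K"), (39, "D", "Y"))


@dataclass
class PanelSpec:
    """Planted allele panel around an A*11:01-like reference.

    MFI bands default to (0-400) for nonreactive and (600-20000) for
    reactive alleles, straddling the 500 threshold with a margin.
    """

    n_alleles: int = 20
    n_nonreactive: int = 8
    n_weakened_reactive: int = 3
    epitope_positions: tuple[int, ...] = (14, 17, 19, 39, 90)
    nonreactive_band: tuple[float, float] = (0.0, 400.0)
    reactive_band: tuple[float, float] = (600.0, 20000.0)
    sequence_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonreactive + self.n_weakened_reactive >= self.n_alleles:
            raise ValueError("variant alleles must leave room for the reference")


def make_allele_panel(spec: PanelSpec) -> tuple[AllelePanel, dict[str, str]]:
    """Generate sequences + MFI with truth labels ('reactive'/'nonreactive').

    The reference (first allele, named SYN*11:01) carries the canonical
    epitope residues (R14, R17, E19, D39, D90); nonreactive alleles get at
    least one abrogating substitution, 'weakened' alleles only weakening
    ones, the rest are identical to the reference at every epitope
    position. Off-epitope positions vary freely.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    base = rng.choice(alphabet, size=spec.sequence_length)
    canonical = {14: "R", 17: "R", 19: "E", 39: "D", 90: "D"}
    for pos, aa in canonical.items():
        if pos <= spec.sequence_length:
            base[pos - 1] = aa

    labels: dict[str, str] = {}
    alleles: dict[str, str] = {}
    mfi: dict[str, float] = {}

    def sample_mfi(band: tuple[float, float]) -> float:
        return float(rng.uniform(*band))

    names = ["SYN*11:01"] + [f"SYN*{i:02d}:01" for i in range(1, spec.n_alleles)]
    kinds = (["reference"] + ["nonreactive"] * spec.n_nonreactive
             + ["weakened"] * spec.n_weakened_reactive)
    kinds += ["identical"] * (spec.n_alleles - len(kinds))

    for name, kind in zip(names, kinds):
        seq = base.copy()
        # free variation away from the epitope
        for _ in range(rng.integers(0, 4)):
            pos = int(rng.integers(1, spec.sequence_length + 1))
            if pos not in spec.epitope_positions:
                seq[pos - 1] = rng.choice(alphabet)
        if kind == "nonreactive":
            n_ab = int(rng.integers(1, len(ABROGATING_SUBSTITUTIONS) + 1))
            picks = rng.choice(len(ABROGATING_SUBSTITUTIONS), size=n_ab, replace=False)
            for k in picks:
                pos, _, alt = ABROGATING_SUBSTITUTIONS[k]
                seq[pos - 1] = alt
            label = "nonreactive"
        elif kind == "weakened":
            pos, _, alt = WEAKENING_SUBSTITUTIONS[int(rng.integers(len(WEAKENING_SUBSTITUTIONS)))]
            seq[pos - 1] = alt
            label = "reactive"
        else:
            label = "reactive"
        alleles[name] = "".join(seq)
        labels[name] = label
        band = spec.reactive_band if label == "reactive" else spec.nonreactive_band
        mfi[name] = sample_mfi(band)
    return AllelePanel(alleles, mfi, first_position=1), labels


def write_panel(panel: AllelePanel, fasta_path: str | Path, mfi_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in panel.alleles.items():
            fh.write(f">{name}\n{seq}\n")
    with open(mfi_path, "w") as fh:
        fh.write("allele,mfi\n")
        for name, value in panel.mfi.items():
            fh.write(f"{name},{value:.1f}\n")


# ---------------------------------------------------------------------------
# sensorgrams


def make_sensorgram_set(
    params: KineticParams,
    schedule: InjectionSchedule | None = None,
    noise_sd: float = 0.0,
    n_seeds: int = 1,
    base_seed: int = 0,
    sampling_rate_hz: float = 1.0,
) -> list[Sensorgram]:
    """Seed-deterministic collection of simulated SCK sensorgrams."""
    schedule = schedule or InjectionSchedule.single_cycle()
    return [simulate_sck(params, schedule, sampling_rate_hz, noise_sd, seed=base_seed + k)
            for k in range(n_seeds)]


# ---------------------------------------------------------------------------
# cytotoxicity replicate tables


def make_cytotox_experiment(
    scenario: str = "separation",
    n_replicates: int = 4,
    seed: int = 0,
    conditions: Sequence[str] = ("treated", "isotype_control"),
) -> dict[str, CytotoxicityTable]:
    """Replicate (experimental, baseline, maximum) death fractions.

    ``separation``: treated killing is well above control in every
    replicate (complete separation, the boundary case of the exact rank
    test). ``null``: both conditions share the same distribution. Fractions
    are scaled Beta draws: baseline around 0.10, maximum around 0.90.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    if scenario not in ("separation", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)

    def beta_in(lo: float, hi: float) -> float:
        return float(lo + (hi - lo) * rng.beta(2.0, 2.0))

    out = {}
    for cond in conditions:
        reps = []
        for _ in range(n_replicates):
            base = beta_in(0.08, 0.12)
            mx = beta_in(0.85, 0.95)
            if scenario == "null" or cond != "treated":
                exp = beta_in(base, base + 0.08)
            else:
                exp = beta_in(0.45, 0.65)
            reps.append((exp, base, mx))
        out[cond] = CytotoxicityTable(cond, reps)
    return out
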