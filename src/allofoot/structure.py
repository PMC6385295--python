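"""Macromolecular structure I/O and chain-role bookkeeping.

Parsing of mmCIF/PDB files is delegated to gemmi; this module reduces the
parsed model to a light hierarchy (chains -> residues -> heavy atoms) with
a per-chain role map (HLA alpha chain, beta-2-microglobulin, peptide, Fab
heavy/light chain, receptor) that the downstream interface, specificity
and superposition analyses key off.

Conventions
-----------
* Alternate conformations are collapsed to the highest-occupancy conformer
  (ties broken by altloc identifier order).
* Waters and small-molecule heteroatoms are segregated from polymer chains.
* Structures are treated as hydrogen-free; hydrogens present in the file
  are dropped unless explicitly requested.
* Residue numbering may be shifted per chain with a configurable offset to
  reconcile author numbering with mature-protein numbering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from ._chem import AA3_TO_1, STANDARD_AA1

ROLES = ("hla_alpha", "b2m", "peptide", "fab_heavy", "fab_light", "receptor", "other")
CORE_ROLES = ("hla_alpha", "b2m", "peptide", "fab_heavy", "fab_light")


class StructureError(ValueError):
    """Raised for unreadable files, empty polymers or inconsistent roles."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_position: int
    aa_code: str              # one-letter; 'X' flags a nonstandard residue
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    name3: str = ""           # original three-letter name

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_position)


@dataclass
class Structure:
    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    role_map: dict[str, str] = field(default_factory=dict)
    het: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, role in self.role_map.items():
            if cid not in self.chains:
                raise StructureError(f"role map names unknown chain {cid!r}")
            if role not in ROLES:
                raise StructureError(f"unknown role {role!r} for chain {cid!r}")

    def chain_for_role(self, role: str) -> str:
        hits = [cid for cid, r in self.role_map.items() if r == role]
        if not hits:
            raise StructureError(f"no chain assigned to role {role!r}")
        if len(hits) > 1 and role in CORE_ROLES:
            raise StructureError(f"multiple chains assigned to core role {role!r}: {hits}")
        return hits[0]

    def chains_for_roles(self, roles: Iterable[str]) -> list[str]:
        wanted = set(roles)
        return [cid for cid, r in self.role_map.items() if r in wanted]

    def residue(self, chain_id: str, position: int) -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if res.seq_position == position:
                return res
        return None

    def n_atoms(self, chain_ids: Iterable[str] | None = None) -> int:
        cids = list(chain_ids) if chain_ids is not None else list(self.chains)
        return sum(len(r.atoms) for c in cids for r in self.chains[c])

    def copy(self) -> "Structure":
        new_chains = {
            cid: [
                Residue(r.chain_id, r.seq_position, r.aa_code,
                        [Atom(a.name, a.element, a.coord.copy(), a.occupancy) for a in r.atoms],
                        r.insertion_code, r.name3)
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return Structure(self.identifier, new_chains, dict(self.role_map), dict(self.het))


@dataclass
class AtomTable:
    """Flat array view over a set of chains, used by the geometric modules."""

    coords: np.ndarray           # (N, 3)
    elements: list[str]
    atom_names: list[str]
    chain_ids: list[str]
    res_positions: np.ndarray    # (N,) int
    res_codes: list[str]         # one-letter
    res_names3: list[str]

    def __len__(self) -> int:
        return len(self.elements)


def atom_table(structure: Structure, chain_ids: Iterable[str] | None = None) -> AtomTable:
    cids = list(chain_ids) if chain_ids is not None else list(structure.chains)
    coords, elements, names, chains, positions, codes, names3 = [], [], [], [], [], [], []
    for cid in cids:
        if cid not in structure.chains:
            raise StructureError(f"unknown chain {cid!r}")
        for res in structure.chains[cid]:
            for a in res.atoms:
                coords.append(a.coord)
                elements.append(a.element)
                names.append(a.name)
                chains.append(cid)
                positions.append(res.seq_position)
                codes.append(res.aa_code)
                names3.append(res.name3)
    if not coords:
        raise StructureError(f"no atoms in chains {cids}")
    return AtomTable(np.asarray(coords, dtype=float), elements, names, chains,
                     np.asarray(positions, dtype=int), codes, names3)


# ---------------------------------------------------------------------------
# parsing


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties broken by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.occ <= 0.0:
            continue
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            by_name[atom.name] = atom
    return list(by_name.values())


def parse_structure(
    path: str | Path,
    fmt: str | None = None,
    identifier: str | None = None,
    numbering_offset: Mapping[str, int] | int = 0,
    model_index: int = 0,
    keep_hydrogens: bool = False,
) -> Structure:
    """Parse an mmCIF or PDB file into a :class:`Structure`.

    Parameters
    ----------
    fmt
        ``"mmcif"``, ``"pdb"`` or ``None`` to auto-detect from the file.
    numbering_offset
        Integer added to every author residue number, or a per-chain mapping,
        used to express sequences in mature-protein numbering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt.lower() in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt.lower() == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[model_index]

    def offset_for(cid: str) -> int:
        if isinstance(numbering_offset, int):
            return numbering_offset
        return int(numbering_offset.get(cid, 0))

    chains: dict[str, list[Residue]] = {}
    het: dict[str, list[Residue]] = {}
    for chain in model:
        cid = chain.name
        for res in chain:
            atoms = []
            for a in _resolve_altlocs(res):
                elem = a.element.name.upper()
                if not keep_hydrogens and elem in ("H", "D"):
                    continue
                atoms.append(Atom(a.name, elem, np.array([a.pos.x, a.pos.y, a.pos.z]), min(a.occ, 1.0)))
            if not atoms:
                continue
            name3 = res.name.strip().upper()
            is_water = name3 in ("HOH", "WAT", "DOD")
            aa1 = AA3_TO_1.get(name3)
            residue = Residue(
                chain_id=cid,
                seq_position=res.seqid.num + offset_for(cid),
                aa_code=aa1 if aa1 else "X",
                atoms=atoms,
                insertion_code=(res.seqid.icode or "").strip(),
                name3=name3,
            )
            if is_water or aa1 is None:
                het.setdefault(cid, []).append(residue)
            else:
                chains.setdefault(cid, []).append(residue)

    if not chains:
        raise StructureError(f"{path}: no polymer chains with occupied atoms")
    for residues in chains.values():
        residues.sort(key=lambda r: (r.seq_position, r.insertion_code))
    return Structure(identifier or (st.name or path.stem).upper(), chains, {}, het)


# ---------------------------------------------------------------------------
# role assignment


def assign_roles(structure: Structure, config: Mapping[str, str] | str = "auto") -> Structure:
    """Populate ``role_map`` from an explicit chain->role mapping or heuristics.

    Auto mode assigns by polymer length: the ~275-residue chain is the HLA
    alpha chain, the ~99-residue chain beta-2-microglobulin, a chain of at
    most 15 residues the presented peptide. Fab-sized chains (150-250
    residues) cannot be told apart (heavy vs light) from length alone, so
    auto mode refuses to guess and demands an explicit mapping.
    """
    result = structure.copy()
    if config != "auto":
        for cid, role in dict(config).items():
            if cid not in result.chains:
                raise StructureError(f"role config names unknown chain {cid!r}")
            if role not in ROLES:
                raise StructureError(f"unknown role {role!r}")
        role_map = dict(config)
        for role in CORE_ROLES:
            hits = [c for c, r in role_map.items() if r == role]
            if len(hits) > 1:
                raise StructureError(f"role {role!r} assigned to multiple chains: {hits}")
        result.role_map = role_map
        return result

    lengths = {cid: len(res) for cid, res in result.chains.items()}
    role_map: dict[str, str] = {}
    fab_candidates = []
    for cid, n in lengths.items():
        if n <= 15:
            role = "peptide"
        elif 60 <= n <= 130:
            role = "b2m"
        elif 250 <= n <= 320:
            role = "hla_alpha"
        elif 150 <= n < 250:
            fab_candidates.append(cid)
            continue
        else:
            role = "other"
        if role in CORE_ROLES and role in role_map.values():
            clash = [c for c, r in role_map.items() if r == role] + [cid]
            raise StructureError(f"ambiguous auto-assignment for role {role!r}: chains {clash}")
        role_map[cid] = role
    if fab_candidates:
        raise StructureError(
            "auto role assignment cannot disambiguate Fab heavy vs light chains "
            f"for candidates {sorted(fab_candidates)}; provide an explicit config"
        )
    result.role_map = role_map
    return result


# ---------------------------------------------------------------------------
# sequences


@dataclass
class ChainSequence:
    """One-letter sequence of a chain in ascending residue-number order.

    ``positions`` carries the observed residue numbers; numbers absent from
    the chain within [min, max] are reported in ``missing``.
    """

    chain_id: str
    positions: list[int]
    letters: str

    @property
    def missing(self) -> list[int]:
        if not self.positions:
            return []
        present = set(self.positions)
        return [p for p in range(self.positions[0], self.positions[-1] + 1) if p not in present]

    def at(self, position: int) -> str | None:
        try:
            return self.letters[self.positions.index(position)]
        except ValueError:
            return None

    def __str__(self) -> str:
        return self.letters


def extract_sequence(structure: Structure, chain_id: str) -> ChainSequence:
    if chain_id not in structure.chains:
        raise StructureError(f"unknown chain {chain_id!r}")
    residues = structure.chains[chain_id]
    return ChainSequence(chain_id, [r.seq_position for r in residues],
                         "".join(r.aa_code for r in residues))


# ---------------------------------------------------------------------------
# PDB writing (fixtures, transformed models)


def write_pdb(structure: Structure, path: str | Path, include_het: bool = False) -> None:
    """Write a normalized PDB file (heavy atoms, single conformer)."""
    lines = []
    serial = 1
    element_field = {"SE": "SE", "CL": "CL", "BR": "BR"}
    for cid in structure.chains:
        groups = [("ATOM", structure.chains[cid])]
        if include_het and cid in structure.het:
            groups.append(("HETATM", structure.het[cid]))
        for record, residues in groups:
            for res in residues:
                name3 = res.name3 or "UNK"
                for a in res.atoms:
                    el = element_field.get(a.element.upper(), a.element.upper()[:2])
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    lines.append(
                        f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{name3:>3s} "
                        f"{cid[:1]:1s}{res.seq_position:>4d}{res.insertion_code[:1]:1s}   "
                        f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                        f"{a.occupancy:6.2f}{0.0:6.2f}          {el:>2s}"
                    )
                    serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def structure_from_arrays(
    identifier: str,
    residues: Sequence[tuple[str, int, str, Sequence[tuple[str, str, Sequence[float]]]]],
    role_map: Mapping[str, str] | None = None,
) -> Structure:
    """Build a Structure from (chain_id, position, aa1, atoms) tuples.

    Convenience constructor used by the synthetic generators and tests;
    ``atoms`` entries are (atom_name, element, xyz).
    """
    from ._chem import AA1_TO_3

    chains: dict[str, list[Residue]] = {}
    for chain_id, pos, aa1, atoms in residues:
        res = Residue(chain_id, pos, aa1,
                      [Atom(n, e, np.asarray(c, dtype=float)) for n, e, c in atoms],
                      name3=AA1_TO_3.get(aa1, "UNK"))
        chains.setdefault(chain_id, []).append(res)
    for rs in chains.values():
        rs.sort(key=lambda r: r.seq_position)
    return Structure(identifier, chains, dict(role_map or {}))
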