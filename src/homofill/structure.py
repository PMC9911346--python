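"""Coordinate data model and mmCIF input/output.

The hierarchy is deliberately minimal: a :class:`Structure` holds ordered
chains of residues of atoms, plus ``struct_conn`` connection records.  It is
built from, and written back to, PDBx/mmCIF via gemmi's CIF document API so
that the fields the pipeline cares about (label_* addressing, occupancies,
altlocs, struct_conn) survive a round trip exactly.

Conventions
-----------
* label_asym_id / label_seq_id are the internal addressing scheme; auth_*
  values are carried along for output fidelity.
* Coordinates are in Angstrom; sequence positions are 1-based.
* Hydrogens are parsed and kept, but every geometric computation downstream
  must skip them (donor crystal structures may contain H; predicted models
  do not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "AtomAddress",
    "StructConn",
    "Structure",
    "FormatError",
    "EmptyModelError",
    "ChainLookupError",
    "ConsistencyError",
    "read_structure",
    "extract_sequence",
    "write_structure",
    "write_filled_structure",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as mmCIF with atom_site rows."""


class EmptyModelError(ValueError):
    """Raised when a structure contains no polymer chains."""


class ChainLookupError(KeyError):
    """Raised when a chain id does not resolve."""


class ConsistencyError(ValueError):
    """Raised when records reference atoms that do not exist."""


# Elements treated as hydrogen for the "skip hydrogens" rule.
_HYDROGEN = {"H", "D"}


@dataclass
class Atom:
    """A single atom site.

    ``b_factor`` carries the isotropic B in experimental structures and the
    pLDDT column in predicted models; the pipeline never interprets it.
    """

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside (0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.occupancy, self.altloc, self.b_factor)


@dataclass
class Residue:
    comp_id: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    is_polymer: bool = True
    auth_seq_id: int | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for a in self.atoms:
            key = (a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom {a.name!r} (altloc {a.altloc!r}) in {self.comp_id} {self.seq_id}")
            seen.add(key)

    def atom(self, name: str, altloc: str | None = None) -> Atom | None:
        """First atom with this name; if ``altloc`` is None, lowest altloc label wins."""
        hits = [a for a in self.atoms if a.name == name and (altloc is None or a.altloc == altloc)]
        if not hits:
            return None
        return min(hits, key=lambda a: a.altloc)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.heavy_atoms], dtype=float).reshape(-1, 3)

    def centroid(self) -> np.ndarray:
        """Unweighted mean over all non-hydrogen atoms (all conformers)."""
        coords = self.heavy_coords()
        if len(coords) == 0:
            raise ValueError(f"residue {self.comp_id} has no heavy atoms")
        return coords.mean(axis=0)

    def copy(self) -> "Residue":
        return Residue(self.comp_id, self.seq_id, [a.copy() for a in self.atoms], self.is_polymer, self.auth_seq_id)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    auth_id: str | None = None

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def residue(self, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues], self.auth_id)


@dataclass(frozen=True)
class AtomAddress:
    chain_id: str
    seq_id: int
    comp_id: str
    atom_name: str


@dataclass
class StructConn:
    """One connection record (covalent bond, metal coordination, ...)."""

    conn_type: str
    ptnr1: AtomAddress
    ptnr2: AtomAddress
    distance: float | None = None


@dataclass
class Structure:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    struct_conn: list[StructConn] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise ChainLookupError(f"no chain {chain_id!r} in entry {self.entry_id!r}")

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_residues]

    def het_groups(self) -> list[tuple[str, str, int, Residue]]:
        """Non-polymer residues as (chain_id, comp_id, copy_index, residue).

        Copy indices count per (chain, comp_id) in file order, starting at 1.
        """
        out: list[tuple[str, str, int, Residue]] = []
        counter: dict[tuple[str, str], int] = {}
        for chain in self.chains:
            for res in chain.residues:
                if res.is_polymer:
                    continue
                key = (chain.id, res.comp_id)
                counter[key] = counter.get(key, 0) + 1
                out.append((chain.id, res.comp_id, counter[key], res))
        return out

    def find_atom(self, addr: AtomAddress) -> Atom | None:
        for chain in self.chains:
            if chain.id != addr.chain_id:
                continue
            for res in chain.residues:
                if res.seq_id == addr.seq_id and res.comp_id == addr.comp_id:
                    a = res.atom(addr.atom_name)
                    if a is not None:
                        return a
        return None

    def atoms(self) -> Iterator[Atom]:
        for chain in self.chains:
            for res in chain.residues:
                yield from res.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def polymer_heavy_coords(self) -> np.ndarray:
        """Coordinates of all non-hydrogen polymer atoms, (n, 3)."""
        coords = [
            a.pos
            for c in self.chains
            for r in c.residues
            if r.is_polymer
            for a in r.atoms
            if not a.is_hydrogen
        ]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def validate_struct_conn(self) -> None:
        for rec in self.struct_conn:
            for addr in (rec.ptnr1, rec.ptnr2):
                if self.find_atom(addr) is None:
                    raise ConsistencyError(f"struct_conn endpoint does not resolve: {addr}")

    def copy(self) -> "Structure":
        return Structure(self.entry_id, [c.copy() for c in self.chains], [replace(r) for r in self.struct_conn])


# ---------------------------------------------------------------------------
# Sequence extraction

# Fallback for components gemmi does not know; gemmi handles MSE etc. itself.
_THREE_TO_ONE_EXTRA = {"UNK": "X"}


def _one_letter(comp_id: str) -> str:
    info = gemmi.find_tabulated_residue(comp_id)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return _THREE_TO_ONE_EXTRA.get(comp_id, "X")


def extract_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain's polymer residues in seq_id order.

    Nonstandard residues are mapped to their parent amino acid where known
    (e.g. selenomethionine to M), otherwise to X.
    """
    chain = structure.chain(chain_id)
    residues = sorted(chain.polymer_residues, key=lambda r: r.seq_id)
    if not residues:
        raise ChainLookupError(f"chain {chain_id!r} has no polymer residues")
    return "".join(_one_letter(r.comp_id) for r in residues)


# ---------------------------------------------------------------------------
# mmCIF reading

_STANDARD_AA = set(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def _is_polymer_row(group: str, comp_id: str) -> bool:
    if group == "ATOM":
        return True
    # HETATM polymer residues (e.g. MSE) still belong to the chain sequence
    info = gemmi.find_tabulated_residue(comp_id)
    return comp_id in _STANDARD_AA or (info is not None and info.is_amino_acid() and comp_id != "UNL")


def _cif_str(value: str) -> str:
    return "" if value in (".", "?") else value


def read_structure(path: str | Path) -> Structure:
    """Read an mmCIF file into the in-memory hierarchy.

    Hydrogens and alternate conformers are retained; occupancies preserved.
    Raises :class:`FormatError` on parse failure or missing atom_site records,
    :class:`EmptyModelError` if no polymer chain is present.
    """
    path = Path(path)
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on bad syntax
        raise FormatError(f"{path}: not parseable as mmCIF: {exc}") from exc

    cols = [
        "group_PDB", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_seq_id",
        "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
        "auth_seq_id", "auth_asym_id",
    ]
    table = block.find("_atom_site.", cols)
    if len(table) == 0:
        raise FormatError(f"{path}: no _atom_site records (category atom_site missing or empty)")

    structure = Structure(entry_id=block.name or path.stem)
    chains: dict[str, Chain] = {}
    current: dict[str, Residue] = {}  # chain id -> residue being accumulated
    het_counter: dict[str, int] = {}

    for row in table:
        group = row[0]
        element = _cif_str(row[1]).upper()
        name = gemmi.cif.as_string(row[2])
        altloc = _cif_str(row[3])
        comp_id = row[4]
        asym = row[5]
        seq_raw = _cif_str(row[6])
        x, y, z = float(row[7]), float(row[8]), float(row[9])
        occ = float(row[10]) if _cif_str(row[10]) else 1.0
        biso = float(row[11]) if _cif_str(row[11]) else 0.0
        auth_seq = _cif_str(row[12])
        auth_asym = _cif_str(row[13])

        is_poly = bool(seq_raw) and _is_polymer_row(group, comp_id)
        if is_poly:
            seq_id = int(seq_raw)
        else:
            # het groups carry '.' label_seq_id; address them by auth_seq_id
            seq_id = int(auth_seq) if auth_seq else int(seq_raw or 0)

        if asym not in chains:
            chains[asym] = Chain(asym, auth_id=auth_asym or asym)
            structure.chains.append(chains[asym])

        res = current.get(asym)
        if res is None or res.seq_id != seq_id or res.comp_id != comp_id:
            res = Residue(comp_id, seq_id, [], is_poly, auth_seq_id=int(auth_seq) if auth_seq else None)
            chains[asym].residues.append(res)
            current[asym] = res

        res.atoms.append(Atom(name, element, np.array([x, y, z]), occ, altloc, biso))

    if not structure.polymer_chains:
        raise EmptyModelError(f"{path}: no polymer chains found")

    _read_struct_conn(block, structure)
    return structure


def _read_struct_conn(block: "gemmi.cif.Block", structure: Structure) -> None:
    cols = [
        "conn_type_id",
        "ptnr1_label_asym_id", "ptnr1_label_comp_id", "ptnr1_label_seq_id", "ptnr1_label_atom_id",
        "ptnr2_label_asym_id", "ptnr2_label_comp_id", "ptnr2_label_seq_id", "ptnr2_label_atom_id",
        "pdbx_dist_value",
    ]
    table = block.find("_struct_conn.", cols)
    for row in table:
        def addr(off: int) -> AtomAddress:
            asym = row[off]
            comp = row[off + 1]
            seq_raw = _cif_str(row[off + 2])
            seq = int(seq_raw) if seq_raw else _het_seq_id(structure, asym, comp)
            return AtomAddress(asym, seq, comp, gemmi.cif.as_string(row[off + 3]))

        dist_raw = _cif_str(row[9])
        structure.struct_conn.append(
            StructConn(row[0], addr(1), addr(5), float(dist_raw) if dist_raw else None)
        )


def _het_seq_id(structure: Structure, chain_id: str, comp_id: str) -> int:
    """Resolve a '.'-seq_id struct_conn endpoint to the het residue's number."""
    for chain in structure.chains:
        if chain.id != chain_id:
            continue
        for res in chain.residues:
            if res.comp_id == comp_id and not res.is_polymer:
                return res.seq_id
    return 0


# ---------------------------------------------------------------------------
# mmCIF writing

def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the hierarchy as PDBx/mmCIF (atom_site + struct_conn)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(structure.entry_id or "model")
    block.set_pair("_entry.id", gemmi.cif.quote(structure.entry_id or "model"))

    loop = block.init_loop("_atom_site.", [
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
        "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
        "auth_seq_id", "auth_asym_id",
    ])
    serial = 0
    for entity_idx, chain in enumerate(structure.chains, start=1):
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                loop.add_row([
                    "ATOM" if res.is_polymer and res.comp_id in _STANDARD_AA else "HETATM",
                    str(serial),
                    atom.element,
                    gemmi.cif.quote(atom.name),
                    atom.altloc or ".",
                    res.comp_id,
                    chain.id,
                    str(entity_idx),
                    str(res.seq_id) if res.is_polymer else ".",
                    f"{atom.pos[0]:.3f}", f"{atom.pos[1]:.3f}", f"{atom.pos[2]:.3f}",
                    f"{atom.occupancy:.2f}",
                    f"{atom.b_factor:.2f}",
                    str(res.auth_seq_id if res.auth_seq_id is not None else res.seq_id),
                    chain.auth_id or chain.id,
                ])

    if structure.struct_conn:
        conn_loop = block.init_loop("_struct_conn.", [
            "id", "conn_type_id",
            "ptnr1_label_asym_id", "ptnr1_label_comp_id", "ptnr1_label_seq_id", "ptnr1_label_atom_id",
            "ptnr2_label_asym_id", "ptnr2_label_comp_id", "ptnr2_label_seq_id", "ptnr2_label_atom_id",
            "pdbx_dist_value",
        ])
        for i, rec in enumerate(structure.struct_conn, start=1):
            conn_loop.add_row([
                f"{rec.conn_type}{i}", rec.conn_type,
                rec.ptnr1.chain_id, rec.ptnr1.comp_id, str(rec.ptnr1.seq_id), gemmi.cif.quote(rec.ptnr1.atom_name),
                rec.ptnr2.chain_id, rec.ptnr2.comp_id, str(rec.ptnr2.seq_id), gemmi.cif.quote(rec.ptnr2.atom_name),
                f"{rec.distance:.3f}" if rec.distance is not None else "?",
            ])

    doc.write_file(str(Path(path)))


def next_het_chain_ids(structure: Structure) -> Iterator[str]:
    """Fresh chain identifiers for transplanted het groups, in placement order."""
    used = {c.id for c in structure.chains}
    alphabet = "BCDEFGHIJKLMNOPQRSTUVWXYZA"
    for first in alphabet:
        if first not in used:
            yield first
            used.add(first)
    i = 1
    while True:
        cid = f"Z{i}"
        if cid not in used:
            yield cid
            used.add(cid)
        i += 1


def write_filled_structure(model: Structure, transplants: Iterable, path: str | Path) -> Structure:
    """Write the query model plus one het group per transplant as mmCIF.

    Transplant coordinates must already be in the model frame.  Donor
    occupancies, altloc conformers and B-factors are retained; inherited
    struct_conn records are appended.  Returns the assembled structure
    (which round-trips through :func:`read_structure`).
    """
    filled = model.copy()
    for rec in transplants:  # TransplantRecord instances (engine module)
        res = rec.residue
        chain = Chain(rec.placed_chain_id, [res.copy()], auth_id=rec.placed_chain_id)
        filled.chains.append(chain)
        for conn in rec.inherited_conns:
            filled.struct_conn.append(conn)
    for conn in filled.struct_conn:
        for addr in (conn.ptnr1, conn.ptnr2):
            if filled.find_atom(addr) is None:
                raise ConsistencyError(f"transplant connection references missing atom: {addr}")
    write_structure(filled, path)
    return filled
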