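"""Deterministic synthetic fixtures: toy models, donor homologs, registries.

The generator stands in for the real inputs — predicted protein models and a
mirror of re-refined experimental structures — so every pipeline stage can be
exercised without downloads, with *known* ground truth:

* :func:`make_model` builds an ideal alpha-helical backbone (rise 1.5 A,
  twist 100 deg per residue) with N, CA, C, O and CB at fixed local-frame
  offsets and a seeded random sequence.
* :func:`make_donor` derives a homolog at an exactly controlled sequence
  identity (point mutations only, no indels, spread evenly and chosen among
  substitutions that score >= 0 in BLOSUM62 so a local alignment spans the
  full chain and reports the planted identity exactly), perturbs all atoms
  with isotropic Gaussian noise, optionally displaces one domain rigidly,
  plants ligands at chosen pockets, and finally moves the whole structure
  into a random rigid frame so superposition is non-trivial.
* :func:`make_registry` writes a loadable compound-list CIF.

The geometry is deliberately schematic (no rotamers, no real covalent
chemistry): ligands are named point sets, which is all the pipeline ever
perceives beyond struct_conn records.

Everything derives from ``FixtureSpec.seed``; equal seeds give
byte-identical mmCIF output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.Align import substitution_matrices

from .structure import Atom, Chain, Residue, Structure

__all__ = ["FixtureSpec", "LigandSpec", "make_model", "make_donor", "make_registry"]

# G excluded so every residue carries a CB; P excluded because it has no
# non-identical BLOSUM62 partner scoring >= 0 (see make_donor's mutation rule).
_ALPHABET = "ACDEFHIKLMNQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

_ION_ELEMENTS = {
    "ZN": "ZN", "FE": "FE", "MG": "MG", "CA": "CA", "NA": "NA", "K": "K",
    "CO": "CO", "NI": "NI", "CU": "CU", "MN": "MN", "CL": "CL",
}

_BLOSUM = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class LigandSpec:
    comp_id: str
    n_atoms: int
    pocket_residues: tuple[int, ...]  # 1-based seq ids defining the pocket
    offset: float = 3.5               # A, outward shift from the pocket centroid


@dataclass(frozen=True)
class DomainMotion:
    split_after: int      # last seq_id of the fixed domain
    displacement: float   # A
    rotation_deg: float = 0.0


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int = 120
    target_identity: float = 1.0
    coord_noise_sigma: float = 0.0
    domain_motion: DomainMotion | None = None
    ligands: tuple[LigandSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must be in (0, 1]")
        if self.coord_noise_sigma < 0:
            raise ValueError("coord_noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Model construction

_RISE = 1.5        # A per residue along the helix axis
_TWIST = 100.0     # degrees per residue
_RADIUS = 2.3      # A, CA distance from the helix axis

# atom offsets in the local (radial, tangent, axial) frame of each CA
_LOCAL_OFFSETS = {
    "N": (-0.45, -1.22, -0.65),
    "C": (-0.45, 1.22, 0.65),
    "O": (-0.90, 1.90, 1.40),
    "CB": (1.45, 0.15, -0.45),
}


def make_model(spec: FixtureSpec) -> Structure:
    """Idealized single-chain helical protein with a seeded random sequence."""
    if spec.n_residues < 10:
        raise ValueError(f"n_residues must be >= 10, got {spec.n_residues}")
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(rng.choice(list(_ALPHABET), size=spec.n_residues))
    chain = Chain("A")
    for i, letter in enumerate(sequence):
        theta = math.radians(_TWIST * i)
        e_r = np.array([math.cos(theta), math.sin(theta), 0.0])
        e_t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        ca = _RADIUS * e_r + np.array([0.0, 0.0, _RISE * i])
        atoms = [Atom("CA", "C", ca)]
        for name, (r, t, z) in _LOCAL_OFFSETS.items():
            element = name[0]
            atoms.append(Atom(name, element, ca + r * e_r + t * e_t + z * e_z))
        chain.residues.append(Residue(_ONE_TO_THREE[letter], i + 1, atoms))
    return Structure(entry_id=f"model{spec.seed}", chains=[chain])


# ---------------------------------------------------------------------------
# Donor construction


def _mutation_positions(n: int, n_mut: int, rng: np.random.Generator) -> list[int]:
    """Evenly spread 0-based positions, avoiding the first/last two residues."""
    lo, hi = 2, n - 2
    available = hi - lo
    if n_mut > available:
        raise ValueError(f"cannot place {n_mut} mutations in {available} interior positions")
    edges = np.linspace(lo, hi, n_mut + 1)
    positions = []
    for k in range(n_mut):
        a, b = int(math.ceil(edges[k])), int(edges[k + 1])
        b = max(b, a + 1)
        choices = [p for p in range(a, min(b, hi)) if p not in positions]
        positions.append(int(rng.choice(choices)) if choices else a)
    return sorted(set(positions))


def _conservative_substitution(letter: str, rng: np.random.Generator) -> str:
    candidates = [
        aa for aa in _ALPHABET
        if aa != letter and _BLOSUM[letter][aa] >= 0
    ]
    if not candidates:  # should not happen for the fixture alphabet
        candidates = [aa for aa in _ALPHABET if aa != letter]
    return str(rng.choice(candidates))


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


def _ligand_atoms(lig: LigandSpec, center: np.ndarray, rng: np.random.Generator) -> list[Atom]:
    if lig.n_atoms == 1:
        element = _ION_ELEMENTS.get(lig.comp_id, "C")
        name = lig.comp_id if lig.comp_id in _ION_ELEMENTS else "C1"
        return [Atom(name, element, center)]
    atoms = []
    for k in range(lig.n_atoms):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = 0.0 if k == 0 else 0.8 + 0.4 * ((k - 1) % 3)
        atoms.append(Atom(f"C{k + 1}", "C", center + radius * direction))
    return atoms


def make_donor(model: Structure, spec: FixtureSpec) -> Structure:
    """A homolog of ``model`` at exactly ``spec.target_identity`` with noise,
    optional domain motion, planted ligands and a random rigid frame."""
    n = len(model.polymer_chains[0].polymer_residues)
    n_identical = spec.target_identity * n
    if abs(n_identical - round(n_identical)) > 1e-9:
        raise ValueError(
            f"identity {spec.target_identity} not representable at length {n}"
        )
    n_mut = n - int(round(n_identical))
    rng = np.random.default_rng(spec.seed + 1)

    donor = model.copy()
    donor.entry_id = f"donor{spec.seed}"
    chain = donor.polymer_chains[0]
    residues = sorted(chain.polymer_residues, key=lambda r: r.seq_id)

    # exact-identity point mutations, conservative and evenly spread
    if n_mut:
        rev = {v: k for k, v in _ONE_TO_THREE.items()}
        for pos in _mutation_positions(n, n_mut, rng):
            res = residues[pos]
            res.comp_id = _ONE_TO_THREE[_conservative_substitution(rev[res.comp_id], rng)]

    # rigid motion of the second domain
    if spec.domain_motion is not None:
        dm = spec.domain_motion
        ang = math.radians(dm.rotation_deg)
        rot = np.array([
            [math.cos(ang), -math.sin(ang), 0.0],
            [math.sin(ang), math.cos(ang), 0.0],
            [0.0, 0.0, 1.0],
        ])
        pivot = np.array([0.0, 0.0, _RISE * dm.split_after])
        shift = np.array([dm.displacement, 0.0, 0.0])
        for res in residues:
            if res.seq_id > dm.split_after:
                for atom in res.atoms:
                    atom.pos = rot @ (atom.pos - pivot) + pivot + shift

    # isotropic coordinate noise
    if spec.coord_noise_sigma > 0:
        for res in residues:
            for atom in res.atoms:
                atom.pos = atom.pos + rng.normal(0.0, spec.coord_noise_sigma, size=3)

    # plant ligands at the (possibly moved, noisy) pockets
    if spec.ligands:
        lig_chain = Chain("L")
        for idx, lig in enumerate(spec.ligands):
            pocket = np.mean([residues[i - 1].atom("CA").pos for i in lig.pocket_residues], axis=0)
            # outward = radial from the helix axis, so the ligand sits against
            # the pocket face rather than inside the coil
            direction = np.array([pocket[0], pocket[1], 0.0])
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            center = pocket + lig.offset * direction
            lig_chain.residues.append(
                Residue(lig.comp_id, 1001 + idx, _ligand_atoms(lig, center, rng),
                        is_polymer=False, auth_seq_id=1001 + idx)
            )
        donor.chains.append(lig_chain)

    # whole-structure rigid frame change
    rot, trans = _random_rigid(rng)
    for atom in donor.atoms():
        atom.pos = rot @ atom.pos + trans
    return donor


# ---------------------------------------------------------------------------
# Registry files


def make_registry(
    comp_ids,
    mappings: dict[str, tuple[str, dict[str, str], set[str]]] | None = None,
    path: str | Path = "registry.cif",
    excluded=("HOH",),
) -> Path:
    """Write a compound-list CIF.

    ``mappings`` maps analog id -> (canonical id, atom renames, atom
    deletions); plain ``comp_ids`` become identity rows.  Duplicate ids are
    written as given so loader validation can be exercised.
    """
    mappings = mappings or {}
    doc = gemmi.cif.Document()
    block = doc.add_new_block("compound_registry")
    loop = block.init_loop("_transplant_compound.", ["id", "canonical_id", "atom_renames", "atom_deletions"])
    for comp in comp_ids:
        loop.add_row([comp, comp, ".", "."])
    for analog, (canonical, renames, deletions) in mappings.items():
        rename_str = ";".join(f"{o}:{n}" for o, n in renames.items())
        deletion_str = ";".join(sorted(deletions))
        loop.add_row([
            analog, canonical,
            gemmi.cif.quote(rename_str) if rename_str else ".",
            gemmi.cif.quote(deletion_str) if deletion_str else ".",
        ])
    if excluded:
        ex_loop = block.init_loop("_excluded_compound.", ["id"])
        for comp in excluded:
            ex_loop.add_row([comp])
    path = Path(path)
    doc.write_file(str(path))
    return path
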