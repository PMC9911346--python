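"""Transplant orchestration: from a bare model and a donor collection to a
filled structure with scored, provenance-tagged transplants.

The procedure:

1. extract the model sequence and search the donor sequence database
   (HSPs sorted ascending by E-value, at most ``max_hits``);
2. filter hits to sufficiently close homologs (identity >= 25% over >= 85
   aligned residues);
3. per HSP, superpose donor on model over the matched C-alphas (global
   r.m.s.d.);
4. per transplantable compound copy in the hit (donor file order), gather
   the donor backbone within 6 A, superpose that environment on the model
   (local r.m.s.d.) and place the compound with the local transform;
5. reject the candidate if the same (canonical) compound already sits
   within 3.5 A of its centroid, or if no protein atom lies within 4 A of
   it;
6. score the placement (TCS), annotate confidence, inherit struct_conn
   records, and append the record.

Candidate order — hits ascending by E-value, compounds in donor file order
— fixes deterministically which donor wins a deduplication race.
Canonicalization happens *before* deduplication, so two analogs of the
same parent compound from different donors deduplicate against each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy.spatial import cKDTree

from .homology import Hsp, build_donor_db, filter_hits, find_homologs
from .registry import Registry, canonicalize
from .scoring import ClashAssessment, ConfidenceThresholds, assign_confidence, load_vdw_radii, tcs
from .structure import (
    Atom,
    AtomAddress,
    Residue,
    StructConn,
    Structure,
    next_het_chain_ids,
    read_structure,
    write_filled_structure,
)
from .superpose import AlignmentError, RigidTransform, global_align, local_align, local_environment

logger = logging.getLogger(__name__)

__all__ = [
    "FillConfig",
    "TransplantRecord",
    "FillResult",
    "DonorDirectory",
    "fill",
    "is_duplicate",
    "has_protein_contact",
    "place_compound",
    "inherit_struct_conn",
]


@dataclass(frozen=True)
class FillConfig:
    min_identity: float = 0.25
    min_hsp_length: int = 85
    env_radius: float = 6.0       # A, local-environment gathering
    dedup_radius: float = 3.5     # A, same-compound centroid deduplication
    contact_radius: float = 4.0   # A, minimum protein proximity
    clash_cutoff: float = 4.0     # A, TCS pair cutoff
    max_hits: int = 250
    thresholds: ConfidenceThresholds = field(default_factory=ConfidenceThresholds)

    def __post_init__(self) -> None:
        for name in ("env_radius", "dedup_radius", "contact_radius", "clash_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be a fraction in [0, 1]")
        if self.min_hsp_length < 1 or self.max_hits < 1:
            raise ValueError("min_hsp_length and max_hits must be >= 1")


@dataclass
class TransplantRecord:
    """One placed compound with provenance and quality scores."""

    comp_id: str               # canonical id
    original_comp_id: str      # donor id before analog mapping
    donor_entry: str
    donor_chain: str
    donor_copy: int
    evalue: float
    identity_fraction: float
    alignment_length: int
    global_rmsd: float
    local_rmsd: float
    tcs: float
    confidence_local: str
    confidence_tcs: str
    residue: Residue           # placed het group, model frame
    placed_chain_id: str
    centroid: np.ndarray
    inherited_conns: list[StructConn] = field(default_factory=list)
    mono_atomic: bool = False  # tagged for exclusion from population stats

    @property
    def placed_atoms(self) -> list[Atom]:
        return self.residue.atoms


@dataclass
class FillResult:
    model: Structure
    transplants: list[TransplantRecord]
    rejections: list[dict] = field(default_factory=list)  # machine-readable skip log

    def filled_structure(self, path: str | Path) -> Structure:
        return write_filled_structure(self.model, self.transplants, path)


class DonorDirectory:
    """Donor access over a directory of mmCIF files keyed by entry id
    (the layout of a local re-refined-structure mirror)."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self._cache: dict[str, Structure] = {}

    def entry_ids(self) -> list[str]:
        return sorted(p.stem for p in self.directory.glob("*.cif"))

    def get(self, entry_id: str) -> Structure:
        if entry_id not in self._cache:
            self._cache[entry_id] = read_structure(self.directory / f"{entry_id}.cif")
        return self._cache[entry_id]

    def structures(self) -> list[Structure]:
        return [self.get(e) for e in self.entry_ids()]


def is_duplicate(
    candidate_centroid: np.ndarray,
    comp_id: str,
    placed: list[TransplantRecord],
    dedup_radius: float = 3.5,
) -> bool:
    """True iff the same (canonical) compound was already placed within
    ``dedup_radius`` (inclusive) of the candidate centroid."""
    for rec in placed:
        if rec.comp_id == comp_id:
            if np.linalg.norm(rec.centroid - candidate_centroid) <= dedup_radius + 1e-9:
                return True
    return False


def has_protein_contact(
    candidate_atoms: list[Atom], model: Structure, contact_radius: float = 4.0
) -> bool:
    """True iff any non-hydrogen model polymer atom lies within
    ``contact_radius`` (inclusive) of any non-hydrogen candidate atom.
    Previously placed transplants do not count as protein."""
    prot = model.polymer_heavy_coords()
    cand = np.array([a.pos for a in candidate_atoms if not a.is_hydrogen], dtype=float).reshape(-1, 3)
    if len(prot) == 0 or len(cand) == 0:
        return False
    tree = cKDTree(prot)
    d, _ = tree.query(cand)
    return bool(np.min(d) <= contact_radius + 1e-9)


def place_compound(compound: Residue, transform: RigidTransform) -> Residue:
    """Map every atom of the het group (all conformers) into the model frame.

    Names, elements, occupancies, altlocs and B-factors are unchanged.
    """
    placed = compound.copy()
    for atom in placed.atoms:
        atom.pos = transform.apply(atom.pos)
    return placed


def inherit_struct_conn(
    donor: Structure,
    compound_chain_id: str,
    compound: Residue,
    placed: Residue,
    placed_chain_id: str,
    hsp: Hsp,
    model: Structure,
) -> list[StructConn]:
    """Re-address donor struct_conn records touching the compound.

    The compound endpoint is redirected to the placed copy; a protein
    endpoint is mapped through the HSP residue correspondence to the model
    residue if it is covered, otherwise the record is dropped with a
    warning.  Records whose mapped endpoints no longer resolve (deleted or
    renamed-away atoms) are dropped likewise.
    """
    d2q = hsp.donor_to_query()
    model_chain = model.polymer_chains[0]
    placed_names = {a.name for a in placed.atoms}
    out: list[StructConn] = []
    for rec in donor.struct_conn:
        ends = (rec.ptnr1, rec.ptnr2)
        on_compound = [
            e.chain_id == compound_chain_id and e.seq_id == compound.seq_id and e.comp_id == compound.comp_id
            for e in ends
        ]
        if not any(on_compound):
            continue
        new_ends: list[AtomAddress | None] = []
        for endpoint, is_comp in zip(ends, on_compound):
            if is_comp:
                if endpoint.atom_name not in placed_names:
                    new_ends.append(None)
                else:
                    new_ends.append(
                        AtomAddress(placed_chain_id, placed.seq_id, placed.comp_id, endpoint.atom_name)
                    )
            else:
                q_seq = d2q.get(endpoint.seq_id) if endpoint.chain_id == hsp.donor_chain else None
                res = model_chain.residue(q_seq) if q_seq is not None else None
                if res is None or res.atom(endpoint.atom_name) is None:
                    new_ends.append(None)
                else:
                    new_ends.append(AtomAddress(model_chain.id, res.seq_id, res.comp_id, endpoint.atom_name))
        if any(e is None for e in new_ends):
            logger.warning(
                "struct_conn %s of %s %s dropped: partner not mappable",
                rec.conn_type, donor.entry_id, compound.comp_id,
            )
            continue
        out.append(StructConn(rec.conn_type, new_ends[0], new_ends[1], rec.distance))
    return out


def _reject(log: list[dict], reason: str, **info) -> None:
    entry = {"reason": reason, **info}
    log.append(entry)
    logger.info("candidate rejected: %s", entry)


def fill(
    model: Structure,
    donors: DonorDirectory | Iterable[Structure],
    registry: Registry,
    config: FillConfig | None = None,
    post_process: Callable[[TransplantRecord, Structure], TransplantRecord] | None = None,
) -> FillResult:
    """Run the full transplant procedure on a protein-only model.

    ``post_process`` is an optional hook applied to each accepted record
    (e.g. an external energy-minimization step); if it moves atoms it must
    return the updated record, whose TCS is then recomputed.
    """
    config = config or FillConfig()
    donor_structures = donors.structures() if isinstance(donors, DonorDirectory) else list(donors)
    by_entry = {s.entry_id: s for s in donor_structures}
    radii = load_vdw_radii()

    query = None
    for chain in model.polymer_chains:
        from .structure import extract_sequence

        query = extract_sequence(model, chain.id)
        break
    if query is None:
        raise ValueError("model has no polymer chain")

    db = build_donor_db(donor_structures)
    hsps = find_homologs(query, db, max_hits=config.max_hits)
    hsps = filter_hits(hsps, config.min_identity, config.min_hsp_length)

    transplants: list[TransplantRecord] = []
    rejections: list[dict] = []
    chain_ids = next_het_chain_ids(model)
    protein_atoms = [
        a
        for c in model.chains
        for r in c.residues
        if r.is_polymer
        for a in r.atoms
        if not a.is_hydrogen
    ]

    for hsp in hsps:
        donor = by_entry[hsp.donor_entry]
        try:
            global_result = global_align(model, donor, hsp)
        except AlignmentError as exc:
            _reject(rejections, "global-align-failed", donor=hsp.donor_entry, chain=hsp.donor_chain, detail=str(exc))
            continue

        for chain_id, comp_id, copy_idx, het in donor.het_groups():
            if not registry.is_transplantable(comp_id):
                continue
            spec = registry.spec(comp_id)
            candidate = canonicalize(het, spec)

            env = local_environment(donor, candidate, config.env_radius)
            try:
                local_result = local_align(model, env, hsp)
            except AlignmentError as exc:
                _reject(
                    rejections, "too-few-pairs",
                    donor=hsp.donor_entry, chain=chain_id, comp=comp_id, copy=copy_idx, detail=str(exc),
                )
                continue

            placed = place_compound(candidate, local_result.transform)
            centroid = placed.centroid()

            if is_duplicate(centroid, placed.comp_id, transplants, config.dedup_radius):
                _reject(rejections, "duplicate", donor=hsp.donor_entry, comp=placed.comp_id, copy=copy_idx)
                continue
            if not has_protein_contact(placed.atoms, model, config.contact_radius):
                _reject(rejections, "no-contact", donor=hsp.donor_entry, comp=placed.comp_id, copy=copy_idx)
                continue

            clash = tcs(placed.heavy_atoms, protein_atoms, config.clash_cutoff, radii)
            conf_local, conf_tcs = assign_confidence(local_result.rmsd, clash.tcs, config.thresholds)
            placed_chain = next(chain_ids)
            record = TransplantRecord(
                comp_id=placed.comp_id,
                original_comp_id=comp_id,
                donor_entry=hsp.donor_entry,
                donor_chain=hsp.donor_chain,
                donor_copy=copy_idx,
                evalue=hsp.evalue,
                identity_fraction=hsp.identity_fraction,
                alignment_length=hsp.alignment_length,
                global_rmsd=global_result.rmsd,
                local_rmsd=local_result.rmsd,
                tcs=clash.tcs,
                confidence_local=conf_local,
                confidence_tcs=conf_tcs,
                residue=placed,
                placed_chain_id=placed_chain,
                centroid=centroid,
                mono_atomic=len(placed.heavy_atoms) == 1,
            )
            record.inherited_conns = inherit_struct_conn(
                donor, chain_id, het, placed, placed_chain, hsp, model
            )
            if post_process is not None:
                record = post_process(record, model)
                clash = tcs(record.residue.heavy_atoms, protein_atoms, config.clash_cutoff, radii)
                record.tcs = clash.tcs
                record.confidence_local, record.confidence_tcs = assign_confidence(
                    record.local_rmsd, record.tcs, config.thresholds
                )
            transplants.append(record)

    return FillResult(model=model, transplants=transplants, rejections=rejections)
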