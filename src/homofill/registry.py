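"""Transferable-compound registry with analog-to-canonical mapping.

The registry is a CIF data file listing every chemical component that may be
transplanted, optionally with a canonicalization rule: cofactor analogs are
mapped to their parent compound by atom renaming and atom deletion (for
example the non-hydrolysable ATP analog AGS maps to ATP), while adducts are
trimmed down to the parent by deletion alone.  Analogs that merely lack atoms
relative to the parent are kept as-is: canonicalization never invents atoms
and never moves one.

File dialect (one loop, one row per compound)::

    loop_
    _transplant_compound.id
    _transplant_compound.canonical_id
    _transplant_compound.atom_renames     # "OLD:NEW;OLD2:NEW2" or .
    _transplant_compound.atom_deletions   # "NAME;NAME2" or .
    HEM  HEM  .          .
    AGS  ATP  S1G:O1G    .

An optional second loop ``_excluded_compound.id`` lists components that are
explicitly never transplanted (crystallization agents and the like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi

from .structure import Residue

logger = logging.getLogger(__name__)

__all__ = ["CompoundSpec", "Registry", "RegistryError", "load_registry", "canonicalize"]


class RegistryError(ValueError):
    """Malformed compound-registry file."""


@dataclass(frozen=True)
class CompoundSpec:
    comp_id: str
    canonical_id: str
    atom_renames: dict[str, str] = field(default_factory=dict)
    atom_deletions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.atom_renames) & set(self.atom_deletions)
        if overlap:
            raise RegistryError(
                f"{self.comp_id}: atoms both renamed and deleted: {sorted(overlap)}"
            )


@dataclass
class Registry:
    specs: dict[str, CompoundSpec] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    def is_transplantable(self, comp_id: str) -> bool:
        return comp_id in self.specs

    def spec(self, comp_id: str) -> CompoundSpec:
        return self.specs[comp_id]

    def __len__(self) -> int:
        return len(self.specs)


def _parse_renames(raw: str, row_no: int) -> dict[str, str]:
    renames: dict[str, str] = {}
    for part in filter(None, (p.strip() for p in raw.split(";"))):
        if ":" not in part:
            raise RegistryError(f"row {row_no}: malformed rename {part!r} (expected OLD:NEW)")
        old, new = part.split(":", 1)
        if old in renames:
            raise RegistryError(f"row {row_no}: atom {old!r} renamed twice")
        renames[old] = new
    return renames


def load_registry(path: str | Path) -> Registry:
    """Load the compound-list CIF into a :class:`Registry`.

    Raises :class:`RegistryError` on duplicate compound ids, malformed
    mapping rules, or rename targets that collide with surviving atom names.
    """
    path = Path(path)
    try:
        block = gemmi.cif.read(str(path)).sole_block()
    except Exception as exc:
        raise RegistryError(f"{path}: not parseable as CIF: {exc}") from exc

    table = block.find("_transplant_compound.", ["id", "canonical_id", "atom_renames", "atom_deletions"])
    specs: dict[str, CompoundSpec] = {}
    for row_no, row in enumerate(table, start=1):
        comp_id = row[0]
        canonical = row[1] if row[1] not in (".", "?") else comp_id
        renames = _parse_renames("" if row[2] in (".", "?") else gemmi.cif.as_string(row[2]), row_no)
        deletions = frozenset(
            filter(None, (p.strip() for p in ("" if row[3] in (".", "?") else gemmi.cif.as_string(row[3])).split(";")))
        )
        if comp_id in specs:
            raise RegistryError(f"row {row_no}: duplicate compound id {comp_id!r}")
        collisions = set(renames.values()) & (set(renames) - set(renames.values()))
        if collisions:
            raise RegistryError(
                f"row {row_no}: rename target collides with surviving atom name: {sorted(collisions)}"
            )
        specs[comp_id] = CompoundSpec(comp_id, canonical, renames, deletions)

    excluded = frozenset(row[0] for row in block.find("_excluded_compound.", ["id"]))
    registry = Registry(specs=specs, excluded=excluded)

    # canonical targets of a mapping must themselves be fixed points
    for spec in specs.values():
        target = specs.get(spec.canonical_id)
        if target is not None and target.canonical_id != target.comp_id:
            raise RegistryError(f"{spec.comp_id}: canonical target {spec.canonical_id} is itself mapped")
    return registry


def is_transplantable(registry: Registry, comp_id: str) -> bool:
    return registry.is_transplantable(comp_id)


def canonicalize(compound: Residue, spec: CompoundSpec) -> Residue:
    """Apply an analog-to-canonical mapping rule to a het group.

    Deletions are applied first, then renames; the component id becomes the
    canonical id.  Coordinates are never touched and no atom is invented: a
    rename whose source atom is absent is logged and skipped (analogs may
    genuinely lack atoms relative to their parent).
    """
    if compound.comp_id != spec.comp_id:
        raise ValueError(f"spec for {spec.comp_id} applied to {compound.comp_id}")
    out = compound.copy()
    out.comp_id = spec.canonical_id
    out.atoms = [a for a in out.atoms if a.name not in spec.atom_deletions]
    present = {a.name for a in out.atoms}
    for old, new in spec.atom_renames.items():
        if old not in present:
            logger.warning("canonicalize %s->%s: atom %s absent, rename skipped",
                           spec.comp_id, spec.canonical_id, old)
    for a in out.atoms:
        if a.name in spec.atom_renames:
            a.name = spec.atom_renames[a.name]
    return out
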