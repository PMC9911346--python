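"""Transplant quality scores and confidence annotation.

Three quantities are computed here:

* **TCS** (transplant clash score) — the root-mean-square van der Waals
  overlap over all transplant-protein atom pairs closer than 4 A::

      TCS = sqrt( sum_i overlap_i^2 / n_distances )

  with ``overlap = max(0, r_a + r_b - d)`` and ``n_distances`` the number of
  pairs with d < 4 A.  Pairs inside the cutoff but without overlap still
  count in the denominator (a literal reading of "over all atomic distances
  shorter than 4 A"); both that choice and the clamp are switchable for
  sensitivity analysis.

* **LEV** (local environment validation) — given a filled model and an
  experimentally determined reference with identical sequence, the all-atom
  r.m.s.d. over the ligand plus all reference protein atoms within 6 A of
  it, after least-squares superposition on the paired binding-site protein
  atoms.

* **Confidence labels** — high/medium/low from two cutoffs per score.  The
  shipped defaults (local r.m.s.d. 0.92 / 3.10 A, TCS 0.64 / 1.27 A) are
  the Q3 + 1.5*IQR outlier bounds of the large-scale transplant populations
  at >=70% donor identity and over all identities respectively;
  :func:`derive_thresholds` recomputes that statistic on any population.

The vdW radius table ships as a small TSV; published tables differ for
metals, so absolute TCS values carry a table-choice caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure
from .superpose import AlignmentError, kabsch

__all__ = [
    "ClashAssessment",
    "ConfidenceThresholds",
    "RadiusTableError",
    "LevUndefinedError",
    "load_vdw_radii",
    "tcs",
    "lev_score",
    "assign_confidence",
    "derive_thresholds",
]


class RadiusTableError(KeyError):
    """An element is missing from the vdW radius table."""


class LevUndefinedError(ValueError):
    """Too few pairable binding-site atoms to define a LEV score."""


class InsufficientDataError(ValueError):
    """Too few observations to derive a threshold."""


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    """Element -> vdW radius (A).  Default table ships with the package."""
    if path is None:
        text = resources.files("homofill.data").joinpath("vdw_radii.tsv").read_text()
    else:
        text = Path(path).read_text()
    radii: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, value = line.split()
        radii[element.upper()] = float(value)
    return radii


@dataclass(frozen=True)
class ClashAssessment:
    overlaps: tuple[float, ...]  # per-pair overlaps (clamped), A
    n_distances: int             # pairs with distance < cutoff
    tcs: float                   # A


def tcs(
    transplant_atoms: list[Atom],
    protein_atoms: list[Atom],
    cutoff: float = 4.0,
    radii: dict[str, float] | None = None,
    *,
    clamp_overlap: bool = True,
    count_nonoverlapping: bool = True,
) -> ClashAssessment:
    """Transplant clash score between a placed compound and the protein.

    Hydrogens must already be excluded from both atom lists.  Raises
    :class:`RadiusTableError` if an element has no tabulated radius.
    """
    if radii is None:
        radii = load_vdw_radii()

    def radius(atom: Atom) -> float:
        try:
            return radii[atom.element.upper()]
        except KeyError:
            raise RadiusTableError(f"no van der Waals radius for element {atom.element!r}") from None

    t_pos = np.array([a.pos for a in transplant_atoms], dtype=float).reshape(-1, 3)
    p_pos = np.array([a.pos for a in protein_atoms], dtype=float).reshape(-1, 3)
    t_rad = np.array([radius(a) for a in transplant_atoms], dtype=float)
    p_rad = np.array([radius(a) for a in protein_atoms], dtype=float)

    overlaps: list[float] = []
    n_distances = 0
    if len(t_pos) and len(p_pos):
        tree = cKDTree(p_pos)
        for i, pos in enumerate(t_pos):
            for j in tree.query_ball_point(pos, cutoff):
                d = float(np.linalg.norm(pos - p_pos[j]))
                if d >= cutoff:  # strict "< 4 A" per the definition
                    continue
                overlap = t_rad[i] + p_rad[j] - d
                if clamp_overlap:
                    overlap = max(0.0, overlap)
                if overlap > 0.0 or count_nonoverlapping:
                    n_distances += 1
                    overlaps.append(overlap)
    if n_distances == 0:
        return ClashAssessment((), 0, 0.0)
    arr = np.array(overlaps)
    return ClashAssessment(tuple(overlaps), n_distances, float(np.sqrt((arr**2).mean())))


# ---------------------------------------------------------------------------
# LEV score


def _protein_atom_index(structure: Structure) -> dict[tuple[int, int, str], Atom]:
    """(chain index, residue seq_id, atom name) -> non-hydrogen polymer atom.

    Chains are keyed by order rather than id so that a reference determined
    in a different chain-naming convention still pairs up.
    """
    index: dict[tuple[int, int, str], Atom] = {}
    for ci, chain in enumerate(structure.polymer_chains):
        for res in chain.residues:
            for atom in res.atoms:
                if not atom.is_hydrogen and (ci, res.seq_id, atom.name) not in index:
                    index[(ci, res.seq_id, atom.name)] = atom
    return index


def lev_score(
    filled: Structure,
    transplant: Residue,
    reference: Structure,
    reference_ligand: Residue,
    radius: float = 6.0,
) -> float:
    """Local environment validation score of one transplant, in Angstrom.

    The binding site is built on the reference: its ligand's non-hydrogen
    atoms plus every non-hydrogen reference protein atom within ``radius``
    of any ligand atom.  Counterparts in the filled model are found by
    residue number + atom name (the sequences are identical by assumption);
    ligand atoms pair by name.  The two sites are superposed by least
    squares on the paired protein atoms and the score is the all-atom
    r.m.s.d. over protein and ligand pairs together.
    """
    lig_ref = reference_ligand.heavy_atoms
    lig_pos = np.array([a.pos for a in lig_ref], dtype=float).reshape(-1, 3)
    if len(lig_pos) == 0:
        raise LevUndefinedError("reference ligand has no heavy atoms")
    tree = cKDTree(lig_pos)

    ref_index = _protein_atom_index(reference)
    fill_index = _protein_atom_index(filled)

    prot_ref, prot_fill = [], []
    for key, atom in ref_index.items():
        d, _ = tree.query(atom.pos)
        if d <= radius + 1e-9:
            other = fill_index.get(key)
            if other is not None:
                prot_ref.append(atom.pos)
                prot_fill.append(other.pos)
    if len(prot_ref) < 3:
        raise LevUndefinedError(f"only {len(prot_ref)} pairable binding-site protein atoms")

    fill_lig = {a.name: a for a in transplant.heavy_atoms}
    lig_pairs_ref, lig_pairs_fill = [], []
    for atom in lig_ref:
        other = fill_lig.get(atom.name)
        if other is None:
            warnings.warn(f"LEV: ligand atom {atom.name} missing in transplant; pair dropped")
            continue
        lig_pairs_ref.append(atom.pos)
        lig_pairs_fill.append(other.pos)

    fit = kabsch(np.array(prot_fill), np.array(prot_ref))
    ref_all = np.vstack([np.array(prot_ref), np.array(lig_pairs_ref).reshape(-1, 3)])
    fill_all = np.vstack([np.array(prot_fill), np.array(lig_pairs_fill).reshape(-1, 3)])
    diff = fit.transform.apply(ref_all) - fill_all
    return float(np.sqrt((diff * diff).sum() / len(ref_all)))


# ---------------------------------------------------------------------------
# Confidence annotation


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Two-cutoff annotation bounds per score, Angstrom.

    The *medium* cutoff separates high from medium confidence, the *low*
    cutoff medium from low; both comparisons are inclusive on the left.
    """

    local_rmsd_medium: float = 0.92
    local_rmsd_low: float = 3.10
    tcs_medium: float = 0.64
    tcs_low: float = 1.27

    def __post_init__(self) -> None:
        if not (self.local_rmsd_medium < self.local_rmsd_low and self.tcs_medium < self.tcs_low):
            raise ValueError("medium cutoff must be below low cutoff")


def _label(value: float, medium: float, low: float) -> str:
    if value <= medium:
        return "high"
    if value <= low:
        return "medium"
    return "low"


def assign_confidence(
    local_rmsd: float, tcs_value: float, thresholds: ConfidenceThresholds | None = None
) -> tuple[str, str]:
    """(confidence_local, confidence_tcs) labels in {high, medium, low}."""
    t = thresholds or ConfidenceThresholds()
    return (
        _label(local_rmsd, t.local_rmsd_medium, t.local_rmsd_low),
        _label(tcs_value, t.tcs_medium, t.tcs_low),
    )


def derive_thresholds(values) -> float:
    """Upper outlier bound Q3 + 1.5*(Q3 - Q1) of a score population.

    Quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise InsufficientDataError(f"need >= 4 values, got {arr.size}")
    q1, q3 = np.percentile(arr, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))
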