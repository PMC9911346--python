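"""Rigid-body least-squares superposition (Kabsch) and its two uses:

* the *global* alignment — C-alpha atoms of the residues matched in an HSP,
  donor chain onto the model; its r.m.s.d. measures overall similarity and
  can be inflated by inter-domain motion;
* the *local* alignment — donor backbone atoms within 6 A of a candidate
  compound, mapped through the HSP residue correspondence onto the model;
  its transform is the one that places the compound, and its r.m.s.d. is
  the per-transplant quality proxy.

Backbone means {N, CA, C, O}.  All distance cutoffs are inclusive.  Only
the lowest-altloc conformer of a donor environment atom contributes to
alignment pairs, which keeps runs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .homology import Hsp
from .structure import Residue, Structure

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "AlignmentError",
    "EnvAtom",
    "kabsch",
    "global_align",
    "local_environment",
    "local_align",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class AlignmentError(ValueError):
    """Too few or degenerate atom pairs for a superposition."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (no reflection)."""

    rotation: np.ndarray   # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AlignmentResult:
    transform: RigidTransform  # maps donor frame -> model frame
    rmsd: float                # A, over the paired atoms
    n_pairs: int


def kabsch(fixed: np.ndarray, moving: np.ndarray) -> AlignmentResult:
    """Least-squares superposition of ``moving`` onto ``fixed``.

    Returns the proper rotation + translation minimizing the sum of squared
    pair distances and the resulting r.m.s.d.  Reflections are excluded.
    Raises :class:`AlignmentError` for fewer than 3 pairs or collinear /
    degenerate point sets.
    """
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    if fixed.shape != moving.shape:
        raise AlignmentError(f"point sets differ in size: {fixed.shape} vs {moving.shape}")
    n = len(fixed)
    if n < 3:
        raise AlignmentError(f"need at least 3 pairs, got {n}")

    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    if np.linalg.matrix_rank(x, tol=1e-9) < 2 and np.linalg.matrix_rank(y, tol=1e-9) < 2:
        raise AlignmentError("degenerate (collinear) point sets")

    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cf - rot @ cm
    transform = RigidTransform(rot, t)
    diff = transform.apply(moving) - fixed
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return AlignmentResult(transform, rmsd, n)


def _ca_position(res: Residue | None) -> np.ndarray | None:
    if res is None:
        return None
    atom = res.atom("CA")
    return None if atom is None or atom.is_hydrogen else atom.pos


def global_align(model: Structure, donor: Structure, hsp: Hsp) -> AlignmentResult:
    """Superpose the donor chain on the model over the HSP-matched C-alphas.

    Each HSP is aligned individually; the returned r.m.s.d. is the stored
    global r.m.s.d. of the hit.
    """
    model_chain = model.polymer_chains[0]
    donor_chain = donor.chain(hsp.donor_chain)
    fixed, moving = [], []
    for q_seq, d_seq in hsp.aligned_pairs:
        mp = _ca_position(model_chain.residue(q_seq))
        dp = _ca_position(donor_chain.residue(d_seq))
        if mp is not None and dp is not None:
            fixed.append(mp)
            moving.append(dp)
    if len(fixed) < 3:
        raise AlignmentError(f"HSP {hsp.donor_entry}_{hsp.donor_chain}: <3 usable CA pairs")
    return kabsch(np.array(fixed), np.array(moving))


@dataclass(frozen=True)
class EnvAtom:
    """A donor backbone atom in a compound's local environment."""

    chain_id: str
    seq_id: int
    atom_name: str
    pos: np.ndarray


def local_environment(donor: Structure, compound: Residue, radius: float = 6.0) -> list[EnvAtom]:
    """All donor polymer backbone atoms within ``radius`` (inclusive) of any
    non-hydrogen compound atom, in the donor frame."""
    lig = compound.heavy_coords()
    if len(lig) == 0:
        return []
    tree = cKDTree(lig)
    env: list[EnvAtom] = []
    for chain in donor.chains:
        for res in chain.residues:
            if not res.is_polymer:
                continue
            for name in BACKBONE_ATOMS:
                atom = res.atom(name)  # lowest altloc conformer
                if atom is None or atom.is_hydrogen:
                    continue
                d, _ = tree.query(atom.pos)
                if d <= radius + 1e-9:
                    env.append(EnvAtom(chain.id, res.seq_id, name, atom.pos))
    return env


def local_align(model: Structure, donor_env: list[EnvAtom], hsp: Hsp) -> AlignmentResult:
    """Superpose the donor binding-site backbone onto the model.

    Donor environment atoms are mapped to model atoms through the HSP
    residue correspondence plus identical atom name; atoms outside the HSP
    (or on other chains) are dropped.  The returned transform is the one
    used to place the compound.  Raises :class:`AlignmentError` when fewer
    than 3 pairs can be mapped — the caller rejects the candidate.
    """
    d2q = hsp.donor_to_query()
    model_chain = model.polymer_chains[0]
    fixed, moving = [], []
    for env in donor_env:
        if env.chain_id != hsp.donor_chain:
            continue
        q_seq = d2q.get(env.seq_id)
        if q_seq is None:
            continue
        res = model_chain.residue(q_seq)
        if res is None:
            continue
        atom = res.atom(env.atom_name)
        if atom is None or atom.is_hydrogen:
            continue
        fixed.append(atom.pos)
        moving.append(env.pos)
    if len(fixed) < 3:
        raise AlignmentError(f"local alignment: only {len(fixed)} mappable backbone pairs")
    return kabsch(np.array(fixed), np.array(moving))
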