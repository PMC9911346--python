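"""Clash scoring (TCS), local-environment validation (LEV), and the
IQR-based confidence machinery."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from homofill.scoring import (
    ConfidenceThresholds,
    LevUndefinedError,
    RadiusTableError,
    assign_confidence,
    derive_thresholds,
    lev_score,
    load_vdw_radii,
    tcs,
)
from homofill.scoring import InsufficientDataError
from homofill.structure import Atom, Chain, Residue, Structure


def atom(name, element, pos):
    return Atom(name, element, np.asarray(pos, dtype=float))


def oracle_tcs(t_atoms, p_atoms, radii, cutoff=4.0):
    """Direct arithmetic evaluation: r.m.s. clamped overlap over all pairs
    with distance strictly below the cutoff."""
    overlaps = []
    for a in t_atoms:
        for b in p_atoms:
            d = math.dist(a.pos, b.pos)
            if d < cutoff:
                overlaps.append(max(0.0, radii[a.element] + radii[b.element] - d))
    if not overlaps:
        return 0.0, 0
    return math.sqrt(sum(o * o for o in overlaps) / len(overlaps)), len(overlaps)


RADII = load_vdw_radii()


def test_no_pair_inside_cutoff():
    result = tcs([atom("C1", "C", (0, 0, 0))], [atom("CA", "C", (5, 0, 0))])
    assert result.n_distances == 0
    assert result.tcs == 0.0


def test_single_pair_hand_value():
    # one C-C pair at 3.0 A with r_C = 1.70: overlap 0.40
    result = tcs([atom("C1", "C", (0, 0, 0))], [atom("CA", "C", (3.0, 0, 0))])
    assert result.n_distances == 1
    assert result.tcs == pytest.approx(2 * RADII["C"] - 3.0, abs=1e-12)


def test_zero_overlap_pair_counts_in_denominator():
    # overlaps 0.3 and 0.4 plus a zero-overlap pair at 3.9 A
    t = [atom("C1", "C", (0, 0, 0))]
    p = [
        atom("A1", "C", (3.10, 0, 0)),   # overlap 0.30
        atom("A2", "C", (0, 3.00, 0)),   # overlap 0.40
        atom("A3", "C", (0, 0, 3.90)),   # within 4 A, no overlap (3.9 > 3.4)
    ]
    result = tcs(t, p)
    assert result.n_distances == 3
    assert result.tcs == pytest.approx(math.sqrt((0.09 + 0.16 + 0.0) / 3), abs=1e-9)


def test_cutoff_is_strict():
    # the definition counts distances strictly shorter than 4 A
    at_cutoff = tcs([atom("C1", "C", (0, 0, 0))], [atom("A1", "C", (4.0, 0, 0))])
    assert at_cutoff.n_distances == 0
    just_inside = tcs([atom("C1", "C", (0, 0, 0))], [atom("A1", "C", (3.999, 0, 0))])
    assert just_inside.n_distances == 1


def test_missing_element_raises():
    with pytest.raises(RadiusTableError, match="XX"):
        tcs([atom("Q1", "XX", (0, 0, 0))], [atom("CA", "C", (3, 0, 0))])


@pytest.mark.parametrize("seed", range(5))
def test_tcs_matches_direct_arithmetic_on_random_configs(seed):
    rng = np.random.default_rng(seed)
    elements = ["C", "N", "O", "S", "P", "ZN"]
    t_atoms = [atom(f"T{i}", rng.choice(elements), rng.uniform(-3, 3, 3)) for i in range(4)]
    p_atoms = [atom(f"P{i}", rng.choice(elements), rng.uniform(-5, 5, 3)) for i in range(25)]
    expected, n = oracle_tcs(t_atoms, p_atoms, RADII)
    result = tcs(t_atoms, p_atoms)
    assert result.n_distances == n
    assert result.tcs == pytest.approx(expected, abs=1e-12)


def test_tcs_invariant_under_common_rigid_motion():
    rng = np.random.default_rng(7)
    t_atoms = [atom(f"T{i}", "C", rng.uniform(-2, 2, 3)) for i in range(3)]
    p_atoms = [atom(f"P{i}", "N", rng.uniform(-4, 4, 3)) for i in range(10)]
    base = tcs(t_atoms, p_atoms)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    shift = np.array([10.0, -5.0, 2.0])
    t2 = [atom(a.name, a.element, rot @ a.pos + shift) for a in t_atoms]
    p2 = [atom(a.name, a.element, rot @ a.pos + shift) for a in p_atoms]
    moved = tcs(t2, p2)
    assert moved.tcs == pytest.approx(base.tcs, abs=1e-9)
    assert moved.n_distances == base.n_distances


def test_tcs_monotone_under_ligand_burial():
    """Pushing the ligand into the protein along a fixed axis never lowers
    the clash score while pair membership is stable."""
    p_atoms = [atom("P1", "C", (0, 0, 0)), atom("P2", "C", (0, 1.5, 0))]
    previous = -1.0
    for d in np.linspace(3.3, 1.0, 8):
        value = tcs([atom("C1", "C", (d, 0, 0))], p_atoms).tcs
        assert value >= previous - 1e-12
        previous = value


# ---------------------------------------------------------------------------
# LEV


def _site_structure(lig_shift=0.0, n_res=15):
    """Protein residues in a ring with a 10-atom ligand at the center."""
    chain = Chain("A")
    for i in range(n_res):
        ang = 2 * math.pi * i / n_res
        center = np.array([6.0 * math.cos(ang), 6.0 * math.sin(ang), 0.0])
        names = ["N", "CA", "C", "O"]
        atoms = [Atom(n, n[0], center + np.array([0.4 * k, 0.0, 0.2 * k])) for k, n in enumerate(names)]
        chain.residues.append(Residue("ALA", i + 1, atoms))
    rng = np.random.default_rng(5)
    lig_atoms = [
        Atom(f"C{k + 1}", "C", rng.uniform(-1.5, 1.5, 3) + np.array([lig_shift, 0.0, 0.0]))
        for k in range(10)
    ]
    lig = Residue("LIG", 500, lig_atoms, is_polymer=False)
    s = Structure("site", [chain, Chain("L", [lig])])
    return s, lig


def test_lev_zero_for_identical_complex():
    ref, ref_lig = _site_structure()
    filled, fill_lig = _site_structure()
    assert lev_score(filled, fill_lig, ref, ref_lig) == pytest.approx(0.0, abs=1e-12)


def test_lev_displaced_ligand_analytic():
    """Ligand displaced by delta in an otherwise identical site: protein fit
    is the identity, so LEV = sqrt(n_lig * delta^2 / n_site)."""
    delta = 1.0
    ref, ref_lig = _site_structure()
    filled, fill_lig = _site_structure(lig_shift=delta)
    n_prot = sum(
        1 for r in ref.chains[0].residues for a in r.atoms
        if min(np.linalg.norm(a.pos - la.pos) for la in ref_lig.atoms) <= 6.0
    )
    n_lig = 10
    expected = math.sqrt(n_lig * delta**2 / (n_prot + n_lig))
    assert n_prot >= 3
    assert lev_score(filled, fill_lig, ref, ref_lig) == pytest.approx(expected, rel=1e-6)


def test_lev_invariant_to_reference_frame():
    ref, ref_lig = _site_structure()
    filled, fill_lig = _site_structure(lig_shift=0.7)
    base = lev_score(filled, fill_lig, ref, ref_lig)
    rot = Rotation.from_euler("zyx", [1.0, 0.4, -0.9]).as_matrix()
    for a in ref.atoms():
        a.pos = rot @ a.pos + np.array([3.0, -8.0, 12.0])
    assert lev_score(filled, fill_lig, ref, ref_lig) == pytest.approx(base, abs=1e-9)


def test_lev_perturbed_site_monte_carlo():
    """Site atoms jittered by sigma: LEV stays in the Monte-Carlo band of the
    sigma*sqrt(3) expectation."""
    sigma = 0.3
    values = []
    for seed in range(20):
        ref, ref_lig = _site_structure()
        filled, fill_lig = _site_structure()
        rng = np.random.default_rng(1000 + seed)
        for a in filled.atoms():
            a.pos = a.pos + rng.normal(0, sigma, 3)
        values.append(lev_score(filled, fill_lig, ref, ref_lig))
    expected = sigma * math.sqrt(3)
    assert 0.6 * expected <= np.mean(values) <= 1.1 * expected


def test_lev_undefined_without_pairable_site():
    ref, ref_lig = _site_structure()
    lone = Residue("LIG", 1, [Atom("C1", "C", (500.0, 0, 0))], is_polymer=False)
    bare = Structure("bare", [Chain("A", [Residue("ALA", 1, [Atom("CA", "C", (490.0, 0, 0))])])])
    with pytest.raises(LevUndefinedError):
        lev_score(bare, lone, bare, lone)


# ---------------------------------------------------------------------------
# thresholds & confidence


def test_derive_thresholds_hand_case():
    # {1,2,3,4}: Q1=1.75, Q3=3.25 under linear interpolation -> 3.25+1.5*1.5
    assert derive_thresholds([1, 2, 3, 4]) == pytest.approx(5.5)
    assert derive_thresholds([2, 2, 2, 2]) == pytest.approx(2.0)


def test_derive_thresholds_needs_four_values():
    with pytest.raises(InsufficientDataError):
        derive_thresholds([1.0, 2.0, 3.0])


def test_derive_thresholds_exponential_closed_form():
    rng = np.random.default_rng(123)
    sample = rng.exponential(1.0, size=10_000)
    analytic = math.log(4) + 1.5 * (math.log(4) - math.log(4 / 3))
    assert derive_thresholds(sample) == pytest.approx(analytic, rel=0.02)


@pytest.mark.parametrize(
    "local_rmsd, tcs_value, expected",
    [
        (0.50, 0.10, ("high", "high")),
        (0.92, 0.64, ("high", "high")),       # boundary inclusive
        (2.00, 1.00, ("medium", "medium")),
        (3.10, 1.27, ("medium", "medium")),   # boundary inclusive
        (4.00, 2.00, ("low", "low")),
    ],
)
def test_assign_confidence(local_rmsd, tcs_value, expected):
    assert assign_confidence(local_rmsd, tcs_value) == expected


def test_confidence_partition_reproducible_from_derived_cutoffs():
    """Deriving cutoffs from a population then labelling it partitions the
    population into three classes with deterministic sizes."""
    rng = np.random.default_rng(9)
    scores = rng.exponential(0.5, size=2000)
    strict = derive_thresholds(scores[scores < np.median(scores) * 2])  # tighter subpopulation
    loose = derive_thresholds(scores)
    assert strict < loose
    t = ConfidenceThresholds(local_rmsd_medium=strict, local_rmsd_low=loose,
                             tcs_medium=0.64, tcs_low=1.27)
    labels = [assign_confidence(s, 0.0, t)[0] for s in scores]
    counts = {k: labels.count(k) for k in ("high", "medium", "low")}
    assert sum(counts.values()) == 2000
    assert counts["high"] == sum(scores <= strict)
    assert counts["medium"] == sum((scores > strict) & (scores <= loose))


def test_thresholds_ordering_enforced():
    with pytest.raises(ValueError):
        ConfidenceThresholds(local_rmsd_medium=3.0, local_rmsd_low=1.0)
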