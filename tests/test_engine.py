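"""Transplant orchestration: placement rules, deduplication, contact checks,
struct_conn inheritance, determinism and monotonicity."""

import numpy as np
import pytest

from homofill.engine import (
    FillConfig,
    TransplantRecord,
    fill,
    has_protein_contact,
    inherit_struct_conn,
    is_duplicate,
    place_compound,
)
from homofill.fixtures import FixtureSpec, LigandSpec, make_donor, make_model
from homofill.homology import build_donor_db, filter_hits, find_homologs
from homofill.structure import Atom, AtomAddress, Residue, StructConn, extract_sequence
from homofill.superpose import RigidTransform

from conftest import tiny_protein


def make_record(comp_id, centroid):
    return TransplantRecord(
        comp_id=comp_id, original_comp_id=comp_id, donor_entry="d", donor_chain="A",
        donor_copy=1, evalue=1e-30, identity_fraction=1.0, alignment_length=100,
        global_rmsd=0.0, local_rmsd=0.0, tcs=0.0, confidence_local="high",
        confidence_tcs="high", residue=Residue(comp_id, 1, [], is_polymer=False),
        placed_chain_id="B", centroid=np.asarray(centroid, dtype=float),
    )


@pytest.mark.parametrize(
    "comp, distance, expected",
    [
        ("HEM", 3.4, True),    # same compound inside 3.5 A
        ("HEM", 3.5, True),    # boundary inclusive
        ("HEM", 3.6, False),
        ("ATP", 0.5, False),   # different compound: both kept (ADP/ATP dual view)
    ],
)
def test_is_duplicate(comp, distance, expected):
    placed = [make_record("HEM", (0.0, 0.0, 0.0))]
    assert is_duplicate(np.array([distance, 0.0, 0.0]), comp, placed, 3.5) is expected


@pytest.mark.parametrize(
    "offset, expected",
    [(3.2, True), (4.0, True), (4.05, False), (10.0, False)],
)
def test_has_protein_contact(offset, expected):
    protein = tiny_protein(n=4)
    coords = protein.polymer_heavy_coords()
    extreme = coords[np.argmax(coords[:, 0])]  # probe beyond the +x face:
    atoms = [Atom("C1", "C", extreme + np.array([offset, 0.0, 0.0]))]
    # nearest protein atom is then exactly `offset` away
    assert np.min(np.linalg.norm(coords - atoms[0].pos, axis=1)) == pytest.approx(offset)
    assert has_protein_contact(atoms, protein, 4.0) is expected


def test_place_compound_translation_and_conformers():
    lig = Residue(
        "ATP", 1,
        [
            Atom("C1", "C", (0.0, 0.0, 0.0), occupancy=0.4, altloc="A", b_factor=17.0),
            Atom("C1", "C", (0.2, 0.0, 0.0), occupancy=0.6, altloc="B"),
            Atom("O1", "O", (1.0, 1.0, 1.0)),
        ],
        is_polymer=False,
    )
    ident = place_compound(lig, RigidTransform.identity())
    np.testing.assert_array_equal(ident.heavy_coords(), lig.heavy_coords())
    shifted = place_compound(lig, RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0])))
    np.testing.assert_allclose(shifted.heavy_coords(), lig.heavy_coords() + [1, 2, 3])
    # both conformers carried, occupancies/altlocs/B untouched
    assert [(a.altloc, a.occupancy) for a in shifted.atoms] == [("A", 0.4), ("B", 0.6), ("", 1.0)]
    assert shifted.atoms[0].b_factor == 17.0


def _fill_fixture(seed=31, ligands=(LigandSpec("HEM", 8, tuple(range(40, 46))),), **kw):
    spec = FixtureSpec(n_residues=120, target_identity=1.0, ligands=ligands, seed=seed, **kw)
    model = make_model(spec)
    donor = make_donor(model, spec)
    return spec, model, donor


def test_fill_identical_donor(registry):
    _, model, donor = _fill_fixture()
    result = fill(model, [donor], registry)
    assert len(result.transplants) == 1
    t = result.transplants[0]
    assert t.comp_id == "HEM"
    assert t.global_rmsd == pytest.approx(0.0, abs=1e-6)
    assert t.local_rmsd == pytest.approx(0.0, abs=1e-6)
    assert t.identity_fraction == 1.0


def test_fill_deduplicates_second_donor(registry):
    """Two donors offering the same compound in the same pocket yield one
    transplant; the rejection is logged with its reason."""
    spec, model, donor1 = _fill_fixture(seed=32)
    donor2 = make_donor(model, FixtureSpec(**{**spec.__dict__, "seed": 33}))
    donor2.entry_id = "donor2nd"
    result = fill(model, [donor1, donor2], registry)
    assert len(result.transplants) == 1
    assert any(r["reason"] == "duplicate" for r in result.rejections)


def test_fill_rejects_distant_ligand(registry):
    """A ligand that lands with no protein atom within 4 A is not placed."""
    _, model, donor = _fill_fixture(seed=34, ligands=(LigandSpec("ZN", 1, (40, 41), offset=5.5),))
    result = fill(model, [donor], registry)
    assert result.transplants == []
    assert any(r["reason"] == "no-contact" for r in result.rejections)


def test_fill_no_hits_gives_empty_result(registry):
    _, model, _ = _fill_fixture()
    result = fill(model, [], registry)
    assert result.transplants == []


def test_fill_canonicalizes_before_dedup(registry):
    """An AGS from one donor and an ATP from another deduplicate as ATP."""
    spec, model, donor1 = _fill_fixture(seed=35, ligands=(LigandSpec("ATP", 8, tuple(range(40, 46))),))
    donor2 = make_donor(model, FixtureSpec(**{**spec.__dict__, "seed": 36,
                                              "ligands": (LigandSpec("AGS", 8, tuple(range(40, 46))),)}))
    donor2.entry_id = "donor_ags"
    result = fill(model, [donor1, donor2], registry)
    assert [t.comp_id for t in result.transplants] == ["ATP"]
    assert any(r["reason"] == "duplicate" and r["comp"] == "ATP" for r in result.rejections)


def test_fill_records_original_compound_of_analog(registry):
    _, model, donor = _fill_fixture(seed=37, ligands=(LigandSpec("AGS", 8, tuple(range(40, 46))),))
    result = fill(model, [donor], registry)
    t = result.transplants[0]
    assert t.comp_id == "ATP" and t.original_comp_id == "AGS"


def test_fill_determinism(registry):
    _, model, donor = _fill_fixture(seed=38, ligands=(
        LigandSpec("HEM", 8, tuple(range(40, 46))), LigandSpec("ZN", 1, (80, 81, 82)),
    ))
    r1 = fill(model, [donor], registry)
    r2 = fill(model.copy(), [donor.copy()], registry)
    assert [(t.comp_id, t.donor_entry, t.local_rmsd, t.tcs, tuple(t.centroid)) for t in r1.transplants] == \
           [(t.comp_id, t.donor_entry, t.local_rmsd, t.tcs, tuple(t.centroid)) for t in r2.transplants]


def test_fill_monotone_in_donor_set(registry):
    """Adding donors never removes a transplant placed from an earlier-ranked
    hit, and refilling against the same donors adds nothing new."""
    spec, model, donor1 = _fill_fixture(seed=39)
    base = fill(model, [donor1], registry)
    extra = make_donor(model, FixtureSpec(**{**spec.__dict__, "seed": 40, "target_identity": 0.5,
                                             "coord_noise_sigma": 0.5}))
    extra.entry_id = "extra"
    bigger = fill(model, [donor1, extra], registry)
    base_keys = {(t.comp_id, t.donor_entry, t.donor_copy) for t in base.transplants}
    bigger_keys = {(t.comp_id, t.donor_entry, t.donor_copy) for t in bigger.transplants}
    assert base_keys <= bigger_keys
    # dedup idempotence: the lower-ranked copy of the same pocket is rejected
    again = fill(model, [donor1, donor1.copy()], registry)
    assert len(again.transplants) == len(base.transplants)


def test_inherit_struct_conn_maps_and_drops(registry):
    spec, model, donor = _fill_fixture(seed=41, ligands=(LigandSpec("HEM", 8, tuple(range(40, 46))),))
    chain_id, comp_id, _, het = donor.het_groups()[0]
    lig_atom = het.atoms[0].name
    donor.struct_conn = [
        # metal bond to an HSP-covered residue: inherited
        StructConn("metalc", AtomAddress(chain_id, het.seq_id, comp_id, lig_atom),
                   AtomAddress("A", 42, donor.chain("A").residue(42).comp_id, "CA"), 2.2),
        # partner residue outside any chain: dropped with a warning
        StructConn("covale", AtomAddress(chain_id, het.seq_id, comp_id, lig_atom),
                   AtomAddress("Q", 999, "ALA", "CA"), 1.5),
        # record not touching the compound: ignored
        StructConn("covale", AtomAddress("A", 1, donor.chain("A").residue(1).comp_id, "CA"),
                   AtomAddress("A", 2, donor.chain("A").residue(2).comp_id, "CA"), 1.3),
    ]
    result = fill(model, [donor], registry)
    t = result.transplants[0]
    assert len(t.inherited_conns) == 1
    conn = t.inherited_conns[0]
    assert conn.conn_type == "metalc"
    assert conn.ptnr1.chain_id == t.placed_chain_id
    assert conn.ptnr2.chain_id == "A" and conn.ptnr2.seq_id == 42


def test_filled_structure_atom_conservation(registry, tmp_path):
    from homofill.structure import read_structure

    _, model, donor = _fill_fixture(seed=42)
    result = fill(model, [donor], registry)
    n_model = model.n_atoms()
    n_lig = sum(len(t.residue.atoms) for t in result.transplants)
    filled = result.filled_structure(tmp_path / "filled.cif")
    assert filled.n_atoms() == n_model + n_lig
    back = read_structure(tmp_path / "filled.cif")
    assert back.n_atoms() == n_model + n_lig
    assert model.n_atoms() == n_model  # query atoms never modified


def test_fill_config_validation():
    with pytest.raises(ValueError):
        FillConfig(dedup_radius=-1.0)
    with pytest.raises(ValueError):
        FillConfig(min_identity=1.5)
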