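import numpy as np
import pytest

from homofill.fixtures import FixtureSpec, LigandSpec, make_donor, make_model, make_registry
from homofill.registry import load_registry
from homofill.structure import Atom, Chain, Residue, Structure


@pytest.fixture
def registry(tmp_path):
    path = make_registry(
        ["HEM", "ZN", "ATP", "ADP"],
        {"AGS": ("ATP", {"S1G": "O1G"}, set())},
        tmp_path / "registry.cif",
    )
    return load_registry(path)


@pytest.fixture
def pocket_spec():
    """One HEM-sized ligand and one zinc planted on a 120-residue helix."""
    return FixtureSpec(
        n_residues=120,
        target_identity=1.0,
        coord_noise_sigma=0.0,
        ligands=(
            LigandSpec("HEM", 8, tuple(range(40, 46))),
            LigandSpec("ZN", 1, (60, 61, 62, 63)),
        ),
        seed=11,
    )


@pytest.fixture
def model(pocket_spec):
    return make_model(pocket_spec)


@pytest.fixture
def donor(model, pocket_spec):
    return make_donor(model, pocket_spec)


def poly_residue(comp_id, seq_id, center, names=("N", "CA", "C", "O", "CB")):
    """Hand-built polymer residue with atoms on fixed offsets around a center."""
    offsets = {
        "N": (-1.3, 0.0, 0.0), "CA": (0.0, 0.0, 0.0), "C": (1.3, 0.4, 0.0),
        "O": (1.8, 1.5, 0.2), "CB": (0.0, -1.0, 1.1),
    }
    center = np.asarray(center, dtype=float)
    atoms = [Atom(n, n[0], center + np.array(offsets[n])) for n in names]
    return Residue(comp_id, seq_id, atoms)


def tiny_protein(n=12, comp="ALA", spacing=3.0):
    chain = Chain("A", [poly_residue(comp, i + 1, (spacing * i, 0.0, 0.0)) for i in range(n)])
    return Structure("tiny", [chain])
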