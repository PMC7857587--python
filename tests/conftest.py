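import numpy as np
import pytest

from spinlabel.fixtures import (
    FixtureRecipe,
    make_structure,
    make_toy_library,
    toy_library,
)


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    """12-residue ideal-helix topology with amide protons and C-betas."""
    path = tmp_path_factory.mktemp("helix") / "helix.pdb"
    path.write_text(make_structure(FixtureRecipe(n_residues=12)))
    return path


@pytest.fixture(scope="session")
def extended_pdb(tmp_path_factory):
    """30-residue extended chain; ends are far (> 3.5 nm) from the middle."""
    path = tmp_path_factory.mktemp("ext") / "extended.pdb"
    path.write_text(make_structure(FixtureRecipe(n_residues=30, geometry="extended")))
    return path


@pytest.fixture(scope="session")
def bundle_manifest(tmp_path_factory):
    """On-disk 3-rotamer bundle with intrinsic weights (2, 1, 1)."""
    d = tmp_path_factory.mktemp("bundle")
    return make_toy_library(d, R=3, weights=np.array([2.0, 1.0, 1.0]), seed=7)


@pytest.fixture(scope="session")
def lib1():
    """Single-rotamer library (drives all S^2 = 1 collapse tests)."""
    return toy_library(1, arm_length=0.7, spread=0.0, seed=3)


@pytest.fixture(scope="session")
def lib5():
    return toy_library(5, seed=4)
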