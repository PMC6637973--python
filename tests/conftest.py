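import numpy as np
import pytest

from capsidcharge import CapsidStructure, ChargeDensityModel, FixtureSpec, make_shell_fixture


def make_structure(positions, charges=None, names=None):
    """Bare structure from raw arrays, for small hand-built cases."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if charges is None:
        charges = np.full(n, np.nan)
    return CapsidStructure(
        positions=positions,
        names=list(names) if names else ["CA"] * n,
        residue_names=["GLY"] * n,
        chain_ids=["A"] * n,
        residue_seqs=np.arange(1, n + 1),
        charges=np.asarray(charges, dtype=float),
    )


@pytest.fixture
def single_unit_charge_model():
    """One +1 e atom at the origin, a = 1 Å — the analytically known case."""
    struct = make_structure([[0.0, 0.0, 0.0]], charges=[1.0])
    return ChargeDensityModel(struct, width_a=1.0)


@pytest.fixture
def small_random_model():
    """25 atoms, random charges in [−1, 1] e, positions in a 30 Å ball."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(-30, 30, size=(80, 3))
    pts = pts[np.linalg.norm(pts, axis=1) <= 30.0][:25]
    charges = rng.uniform(-1, 1, size=len(pts))
    return ChargeDensityModel(make_structure(pts, charges), width_a=1.0)


@pytest.fixture
def two_shell_structure():
    """1000 atoms on concentric 80/100 Å shells, random grid charges."""
    spec = FixtureSpec(
        n_atoms=1000, shell_radii=(80.0, 100.0), charge_scheme="random", seed=7
    )
    return make_shell_fixture(spec)
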