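import numpy as np
import pytest

from solvbox import (
    Atom,
    Structure,
    gen_brownian_water,
    gen_ideal_gas,
    gen_hbond_lattice,
)


@pytest.fixture(scope="session")
def ideal_gas():
    """2000 uniform points in a 30 Å box: the g(r)=1 oracle."""
    return gen_ideal_gas(N=2000, L=30.0, seed=11)


@pytest.fixture(scope="session")
def lattice():
    """5³ periodic cubic oxygen lattice, spacing 2.9 Å."""
    return gen_hbond_lattice(n_side=5, spacing=2.9)


@pytest.fixture(scope="session")
def brownian_small():
    """Small Brownian fixture cheap enough for brute-force oracles."""
    return gen_brownian_water(N=8, L=20.0, D=1.0e-5, dt=1.0, n_frames=50, seed=5)


def make_structure(coords, chain="A", resname="GLY", name="CA", start_resid=1):
    """Structure with one named atom per residue at the given coordinates."""
    atoms = [
        Atom(
            name=name,
            element="C",
            resname=resname,
            resid=start_resid + i,
            chain=chain,
            x=float(x),
            y=float(y),
            z=float(z),
        )
        for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float))
    ]
    return Structure(atoms=atoms, title="synthetic")


@pytest.fixture
def tiny_protein():
    """Ten Cα positions forming an irregular (non-degenerate) shape."""
    rng = np.random.default_rng(42)
    return make_structure(rng.uniform(-5, 5, size=(10, 3)))


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
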