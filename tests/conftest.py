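import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fusescreen.synthetic import (
    ChainPlan,
    ContactPlan,
    ToyComplexSpec,
    build_toy_structure,
    make_toy_complex,
)
from fusescreen.types import Atom, Chain, Residue, Structure


@pytest.fixture
def toy_spec():
    """Two 60-residue chains with 12 planted Cβ contacts and distinct
    uniform pLDDT profiles."""
    return ToyComplexSpec(
        seed=11,
        chains=[ChainPlan("A", 60, plddt=90.0), ChainPlan("B", 60, plddt=80.0)],
        contacts=[ContactPlan("A", "B", 12)],
        metrics=[(0.9, 0.8), (0.7, 0.6), (0.5, 0.4)],
        pae_inter={("A", "B"): 12.5},
    )


@pytest.fixture
def toy_structure(toy_spec):
    return build_toy_structure(toy_spec)


@pytest.fixture
def toy_files(toy_spec, tmp_path):
    return make_toy_complex(toy_spec, tmp_path / "toy")


def make_point_structure(points, model_id="pts", resname="GLY", chain_prefix="C"):
    """One single-atom chain per point; handy for geometry edge cases."""
    chains = []
    for i, p in enumerate(points):
        chains.append(
            Chain(
                f"{chain_prefix}{i}",
                [Residue(1, resname, [Atom("CA", "C", np.asarray(p, float))])],
            )
        )
    return Structure(model_id, chains)


def random_rigid_transform(rng):
    """Uniform-ish proper rotation (QR of a Gaussian matrix) + translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return Q, t
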