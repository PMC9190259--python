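from __future__ import annotations

import math

import numpy as np
import pytest

from abensemble.core import Atom, Ensemble, StructureModel
from abensemble.interactions import InteractionContext, InteractionCriteria
from abensemble.synthetic import ComplexSpec, build_toy_complex

FULL_PLANTED = {
    "hbond": 3,
    "salt": 1,
    "cation_pi": 1,
    "pi_stack": 1,
    "hydrophobic": 2,
    "bridge": 2,
    "solvent": 2,
    "ion": 1,
}


@pytest.fixture(scope="session")
def toy_complex() -> Ensemble:
    """A static complex carrying every interaction class (audited)."""
    return build_toy_complex(ComplexSpec(planted_counts=dict(FULL_PLANTED), seed=7, n_frames=3))


@pytest.fixture(scope="session")
def small_complex() -> Ensemble:
    return build_toy_complex(
        ComplexSpec(planted_counts={"hbond": 2, "bridge": 1, "solvent": 1}, seed=11, n_frames=5)
    )


def _rot(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_interaction_model(seed: int, box: float = 14.0):
    """A random two-chain structure mixing donors, acceptors, charged
    groups, rings and hydrophobic atoms at random geometry, for oracle
    equivalence testing. Returns (model, coords, context)."""
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(chain, resid, resname, name, element, xyz):
        nonlocal serial
        atoms.append(
            Atom(serial=serial, name=name, element=element, residue_name=resname,
                 residue_id=resid, chain_id=chain)
        )
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1

    ring_template = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        ring_template.append(1.4 * np.array([math.cos(ang), math.sin(ang), 0.0]))
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

    for chain in ("F", "G"):
        resid = 1
        for _ in range(int(rng.integers(3, 7))):
            c = rng.uniform(0, box, 3)
            kind = rng.choice(["donor", "acceptor", "pos", "neg", "ring", "phobic"])
            if kind == "donor":
                h_dir = rng.normal(size=3)
                h_dir /= np.linalg.norm(h_dir)
                add(chain, resid, "GLY", "N", "N", c)
                add(chain, resid, "GLY", "H", "H", c + 1.0 * h_dir)
                add(chain, resid, "GLY", "CA", "C", c - 1.5 * h_dir)
            elif kind == "acceptor":
                add(chain, resid, "GLY", "O", "O", c)
                add(chain, resid, "GLY", "C", "C", c + np.array([1.2, 0, 0]))
            elif kind == "pos":
                add(chain, resid, "LYS", "NZ", "N", c)
            elif kind == "neg":
                add(chain, resid, "ASP", "OD1", "O", c)
                add(chain, resid, "ASP", "OD2", "O", c + np.array([0, 1.4, 0]))
            elif kind == "ring":
                rot = _rot(rng)
                for name, offset in zip(ring_names, ring_template):
                    add(chain, resid, "PHE", name, "C", c + rot @ offset)
            else:
                add(chain, resid, "LEU", "CD1", "C", c)
                add(chain, resid, "LEU", "CD2", "C", c + np.array([1.5, 0, 0]))
            resid += 1
    model = StructureModel(atoms=atoms, roles={"F": "heavy", "G": "antigen"})
    xyz = np.array(coords)
    ctx = InteractionContext.from_model(model, xyz, InteractionCriteria())
    return model, xyz, ctx
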