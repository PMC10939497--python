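import numpy as np
import pytest

from polycg.model import CGModel
from polycg.model_builder import assign_bead_properties, build_polypr
from polycg.synthetic_data import ToyComponentSpec, gen_toy_component


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, altloc=" "):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{name.strip()[0]:>2s}"
    )


def make_ca_pdb(entries):
    """PDB text from (chain, resseq, resname3, x, y, z) tuples (Å)."""
    lines = [
        pdb_atom_line(i + 1, "CA", resname, chain, resseq, x, y, z)
        for i, (chain, resseq, resname, x, y, z) in enumerate(entries)
    ]
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture
def three_residue_pdb():
    return make_ca_pdb(
        [
            ("A", 1, "GLY", 0.0, 0.0, 0.0),
            ("A", 2, "ALA", 3.8, 0.0, 0.0),
            ("A", 3, "SER", 7.6, 0.0, 0.0),
        ]
    )


@pytest.fixture
def chain_break_pdb():
    entries = [("A", i, "GLY", 3.8 * i, 0.0, 0.0) for i in (1, 2, 3, 7, 8, 9)]
    return make_ca_pdb(entries)


@pytest.fixture
def helix_pdb():
    """10-residue ideal-helix-like fixture for elastic-network oracle tests."""
    entries = []
    for i in range(10):
        theta = 1.745 * i  # ~100 degrees per residue
        entries.append(
            ("A", i + 1, "ALA", 2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
        )
    return make_ca_pdb(entries)


@pytest.fixture(scope="session")
def pr20():
    return build_polypr(20)


@pytest.fixture(scope="session")
def charged_toy():
    return gen_toy_component(
        ToyComponentSpec(n_residues=80, net_charge=-20, target_dipole=25.0, seed=0)
    )


@pytest.fixture(scope="session")
def neutral_toy():
    return gen_toy_component(
        ToyComponentSpec(n_residues=80, net_charge=0, target_dipole=0.0, seed=1)
    )


def random_bead_model(n, seed, charged_fraction=0.4, spread=2.0, min_sep=0.45):
    """A disordered n-bead molecule with well-separated random positions."""
    rng = np.random.default_rng(seed)
    residues = rng.choice(list("GSEKRDFYWPAL"), size=n)
    pos = np.zeros((n, 3))
    placed = 0
    while placed < n:
        cand = rng.uniform(-spread, spread, 3)
        if placed == 0 or np.linalg.norm(pos[:placed] - cand, axis=1).min() > min_sep:
            pos[placed] = cand
            placed += 1
    model = CGModel(
        residue_names=residues,
        positions=pos,
        disorder_mask=np.ones(n, dtype=bool),
    )
    return assign_bead_properties(model)
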