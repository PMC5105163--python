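import numpy as np
import pytest

from msmex.io import Atom, Topology
from msmex.constants import ELEMENT_MASSES


def make_atom(name, res_id, chain_id, element="C", res_name="ALA"):
    return Atom(name=name, element=element, res_id=res_id, res_name=res_name,
                chain_id=chain_id, heavy=element.upper() not in ("H", "D"),
                mass=ELEMENT_MASSES[element.upper()])


@pytest.fixture
def toy_topology():
    """Three residues of eight heavy atoms each (24 atoms), one chain."""
    names = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]
    elements = ["N", "C", "C", "O", "C", "C", "C", "C"]
    atoms = [make_atom(n, r, "A", e)
             for r in (1, 2, 3) for n, e in zip(names, elements)]
    return Topology(atoms=atoms, chain_roles={"A": "receptor-alpha"})


@pytest.fixture
def ca_chain_topology():
    """CA-only chain of 10 residues for selection geometry tests."""
    atoms = [make_atom("CA", r, "A") for r in range(1, 11)]
    return Topology(atoms=atoms, chain_roles={"A": "receptor-alpha"})


def write_toy_pdb(path, topology, coords_models):
    """Minimal fixed-column PDB writer for fixtures (possibly multi-model)."""
    coords_models = np.asarray(coords_models, dtype=float)
    if coords_models.ndim == 2:
        coords_models = coords_models[None]
    lines = []
    multi = coords_models.shape[0] > 1
    for m, coords in enumerate(coords_models, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i, (a, xyz) in enumerate(zip(topology.atoms, coords), start=1):
            lines.append(
                f"ATOM  {i:5d} {a.name:<4s} {a.res_name:<3s} {a.chain_id}"
                f"{a.res_id:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
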