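import mdtraj as md
import mdtraj.core.element as mdelem
import numpy as np
import pytest

from vardyn.synthdata import _ideal_helix
from vardyn.trajfeatures import AtomRecord


def make_mdtraj(topology, frames_angstrom):
    """Build an mdtraj Trajectory (nm) from a vardyn topology + frames (A)."""
    top = md.Topology()
    chain = top.add_chain()
    residues = {}
    for a in topology:
        if a.residue_index not in residues:
            residues[a.residue_index] = top.add_residue(a.residue_name, chain)
        top.add_atom(a.name, mdelem.get_by_symbol(a.element), residues[a.residue_index])
    xyz = np.asarray(frames_angstrom, float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    return md.Trajectory(xyz=xyz / 10.0, topology=top)


def carbon_cloud(n_atoms, seed=0, spread=6.0):
    """Random all-carbon pseudo-topology + coordinates for oracle comparisons."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=spread, size=(n_atoms, 3))
    topo = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            residue_index=i + 1,
            residue_name="GLY",
            backbone_role="CA",
        )
        for i in range(n_atoms)
    ]
    return topo, coords


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue alpha-helix: (topology, coordinates)."""
    return _ideal_helix(20)
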