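import numpy as np
import pytest

from ensembledyn import Residue, Topology, Trajectory


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z, altloc=" ", occ=1.0):
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           C  \n"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Single-model, single-chain PDB with 3 Cα atoms."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        pdb_atom_line(3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0),
        "END\n",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = []
    serial = 1
    for chain, nums in [("A", (1, 2, 3)), ("B", (1, 2))]:
        for n in nums:
            lines.append(
                pdb_atom_line(serial, "CA", "ALA", chain, n, 3.8 * serial, 0.0, 1.0)
            )
            serial += 1
    lines.append("END\n")
    path = tmp_path / "two_chain.pdb"
    path.write_text("".join(lines))
    return path


def simple_topology(n=4, chain="A"):
    return Topology([Residue(chain, i + 1) for i in range(n)])


def trajectory_from_frames(frames, dt=0.1, chain="A", equilibration_end=0.0):
    frames = np.asarray(frames, dtype=np.float64)
    topo = simple_topology(frames.shape[1], chain)
    times = (np.arange(frames.shape[0]) + 1) * dt
    return Trajectory(topo, frames, times, equilibration_end)
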