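"""Shared fixtures: text-format chemistry fixtures and random toy complexes."""

from __future__ import annotations

import numpy as np
import pytest

from ensift.complex_io import Atom, LigandPose, ReceptorConformation
from ensift.synthetic_data import _toy_residue

BENZENE_SDF = """\
benzene
  fixture

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0
  2  3  1  0
  3  4  2  0
  4  5  1  0
  5  6  2  0
  6  1  1  0
M  END
$$$$
"""

ETHANOL_SDF = """\
ethanol
  fixture

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5200    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0300    1.3300    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""

ACETATE_SDF = """\
acetate
  fixture

  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5200    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.1300    1.0800    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.1300   -1.0800    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  2  0
  2  4  1  0
M  CHG  1   4  -1
M  END
$$$$
"""


@pytest.fixture
def benzene_sdf(tmp_path):
    path = tmp_path / "benzene.sdf"
    path.write_text(BENZENE_SDF)
    return path


@pytest.fixture
def ethanol_sdf(tmp_path):
    path = tmp_path / "ethanol.sdf"
    path.write_text(ETHANOL_SDF)
    return path


@pytest.fixture
def acetate_sdf(tmp_path):
    path = tmp_path / "acetate.sdf"
    path.write_text(ACETATE_SDF)
    return path


def random_complex(seed: int, max_residues: int = 10, max_ligand_atoms: int = 20):
    """A random small receptor/ligand pair with consistent atom flags.

    Residues come from the toy templates, translated into a shared 15 Å box
    so that contacts of every class can arise by chance; ligand atoms get
    random elements and capability flags consistent with their element.
    """
    rng = np.random.default_rng(seed)
    n_res = int(rng.integers(1, max_residues + 1))
    resnames = rng.choice(["ALA", "LEU", "SER", "ASP", "PHE"], size=n_res)
    residues = []
    for i, resname in enumerate(resnames):
        res = _toy_residue(0, str(resname))
        shift = rng.uniform(-7.5, 7.5, 3) - res.atoms[0].coords
        for a in res.atoms:
            a.coords = a.coords + shift
        res.resnum = i + 1
        residues.append(res)
    receptor = ReceptorConformation(f"rand{seed}", residues)

    n_lig = int(rng.integers(1, max_ligand_atoms + 1))
    atoms = []
    for j in range(n_lig):
        element = str(rng.choice(["C", "C", "C", "N", "O", "S", "F"]))
        polar = element in "NOS"
        atoms.append(Atom(
            name=f"{element}{j}", element=element,
            coords=rng.uniform(-9.0, 9.0, 3),
            is_polar=polar,
            is_hydrophobic=element in "CS" and bool(rng.integers(0, 2)),
            is_donor=polar and bool(rng.integers(0, 2)),
            is_acceptor=element in "NOSF" and bool(rng.integers(0, 2)),
            is_aromatic=False,
            formal_charge=int(rng.choice([-1, 0, 0, 0, 1])),
        ))
    rings = []
    if n_lig >= 6 and rng.random() < 0.5:
        center = rng.uniform(-8.0, 8.0, 3)
        start = len(atoms)
        for k in range(6):
            ang = np.pi * k / 3
            atoms.append(Atom(
                name=f"AR{k}", element="C",
                coords=center + 1.39 * np.array([np.cos(ang), np.sin(ang), 0.0]),
                is_polar=False, is_hydrophobic=True, is_aromatic=True,
            ))
        rings.append(frozenset(range(start, start + 6)))
    pose = LigandPose("rand", "conf1", atoms, rings)
    return receptor, pose
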