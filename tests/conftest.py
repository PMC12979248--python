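"""Shared fixtures: tiny text-format structure files and synthetic systems,
all generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from memdiverge.core_io import Selection, Topology, Trajectory, assign_roles

PDB_WATER = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1           1
ATOM      1  OW  HOH A   1       1.000   2.000   3.000  1.00  0.00           O
ATOM      2  HW1 HOH A   1       1.500   2.000   3.000  1.00  0.00           H
ATOM      3  HW2 HOH A   1       0.700   2.700   3.000  1.00  0.00           H
END
"""

GRO_MINIMAL = """\
minimal test system
    3
    1HOH     OW    1   0.100   0.200   0.300
    1HOH    HW1    2   0.150   0.200   0.300
    1HOH    HW2    3   0.070   0.270   0.300
  10.00000  10.00000  10.00000
"""


@pytest.fixture
def pdb_water_file(tmp_path):
    p = tmp_path / "water.pdb"
    p.write_text(PDB_WATER)
    return p


@pytest.fixture
def gro_minimal_file(tmp_path):
    p = tmp_path / "minimal.gro"
    p.write_text(GRO_MINIMAL)
    return p


def make_topology(names, resnames, resids):
    """Build a Topology with roles assigned from the shipped dictionaries."""
    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    n = len(names)
    return Topology(
        names=names,
        resnames=resnames,
        resids=np.asarray(resids, dtype=int),
        chainids=np.array([""] * n, dtype=object),
        segids=np.array(["T"] * n, dtype=object),
        roles=assign_roles(names, resnames),
    )


def make_trajectory(coords, box, names=None, resnames=None, resids=None, dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    names = names if names is not None else ["CA"] * n
    resnames = resnames if resnames is not None else ["GLY"] * n
    resids = resids if resids is not None else list(range(1, n + 1))
    top = make_topology(names, resnames, resids)
    return Trajectory(topology=top, coords=coords, box=np.asarray(box, dtype=float), dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
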