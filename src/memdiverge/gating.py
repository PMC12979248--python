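"""Hydrophobic-gate statistics for a residue pair.

Per frame: the minimum distance between side-chain heavy atoms of the two
gating residues, and the number of water oxygens inside a sphere (default
radius 0.4 nm) centred on the midpoint of the pair's Cα atoms, the sphere
tracking the midpoint every frame. The joint distribution is summarised
by quadrants at 0.35 nm (direct residue interaction below) and 2 waters
(permeation prevented below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Selection, Trajectory, minimum_image_displacement, neighbor_pairs
from MDAnalysis.lib import distances as mdadist

DEFAULT_SPHERE_RADIUS_NM = 0.4
CONTACT_DISTANCE_NM = 0.35
DRY_COUNT_THRESHOLD = 2

#: backbone names excluded from "side-chain heavy atoms" (atomistic + CG)
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "BB", "HN", "HA"}
CALPHA_NAMES = ("CA", "BB")


@dataclass
class GateSeries:
    """Per-frame gate geometry and midpoint-sphere water occupancy."""

    residue_a: int
    residue_b: int
    min_distance: np.ndarray  # nm
    water_count: np.ndarray  # integers
    sphere_radius: float


@dataclass
class GatingDistribution:
    """Normalised 2D histogram over (water count, distance) plus the four
    quadrant fractions at the contact/dry thresholds."""

    histogram: np.ndarray
    count_edges: np.ndarray
    distance_edges: np.ndarray
    fractions: dict  # {"contact_dry", "contact_wet", "open_dry", "open_wet"}
    distance_threshold: float
    count_threshold: int


def _residue_atom_split(trajectory: Trajectory, resid: int) -> tuple[int, np.ndarray]:
    """(Cα index, side-chain heavy atom indices) for one residue.

    Hydrogens are excluded from the side chain; glycine (no side-chain
    heavy atom) falls back to its Cα.
    """
    top = trajectory.topology
    res_idx = np.flatnonzero(top.resids == resid)
    if len(res_idx) == 0:
        raise ValueError(f"residue {resid} not in topology")
    names = np.array([str(top.names[i]).upper() for i in res_idx])
    ca = res_idx[np.isin(names, CALPHA_NAMES)]
    if len(ca) == 0:
        raise ValueError(f"residue {resid} has no Cα/backbone particle")
    side = res_idx[
        ~np.isin(names, sorted(BACKBONE_NAMES)) & ~np.char.startswith(names, "H")
    ]
    if len(side) == 0:
        side = ca  # glycine fallback
    return int(ca[0]), side


def gate_series(
    trajectory: Trajectory,
    residue_a: int,
    residue_b: int,
    water_sel: Selection,
    radius: float = DEFAULT_SPHERE_RADIUS_NM,
) -> GateSeries:
    """Minimum side-chain heavy-atom distance vs. midpoint-sphere water count.

    The sphere centre is recomputed each frame at the minimum-image
    midpoint of the two Cα atoms.
    """
    water_sel.validate(trajectory.topology)
    ca_a, side_a = _residue_atom_split(trajectory, residue_a)
    ca_b, side_b = _residue_atom_split(trajectory, residue_b)

    n = trajectory.n_frames
    dmin = np.empty(n)
    wcount = np.zeros(n, dtype=int)
    for f in range(n):
        box = trajectory.box[f]
        mda_box = np.concatenate([box, [90, 90, 90]]).astype(np.float32)
        arr = mdadist.distance_array(
            np.ascontiguousarray(trajectory.coords[f, side_a]),
            np.ascontiguousarray(trajectory.coords[f, side_b]),
            box=mda_box,
        )
        dmin[f] = arr.min()
        pa = trajectory.coords[f, ca_a]
        pb = trajectory.coords[f, ca_b]
        mid = pa + minimum_image_displacement(pb - pa, box) / 2.0
        if len(water_sel):
            pairs = neighbor_pairs(
                mid[None, :], trajectory.coords[f, water_sel.indices], radius, box
            )
            wcount[f] = len({j for (_, j, _) in pairs})
    return GateSeries(
        residue_a=residue_a, residue_b=residue_b,
        min_distance=dmin, water_count=wcount, sphere_radius=radius,
    )


def gating_distribution(
    series: GateSeries,
    distance_threshold: float = CONTACT_DISTANCE_NM,
    count_threshold: int = DRY_COUNT_THRESHOLD,
    distance_bin: float = 0.05,
) -> GatingDistribution:
    """Joint (water count, distance) histogram and quadrant fractions.

    "Contact" means distance ≤ the 0.35 nm interaction line; "dry" means
    strictly fewer than 2 waters (permeation prevented).
    """
    d = np.asarray(series.min_distance, dtype=float)
    c = np.asarray(series.water_count, dtype=int)
    if len(d) == 0:
        raise ValueError("empty gate series")
    count_edges = np.arange(c.max() + 2) - 0.5
    dmax = max(d.max(), distance_threshold) + distance_bin
    distance_edges = np.arange(0.0, dmax + distance_bin, distance_bin)
    hist, _, _ = np.histogram2d(c, d, bins=(count_edges, distance_edges))
    hist = hist / hist.sum()

    contact = d <= distance_threshold
    dry = c < count_threshold
    fractions = {
        "contact_dry": float((contact & dry).mean()),
        "contact_wet": float((contact & ~dry).mean()),
        "open_dry": float((~contact & dry).mean()),
        "open_wet": float((~contact & ~dry).mean()),
    }
    return GatingDistribution(
        histogram=hist,
        count_edges=count_edges,
        distance_edges=distance_edges,
        fractions=fractions,
        distance_threshold=distance_threshold,
        count_threshold=count_threshold,
    )
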