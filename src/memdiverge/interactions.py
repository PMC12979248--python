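"""Salt-bridge / hydrogen-bond detection, prevalence and tail dissociation.

A salt bridge is present in a frame when any anion-set / cation-set atom
pair sits within the distance cutoff (0.4 nm between glutamate carboxyl O
and lysine/histidine NH groups). A hydrogen bond additionally requires a
donor–H–acceptor angle above the angular cutoff. Prevalence is the
fraction of frames an interaction is present, averaged over replicates.
Tail dissociation couples bond rupture to a sustained RMSD rise: the tail
is classified dissociated when its RMSD exceeds a threshold for a full
window of consecutive frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import RMSDSeries, Selection, Trajectory, minimum_image_displacement
from MDAnalysis.lib import distances as mdadist

#: default salt-bridge cutoff: carboxyl O to N-H group nitrogen
SALT_BRIDGE_CUTOFF_NM = 0.4
#: default hydrogen-bond geometry (donor-acceptor distance, D-H-A angle)
HBOND_CUTOFF_NM = 0.35
HBOND_ANGLE_DEG = 150.0

#: sidechain atom-name templates; histidine nitrogen names are listed but
#: count as cationic only when the residue is flagged protonated
ANION_ATOMS = {"GLU": {"OE1", "OE2"}, "ASP": {"OD1", "OD2"}}
CATION_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
    "HIS": {"ND1", "NE2"},
    "HSD": {"NE2"},
    "HSE": {"ND1"},
    "HSP": {"ND1", "NE2"},
}


@dataclass
class InteractionCriteria:
    """Geometric definition of one interaction type."""

    kind: str  # "salt-bridge" | "hydrogen-bond"
    donor_atoms: set
    acceptor_atoms: set
    distance_cutoff: float
    angle_cutoff: float | None = None  # degrees, hydrogen-bond only
    hydrogen_atoms: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in ("salt-bridge", "hydrogen-bond"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if self.angle_cutoff is not None and not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


def salt_bridge_criteria(
    cation_resname: str = "LYS",
    anion_resname: str = "GLU",
    cutoff: float = SALT_BRIDGE_CUTOFF_NM,
    his_protonated: bool = False,
) -> InteractionCriteria:
    """Salt-bridge criteria from the shipped residue templates.

    Histidine contributes cationic nitrogens only when ``his_protonated``
    — neutral His (e.g. the Nδ tautomer HSD) is excluded unless flagged.
    """
    res = cation_resname.upper()
    if res in ("HIS", "HSD", "HSE") and not his_protonated:
        raise ValueError(
            f"{res} is neutral unless marked protonated; pass his_protonated=True "
            "to treat it as a cation"
        )
    cation = CATION_ATOMS.get("HSP" if res.startswith("HS") or res == "HIS" else res)
    if his_protonated and (res.startswith("HS") or res == "HIS"):
        cation = CATION_ATOMS["HIS"]
    anion = ANION_ATOMS.get(anion_resname.upper())
    if cation is None or anion is None:
        raise ValueError(f"no template for {cation_resname}/{anion_resname}")
    return InteractionCriteria(
        kind="salt-bridge",
        donor_atoms=set(cation),
        acceptor_atoms=set(anion),
        distance_cutoff=cutoff,
    )


def hydrogen_bond_criteria(
    donor_atoms: set,
    acceptor_atoms: set,
    hydrogen_atoms: set,
    cutoff: float = HBOND_CUTOFF_NM,
    angle: float = HBOND_ANGLE_DEG,
) -> InteractionCriteria:
    return InteractionCriteria(
        kind="hydrogen-bond",
        donor_atoms=set(donor_atoms),
        acceptor_atoms=set(acceptor_atoms),
        hydrogen_atoms=set(hydrogen_atoms),
        distance_cutoff=cutoff,
        angle_cutoff=angle,
    )


@dataclass
class PrevalenceResult:
    """Fraction of frames an interaction is present, per replicate."""

    per_replicate: np.ndarray
    mean: float
    sd: float


@dataclass
class DissociationResult:
    classification: str  # "stable" | "dissociated"
    rupture_frame: int | None
    prevalence_before: float | None
    prevalence_after: float | None
    bond_lost_after_rupture: bool | None
    threshold: float
    window: int


def _residue_atoms(
    trajectory: Trajectory, resid: int, names: set
) -> np.ndarray:
    top = trajectory.topology
    mask = (top.resids == resid) & np.isin(
        np.array([str(n).upper() for n in top.names]), sorted(n.upper() for n in names)
    )
    return np.flatnonzero(mask)


def interaction_series(
    trajectory: Trajectory,
    residue_a: int,
    residue_b: int,
    criteria: InteractionCriteria,
) -> np.ndarray:
    """Per-frame boolean presence of the interaction between two residues.

    For salt bridges the test is symmetric: the donor/cation set is looked
    up in either residue. For hydrogen bonds residue_a is the donor side
    (must carry the hydrogens) and residue_b the acceptor.
    """
    idx_a = _residue_atoms(trajectory, residue_a, criteria.donor_atoms)
    idx_b = _residue_atoms(trajectory, residue_b, criteria.acceptor_atoms)
    if criteria.kind == "salt-bridge" and (len(idx_a) == 0 or len(idx_b) == 0):
        # symmetric: try the swapped assignment
        idx_a2 = _residue_atoms(trajectory, residue_b, criteria.donor_atoms)
        idx_b2 = _residue_atoms(trajectory, residue_a, criteria.acceptor_atoms)
        if len(idx_a2) and len(idx_b2):
            idx_a, idx_b = idx_a2, idx_b2
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(
            f"residues {residue_a}/{residue_b} lack atoms from the criteria name sets"
        )

    if criteria.kind == "hydrogen-bond":
        idx_h = _residue_atoms(trajectory, residue_a, criteria.hydrogen_atoms)
        if len(idx_h) == 0:
            raise ValueError(
                f"residue {residue_a} has no hydrogen atoms "
                f"{sorted(criteria.hydrogen_atoms)}; re-run with distance-only "
                "criteria (kind='salt-bridge') if the topology lacks hydrogens"
            )

    present = np.zeros(trajectory.n_frames, dtype=bool)
    for f in range(trajectory.n_frames):
        box = np.concatenate([trajectory.box[f], [90, 90, 90]]).astype(np.float32)
        dmat = mdadist.distance_array(
            np.ascontiguousarray(trajectory.coords[f, idx_a]),
            np.ascontiguousarray(trajectory.coords[f, idx_b]),
            box=box,
        )
        if criteria.kind == "salt-bridge":
            present[f] = bool((dmat <= criteria.distance_cutoff).any())
            continue
        # hydrogen bond: distance AND angle for some (donor, H, acceptor)
        ok = False
        for ia, da_row in zip(idx_a, dmat):
            for ib, d in zip(idx_b, da_row):
                if d > criteria.distance_cutoff:
                    continue
                for ih in idx_h:
                    v1 = minimum_image_displacement(
                        trajectory.coords[f, ia] - trajectory.coords[f, ih],
                        trajectory.box[f],
                    )
                    v2 = minimum_image_displacement(
                        trajectory.coords[f, ib] - trajectory.coords[f, ih],
                        trajectory.box[f],
                    )
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if angle >= criteria.angle_cutoff:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                break
        present[f] = ok
    return present


def prevalence(series_per_replicate: list[np.ndarray]) -> PrevalenceResult:
    """Fraction of frames present per replicate, with mean ± SD across
    replicates (SD = 0 for a single replicate)."""
    if len(series_per_replicate) == 0:
        raise ValueError("need at least one replicate")
    fracs = []
    for s in series_per_replicate:
        s = np.asarray(s, dtype=bool)
        if len(s) == 0:
            raise ValueError("zero-length interaction series")
        fracs.append(float(s.mean()))
    fr = np.asarray(fracs)
    sd = float(fr.std(ddof=1)) if len(fr) > 1 else 0.0
    return PrevalenceResult(per_replicate=fr, mean=float(fr.mean()), sd=sd)


def tail_dissociation(
    rmsd: RMSDSeries,
    bond: np.ndarray,
    threshold: float = 0.6,
    window: int = 25,
) -> DissociationResult:
    """Classify a tail as dissociated when its RMSD stays above
    ``threshold`` for at least ``window`` consecutive frames.

    The rupture frame is the first frame of the first qualifying run. The
    result also restates the bond-rupture correlation per trajectory:
    whether the bond prevalence after the rupture frame is lower than
    before it.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(rmsd.values, dtype=float)
    bond = np.asarray(bond, dtype=bool)
    if len(values) != len(bond):
        raise ValueError("RMSD and bond series must have equal length")

    above = values > threshold
    rupture = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= window:
            rupture = i - window + 1
            break
    if rupture is None:
        return DissociationResult(
            classification="stable", rupture_frame=None,
            prevalence_before=float(bond.mean()), prevalence_after=None,
            bond_lost_after_rupture=None, threshold=threshold, window=window,
        )
    before = float(bond[:rupture].mean()) if rupture > 0 else None
    after = float(bond[rupture:].mean())
    return DissociationResult(
        classification="dissociated",
        rupture_frame=int(rupture),
        prevalence_before=before,
        prevalence_after=after,
        bond_lost_after_rupture=(None if before is None else after < before),
        threshold=threshold,
        window=window,
    )


def ring_centroid_distance(
    trajectory: Trajectory, residue_a: int, residue_b: int, ring_atoms: set | None = None
) -> np.ndarray:
    """Inter-ring centroid distance series for aromatic pairs (qualitative
    stacking readout; no orientation criterion)."""
    ring_atoms = ring_atoms or {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
    ia = _residue_atoms(trajectory, residue_a, ring_atoms)
    ib = _residue_atoms(trajectory, residue_b, ring_atoms)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("residues lack ring atoms")
    ca = trajectory.coords[:, ia].mean(axis=1)
    cb = trajectory.coords[:, ib].mean(axis=1)
    disp = minimum_image_displacement(ca - cb, trajectory.box)
    return np.linalg.norm(disp, axis=1)
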