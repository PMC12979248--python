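"""Ground-truth trajectory generators for every analysis stage.

Each generator emulates the statistical structure one analysis assumes —
a deformed bilayer, two-state lipid binding, Poisson pocket occupancy,
gate open/closed toggling, bond formation with a tail-rupture event — and
returns the planted parameters as a :class:`SyntheticTruth`, so each stage
has a parameter-recovery test without running molecular dynamics. No
forcefield or integrator is involved: particles are placed, not propagated.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SyntheticTruth.seed``; identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import Selection, Topology, Trajectory, assign_roles, write_trajectory


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic trajectory (the recovery oracle).

    Lengths in nm, rates in 1/ns, times in ns. ``koff_true`` may carry two
    components with ``koff_weight_slow`` mixing them (biexponential
    residence laws); ``pocket_rate`` is the Poisson mean water count per
    frame; ``bond_prevalence`` the Bernoulli fraction of bonded frames;
    ``jump_frame`` the frame at which the measured tail is rigidly
    displaced. ``seed`` is mandatory and recorded in all output metadata.
    """

    seed: int
    deformation_amplitude_ec: float = 0.8
    deformation_amplitude_ic: float = 1.0
    deformation_center: tuple[float, float] | None = None  # default: box center
    deformation_width: float = 0.6
    deformation_core_radius: float = 0.8
    noise_sigma: float = 0.1
    koff_true: float = 0.05
    koff_true_fast: float | None = None
    koff_weight_slow: float = 1.0
    kon_true: float = 0.1
    pocket_rate: float = 3.0
    bond_prevalence: float = 0.5
    jump_frame: int = 100
    gate_open_fraction: float = 0.3
    gate_open_waters: int = 4

    def __post_init__(self) -> None:
        for name in ("koff_true", "kon_true", "pocket_rate", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.bond_prevalence <= 1.0:
            raise ValueError("bond_prevalence must lie in [0, 1]")
        if not 0.0 <= self.gate_open_fraction <= 1.0:
            raise ValueError("gate_open_fraction must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = dataclasses.asdict(self)
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in names}
        if kwargs.get("deformation_center") is not None:
            kwargs["deformation_center"] = tuple(kwargs["deformation_center"])
        return cls(**kwargs)


def _make_topology(names, resnames, resids) -> Topology:
    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resids = np.asarray(resids, dtype=int)
    n = len(names)
    return Topology(
        names=names,
        resnames=resnames,
        resids=resids,
        chainids=np.array([""] * n, dtype=object),
        segids=np.array(["SYN"] * n, dtype=object),
        roles=assign_roles(names, resnames),
    )


# ---------------------------------------------------------------------------
# bilayer with a protein-localised deformation funnel
# ---------------------------------------------------------------------------

def funnel_profile(r: np.ndarray, core_radius: float, width: float) -> np.ndarray:
    """Radial deformation profile: full depth inside ``core_radius``,
    Gaussian shoulder of scale ``width`` outside.

    The flat core guarantees the planted amplitude is exactly realised by
    the phosphates an 0.8 nm analysis shell around the deepest point can
    see, making the amplitude a well-defined recovery target.
    """
    excess = np.maximum(np.asarray(r, dtype=float) - core_radius, 0.0)
    return np.exp(-(excess**2) / (2.0 * width**2))


def gen_bilayer(
    truth: SyntheticTruth,
    n_lipids_per_leaflet: int = 400,
    box_xy: float = 15.0,
    half_width: float = 2.0,
    n_frames: int = 200,
    n_protein_residues: int = 21,
    dt: float = 1.0,
) -> tuple[Trajectory, dict]:
    """Quasi-planar two-leaflet bilayer of phosphate beads with a funnel.

    Phosphates sit on jittered square grids at z = ±half_width; a radial
    funnel of depth ``deformation_amplitude_ec``/``_ic`` pulls each leaflet
    toward z = 0 around ``deformation_center``; per-frame Gaussian noise of
    sd ``noise_sigma`` is added. A static protein particle column spans the
    bilayer at the funnel center, one particle per residue, so shell-based
    extreme-residue scans have candidates.

    Returns the trajectory and an info dict with the expected extreme
    residues/z values and the true global deformation (sum of leaflet
    amplitudes).
    """
    if n_lipids_per_leaflet < 16:
        raise ValueError("need at least 16 lipids per leaflet")
    if truth.deformation_width >= box_xy / 4:
        raise ValueError("deformation width must be < box/4")
    a_ec, a_ic = truth.deformation_amplitude_ec, truth.deformation_amplitude_ic
    if max(a_ec, a_ic) >= half_width:
        raise ValueError("deformation amplitude ≥ leaflet half-width (leaflet inversion)")
    rng = truth.rng()
    box_z = 4.0 * half_width
    box = np.array([box_xy, box_xy, box_z])
    center = (
        np.array(truth.deformation_center, dtype=float)
        if truth.deformation_center is not None
        else box[:2] / 2.0
    )

    nside = int(np.ceil(np.sqrt(n_lipids_per_leaflet)))
    spacing = box_xy / nside
    gx, gy = np.meshgrid(np.arange(nside), np.arange(nside))
    base_xy = np.stack([(gx + 0.5) * spacing, (gy + 0.5) * spacing], axis=-1).reshape(-1, 2)
    base_xy = base_xy[:n_lipids_per_leaflet]
    # static jitter (per lipid) keeps the lattice from aliasing into the bins
    jitter = rng.uniform(-0.2, 0.2, size=base_xy.shape) * spacing

    coords_leaflets, names, resnames, resids = [], [], [], []
    resid = 1
    z0 = box_z / 2.0
    leaflet_depths = []
    for sign, amp in ((+1.0, a_ec), (-1.0, a_ic)):
        xy = base_xy + jitter
        r = np.linalg.norm(xy - center, axis=1)
        depth = amp * funnel_profile(r, truth.deformation_core_radius, truth.deformation_width)
        z = z0 + sign * (half_width - depth)
        coords_leaflets.append(np.column_stack([xy, z]))
        leaflet_depths.append(depth)
        for _ in range(len(xy)):
            names.append("PO4")
            resnames.append("POPC")
            resids.append(resid)
            resid += 1

    # protein column: one particle per residue, spanning z = ±half_width
    prot_z = z0 + np.linspace(-half_width, half_width, n_protein_residues)
    prot = np.column_stack(
        [np.full(n_protein_residues, center[0]), np.full(n_protein_residues, center[1]), prot_z]
    )
    prot_resids = list(range(resid, resid + n_protein_residues))
    for rid in prot_resids:
        names.append("BB")
        resnames.append("ALA")
        resids.append(rid)

    static = np.vstack(coords_leaflets + [prot])
    n_phos = 2 * n_lipids_per_leaflet
    coords = np.tile(static, (n_frames, 1, 1))
    if truth.noise_sigma > 0:
        coords[:, :n_phos, :] += rng.normal(
            0.0, truth.noise_sigma, size=(n_frames, n_phos, 3)
        )

    top = _make_topology(names, resnames, resids)
    traj = Trajectory(topology=top, coords=coords, box=box, dt=dt)

    z_ext_ec = half_width - a_ec
    z_ext_ic = -(half_width - a_ic)
    rel_z = prot_z - z0
    info = {
        "extreme_residue_ec": int(prot_resids[int(np.argmin(np.abs(rel_z - z_ext_ec)))]),
        "extreme_residue_ic": int(prot_resids[int(np.argmin(np.abs(rel_z - z_ext_ic)))]),
        "extreme_z_ec": z_ext_ec,
        "extreme_z_ic": z_ext_ic,
        "global_deformation_true": a_ec + a_ic,
        "protein_resids": prot_resids,
        "half_width": half_width,
    }
    return traj, info


# ---------------------------------------------------------------------------
# two-state Markov lipid binding
# ---------------------------------------------------------------------------

def _sample_two_state_chain(
    rng: np.random.Generator,
    kon: float,
    koff_slow: float,
    koff_fast: float | None,
    w_slow: float,
    t_total: float,
    start_bound: bool,
) -> list[tuple[float, float, bool]]:
    """Event-driven unbound↔bound chain; returns (t_start, t_end, bound) epochs.

    Exponential waiting times give exact exponential (or mixture) duration
    laws, which is what the survival-curve fit downstream assumes. A
    biexponential residence law is realised by drawing each bound epoch's
    rate from {koff_slow, koff_fast} with weight ``w_slow`` on slow.
    """
    epochs = []
    t, bound = 0.0, start_bound
    while t < t_total:
        if bound:
            k = koff_slow
            if koff_fast is not None and rng.uniform() > w_slow:
                k = koff_fast
            dwell = rng.exponential(1.0 / k) if k > 0 else np.inf
        else:
            dwell = rng.exponential(1.0 / kon) if kon > 0 else np.inf
        end = min(t + dwell, t_total)
        epochs.append((t, end, bound))
        t = end
        bound = not bound
    return epochs


def gen_binding_kinetics(
    truth: SyntheticTruth,
    n_lipids: int = 30,
    n_frames: int = 800,
    dt: float = 0.5,
    box_edge: float = 10.0,
    site_center: np.ndarray | None = None,
    n_site_residues: int = 3,
    start_bound_fraction: float = 0.5,
) -> tuple[Trajectory, dict]:
    """Lipids hopping between a bound shell (< 0.475 nm of site residues)
    and a far unbound region (> 0.7 nm) under a continuous-time two-state
    Markov chain with rates ``kon_true``/``koff_true``.

    Returns the trajectory plus the exact continuous bound durations per
    lipid (the fit oracle). Placement distances guarantee that the
    0.475/0.7 nm dual-cutoff detector reproduces the sampled chain state
    exactly.
    """
    import warnings as _warnings

    if truth.koff_true > 0 and dt > 1.0 / (10.0 * truth.koff_true):
        _warnings.warn(
            f"frame spacing dt={dt} ns coarser than 1/(10 koff); "
            "discretization will bias short durations",
            stacklevel=2,
        )
    rng = truth.rng()
    box = np.full(3, box_edge)
    center = np.asarray(site_center, dtype=float) if site_center is not None else box / 2.0

    # site residues: compact cluster (≤ 0.05 nm from center)
    site_offsets = rng.normal(0.0, 0.02, size=(n_site_residues, 3))
    site_coords = center + site_offsets

    t_total = n_frames * dt
    frame_times = np.arange(n_frames) * dt
    lipid_coords = np.empty((n_frames, n_lipids, 3))
    true_durations: list[float] = []
    true_censored: list[bool] = []
    bound_states = np.zeros((n_frames, n_lipids), dtype=bool)
    for j in range(n_lipids):
        start_bound = bool(rng.uniform() < start_bound_fraction) and truth.kon_true > 0
        if truth.kon_true == 0 and not start_bound:
            epochs = [(0.0, t_total, False)]
        else:
            epochs = _sample_two_state_chain(
                rng,
                truth.kon_true,
                truth.koff_true,
                truth.koff_true_fast,
                truth.koff_weight_slow,
                t_total,
                start_bound,
            )
        for t0, t1, bound in epochs:
            if bound:
                true_durations.append(t1 - t0)
                true_censored.append(t1 >= t_total)
        # sample state at frame times
        state = np.zeros(n_frames, dtype=bool)
        for t0, t1, bound in epochs:
            if bound:
                state |= (frame_times >= t0) & (frame_times < t1)
        bound_states[:, j] = state
        # positions: bound < lower cutoff, unbound > upper cutoff
        u = rng.normal(size=(n_frames, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r_bound = rng.uniform(0.10, 0.30, size=n_frames)
        r_unbound = rng.uniform(1.2, box_edge / 2.0 - 0.2, size=n_frames)
        r = np.where(state, r_bound, r_unbound)
        lipid_coords[:, j, :] = center + u * r[:, None]

    names = ["BB"] * n_site_residues + ["C1"] * n_lipids
    resnames = ["ALA"] * n_site_residues + ["LIP"] * n_lipids
    resids = list(range(1, n_site_residues + 1)) + list(
        range(101, 101 + n_lipids)
    )
    top = _make_topology(names, resnames, resids)
    coords = np.concatenate(
        [np.tile(site_coords, (n_frames, 1, 1)), lipid_coords], axis=1
    )
    traj = Trajectory(topology=top, coords=coords, box=box, dt=dt)
    info = {
        "true_durations_ns": np.asarray(true_durations),
        "true_censored": np.asarray(true_censored, dtype=bool),
        "bound_states": bound_states,
        "site_resids": list(range(1, n_site_residues + 1)),
        "lipid_resids": list(range(101, 101 + n_lipids)),
        "tau_true_ns": (1.0 / truth.koff_true) if truth.koff_true > 0 else np.inf,
    }
    return traj, info


# ---------------------------------------------------------------------------
# Poisson pocket waters
# ---------------------------------------------------------------------------

def gen_pocket_waters(
    truth: SyntheticTruth,
    pocket_atoms: np.ndarray | None = None,
    n_frames: int = 1000,
    box_edge: float = 6.0,
    shell: float = 0.4,
    n_background: int = 0,
    membrane_slab: tuple[float, float] | None = None,
) -> tuple[Trajectory, dict]:
    """Waters with Poisson(``pocket_rate``) occupancy inside a pocket shell.

    Per frame, K ~ Poisson waters are placed within ``shell`` nm of the
    pocket atoms; surplus water particles are parked in a far corner
    (> 1.5 nm from the pocket) so the particle count stays constant.
    Optional background waters fill the box uniformly, excluded from a
    z-slab emulating the membrane and from the pocket shell.
    """
    rng = truth.rng()
    box = np.full(3, box_edge)
    if pocket_atoms is None:
        pocket_atoms = np.array(
            [box / 2.0 - [0.15, 0.0, 0.0], box / 2.0 + [0.15, 0.0, 0.0]]
        )
    pocket_atoms = np.asarray(pocket_atoms, dtype=float)
    n_pocket_atoms = len(pocket_atoms)

    # enough slots that a Poisson draw essentially never overflows
    from scipy import stats as _st

    n_slots = int(_st.poisson.ppf(1.0 - 1e-12, max(truth.pocket_rate, 1e-9))) + 3
    park = np.array([0.3, 0.3, 0.3])  # box corner, far from central pocket

    counts = rng.poisson(truth.pocket_rate, size=n_frames)
    counts = np.minimum(counts, n_slots)
    pocket_w = np.tile(park, (n_frames, n_slots, 1))
    for f in range(n_frames):
        k = counts[f]
        placed = 0
        while placed < k:
            atom = pocket_atoms[rng.integers(n_pocket_atoms)]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = atom + v * shell * rng.uniform() ** (1.0 / 3.0)
            # keep strictly inside the shell of at least one atom
            if np.min(np.linalg.norm(pocket_atoms - pos, axis=1)) <= shell:
                pocket_w[f, placed] = pos
                placed += 1

    bg = None
    if n_background > 0:
        bg = rng.uniform(0.0, box_edge, size=(n_frames, n_background, 3))
        for f in range(n_frames):
            for i in range(n_background):
                while True:
                    p = bg[f, i]
                    in_slab = (
                        membrane_slab is not None
                        and membrane_slab[0] <= p[2] <= membrane_slab[1]
                    )
                    in_shell = (
                        np.min(np.linalg.norm(pocket_atoms - p, axis=1)) <= shell + 0.1
                    )
                    if not in_slab and not in_shell:
                        break
                    bg[f, i] = rng.uniform(0.0, box_edge, size=3)

    n_waters = n_slots + (n_background or 0)
    names = ["CA"] * n_pocket_atoms + ["OW"] * n_waters
    resnames = ["GLY"] * n_pocket_atoms + ["SOL"] * n_waters
    resids = list(range(1, n_pocket_atoms + 1)) + list(
        range(50, 50 + n_waters)
    )
    top = _make_topology(names, resnames, resids)
    parts = [np.tile(pocket_atoms, (n_frames, 1, 1)), pocket_w]
    if bg is not None:
        parts.append(bg)
    coords = np.concatenate(parts, axis=1)
    traj = Trajectory(topology=top, coords=coords, box=box, dt=1.0)
    info = {
        "pocket_atom_coords": pocket_atoms,
        "counts": counts,
        "normalized_true": truth.pocket_rate / n_pocket_atoms,
        "n_pocket_atoms": n_pocket_atoms,
    }
    return traj, info


# ---------------------------------------------------------------------------
# hydrophobic gate toggling
# ---------------------------------------------------------------------------

def gen_gating_toggle(
    truth: SyntheticTruth,
    n_frames: int = 1000,
    closed_distance: float = 0.30,
    open_distance: float = 0.55,
    sphere_radius: float = 0.4,
    box_edge: float = 6.0,
) -> tuple[Trajectory, dict]:
    """Two gating residues whose side-chain tip distance toggles between a
    closed (< 0.35 nm) and an open value, with waters injected into the Cα
    midpoint sphere only in open frames.

    Open/closed states are i.i.d. Bernoulli(``gate_open_fraction``); open
    frames carry ``gate_open_waters`` waters inside the sphere, closed
    frames none.
    """
    rng = truth.rng()
    box = np.full(3, box_edge)
    c = box / 2.0
    ca_sep = 1.0
    ca_a = c - [ca_sep / 2, 0, 0]
    ca_b = c + [ca_sep / 2, 0, 0]
    open_states = rng.uniform(size=n_frames) < truth.gate_open_fraction

    # side-chain tips point toward each other along x; distance toggles
    tip_a = np.tile(c, (n_frames, 1))
    tip_b = np.tile(c, (n_frames, 1))
    half = np.where(open_states, open_distance, closed_distance) / 2.0
    tip_a[:, 0] = c[0] - half
    tip_b[:, 0] = c[0] + half

    n_w = truth.gate_open_waters
    park = np.array([0.3, 0.3, 0.3])
    waters = np.tile(park, (n_frames, max(n_w, 1), 1))
    mid = c
    for f in np.flatnonzero(open_states):
        v = rng.normal(size=(n_w, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        rr = sphere_radius * 0.9 * rng.uniform(size=n_w) ** (1 / 3)
        waters[f, :n_w] = mid + v * rr[:, None]

    names = ["CA", "CB", "CA", "CB"] + ["OW"] * max(n_w, 1)
    resnames = ["TRP", "TRP", "PHE", "PHE"] + ["SOL"] * max(n_w, 1)
    resids = [1, 1, 2, 2] + list(range(10, 10 + max(n_w, 1)))
    top = _make_topology(names, resnames, resids)
    coords = np.empty((n_frames, len(names), 3))
    coords[:, 0] = ca_a
    coords[:, 1] = tip_a
    coords[:, 2] = ca_b
    coords[:, 3] = tip_b
    coords[:, 4:] = waters
    traj = Trajectory(topology=top, coords=coords, box=box, dt=1.0)
    info = {
        "open_states": open_states,
        "open_fraction_true": truth.gate_open_fraction,
        "open_fraction_realized": float(open_states.mean()),
        "residue_pair": (1, 2),
    }
    return traj, info


# ---------------------------------------------------------------------------
# hydrogen-bond toggling with tail rupture
# ---------------------------------------------------------------------------

def gen_bond_toggle(
    truth: SyntheticTruth,
    n_frames: int = 2000,
    bond_distance: float = 0.28,
    unbond_distance: float = 0.60,
    n_tail_particles: int = 5,
    tail_displacement: float = 1.0,
    tail_noise: float = 0.03,
    box_edge: float = 8.0,
) -> tuple[Trajectory, dict]:
    """Donor/acceptor pair bonded in a Bernoulli(``bond_prevalence``) subset
    of frames, plus a tail whose RMSD jumps at ``jump_frame``.

    The system contains a His-like donor (ND1 + HD1), a Thr-like acceptor
    (OG1), four static anchor Cα atoms (the fit selection) and an
    ``n_tail_particles``-residue Cα tail (the measure selection). Before
    ``jump_frame`` the tail wobbles around its reference with sd
    ``tail_noise``; from ``jump_frame`` on it is rigidly displaced by
    ``tail_displacement`` nm, sending the post-fit RMSD over any
    sub-nanometre dissociation threshold.
    """
    rng = truth.rng()
    box = np.full(3, box_edge)
    c = box / 2.0

    bonded = rng.uniform(size=n_frames) < truth.bond_prevalence
    donor = c + np.array([0.0, 1.5, 0.0])
    # acceptor along +x from donor; H sits on the donor→acceptor axis
    acc_dist = np.where(bonded, bond_distance, unbond_distance)
    acceptor = np.tile(donor, (n_frames, 1))
    acceptor[:, 0] += acc_dist
    hydrogen = np.tile(donor, (n_frames, 1))
    hydrogen[:, 0] += 0.10  # N–H bond length ~0.1 nm, pointing at acceptor

    anchors = c + np.array(
        [[-1.0, -1.0, 0.0], [1.0, -1.0, 0.0], [0.0, -1.0, 1.0], [0.0, -1.0, -1.0]]
    )
    tail_ref = c + np.column_stack(
        [np.linspace(-0.6, 0.6, n_tail_particles),
         np.full(n_tail_particles, -2.0),
         np.zeros(n_tail_particles)]
    )
    tail = np.tile(tail_ref, (n_frames, 1, 1))
    tail += rng.normal(0.0, tail_noise, size=tail.shape)
    jf = int(truth.jump_frame)
    if 0 <= jf < n_frames:
        tail[jf:] += np.array([0.0, 0.0, tail_displacement])

    names = (
        ["ND1", "HD1"] + ["OG1"] + ["CA"] * 4 + ["CA"] * n_tail_particles
    )
    resnames = (
        ["HSD", "HSD"] + ["THR"] + ["GLY"] * 4 + ["ALA"] * n_tail_particles
    )
    tail_resids = list(range(80, 80 + n_tail_particles))
    resids = [69, 69, 260] + [301, 302, 303, 304] + tail_resids
    top = _make_topology(names, resnames, resids)
    n_atoms = len(names)
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, 0] = donor
    coords[:, 1] = hydrogen
    coords[:, 2] = acceptor
    coords[:, 3:7] = anchors
    coords[:, 7:] = tail
    traj = Trajectory(topology=top, coords=coords, box=box, dt=1.0)

    reference = coords[0].copy()
    reference[7:] = tail_ref  # noise-free tail reference
    info = {
        "bonded": bonded,
        "prevalence_true": truth.bond_prevalence,
        "prevalence_realized": float(bonded.mean()),
        "jump_frame": jf,
        "reference": reference,
        "fit_resids": [301, 302, 303, 304],
        "tail_resids": tail_resids,
        "donor_resid": 69,
        "acceptor_resid": 260,
    }
    return traj, info


SCENARIOS = {
    "bilayer": gen_bilayer,
    "binding": gen_binding_kinetics,
    "pocket": gen_pocket_waters,
    "gating": gen_gating_toggle,
    "bond": gen_bond_toggle,
}


def simulate_to_dir(
    scenario: str, truth: SyntheticTruth, out_dir: str | Path, **kwargs
) -> tuple[Trajectory, dict]:
    """Run one generator and write GRO + XTC + truth JSON into ``out_dir``."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj, info = SCENARIOS[scenario](truth, **kwargs)
    write_trajectory(traj, out / f"{scenario}.xtc", out / f"{scenario}.gro")
    extra = {
        k: v.tolist() if isinstance(v, np.ndarray) else v
        for k, v in info.items()
        if k != "reference"
    }
    truth.to_json(out / f"{scenario}_truth.json", extra={"scenario": scenario, **extra})
    return traj, info
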