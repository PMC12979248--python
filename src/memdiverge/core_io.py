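"""Data model and I/O for membrane-protein trajectory analysis.

Internal units are nm for lengths and ns for times everywhere; conversion
happens only at file boundaries (PDB/MDAnalysis work in Å). Only
orthorhombic boxes are supported: every analysis here treats the membrane
normal as the z axis, and an axis-aligned box keeps minimum-image
distances exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.lib import distances as mdadist

A_PER_NM = 10.0

# ---------------------------------------------------------------------------
# role dictionaries (user-extensible via read_topology arguments)
# ---------------------------------------------------------------------------

#: particle names treated as lipid phosphate beads / phosphorus atoms
PHOSPHATE_NAMES = {"PO4", "PO41", "PO42", "P", "P8", "P04"}

#: water residue names (atomistic and CG)
WATER_RESNAMES = {"HOH", "SOL", "TIP3", "TIP4", "SPC", "WAT", "W", "PW"}

#: water oxygen particle names within a water residue
WATER_OXYGEN_NAMES = {"OW", "OH2", "O", "W"}

ION_NAMES = {"NA", "NA+", "CL", "CL-", "K", "K+", "CA2+", "MG", "ZN", "ION"}

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "GLH", "ASH", "LYN",
}

LIPID_RESNAMES = {
    "POPC", "DOPC", "POPE", "DOPE", "POPG", "DOPG", "POPS", "DOPS",
    "DPPC", "DSPC", "DLPC", "CHOL", "CDL", "CDL0", "CDL1", "CDL2",
    "PIP2", "POP2", "DPSM", "LIP",
}

ROLES = ("protein", "lipid", "water-oxygen", "phosphate", "ion", "unassigned")


class FormatError(ValueError):
    """A structure/trajectory file failed to parse under its declared format."""


class DegenerateGeometryError(ValueError):
    """Geometry is too degenerate for the requested operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Static description of every particle in the system.

    Arrays are aligned per particle. ``roles`` carries exactly one label per
    particle from :data:`ROLES`. ``frame0``/``box0`` hold the coordinates
    embedded in the source structure file (nm), when one was read.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chainids: np.ndarray
    segids: np.ndarray
    roles: np.ndarray
    masses: np.ndarray | None = None
    frame0: np.ndarray | None = None
    box0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        n = self.n_particles
        if n == 0:
            raise ValueError("topology must contain at least one particle")
        for attr in ("resnames", "resids", "chainids", "segids", "roles"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have one entry per particle")
            setattr(self, attr, arr)
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown role labels: {sorted(bad)}")

    @property
    def n_particles(self) -> int:
        return len(self.names)

    def indices_where(self, mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(np.asarray(mask, dtype=bool))


@dataclass
class Trajectory:
    """Ordered frames of particle coordinates in nm with orthorhombic boxes.

    ``coords`` has shape (n_frames, n_particles, 3); ``box`` holds per-frame
    (lx, ly, lz) edge lengths in nm; ``dt`` is the uniform inter-frame time
    in ns (None when the source format carries no time axis and no override
    was given).
    """

    topology: Topology
    coords: np.ndarray
    box: np.ndarray
    dt: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if self.coords.shape[1] != self.topology.n_particles:
            raise ValueError(
                f"frame has {self.coords.shape[1]} particles, topology has "
                f"{self.topology.n_particles}"
            )
        if self.coords.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape == (3,):
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have per-frame (lx, ly, lz)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        if self.dt is None:
            raise ValueError("trajectory has no time axis; supply dt")
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class Selection:
    """An ordered, duplicate-free set of particle indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, topology: Topology) -> "Selection":
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= topology.n_particles
        ):
            raise IndexError(f"selection {self.label!r} out of topology bounds")
        return self


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping a mobile set onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSeries:
    """Per-frame RMSD (nm) of a measured selection after fitting on another."""

    values: np.ndarray
    fit_selection: Selection
    measure_selection: Selection


# ---------------------------------------------------------------------------
# role assignment
# ---------------------------------------------------------------------------

def assign_roles(
    names: Sequence[str],
    resnames: Sequence[str],
    *,
    phosphate_names: set[str] | None = None,
    water_resnames: set[str] | None = None,
    water_oxygen_names: set[str] | None = None,
    extra_lipid_resnames: set[str] = frozenset(),
) -> np.ndarray:
    """Assign exactly one role label to each particle from name dictionaries.

    Precedence: phosphate > water-oxygen > ion > protein > lipid. Anything
    not matched becomes ``"unassigned"`` with a warning (never a failure).
    """
    phosphate_names = phosphate_names or PHOSPHATE_NAMES
    water_resnames = water_resnames or WATER_RESNAMES
    water_oxygen_names = water_oxygen_names or WATER_OXYGEN_NAMES
    lipids = LIPID_RESNAMES | set(extra_lipid_resnames)

    roles = np.empty(len(names), dtype=object)
    unknown: set[str] = set()
    for i, (name, resname) in enumerate(zip(names, resnames)):
        name_u, res_u = str(name).upper(), str(resname).upper()
        if res_u in lipids and name_u in phosphate_names:
            roles[i] = "phosphate"
        elif res_u in water_resnames:
            # non-oxygen water particles (H, virtual sites) stay unassigned
            roles[i] = "water-oxygen" if name_u in water_oxygen_names else "unassigned"
        elif name_u in ION_NAMES or res_u in ION_NAMES:
            roles[i] = "ion"
        elif res_u in PROTEIN_RESNAMES:
            roles[i] = "protein"
        elif res_u in lipids:
            roles[i] = "lipid"
        elif name_u in phosphate_names:
            roles[i] = "phosphate"
        else:
            roles[i] = "unassigned"
            unknown.add(res_u)
    if unknown:
        warnings.warn(
            f"residue names not in role dictionaries, labelled 'unassigned': "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    return roles


# ---------------------------------------------------------------------------
# readers / writers (MDAnalysis behind the module surface)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions: np.ndarray | None, where: str) -> np.ndarray | None:
    if dimensions is None or np.all(dimensions[:3] == 0):
        return None
    angles = dimensions[3:6]
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise ValueError(
            f"{where}: triclinic box (angles {angles}) not supported; "
            "only orthorhombic boxes are handled"
        )
    return np.asarray(dimensions[:3], dtype=float) / A_PER_NM


def read_topology(path: str | Path, format: str | None = None, **role_kwargs) -> Topology:
    """Read a PDB or GRO structure file into a :class:`Topology`.

    Embedded coordinates become ``frame0`` (nm; PDB Å are divided by 10 via
    MDAnalysis' internal Å representation). Role labels come from the
    shipped dictionaries, extensible through ``role_kwargs``.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=format)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"could not parse {path}: {exc}") from exc

    atoms = u.atoms
    names = atoms.names
    resnames = atoms.resnames
    try:
        chainids = atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chainids = np.array([""] * len(atoms), dtype=object)
    try:
        masses = np.asarray(atoms.masses, dtype=float)
        if np.all(masses == 0):
            masses = None
    except (AttributeError, mda.exceptions.NoDataError):
        masses = None

    roles = assign_roles(names, resnames, **role_kwargs)
    top = Topology(
        names=np.asarray(names, dtype=object),
        resnames=np.asarray(resnames, dtype=object),
        resids=np.asarray(atoms.resids, dtype=int),
        chainids=np.asarray(chainids, dtype=object),
        segids=np.asarray(atoms.segids, dtype=object),
        roles=roles,
        masses=masses,
    )
    top.frame0 = np.asarray(atoms.positions, dtype=float) / A_PER_NM
    dims = u.dimensions
    if dims is None and path.suffix.lower() in {".pdb", ".ent"}:
        # multi-model PDBs keep CRYST1 in the header, which the frame
        # reader does not associate with any MODEL; recover it directly
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    dims = np.array(
                        [line[6:15], line[15:24], line[24:33],
                         line[33:40], line[40:47], line[47:54]],
                        dtype=float,
                    )
                    break
                if line.startswith(("MODEL", "ATOM", "HETATM")):
                    break
    top.box0 = _check_orthorhombic(dims, str(path))
    return top


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: str | None = None,
    dt: float | None = None,
) -> Trajectory:
    """Read an XTC, DCD or multi-model PDB trajectory against ``topology``.

    ``dt`` (ns) overrides file metadata; formats without time stamps
    (multi-model PDB, most DCDs) leave ``Trajectory.dt`` as None unless an
    override is supplied — downstream kinetics then refuse to run rather
    than guess.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = mda.coordinates.core.get_reader_for(str(path), format=format)(
            str(path)
        )
    if reader.n_atoms != topology.n_particles:
        raise ValueError(
            f"particle count mismatch: file {path} has {reader.n_atoms}, "
            f"topology has {topology.n_particles}"
        )
    frames, boxes = [], []
    file_dt_ps: float | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in reader:
            frames.append(np.array(ts.positions, dtype=float) / A_PER_NM)
            box = _check_orthorhombic(ts.dimensions, str(path))
            boxes.append(box if box is not None else np.full(3, np.nan))
        if hasattr(reader, "dt"):
            try:
                file_dt_ps = float(reader.dt)
            except Exception:
                file_dt_ps = None
        reader.close()
    if not frames:
        raise ValueError(f"{path}: trajectory contains zero frames")
    boxes_arr = np.asarray(boxes)
    if np.any(np.isnan(boxes_arr)):
        if topology.box0 is None:
            raise ValueError(f"{path}: no box information in file or topology")
        boxes_arr = np.tile(topology.box0, (len(frames), 1))
    if dt is None and file_dt_ps is not None and path.suffix.lower() in {".xtc", ".trr"}:
        dt = file_dt_ps / 1000.0  # MDAnalysis reports ps
    return Trajectory(topology=topology, coords=np.asarray(frames), box=boxes_arr, dt=dt)


def _as_universe(traj: Trajectory) -> mda.Universe:
    top = traj.topology
    # map resids to contiguous residue indices preserving order of appearance
    order = {rid: k for k, rid in enumerate(dict.fromkeys(top.resids.tolist()))}
    res_index = np.array([order[r] for r in top.resids])
    n_res = len(order)
    u = mda.Universe.empty(
        n_atoms=top.n_particles,
        n_residues=n_res,
        atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in top.names])
    resnames, resids = [], []
    seen: dict[int, str] = {}
    for rid, rname in zip(top.resids, top.resnames):
        if rid not in seen:
            seen[rid] = str(rname)
            resids.append(int(rid))
            resnames.append(str(rname))
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("segids", ["SYS"])
    coords_A = traj.coords * A_PER_NM
    dims = np.zeros((traj.n_frames, 6))
    dims[:, :3] = traj.box * A_PER_NM
    dims[:, 3:] = 90.0
    u.load_new(coords_A.astype(np.float32), format="memory", dimensions=dims)
    return u


def write_trajectory(traj: Trajectory, coord_path: str | Path, structure_path: str | Path | None = None) -> None:
    """Write a trajectory as XTC/GRO/multi-model PDB (by extension).

    When ``structure_path`` is given, frame 0 is additionally written there
    as a GRO/PDB topology companion.
    """
    u = _as_universe(traj)
    coord_path = Path(coord_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if structure_path is not None:
            u.trajectory[0]
            u.atoms.write(str(structure_path))
        with mda.Writer(str(coord_path), n_atoms=u.atoms.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "(", ")", "name", "resname", "resid", "chain",
             "segid", "protein", "water", "lipid", "phosphate", "ion", "all"}


def _tokenize(expr: str) -> list[str]:
    return expr.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    """Tiny recursive-descent parser for selection expressions.

    Grammar: ``expr := term ('or' term)*``, ``term := factor ('and' factor)*``,
    ``factor := 'not' factor | '(' expr ')' | primitive``. Primitives:
    role keywords, ``name A B``, ``resname A B``, ``resid 5 7-9``,
    ``chain A``, ``segid S``, ``all``.
    """

    def __init__(self, tokens: list[str], top: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = top

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def _collect_args(self) -> list[str]:
        args = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            args.append(self.next())
        if not args:
            raise ValueError("selection keyword needs at least one argument")
        return args

    def primitive(self) -> np.ndarray:
        top = self.top
        tok = self.next()
        if tok == "all":
            return np.ones(top.n_particles, dtype=bool)
        if tok in ("protein", "water", "lipid", "phosphate", "ion"):
            role = "water-oxygen" if tok == "water" else tok
            return top.roles == role
        if tok == "name":
            vals = {v.upper() for v in self._collect_args()}
            return np.array([str(n).upper() in vals for n in top.names])
        if tok == "resname":
            vals = {v.upper() for v in self._collect_args()}
            return np.array([str(n).upper() in vals for n in top.resnames])
        if tok == "chain":
            vals = set(self._collect_args())
            return np.array([str(c) in vals for c in top.chainids])
        if tok == "segid":
            vals = set(self._collect_args())
            return np.array([str(s) in vals for s in top.segids])
        if tok == "resid":
            mask = np.zeros(top.n_particles, dtype=bool)
            for arg in self._collect_args():
                if "-" in arg and not arg.lstrip("-").isdigit():
                    lo, hi = arg.split("-", 1)
                    mask |= (top.resids >= int(lo)) & (top.resids <= int(hi))
                elif ":" in arg:
                    lo, hi = arg.split(":", 1)
                    mask |= (top.resids >= int(lo)) & (top.resids <= int(hi))
                else:
                    mask |= top.resids == int(arg)
            return mask
        raise ValueError(f"unknown selection token {tok!r}")


def select(topology: Topology, expr: str, label: str | None = None) -> Selection:
    """Resolve a selection expression (e.g. ``"protein and name CA"``)."""
    mask = _SelParser(_tokenize(expr), topology).parse()
    return Selection(indices=np.flatnonzero(mask), label=label or expr)


# ---------------------------------------------------------------------------
# geometry kernels
# ---------------------------------------------------------------------------

def _mda_box(box: np.ndarray) -> np.ndarray:
    return np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float32)


def neighbor_pairs(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
    box: np.ndarray,
) -> list[tuple[int, int, float]]:
    """All (i, j, d) pairs with minimum-image distance d ≤ cutoff (nm).

    The minimum-image convention is only valid up to half the smallest box
    edge; larger cutoffs raise.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    box = np.asarray(box, dtype=float)
    if cutoff > box.min() / 2:
        raise ValueError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({box.min() / 2} nm); minimum image invalid"
        )
    a = np.ascontiguousarray(coords_a, dtype=np.float64)
    b = np.ascontiguousarray(coords_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        return []
    pairs, dists = mdadist.capped_distance(
        a, b, max_cutoff=cutoff + 1e-9, box=_mda_box(box), return_distances=True
    )
    keep = dists <= cutoff + 1e-12
    return [(int(i), int(j), float(d)) for (i, j), d in zip(pairs[keep], dists[keep])]


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_distance(
    coords_a: np.ndarray, coords_b: np.ndarray, box: np.ndarray
) -> float:
    """Minimum-image minimum distance between two coordinate sets (nm)."""
    arr = mdadist.distance_array(
        np.ascontiguousarray(coords_a, dtype=np.float64),
        np.ascontiguousarray(coords_b, dtype=np.float64),
        box=_mda_box(np.asarray(box, dtype=float)),
    )
    return float(arr.min())


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid superposition (proper rotation only).

    Solves the weighted orthogonal Procrustes problem by SVD of the
    covariance matrix, with the determinant sign corrected so reflections
    are excluded. Needs ≥ 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = (w[:, None] * mobile).sum(axis=0)
    cr = (w[:, None] * reference).sum(axis=0)
    x = mobile - cm
    y = reference - cr
    # collinearity: second singular value of the centered cloud vanishes
    for cloud, tag in ((x, "mobile"), (y, "reference")):
        sv = np.linalg.svd(np.sqrt(w)[:, None] * cloud, compute_uv=False)
        if sv[1] <= 1e-10 * max(sv[0], 1e-30):
            raise DegenerateGeometryError(f"{tag} points are collinear")

    cov = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cr - rot @ cm
    resid = x @ rot.T - y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", resid, resid)).sum()))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray,
    fit_sel: Selection,
    measure_sel: Selection,
) -> RMSDSeries:
    """Per-frame RMSD of ``measure_sel`` after superposing each frame on
    ``fit_sel`` against the reference — the measured selection is carried
    along by the fitted transform, never refit.

    ``reference`` is a full-system coordinate array (nm) so both selections
    resolve in it by index.
    """
    for sel in (fit_sel, measure_sel):
        if len(sel) == 0:
            raise ValueError(f"empty selection {sel.label!r}")
        sel.validate(trajectory.topology)
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != trajectory.topology.n_particles:
        raise ValueError("reference must cover the full topology")
    ref_fit = reference[fit_sel.indices]
    ref_meas = reference[measure_sel.indices]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        sup = kabsch_superpose(frame[fit_sel.indices], ref_fit)
        moved = sup.apply(frame[measure_sel.indices])
        diff = moved - ref_meas
        values[f] = np.sqrt(np.einsum("ij,ij->i", diff, diff).mean())
    return RMSDSeries(values=values, fit_selection=fit_sel, measure_selection=measure_sel)
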