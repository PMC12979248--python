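"""Bilayer deformation mapping around a membrane protein.

The bilayer midplane is defined per frame as the mean z coordinate of all
phosphate beads; leaflet phosphate positions are normalised to it. Global
deformation is the reduction in bilayer width between the most extreme
deformation in each leaflet (mean phosphate z within an 0.8 nm shell of
the extreme residues) and all phosphate positions (≈ far field); local
deformation uses only protein-contacting phosphates (within 0.8 nm of the
protein) as the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Selection, Trajectory, minimum_image_displacement, neighbor_pairs
from .stats_report import TTestResult, students_t

DEFAULT_SHELL_NM = 0.8
DEFAULT_BIN_NM = 0.4


class LeafletDegeneracyError(ValueError):
    """All phosphates fell on one side of the midplane."""


@dataclass
class LeafletAssignment:
    """Per-phosphate leaflet label, fixed at one assignment frame.

    Labels are "EC" (extracellular/luminal, z > midplane) or "IC"
    (intracellular/cytoplasmic). No flip-flop tracking: labels are
    constant across frames.
    """

    labels: np.ndarray
    assignment_frame: int


@dataclass
class NormalizedPhosphates:
    """Per-frame midplane and midplane-normalised phosphate z values."""

    normalized_z: np.ndarray  # (n_frames, n_phosphates)
    midplane: np.ndarray  # (n_frames,) raw z of the midplane
    leaflets: LeafletAssignment
    phosphate_sel: Selection

    def leaflet_mask(self, leaflet: str) -> np.ndarray:
        return self.leaflets.labels == leaflet


@dataclass
class DeformationMap:
    """Per-leaflet 2D binned array of time-averaged normalised phosphate z.

    Bins are fixed in the protein-centred frame. Empty bins hold NaN in
    ``mean_z`` and 0 in ``counts`` — they are flagged, never zero-filled.
    """

    mean_z: dict  # leaflet -> (nx, ny) array, NaN where empty
    counts: dict  # leaflet -> (nx, ny) int array
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float
    midplane_definition: str = "per-frame mean phosphate z"

    def leaflet_weighted_mean(self, leaflet: str) -> float:
        m, c = self.mean_z[leaflet], self.counts[leaflet]
        good = c > 0
        return float((m[good] * c[good]).sum() / c[good].sum())


@dataclass
class ExtremeResult:
    """Extreme-deformation residue and its shell statistics for one leaflet."""

    residue: int
    shell_z_mean: float
    shell_z_sd: float
    per_residue_z: dict


@dataclass
class DeformationSummary:
    """Global/local deformation (nm) with per-frame spread.

    ``global_deformation`` sums the EC and IC width reductions (far-field
    baseline = all phosphates); ``local_deformation`` baselines on
    protein-contacting phosphates only. Per-leaflet components are kept so
    either convention can be reported.
    """

    extreme_ec: ExtremeResult
    extreme_ic: ExtremeResult
    global_deformation: float
    global_sd: float
    local_deformation: float
    local_sd: float
    per_leaflet_global: dict
    per_leaflet_local: dict
    shell: float


def compute_midplane_and_normalize(
    trajectory: Trajectory,
    phosphate_sel: Selection,
    assignment_frame: int = 0,
) -> NormalizedPhosphates:
    """Normalise phosphate z to the per-frame bilayer midplane.

    The midplane is the mean z of all selected phosphates in that frame;
    leaflet labels come from the sign of the normalised z at the
    assignment frame. All downstream deformation quantities are invariant
    to a global z translation by construction.
    """
    if len(phosphate_sel) == 0:
        raise ValueError("phosphate selection is empty")
    phosphate_sel.validate(trajectory.topology)
    z = trajectory.coords[:, phosphate_sel.indices, 2]
    midplane = z.mean(axis=1)
    normalized = z - midplane[:, None]
    signs = np.sign(normalized[assignment_frame])
    if np.all(signs >= 0) or np.all(signs <= 0):
        raise LeafletDegeneracyError(
            "all phosphates on one side of the midplane; not a bilayer"
        )
    labels = np.where(signs > 0, "EC", "IC")
    return NormalizedPhosphates(
        normalized_z=normalized,
        midplane=midplane,
        leaflets=LeafletAssignment(labels=labels, assignment_frame=assignment_frame),
        phosphate_sel=phosphate_sel,
    )


def _protein_centered_xy(
    trajectory: Trajectory, phosphate_sel: Selection, protein_sel: Selection | None
) -> np.ndarray:
    """Phosphate (x, y) per frame, re-centred on the protein's xy centroid.

    Centering (no rotation) keeps the map protein-centred without blurring
    from fitting a rotation to a wobbly elastic-network protein.
    """
    xy = trajectory.coords[:, phosphate_sel.indices, :2].copy()
    if protein_sel is not None and len(protein_sel) > 0:
        centroid = trajectory.coords[:, protein_sel.indices, :2].mean(axis=1)
        box_xy = trajectory.box[:, :2]
        xy = xy - centroid[:, None, :]
        # wrap into [-L/2, L/2) around the protein, then shift to [0, L)
        xy = minimum_image_displacement(xy, box_xy[:, None, :]) + box_xy[:, None, :] / 2.0
    return xy


def deformation_map(
    trajectory: Trajectory,
    phosphate_sel: Selection,
    bin_size: float = DEFAULT_BIN_NM,
    protein_sel: Selection | None = None,
    normalized: NormalizedPhosphates | None = None,
) -> DeformationMap:
    """Time-averaged normalised phosphate z on a 2D (x, y) grid per leaflet."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if normalized is None:
        normalized = compute_midplane_and_normalize(trajectory, phosphate_sel)
    box_xy = trajectory.box[0, :2]
    n_bins = np.maximum((box_xy / bin_size).astype(int), 1)
    x_edges = np.linspace(0, box_xy[0], n_bins[0] + 1)
    y_edges = np.linspace(0, box_xy[1], n_bins[1] + 1)
    xy = _protein_centered_xy(trajectory, phosphate_sel, protein_sel)
    xy = np.mod(xy, box_xy)  # fold into the primary box

    mean_z, counts = {}, {}
    occupied = 0
    for leaflet in ("EC", "IC"):
        mask = normalized.leaflet_mask(leaflet)
        xs = xy[:, mask, 0].ravel()
        ys = xy[:, mask, 1].ravel()
        zs = normalized.normalized_z[:, mask].ravel()
        cnt, _, _ = np.histogram2d(xs, ys, bins=(x_edges, y_edges))
        zsum, _, _ = np.histogram2d(xs, ys, bins=(x_edges, y_edges), weights=zs)
        with np.errstate(invalid="ignore"):
            mz = np.where(cnt > 0, zsum / np.maximum(cnt, 1), np.nan)
        mean_z[leaflet] = mz
        counts[leaflet] = cnt.astype(int)
        occupied += int((cnt > 0).sum())
    if occupied < 4:
        raise ValueError("fewer than 4 occupied bins; bilayer too small for a map")
    return DeformationMap(
        mean_z=mean_z, counts=counts, x_edges=x_edges, y_edges=y_edges, bin_size=bin_size
    )


def _shell_phosphate_z(
    trajectory: Trajectory,
    normalized: NormalizedPhosphates,
    particle_indices: np.ndarray,
    shell: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (EC mean, IC mean) of normalised z for phosphates within
    ``shell`` nm of any of the given particles; NaN when the shell is empty."""
    phos_idx = normalized.phosphate_sel.indices
    ec_mask = normalized.leaflet_mask("EC")
    out_ec = np.full(trajectory.n_frames, np.nan)
    out_ic = np.full(trajectory.n_frames, np.nan)
    for f in range(trajectory.n_frames):
        pairs = neighbor_pairs(
            trajectory.coords[f, particle_indices],
            trajectory.coords[f, phos_idx],
            shell,
            trajectory.box[f],
        )
        if not pairs:
            continue
        hit = np.unique([j for (_, j, _) in pairs])
        hit_ec = hit[ec_mask[hit]]
        hit_ic = hit[~ec_mask[hit]]
        if len(hit_ec):
            out_ec[f] = normalized.normalized_z[f, hit_ec].mean()
        if len(hit_ic):
            out_ic[f] = normalized.normalized_z[f, hit_ic].mean()
    return out_ec, out_ic


def locate_extremes(
    trajectory: Trajectory,
    phosphate_sel: Selection,
    protein_residues: Selection | list[int],
    shell: float = DEFAULT_SHELL_NM,
    normalized: NormalizedPhosphates | None = None,
    explicit: bool | None = None,
) -> tuple[ExtremeResult, ExtremeResult]:
    """Find the extreme-deformation residue per leaflet.

    For each candidate residue the mean normalised z of phosphates within
    ``shell`` of any of its particles is taken per frame, then
    frame-averaged; the extreme residue minimises |z| (deformation toward
    the midplane). Passing an explicit residue-id list (or explicit=True)
    skips the scan and reports those residues directly. Residues whose
    shell is empty in more than half the frames are excluded with a
    warning.
    """
    if shell <= 0:
        raise ValueError("shell must be positive")
    if normalized is None:
        normalized = compute_midplane_and_normalize(trajectory, phosphate_sel)
    top = trajectory.topology

    if isinstance(protein_residues, Selection):
        resids = sorted(set(top.resids[protein_residues.indices].tolist()))
        explicit = bool(explicit)
    else:
        resids = sorted(set(int(r) for r in protein_residues))
        explicit = True if explicit is None else explicit

    per_res: dict[int, dict] = {}
    excluded: list[int] = []
    for rid in resids:
        idx = np.flatnonzero(top.resids == rid)
        ec, ic = _shell_phosphate_z(trajectory, normalized, idx, shell)
        entry = {}
        for name, series in (("EC", ec), ("IC", ic)):
            ok = ~np.isnan(series)
            if ok.mean() <= 0.5:
                continue
            entry[name] = (float(np.nanmean(series)), float(np.nanstd(series)))
        if entry:
            per_res[rid] = entry
        else:
            excluded.append(rid)
    if excluded and not explicit:
        warnings.warn(
            f"residues with empty phosphate shells in >50% of frames excluded: "
            f"{excluded}",
            stacklevel=2,
        )
    if not per_res:
        raise ValueError("no candidate residue has phosphates within the shell")

    results = []
    for leaflet in ("EC", "IC"):
        cands = {r: v[leaflet] for r, v in per_res.items() if leaflet in v}
        if not cands:
            raise ValueError(f"no candidate residue contacts the {leaflet} leaflet")
        best = min(cands, key=lambda r: abs(cands[r][0]))
        mean, sd = cands[best]
        results.append(
            ExtremeResult(
                residue=int(best),
                shell_z_mean=mean,
                shell_z_sd=sd,
                per_residue_z={r: v[0] for r, v in cands.items()},
            )
        )
    return results[0], results[1]


def deformation_summary(
    trajectory: Trajectory,
    phosphate_sel: Selection,
    protein_sel: Selection,
    protein_residues: Selection | list[int] | None = None,
    shell: float = DEFAULT_SHELL_NM,
) -> DeformationSummary:
    """Global and local deformation from extreme shells vs. baselines.

    Global deformation = (mean |normalised z| over all phosphates, EC+IC)
    − (|extreme shell z|, EC+IC): the bilayer-width reduction between the
    most deformed protein-adjacent points and the far field. Local
    deformation baselines instead on phosphates within ``shell`` of any
    protein particle. Negative reductions are reported signed, with a
    warning, never clipped.
    """
    normalized = compute_midplane_and_normalize(trajectory, phosphate_sel)
    cand = protein_residues if protein_residues is not None else protein_sel
    ext_ec, ext_ic = locate_extremes(
        trajectory, phosphate_sel, cand, shell=shell, normalized=normalized
    )

    per_frame = {}
    for leaflet, ext in (("EC", ext_ec), ("IC", ext_ic)):
        mask = normalized.leaflet_mask(leaflet)
        per_frame[leaflet] = np.abs(normalized.normalized_z[:, mask]).mean(axis=1)
    # local baseline: phosphates within shell of ANY protein particle
    loc_ec, loc_ic = _shell_phosphate_z(
        trajectory, normalized, protein_sel.indices, shell
    )

    g_ec = per_frame["EC"] - abs(ext_ec.shell_z_mean)
    g_ic = per_frame["IC"] - abs(ext_ic.shell_z_mean)
    global_series = g_ec + g_ic
    l_ec = np.abs(loc_ec) - abs(ext_ec.shell_z_mean)
    l_ic = np.abs(loc_ic) - abs(ext_ic.shell_z_mean)
    local_series = l_ec + l_ic

    global_def = float(np.nanmean(global_series))
    local_def = float(np.nanmean(local_series))
    if global_def < 0 or local_def < 0:
        warnings.warn(
            "negative width reduction (bilayer thicker at the extremes); "
            "reported signed",
            stacklevel=2,
        )
    return DeformationSummary(
        extreme_ec=ext_ec,
        extreme_ic=ext_ic,
        global_deformation=global_def,
        global_sd=float(np.nanstd(global_series)),
        local_deformation=local_def,
        local_sd=float(np.nanstd(local_series)),
        per_leaflet_global={"EC": float(np.nanmean(g_ec)), "IC": float(np.nanmean(g_ic))},
        per_leaflet_local={"EC": float(np.nanmean(l_ec)), "IC": float(np.nanmean(l_ic))},
        shell=shell,
    )


def compare_groups(summaries_a: list[float], summaries_b: list[float]) -> TTestResult:
    """Pooled-variance two-sided unpaired t test between per-replicate values."""
    return students_t(summaries_a, summaries_b)
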