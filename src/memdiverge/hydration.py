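"""Water density grids and substrate-pocket hydration counts.

The density grid is the time-averaged number density (waters·nm⁻³) of
water oxygens on a regular voxel grid, reported only within 1 nm of the
protein. Pocket hydration counts distinct water oxygens within 0.4 nm of
a substrate-atom subset per frame — the acyl tail up to (and including)
the thioester sulfur, or the CoA headgroup (all other substrate atoms) —
and normalises by the subset's atom count so pockets of different size
compare directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import Selection, Trajectory, kabsch_superpose, neighbor_pairs

DEFAULT_VOXEL_NM = 0.1
DEFAULT_MASK_RADIUS_NM = 1.0
DEFAULT_SHELL_NM = 0.4


@dataclass
class DensityGrid:
    """Time-averaged water number density on a protein-proximal voxel grid.

    ``density`` is NaN outside the protein-proximity mask; inside, the
    masked integral (density × voxel volume summed over masked voxels)
    equals the mean per-frame water count in the masked region exactly,
    because the density is defined as that mean count per voxel volume.
    """

    origin: np.ndarray
    voxel: float
    density: np.ndarray  # (nx, ny, nz), NaN outside the mask
    mask: np.ndarray  # boolean, True within mask_radius of the protein
    mask_radius: float
    n_frames: int

    def masked_integral(self) -> float:
        vol = self.voxel**3
        return float(np.nansum(self.density[self.mask]) * vol)

    def to_dx(self, path) -> None:
        """Write the grid in OpenDX format (NaN outside the mask → 0)."""
        from gridData import Grid

        dens = np.where(self.mask, np.nan_to_num(self.density), 0.0)
        g = Grid(dens, origin=self.origin, delta=self.voxel)
        g.export(str(path), file_format="dx")


@dataclass
class PocketHydrationResult:
    """Per-frame water counts in one substrate pocket, normalised per atom."""

    subset: str  # "acyl-tail" | "CoA-headgroup"
    reference_atom_count: int
    per_frame_counts: np.ndarray
    normalized_mean: float
    normalized_sd: float


def water_density_grid(
    trajectory: Trajectory,
    water_sel: Selection,
    protein_sel: Selection,
    voxel: float = DEFAULT_VOXEL_NM,
    mask_radius: float = DEFAULT_MASK_RADIUS_NM,
) -> DensityGrid:
    """Count water oxygens per voxel per frame, average, divide by volume.

    The trajectory is assumed pre-aligned on the protein (use
    :func:`memdiverge.core_io.kabsch_superpose` per frame upstream for
    atomistic runs). The proximity mask marks voxels whose centre lies
    within ``mask_radius`` of any protein particle at frame 0.
    """
    if voxel <= 0:
        raise ValueError("voxel edge must be positive")
    if len(water_sel) == 0:
        raise ValueError("water selection is empty")
    water_sel.validate(trajectory.topology)
    protein_sel.validate(trajectory.topology)

    box = trajectory.box[0]
    if not np.allclose(trajectory.box, box, atol=1e-6):
        warnings.warn("box fluctuates; grid uses the frame-0 box", stacklevel=2)
    nbins = np.maximum((box / voxel).round().astype(int), 1)
    edges = [np.linspace(0, box[d], nbins[d] + 1) for d in range(3)]

    counts = np.zeros(tuple(nbins))
    for f in range(trajectory.n_frames):
        w = np.mod(trajectory.coords[f, water_sel.indices], box)
        h, _ = np.histogramdd(w, bins=edges)
        counts += h
    mean_counts = counts / trajectory.n_frames
    density = mean_counts / voxel**3

    centers = np.meshgrid(
        *[(e[:-1] + e[1:]) / 2 for e in edges], indexing="ij"
    )
    centers = np.stack([c.ravel() for c in centers], axis=1)
    prot = trajectory.coords[0, protein_sel.indices]
    mask_flat = np.zeros(len(centers), dtype=bool)
    pairs = neighbor_pairs(centers, prot, mask_radius, box)
    if pairs:
        mask_flat[np.unique([i for (i, _, _) in pairs])] = True
    mask = mask_flat.reshape(tuple(nbins))

    density = np.where(mask, density, np.nan)
    return DensityGrid(
        origin=np.zeros(3), voxel=voxel, density=density, mask=mask,
        mask_radius=mask_radius, n_frames=trajectory.n_frames,
    )


def count_waters_in_shell(
    water_coords: np.ndarray, subset_coords: np.ndarray, shell: float, box: np.ndarray
) -> int:
    """Distinct waters within ``shell`` of ANY subset atom (counted once)."""
    pairs = neighbor_pairs(water_coords, subset_coords, shell, box)
    return len({i for (i, _, _) in pairs})


def pocket_hydration(
    trajectory: Trajectory,
    water_sel: Selection,
    acyl_atoms: np.ndarray,
    headgroup_atoms: np.ndarray,
    shell: float = DEFAULT_SHELL_NM,
    fit_sel: Selection | None = None,
    reference: np.ndarray | None = None,
) -> tuple[PocketHydrationResult, PocketHydrationResult]:
    """Normalised water counts in the acyl-tail and CoA-headgroup pockets.

    ``acyl_atoms``/``headgroup_atoms`` are substrate atom coordinate
    arrays (nm) in the reference frame — the split puts the thioester S
    on the acyl side. When ``fit_sel`` and a full-system ``reference``
    are given, each frame is superposed on the reference (protein Cα
    alignment) before counting; an alignment RMSD above 0.5 nm triggers a
    reference-mismatch warning. A water near both subsets counts once per
    subset; within one subset it is never double-counted.
    """
    if len(water_sel) == 0:
        raise ValueError("water selection is empty")
    acyl_atoms = np.atleast_2d(np.asarray(acyl_atoms, dtype=float))
    headgroup_atoms = np.atleast_2d(np.asarray(headgroup_atoms, dtype=float))
    for name, arr in (("acyl", acyl_atoms), ("headgroup", headgroup_atoms)):
        if arr.size == 0:
            raise ValueError(f"{name} subset is empty")

    counts = {"acyl-tail": np.zeros(trajectory.n_frames),
              "CoA-headgroup": np.zeros(trajectory.n_frames)}
    warned = False
    for f in range(trajectory.n_frames):
        waters = trajectory.coords[f, water_sel.indices]
        if fit_sel is not None and reference is not None:
            sup = kabsch_superpose(
                trajectory.coords[f, fit_sel.indices], reference[fit_sel.indices]
            )
            if sup.rmsd > 0.5 and not warned:
                warnings.warn(
                    f"alignment RMSD {sup.rmsd:.2f} nm > 0.5 nm; reference may "
                    "not match this system",
                    stacklevel=2,
                )
                warned = True
            waters = sup.apply(waters)
        box = trajectory.box[f]
        counts["acyl-tail"][f] = count_waters_in_shell(waters, acyl_atoms, shell, box)
        counts["CoA-headgroup"][f] = count_waters_in_shell(
            waters, headgroup_atoms, shell, box
        )

    results = []
    for subset, ref_atoms in (
        ("acyl-tail", acyl_atoms),
        ("CoA-headgroup", headgroup_atoms),
    ):
        n_atoms = len(ref_atoms)
        norm = counts[subset] / n_atoms
        results.append(
            PocketHydrationResult(
                subset=subset,
                reference_atom_count=n_atoms,
                per_frame_counts=counts[subset],
                normalized_mean=float(norm.mean()),
                normalized_sd=float(norm.std()),
            )
        )
    return results[0], results[1]
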