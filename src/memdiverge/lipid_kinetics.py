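"""Protein–lipid contact kinetics and binding-site detection.

Contacts use a dual-cutoff (hysteresis) scheme — on when the minimum
residue–lipid distance drops below 0.475 nm, off only when it exceeds
0.7 nm — which suppresses boundary flicker. Residence times come from a
biexponential least-squares fit of the contact-duration survival function
S(t) = A·exp(−k1 t) + (1−A)·exp(−k2 t), with τ = 1/koff taken from the
slow component and asymmetric bounds from bootstrap resampling of the
durations. Binding sites are communities of residues whose per-residue
occupancy series correlate: nodes are residues, edges Pearson-weighted,
negative weights dropped, partitioned by the Louvain algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.optimize import curve_fit

from .core_io import Selection, Trajectory
from MDAnalysis.lib import distances as mdadist

LOWER_CUTOFF_NM = 0.475
UPPER_CUTOFF_NM = 0.7


@dataclass
class ContactSeries:
    """Boolean occupancy of one residue–lipid contact under hysteresis."""

    residue: int
    lipid: int
    occupancy: np.ndarray
    lower: float
    upper: float

    def durations(self, dt: float | None = None) -> "DurationSet":
        """Contiguous on-runs as durations (ns if dt given, else frames)."""
        return durations_from_occupancy(self.occupancy[None, :], dt)


@dataclass
class DurationSet:
    """Pooled contact durations with trajectory-end censoring flags."""

    durations: np.ndarray  # ns (or frames when dt unknown)
    censored: np.ndarray  # True where the contact persisted to the last frame
    unit: str = "ns"

    @property
    def n_events(self) -> int:
        return len(self.durations)

    def pooled_with(self, other: "DurationSet") -> "DurationSet":
        if self.unit != other.unit:
            raise ValueError("cannot pool durations with different units")
        return DurationSet(
            durations=np.concatenate([self.durations, other.durations]),
            censored=np.concatenate([self.censored, other.censored]),
            unit=self.unit,
        )


@dataclass
class ResidenceFit:
    """Biexponential survival-fit parameters; τ = 1/k1 (slow component)."""

    k1: float
    k2: float
    A: float
    tau: float
    r_squared: float
    tau_ci: tuple[float, float] | None = None
    n_events: int = 0
    monoexponential: bool = False
    mean_duration: float = 0.0


@dataclass
class BindingSite:
    """A community of residues acting as one lipid binding site."""

    site_id: int
    residues: tuple[int, ...]
    modularity: float
    fits: dict = field(default_factory=dict)  # species -> ResidenceFit
    representative_pose: tuple[int, int] | None = None  # (lipid, frame)


# ---------------------------------------------------------------------------
# dual-cutoff contact detection
# ---------------------------------------------------------------------------

def hysteresis_occupancy(distances: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Apply the dual-cutoff rule to a per-frame distance series.

    The contact switches on only when d < lower and off only when
    d > upper; the initial state is on iff the first frame is < lower.
    With lower == upper this reduces to a plain single-cutoff threshold
    (on iff d < cutoff, off iff d > cutoff; d == cutoff keeps state).
    """
    if lower > upper:
        raise ValueError("lower cutoff must not exceed upper cutoff")
    d = np.asarray(distances, dtype=float)
    occ = np.zeros(len(d), dtype=bool)
    state = bool(d[0] < lower)
    occ[0] = state
    for i in range(1, len(d)):
        if state:
            if d[i] > upper:
                state = False
        else:
            if d[i] < lower:
                state = True
        occ[i] = state
    return occ


def durations_from_occupancy(
    occupancy: np.ndarray, dt: float | None = None
) -> DurationSet:
    """Extract on-run durations from (n_series, n_frames) boolean occupancy.

    Runs reaching the final frame are censored (the true duration is at
    least what was observed); they are kept, flagged, in the survival fit
    — dropping them would bias τ low.
    """
    occ = np.atleast_2d(np.asarray(occupancy, dtype=bool))
    durs, cens = [], []
    for row in occ:
        padded = np.concatenate([[False], row, [False]])
        edges = np.diff(padded.astype(int))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for s, e in zip(starts, ends):
            durs.append(e - s)
            cens.append(e == len(row))
    scale = dt if dt is not None else 1.0
    return DurationSet(
        durations=np.asarray(durs, dtype=float) * scale,
        censored=np.asarray(cens, dtype=bool),
        unit="ns" if dt is not None else "frames",
    )


def _group_indices(trajectory: Trajectory, sel: Selection) -> dict[int, np.ndarray]:
    """Selection particle indices grouped by residue id."""
    top = trajectory.topology
    out: dict[int, np.ndarray] = {}
    for rid in dict.fromkeys(top.resids[sel.indices].tolist()):
        out[int(rid)] = sel.indices[top.resids[sel.indices] == rid]
    return out


def min_distance_series(
    trajectory: Trajectory,
    indices_a: np.ndarray,
    indices_b: np.ndarray,
) -> np.ndarray:
    """Per-frame minimum-image minimum distance between two particle groups."""
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        box = np.concatenate([trajectory.box[f], [90.0, 90.0, 90.0]]).astype(np.float32)
        arr = mdadist.distance_array(
            np.ascontiguousarray(trajectory.coords[f, indices_a]),
            np.ascontiguousarray(trajectory.coords[f, indices_b]),
            box=box,
        )
        out[f] = arr.min()
    return out


def dual_cutoff_contacts(
    trajectory: Trajectory,
    residue_sel: Selection,
    lipid_species: str,
    lower: float = LOWER_CUTOFF_NM,
    upper: float = UPPER_CUTOFF_NM,
) -> list[ContactSeries]:
    """Hysteresis contact series for every (residue, lipid) pair.

    ``lipid_species`` names a residue name present in the topology; the
    per-frame distance is the minimum over all (residue particle, lipid
    particle) pairs under the minimum-image convention.
    """
    if not lower <= upper:
        raise ValueError("need lower <= upper")
    if upper > trajectory.box.min() / 2:
        raise ValueError("upper cutoff exceeds half the smallest box edge")
    top = trajectory.topology
    lipid_mask = np.array([str(r).upper() == lipid_species.upper() for r in top.resnames])
    if not lipid_mask.any():
        available = sorted(
            {str(r) for r, role in zip(top.resnames, top.roles) if role in ("lipid", "phosphate")}
        )
        raise ValueError(
            f"lipid species {lipid_species!r} not in topology; available: {available}"
        )
    lipid_sel = Selection(np.flatnonzero(lipid_mask), label=lipid_species)
    residues = _group_indices(trajectory, residue_sel)
    lipids = _group_indices(trajectory, lipid_sel)

    out = []
    for rid, ridx in residues.items():
        for lid, lidx in lipids.items():
            d = min_distance_series(trajectory, ridx, lidx)
            out.append(
                ContactSeries(
                    residue=rid,
                    lipid=lid,
                    occupancy=hysteresis_occupancy(d, lower, upper),
                    lower=lower,
                    upper=upper,
                )
            )
    return out


# ---------------------------------------------------------------------------
# survival-function residence-time fit
# ---------------------------------------------------------------------------

def survival_function(durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical S(t) = fraction of durations ≥ t on the observed grid.

    The grid is the sorted unique durations with 0 prepended and one point
    beyond the maximum appended (where S = 0), so even degenerate duration
    sets constrain the decay.
    """
    d = np.sort(np.asarray(durations, dtype=float))
    if len(d) == 0:
        raise ValueError("no durations")
    grid = np.unique(np.concatenate([[0.0], d]))
    step = np.median(np.diff(grid)) if len(grid) > 1 else max(d[-1], 1.0)
    grid = np.concatenate([grid, [d[-1] + step]])
    s = np.array([(d >= t).mean() for t in grid])
    return grid, s


def _biexp(t, a, k1, k2):
    return a * np.exp(-k1 * t) + (1 - a) * np.exp(-k2 * t)


def _monoexp(t, k):
    return np.exp(-k * t)


def _fit_once(grid: np.ndarray, s: np.ndarray, mean: float) -> tuple[float, float, float, bool]:
    """Best biexponential (A, k1, k2) by multi-start least squares; falls
    back to monoexponential on non-convergence. Returns (A, k1, k2, mono)."""
    km = 1.0 / max(mean, 1e-12)
    starts = [
        (0.5, 0.5 * km, 2.0 * km),
        (0.3, 0.1 * km, 1.0 * km),
        (0.8, 1.0 * km, 5.0 * km),
        (0.95, km, km),
    ]
    best, best_ssr = None, np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _biexp, grid, s, p0=p0,
                    bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
                    maxfev=5000,
                )
            ssr = float(((_biexp(grid, *popt) - s) ** 2).sum())
            if ssr < best_ssr:
                best, best_ssr = popt, ssr
        except (RuntimeError, ValueError):
            continue
    if best is not None:
        a, k1, k2 = best
        if k1 > k2:  # slow component first
            a, k1, k2 = 1 - a, k2, k1
        if a >= 0.05:
            return float(a), float(k1), float(k2), False
        # a slow component carrying < 5% of the events is unidentifiable
        # (its rate is unconstrained and would dominate tau = 1/k1);
        # collapse to a monoexponential fit instead
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_monoexp, grid, s, p0=[km], bounds=(1e-9, np.inf))
        k = float(popt[0])
        return 1.0, k, k, True
    except (RuntimeError, ValueError):
        return 1.0, km, km, True


def fit_residence_time(
    durations: DurationSet,
    n_boot: int = 200,
    seed: int | None = None,
) -> ResidenceFit:
    """Fit the duration survival curve and report τ = 1/k1 (slow component).

    Needs ≥ 5 events for a curve fit; below that only the mean duration is
    reported. All-equal durations make k2 unidentifiable and trigger the
    monoexponential fallback. Bootstrap (resampling durations with
    replacement) gives asymmetric 2.5/97.5 percentile bounds on τ.
    """
    d = durations.durations
    mean = float(d.mean()) if len(d) else 0.0
    if durations.n_events < 5:
        return ResidenceFit(
            k1=np.nan, k2=np.nan, A=np.nan,
            tau=mean, r_squared=np.nan,
            n_events=durations.n_events, monoexponential=True, mean_duration=mean,
        )
    grid, s = survival_function(d)
    degenerate = np.allclose(d, d[0])
    if degenerate:
        # all-equal durations: k2 unidentifiable; use the exponential MLE
        # (rate = 1/mean) instead of least squares against a step function
        a, k1, k2, mono = 1.0, 1.0 / mean, 1.0 / mean, True
        pred = _monoexp(grid, k1)
    else:
        a, k1, k2, mono = _fit_once(grid, s, mean)
        pred = _monoexp(grid, k1) if mono else _biexp(grid, a, k1, k2)
    ss_res = float(((s - pred) ** 2).sum())
    ss_tot = float(((s - s.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    tau_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        taus = []
        for _ in range(n_boot):
            sample = rng.choice(d, size=len(d), replace=True)
            if np.allclose(sample, sample[0]):
                taus.append(float(sample.mean()))
                continue
            g, ss = survival_function(sample)
            _, bk1, _, _ = _fit_once(g, ss, float(sample.mean()))
            taus.append(1.0 / bk1)
        tau_ci = (float(np.percentile(taus, 2.5)), float(np.percentile(taus, 97.5)))

    return ResidenceFit(
        k1=k1, k2=k2, A=a, tau=1.0 / k1, r_squared=r2,
        tau_ci=tau_ci, n_events=durations.n_events,
        monoexponential=mono, mean_duration=mean,
    )


# ---------------------------------------------------------------------------
# binding-site detection (residue community analysis)
# ---------------------------------------------------------------------------

def detect_binding_sites(
    contacts: list[ContactSeries],
    resolution: float = 1.0,
    min_site_residues: int = 3,
    seed: int = 0,
    min_correlation: float = 0.0,
) -> list[BindingSite]:
    """Partition residues into binding sites by Louvain community analysis.

    Each residue's occupancy count series (summed over lipids) is a node;
    edges carry the pairwise Pearson correlation, with non-positive
    weights dropped. Communities smaller than ``min_site_residues`` are
    discarded.
    """
    by_res: dict[int, np.ndarray] = {}
    for c in contacts:
        series = c.occupancy.astype(float)
        by_res[c.residue] = by_res.get(c.residue, 0) + series
    residues = [r for r, s in by_res.items() if s.sum() > 0]
    if len(residues) < 2:
        warnings.warn("fewer than 2 residues with contact events; no sites", stacklevel=2)
        return []

    mat = np.vstack([by_res[r] for r in residues])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    g = nx.Graph()
    g.add_nodes_from(residues)
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            w = corr[i, j]
            if np.isfinite(w) and w > min_correlation:
                g.add_edge(residues[i], residues[j], weight=float(w))

    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    mod = (
        nx.community.modularity(g, communities, weight="weight")
        if g.number_of_edges()
        else 0.0
    )
    sites = []
    for comm in sorted(communities, key=lambda c: -len(c)):
        if len(comm) < min_site_residues:
            continue
        sites.append(
            BindingSite(
                site_id=len(sites) + 1,
                residues=tuple(sorted(int(r) for r in comm)),
                modularity=float(mod),
            )
        )
    return sites


def site_kinetics(
    site: BindingSite,
    contacts: list[ContactSeries],
    trajectory: Trajectory,
    lipid_species: str | None = None,
    lower: float = LOWER_CUTOFF_NM,
    upper: float = UPPER_CUTOFF_NM,
    n_boot: int = 200,
    seed: int | None = None,
) -> BindingSite:
    """Site-level residence fit and representative pose.

    A lipid contacts the site in a frame when it touches ANY site residue;
    hysteresis is applied to the per-lipid minimum distance over all site
    residues, so durations are unchanged by residue ordering. The
    representative pose is the (lipid, frame) maximising simultaneous
    site-residue contacts, earliest frame on ties.
    """
    if not site.residues:
        raise ValueError("empty binding site")
    top = trajectory.topology
    site_idx = np.flatnonzero(np.isin(top.resids, site.residues))

    by_lipid: dict[int, list[ContactSeries]] = {}
    for c in contacts:
        if c.residue in site.residues:
            by_lipid.setdefault(c.lipid, []).append(c)

    all_durations: DurationSet | None = None
    best = (-1, 0, 0)  # (count, frame, lipid)
    for lid, series_list in sorted(by_lipid.items()):
        lidx = np.flatnonzero(top.resids == lid)
        d = min_distance_series(trajectory, site_idx, lidx)
        occ = hysteresis_occupancy(d, lower, upper)
        ds = durations_from_occupancy(occ[None, :], trajectory.dt)
        all_durations = ds if all_durations is None else all_durations.pooled_with(ds)
        # simultaneous residue contacts per frame for the pose ranking
        simultaneous = np.sum([c.occupancy for c in series_list], axis=0)
        f_best = int(np.argmax(simultaneous))
        if simultaneous[f_best] > best[0]:
            best = (int(simultaneous[f_best]), f_best, lid)

    if all_durations is None or all_durations.n_events == 0:
        warnings.warn("no site-level contact events", stacklevel=2)
        return site
    fit = fit_residence_time(all_durations, n_boot=n_boot, seed=seed)
    species = lipid_species or "lipid"
    site.fits[species] = fit
    if best[0] > 0:
        site.representative_pose = (best[2], best[1])
    return site
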