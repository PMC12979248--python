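"""Deformation mapping: midplane, maps, extremes, summaries, group stats."""

import numpy as np
import pytest

from memdiverge.core_io import Selection, select
from memdiverge.deformation import (
    LeafletDegeneracyError,
    compare_groups,
    compute_midplane_and_normalize,
    deformation_map,
    deformation_summary,
    locate_extremes,
)
from memdiverge.synthetic_data import SyntheticTruth, gen_bilayer

from conftest import make_trajectory


def _four_phosphate_traj(z_values, n_frames=1):
    coords = np.zeros((n_frames, len(z_values), 3))
    coords[:, :, 0] = np.arange(len(z_values)) + 1.0
    coords[:, :, 1] = 5.0
    coords[:, :, 2] = z_values
    return make_trajectory(
        coords, [10.0, 10.0, 20.0],
        names=["PO4"] * len(z_values), resnames=["POPC"] * len(z_values),
        resids=list(range(1, len(z_values) + 1)),
    )


class TestMidplane:
    def test_hand_computed_midplane_and_leaflet_means(self):
        traj = _four_phosphate_traj([3.9, 4.1, -4.0, -4.0])
        phos = select(traj.topology, "phosphate")
        norm = compute_midplane_and_normalize(traj, phos)
        assert norm.midplane[0] == pytest.approx(0.0, abs=1e-12)
        ec = norm.normalized_z[0, norm.leaflet_mask("EC")]
        ic = norm.normalized_z[0, norm.leaflet_mask("IC")]
        assert ec.mean() == pytest.approx(4.0)
        assert ic.mean() == pytest.approx(-4.0)

    def test_global_z_translation_invariance(self):
        traj = _four_phosphate_traj([3.9, 4.1, -4.0, -4.0])
        phos = select(traj.topology, "phosphate")
        base = compute_midplane_and_normalize(traj, phos).normalized_z
        traj.coords[:, :, 2] += 5.0
        shifted = compute_midplane_and_normalize(traj, phos).normalized_z
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_one_sided_phosphates_degenerate(self):
        traj = _four_phosphate_traj([4.0, 4.0, 4.0, 4.0])
        phos = select(traj.topology, "phosphate")
        with pytest.raises(LeafletDegeneracyError):
            compute_midplane_and_normalize(traj, phos)

    def test_synthetic_leaflet_mean_recovers_half_width(self):
        truth = SyntheticTruth(
            seed=21, deformation_amplitude_ec=0.0, deformation_amplitude_ic=0.0
        )
        traj, _ = gen_bilayer(truth, n_frames=200, half_width=2.0)
        phos = select(traj.topology, "phosphate")
        norm = compute_midplane_and_normalize(traj, phos)
        for leaflet in ("EC", "IC"):
            mean_abs = np.abs(norm.normalized_z[:, norm.leaflet_mask(leaflet)]).mean()
            assert mean_abs == pytest.approx(2.0, abs=0.02)


class TestDeformationMap:
    def test_flat_noiseless_bins_exact(self):
        truth = SyntheticTruth(
            seed=2, deformation_amplitude_ec=0.0, deformation_amplitude_ic=0.0,
            noise_sigma=0.0,
        )
        traj, _ = gen_bilayer(truth, n_frames=2, half_width=2.0)
        phos = select(traj.topology, "phosphate")
        dmap = deformation_map(traj, phos, bin_size=1.0)
        ec = dmap.mean_z["EC"]
        occupied = dmap.counts["EC"] > 0
        np.testing.assert_allclose(ec[occupied], 2.0, atol=1e-9)
        # empty bins are NaN-flagged, never zero-filled
        assert np.all(np.isnan(ec[~occupied]))

    def test_funnel_center_bin_depth(self):
        truth = SyntheticTruth(
            seed=3, deformation_amplitude_ec=0.8, deformation_amplitude_ic=0.0,
            noise_sigma=0.05,
        )
        traj, _ = gen_bilayer(truth, n_frames=100, half_width=2.0)
        phos = select(traj.topology, "phosphate")
        prot = select(traj.topology, "protein")
        dmap = deformation_map(traj, phos, bin_size=0.5, protein_sel=prot)
        ec = dmap.mean_z["EC"]
        nx, ny = ec.shape
        center = ec[nx // 2 - 1: nx // 2 + 1, ny // 2 - 1: ny // 2 + 1]
        # closed-form field value at the funnel core: half_width - amplitude
        assert np.nanmean(center) == pytest.approx(2.0 - 0.8, abs=0.05)

    def test_degenerate_single_bin_equals_leaflet_mean(self):
        truth = SyntheticTruth(seed=4, noise_sigma=0.0)
        traj, _ = gen_bilayer(truth, n_frames=1, half_width=2.0, n_lipids_per_leaflet=25)
        phos = select(traj.topology, "phosphate")
        with pytest.raises(ValueError, match="occupied bins"):
            deformation_map(traj, phos, bin_size=100.0)
        dmap = deformation_map(traj, phos, bin_size=traj.box[0, 0] / 2)
        norm = compute_midplane_and_normalize(traj, phos)
        ec_mean = norm.normalized_z[0, norm.leaflet_mask("EC")].mean()
        assert dmap.leaflet_weighted_mean("EC") == pytest.approx(ec_mean, abs=1e-9)

    def test_weighted_mean_invariant(self):
        truth = SyntheticTruth(seed=5)
        traj, _ = gen_bilayer(truth, n_frames=20)
        phos = select(traj.topology, "phosphate")
        norm = compute_midplane_and_normalize(traj, phos)
        dmap = deformation_map(traj, phos, bin_size=0.4, normalized=norm)
        for leaflet in ("EC", "IC"):
            direct = norm.normalized_z[:, norm.leaflet_mask(leaflet)].mean()
            assert dmap.leaflet_weighted_mean(leaflet) == pytest.approx(direct, abs=1e-9)


class TestLocateExtremes:
    def test_funnel_selects_designated_residue(self):
        truth = SyntheticTruth(
            seed=7, deformation_amplitude_ec=1.0, deformation_amplitude_ic=1.0
        )
        traj, info = gen_bilayer(truth, n_frames=100)
        phos = select(traj.topology, "phosphate")
        prot = select(traj.topology, "protein")
        with pytest.warns(UserWarning, match="excluded"):
            ext_ec, ext_ic = locate_extremes(traj, phos, prot)
        # the chosen residue must sit within the 0.8 nm shell of the true
        # extreme surface (several column residues are equivalent there)
        half_width, shell = info["half_width"], 0.8
        resids = np.array(info["protein_resids"])
        z = np.linspace(-half_width, half_width, len(resids))
        z_of = dict(zip(resids, z))
        assert abs(z_of[ext_ec.residue] - info["extreme_z_ec"]) <= shell
        assert abs(z_of[ext_ic.residue] - info["extreme_z_ic"]) <= shell
        assert ext_ec.shell_z_mean == pytest.approx(info["extreme_z_ec"], abs=0.1)
        assert ext_ic.shell_z_mean == pytest.approx(info["extreme_z_ic"], abs=0.1)

    def test_explicit_list_overrides_scan(self):
        truth = SyntheticTruth(
            seed=8, deformation_amplitude_ec=0.0, deformation_amplitude_ic=0.0
        )
        traj, info = gen_bilayer(truth, n_frames=30)
        phos = select(traj.topology, "phosphate")
        # pick non-extreme residues near each leaflet surface explicitly
        rid_ec = info["protein_resids"][-1]
        rid_ic = info["protein_resids"][0]
        ext_ec, ext_ic = locate_extremes(traj, phos, [rid_ec, rid_ic])
        assert ext_ec.residue == rid_ec
        assert ext_ic.residue == rid_ic


class TestSummary:
    def test_arithmetic_oracle(self):
        # far-field leaflets at ±2.0 nm, extreme shells at +0.8 / −1.0
        # global deformation = (2.0 − 0.8) + (2.0 − 1.0) = 2.2 nm
        assert (2.0 - 0.8) + (2.0 - 1.0) == pytest.approx(2.2)
        truth = SyntheticTruth(
            seed=11, deformation_amplitude_ec=1.2, deformation_amplitude_ic=1.0,
            noise_sigma=0.05,
        )
        traj, info = gen_bilayer(truth, n_frames=100)
        phos = select(traj.topology, "phosphate")
        prot = select(traj.topology, "protein")
        s = deformation_summary(
            traj, phos, prot,
            protein_residues=[info["extreme_residue_ec"], info["extreme_residue_ic"]],
        )
        assert s.global_deformation == pytest.approx(2.2, abs=0.1)

    def test_zero_amplitude_near_zero(self):
        truth = SyntheticTruth(
            seed=12, deformation_amplitude_ec=0.0, deformation_amplitude_ic=0.0
        )
        traj, info = gen_bilayer(truth, n_frames=100)
        phos = select(traj.topology, "phosphate")
        prot = select(traj.topology, "protein")
        s = deformation_summary(
            traj, phos, prot,
            protein_residues=[info["protein_resids"][-1], info["protein_resids"][0]],
        )
        assert abs(s.global_deformation) < 0.1

    def test_truth_recovery_and_local_le_global(self):
        truth = SyntheticTruth(
            seed=7, deformation_amplitude_ec=0.8, deformation_amplitude_ic=1.0
        )
        traj, info = gen_bilayer(truth, n_frames=200)
        phos = select(traj.topology, "phosphate")
        prot = select(traj.topology, "protein")
        s = deformation_summary(
            traj, phos, prot,
            protein_residues=[info["extreme_residue_ec"], info["extreme_residue_ic"]],
        )
        assert s.global_deformation == pytest.approx(1.8, abs=0.1)
        # the local baseline (protein-contacting phosphates, all deformed)
        # sits below the far field, so local ≤ global
        assert s.local_deformation <= s.global_deformation + 1e-9

    def test_map_summary_consistency(self):
        truth = SyntheticTruth(
            seed=13, deformation_amplitude_ec=1.0, deformation_amplitude_ic=0.8
        )
        traj, info = gen_bilayer(truth, n_frames=100)
        phos = select(traj.topology, "phosphate")
        prot = select(traj.topology, "protein")
        norm = compute_midplane_and_normalize(traj, phos)
        dmap = deformation_map(traj, phos, bin_size=0.4, protein_sel=prot, normalized=norm)
        ext_ec, _ = locate_extremes(
            traj, phos, [info["extreme_residue_ec"], info["extreme_residue_ic"]],
            normalized=norm,
        )
        # the shallowest EC map bin brackets the extreme shell value
        min_bin = np.nanmin(dmap.mean_z["EC"])
        assert min_bin <= ext_ec.shell_z_mean + 0.1


class TestCompareGroups:
    def test_closed_form_t(self):
        res = compare_groups([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p == pytest.approx(0.286, abs=0.005)
        assert res.star == "ns"

    def test_identical_groups(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p == 1.0
        assert res.star == "ns"
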