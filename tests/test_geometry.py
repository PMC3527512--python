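"""Filament geometry: head coarse-graining and the three region builders."""

import numpy as np
import pytest

from thickfil.geometry import (CProteinParams, CrossbridgeParams,
                               PerturbationProfile, SphereSet,
                               assemble_filament, build_cprotein_array,
                               build_crossbridge, build_perturbed_region,
                               build_regular_region, coarse_grain_head)
from thickfil.synthetic import synth_head
from thickfil.transform import RadialGrid, cylindrical_intensity


class TestSphereSet:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SphereSet([-1.0], [0.0], [0.0], 0.7, 1.0)
        with pytest.raises(ValueError):
            SphereSet([1.0], [0.0], [0.0], 0.7, -1.0)
        with pytest.raises(ValueError):
            SphereSet([1.0], [0.0], [0.0], 0.7, 1.0, sigma=-0.1)

    def test_cartesian_round_trip(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(20, 3)) * 5
        s = SphereSet.from_cartesian(xyz, 0.72, 1.0)
        assert np.allclose(s.to_cartesian(), xyz)


class TestCoarseGrainHead:
    def test_identity_partition_when_counts_match(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(68, 3))
        hm = coarse_grain_head(pts, n_spheres=68)
        assert hm.n_spheres == 68
        assert np.allclose(np.sort(hm.xyz, axis=0), np.sort(pts, axis=0))
        assert np.allclose(hm.weights, 1.0)

    def test_center_of_mass_preserved(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(500, 3)) * np.array([6.0, 2.0, 2.0])
        hm = coarse_grain_head(pts, n_spheres=68)
        assert np.linalg.norm(hm.center_of_mass() - pts.mean(axis=0)) < 0.01

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least"):
            coarse_grain_head(np.zeros((10, 3)), n_spheres=68)

    def test_transform_correlation_against_full_cloud(self, coarse_grid):
        # dense synthetic stand-in for an atomic C-alpha cloud: the 68-bead
        # reduction must reproduce the all-point transform essentially
        # exactly over the working resolution range
        rng = np.random.default_rng(5)
        base = synth_head(0).xyz
        cloud = np.repeat(base, 8, axis=0) + rng.normal(scale=0.35,
                                                        size=(68 * 8, 3))
        hm = coarse_grain_head(cloud, n_spheres=68)
        full = SphereSet.from_cartesian(cloud + [0, 12, 0], 0.72,
                                        np.ones(len(cloud)))
        red = SphereSet.from_cartesian(hm.xyz + [0, 12, 0], 0.72, hm.weights)
        corrs = []
        for l in range(0, 12, 2):
            a = cylindrical_intensity(full, coarse_grid, layers=[l]).intensity[0]
            b = cylindrical_intensity(red, coarse_grid, layers=[l]).intensity[0]
            corrs.append(np.corrcoef(a, b)[0, 1])
        assert min(corrs) >= 0.99


class TestCrossbridge:
    def test_com_radius_and_level(self, small_head, perturbed_params):
        cb = build_crossbridge(small_head, perturbed_params, z=10.0)
        com = cb.center_of_mass()
        assert np.hypot(com[0], com[1]) == pytest.approx(12.7, abs=1e-9)
        assert com[2] == pytest.approx(10.0, abs=1e-9)

    def test_weight_conserved(self, small_head, perturbed_params):
        cb = build_crossbridge(small_head, perturbed_params)
        assert cb.total_weight() == pytest.approx(2 * small_head.weights.sum())


def _sorted_rows(arr):
    arr = np.round(np.asarray(arr), 6)
    order = np.lexsort(arr.T[::-1])
    return arr[order]


class TestRegularRegion:
    def test_crown_screw_symmetry(self, small_head, regular_params):
        reg = build_regular_region(small_head, regular_params, length=3 * 14.3)
        n_cb = 2 * len(small_head.xyz) * 3  # beads per crown (3 strands)
        crown0 = np.column_stack([reg.r[:n_cb], (reg.phi[:n_cb] + 40.0) % 360,
                                  reg.z[:n_cb] + 14.3])
        crown1 = np.column_stack([reg.r[n_cb:2 * n_cb],
                                  reg.phi[n_cb:2 * n_cb] % 360,
                                  reg.z[n_cb:2 * n_cb]])
        assert np.allclose(_sorted_rows(crown0), _sorted_rows(crown1),
                           atol=1e-9)

    def test_successive_crown_twist_is_40_degrees(self, small_head,
                                                  regular_params):
        reg = build_regular_region(small_head, regular_params, length=2 * 14.3)
        n_cb = 2 * len(small_head.xyz) * 3
        d = (reg.phi[n_cb:2 * n_cb] - reg.phi[:n_cb]) % 360.0
        assert np.allclose(d, 40.0)

    def test_three_fold_rotation_invariance(self, small_head, regular_params):
        reg = build_regular_region(small_head, regular_params, length=5 * 14.3)
        rot = reg.rotated(120.0)
        a = np.column_stack([reg.to_cartesian()])
        b = np.column_stack([rot.to_cartesian()])
        assert np.allclose(_sorted_rows(a), _sorted_rows(b), atol=1e-5)

    def test_head_count_scales_with_crowns(self, small_head, regular_params):
        reg = build_regular_region(small_head, regular_params, length=215.0)
        n_crowns = int(215.0 / 14.3)
        assert len(reg) == n_crowns * 3 * 2 * len(small_head.xyz)


class TestPerturbedRegion:
    def test_axial_seps_must_sum_to_repeat(self):
        with pytest.raises(ValueError, match="repeat"):
            PerturbationProfile(axial_seps=(10.0, 14.0, 17.0))

    def test_gap_between_crowns_2_and_3_is_largest(self, perturbation):
        assert max(perturbation.axial_seps[:2]) < perturbation.axial_seps[1] \
            or perturbation.axial_seps.index(max(perturbation.axial_seps)) == 2
        # the crown-2 -> crown-3 separation is the largest of the triplet
        assert perturbation.axial_seps[2] == max(perturbation.axial_seps)

    def test_consecutive_azimuthal_steps(self, perturbation):
        p1, p2, p3 = perturbation.phis
        assert {round(p2 - p1), round(p3 - p2)} == {47, 73}

    def test_crown4_equals_crown3_azimuth(self, perturbation):
        # next repeat carries +120 deg: crown 4 = phi1 + 120 = phi3
        assert perturbation.phis[0] + 120.0 == pytest.approx(
            perturbation.phis[2], abs=1e-9)

    def test_repeat_screw_symmetry_and_broken_crown_screw(
            self, small_head, perturbed_params, perturbation):
        per = build_perturbed_region(small_head, perturbed_params,
                                     perturbation, length=3 * 42.9)
        n_rep = len(per) // 3
        a = np.column_stack([per.r, per.phi % 360.0, per.z])
        # (dz=42.9, dphi=120) maps repeat 1 onto repeat 2
        moved = np.column_stack([per.r[:n_rep], (per.phi[:n_rep] + 120) % 360,
                                 per.z[:n_rep] + 42.9])
        assert np.allclose(_sorted_rows(moved),
                           _sorted_rows(a[n_rep:2 * n_rep]), atol=1e-9)
        # but the 14.33-nm crown screw does NOT hold
        n_crown = n_rep // 3
        crown_moved = np.column_stack([
            per.r[:n_crown], (per.phi[:n_crown] + 40.0) % 360.0,
            per.z[:n_crown] + 42.9 / 3.0])
        assert not np.allclose(
            _sorted_rows(crown_moved),
            _sorted_rows(a[n_crown:2 * n_crown]), atol=1e-6)


class TestCProteinArray:
    def test_molecule_layout(self):
        arr = build_cprotein_array(CProteinParams(), n_levels=1)
        assert len(arr) == 3 * 11
        mol = SphereSet(arr.r[:11], arr.phi[:11], arr.z[:11], arr.a[:11],
                        arr.w[:11], arr.sigma[:11])
        xyz = mol.to_cartesian()
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        assert np.allclose(steps, 4.0, atol=1e-6)

    def test_level_spacing(self):
        arr = build_cprotein_array(CProteinParams(), n_levels=2)
        z1 = arr.z[:33]
        z2 = arr.z[33:]
        assert np.allclose(np.sort(z2) - np.sort(z1), 45.33)

    def test_projecting_arm_reaches_high_radius(self):
        arr = build_cprotein_array(CProteinParams(), n_levels=1)
        assert arr.max_radius() > 25.0

    def test_projecting_beads_carry_disorder(self):
        arr = build_cprotein_array(CProteinParams(sigma_proj=1.0), n_levels=1)
        assert (arr.sigma > 0).sum() == 3 * 8
        assert (arr.sigma == 0).sum() == 3 * 3


class TestAssembleFilament:
    def test_region_layout_and_fraction(self, small_head, regular_params,
                                        perturbed_params, perturbation):
        reg = build_regular_region(small_head, regular_params, 215.0)
        per = build_perturbed_region(small_head, perturbed_params,
                                     perturbation, 516.0)
        cp = build_cprotein_array(CProteinParams(), n_levels=11)
        fil = assemble_filament(reg, per, cp)
        assert fil.perturbed_fraction() == pytest.approx(0.70, abs=0.02)
        assert fil.regular.z.min() > fil.perturbed.z.max()

    def test_zero_length_regular_region(self, small_head, perturbed_params,
                                        perturbation):
        per = build_perturbed_region(small_head, perturbed_params,
                                     perturbation, 516.0)
        fil = assemble_filament(SphereSet.empty(), per, SphereSet.empty(),
                                regular_length=0.0)
        assert len(fil.regular) == 0
        assert len(fil.all_spheres()) == len(per)

    def test_total_crossbridge_count(self, small_head, regular_params,
                                     perturbed_params, perturbation):
        reg = build_regular_region(small_head, regular_params, 215.0)
        per = build_perturbed_region(small_head, perturbed_params,
                                     perturbation, 516.0)
        fil = assemble_filament(reg, per, SphereSet.empty())
        crowns = int(215.0 / 14.3) + 3 * int(516.0 / 42.9)
        n_heads = 2 * 3 * crowns
        assert len(fil.myosin_spheres()) == n_heads * len(small_head.xyz)
        assert fil.myosin_spheres().total_weight() == pytest.approx(
            n_heads * small_head.weights.sum())

    def test_overlapping_regions_rejected(self, small_head, regular_params,
                                          perturbed_params, perturbation):
        reg = build_regular_region(small_head, regular_params, 215.0)
        per = build_perturbed_region(small_head, perturbed_params,
                                     perturbation, 516.0)
        with pytest.raises(ValueError, match="overlap"):
            assemble_filament(reg, per, SphereSet.empty(),
                              perturbed_length=100.0)
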