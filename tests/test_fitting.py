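"""RDI statistic, pattern normalization and the orientation grid search."""

import numpy as np
import pytest

from thickfil.fitting import (FitConfig, OrientationSearch, normalize_patterns,
                              optimize_axial_tilt, phi_triplet_allowed, rdi)
from thickfil.geometry import (CrossbridgeParams, PerturbationProfile,
                               build_perturbed_region)
from thickfil.synthetic import synth_head
from thickfil.transform import (DiffractionPattern, RadialGrid,
                                cylindrical_intensity, sphere_form_factor)


@pytest.fixture(scope="module")
def search_setup(small_head):
    """Observed pattern generated from known on-grid parameters plus the
    builder that regenerates candidate models."""
    grid = RadialGrid(np.linspace(0.0, 0.25, 51))
    truth = {"phi1": 3.0, "phi2": 50.0, "phi3": 123.0, "r_h": 12.7}

    def builder(p):
        prof = PerturbationProfile(phis=(p["phi1"], p["phi2"], p["phi3"]))
        cb = CrossbridgeParams(eps_head1=-13.0, eps_head2=15.0, r_h=p["r_h"])
        return build_perturbed_region(small_head, cb, prof, length=2 * 42.9)

    observed = cylindrical_intensity(builder(truth), grid, layers=range(1, 12))
    return truth, builder, observed


def random_pattern(seed, grid):
    rng = np.random.default_rng(seed)
    return DiffractionPattern(range(12), rng.uniform(0.1, 1.0, (12, grid.R_values.size)),
                              grid)


class TestNormalize:
    def test_double_reference_halves(self, coarse_grid):
        ref = random_pattern(0, coarse_grid)
        obj = ref.scaled(2.0)
        out = normalize_patterns(ref, obj)
        assert np.allclose(out.intensity, ref.intensity)

    def test_identity(self, coarse_grid):
        ref = random_pattern(1, coarse_grid)
        out = normalize_patterns(ref, ref.copy())
        assert np.allclose(out.intensity, ref.intensity)

    def test_meridional_region_excluded_from_scale(self, coarse_grid):
        ref = random_pattern(2, coarse_grid)
        obj = ref.scaled(3.0)
        tampered = obj.copy()
        mask = coarse_grid.R_values < coarse_grid.R_min_fit
        tampered.intensity[:, mask] *= 17.0
        a = normalize_patterns(ref, obj)
        b = normalize_patterns(ref, tampered)
        out_mask = ~mask
        assert np.allclose(a.intensity[:, out_mask], b.intensity[:, out_mask])

    def test_zero_intensity_rejected(self, coarse_grid):
        ref = random_pattern(3, coarse_grid)
        zero = DiffractionPattern(range(12),
                                  np.zeros((12, coarse_grid.R_values.size)),
                                  coarse_grid)
        with pytest.raises(ValueError, match="zero"):
            normalize_patterns(ref, zero)


class TestRDI:
    def test_zero_at_identity(self, coarse_grid):
        p = random_pattern(4, coarse_grid)
        assert rdi(p, p.copy()) < 1e-5

    @pytest.mark.parametrize("k", [0.3, 1.0, 7.5])
    def test_scale_absorbed(self, coarse_grid, k):
        p = random_pattern(5, coarse_grid)
        assert rdi(p, p.scaled(k)) < 1e-5

    def test_symmetric_under_common_rescaling(self, coarse_grid):
        a = random_pattern(6, coarse_grid)
        b = random_pattern(7, coarse_grid)
        assert rdi(a, b) == pytest.approx(rdi(a.scaled(2.0), b.scaled(2.0)),
                                          rel=1e-6)

    def test_linear_in_small_perturbations(self, coarse_grid):
        p = random_pattern(8, coarse_grid)
        rng = np.random.default_rng(9)
        delta = rng.uniform(0, 1, p.intensity.shape)
        vals = []
        for eps in (1e-3, 2e-3, 4e-3):
            q = DiffractionPattern(p.layers, p.intensity + eps * delta,
                                   p.grid)
            vals.append(rdi(p, q))
        # halving the perturbation halves the RDI (within s_c slack)
        assert vals[1] == pytest.approx(2 * vals[0], rel=0.05)
        assert vals[2] == pytest.approx(2 * vals[1], rel=0.05)

    def test_zero_layer_line_dropped_with_warning(self, coarse_grid):
        ref = random_pattern(10, coarse_grid)
        ref.intensity[4] = 0.0
        obj = ref.scaled(2.0)
        with pytest.warns(UserWarning, match="dropped"):
            assert rdi(ref, obj) < 1e-5

    def test_mismatched_grids_rejected(self, coarse_grid):
        other = RadialGrid(np.linspace(0.0, 0.25, 31))
        with pytest.raises(ValueError, match="grid"):
            rdi(random_pattern(11, coarse_grid), random_pattern(11, other))


class TestPhiConstraint:
    def test_unequal_narrow_triplet_rejected(self):
        assert not phi_triplet_allowed(0.0, 50.0, 110.0)

    def test_equal_pair_allowed(self):
        assert phi_triplet_allowed(10.0, 10.0, 40.0)

    def test_wide_span_allowed(self):
        assert phi_triplet_allowed(3.0, 50.0, 123.0)


class TestOrientationSearch:
    def test_recovers_generating_parameters(self, search_setup):
        truth, builder, observed = search_setup
        cfg = FitConfig(grids={"phi1": [0, 3, 6], "phi2": [44, 50, 56],
                               "phi3": [117, 123, 129],
                               "r_h": [12.3, 12.7, 13.1]})
        res = OrientationSearch(observed, builder, cfg).fit()
        assert res.params == truth
        assert res.rdi < 1e-5
        assert res.s_c == pytest.approx(1.0, abs=1e-4)

    def test_deterministic_repeat(self, search_setup):
        truth, builder, observed = search_setup
        cfg = FitConfig(grids={"phi1": [0, 3], "phi2": [50],
                               "phi3": [123], "r_h": [12.5, 12.7]})
        r1 = OrientationSearch(observed, builder, cfg).fit()
        r2 = OrientationSearch(observed, builder, cfg).fit()
        assert r1.params == r2.params
        assert r1.rdi == r2.rdi
        assert r1.table.equals(r2.table)

    def test_sensitivity_rises_off_optimum(self, search_setup):
        truth, builder, observed = search_setup
        cfg = FitConfig(grids={"phi1": [3], "phi2": [40, 45, 50, 55, 60],
                               "phi3": [123], "r_h": [12.7]})
        res = OrientationSearch(observed, builder, cfg).fit()
        tr = res.sensitivity("phi2").sort_values("phi2")
        r = tr["rdi"].to_numpy()
        k = int(np.argmin(r))
        assert tr["phi2"].iloc[k] == truth["phi2"]
        assert np.all(np.diff(r[: k + 1]) < 0)  # falls toward the optimum
        assert np.all(np.diff(r[k:]) > 0)       # rises past it

    def test_infeasible_grid_raises_with_reason(self, search_setup):
        _, builder, observed = search_setup
        cfg = FitConfig(grids={"phi1": [0], "phi2": [50], "phi3": [110],
                               "r_h": [12.7]})
        with pytest.raises(ValueError, match="constraint"):
            OrientationSearch(observed, builder, cfg).fit()

    def test_backbone_penetration_rejected(self, search_setup):
        _, builder, observed = search_setup
        # r_h small enough that head beads dip under the backbone radius
        cfg = FitConfig(grids={"phi1": [3], "phi2": [50], "phi3": [123],
                               "r_h": [5.0]}, backbone_radius=7.0)
        with pytest.raises(ValueError, match="backbone"):
            OrientationSearch(observed, builder, cfg).fit()

    def test_coarse_to_fine_refinement(self, search_setup):
        truth, builder, observed = search_setup
        cfg = FitConfig(grids={"phi1": [3], "phi2": [45, 51, 57],
                               "phi3": [123], "r_h": [12.7]},
                        refine_steps=1, refine_factor=1.0 / 6.0)
        res = OrientationSearch(observed, builder, cfg).fit()
        assert res.params["phi2"] == pytest.approx(50.0, abs=1.0)


class TestNoisyRecovery:
    def test_phis_within_one_grid_step_at_two_percent_noise(self,
                                                            search_setup):
        """With 2% multiplicative noise the crown azimuths are recovered
        within one grid step (gauge-invariant differences) in at least
        90% of runs."""
        truth, builder, clean = search_setup
        cfg = FitConfig(grids={"phi1": [0, 3, 6], "phi2": [44, 50, 56],
                               "phi3": [117, 123, 129],
                               "r_h": [12.3, 12.7, 13.1]})
        step = 6.0
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            noisy = DiffractionPattern(
                clean.layers,
                np.clip(clean.intensity *
                        (1 + 0.02 * rng.standard_normal(clean.intensity.shape)),
                        0, None),
                clean.grid)
            res = OrientationSearch(noisy, builder, cfg).fit()
            d_true = (truth["phi2"] - truth["phi1"],
                      truth["phi3"] - truth["phi1"])
            d_fit = (res.params["phi2"] - res.params["phi1"],
                     res.params["phi3"] - res.params["phi1"])
            if all(abs(a - b) <= step for a, b in zip(d_true, d_fit)):
                hits += 1
        assert hits >= 0.9 * n_runs


class TestAxialTilt:
    @staticmethod
    def _profile_fn(head):
        # meridional intensity of one crossbridge at R = 0: only the axial
        # phase and the form factor survive
        Z = np.arange(1, 12) / 42.9
        z = head.xyz[:, 2]
        f = sphere_form_factor(Z[:, None], head.radius)
        F = (head.weights[None, :] * f *
             np.exp(2j * np.pi * Z[:, None] * z[None, :])).sum(axis=1)
        return np.abs(F) ** 2

    def test_untilted_reference_recovers_zero(self, small_head):
        ref = self._profile_fn(small_head)
        _, tilt = optimize_axial_tilt(small_head, ref, self._profile_fn)
        assert tilt == 0.0

    def test_known_tilt_recovered(self):
        head = synth_head(3)
        import math
        t = math.radians(6.0)
        Ry = np.array([[math.cos(t), 0, math.sin(t)], [0, 1, 0],
                       [-math.sin(t), 0, math.cos(t)]])
        ref = self._profile_fn(head.transformed(Ry))
        _, tilt = optimize_axial_tilt(head, ref, self._profile_fn, step=1.0)
        assert tilt == pytest.approx(6.0, abs=1.0)

    def test_result_bounded(self):
        head = synth_head(4)
        rng = np.random.default_rng(0)
        ref = rng.uniform(0.1, 1.0, 11)
        _, tilt = optimize_axial_tilt(head, ref, self._profile_fn,
                                      bounds=(-15.0, 15.0))
        assert -15.0 <= tilt <= 15.0
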