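import numpy as np
import pytest

from thickfil.geometry import CrossbridgeParams, HeadModel, PerturbationProfile
from thickfil.transform import RadialGrid


@pytest.fixture(scope="session")
def small_head() -> HeadModel:
    """A cheap 8-bead head for builder/search tests (geometry only cares
    that the cloud is rigid and asymmetric)."""
    xyz = np.column_stack([
        np.linspace(0.0, 9.0, 8),
        0.3 * np.sin(np.linspace(0, 3, 8)),
        np.linspace(0.0, 3.0, 8) ** 1.2,
    ])
    w = np.array([1.0, 1.0, 1.0, 1.5, 2.0, 2.5, 2.5, 2.0])
    return HeadModel(xyz, w)


@pytest.fixture(scope="session")
def coarse_grid() -> RadialGrid:
    return RadialGrid(np.linspace(0.0, 0.25, 41))


@pytest.fixture(scope="session")
def default_grid() -> RadialGrid:
    return RadialGrid()


@pytest.fixture(scope="session")
def regular_params() -> CrossbridgeParams:
    return CrossbridgeParams(eps_head1=2.0, eps_head2=26.0, r_h=9.8)


@pytest.fixture(scope="session")
def perturbed_params() -> CrossbridgeParams:
    return CrossbridgeParams(eps_head1=-13.0, eps_head2=15.0, r_h=12.7)


@pytest.fixture(scope="session")
def perturbation() -> PerturbationProfile:
    return PerturbationProfile()


def azimuthal_average_intensity(spheres, l, grid, c=42.9, n_psi=512):
    """Independent oracle: numeric azimuthal average of the squared
    structure factor, no Bessel functions involved."""
    from thickfil.transform import sphere_form_factor

    Z = l / c
    R = grid.R_values
    psi = 2.0 * np.pi * np.arange(n_psi) / n_psi
    s = np.sqrt(R ** 2 + Z ** 2)
    F = np.zeros((n_psi, R.size), complex)
    for j in range(len(spheres)):
        f = sphere_form_factor(s, spheres.a[j]) * np.exp(
            -4.0 * np.pi ** 2 * spheres.sigma[j] ** 2 * Z ** 2)
        phase = np.exp(2j * np.pi * (
            np.outer(np.cos(psi - np.radians(spheres.phi[j])), R) * spheres.r[j]
            + Z * spheres.z[j]))
        F += spheres.w[j] * f * phase
    return (np.abs(F) ** 2).mean(axis=0)
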