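"""Synthetic diffraction data with known ground truth.

No experimental intensities are distributed with this package, so every
pipeline input can be generated here with its generating parameters recorded
alongside:

* :func:`synth_head` — a deterministic 68-sphere stand-in for the
  coarse-grained myosin subfragment-1 (elongated, kinked pear: a globular
  motor lobe plus a slimmer lever arm, ~16 nm long, radius of gyration
  ~4.4 nm);
* :func:`synth_layer_lines` — layer-line patterns of a filament model,
  optionally sampled by a superlattice unit cell, with multiplicative
  Gaussian noise;
* :func:`synth_meridional` — meridional profiles with clusters at the
  orders of the C-protein (45.33 nm) and myosin (42.96 nm) repeats, each
  cluster split into interference fringes by the two mirrored zones of the
  A-band.

The meridional model: a zone of N unit repeats of period p has the grating
intensity [sin(N pi p Z) / (N sin(pi p Z))]^2 peaking at every order k/p;
two mirrored zones a distance D apart multiply the amplitude by
2 cos(pi D Z), i.e. the intensity by cos^2(pi D Z), which splits each
reflection into fringes spaced 1/D.  An overall Gaussian axial-disorder
factor damps higher orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (CProteinParams, CrossbridgeParams, FilamentModel,
                       HeadModel, PerturbationProfile, assemble_filament,
                       build_cprotein_array, build_perturbed_region,
                       build_regular_region)
from .meridional import MeridionalProfile
from .transform import (DiffractionPattern, LatticeSpec, RadialGrid,
                        cylindrical_intensity, lattice_sampled_pattern)

__all__ = [
    "SynthConfig",
    "synth_head",
    "default_filament",
    "synth_layer_lines",
    "synth_meridional",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    noise : multiplicative Gaussian noise fraction on intensities (0.01
        emulates well-exposed imaging-plate data).
    lattice : optional :class:`LatticeSpec`; None means a single filament.
    c_period / m_period : C-protein and myosin meridional repeats (nm).
    c_zone_repeats : repeats per C-zone (seven C-protein stripes).
    m_zone_repeats : repeats in one half crossbridge array (~16 x 42.96 nm
        ~ 690 nm, the crossbridge-bearing half-filament length).
    D_c : center-to-center distance of the two mirrored C-zones (nm).
    D_m : ditto for the two half crossbridge arrays.
    sigma_axial : Gaussian axial disorder damping the meridional orders (nm).
    """

    seed: int = 0
    noise: float = 0.01
    lattice: LatticeSpec | None = None
    c_period: float = 45.33
    m_period: float = 42.96
    c_zone_repeats: int = 7
    m_zone_repeats: int = 16
    D_c: float = 660.0
    D_m: float = 890.0
    c_amplitude: float = 1.0
    m_amplitude: float = 3.0
    two_zones: bool = True      # False: one zone per species, no fringes
    fringe_sd: float = 2.5e-4   # nm^-1; instrumental width of one fringe
    sigma_axial: float = 1.5
    Z_range: tuple = (0.035, 0.150)
    Z_step: float = 4e-5
    replicates: int = 1


# ----------------------------------------------------------------------
def synth_head(seed: int = 0, n_spheres: int = 68,
               radius: float = 0.72) -> HeadModel:
    """Deterministic bead model of one myosin head.

    The head-head junction sits at the local origin; the lever arm runs
    along +x with a slight kink, ending in a globular motor lobe, for an
    overall length of ~16 nm.  A small seeded jitter individualises bead
    positions without changing the gross shape.
    """
    rng = np.random.default_rng(seed)
    n_arm = max(4, int(round(n_spheres * 24 / 68)))
    n_motor = n_spheres - n_arm

    # lever arm: kinked polyline from the junction toward the motor lobe,
    # rising axially so that the paired heads of one crossbridge (mirrored
    # through the junction) end up staggered by ~8 nm along the filament
    t = np.linspace(0.0, 1.0, n_arm)
    kink = 0.55
    x = t * 8.4
    z = np.where(t < kink, t * 1.6, kink * 1.6 + (t - kink) * 3.4)
    arm = np.column_stack([x, np.zeros(n_arm), z])
    arm[:, 1] += 0.35 * np.sin(3.0 * np.pi * t)   # mild writhe

    # motor lobe: deterministic spherical-spiral fill of an ellipsoid
    k = np.arange(n_motor)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    cz = 1.0 - 2.0 * (k + 0.5) / n_motor
    rad = np.sqrt(1.0 - cz ** 2) * (k / max(n_motor - 1, 1)) ** 0.33
    th = golden * k
    sphere = np.column_stack([rad * np.cos(th), rad * np.sin(th),
                              cz * (k / max(n_motor - 1, 1)) ** 0.33])
    semi = np.array([3.2, 2.4, 2.2])
    center = arm[-1] + np.array([2.8, 0.4, 1.6])
    motor = sphere * semi + center

    xyz = np.vstack([arm, motor])
    xyz += rng.normal(scale=0.08, size=xyz.shape)   # seeded individuality
    return HeadModel(xyz, np.ones(n_spheres), radius, provenance="synthetic")


def default_filament(head: HeadModel | None = None,
                     regular_length: float = 215.0,
                     perturbed_length: float = 516.0,
                     with_cprotein: bool = True,
                     sigma_proj: float = 1.0,
                     seed: int = 0) -> FilamentModel:
    """The default half-filament model at the published parameter set.

    Regular region: eps = (2, 26) deg, r_h = 9.8 nm; perturbed region:
    eps = (-13, 15) deg, r_h = 12.7 nm, crown azimuths (3, 50, 123) deg and
    axial separations (10.84, 14.94, 17.24) nm; C-protein levels every
    45.33 nm over the perturbed region.
    """
    if head is None:
        head = synth_head(seed)
    reg = build_regular_region(
        head, CrossbridgeParams(eps_head1=2.0, eps_head2=26.0, r_h=9.8),
        length=regular_length)
    per = build_perturbed_region(
        head, CrossbridgeParams(eps_head1=-13.0, eps_head2=15.0, r_h=12.7),
        PerturbationProfile(), length=perturbed_length)
    if with_cprotein:
        cparams = CProteinParams(sigma_proj=sigma_proj)
        n_levels = max(1, int(perturbed_length / cparams.repeat))
        cp = build_cprotein_array(cparams, n_levels=n_levels)
    else:
        from .geometry import SphereSet
        cp = SphereSet.empty()
    return assemble_filament(reg, per, cp, perturbed_length=perturbed_length,
                             regular_length=regular_length)


# ----------------------------------------------------------------------
def synth_layer_lines(model: FilamentModel, cfg: SynthConfig,
                      grid: RadialGrid | None = None,
                      layers=range(0, 12)) -> tuple[DiffractionPattern, dict]:
    """Forward-computed layer lines with multiplicative noise.

    Returns (pattern, truth record).  With cfg.lattice set, the pattern is
    the coherently sampled superlattice cell; noise fraction 0 returns the
    exact forward transform.
    """
    if grid is None:
        grid = RadialGrid()
    if cfg.lattice is not None:
        clean = lattice_sampled_pattern(model, cfg.lattice, grid, layers)
    else:
        clean = cylindrical_intensity(model, grid, layers)
    rng = np.random.default_rng(cfg.seed)
    noisy = clean.intensity.copy()
    if cfg.noise > 0:
        noisy = np.clip(
            noisy * (1.0 + cfg.noise * rng.standard_normal(noisy.shape)),
            0.0, None)
    truth = {
        "seed": cfg.seed,
        "noise": cfg.noise,
        "lattice_spacing": None if cfg.lattice is None else cfg.lattice.spacing,
    }
    pat = DiffractionPattern(clean.layers, noisy, grid, clean.c,
                             meta={**clean.meta, "synthetic": True,
                                   "noise": cfg.noise, "seed": cfg.seed})
    return pat, truth


def _sinc2(x) -> np.ndarray:
    """sinc^2 with sinc(x) = sin(pi x)/(pi x)."""
    return np.sinc(np.asarray(x, float)) ** 2


def _species_envelope(Z, period, n_repeats, amplitude):
    """Single-zone limit: smooth |sinc|^2 envelopes at every order, no
    interference fringes."""
    L = n_repeats * period
    I = np.zeros_like(Z)
    k_lo = max(1, int(np.floor(Z[0] * period)))
    k_hi = int(np.ceil(Z[-1] * period))
    for k in range(k_lo, k_hi + 1):
        I += amplitude * _sinc2((Z - k / period) * L)
    return I


def _species_clusters(Z, period, n_repeats, D, amplitude, fringe_sd):
    """Fringe-comb clusters of one zone species.

    The two mirrored zones split every reflection order k/period into
    interference fringes at the maxima of cos^2(pi D Z), i.e. at Z = m/D
    exactly.  Each fringe is rendered as a Gaussian line of width
    ``fringe_sd`` (instrumental resolution) whose weight samples the
    |sinc|^2 envelope of the finite zone (length n_repeats * period)
    centred on the parent order.  Adjacent intra-cluster peaks are
    therefore spaced exactly 1/D by construction.
    """
    L = n_repeats * period
    I = np.zeros_like(Z)
    k_lo = max(1, int(np.floor(Z[0] * period)))
    k_hi = int(np.ceil(Z[-1] * period))
    for k in range(k_lo, k_hi + 1):
        z0 = k / period
        # fringes within the first two envelope nulls of this order
        m_lo = int(np.floor((z0 - 2.0 / L) * D))
        m_hi = int(np.ceil((z0 + 2.0 / L) * D))
        for m in range(m_lo, m_hi + 1):
            zf = m / D
            w = _sinc2((zf - z0) * L)
            if w < 1e-6:
                continue
            I += amplitude * w * np.exp(-0.5 * ((Z - zf) / fringe_sd) ** 2)
    return I


def synth_meridional(cfg: SynthConfig) -> tuple[MeridionalProfile, dict]:
    """Meridional profile with C-protein and myosin reflection clusters.

    Each species contributes clusters of interference fringes at the orders
    of its repeat (see :func:`_species_clusters`), damped by a Gaussian
    axial-disorder envelope; multiplicative noise is applied on top.  The
    truth record stores both periods and both interference distances.
    """
    if cfg.c_period <= 0 or cfg.m_period <= 0 or cfg.D_c <= 0 or cfg.D_m <= 0:
        raise ValueError("periods and interference distances must be positive")
    Z = np.arange(cfg.Z_range[0], cfg.Z_range[1] + cfg.Z_step / 2,
                  cfg.Z_step)
    env = np.exp(-4.0 * np.pi ** 2 * cfg.sigma_axial ** 2 * Z ** 2)
    if cfg.two_zones:
        I_c = _species_clusters(Z, cfg.c_period, cfg.c_zone_repeats, cfg.D_c,
                                cfg.c_amplitude, cfg.fringe_sd)
        I_m = _species_clusters(Z, cfg.m_period, cfg.m_zone_repeats, cfg.D_m,
                                cfg.m_amplitude, cfg.fringe_sd)
    else:
        I_c = _species_envelope(Z, cfg.c_period, cfg.c_zone_repeats,
                                cfg.c_amplitude)
        I_m = _species_envelope(Z, cfg.m_period, cfg.m_zone_repeats,
                                cfg.m_amplitude)
    I = (I_c + I_m) * env
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise > 0:
        I = np.clip(I * (1.0 + cfg.noise * rng.standard_normal(I.shape)),
                    0.0, None)
    truth = {
        "seed": cfg.seed,
        "noise": cfg.noise,
        "c_period": cfg.c_period,
        "m_period": cfg.m_period,
        "D_c": cfg.D_c,
        "D_m": cfg.D_m,
        "c_zone_repeats": cfg.c_zone_repeats,
        "m_zone_repeats": cfg.m_zone_repeats,
    }
    prof = MeridionalProfile(Z, I, calibrated=True,
                             meta={"synthetic": True, **truth})
    return prof, truth
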