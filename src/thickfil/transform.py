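"""Cylindrically averaged layer-line intensities by Fourier-Bessel transform.

An axially periodic filament (repeat ``c``) diffracts onto layer lines at
Z_l = l/c.  For a bead model the cylindrically averaged intensity on layer
line l is

    I_l(R) = sum_n |G_n(R)|^2,
    G_n(R) = sum_j w_j f_j(s) exp(-4 pi^2 sigma_j^2 Z_l^2)
             J_n(2 pi R r_j) exp(i(-n phi_j + 2 pi Z_l z_j)),

with f_j the uniform-sphere form factor evaluated at the full reciprocal
magnitude s = sqrt(R^2 + Z_l^2) and the Gaussian term an isotropic
temperature factor for axially disordered beads.  The phase convention is
such that the in-plane amplitude at azimuth psi is
F(R, psi) = sum_n G_n(R) i^n exp(i n psi); intensities are invariant to this
choice.

The same machinery supplies the myosin/C-protein component decomposition
(I = I_M + I_C + I_cross) and the hexagonal-superlattice sampled pattern in
which several filaments interfere coherently within one ~100-nm unit cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

from .geometry import MYOSIN_REPEAT, FilamentModel, SphereSet

__all__ = [
    "RadialGrid",
    "DiffractionPattern",
    "BesselAmplitudes",
    "ComponentIntensities",
    "LatticeSpec",
    "sphere_form_factor",
    "bessel_order_cutoff",
    "layer_line_amplitudes",
    "cylindrical_intensity",
    "decompose_components",
    "lattice_sampled_pattern",
]

R_MIN_FIT_DEFAULT = 0.0254  # nm^-1; meridional exclusion bound for fitting


@dataclass(frozen=True)
class RadialGrid:
    """Uniform grid of reciprocal radii R (nm^-1)."""

    R_values: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.25, 101))
    R_min_fit: float = R_MIN_FIT_DEFAULT

    def __post_init__(self):
        R = np.asarray(self.R_values, dtype=float)
        object.__setattr__(self, "R_values", R)
        if R.ndim != 1 or R.size < 2 or np.any(np.diff(R) <= 0):
            raise ValueError("R_values must be strictly increasing 1-D")
        if not (R[0] <= self.R_min_fit <= R[-1]):
            raise ValueError("R_min_fit must lie within the grid range")

    @property
    def R_max(self) -> float:
        return float(self.R_values[-1])

    def fit_mask(self) -> np.ndarray:
        """Boolean mask of the off-meridional region used for fitting."""
        return self.R_values >= self.R_min_fit


class DiffractionPattern:
    """Layer-line intensity set {l, Z_l = l/c, I_l(R)}.

    ``intensity`` is an (n_layers, n_R) array over ``layers`` (ascending
    integer indices) on ``grid``; ``c`` is the axial repeat (nm).
    """

    def __init__(self, layers, intensity, grid: RadialGrid,
                 c: float = MYOSIN_REPEAT, meta: dict | None = None):
        self.layers = np.asarray(layers, dtype=int)
        self.intensity = np.asarray(intensity, dtype=float)
        self.grid = grid
        self.c = float(c)
        self.meta = dict(meta or {})
        if self.intensity.shape != (self.layers.size, grid.R_values.size):
            raise ValueError("intensity must be (n_layers, n_R)")
        if np.any(self.intensity < 0):
            raise ValueError("layer-line intensities must be non-negative")

    def Z(self, l: int) -> float:
        return l / self.c

    @property
    def Z_values(self) -> np.ndarray:
        return self.layers / self.c

    def layer(self, l: int) -> np.ndarray:
        idx = np.nonzero(self.layers == l)[0]
        if idx.size == 0:
            raise KeyError(f"layer line {l} not present")
        return self.intensity[idx[0]]

    def copy(self) -> "DiffractionPattern":
        return DiffractionPattern(self.layers.copy(), self.intensity.copy(),
                                  self.grid, self.c, dict(self.meta))

    def scaled(self, factor: float) -> "DiffractionPattern":
        return DiffractionPattern(self.layers, factor * self.intensity,
                                  self.grid, self.c, dict(self.meta))

    def total(self, R_min: float | None = None,
              exclude_equator: bool = False) -> float:
        """Summed intensity over the grid, optionally off-meridian only."""
        mask = (self.grid.R_values >= R_min) if R_min is not None else \
            np.ones_like(self.grid.R_values, dtype=bool)
        rows = self.layers != 0 if exclude_equator else slice(None)
        return float(self.intensity[rows][:, mask].sum())


@dataclass
class BesselAmplitudes:
    """Complex Bessel-order amplitudes G_n(R) for one layer line."""

    layer: int
    orders: np.ndarray          # n values, shape (n_orders,)
    G: np.ndarray               # complex, (n_orders, n_R)
    grid: RadialGrid
    c: float = MYOSIN_REPEAT

    def intensity(self) -> np.ndarray:
        return (np.abs(self.G) ** 2).sum(axis=0)


@dataclass
class ComponentIntensities:
    """Myosin / C-protein / cross-term intensity decomposition."""

    layers: np.ndarray
    I_M: np.ndarray
    I_C: np.ndarray
    I_cross: np.ndarray
    grid: RadialGrid
    c: float = MYOSIN_REPEAT

    def total(self) -> np.ndarray:
        return self.I_M + self.I_C + self.I_cross


@dataclass
class LatticeSpec:
    """A coherent unit cell of filaments in the hexagonal superlattice.

    Default realisation of the "no three-alike" packing rule: three
    filaments per cell at hexagonal sites, two at azimuthal setting 0 and
    one rotated by 60 degrees.  ``spacing`` is the nearest-neighbour
    filament distance d (nm); the cell side is sqrt(3) d.  ``domain`` is the
    coherent domain size (nm), one superlattice cell by default (~100 nm).
    """

    spacing: float = 43.2
    positions: np.ndarray | None = None   # (n_filaments, 2) nm
    rotations: np.ndarray | None = None   # deg per filament
    domain: float = 100.0
    n_psi: int = 720

    def __post_init__(self):
        d = self.spacing
        if d <= 0:
            raise ValueError("filament spacing must be positive")
        if self.positions is None:
            self.positions = np.array([
                [0.0, 0.0],
                [d, 0.0],
                [d / 2.0, d * np.sqrt(3.0) / 2.0],
            ])
        else:
            self.positions = np.asarray(self.positions, dtype=float)
        if self.rotations is None:
            self.rotations = np.array([0.0, 0.0, 60.0])[: len(self.positions)]
            if len(self.rotations) < len(self.positions):
                extra = len(self.positions) - len(self.rotations)
                self.rotations = np.concatenate(
                    [self.rotations, np.zeros(extra)])
        else:
            self.rotations = np.asarray(self.rotations, dtype=float)
        if len(self.rotations) != len(self.positions):
            raise ValueError("one rotation per filament position required")


# ----------------------------------------------------------------------
def sphere_form_factor(s, a: float):
    """Normalised transform of a uniform sphere of radius ``a``.

    f(s) = 3 [sin x - x cos x] / x^3 with x = 2 pi s a; f(0) = 1.  The small-x
    limit is evaluated by its Taylor series to avoid cancellation.
    """
    if a <= 0:
        raise ValueError("sphere radius must be positive")
    x = 2.0 * np.pi * np.asarray(s, dtype=float) * a
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = 1.0 - xs ** 2 / 10.0 + xs ** 4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl ** 3
    return out if out.ndim else float(out)


def bessel_order_cutoff(R_max: float, r_max: float) -> int:
    """Truncation order: J_n(x) is negligible for n > x + margin."""
    return int(np.ceil(2.0 * np.pi * R_max * r_max)) + 12


def _grouped(spheres: SphereSet):
    """Group beads sharing (r, a, sigma) so Bessel tables are computed once
    per unique radial position."""
    key = np.round(np.column_stack([spheres.r, spheres.a, spheres.sigma]), 9)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    return uniq, inv


def _amplitudes_multi(spheres: SphereSet, layers, grid: RadialGrid,
                      n_max: int, c: float) -> np.ndarray:
    """G[layer, n, R] for all requested layer lines with one Bessel table.

    The table J_n(2 pi R r) does not depend on Z, so it is computed once per
    bead set and reused for every layer line.
    """
    R = grid.R_values
    layers = np.asarray(list(layers), int)
    n = np.arange(-n_max, n_max + 1)
    G = np.zeros((layers.size, n.size, R.size), dtype=complex)
    if len(spheres) == 0:
        return G

    uniq, inv = _grouped(spheres)
    r_u, a_u, sig_u = uniq[:, 0], uniq[:, 1], uniq[:, 2]
    x = 2.0 * np.pi * np.outer(r_u, R)          # (n_g, n_R)
    J = jv(n[:, None, None], x[None, :, :])     # (n_n, n_g, n_R)
    phi_rad = np.radians(spheres.phi)
    ph_n = np.exp(-1j * np.outer(n, phi_rad))   # (n_n, n_beads)

    for i, l in enumerate(layers):
        Z = l / c
        s = np.sqrt(R ** 2 + Z ** 2)
        fT = np.empty((len(uniq), R.size))
        for g in range(len(uniq)):
            fT[g] = sphere_form_factor(s, a_u[g]) * np.exp(
                -4.0 * np.pi ** 2 * sig_u[g] ** 2 * Z ** 2)
        phase_z = np.exp(2j * np.pi * Z * spheres.z) * spheres.w
        C = np.zeros((n.size, len(uniq)), dtype=complex)
        np.add.at(C.T, inv, (ph_n * phase_z[None, :]).T)
        G[i] = np.einsum("ng,ngr,gr->nr", C, J, fT)
    return G


def layer_line_amplitudes(spheres: SphereSet, l: int, grid: RadialGrid,
                          n_max: int | None = None,
                          c: float = MYOSIN_REPEAT,
                          check_truncation: bool = True) -> BesselAmplitudes:
    """Complex amplitudes G_n(R) of one layer line for a bead set."""
    orders_needed = bessel_order_cutoff(grid.R_max, spheres.max_radius())
    if n_max is None:
        n_max = orders_needed
    n = np.arange(-n_max, n_max + 1)
    G = _amplitudes_multi(spheres, [l], grid, n_max, c)[0]

    if check_truncation and n_max < orders_needed and len(spheres):
        # estimate discarded weight from the first few omitted orders
        wide = _amplitudes_multi(spheres, [l], grid, n_max + 4, c)[0]
        tot = (np.abs(wide) ** 2).sum()
        lost = tot - (np.abs(G) ** 2).sum()
        if tot > 0 and lost / tot > 1e-6:
            warnings.warn(
                f"Bessel truncation at |n|<={n_max} keeps only "
                f"{1 - lost / tot:.8f} of the layer-{l} intensity; "
                f"recommended n_max >= {orders_needed}", stacklevel=2)
    return BesselAmplitudes(l, n, G, grid, c)


def _region_sets(model) -> list[SphereSet]:
    if isinstance(model, FilamentModel):
        return [s for s in model.regions().values() if len(s)]
    return [model]


def cylindrical_intensity(model, grid: RadialGrid,
                          layers=range(0, 12),
                          c: float = MYOSIN_REPEAT,
                          n_max: int | None = None) -> DiffractionPattern:
    """Cylindrically averaged layer-line intensities of a model.

    For a :class:`FilamentModel` the amplitudes of its regions are summed
    coherently per Bessel order before squaring.
    """
    sets = _region_sets(model)
    if sum(len(s) for s in sets) == 0:
        layers = np.asarray(list(layers), int)
        return DiffractionPattern(
            layers, np.zeros((layers.size, grid.R_values.size)), grid, c)
    if n_max is None:
        r_max = max(s.max_radius() for s in sets)
        n_max = bessel_order_cutoff(grid.R_max, r_max)
    layers = list(layers)
    G = None
    for s in sets:
        Gs = _amplitudes_multi(s, layers, grid, n_max, c)
        G = Gs if G is None else G + Gs
    I = (np.abs(G) ** 2).sum(axis=1)
    return DiffractionPattern(np.asarray(layers, int), I, grid, c,
                              meta={"n_max": n_max})


def decompose_components(myosin: SphereSet, cprotein: SphereSet,
                         grid: RadialGrid, layers=range(0, 12),
                         c: float = MYOSIN_REPEAT,
                         n_max: int | None = None) -> ComponentIntensities:
    """Split the total intensity into myosin, C-protein and cross terms.

    I = sum_n |F_Mn + F_Cn|^2 = I_M + I_C + I_cross with
    I_cross = sum_n (F_Mn F_Cn* + F_Mn* F_Cn).  The identity
    I_M + I_C + I_cross == cylindrical_intensity(union) holds pointwise.
    """
    if n_max is None:
        r_max = max(myosin.max_radius(),
                    cprotein.max_radius() if len(cprotein) else 0.0)
        n_max = bessel_order_cutoff(grid.R_max, r_max)
    layers = list(layers)
    GM = _amplitudes_multi(myosin, layers, grid, n_max, c)
    GC = _amplitudes_multi(cprotein, layers, grid, n_max, c)
    I_M = (np.abs(GM) ** 2).sum(axis=1)
    I_C = (np.abs(GC) ** 2).sum(axis=1)
    I_x = 2.0 * (GM * GC.conj()).real.sum(axis=1)
    return ComponentIntensities(np.asarray(layers, int), I_M, I_C, I_x,
                                grid, c)


def lattice_sampled_pattern(model, lattice: LatticeSpec, grid: RadialGrid,
                            layers=range(0, 12), c: float = MYOSIN_REPEAT,
                            n_max: int | None = None) -> DiffractionPattern:
    """Layer-line pattern of one coherent superlattice unit cell.

    Per-filament transforms (identical filaments at positions x_k with
    azimuthal settings alpha_k) are summed coherently and the squared
    modulus is averaged numerically over the cell orientation psi:

        I(R, Z) = < | sum_k e^{2 pi i R x_k . u(psi)}
                      sum_n G_n(R) i^n e^{i n (psi - alpha_k)} |^2 >_psi

    With a single filament at the origin this reduces exactly to
    :func:`cylindrical_intensity`.
    """
    sets = _region_sets(model)
    if n_max is None:
        r_max = max(s.max_radius() for s in sets)
        n_max = bessel_order_cutoff(grid.R_max, r_max)
    layers = list(layers)
    R = grid.R_values
    psi = 2.0 * np.pi * np.arange(lattice.n_psi) / lattice.n_psi
    u = np.column_stack([np.cos(psi), np.sin(psi)])        # (n_psi, 2)
    proj = lattice.positions @ u.T                         # (n_k, n_psi)
    n = np.arange(-n_max, n_max + 1)
    i_pow = 1j ** np.mod(n, 4)
    E = np.exp(1j * np.outer(psi, n))                      # (n_psi, n_n)
    alpha = np.radians(lattice.rotations)

    Gall = None
    for s in sets:
        Gs = _amplitudes_multi(s, layers, grid, n_max, c)
        Gall = Gs if Gall is None else Gall + Gs
    I = np.zeros((len(layers), R.size))
    for i, l in enumerate(layers):
        Gi = i_pow[:, None] * Gall[i]                      # (n_n, n_R)
        total = np.zeros((lattice.n_psi, R.size), dtype=complex)
        for k in range(len(lattice.positions)):
            Ek = E * np.exp(-1j * np.outer(np.ones(lattice.n_psi),
                                           n * alpha[k]))
            Fk = Ek @ Gi                                   # (n_psi, n_R)
            phase = np.exp(2j * np.pi * np.outer(proj[k], R))
            total += phase * Fk
        I[i] = (np.abs(total) ** 2).mean(axis=0)
    return DiffractionPattern(np.asarray(layers, int), I, grid, c,
                              meta={"lattice_spacing": lattice.spacing,
                                    "n_max": n_max})
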