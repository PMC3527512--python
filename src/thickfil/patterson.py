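"""Difference-Patterson desampling of lattice-sampled layer lines.

The cylindrically averaged difference Patterson function

    dQ(r, z) = sum_{l>=1} 2 cos(2 pi Z_l z) H_l(r),
    H_l(r)   = integral I_l(R) J_0(2 pi R r) 2 pi R dR,

is the autocorrelation of the deviation from the axially averaged density.
The equator is always excluded: in muscle it is dominated by crystalline
inter-filament interference and carries no single-filament information.

Vectors between crossbridges of *different* filaments are at least one
nearest-neighbour spacing long (minus the filament's own radial extent), so
they populate the large-r part of the map.  Zeroing dQ outside a borderline
r_border(z) and transforming back (cosine projection in z per layer line,
then the self-inverse J_0 Hankel transform) yields desampled single-filament
layer-line intensities — the "cut-off correction".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0

from .geometry import MYOSIN_REPEAT
from .transform import DiffractionPattern, RadialGrid

__all__ = [
    "PattersonMap",
    "Borderline",
    "delta_q",
    "cutoff_correct",
    "estimate_crossbridge_radius",
]


@dataclass
class PattersonMap:
    """dQ values on a uniform (r, z) grid (nm)."""

    r: np.ndarray
    z: np.ndarray
    values: np.ndarray      # (n_z, n_r)
    c: float = MYOSIN_REPEAT
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        self.z = np.asarray(self.z, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.z.size, self.r.size):
            raise ValueError("values must be (n_z, n_r)")


@dataclass
class Borderline:
    """Piecewise-linear curve r_border(z) separating intra- from
    inter-filament vector regions.  Constant by default."""

    z_knots: np.ndarray
    r_knots: np.ndarray

    def __post_init__(self):
        self.z_knots = np.atleast_1d(np.asarray(self.z_knots, float))
        self.r_knots = np.atleast_1d(np.asarray(self.r_knots, float))
        if self.z_knots.shape != self.r_knots.shape:
            raise ValueError("z and r knots must have equal length")
        if np.any(self.r_knots <= 0):
            raise ValueError("borderline radius must be positive everywhere")

    @classmethod
    def constant(cls, r_border: float) -> "Borderline":
        return cls(np.array([0.0]), np.array([float(r_border)]))

    @classmethod
    def from_lattice(cls, d_nn: float, rho_max: float) -> "Borderline":
        """Default principled border: nearest-neighbour spacing minus the
        filament's maximal bead radius; every inter-filament vector is at
        least this long."""
        r = d_nn - rho_max
        if r <= 0:
            raise ValueError("filament radial extent exceeds the lattice "
                             "spacing; no separating border exists")
        return cls.constant(r)

    def __call__(self, z) -> np.ndarray:
        z = np.asarray(z, float)
        if self.z_knots.size == 1:
            return np.full(z.shape, self.r_knots[0])
        return np.interp(z, self.z_knots, self.r_knots)


def _hankel_forward(I_R: np.ndarray, R: np.ndarray, r: np.ndarray) -> np.ndarray:
    """H(r) = int I(R) J0(2 pi R r) 2 pi R dR by trapezoid on the R grid."""
    kernel = j0(2.0 * np.pi * np.outer(r, R)) * (2.0 * np.pi * R)[None, :]
    return np.trapezoid(kernel * I_R[None, :], R, axis=1)


def delta_q(pattern: DiffractionPattern,
            r_grid: np.ndarray | None = None,
            z_grid: np.ndarray | None = None) -> PattersonMap:
    """Cylindrically averaged difference Patterson map of a pattern.

    The equator (l = 0) is excluded always; a pattern containing only the
    equator raises.  Default grids: r in [0, 45] nm and z in [0, c/2] at
    0.25 nm steps.
    """
    keep = pattern.layers >= 1
    if not keep.any():
        raise ValueError("pattern must contain at least one non-equatorial "
                         "layer line (the equator is never used)")
    if r_grid is None:
        r_grid = np.arange(0.0, 45.0 + 1e-9, 0.25)
    if z_grid is None:
        z_grid = np.arange(0.0, pattern.c / 2.0 + 1e-9, 0.25)
    r_grid = np.asarray(r_grid, float)
    z_grid = np.asarray(z_grid, float)

    R = pattern.grid.R_values
    values = np.zeros((z_grid.size, r_grid.size))
    for l, I_R in zip(pattern.layers, pattern.intensity):
        if l < 1:
            continue
        H = _hankel_forward(I_R, R, r_grid)
        Z = l / pattern.c
        values += 2.0 * np.cos(2.0 * np.pi * Z * z_grid)[:, None] * H[None, :]
    return PattersonMap(r_grid, z_grid, values, pattern.c,
                        meta={"layers": pattern.layers[keep].tolist()})


def cutoff_correct(pmap: PattersonMap, border: Borderline,
                   pattern: DiffractionPattern) -> DiffractionPattern:
    """Back-transform a border-truncated dQ map to desampled layer lines.

    dQ is zeroed for r > r_border(z).  Per layer line l >= 1 the cosine
    projection over z in [0, c/2] recovers H_l(r) (the cos(2 pi l z / c) are
    orthogonal there), and the self-inverse J_0 Hankel transform returns the
    corrected I_l(R) on the grid of ``pattern``.  Negative outputs are
    clipped to zero; the clipped intensity fraction is recorded in the
    returned pattern's metadata.  The equator is passed through unchanged.

    The region R < R_min_fit remains contaminated by "face-to-face"
    inter-filament vectors that the cut-off cannot remove; it is flagged in
    the metadata, not corrected.
    """
    z, r = pmap.z, pmap.r
    if abs(z[-1] - pmap.c / 2.0) > z[1] - z[0]:
        warnings.warn("z grid does not span [0, c/2]; the cosine projection "
                      "is only approximately orthogonal", stacklevel=2)
    cut = pmap.values * (r[None, :] <= border(z)[:, None])

    R = pattern.grid.R_values
    out = np.array(pattern.intensity, float)
    clipped = 0.0
    total = 0.0
    for i, l in enumerate(pattern.layers):
        if l < 1:
            continue
        Z = l / pmap.c
        cosz = np.cos(2.0 * np.pi * Z * z)
        # dQ = sum_l 2 cos(2 pi Z_l z) H_l(r);  projection on [0, c/2]
        H = (2.0 / pmap.c) * np.trapezoid(cut * cosz[:, None], z, axis=0)
        kernel = j0(2.0 * np.pi * np.outer(R, r)) * (2.0 * np.pi * r)[None, :]
        I_corr = np.trapezoid(kernel * H[None, :], r, axis=1)
        total += np.abs(I_corr).sum()
        clipped += np.abs(I_corr[I_corr < 0]).sum()
        out[i] = np.clip(I_corr, 0.0, None)
    meta = dict(pattern.meta)
    meta.update({
        "cutoff_corrected": True,
        "clip_fraction": clipped / total if total > 0 else 0.0,
        "face_to_face_uncorrected_below_R": pattern.grid.R_min_fit,
    })
    return DiffractionPattern(pattern.layers, out, pattern.grid,
                              pattern.c, meta)


def estimate_crossbridge_radius(peak_r: float, peak_z: float,
                                C_pitch: float = 3.0 * MYOSIN_REPEAT) -> float:
    """Helical radius of the crossbridge centre of mass from a dQ peak.

    A peak at (r, z) in the map is the vector between crossbridge centres on
    one long-period strand of pitch C; its length obeys
    r = 2 r_h sin[pi (z/C + 1/3)], so r_h = r / (2 sin[pi (z/C + 1/3)]).
    """
    arg = np.pi * (peak_z / C_pitch + 1.0 / 3.0)
    s = np.sin(arg)
    if s <= 1e-9:
        raise ValueError(
            f"peak_z = {peak_z} makes sin(pi(z/C + 1/3)) non-positive; the "
            "relation does not apply")
    return float(peak_r / (2.0 * s))
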