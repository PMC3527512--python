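"""Sphere-bead models of the vertebrate skeletal thick filament.

The half thick filament is represented as a collection of spheres ("beads") in
cylindrical coordinates.  Three regions are built independently and summed in
reciprocal space:

* a *regular* region in which myosin crossbridges follow the exact
  three-stranded 9/1 helix (crown rise 14.3 nm, 40 deg twist per crown);
* a *perturbed* region in which the three crowns of each 42.9-nm repeat carry
  axial and azimuthal displacements from helical symmetry;
* a *C-protein* (MyBP-C) array of 11-domain bead chains bound at every third
  crown level with a repeat slightly longer than the myosin repeat.

Each myosin crossbridge is a pair of heads, each head a rigid cloud of equal
spheres (68 spheres of radius 0.72 nm by default, mimicking a subfragment-1
coarse-grained from C-alpha coordinates).  The filament backbone is treated as
a featureless cylinder: it is excluded from the diffraction calculation and
only constrains how close beads may approach the axis.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SphereSet",
    "HeadModel",
    "CrossbridgeParams",
    "PerturbationProfile",
    "CProteinParams",
    "FilamentModel",
    "coarse_grain_head",
    "read_calpha",
    "build_crossbridge",
    "build_regular_region",
    "build_perturbed_region",
    "build_cprotein_array",
    "assemble_filament",
]

# Canonical axial geometry of the vertebrate thick filament (nm).
MYOSIN_REPEAT = 42.9            # basic crystallographic repeat c
CROWN_RISE = MYOSIN_REPEAT / 3  # 14.3 nm between successive crowns
STRAND_PITCH = 3 * MYOSIN_REPEAT  # 129 nm: pitch of one 9/1 helical strand
N_STRANDS = 3
CROWN_TWIST = 360.0 / 9.0       # 40 deg between successive crowns (9/1 helix)


class SphereSet:
    """A set of spheres in cylindrical coordinates (r, phi, z).

    Stored columnar as float arrays: ``r`` (nm), ``phi`` (degrees), ``z``
    (nm), ``a`` sphere radius (nm), ``w`` scattering weight, ``sigma`` axial
    disorder (nm; 0 means rigid).
    """

    __slots__ = ("r", "phi", "z", "a", "w", "sigma")

    def __init__(self, r, phi, z, a, w, sigma=None):
        self.r = np.asarray(r, dtype=float)
        self.phi = np.asarray(phi, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.a = np.broadcast_to(np.asarray(a, dtype=float), self.r.shape).copy()
        self.w = np.broadcast_to(np.asarray(w, dtype=float), self.r.shape).copy()
        if sigma is None:
            sigma = 0.0
        self.sigma = np.broadcast_to(np.asarray(sigma, dtype=float), self.r.shape).copy()
        if np.any(self.r < 0):
            raise ValueError("sphere radial coordinates must be >= 0")
        if np.any(self.a <= 0) or np.any(self.w <= 0):
            raise ValueError("sphere radii and weights must be > 0")
        if np.any(self.sigma < 0):
            raise ValueError("axial disorder sigma must be >= 0")

    # ------------------------------------------------------------------
    @classmethod
    def empty(cls) -> "SphereSet":
        z = np.empty(0)
        s = cls.__new__(cls)
        s.r = z.copy(); s.phi = z.copy(); s.z = z.copy()
        s.a = z.copy(); s.w = z.copy(); s.sigma = z.copy()
        return s

    @classmethod
    def from_cartesian(cls, xyz, a, w, sigma=0.0) -> "SphereSet":
        xyz = np.asarray(xyz, dtype=float)
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        phi = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0]))
        return cls(r, phi, xyz[:, 2], a, w, sigma)

    def to_cartesian(self) -> np.ndarray:
        p = np.radians(self.phi)
        return np.column_stack([self.r * np.cos(p), self.r * np.sin(p), self.z])

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return self.r.size

    def total_weight(self) -> float:
        return float(self.w.sum())

    def center_of_mass(self) -> np.ndarray:
        """Weighted center of mass in Cartesian coordinates."""
        xyz = self.to_cartesian()
        return (self.w[:, None] * xyz).sum(axis=0) / self.w.sum()

    def min_radius(self) -> float:
        return float(self.r.min()) if len(self) else math.inf

    def max_radius(self) -> float:
        return float(self.r.max()) if len(self) else 0.0

    # ------------------------------------------------------------------
    def rotated(self, dphi: float) -> "SphereSet":
        """Rigid rotation about the filament axis by ``dphi`` degrees."""
        return SphereSet(self.r, self.phi + dphi, self.z, self.a, self.w, self.sigma)

    def translated(self, dz: float) -> "SphereSet":
        """Rigid axial translation by ``dz`` nm."""
        return SphereSet(self.r, self.phi, self.z + dz, self.a, self.w, self.sigma)

    def with_sigma(self, sigma: float) -> "SphereSet":
        return SphereSet(self.r, self.phi, self.z, self.a, self.w,
                         np.full(len(self), float(sigma)))

    @staticmethod
    def concatenate(sets: Iterable["SphereSet"]) -> "SphereSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return SphereSet.empty()
        return SphereSet(
            np.concatenate([s.r for s in sets]),
            np.concatenate([s.phi for s in sets]),
            np.concatenate([s.z for s in sets]),
            np.concatenate([s.a for s in sets]),
            np.concatenate([s.w for s in sets]),
            np.concatenate([s.sigma for s in sets]),
        )

    def __add__(self, other: "SphereSet") -> "SphereSet":
        return SphereSet.concatenate([self, other])


# ----------------------------------------------------------------------
@dataclass
class HeadModel:
    """Rigid bead model of one myosin head (S1) in a local frame.

    The local frame is anchored at the head-head junction (the point from
    which the two conjoined heads of a crossbridge diverge), which sits at the
    local origin.  The head's long axis runs along local +x with the motor
    domain at the far (distal) end; local +z maps onto the filament axis when
    the head is mounted.  Rotation conventions for the crossbridge parameters
    are defined relative to this frame.

    ``xyz`` is an (n, 3) array of bead centers (nm), ``weights`` the per-bead
    scattering weights, ``radius`` the common bead radius (0.72 nm default).
    """

    xyz: np.ndarray
    weights: np.ndarray
    radius: float = 0.72
    provenance: str = "synthetic"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("head bead coordinates must be (n, 3)")
        if self.weights.shape != (self.xyz.shape[0],):
            raise ValueError("one weight per bead required")
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")

    @property
    def n_spheres(self) -> int:
        return self.xyz.shape[0]

    def center_of_mass(self) -> np.ndarray:
        return (self.weights[:, None] * self.xyz).sum(axis=0) / self.weights.sum()

    def radius_of_gyration(self) -> float:
        com = self.center_of_mass()
        d2 = ((self.xyz - com) ** 2).sum(axis=1)
        return float(np.sqrt((self.weights * d2).sum() / self.weights.sum()))

    def transformed(self, matrix: np.ndarray, offset=(0.0, 0.0, 0.0)) -> "HeadModel":
        xyz = self.xyz @ np.asarray(matrix, dtype=float).T + np.asarray(offset, float)
        return HeadModel(xyz, self.weights.copy(), self.radius, self.provenance)


@dataclass
class CrossbridgeParams:
    """Orientation of a two-headed crossbridge on the filament surface.

    eps_head1/eps_head2 : rotation (deg) of each head about the axis parallel
        to the filament axis through the head-head junction.
    phi_cb : azimuth (deg) of the crossbridge center of mass about the
        filament axis (per-crown offsets are added on top in the perturbed
        region).
    r_h : helical radius (nm) of the crossbridge center of mass.
    """

    eps_head1: float = 0.0
    eps_head2: float = 0.0
    phi_cb: float = 90.0
    r_h: float = 9.8

    def __post_init__(self):
        self.eps_head1 %= 360.0
        self.eps_head2 %= 360.0
        if self.r_h <= 0:
            raise ValueError("helical radius r_h must be positive")


@dataclass
class PerturbationProfile:
    """Axial and azimuthal crown displacements inside one 42.9-nm repeat.

    ``axial_seps`` are the three crown-to-crown separations (crown1->2,
    2->3, 3->next repeat's crown 1); they must sum to the basic repeat.
    ``phis`` are the azimuths of crowns 1..3 (deg).
    """

    axial_seps: tuple = (10.84, 14.94, 17.24)
    phis: tuple = (3.0, 50.0, 123.0)

    def __post_init__(self):
        if len(self.axial_seps) != 3 or len(self.phis) != 3:
            raise ValueError("need exactly three crown separations and azimuths")
        total = float(sum(self.axial_seps))
        if abs(total - MYOSIN_REPEAT) > 0.2:
            raise ValueError(
                f"axial separations sum to {total:.2f} nm; must equal the "
                f"{MYOSIN_REPEAT} nm repeat within 0.2 nm")

    def crown_offsets(self) -> np.ndarray:
        """Axial offsets of crowns 1..3 from the repeat origin (nm)."""
        return np.array([0.0, self.axial_seps[0],
                         self.axial_seps[0] + self.axial_seps[1]])


@dataclass
class CProteinParams:
    """Bead-chain model of myosin-binding protein C (MyBP-C).

    One molecule is 11 globular domains of ~4 nm diameter strung at ~4 nm
    spacing; 3 C-terminal domains are anchored axially along the backbone and
    8 N-terminal domains project outward, bent near the middle of the
    projecting arm.  Molecules sit with three-fold rotational symmetry at
    every level, levels repeating at 45.33 nm (slightly longer than the
    myosin repeat).  The projecting arm carries axial disorder sigma_proj.
    """

    repeat: float = 45.33
    n_domains: int = 11
    bead_diameter: float = 4.0
    # one MyBP-C molecule has a molecular weight comparable to one myosin
    # head, so its 11 domains together carry the weight of a 68-bead head
    bead_weight: float = 68.0 / 11.0
    n_anchored: int = 3
    bend_after: int = 5        # projecting beads before the elbow; 5 puts the
                               # arm tip beyond the myosin crowns (r > 25 nm)
    bend_angle: float = 90.0   # deg, single elbow
    anchor_radius: float = 7.0
    sigma_proj: float = 1.0    # nm; 2*sigma = 2 nm default

    def __post_init__(self):
        if not (0 < self.n_anchored < self.n_domains):
            raise ValueError("need at least one anchored and one projecting bead")
        if self.repeat <= 0 or self.bead_diameter <= 0:
            raise ValueError("repeat and bead diameter must be positive")

    @property
    def n_projecting(self) -> int:
        return self.n_domains - self.n_anchored


@dataclass
class FilamentModel:
    """Half thick filament assembled from its three regions.

    The perturbed region (carrying C-protein) occupies the proximal part
    (bare-zone side, low z); the regular region sits distally.  Region
    transforms are computed independently and summed coherently, so the model
    only records the bead sets with their axial offsets already applied.
    """

    regular: SphereSet
    perturbed: SphereSet
    cprotein: SphereSet
    c: float = MYOSIN_REPEAT
    n_strands: int = N_STRANDS
    backbone_radius: float = 7.0
    regular_length: float = 215.0
    perturbed_length: float = 516.0

    @property
    def C_pitch(self) -> float:
        return 3.0 * self.c

    @property
    def crown_rise(self) -> float:
        return self.c / 3.0

    def regions(self) -> dict:
        return {"regular": self.regular, "perturbed": self.perturbed,
                "cprotein": self.cprotein}

    def all_spheres(self) -> SphereSet:
        return SphereSet.concatenate(
            [self.perturbed, self.regular, self.cprotein])

    def myosin_spheres(self) -> SphereSet:
        return SphereSet.concatenate([self.perturbed, self.regular])

    def perturbed_fraction(self) -> float:
        """Fraction of the crossbridge-bearing length that is perturbed."""
        return self.perturbed_length / (self.perturbed_length + self.regular_length)


# ----------------------------------------------------------------------
# head coarse-graining

def coarse_grain_head(calpha_points, n_spheres: int = 68, radius: float = 0.72,
                      seed: int = 0, n_iter: int = 60) -> HeadModel:
    """Coarse-grain a C-alpha point cloud to an ``n_spheres`` bead model.

    Plain Lloyd (k-means) iterations from a deterministic farthest-point
    initialisation partition the cloud into ``n_spheres`` clusters; each bead
    sits at a cluster centroid with weight proportional to its member count,
    so the bead-weighted center of mass reproduces the cloud's center of mass
    exactly.
    """
    pts = np.asarray(calpha_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("calpha_points must be an (n, 3) array")
    n = pts.shape[0]
    if n < n_spheres:
        raise ValueError(
            f"need at least {n_spheres} input points, got {n}")
    if n == n_spheres:
        return HeadModel(pts.copy(), np.ones(n), radius,
                         provenance="coarse-grained-from-atomic")

    rng = np.random.default_rng(seed)
    # farthest-point seeding, deterministic given seed
    centers = np.empty((n_spheres, 3))
    centers[0] = pts[int(rng.integers(n))]
    d2 = ((pts - centers[0]) ** 2).sum(axis=1)
    for k in range(1, n_spheres):
        centers[k] = pts[int(np.argmax(d2))]
        d2 = np.minimum(d2, ((pts - centers[k]) ** 2).sum(axis=1))

    for _ in range(n_iter):
        lab = np.argmin(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1)
        newc = centers.copy()
        for k in range(n_spheres):
            m = lab == k
            if m.any():
                newc[k] = pts[m].mean(axis=0)
        if np.allclose(newc, centers, atol=1e-10):
            centers = newc
            break
        centers = newc
    lab = np.argmin(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1)
    counts = np.bincount(lab, minlength=n_spheres).astype(float)
    # empty clusters keep their seeding position with zero count; drop them
    keep = counts > 0
    centers, counts = centers[keep], counts[keep]
    for k in range(len(centers)):
        centers[k] = pts[lab == np.nonzero(keep)[0][k]].mean(axis=0)
    return HeadModel(centers, counts, radius,
                     provenance="coarse-grained-from-atomic")


def read_calpha(pdb_path, chains: Sequence[str] | None = None) -> np.ndarray:
    """Extract C-alpha coordinates (nm) from a PDB file via Biopython.

    ``chains`` optionally restricts extraction to the given chain
    identifiers.  PDB files are in Angstrom; coordinates are returned in nm.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("head", str(pdb_path))
    coords = []
    for model in structure:
        for chain in model:
            if chains is not None and chain.id not in chains:
                continue
            for residue in chain:
                if "CA" in residue:
                    coords.append(residue["CA"].coord)
        break  # first model only
    if not coords:
        raise ValueError("no C-alpha atoms found for the requested chains")
    return np.asarray(coords, dtype=float) / 10.0  # A -> nm


# ----------------------------------------------------------------------
# crossbridge and region builders

def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def build_crossbridge(head: HeadModel, params: CrossbridgeParams,
                      z: float = 0.0, phi_extra: float = 0.0,
                      sigma: float = 0.0) -> SphereSet:
    """Place one two-headed crossbridge at axial level ``z``.

    The two heads share the head-head junction at the local origin.  In the
    mounted frame local +x is the azimuthal (helix-tangent) direction and
    local +z the filament axis; head 2 is the 180-degree rotation of head 1
    about the local x axis, so the untwisted pair is symmetric about the
    junction.  Each head is then rotated by its own epsilon about the local z
    axis through the junction.  Finally the pair is translated radially so
    that its center of mass sits at radius ``r_h`` and rotated to azimuth
    ``phi_cb + phi_extra``.
    """
    h1 = head.transformed(_rot_z(params.eps_head1))
    h2 = head.transformed(_rot_z(params.eps_head2) @ _rot_x(180.0))
    xyz = np.vstack([h1.xyz, h2.xyz])
    w = np.concatenate([h1.weights, h2.weights])
    com = (w[:, None] * xyz).sum(axis=0) / w.sum()
    # move the pair's center of mass onto the +y axis at radius r_h, keeping
    # its axial center at the crown level z
    xyz = xyz + np.array([-com[0], params.r_h - com[1], z - com[2]])
    phi_tot = params.phi_cb + phi_extra - 90.0  # +y axis is azimuth 90 deg
    s = SphereSet.from_cartesian(xyz, head.radius, w, sigma)
    return s.rotated(phi_tot)


def build_regular_region(head: HeadModel, params: CrossbridgeParams,
                         length: float = 215.0) -> SphereSet:
    """Crossbridges on the exact three-stranded 9/1 helix.

    Crowns every 14.3 nm, successive crowns twisted by 40 degrees, three
    strand copies at 120-degree intervals.  ``length`` is rounded down to a
    whole number of crown rises (at least one crown).
    """
    if length <= 0:
        raise ValueError("region length must be positive")
    n_crowns = max(1, int(length / CROWN_RISE))
    cb0 = build_crossbridge(head, params)
    parts = []
    for j in range(n_crowns):
        for strand in range(N_STRANDS):
            dphi = j * CROWN_TWIST + strand * 120.0
            parts.append(cb0.rotated(dphi).translated(j * CROWN_RISE))
    return SphereSet.concatenate(parts)


def build_perturbed_region(head: HeadModel, params: CrossbridgeParams,
                           pert: PerturbationProfile,
                           length: float = 516.0) -> SphereSet:
    """Crossbridges on the axially/azimuthally perturbed 42.9-nm lattice.

    Within each repeat the three crowns sit at the perturbation profile's
    axial offsets and azimuths phi1..phi3 (the crossbridge's own phi_cb is
    not applied here; the profile azimuths are absolute).  Successive repeats
    are stacked with a +120-degree twist so that each 9/1 strand remains
    continuous across repeats.
    """
    if length <= 0:
        raise ValueError("region length must be positive")
    n_repeats = max(1, int(length / MYOSIN_REPEAT))
    offsets = pert.crown_offsets()
    base = dataclasses.replace(params, phi_cb=0.0)
    cb0 = build_crossbridge(head, base)
    parts = []
    for rep in range(n_repeats):
        z0 = rep * MYOSIN_REPEAT
        twist = rep * 120.0
        for crown in range(3):
            for strand in range(N_STRANDS):
                dphi = pert.phis[crown] + strand * 120.0 + twist
                parts.append(cb0.rotated(dphi).translated(z0 + offsets[crown]))
    return SphereSet.concatenate(parts)


def build_cprotein_array(params: CProteinParams, n_levels: int = 11,
                         z0: float = 0.0) -> SphereSet:
    """C-protein molecules at ``n_levels`` axial levels.

    Per level, three molecules related by three-fold rotational symmetry.
    Each molecule: ``n_anchored`` beads run axially along the backbone
    surface at the anchor radius; the remaining beads project radially
    outward in the (r, z) plane of the molecule's azimuth, with one elbow of
    ``bend_angle`` degrees after ``bend_after`` projecting beads turning the
    arm axially.  Projecting beads carry the sigma_proj axial disorder.
    Levels are spaced by the C-protein repeat starting at ``z0`` (the crown-1
    level of the perturbed region).
    """
    if n_levels < 1:
        raise ValueError("need at least one C-protein level")
    p = params
    step = p.bead_diameter
    beads = []   # (x=r-direction handled later) local (radial, axial) layout
    sig = []
    # anchored beads: axial run on the backbone surface
    for i in range(p.n_anchored):
        beads.append((p.anchor_radius, -(p.n_anchored - 1 - i) * step))
        sig.append(0.0)
    # projecting arm: radially outward, elbow after bend_after beads
    r_cur, z_cur = p.anchor_radius, 0.0
    direction = np.array([1.0, 0.0])  # (radial, axial) unit
    elbow = _rot2(p.bend_angle)
    for i in range(p.n_projecting):
        r_cur += direction[0] * step
        z_cur += direction[1] * step
        beads.append((r_cur, z_cur))
        sig.append(p.sigma_proj)
        if i + 1 == p.bend_after:
            direction = elbow @ direction
    beads = np.asarray(beads)
    sig = np.asarray(sig)

    parts = []
    for level in range(n_levels):
        z_lev = z0 + level * p.repeat
        for k in range(3):
            parts.append(SphereSet(
                beads[:, 0], np.full(len(beads), k * 120.0),
                beads[:, 1] + z_lev, p.bead_diameter / 2.0, p.bead_weight,
                sig))
    return SphereSet.concatenate(parts)


def _rot2(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def assemble_filament(regular: SphereSet, perturbed: SphereSet,
                      cprotein: SphereSet,
                      perturbed_length: float = 516.0,
                      regular_length: float = 215.0,
                      backbone_radius: float = 7.0) -> FilamentModel:
    """Assemble the half filament: perturbed region proximal, regular distal.

    The perturbed (and overlaid C-protein) beads are kept at their built
    offsets starting at z = 0 (bare-zone end); the regular region is shifted
    distally to start where the perturbed region ends.  Overlapping region
    definitions (a regular bead landing below the perturbed span) raise.
    """
    if perturbed_length <= 0 or (regular_length < 0):
        raise ValueError("region lengths must be positive")
    reg = regular.translated(perturbed_length) if len(regular) else regular
    if len(reg) and len(perturbed):
        # crossbridge crowns must not interleave between the regions
        if reg.z.min() < perturbed.z.max() - CROWN_RISE / 2:
            raise ValueError("regular and perturbed regions overlap")
    return FilamentModel(reg, perturbed, cprotein,
                         backbone_radius=backbone_radius,
                         regular_length=regular_length,
                         perturbed_length=perturbed_length)
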