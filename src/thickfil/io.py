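"""Plain-text readers/writers and flat key-value model configuration.

All numeric tables are self-describing text: a ``#``-prefixed header records
the quantities needed to reinterpret the numbers (axial repeat, grid,
normalization state), and floats are written with ``repr`` precision so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .geometry import (CProteinParams, CrossbridgeParams, FilamentModel,
                       HeadModel, PerturbationProfile, SphereSet,
                       assemble_filament, build_cprotein_array,
                       build_perturbed_region, build_regular_region)
from .meridional import MeridionalProfile
from .patterson import Borderline, PattersonMap
from .transform import DiffractionPattern, RadialGrid

__all__ = [
    "write_pattern", "read_pattern",
    "write_patterson", "read_patterson",
    "write_borderline", "read_borderline",
    "write_profile", "read_profile",
    "write_keyvalue", "read_keyvalue",
    "default_config", "load_config", "model_from_config",
    "write_manifest",
]

_FMT = "%.17g"


# ----------------------------------------------------------------------
# diffraction patterns

def write_pattern(pattern: DiffractionPattern, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# thickfil layer-line intensities\n")
        fh.write(f"# c_nm = {pattern.c!r}\n")
        fh.write(f"# R_min_fit = {pattern.grid.R_min_fit!r}\n")
        fh.write(f"# n_R = {pattern.grid.R_values.size}\n")
        for key, val in sorted(pattern.meta.items()):
            fh.write(f"# meta {key} = {json.dumps(val)}\n")
        fh.write("# columns: l R I\n")
        for l, row in zip(pattern.layers, pattern.intensity):
            for R, I in zip(pattern.grid.R_values, row):
                fh.write(f"{l:d} {float(R)!r} {float(I)!r}\n")


def read_pattern(path) -> DiffractionPattern:
    path = Path(path)
    c = None
    R_min_fit = 0.0
    meta = {}
    rows = []
    for line in path.open():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("c_nm ="):
                c = float(body.split("=", 1)[1])
            elif body.startswith("R_min_fit ="):
                R_min_fit = float(body.split("=", 1)[1])
            elif body.startswith("meta "):
                key, val = body[5:].split("=", 1)
                meta[key.strip()] = json.loads(val.strip())
            continue
        l, R, I = line.split()
        rows.append((int(l), float(R), float(I)))
    if not rows or c is None:
        raise ValueError(f"{path} is not a layer-line intensity table")
    layers = sorted({r[0] for r in rows})
    R_values = np.array(sorted({r[1] for r in rows}))
    grid = RadialGrid(R_values, R_min_fit=R_min_fit)
    I = np.zeros((len(layers), R_values.size))
    l_index = {l: i for i, l in enumerate(layers)}
    R_index = {R: j for j, R in enumerate(R_values)}
    for l, R, v in rows:
        I[l_index[l], R_index[R]] = v
    return DiffractionPattern(layers, I, grid, c, meta)


# ----------------------------------------------------------------------
# Patterson maps and borderlines

def write_patterson(pmap: PattersonMap, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# thickfil difference Patterson map dQ(r, z)\n")
        fh.write(f"# c_nm = {pmap.c!r}\n")
        fh.write("# r_nm: " + " ".join(_FMT % v for v in pmap.r) + "\n")
        fh.write("# z_nm: " + " ".join(_FMT % v for v in pmap.z) + "\n")
        fh.write("# rows: one z level per line, values over r\n")
        for row in pmap.values:
            fh.write(" ".join(_FMT % v for v in row) + "\n")


def read_patterson(path) -> PattersonMap:
    path = Path(path)
    r = z = None
    c = 42.9
    vals = []
    for line in path.open():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("r_nm:"):
                r = np.array([float(v) for v in body[5:].split()])
            elif body.startswith("z_nm:"):
                z = np.array([float(v) for v in body[5:].split()])
            elif body.startswith("c_nm ="):
                c = float(body.split("=", 1)[1])
            continue
        vals.append([float(v) for v in line.split()])
    if r is None or z is None:
        raise ValueError(f"{path} is not a Patterson map table")
    return PattersonMap(r, z, np.asarray(vals), c)


def write_borderline(border: Borderline, path) -> None:
    np.savetxt(path, np.column_stack([border.z_knots, border.r_knots]),
               header="borderline polyline: z_nm r_nm", fmt=_FMT)


def read_borderline(path) -> Borderline:
    arr = np.atleast_2d(np.loadtxt(path))
    return Borderline(arr[:, 0], arr[:, 1])


# ----------------------------------------------------------------------
# meridional profiles

def write_profile(profile: MeridionalProfile, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# thickfil meridional intensity profile\n")
        fh.write(f"# calibrated = {profile.calibrated}\n")
        for key, val in sorted(profile.meta.items()):
            fh.write(f"# meta {key} = {json.dumps(val)}\n")
        fh.write("# columns: Z_invnm I\n")
        for Z, I in zip(profile.Z, profile.I):
            fh.write(f"{float(Z)!r} {float(I)!r}\n")


def read_profile(path) -> MeridionalProfile:
    path = Path(path)
    Z, I = [], []
    calibrated = False
    meta = {}
    for line in path.open():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("calibrated ="):
                calibrated = body.split("=", 1)[1].strip() == "True"
            elif body.startswith("meta "):
                key, val = body[5:].split("=", 1)
                meta[key.strip()] = json.loads(val.strip())
            continue
        z, i = line.split()
        Z.append(float(z))
        I.append(float(i))
    if not Z:
        raise ValueError(f"{path} contains no profile samples")
    return MeridionalProfile(np.array(Z), np.array(I), calibrated, meta)


# ----------------------------------------------------------------------
# flat key-value files (configs, truth records)

def write_keyvalue(mapping: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dict(mapping), fh, sort_keys=True,
                       default_flow_style=False)


def read_keyvalue(path) -> dict:
    with Path(path).open() as fh:
        out = yaml.safe_load(fh)
    return out or {}


def default_config() -> dict:
    """The packaged model description reproducing the published
    full-filament-overlap parameter set."""
    with resources.files("thickfil").joinpath("data/default_model.yaml") \
            .open() as fh:
        return yaml.safe_load(fh)


def load_config(path=None) -> dict:
    """Load a flat key-value model config, overlaying the defaults."""
    cfg = default_config()
    if path is not None:
        cfg.update(read_keyvalue(path))
    return cfg


def model_from_config(cfg: dict, head: HeadModel | None = None) -> FilamentModel:
    """Build the half-filament model a flat config describes."""
    if head is None:
        from .synthetic import synth_head
        head = synth_head(int(cfg.get("head_seed", 0)),
                          n_spheres=int(cfg.get("head_n_spheres", 68)),
                          radius=float(cfg.get("head_radius", 0.72)))
    reg = build_regular_region(
        head,
        CrossbridgeParams(eps_head1=float(cfg["regular_eps_head1"]),
                          eps_head2=float(cfg["regular_eps_head2"]),
                          r_h=float(cfg["regular_r_h"])),
        length=float(cfg["regular_length"]))
    pert = PerturbationProfile(
        axial_seps=(float(cfg["axial_sep1"]), float(cfg["axial_sep2"]),
                    float(cfg["axial_sep3"])),
        phis=(float(cfg["phi1"]), float(cfg["phi2"]), float(cfg["phi3"])))
    per = build_perturbed_region(
        head,
        CrossbridgeParams(eps_head1=float(cfg["perturbed_eps_head1"]),
                          eps_head2=float(cfg["perturbed_eps_head2"]),
                          r_h=float(cfg["perturbed_r_h"])),
        pert, length=float(cfg["perturbed_length"]))
    if cfg.get("cprotein_enabled", True):
        cpar = CProteinParams(
            repeat=float(cfg.get("cprotein_repeat", 45.33)),
            n_domains=int(cfg.get("cprotein_n_domains", 11)),
            bead_diameter=float(cfg.get("cprotein_bead_diameter", 4.0)),
            n_anchored=int(cfg.get("cprotein_n_anchored", 3)),
            bend_after=int(cfg.get("cprotein_bend_after", 5)),
            bend_angle=float(cfg.get("cprotein_bend_angle", 90.0)),
            anchor_radius=float(cfg.get("cprotein_anchor_radius", 7.0)),
            sigma_proj=float(cfg.get("cprotein_sigma_proj", 1.0)))
        n_levels = max(1, int(float(cfg["perturbed_length"]) / cpar.repeat))
        cp = build_cprotein_array(cpar, n_levels=n_levels)
    else:
        cp = SphereSet.empty()
    return assemble_filament(
        reg, per, cp,
        perturbed_length=float(cfg["perturbed_length"]),
        regular_length=float(cfg["regular_length"]),
        backbone_radius=float(cfg.get("backbone_radius", 7.0)))


def write_manifest(path, seed=None, inputs=(), config: dict | None = None) -> None:
    """Record provenance of a run: inputs, config hash, versions, seed."""
    import thickfil
    entry = {
        "package": "thickfil",
        "version": getattr(thickfil, "__version__", "unknown"),
        "numpy": np.__version__,
        "seed": seed,
        "inputs": [str(p) for p in inputs],
    }
    if config is not None:
        blob = json.dumps(config, sort_keys=True).encode()
        entry["config_sha256"] = hashlib.sha256(blob).hexdigest()
    with Path(path).open("w") as fh:
        json.dump(entry, fh, indent=2, sort_keys=True)
        fh.write("\n")
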