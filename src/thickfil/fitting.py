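"""RDI-based comparison of layer-line patterns and crossbridge fitting.

The residual deviation of intensity between a reference and an objective
pattern is

    RDI = sum_i int |I_ref,i(R) - s_c I_obj,i(R)| dR
          / sum_i int I_ref,i(R) dR,

with the scale factor s_c chosen to minimise the numerator and the
integration restricted to the off-meridional region R >= R_min (the region
nearer the meridian is contaminated by residual "face-to-face" inter-filament
interference and is excluded from all fitting).  RDI is zero iff the two
patterns agree up to scale on the fit region, and is invariant to rescaling
the objective.

Crossbridge orientations (head rotations epsilon, crown azimuths phi1..phi3,
helical radii r_h) are fitted by a deterministic exhaustive grid search,
organised as a Model object (:class:`OrientationSearch`) whose ``fit()``
returns a Results object with the best parameters, the RDI surface, and
per-parameter sensitivity traces.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import FilamentModel, HeadModel, SphereSet
from .transform import DiffractionPattern, R_MIN_FIT_DEFAULT

__all__ = [
    "normalize_patterns",
    "optimal_scale",
    "rdi",
    "FitConfig",
    "OrientationSearch",
    "OrientationSearchResults",
    "optimize_axial_tilt",
]


def _fit_arrays(ref: DiffractionPattern, obj: DiffractionPattern,
                R_min: float):
    if ref.grid.R_values.shape != obj.grid.R_values.shape or \
            not np.allclose(ref.grid.R_values, obj.grid.R_values):
        raise ValueError("patterns must share a common radial grid")
    common = np.intersect1d(ref.layers, obj.layers)
    common = common[common >= 1]  # equator never enters the comparison
    if common.size == 0:
        raise ValueError("no common non-equatorial layer lines")
    mask = ref.grid.R_values >= R_min
    if not mask.any():
        raise ValueError("empty fit region: R_min exceeds the grid range")
    A = np.vstack([ref.layer(l)[mask] for l in common])
    B = np.vstack([obj.layer(l)[mask] for l in common])
    # drop layer lines that are identically zero in the reference
    keep = A.sum(axis=1) > 0
    if not keep.all():
        dropped = common[~keep].tolist()
        warnings.warn(f"layer line(s) {dropped} are zero in the reference "
                      "and were dropped from the RDI sums", stacklevel=3)
        A, B = A[keep], B[keep]
    if A.size == 0 or A.sum() == 0:
        raise ValueError("reference pattern has zero intensity on the fit region")
    return A.ravel(), B.ravel()


def normalize_patterns(ref: DiffractionPattern, obj: DiffractionPattern,
                       R_min: float = R_MIN_FIT_DEFAULT) -> DiffractionPattern:
    """Rescale ``obj`` so its off-meridional total matches ``ref``'s.

    The sum of intensities over all layer lines for R >= R_min is equalised;
    the region closer to the meridian does not influence the scale.
    """
    mask = ref.grid.R_values >= R_min
    tot_ref = float(ref.intensity[:, mask].sum())
    tot_obj = float(obj.intensity[:, mask].sum())
    if tot_obj == 0 or tot_ref == 0:
        raise ValueError("cannot normalize a pattern with zero total intensity")
    return obj.scaled(tot_ref / tot_obj)


def optimal_scale(ref_flat: np.ndarray, obj_flat: np.ndarray,
                  tol: float = 1e-6) -> float:
    """Scale s minimising sum |ref - s obj| by golden-section search.

    The L1 objective is convex (hence unimodal) in s; the bracket spans the
    ratio of totals by a wide margin.
    """
    if obj_flat.sum() == 0:
        return 0.0
    pos = obj_flat > 0
    hi = float(np.max(ref_flat[pos] / obj_flat[pos], initial=0.0))
    if hi == 0.0:
        return 0.0
    f = lambda s: np.abs(ref_flat - s * obj_flat).sum()
    # golden-section on [0, hi]: the convex L1 objective has its minimiser
    # at a weighted median of the pointwise ratios, which cannot exceed hi
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.0, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol * hi:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return float((a + b) / 2.0)


def rdi(ref: DiffractionPattern, obj: DiffractionPattern,
        R_min: float = R_MIN_FIT_DEFAULT) -> float:
    """Residual deviation of intensity between two patterns (see module doc)."""
    a, b = _fit_arrays(ref, obj, R_min)
    s_c = optimal_scale(a, b)
    return float(np.abs(a - s_c * b).sum() / a.sum())


def _rdi_and_scale(ref, obj, R_min):
    a, b = _fit_arrays(ref, obj, R_min)
    s_c = optimal_scale(a, b)
    return float(np.abs(a - s_c * b).sum() / a.sum()), s_c


# ----------------------------------------------------------------------
def phi_triplet_allowed(phi1: float, phi2: float, phi3: float,
                        min_span: float = 120.0) -> bool:
    """Azimuthal-perturbation constraint on the three crown angles.

    Either some pair among (phi1, phi2, phi3) is equal, or the span
    phi3 - phi1 is at least ``min_span`` degrees.  This enforces the
    pseudo-six-fold (rather than nine-fold) projected symmetry seen on the
    equator of vertebrate muscle patterns.
    """
    if phi1 == phi2 or phi2 == phi3 or phi1 == phi3:
        return True
    return (phi3 - phi1) >= min_span


@dataclass
class FitConfig:
    """Grids and constraints for the orientation grid search.

    ``grids`` maps parameter names (as understood by the model builder) to
    1-D value arrays; the search is the full product in deterministic order
    (first-listed parameter varying slowest, ties broken by first
    encounter).  ``phi_params`` names the crown-azimuth triplet subject to
    the equal-pair-or-120-degree-span constraint; ``backbone_radius`` sets
    the bead-penetration bound (heads may not point toward the backbone).
    ``refine_steps`` > 0 adds coarse-to-fine passes: after each pass the
    grids are rebuilt around the optimum at the given ``refine_factor`` of
    the previous step size.
    """

    grids: Mapping[str, Sequence[float]]
    phi_params: tuple = ("phi1", "phi2", "phi3")
    phi_min_span: float = 120.0
    R_min_fit: float = R_MIN_FIT_DEFAULT
    backbone_radius: float = 7.0
    refine_steps: int = 0
    refine_factor: float = 0.2

    def __post_init__(self):
        self.grids = {k: np.atleast_1d(np.asarray(v, float))
                      for k, v in self.grids.items()}
        for k, g in self.grids.items():
            if g.size == 0 or np.any(np.diff(g) < 0):
                raise ValueError(f"grid for {k!r} must be non-empty and ordered")

    def feasible(self, params: Mapping[str, float]) -> bool:
        names = self.phi_params
        if all(n in params for n in names):
            return phi_triplet_allowed(params[names[0]], params[names[1]],
                                       params[names[2]], self.phi_min_span)
        return True


class OrientationSearchResults:
    """Results of an orientation grid search.

    Attributes
    ----------
    params : dict of best-fitting parameter values.
    rdi : the RDI at the optimum.
    s_c : the optimal intensity scale factor at the optimum.
    table : DataFrame of every feasible grid point with its RDI.
    n_rejected : grid points rejected by the constraints.
    """

    def __init__(self, model, params, rdi_value, s_c, table, n_rejected):
        self.model = model
        self.params = dict(params)
        self.rdi = float(rdi_value)
        self.s_c = float(s_c)
        self.table = table
        self.n_rejected = int(n_rejected)
        self._traces: dict[str, pd.DataFrame] = {}

    def sensitivity(self, name: str) -> pd.DataFrame:
        """1-D RDI trace: vary one parameter over its grid, others at the
        optimum.  Infeasible points are skipped."""
        if name not in self._traces:
            cfg = self.model.config
            rows = []
            for v in cfg.grids[name]:
                p = dict(self.params)
                p[name] = float(v)
                if not cfg.feasible(p):
                    continue
                score, _ = self.model._evaluate(p)
                if score is not None:
                    rows.append({name: float(v), "rdi": score})
            self._traces[name] = pd.DataFrame(rows)
        return self._traces[name]

    def summary(self) -> str:
        lines = ["Crossbridge orientation search",
                 "=" * 38,
                 f"{'parameter':<22}{'value':>12}"]
        lines += [f"{k:<22}{v:>12.4g}" for k, v in self.params.items()]
        lines += ["-" * 38,
                  f"{'RDI':<22}{self.rdi:>12.5f}",
                  f"{'scale factor s_c':<22}{self.s_c:>12.5g}",
                  f"{'grid points scored':<22}{len(self.table):>12d}",
                  f"{'rejected (constraints)':<22}{self.n_rejected:>12d}"]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<OrientationSearchResults rdi={self.rdi:.5f} "
                f"params={self.params}>")


class OrientationSearch:
    """Exhaustive grid search of crossbridge orientation parameters.

    Parameters
    ----------
    observed : the (desampled) reference pattern to fit.
    model_builder : callable mapping a parameter dict to a
        :class:`FilamentModel` or :class:`SphereSet`.
    config : grids and constraints.
    pattern_fn : optional callable(model) -> DiffractionPattern; defaults to
        the cylindrically averaged transform on the observed pattern's grid
        and layer lines.
    """

    def __init__(self, observed: DiffractionPattern,
                 model_builder: Callable[[dict], object],
                 config: FitConfig,
                 pattern_fn: Callable[[object], DiffractionPattern] | None = None):
        from .transform import cylindrical_intensity
        self.observed = observed
        self.builder = model_builder
        self.config = config
        if pattern_fn is None:
            pattern_fn = lambda m: cylindrical_intensity(
                m, observed.grid, layers=observed.layers, c=observed.c)
        self.pattern_fn = pattern_fn
        self._violations: list[str] = []

    # ------------------------------------------------------------------
    def _evaluate(self, params: dict):
        """(rdi, s_c) for one parameter set, or (None, reason) if the built
        model violates the backbone-penetration constraint."""
        model = self.builder(params)
        spheres = model.myosin_spheres() if isinstance(model, FilamentModel) \
            else model
        if len(spheres) and spheres.min_radius() < self.config.backbone_radius:
            return None, "head beads penetrate the backbone cylinder"
        calc = self.pattern_fn(model)
        return _rdi_and_scale(self.observed, calc, self.config.R_min_fit)

    def _search(self, grids: Mapping[str, np.ndarray]):
        names = list(grids)
        best = None
        rows = []
        n_rejected = 0
        for combo in itertools.product(*(grids[n] for n in names)):
            params = {n: float(v) for n, v in zip(names, combo)}
            if not self.config.feasible(params):
                n_rejected += 1
                self._violations.append("phi triplet constraint")
                continue
            score, s_c = self._evaluate(params)
            if score is None:
                n_rejected += 1
                self._violations.append(s_c)
                continue
            rows.append({**params, "rdi": score, "s_c": s_c})
            if best is None or score < best[0]:  # strict: first wins ties
                best = (score, s_c, params)
        return best, rows, n_rejected

    def fit(self) -> OrientationSearchResults:
        grids = dict(self.config.grids)
        self._violations = []
        best, rows, n_rejected = self._search(grids)
        all_rows = rows
        for _ in range(self.config.refine_steps):
            if best is None:
                break
            grids = self._refined_grids(grids, best[2])
            b2, rows2, rej2 = self._search(grids)
            all_rows += rows2
            n_rejected += rej2
            if b2 is not None and b2[0] < best[0]:
                best = b2
        if best is None:
            reasons = sorted(set(self._violations))
            raise ValueError(
                "no feasible grid point; constraints violated: "
                + "; ".join(reasons))
        score, s_c, params = best
        table = pd.DataFrame(all_rows)
        return OrientationSearchResults(self, params, score, s_c, table,
                                        n_rejected)

    def _refined_grids(self, grids, center):
        out = {}
        for name, g in grids.items():
            if g.size < 2:
                out[name] = g
                continue
            step = float(np.min(np.diff(g)))
            fine = step * self.config.refine_factor
            c = center[name]
            vals = np.arange(c - step, c + step + fine / 2, fine)
            out[name] = np.round(vals, 9)
        return out


# ----------------------------------------------------------------------
def optimize_axial_tilt(head: HeadModel, meridional_ref: np.ndarray,
                        profile_fn: Callable[[HeadModel], np.ndarray],
                        bounds: tuple = (-15.0, 15.0),
                        step: float = 1.0) -> tuple[HeadModel, float]:
    """Scan the head's axial tilt to fit a meridional intensity profile.

    The head is rotated about the local y axis (perpendicular to both its
    long axis and the filament axis) through the junction, in ``step``-degree
    increments over ``bounds``; the tilt minimising the L1 residual between
    ``profile_fn(tilted_head)`` and ``meridional_ref`` (after optimal
    scaling) is applied.  Returns (tilted head, tilt in degrees).
    """
    ref = np.asarray(meridional_ref, float)
    lo, hi = bounds
    tilts = np.arange(lo, hi + step / 2, step)
    best = None
    for t in tilts:
        rad = math.radians(t)
        cy, sy = math.cos(rad), math.sin(rad)
        Ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
        cand = head.transformed(Ry)
        prof = np.asarray(profile_fn(cand), float)
        s = optimal_scale(ref, prof)
        score = np.abs(ref - s * prof).sum() / max(ref.sum(), 1e-300)
        if best is None or score < best[0]:
            best = (score, t, cand)
    return best[2], float(best[1])
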