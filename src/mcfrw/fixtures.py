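"""Synthetic geometries, deterministic trajectories and brute-force oracles.

Everything here exists so the production code can be tested without any
external data: fixture geometries with closed-form properties, ballistic
trajectories with known MSD and tortuosity, and deliberately naive
reference implementations (full scans, double loops, corner projections)
that share no code with the indexed production paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .geometry import (CollagenLattice, MCFGeometry, Platelet, PlateletDims,
                       build_lattice, default_dim_ranges)
from .walker import DELTA_T, Trajectory

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "ballistic_trajectory",
    "oracle_msd",
    "oracle_point_blocked",
    "oracle_segment_blocked",
    "oracle_platelet_overlaps",
]

_KINDS = ("empty", "single_box", "slab_array", "regular_lattice",
          "sealed_box")


@dataclass(frozen=True)
class FixtureSpec:
    """Named test geometry with per-kind parameters."""
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(
                f"unknown fixture kind {self.kind!r}; choose from {_KINDS}")


def make_fixture(spec, **parameters) -> MCFGeometry:
    """Build one of the named fixture geometries.

    ``spec`` may be a :class:`FixtureSpec` or a kind name plus keyword
    parameters.
    """
    if not isinstance(spec, FixtureSpec):
        spec = FixtureSpec(str(spec), parameters)
    p = dict(spec.parameters)
    builder = {"empty": _empty, "single_box": _single_box,
               "slab_array": _slab_array, "regular_lattice": _regular_lattice,
               "sealed_box": _sealed_box}[spec.kind]
    return builder(p, spec.seed)


def _empty(p, seed):
    return MCFGeometry([], CollagenLattice(enabled=False),
                       p.get("envelope_radius", 100.0),
                       p.get("envelope_length", 1000.0))


def _single_box(p, seed):
    """One axis-aligned platelet of exactly known volume."""
    w, t, l = p.get("box", (10.0, 10.0, 10.0))
    center = np.asarray(p.get("center", (0.0, 0.0, 500.0)), dtype=float)
    plat = Platelet(center, PlateletDims(w, t, l))
    return MCFGeometry([plat], CollagenLattice(enabled=False),
                       p.get("envelope_radius", 100.0),
                       p.get("envelope_length", 1000.0))


def _slab_array(p, seed):
    """Periodic thin walls across the fibril, each pierced by one aperture.

    The aperture alternates between two off-axis positions so that any
    path spanning the fibril must zig-zag laterally: ensemble tortuosity
    exceeds 1 by construction and the axial diffusivity drops below D0.
    """
    R = p.get("envelope_radius", 50.0)
    Lz = p.get("envelope_length", 500.0)
    spacing = p.get("spacing", 100.0)
    thick = p.get("thickness", 2.0)
    ap = p.get("aperture", 20.0)
    off = p.get("aperture_offset", 0.5 * R)
    side = 2.0 * R + 2.0  # walls overhang the envelope; clipped by it
    plats = []
    n_walls = int(Lz // spacing)
    for w in range(1, n_walls + 1):
        z = w * spacing
        cx = off if w % 2 else -off
        # four boxes around a square aperture centred at (cx, 0)
        lo, hi = cx - ap / 2.0, cx + ap / 2.0
        spans = [(-R - 1.0, lo), (hi, R + 1.0)]
        for x0, x1 in spans:
            if x1 <= x0:
                continue
            plats.append(Platelet(
                np.array([(x0 + x1) / 2.0, 0.0, z]),
                PlateletDims(x1 - x0, side, thick)))
        for y0, y1 in [(-R - 1.0, -ap / 2.0), (ap / 2.0, R + 1.0)]:
            plats.append(Platelet(
                np.array([(lo + hi) / 2.0, (y0 + y1) / 2.0, z]),
                PlateletDims(ap, y1 - y0, thick)))
    return MCFGeometry(plats, CollagenLattice(enabled=False), R, Lz)


def _regular_lattice(p, seed):
    """The unperturbed staggered lattice with zero dimension scatter."""
    ranges = default_dim_ranges(calibrated=False, sd_fraction=0.0)
    return build_lattice(dim_ranges=ranges,
                         envelope_radius=p.get("envelope_radius", 100.0),
                         envelope_length=p.get("envelope_length", 1000.0),
                         rng=seed,
                         collagen=p.get("collagen",
                                        CollagenLattice(enabled=True)))


def _sealed_box(p, seed):
    """A closed cavity smaller than the step length: walkers get trapped."""
    c = np.asarray(p.get("center", (0.0, 0.0, 0.5)), dtype=float)
    half = p.get("cavity_half", 0.25)
    thick = p.get("thickness", 3.0)
    outer = 2.0 * (half + thick)
    plats = []
    for ax in range(3):
        for sign in (-1.0, 1.0):
            center = c.copy()
            center[ax] += sign * (half + thick / 2.0)
            dims = [outer, outer, outer]
            dims[ax] = thick
            plats.append(Platelet(center, PlateletDims(*dims)))
    return MCFGeometry(plats, CollagenLattice(enabled=False),
                       p.get("envelope_radius", 100.0),
                       p.get("envelope_length", 1000.0))


# ---------------------------------------------------------------------------
# deterministic trajectories
# ---------------------------------------------------------------------------

def ballistic_trajectory(n: int, step, delta_t: float = DELTA_T) -> Trajectory:
    """Positions j * step for j = 0..n-1: MSD(k) = k^2 |step|^2, tortuosity 1."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    step = np.asarray(step, dtype=float)
    pos = np.arange(n)[:, None] * step[None, :]
    return Trajectory(positions=pos, delta_t=delta_t, seed=0,
                      n_steps=n - 1, status="reached")


# ---------------------------------------------------------------------------
# oracles (naive reference implementations, no shared code)
# ---------------------------------------------------------------------------

def oracle_msd(trajectory, lag: int) -> float:
    """Literal double-loop time-averaged MSD at one lag (nm^2)."""
    pos = trajectory.positions if isinstance(trajectory, Trajectory) \
        else np.asarray(trajectory, dtype=float)
    N = pos.shape[0]
    if not 1 <= lag <= N - 1:
        raise ParameterError(f"lag must lie in 1..{N - 1}")
    total = 0.0
    for j in range(N - lag):
        d = pos[j + lag] - pos[j]
        total += float(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    return total / (N - lag)


def oracle_point_blocked(geometry: MCFGeometry, point) -> bool:
    """Index-free occupancy scan over every obstacle."""
    x, y, z = (float(v) for v in point)
    if x * x + y * y > geometry.envelope_radius ** 2:
        return True
    if z < 0.0 or z > geometry.envelope_length:
        return True
    for cyl in geometry.collagen_cylinders:
        cx, cy, _ = cyl.axis_origin
        if (x - cx) ** 2 + (y - cy) ** 2 <= cyl.radius ** 2:
            return True
    for plat in geometry.platelets:
        local = plat.rotation.T @ (np.array([x, y, z]) - plat.center)
        if (np.abs(local) <= plat.half_extents).all():
            return True
    return False


def oracle_segment_blocked(geometry: MCFGeometry, p0, p1,
                           n_samples: int = 1000) -> bool:
    """Dense point-sampling segment test (vectorized naive scan).

    Detects any obstacle hit down to features larger than
    |p1 - p0| / n_samples; used as a one-sided oracle (a hit it reports
    must also be reported by the production slab/cylinder tests).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    rad2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
    if (rad2 > geometry.envelope_radius ** 2).any():
        return True
    if (pts[:, 2] < 0.0).any() or (pts[:, 2] > geometry.envelope_length).any():
        return True
    cyls = geometry.collagen_cylinders
    if cyls:
        centers = np.array([c.axis_origin[:2] for c in cyls])
        r2 = np.array([c.radius ** 2 for c in cyls])
        d2 = ((pts[:, None, :2] - centers[None, :, :]) ** 2).sum(axis=2)
        if (d2 <= r2[None, :]).any():
            return True
    for plat in geometry.platelets:
        local = (pts - plat.center) @ plat.rotation
        if (np.abs(local) <= plat.half_extents).all(axis=1).any():
            return True
    return False


def _project_obb(corners: np.ndarray, axis: np.ndarray):
    proj = corners @ axis
    return float(proj.min()), float(proj.max())


def oracle_platelet_overlaps(geometry: MCFGeometry, tol: float = 1e-6):
    """Brute-force pairwise platelet overlap detection by corner projection.

    Projects the 8 corners of each box of a candidate pair onto all 15
    separating-axis directions; a pair overlaps iff every axis shows the
    projection intervals interpenetrating by more than ``tol`` (touching
    boxes do not count).  Returns the list of overlapping index pairs.
    """
    P = len(geometry.platelets)
    signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                      for sz in (-1, 1)], dtype=float)
    corners = []
    axes = []
    aabb_lo = np.empty((P, 3))
    aabb_hi = np.empty((P, 3))
    for i, plat in enumerate(geometry.platelets):
        pts = plat.center + (signs * plat.half_extents) @ plat.rotation.T
        corners.append(pts)
        axes.append(plat.rotation.T.copy())  # rows are the box axes
        aabb_lo[i] = pts.min(axis=0)
        aabb_hi[i] = pts.max(axis=0)

    overlaps = []
    for a in range(P):
        for b in range(a + 1, P):
            if (aabb_lo[a] > aabb_hi[b] - tol).any() \
                    or (aabb_lo[b] > aabb_hi[a] - tol).any():
                continue
            cand = [axes[a][k] for k in range(3)]
            cand += [axes[b][k] for k in range(3)]
            for i in range(3):
                for j in range(3):
                    cr = np.cross(axes[a][i], axes[b][j])
                    nrm = np.linalg.norm(cr)
                    if nrm > 1e-12:
                        cand.append(cr / nrm)
            separated = False
            for axis in cand:
                lo_a, hi_a = _project_obb(corners[a], axis)
                lo_b, hi_b = _project_obb(corners[b], axis)
                if lo_a > hi_b - tol or lo_b > hi_a - tol:
                    separated = True
                    break
            if not separated:
                overlaps.append((a, b))
    return overlaps
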