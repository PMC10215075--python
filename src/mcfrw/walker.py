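"""Obstructed Gaussian random walks through the fibril geometry.

Water particles start uniformly on the free part of the equatorial plane
at L = 0 and take Gaussian steps (per-coordinate standard deviation
sigma = sqrt(2 D0 dt)) until they first cross the upper extremity of the
fibril.  A proposed move whose straight path would touch an apatite
platelet, a tropocollagen cylinder or the envelope wall is rejected.

Two rejection policies are available:

``"stay"`` (default)
    One proposal per time step; on rejection the particle stays where it
    is for that step.  Blocked-move dynamics of this kind slow the walk
    down in proportion to the local rejection rate, which is what produces
    effective diffusivities well below the free-water value.
``"resample"``
    Rejected proposals are redrawn within the same time step, so a step
    is always taken; obstruction then acts only through path geometry.

Full-step segments (not just endpoints) are tested so that particles
cannot tunnel through obstacles thinner than the step length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import GeometryError, ParameterError, TrappedWalkerError
from .geometry import MCFGeometry

__all__ = [
    "WalkConfig",
    "Trajectory",
    "Ensemble",
    "step_sigma",
    "propose_step",
    "advance",
    "simulate_trajectory",
    "simulate_ensemble",
]

#: Free-water diffusivity at 27 C, m^2/s.
D0_WATER = 2.66e-9
#: Default time step, s.
DELTA_T = 2e-10
#: Tropocollagen cylinder diameter, nm (smallest obstacle dimension).
MIN_OBSTACLE_NM = 1.23

_MAX_RECORD_ROWS = 15_000_000  # ~360 MB position buffer guard


def step_sigma(D0: float, delta_t: float) -> float:
    """Per-coordinate step standard deviation sigma = sqrt(2 D0 dt), meters.

    Warns if the step is not smaller than the thinnest obstacle (the
    tropocollagen cross-section), since steps of that size can only be
    kept honest by the full-segment collision test.
    """
    if D0 < 0 or delta_t <= 0:
        raise ParameterError("require D0 >= 0 and delta_t > 0")
    sigma = math.sqrt(2.0 * D0 * delta_t)
    if sigma * 1e9 >= MIN_OBSTACLE_NM:
        warnings.warn(
            f"step sigma {sigma * 1e9:.3f} nm is not smaller than the "
            f"minimum obstacle dimension {MIN_OBSTACLE_NM} nm",
            stacklevel=2)
    return sigma


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk ensemble parameters."""
    delta_t: float = DELTA_T
    D0: float = D0_WATER
    n_trajectories: int = 1000
    max_steps: int = 50_000_000
    record_stride: int = 1
    master_seed: int = 0
    blocked_move: str = "stay"
    max_consecutive_rejections: int = 10_000

    def __post_init__(self):
        if self.delta_t <= 0 or self.D0 < 0:
            raise ParameterError("require delta_t > 0 and D0 >= 0")
        if self.n_trajectories < 1:
            raise ParameterError("n_trajectories must be >= 1")
        if self.record_stride < 1 or self.max_steps < 0:
            raise ParameterError("record_stride >= 1, max_steps >= 0")
        if self.blocked_move not in ("stay", "resample"):
            raise ParameterError("blocked_move must be 'stay' or 'resample'")

    @property
    def sigma(self) -> float:
        """Per-coordinate step standard deviation, meters."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return step_sigma(self.D0, self.delta_t)

    @property
    def sigma_nm(self) -> float:
        return self.sigma * 1e9


@dataclass
class Trajectory:
    """Recorded particle path with uniform time spacing.

    ``delta_t`` is the interval between recorded positions, i.e. the base
    time step times ``record_stride``.
    """
    positions: np.ndarray  # (N, 3) nm, columns W, T, L
    delta_t: float  # s between recorded positions
    seed: int
    n_steps: int = 0
    n_rejections: int = 0
    status: str = "reached"
    record_stride: int = 1
    base_delta_t: float = DELTA_T
    stop_L: float | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("positions must be (N, 3)")

    def __len__(self):
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Times (s) of the recorded positions."""
        return np.arange(len(self)) * self.delta_t

    @property
    def duration(self) -> float:
        """Total simulated time, s."""
        return self.n_steps * self.base_delta_t


@dataclass
class Ensemble:
    """Trajectories plus the ids of any that failed to simulate."""
    trajectories: list
    failed: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return len(self.trajectories)

    def __getitem__(self, i):
        return self.trajectories[i]


def propose_step(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """One Gaussian trial displacement (nm) from a step SD given in meters."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    return rng.normal(0.0, sigma * 1e9, size=3)


def advance(position, geometry: MCFGeometry, rng: np.random.Generator,
            config: WalkConfig, policy: str | None = None) -> np.ndarray:
    """Advance one time step from an un-blocked position.

    Under the ``"resample"`` policy, proposals are redrawn until one is
    unobstructed (consuming no extra simulation time); under ``"stay"``
    a single blocked proposal leaves the particle in place for the step.
    Raises :class:`TrappedWalkerError` when the rejection bound is hit.
    """
    policy = policy or config.blocked_move
    pos = np.asarray(position, dtype=float)
    args = geometry.kernel_args()
    attempts = 0
    while True:
        cand = pos + propose_step(rng, config.sigma)
        hit = _kernels.segment_blocked(pos[0], pos[1], pos[2],
                                       cand[0], cand[1], cand[2],
                                       *args, True)
        if not hit:
            return cand
        attempts += 1
        if attempts > config.max_consecutive_rejections:
            raise TrappedWalkerError(pos, attempts)
        if policy == "stay":
            return pos.copy()


def _record_capacity(config: WalkConfig) -> int:
    rows = config.max_steps // config.record_stride + 3
    if rows > _MAX_RECORD_ROWS:
        raise ParameterError(
            f"recording {rows} positions would need too much memory; "
            f"increase record_stride (currently {config.record_stride}) "
            f"or lower max_steps")
    return rows


_STATUS_NAMES = {_kernels.STATUS_REACHED: "reached",
                 _kernels.STATUS_TRUNCATED: "truncated"}


def simulate_trajectory(geometry: MCFGeometry, config: WalkConfig, seed: int,
                        start=None, stop_L: float | None = None,
                        engine: str = "numba") -> Trajectory:
    """Simulate one walk from the L = 0 plane to the first crossing of stop_L.

    The start position is sampled uniformly on the un-blocked part of the
    L = 0 disc unless ``start`` is given.  The ``"python"`` engine mirrors
    the compiled kernel draw-for-draw (both use the legacy Mersenne
    Twister), so the two engines produce identical trajectories.
    """
    stop = geometry.envelope_length if stop_L is None else float(stop_L)
    seed = int(seed) % 2**31
    if engine == "numba":
        rec = np.empty((_record_capacity(config), 3))
        sx, sy, sz = (0.0, 0.0, 0.0) if start is None else map(float, start)
        n_rec, n_steps, n_rej, status = _kernels.walk(
            seed, sx, sy, sz, start is not None,
            config.sigma_nm, config.record_stride, stop,
            config.max_steps, config.max_consecutive_rejections,
            config.blocked_move == "resample",
            *geometry.kernel_args(), rec)
        if status == _kernels.STATUS_NO_START:
            raise GeometryError("no free space found on the start plane")
        if status == _kernels.STATUS_TRAPPED:
            raise TrappedWalkerError(rec[max(n_rec - 1, 0)],
                                     config.max_consecutive_rejections)
        positions = rec[:n_rec].copy()
    elif engine == "python":
        positions, n_steps, n_rej, status = _walk_python(
            geometry, config, seed, start, stop)
    else:
        raise ParameterError("engine must be 'numba' or 'python'")
    return Trajectory(positions=positions,
                      delta_t=config.delta_t * config.record_stride,
                      seed=seed, n_steps=n_steps, n_rejections=n_rej,
                      status=_STATUS_NAMES[status],
                      record_stride=config.record_stride,
                      base_delta_t=config.delta_t, stop_L=stop)


def _walk_python(geometry, config, seed, start, stop):
    """Pure-Python twin of the compiled walk kernel (same RNG stream)."""
    rs = np.random.RandomState(seed)
    args = geometry.kernel_args()
    env_r = geometry.envelope_radius
    if start is not None:
        x, y, z = (float(v) for v in start)
    else:
        for _ in range(1000000):
            u = rs.random_sample()
            th = 2.0 * np.pi * rs.random_sample()
            rad = env_r * np.sqrt(u)
            x, y, z = rad * np.cos(th), rad * np.sin(th), 0.0
            if not _kernels.point_blocked(x, y, z, *args, True):
                break
        else:
            raise GeometryError("no free space found on the start plane")
    sigma = config.sigma_nm
    resample = config.blocked_move == "resample"
    out = [(x, y, z)]
    if z >= stop:
        return np.asarray(out, dtype=float), 0, 0, _kernels.STATUS_REACHED
    steps = n_rej = consec = 0
    status = _kernels.STATUS_TRUNCATED
    last_rec = 0
    while steps < config.max_steps:
        px = x + sigma * rs.standard_normal()
        py = y + sigma * rs.standard_normal()
        pz = z + sigma * rs.standard_normal()
        hit = _kernels.segment_blocked(x, y, z, px, py, pz, *args, True)
        if hit:
            n_rej += 1
            consec += 1
            if consec > config.max_consecutive_rejections:
                raise TrappedWalkerError((x, y, z), consec)
            if resample:
                continue
        else:
            x, y, z = px, py, pz
            consec = 0
        steps += 1
        if steps % config.record_stride == 0:
            out.append((x, y, z))
            last_rec = steps
        if z >= stop:
            status = _kernels.STATUS_REACHED
            break
    if last_rec != steps:
        out.append((x, y, z))
    return np.asarray(out, dtype=float), steps, n_rej, status


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent int32 per-trajectory seeds from one master seed."""
    return (np.random.SeedSequence(int(master_seed)).generate_state(n)
            % 2**31).astype(np.int64)


def simulate_ensemble(geometry: MCFGeometry, config: WalkConfig,
                      stop_L: float | None = None, engine: str = "numba",
                      out_dir=None, progress=None) -> Ensemble:
    """Simulate ``config.n_trajectories`` independent walks.

    Per-trajectory errors (trapped walkers, no free start) are collected
    in ``Ensemble.failed`` instead of aborting the run.  With ``out_dir``
    each finished trajectory is persisted immediately and existing files
    are reused, making interrupted ensembles resumable.
    """
    from . import io as _io  # local import: io depends on this module

    seeds = derive_seeds(config.master_seed, config.n_trajectories)
    trajectories = []
    failed = {}
    for i, seed in enumerate(seeds):
        path = None
        if out_dir is not None:
            path = _io.trajectory_path(out_dir, i)
            if path.exists():
                trajectories.append(_io.load_trajectory(path))
                continue
        try:
            traj = simulate_trajectory(geometry, config, int(seed),
                                       stop_L=stop_L, engine=engine)
        except (TrappedWalkerError, GeometryError) as exc:
            failed[i] = str(exc)
            continue
        if path is not None:
            _io.save_trajectory(traj, path)
        trajectories.append(traj)
        if progress is not None:
            progress(i, traj)
    return Ensemble(trajectories, failed)
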