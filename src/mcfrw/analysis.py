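"""Trajectory statistics: MSD curves, diffusivity, tortuosity, quote sweeps.

The diffusion coefficient of a single trajectory follows the Einstein
relation in three dimensions: the time-averaged mean squared displacement

    MSD(n dt) = (1/(N-n)) sum_j |r((j+n) dt) - r(j dt)|^2

grows as MSD = b0 + b1 t for normal diffusion, and D = b1 / 6.

Tortuosity is the effective path length divided by the straight-line
distance between the first and last points.  A Brownian path has no
intrinsic length - the raw sum of recorded segments grows without bound
as the recording gets finer - so the structural tortuosity reported by
quote sweeps is evaluated on the path coarse-grained at the axial period
of the fibril (67 nm), the natural length scale of the obstacle lattice.
``tortuosity`` itself defaults to the exact sum over recorded segments.

A "quote" is an equatorial plane at a fixed L coordinate; sub-trajectories
run from the start plane to the first crossing of a quote plane, and a
quote sweep aggregates tortuosity and diffusivity over the ensemble of
sub-trajectories reaching each quote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import stats

from ._kernels import coarse_path_length
from .errors import ParameterError, UndefinedTortuosityError
from .geometry import D_PERIOD
from .walker import Trajectory

__all__ = [
    "MSDCurve",
    "LinearFit",
    "QuoteReport",
    "DEFAULT_QUOTES",
    "msd_time_average",
    "fit_msd",
    "diffusion_coefficient",
    "tortuosity",
    "extract_subtrajectory",
    "quote_sweep",
    "confidence_interval",
    "order_of_magnitude",
    "quote_summary_table",
]

#: Reference quotes (nm): multiples of the 134 nm building block.
DEFAULT_QUOTES = tuple(134.0 * k for k in range(1, 8))

NM2_TO_M2 = 1e-18


@dataclass
class MSDCurve:
    """Time-averaged MSD per lag; values in nm^2, lag spacing delta_t (s)."""
    lags: np.ndarray
    values: np.ndarray
    delta_t: float

    @property
    def times(self) -> np.ndarray:
        return self.lags * self.delta_t


@dataclass(frozen=True)
class LinearFit:
    """OLS fit MSD = beta0 + beta1 t over a lag window."""
    beta0: float  # nm^2
    beta1: float  # nm^2 / s
    fit_lag_window: tuple
    r_squared: float


def _positions(traj) -> np.ndarray:
    return traj.positions if isinstance(traj, Trajectory) \
        else np.asarray(traj, dtype=float)


def msd_time_average(trajectory, lags=None) -> MSDCurve:
    """Time-averaged MSD over all overlapping position pairs.

    Uses the FFT decomposition of the overlapping-pair sum, which is
    O(N log N); agrees with the direct double loop to ~1e-12 relative.
    """
    pos = _positions(trajectory)
    N = pos.shape[0]
    if N < 2:
        raise ParameterError("need at least two positions")
    if lags is None:
        lag_arr = np.arange(1, N)
    else:
        lag_arr = np.atleast_1d(np.asarray(lags, dtype=np.int64))
        if lag_arr.size == 0 or lag_arr.min() < 1 or lag_arr.max() >= N:
            raise ParameterError(f"lags must lie in 1..{N - 1}")

    # MSD is translation invariant; centring conditions the FFT sums
    pos = pos - pos.mean(axis=0)
    nfft = sp_fft.next_fast_len(2 * N)
    sq = np.einsum("ij,ij->i", pos, pos)
    # autocorrelation sum S2(n) = sum_j r_j . r_{j+n} via FFT
    S2 = np.zeros(N)
    for d in range(3):
        f = sp_fft.rfft(pos[:, d], nfft)
        ac = sp_fft.irfft(f * np.conj(f), nfft)[:N]
        S2 += ac
    # Q(n) = sum_{j=0}^{N-n-1} (|r_j|^2 + |r_{j+n}|^2), by recursion
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    total = csum[N]
    n = np.arange(N)
    Q = (csum[N - n] - 0.0) + (total - csum[n])
    counts = N - n
    msd_all = (Q - 2.0 * S2) / counts
    msd_all = np.maximum(msd_all, 0.0)  # clip FFT round-off at tiny lags
    dt = trajectory.delta_t if isinstance(trajectory, Trajectory) else 1.0
    return MSDCurve(lags=lag_arr.copy(), values=msd_all[lag_arr], delta_t=dt)


def fit_msd(curve: MSDCurve, window=None) -> LinearFit:
    """Ordinary least squares of MSD against time over a lag window.

    The default window spans lags 1 .. max(2, N/10): early lags carry the
    best statistics in a time-averaged MSD, late lags are dominated by a
    handful of pairs.
    """
    lags = np.asarray(curve.lags)
    if window is None:
        n_pos = int(lags.max()) + 1
        window = (1, max(2, n_pos // 10))
    lo, hi = int(window[0]), int(window[1])
    mask = (lags >= lo) & (lags <= hi)
    t = lags[mask] * curve.delta_t
    y = np.asarray(curve.values)[mask]
    if t.size < 2 or np.unique(t).size < 2:
        raise ParameterError(
            f"fit window {window} must contain >= 2 distinct lags")
    beta1, beta0 = np.polyfit(t, y, 1)
    resid = y - (beta0 + beta1 * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(beta0=float(beta0), beta1=float(beta1),
                     fit_lag_window=(lo, hi), r_squared=r2)


def diffusion_coefficient(fit: LinearFit) -> float:
    """D = beta1 / (2 d_S) with d_S = 3, converted from nm^2/s to m^2/s."""
    return fit.beta1 / 6.0 * NM2_TO_M2


def tortuosity(trajectory, resolution: float | None = None) -> float:
    """Effective path length over straight-line start-to-end distance.

    With ``resolution`` set, the path is first coarse-grained at that
    spatial scale (see module docstring); ``None`` sums every recorded
    segment.  Always >= 1; raises for coincident endpoints.
    """
    pos = _positions(trajectory)
    if pos.shape[0] < 2:
        raise ParameterError("need at least two positions")
    chord = float(np.linalg.norm(pos[-1] - pos[0]))
    if chord < 1e-12:
        raise UndefinedTortuosityError(
            "start and end positions coincide; tortuosity undefined")
    if resolution is None or resolution <= 0:
        eff = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
    else:
        eff = float(coarse_path_length(np.ascontiguousarray(pos),
                                       float(resolution)))
    return eff / chord


def extract_subtrajectory(trajectory: Trajectory, quote_L: float):
    """Prefix of the walk up to its first recorded crossing of quote_L.

    Returns ``None`` if the trajectory never reaches the quote plane.
    """
    if quote_L <= 0:
        raise ParameterError("quote_L must be positive")
    L = trajectory.positions[:, 2]
    reached = L >= quote_L
    if not reached.any():
        return None
    idx = int(np.argmax(reached))
    return Trajectory(positions=trajectory.positions[:idx + 1].copy(),
                      delta_t=trajectory.delta_t,
                      seed=trajectory.seed,
                      n_steps=idx * trajectory.record_stride,
                      n_rejections=trajectory.n_rejections,
                      status="reached",
                      record_stride=trajectory.record_stride,
                      base_delta_t=trajectory.base_delta_t,
                      stop_L=float(quote_L))


def confidence_interval(values, level: float = 0.95):
    """Student-t confidence interval for the mean: m +/- t s / sqrt(n)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ParameterError("need at least two values")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    m = float(v.mean())
    s = float(v.std(ddof=1))
    t = float(stats.t.ppf(0.5 * (1.0 + level), v.size - 1))
    half = t * s / math.sqrt(v.size)
    return (m - half, m + half)


def order_of_magnitude(x: float) -> float:
    """The power of ten bracketing x from below: 10^floor(log10 x)."""
    if x <= 0:
        raise ParameterError("x must be positive")
    return 10.0 ** math.floor(math.log10(x))


@dataclass
class QuoteReport:
    """Ensemble statistics for sub-trajectories reaching one quote plane."""
    quote_L: float
    n_subtrajectories: int
    mean_tortuosity: float
    tortuosity_ci95: tuple
    mean_D: float
    D_ci95: tuple
    per_trajectory: pd.DataFrame


def quote_sweep(ensemble, quotes=DEFAULT_QUOTES, fit_window=None,
                tortuosity_resolution: float | None = D_PERIOD,
                level: float = 0.95) -> list:
    """Per-quote tortuosity and diffusivity aggregates over an ensemble.

    For every quote plane: each trajectory that reaches it contributes its
    first-passage prefix, whose tortuosity (coarse-grained at
    ``tortuosity_resolution``, default the 67 nm axial period) and MSD-fit
    diffusivity are averaged; 95% Student-t confidence intervals are
    attached.  Quotes that no trajectory reaches yield a report with
    ``n_subtrajectories = 0`` and NaN means.
    """
    quotes = sorted(float(q) for q in quotes)
    reports = []
    for q in quotes:
        rows = []
        for tid, traj in enumerate(ensemble):
            sub = extract_subtrajectory(traj, q)
            if sub is None or len(sub) < 2:
                continue
            try:
                tort = tortuosity(sub, resolution=tortuosity_resolution)
            except UndefinedTortuosityError:
                continue
            D = beta0 = beta1 = r2 = math.nan
            if len(sub) >= 3:
                curve = msd_time_average(sub)
                try:
                    fit = fit_msd(curve, window=fit_window)
                except ParameterError:
                    fit = None
                if fit is not None:
                    D = diffusion_coefficient(fit)
                    beta0, beta1, r2 = fit.beta0, fit.beta1, fit.r_squared
            rows.append((tid, q, tort, D, beta0, beta1, r2, len(sub)))
        table = pd.DataFrame(
            rows, columns=["trajectory_id", "quote_L_nm", "tortuosity",
                           "D_m2_per_s", "beta0", "beta1", "r2", "n_points"])
        n = len(table)
        torts = table["tortuosity"].to_numpy()
        Ds = table["D_m2_per_s"].dropna().to_numpy()
        reports.append(QuoteReport(
            quote_L=q,
            n_subtrajectories=n,
            mean_tortuosity=float(torts.mean()) if n else math.nan,
            tortuosity_ci95=(confidence_interval(torts, level)
                             if n >= 2 else (math.nan, math.nan)),
            mean_D=float(Ds.mean()) if Ds.size else math.nan,
            D_ci95=(confidence_interval(Ds, level)
                    if Ds.size >= 2 else (math.nan, math.nan)),
            per_trajectory=table))
    return reports


def quote_summary_table(reports) -> pd.DataFrame:
    """One-row-per-quote summary suitable for CSV export."""
    rows = []
    for r in reports:
        rows.append({
            "quote_L_nm": r.quote_L,
            "n_subtraj": r.n_subtrajectories,
            "mean_tortuosity": r.mean_tortuosity,
            "tort_ci_lo": r.tortuosity_ci95[0],
            "tort_ci_hi": r.tortuosity_ci95[1],
            "mean_D_m2_per_s": r.mean_D,
            "D_ci_lo": r.D_ci95[0],
            "D_ci_hi": r.D_ci95[1],
        })
    return pd.DataFrame(rows)
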