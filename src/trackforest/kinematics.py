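"""Trajectory smoothing, speed, track length and moving power means.

Raw tracked positions are noisy and frame-quantized, so speed is defined
through a Gaussian-kernel estimate of the trajectory: the smoothed position
is the Nadaraya–Watson weighted mean

    x_hat(t) = sum_i w_i(t) x_i / sum_i w_i(t),
    w_i(t) = exp(-(t - t_i)^2 / (2 h^2)),

with bandwidth h the Gaussian standard deviation (default 0.25 h, i.e.
15 min).  The estimate is evaluable at any time within the cell's
lifespan, including between frames, and speed is the norm of its analytic
time derivative — finite differencing of raw points would make speed
depend on the recording resolution.  Track length over an interval is the
integral of speed, and windowed speed is summarized by generalized power
means

    M_p = (mean of v^p)^(1/p),

which weight high speeds increasingly with p (M_1 is the plain mean; the
power-mean inequality guarantees M_p non-decreasing in p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateTrackError, EmptySelectionError, ParameterError, RangeError

DEFAULT_BANDWIDTH_H = 0.25  # 15 min
DEFAULT_POWER_MEAN_WINDOW_H = 8.0

#: kernel support truncated at +-6 sigma; the discarded weight mass (~1e-9)
#: is negligible against the estimator's own bias, so truncation is purely
#: an efficiency device
KERNEL_TRUNCATION_SIGMAS = 6.0


@dataclass
class SmoothedTrajectory:
    """Gaussian-kernel smoothed trajectory of one cell.

    Holds the raw samples and exposes vectorized evaluation of smoothed
    position, velocity and speed at arbitrary times within the lifespan.
    """

    cell_id: str
    sample_times: np.ndarray
    sample_x: np.ndarray
    sample_y: np.ndarray
    bandwidth_h: float = DEFAULT_BANDWIDTH_H

    @property
    def t_min(self) -> float:
        return float(self.sample_times[0])

    @property
    def t_max(self) -> float:
        return float(self.sample_times[-1])

    def _weights(self, t: np.ndarray):
        dt = self.sample_times[None, :] - np.asarray(t, float)[:, None]
        z = dt / self.bandwidth_h
        w = np.exp(-0.5 * z * z)
        w[np.abs(z) > KERNEL_TRUNCATION_SIGMAS] = 0.0
        return w, dt

    def position(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed position (x_hat, y_hat) at times ``t``."""
        t = np.atleast_1d(np.asarray(t, float))
        w, _ = self._weights(t)
        den = w.sum(axis=1)
        empty = den == 0.0  # can only happen with sampling gaps > 4 sigma
        if empty.any():
            nearest = np.argmin(
                np.abs(self.sample_times[None, :] - t[empty, None]), axis=1
            )
            w[empty, :] = 0.0
            w[empty, nearest] = 1.0
            den = w.sum(axis=1)
        return (w @ self.sample_x) / den, (w @ self.sample_y) / den

    def velocity(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Analytic derivative of the smoothed position at times ``t``."""
        t = np.atleast_1d(np.asarray(t, float))
        w, dt = self._weights(t)
        den = w.sum(axis=1)
        bad = den == 0.0
        den[bad] = 1.0
        dw = w * dt / self.bandwidth_h**2  # d w_i / d t
        dden = dw.sum(axis=1)
        vx = ((dw @ self.sample_x) * den - (w @ self.sample_x) * dden) / den**2
        vy = ((dw @ self.sample_y) * den - (w @ self.sample_y) * dden) / den**2
        vx[bad] = 0.0
        vy[bad] = 0.0
        return vx, vy

    def speed(self, t) -> np.ndarray:
        vx, vy = self.velocity(t)
        return np.hypot(vx, vy)

    def median_spacing(self) -> float:
        return float(np.median(np.diff(self.sample_times)))


def smooth_trajectory(points, bandwidth_h: float = DEFAULT_BANDWIDTH_H) -> SmoothedTrajectory:
    """Build a smoothed trajectory from one cell's track points.

    ``points`` is a DataFrame with columns cell_id, time_h, x, y (one cell
    only).  Raises :class:`DegenerateTrackError` for fewer than 2 points.
    """
    if isinstance(points, pd.DataFrame):
        if len(points) and points["cell_id"].nunique() > 1:
            raise ParameterError("smooth_trajectory expects points of a single cell")
        cid = str(points["cell_id"].iloc[0]) if len(points) else ""
        t = points["time_h"].to_numpy(float)
        x = points["x"].to_numpy(float)
        y = points["y"].to_numpy(float)
    else:  # (cell_id, t, x, y) tuple
        cid, t, x, y = points
        t, x, y = (np.asarray(a, float) for a in (t, x, y))
    if len(t) < 2:
        raise DegenerateTrackError(f"cell {cid!r}: {len(t)} track point(s), need >= 2")
    if bandwidth_h <= 0:
        raise ParameterError("bandwidth must be positive")
    order = np.argsort(t)
    return SmoothedTrajectory(cid, t[order], x[order], y[order], bandwidth_h)


def smooth_all(ds, cell_ids=None, bandwidth_h: float = DEFAULT_BANDWIDTH_H,
               skip_degenerate: bool = False) -> dict[str, SmoothedTrajectory]:
    """Smoothed trajectories for many cells of a dataset, keyed by cell id."""
    out = {}
    groups = ds.tracks.groupby("cell_id", sort=True)
    ids = cell_ids if cell_ids is not None else [k for k, _ in groups]
    for cid in ids:
        try:
            out[cid] = smooth_trajectory(groups.get_group(cid), bandwidth_h)
        except (KeyError, DegenerateTrackError):
            if not skip_degenerate:
                raise
    return out


def speed_series(st: SmoothedTrajectory, times=None) -> tuple[np.ndarray, np.ndarray]:
    """Speed on an evaluation grid (default: the cell's own sample times)."""
    t = np.asarray(times, float) if times is not None else st.sample_times
    return t, st.speed(t)


def track_length(st: SmoothedTrajectory, t0: float, t1: float,
                 max_step_h: float | None = None) -> float:
    """Arc length of the smoothed trajectory over [t0, t1]: the integral of
    speed by the trapezoid rule on a grid no coarser than the frame
    spacing.  Additive over adjacent intervals to numerical tolerance."""
    if not (t0 < t1):
        raise RangeError(f"empty interval [{t0}, {t1}]")
    eps = 1e-9
    if t0 < st.t_min - eps or t1 > st.t_max + eps:
        raise RangeError(
            f"cell {st.cell_id!r}: [{t0}, {t1}] outside lifespan [{st.t_min}, {st.t_max}]"
        )
    step = max_step_h if max_step_h is not None else st.median_spacing()
    n = max(2, int(np.ceil((t1 - t0) / step)) + 1)
    grid = np.linspace(t0, t1, n)
    return float(np.trapezoid(st.speed(grid), grid))


@dataclass
class PowerMeanSeries:
    """Centered moving generalized mean of speed."""

    center_times: np.ndarray
    values: np.ndarray
    p: float
    window_h: float


def power_mean(values: np.ndarray, p: float) -> float:
    """Generalized power mean M_p = (mean v^p)^(1/p) of non-negative values."""
    v = np.asarray(values, float)
    if p == 1:
        return float(v.mean())
    return float(np.mean(v**p) ** (1.0 / p))


def moving_power_mean(times, speeds, p: float = 1.0,
                      window_h: float = DEFAULT_POWER_MEAN_WINDOW_H) -> PowerMeanSeries:
    """Centered running power mean of a speed series.

    Centers are restricted to times whose full window [t - w/2, t + w/2]
    lies inside the sampled span; a window longer than the span yields an
    empty (not erroneous) series.
    """
    if p < 1:
        raise ParameterError("power-mean order p must be >= 1")
    if window_h <= 0:
        raise ParameterError("window must be positive")
    t = np.asarray(times, float)
    v = np.asarray(speeds, float)
    half = window_h / 2.0
    ok = (t - half >= t[0] - 1e-12) & (t + half <= t[-1] + 1e-12)
    centers = t[ok]
    vals = np.empty(len(centers))
    for i, c in enumerate(centers):
        sel = (t >= c - half - 1e-12) & (t <= c + half + 1e-12)
        vals[i] = power_mean(v[sel], p)
    return PowerMeanSeries(centers, vals, p, window_h)


@dataclass
class SpeedDistribution:
    """Per-time-bin distribution summaries of pooled power-mean speeds."""

    time_edges: np.ndarray
    hist_edges: np.ndarray
    counts: np.ndarray      # (n_time_bins, n_hist_bins)
    n: np.ndarray           # pooled values per time bin
    median: np.ndarray      # NaN where a bin is empty
    q1: np.ndarray
    q3: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_h": self.time_edges[:-1],
                "bin_end_h": self.time_edges[1:],
                "n": self.n,
                "median": self.median,
                "q1": self.q1,
                "q3": self.q3,
            }
        )


def speed_distribution(
    trajectories: dict[str, SmoothedTrajectory],
    time_edges,
    p: float = 1.0,
    window_h: float = DEFAULT_POWER_MEAN_WINDOW_H,
    hist_edges=None,
) -> SpeedDistribution:
    """Pool per-cell moving power-mean speeds into time bins.

    Each cell contributes its M_p values at the window centers falling in a
    bin; fixed histogram edges keep different datasets comparable.
    """
    if not trajectories:
        raise EmptySelectionError("no trajectories selected")
    time_edges = np.asarray(time_edges, float)
    centers_all, values_all = [], []
    for st in trajectories.values():
        series = moving_power_mean(st.sample_times, st.speed(st.sample_times), p, window_h)
        centers_all.append(series.center_times)
        values_all.append(series.values)
    centers = np.concatenate(centers_all) if centers_all else np.empty(0)
    values = np.concatenate(values_all) if values_all else np.empty(0)
    if hist_edges is None:
        top = float(np.max(values)) if len(values) else 1.0
        hist_edges = np.linspace(0.0, max(top, 1e-9), 41)
    hist_edges = np.asarray(hist_edges, float)

    nbins = len(time_edges) - 1
    counts = np.zeros((nbins, len(hist_edges) - 1), dtype=int)
    n = np.zeros(nbins, dtype=int)
    med = np.full(nbins, np.nan)
    q1 = np.full(nbins, np.nan)
    q3 = np.full(nbins, np.nan)
    which = np.digitize(centers, time_edges) - 1
    for b in range(nbins):
        sel = values[which == b]
        n[b] = len(sel)
        if len(sel):
            counts[b] = np.histogram(sel, bins=hist_edges)[0]
            med[b], q1[b], q3[b] = (np.quantile(sel, q) for q in (0.5, 0.25, 0.75))
    return SpeedDistribution(time_edges, hist_edges, counts, n, med, q1, q3)
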