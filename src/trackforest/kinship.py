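"""Sister-cell and lineage-downstream statistics.

The two daughters of a founder's first division ("first-generation
sisters") start from the same place with the same inheritance, so joint
statistics of their subtrees probe heritability and downstream signalling:

* **descendant counts** — for each sister, how many distinct cells are born
  in her subtree within a horizon of the sisters' birth (default 70 h,
  sisters born within 20 h of the recording start);
* **subtree track lengths** — the summed smoothed track length of each
  sister and her descendants, truncated at the sisters' birth + horizon
  (default 60 h, sisters born within 30 h);
* joint densities of these pair statistics, either a Gaussian-smoothed
  histogram on the integer count lattice (bandwidth in count units) or a
  Gaussian product KDE with Scott's bandwidth (covariance scaled by
  n^(-2/(d+4)), d=2);
* **displacement statistics** — with r(t) the displacement of a cell t
  hours after its birth, the mean squared displacement c(t) = r(t)·r(t)
  and the sibling cross-displacement c12(t) = r1(t)·r2(t); c(t)/t is flat
  for memoryless Brownian motion and positive c12(t)/t means sisters keep
  moving together;
* a **memory-time** estimate: the persistence time P of the persistent-
  random-walk (Fürth) form c(t) = 4 D (t - P (1 - exp(-t/P))) fitted to
  the mean MSD curve.

All pair statistics are symmetrized — every pair (v1, v2) enters as both
(v1, v2) and (v2, v1) — so results do not depend on an arbitrary ordering
of sisters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .errors import (
    EmptySelectionError,
    FitError,
    ParameterError,
    RankError,
    UndefinedCorrelationError,
)
from .kinematics import (
    DEFAULT_BANDWIDTH_H,
    SmoothedTrajectory,
    smooth_all,
    track_length,
)
from .lineage import PedigreeForest
from .trackio import FATE_DIVIDED

DEFAULT_DESCENDANT_HORIZON_H = 70.0
DEFAULT_DESCENDANT_BIRTH_WINDOW_H = 20.0
DEFAULT_LENGTH_HORIZON_H = 60.0
DEFAULT_LENGTH_BIRTH_WINDOW_H = 30.0
DEFAULT_COUNT_BANDWIDTH = 1.5  # lattice (count) units
DEFAULT_MSD_T_MAX_H = 15.0

METHOD_SMOOTHED_HISTOGRAM = "GAUSSIAN_SMOOTHED_HISTOGRAM"
METHOD_KDE_SCOTT = "KDE_SCOTT"


@dataclass(frozen=True)
class SisterPair:
    """One first-generation sister pair and a per-subtree statistic.

    The pair is unordered; values are stored in canonical (sorted by
    daughter id) order and every analysis symmetrizes them.
    """

    mother_id: str
    cell_id1: str
    cell_id2: str
    value1: float
    value2: float
    birth_time_h: float


def pairs_to_frame(pairs: list[SisterPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mother_id": [p.mother_id for p in pairs],
            "cell_id1": [p.cell_id1 for p in pairs],
            "cell_id2": [p.cell_id2 for p in pairs],
            "value1": [p.value1 for p in pairs],
            "value2": [p.value2 for p in pairs],
            "birth_time_h": [p.birth_time_h for p in pairs],
        }
    )


def symmetrized(pairs: list[SisterPair]) -> np.ndarray:
    """(2n, 2) array with every pair in both orders."""
    v = np.array([[p.value1, p.value2] for p in pairs], float).reshape(-1, 2)
    return np.vstack([v, v[:, ::-1]]) if len(v) else np.empty((0, 2))


def first_generation_sisters(
    forest: PedigreeForest, birth_window_h: float | None = None
) -> list[tuple[str, str, str, float]]:
    """(root, daughter1, daughter2, birth time) for every root whose first
    division falls within ``birth_window_h`` of the recording start."""
    out = []
    for r in forest.roots:
        rec = forest.record(r)
        if rec.fate != FATE_DIVIDED:
            continue
        tdiv = rec.end_time_h
        if birth_window_h is not None and tdiv > birth_window_h:
            continue
        kids = forest.children(r)
        if len(kids) == 2:
            out.append((r, kids[0], kids[1], tdiv))
    return out


def sister_descendant_pairs(
    forest: PedigreeForest,
    horizon_h: float = DEFAULT_DESCENDANT_HORIZON_H,
    birth_window_h: float = DEFAULT_DESCENDANT_BIRTH_WINDOW_H,
    count_mode: str = "ever_born",
) -> list[SisterPair]:
    """Descendant counts of first-generation sisters within a horizon.

    For each qualifying root, counts per daughter the distinct descendant
    cells (the daughter herself excluded) born within ``horizon_h`` of the
    sisters' birth.  ``count_mode='ever_born'`` counts cumulatively (the
    default reading of "descendants within the horizon");
    ``'alive_at_horizon'`` instead counts descendants still alive then.
    """
    if horizon_h <= 0 or birth_window_h <= 0:
        raise ParameterError("horizons must be positive")
    pairs = []
    for root, d1, d2, tdiv in first_generation_sisters(forest, birth_window_h):
        cutoff = tdiv + horizon_h
        vals = []
        for d in (d1, d2):
            n = 0
            for m in forest.subtree(d):
                if m == d:
                    continue
                rec = forest.record(m)
                if count_mode == "ever_born":
                    n += rec.birth_time_h <= cutoff + 1e-9
                elif count_mode == "alive_at_horizon":
                    n += rec.birth_time_h <= cutoff + 1e-9 and rec.end_time_h > cutoff
                else:
                    raise ParameterError(f"unknown count_mode {count_mode!r}")
            vals.append(float(n))
        pairs.append(SisterPair(root, d1, d2, vals[0], vals[1], tdiv))
    return pairs


def subtree_length_pairs(
    forest: PedigreeForest,
    horizon_h: float = DEFAULT_LENGTH_HORIZON_H,
    birth_window_h: float = DEFAULT_LENGTH_BIRTH_WINDOW_H,
    bandwidth_h: float = DEFAULT_BANDWIDTH_H,
    trajectories: dict[str, SmoothedTrajectory] | None = None,
) -> list[SisterPair]:
    """Total smoothed track length of each sister's subtree.

    Per daughter: the sum over the daughter and every descendant of its
    track length, each truncated to [cell birth, sisters' birth +
    horizon] intersected with the cell's lifespan.  Cells born after the
    horizon contribute nothing, and so do cells observed in fewer than two
    frames (their path is unmeasurable).
    """
    sisters = first_generation_sisters(forest, birth_window_h)
    if trajectories is None:
        needed = sorted({m for _, d1, d2, _ in sisters
                         for d in (d1, d2) for m in forest.subtree(d)})
        trajectories = smooth_all(forest.dataset, needed, bandwidth_h,
                                  skip_degenerate=True)
    pairs = []
    for root, d1, d2, tdiv in sisters:
        cutoff = tdiv + horizon_h
        vals = []
        for d in (d1, d2):
            total = 0.0
            for m in forest.subtree(d):
                st = trajectories.get(m)
                if st is None:
                    continue
                t0 = max(st.t_min, forest.record(m).birth_time_h)
                t1 = min(st.t_max, cutoff)
                if t1 > t0:
                    total += track_length(st, t0, t1)
            vals.append(total)
        pairs.append(SisterPair(root, d1, d2, vals[0], vals[1], tdiv))
    return pairs


@dataclass
class JointDensity:
    """Joint density / smoothed counts of a pair statistic on a grid."""

    grid1: np.ndarray
    grid2: np.ndarray
    values: np.ndarray  # shape (len(grid1), len(grid2))
    method: str
    bandwidth: float | np.ndarray

    def integral(self) -> float:
        """Integral (KDE) or total mass (smoothed histogram) over the grid."""
        if self.method == METHOD_SMOOTHED_HISTOGRAM:
            return float(self.values.sum())
        inner = np.trapezoid(self.values, self.grid2, axis=1)
        return float(np.trapezoid(inner, self.grid1))

    def n_local_maxima(self, rel_threshold: float = 0.2) -> int:
        """Strict 8-neighbourhood local maxima above a fraction of the peak."""
        v = self.values
        peak = v.max()
        footprint = np.ones((3, 3), bool)
        local_max = v == ndimage.maximum_filter(v, footprint=footprint, mode="constant")
        # exclude plateaus counted multiple times: label connected maxima
        labels, n = ndimage.label(local_max & (v > rel_threshold * peak))
        return int(n)


def smoothed_pair_histogram(
    pairs: list[SisterPair], bandwidth: float = DEFAULT_COUNT_BANDWIDTH
) -> JointDensity:
    """Gaussian-smoothed stacked histogram of symmetrized integer pairs.

    Counts are placed on the integer lattice, convolved with an isotropic
    Gaussian of sigma = ``bandwidth`` lattice units (truncated at 4 sigma)
    and renormalized so the total smoothed mass equals twice the number of
    pairs exactly.
    """
    if not pairs:
        raise EmptySelectionError("no sister pairs")
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    pts = symmetrized(pairs)
    vmax = int(np.ceil(pts.max()))
    pad = int(np.ceil(4 * bandwidth))
    size = vmax + pad + 1
    hist = np.zeros((size, size))
    idx = np.rint(pts).astype(int)
    np.add.at(hist, (idx[:, 0], idx[:, 1]), 1.0)
    smoothed = ndimage.gaussian_filter(hist, sigma=bandwidth, truncate=4.0, mode="constant")
    smoothed *= hist.sum() / smoothed.sum()
    grid = np.arange(size, dtype=float)
    return JointDensity(grid, grid, smoothed, METHOD_SMOOTHED_HISTOGRAM, bandwidth)


def joint_kde(
    pairs: list[SisterPair],
    grid_size: int = 101,
    pad_bandwidths: float = 4.0,
) -> JointDensity:
    """Gaussian product KDE of symmetrized pairs with Scott's bandwidth.

    Scott's rule scales the empirical covariance of the (symmetrized)
    sample by n^(-2/(d+4)) with d = 2.  The density is evaluated on a
    square grid extending ``pad_bandwidths`` marginal kernel widths beyond
    the data range; its grid integral is within 2% of 1 when the padding
    is adequate.
    """
    if len(pairs) < 3:
        raise EmptySelectionError("need at least 3 pairs for a KDE")
    pts = symmetrized(pairs)
    cov = np.cov(pts.T)
    if np.linalg.matrix_rank(cov) < 2:
        raise RankError("degenerate pair covariance")
    kde = stats.gaussian_kde(pts.T, bw_method="scott")
    bw_marg = np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=0) - pad_bandwidths * bw_marg
    hi = pts.max(axis=0) + pad_bandwidths * bw_marg
    g1 = np.linspace(lo[0], hi[0], grid_size)
    g2 = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(g1, g2, indexing="ij")
    vals = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return JointDensity(g1, g2, vals, METHOD_KDE_SCOTT, bw_marg)


def pair_correlation(pairs: list[SisterPair]) -> float:
    """Pearson correlation of the symmetrized pair values.

    Symmetrization forces the two marginals to share mean and variance, so
    this is the natural intraclass-style summary of sister similarity.
    """
    if len(pairs) < 3:
        raise EmptySelectionError("need at least 3 pairs")
    pts = symmetrized(pairs)
    if np.var(pts[:, 0]) == 0 or np.var(pts[:, 1]) == 0:
        raise UndefinedCorrelationError("zero variance in pair values")
    return float(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1])


@dataclass
class DisplacementCurves:
    """Birth-aligned displacement statistics on a regular grid.

    ``mean_c`` is the mean squared displacement c(t) averaged over cells
    still alive at birth + t; ``mean_c_over_t`` divides the mean by t
    (0 at t = 0 by convention); ``mean_c12_over_t`` is the sibling
    cross-displacement mean, present when sister pairs were supplied.
    """

    time_h: np.ndarray
    mean_c: np.ndarray
    mean_c_over_t: np.ndarray
    n_cells: np.ndarray
    mean_c12_over_t: np.ndarray | None = None
    n_pairs: np.ndarray | None = None
    label: str = ""
    per_cell_c: dict = field(default_factory=dict, repr=False)
    per_pair_c12: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "t_h": self.time_h,
            "mean_c": self.mean_c,
            "mean_c_over_t": self.mean_c_over_t,
            "n_cells": self.n_cells,
        }
        if self.mean_c12_over_t is not None:
            d["mean_c12_over_t"] = self.mean_c12_over_t
            d["n_pairs"] = self.n_pairs
        return pd.DataFrame(d)


class _Path:
    """Position lookup for birth-relative displacements.

    ``raw`` mode interpolates the observed frame positions linearly; it is
    the default because anchoring displacements at a *smoothed* birth
    position correlates the anchor with the early path and subtracts an
    O(bandwidth) constant from c(t), which breaks the flat-c(t)/t
    diagnostic for memoryless motion.  ``smoothed`` mode evaluates the
    kernel estimate instead (useful when positional noise dominates).
    """

    def __init__(self, t, x, y):
        self.t, self.x, self.y = t, x, y

    @classmethod
    def from_trajectory(cls, st: SmoothedTrajectory, smoothed: bool):
        if smoothed:
            x, y = st.position(st.sample_times)
            return cls(st.sample_times, x, y)
        return cls(st.sample_times, st.sample_x, st.sample_y)

    def position(self, tt):
        return np.interp(tt, self.t, self.x), np.interp(tt, self.t, self.y)

    @property
    def t_max(self):
        return float(self.t[-1])

    @property
    def t_min(self):
        return float(self.t[0])


def _birth_displacements(
    path: _Path, birth: float, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement vectors r(t) from the birth position; rows are NaN
    where the lag exceeds the lifespan (the cell has dropped out).

    Births fall between frames, so the anchor is the first observation at
    or after the recorded birth and every lag is measured from that anchor
    time — anchoring at the nominal birth while sampling the far point at
    ``birth + t`` would shorten each lag by up to one frame interval and
    bias c(t) low at small t.
    """
    anchor = max(birth, path.t_min)
    tt = anchor + times
    ok = tt <= path.t_max + 1e-9
    r = np.full((len(times), 2), np.nan)
    if ok.any():
        x0, y0 = path.position(anchor)
        x, y = path.position(np.clip(tt[ok], path.t_min, path.t_max))
        r[ok, 0] = x - x0
        r[ok, 1] = y - y0
    return r, ok


def msd_curves(
    forest: PedigreeForest,
    cell_ids: list[str],
    t_max_h: float = DEFAULT_MSD_T_MAX_H,
    step_h: float = 0.5,
    bandwidth_h: float = DEFAULT_BANDWIDTH_H,
    trajectories: dict[str, SmoothedTrajectory] | None = None,
    use_smoothed: bool = False,
    label: str = "",
) -> DisplacementCurves:
    """Mean squared displacement of a cohort as a function of time from
    birth.  Cells that die or divide before birth + t drop out of the mean
    at that t; the per-point counts expose the attrition.  Displacements
    are measured on raw frame positions unless ``use_smoothed`` is set
    (see :class:`_Path` for why raw is the default)."""
    if not cell_ids:
        raise EmptySelectionError("empty cohort")
    if trajectories is None:
        trajectories = smooth_all(forest.dataset, sorted(cell_ids), bandwidth_h,
                                  skip_degenerate=True)
    times = np.arange(0.0, t_max_h + step_h / 2, step_h)
    c_sum = np.zeros(len(times))
    n = np.zeros(len(times), dtype=int)
    per_cell = {}
    for cid in cell_ids:
        st = trajectories.get(cid)
        if st is None:
            continue
        path = _Path.from_trajectory(st, use_smoothed)
        birth = forest.record(cid).birth_time_h
        r, ok = _birth_displacements(path, birth, times)
        c = np.einsum("ij,ij->i", r, r)
        per_cell[cid] = c
        c_sum[ok] += c[ok]
        n[ok] += 1
    if n[0] == 0:
        raise EmptySelectionError("no usable trajectories in the cohort")
    mean_c = np.divide(c_sum, n, out=np.full(len(times), np.nan), where=n > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_c_over_t = np.where(times > 0, mean_c / times, 0.0)
    return DisplacementCurves(times, mean_c, mean_c_over_t, n, label=label,
                              per_cell_c=per_cell)


def sibling_cross_msd(
    forest: PedigreeForest,
    sister_ids: list[tuple[str, str]],
    t_max_h: float = DEFAULT_MSD_T_MAX_H,
    step_h: float = 0.5,
    bandwidth_h: float = DEFAULT_BANDWIDTH_H,
    trajectories: dict[str, SmoothedTrajectory] | None = None,
    use_smoothed: bool = False,
    label: str = "",
) -> DisplacementCurves:
    """Mean sibling cross-displacement c12(t)/t = r1(t)·r2(t)/t over sister
    pairs, both sisters required alive at birth + t for inclusion."""
    if not sister_ids:
        raise EmptySelectionError("empty sister cohort")
    if trajectories is None:
        needed = sorted({c for pair in sister_ids for c in pair})
        trajectories = smooth_all(forest.dataset, needed, bandwidth_h,
                                  skip_degenerate=True)
    times = np.arange(0.0, t_max_h + step_h / 2, step_h)
    c12_sum = np.zeros(len(times))
    c_sum = np.zeros(len(times))
    npairs = np.zeros(len(times), dtype=int)
    per_pair = {}
    for c1, c2 in sister_ids:
        st1, st2 = trajectories.get(c1), trajectories.get(c2)
        if st1 is None or st2 is None:
            continue
        b1 = forest.record(c1).birth_time_h
        b2 = forest.record(c2).birth_time_h
        r1, ok1 = _birth_displacements(_Path.from_trajectory(st1, use_smoothed), b1, times)
        r2, ok2 = _birth_displacements(_Path.from_trajectory(st2, use_smoothed), b2, times)
        ok = ok1 & ok2
        c12 = np.einsum("ij,ij->i", r1, r2)
        per_pair[(c1, c2)] = c12
        c12_sum[ok] += c12[ok]
        c_sum[ok] += 0.5 * (np.einsum("ij,ij->i", r1, r1)[ok]
                            + np.einsum("ij,ij->i", r2, r2)[ok])
        npairs[ok] += 1
    if npairs.max() == 0:
        raise EmptySelectionError("no usable sister pairs")
    mean_c12 = np.divide(c12_sum, npairs, out=np.full(len(times), np.nan), where=npairs > 0)
    mean_c = np.divide(c_sum, npairs, out=np.full(len(times), np.nan), where=npairs > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_c12_over_t = np.where(times > 0, mean_c12 / times, 0.0)
        mean_c_over_t = np.where(times > 0, mean_c / times, 0.0)
    return DisplacementCurves(times, mean_c, mean_c_over_t, npairs,
                              mean_c12_over_t=mean_c12_over_t, n_pairs=npairs,
                              label=label, per_pair_c12=per_pair)


def flatness_slope(curves: DisplacementCurves) -> tuple[float, float, float]:
    """Slope of mean c(t)/t against t with a cell-level standard error.

    For memoryless (Brownian) motion c(t)/t is flat, so the slope is a
    directional-persistence diagnostic.  The grid values of the mean curve
    are serially correlated (cells' paths are cumulative), so the naive
    regression standard error is invalid; instead the slope is computed
    per cell — on a common grid the mean of per-cell slopes equals the
    slope of the mean curve — and the standard error taken across cells.
    Returns (slope, stderr, z).  Cells with attrition inside the grid are
    excluded (they would break the mean-of-slopes identity).
    """
    t = curves.time_h
    pos = t > 0
    tc = t[pos] - t[pos].mean()
    denom = float((tc**2).sum())
    slopes = []
    for c in curves.per_cell_c.values():
        y = c[pos] / t[pos]
        if np.isfinite(y).all():
            slopes.append(float((tc * y).sum()) / denom)
    if len(slopes) < 2:
        raise EmptySelectionError("need >= 2 complete cells for the flatness test")
    slopes = np.asarray(slopes)
    se = float(slopes.std(ddof=1) / np.sqrt(len(slopes)))
    mean = float(slopes.mean())
    return mean, se, mean / se if se > 0 else np.inf


def cross_msd_zero_test(curves: DisplacementCurves) -> tuple[float, float, float]:
    """Mean of per-pair time-averaged c12(t)/t with its standard error.

    For independent sisters the statistic is zero in expectation; pairs
    are independent of each other, so the cross-pair standard error is
    valid.  Returns (mean, stderr, z).
    """
    t = curves.time_h
    pos = t > 0
    vals = []
    for c12 in curves.per_pair_c12.values():
        y = c12[pos] / t[pos]
        ok = np.isfinite(y)
        if ok.any():
            vals.append(float(y[ok].mean()))
    if len(vals) < 2:
        raise EmptySelectionError("need >= 2 sister pairs")
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    mean = float(vals.mean())
    return mean, se, mean / se if se > 0 else np.inf


def furth_msd(t, D, P):
    """Persistent-random-walk MSD in 2D: c(t) = 4 D (t - P (1 - exp(-t/P)))."""
    t = np.asarray(t, float)
    return 4.0 * D * (t - P * (1.0 - np.exp(-t / np.maximum(P, 1e-12))))


@dataclass
class MemoryTimeFit:
    """Persistence ("memory") time estimate from a mean MSD curve."""

    persistence_h: float
    diffusion: float
    rss: float
    censored: str | None  # 'low' (below grid step), 'high' (>= t_max), or None

    @property
    def memory_time_h(self) -> float:
        return self.persistence_h


def estimate_memory_time(curves: DisplacementCurves) -> MemoryTimeFit:
    """Fit the Fürth form to mean c(t) and return the persistence time.

    Initialization: 4D from the late plateau of c(t)/t, P from the time at
    which c(t)/t reaches half the plateau (the Fürth curve crosses half
    its plateau near t ≈ 1.6 P).  The fit minimizes *relative* residuals:
    the sampling standard deviation of a mean squared displacement is
    proportional to its value (squared norms of near-Gaussian vectors), so
    relative residuals weight the grid approximately uniformly — an
    unweighted fit lets the noisiest large-t points dominate and roughly
    doubles the variance of P.  P is box-constrained to [grid step,
    10 t_max]; hitting a bound is reported as censoring, with 'high'
    meaning the window never leaves the ballistic regime.
    """
    ok = np.isfinite(curves.mean_c) & (curves.time_h > 0)
    t = curves.time_h[ok]
    c = curves.mean_c[ok]
    if len(t) < 6:
        raise EmptySelectionError("need >= 6 grid points beyond t=0")
    step = float(np.min(np.diff(curves.time_h)))
    t_max = float(t[-1])
    cot = c / t
    plateau = float(np.mean(cot[-max(3, len(t) // 4):]))
    if plateau <= 0:
        return MemoryTimeFit(step, 0.0, float(np.sum(c**2)), "low")
    half_idx = np.argmax(cot >= 0.5 * plateau)
    p0 = float(np.clip(t[half_idx] / 1.6, step, 10 * t_max))
    d0 = plateau / 4.0

    scale = np.maximum(c, 1e-12 * max(float(c.max()), 1e-300))

    def resid(theta):
        D, P = theta
        return (furth_msd(t, D, P) - c) / scale

    try:
        res = optimize.least_squares(
            resid, x0=[d0, p0],
            bounds=([1e-12, step], [np.inf, 10 * t_max]),
            xtol=1e-12, ftol=1e-12,
        )
    except Exception as exc:  # pragma: no cover - scipy internal failure
        raise FitError(f"memory-time fit failed: {exc}") from exc
    if not res.success:
        raise FitError("memory-time fit did not converge",
                       diagnostics={"status": res.status, "message": res.message})
    D, P = res.x
    censored = None
    if P <= step * (1 + 1e-6):
        censored = "low"
    elif P >= t_max:
        censored = "high"
    return MemoryTimeFit(float(P), float(D), float(np.sum(res.fun**2)), censored)
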