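"""Pedigree forests, root-frame selection, tree classification and
population growth curves.

A *pedigree tree* is the rooted binary tree of one founder cell (a cell
present at the start of recording) and all of its descendants; the
*forest* is the set of such trees for all selected founders.  Trees are
classified by what happened to them during recording:

* ``SURVIVING`` — at least one member is alive at the end of recording;
* ``EXTINCT`` — no member survives (everything died or was lost);
* the ``NO_DEATH`` flag marks surviving trees with no death event at all,
  the operational proxy for a resistant subpopulation.

Population growth is summarized as a percentage curve.  ``FROM_START``
curves count cells alive at each grid time among the selected trees as a
percentage of the count at time zero (so they start at 100%).
``POST_FIRST_DIVISION`` curves align each tree at its own first division
and express the tree's census as a percentage of its single founder, then
average across trees; immediately after the first division two daughters
replace one mother, so these curves start at exactly 200%.

The curve is compressed into three numbers by the cubic model

    P3(t) = 100 + a*t + b*t^2 + c*t^3

with the intercept fixed at 100 (the normalization makes it exact), fitted
by least squares on the basis {t, t^2, t^3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import (
    EmptySelectionError,
    InsufficientCellsError,
    LineageError,
    RankError,
)
from .trackio import Dataset, DEATH_FATES, FATE_ALIVE_AT_END, FATE_DIVIDED

MODE_FROM_START = "FROM_START"
MODE_POST_FIRST_DIVISION = "POST_FIRST_DIVISION"

CLASS_NO_DEATH = "NO_DEATH"
CLASS_SURVIVING = "SURVIVING"
CLASS_EXTINCT = "EXTINCT"


@dataclass
class PedigreeForest:
    """A set of disjoint pedigree trees over a dataset.

    ``graph`` is the parent→child digraph restricted to the selected roots
    and their descendants; ``trees`` maps each root id to the sorted list
    of member ids (root included).
    """

    dataset: Dataset
    graph: nx.DiGraph
    roots: list[str]
    trees: dict[str, list[str]] = field(repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.roots)

    def members(self, root: str) -> list[str]:
        return self.trees[root]

    def children(self, cell_id: str) -> list[str]:
        return sorted(self.graph.successors(cell_id))

    def tree_of(self, cell_id: str) -> str:
        return self.graph.nodes[cell_id]["root"]

    def subtree(self, cell_id: str) -> list[str]:
        """The cell and all of its descendants, sorted by id."""
        return sorted({cell_id} | nx.descendants(self.graph, cell_id))

    def record(self, cell_id: str):
        return self.graph.nodes[cell_id]["record"]

    def first_division_time(self, root: str) -> float | None:
        """Time of the earliest division in the tree, or None if none divides."""
        times = [
            self.record(m).end_time_h
            for m in self.trees[root]
            if self.record(m).fate == FATE_DIVIDED
        ]
        return min(times) if times else None


def build_forest(ds: Dataset, roots: list[str] | None = None) -> PedigreeForest:
    """Assemble the pedigree forest of ``roots`` (default: all roots) from a
    validated dataset.  Raises :class:`LineageError` on cyclic parent links."""
    g = nx.DiGraph()
    records = {}
    for row in ds.cells.itertuples(index=False):
        records[row.cell_id] = row
        g.add_node(row.cell_id, record=row)
    for row in ds.cells.itertuples(index=False):
        pid = row.parent_id
        if pid is not None and not (isinstance(pid, float) and np.isnan(pid)):
            if pid not in records:
                raise LineageError(f"cell {row.cell_id}: parent {pid!r} not in cell table")
            g.add_edge(pid, row.cell_id)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise LineageError(f"cycle in parent links: {cycle}")

    all_roots = [cid for cid in records if g.in_degree(cid) == 0]
    if roots is None:
        roots = sorted(all_roots)
    else:
        roots = list(roots)
        bad = [r for r in roots if r not in records or g.in_degree(r) != 0]
        if bad:
            raise LineageError(f"not root cells: {bad}")

    keep: set[str] = set()
    trees: dict[str, list[str]] = {}
    for r in roots:
        members = {r} | nx.descendants(g, r)
        trees[r] = sorted(members)
        keep |= members
    sub = g.subgraph(keep).copy()
    for r in roots:
        for m in trees[r]:
            sub.nodes[m]["root"] = r
    return PedigreeForest(dataset=ds, graph=sub, roots=roots, trees=trees)


def select_root_frame(ds: Dataset, n: int = 100):
    """Select the centered analysis frame that is just large enough to
    contain ``n`` root cells at the start of recording.

    The candidate rectangle is centered at the midpoint of the bounding box
    of all time-zero positions, keeps the field's aspect ratio, and is
    scaled by the minimal factor such that at least ``n`` root positions
    fall inside (boundaries closed).  Returns ``((xmin, ymin, xmax, ymax),
    selected_ids)``.  When several roots sit exactly on the minimal
    boundary all ties are included, so the selection may exceed ``n``.
    """
    roots = ds.root_ids()
    if len(roots) < n:
        raise InsufficientCellsError(f"{len(roots)} root cells present, {n} required")
    t0 = ds.tracks[ds.tracks["frame"] == ds.tracks["frame"].min()]
    t0 = t0[t0["cell_id"].isin(roots)]
    ids = t0["cell_id"].to_numpy()
    if len(ids) < n:
        raise InsufficientCellsError(
            f"only {len(ids)} roots observed at the first frame, {n} required"
        )
    x = t0["x"].to_numpy(float)
    y = t0["y"].to_numpy(float)
    cx, cy = (x.min() + x.max()) / 2.0, (y.min() + y.max()) / 2.0
    hw, hh = (x.max() - x.min()) / 2.0, (y.max() - y.min()) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sx = np.abs(x - cx) / hw if hw > 0 else np.where(np.abs(x - cx) > 0, np.inf, 0.0)
        sy = np.abs(y - cy) / hh if hh > 0 else np.where(np.abs(y - cy) > 0, np.inf, 0.0)
    s = np.maximum(sx, sy)  # minimal scale factor at which each root enters
    s_min = np.sort(s)[n - 1]
    inside = s <= s_min + 1e-12
    rect = (cx - s_min * hw, cy - s_min * hh, cx + s_min * hw, cy + s_min * hh)
    return rect, sorted(ids[inside])


@dataclass(frozen=True)
class TreeClass:
    """Classification of one pedigree tree."""

    surviving: bool
    no_death: bool

    @property
    def label(self) -> str:
        if self.no_death:
            return CLASS_NO_DEATH
        return CLASS_SURVIVING if self.surviving else CLASS_EXTINCT


def classify_trees(forest: PedigreeForest, t_end: float | None = None) -> dict[str, TreeClass]:
    """Classify every tree as surviving/extinct, flagging death-free trees.

    A tree is SURVIVING iff at least one member has fate ALIVE_AT_END; the
    NO_DEATH flag additionally requires that no member died.  LOST cells
    neither confer survival nor count as deaths.
    """
    out = {}
    for r in forest.roots:
        fates = [forest.record(m).fate for m in forest.trees[r]]
        surviving = any(f == FATE_ALIVE_AT_END for f in fates)
        no_death = surviving and not any(f in DEATH_FATES for f in fates)
        out[r] = TreeClass(surviving=surviving, no_death=no_death)
    return out


def filter_roots(forest: PedigreeForest, class_label: str | None,
                 t_end: float | None = None) -> list[str]:
    """Roots whose trees belong to a class (``None`` = all trees)."""
    if class_label is None:
        return list(forest.roots)
    classes = classify_trees(forest, t_end)
    return [r for r in forest.roots if classes[r].label == class_label
            or (class_label == CLASS_SURVIVING and classes[r].surviving)]


@dataclass
class GrowthCurve:
    """Percentage population-size curve on a regular time grid."""

    time_h: np.ndarray
    percent: np.ndarray
    mode: str
    label: str = ""
    n_trees: int = 0
    n_at_grid: np.ndarray | None = None  # trees contributing per grid point


@dataclass
class GrowthFit:
    """Cubic growth-model coefficients with fixed 100% intercept."""

    a: float
    b: float
    c: float
    rss: float
    intercept: float = 100.0

    def __call__(self, t):
        t = np.asarray(t, float)
        return self.intercept + self.a * t + self.b * t**2 + self.c * t**3


def _alive_matrix(forest: PedigreeForest, roots: list[str], times: np.ndarray) -> np.ndarray:
    """counts[i, j] = number of cells of tree roots[i] alive at times[j].

    A cell is alive at t iff birth <= t < end, except that a cell alive at
    the end of recording is also counted at t == end.  Half-open lifespans
    avoid double counting at division: at the division instant the mother
    is out and her daughters are in.
    """
    counts = np.zeros((len(roots), len(times)))
    for i, r in enumerate(roots):
        for m in forest.trees[r]:
            rec = forest.record(m)
            if rec.fate == FATE_ALIVE_AT_END:
                alive = (times >= rec.birth_time_h - 1e-12) & (times <= rec.end_time_h + 1e-12)
            else:
                alive = (times >= rec.birth_time_h - 1e-12) & (times < rec.end_time_h - 1e-12)
            counts[i] += alive
    return counts


def population_growth_curve(
    forest: PedigreeForest,
    class_label: str | None = None,
    mode: str = MODE_FROM_START,
    step_h: float | None = None,
    t_end: float | None = None,
) -> GrowthCurve:
    """Compute a percentage growth curve for one class of trees.

    FROM_START: census of all selected trees on the absolute time grid as a
    percentage of the time-zero census.  POST_FIRST_DIVISION: per-tree
    census aligned at the tree's first division, as a percentage of the
    single founder (200% immediately after the division), averaged without
    weights across the trees that have divided and are still being
    recorded at each aligned time.
    """
    step = step_h if step_h is not None else forest.dataset.meta.frame_interval_h
    duration = t_end if t_end is not None else forest.dataset.meta.duration_h
    roots = filter_roots(forest, class_label, duration)
    if not roots:
        raise EmptySelectionError(f"no trees in class {class_label!r}")
    label = class_label or "ALL"

    if mode == MODE_FROM_START:
        times = np.arange(0.0, duration + step / 2, step)
        counts = _alive_matrix(forest, roots, times).sum(axis=0)
        if counts[0] == 0:
            raise EmptySelectionError("no cells alive at t=0 in the selection")
        percent = 100.0 * counts / counts[0]
        return GrowthCurve(times, percent, mode, label, len(roots),
                           np.full(len(times), len(roots)))

    if mode != MODE_POST_FIRST_DIVISION:
        raise ValueError(f"unknown mode {mode!r}")

    div_roots = [(r, forest.first_division_time(r)) for r in roots]
    div_roots = [(r, t) for r, t in div_roots if t is not None]
    if not div_roots:
        raise EmptySelectionError("no dividing trees in the selection")
    horizon = max(duration - t for _, t in div_roots)
    times = np.arange(0.0, horizon + step / 2, step)
    total = np.zeros(len(times))
    n_at = np.zeros(len(times), dtype=int)
    for r, tdiv in div_roots:
        valid = times <= duration - tdiv + 1e-9
        counts = _alive_matrix(forest, [r], tdiv + times[valid])[0]
        total[valid] += 100.0 * counts  # founder count is 1 by construction
        n_at[valid] += 1
    percent = np.divide(total, n_at, out=np.full_like(total, np.nan), where=n_at > 0)
    return GrowthCurve(times, percent, mode, label, len(div_roots), n_at)


def fit_growth_polynomial(curve: GrowthCurve) -> GrowthFit:
    """Least-squares fit of the cubic growth model to a FROM_START curve.

    The intercept is not a free parameter: y - 100 is regressed on the
    basis {t, t^2, t^3}, so the fitted polynomial equals 100 at t = 0
    exactly.
    """
    if curve.mode != MODE_FROM_START:
        raise ValueError("growth polynomial is defined for FROM_START curves")
    t = np.asarray(curve.time_h, float)
    y = np.asarray(curve.percent, float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 4:
        raise RankError("need at least 4 grid points to fit a cubic")
    if np.ptp(t) == 0:
        raise RankError("degenerate time grid (all times equal)")
    basis = np.column_stack([t, t**2, t**3])
    coef, _, rank, _ = np.linalg.lstsq(basis, y - 100.0, rcond=None)
    if rank < 3:
        raise RankError("rank-deficient design matrix")
    resid = y - 100.0 - basis @ coef
    return GrowthFit(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
                     rss=float(resid @ resid))


def largest_trees(forest: PedigreeForest, k: int = 30, by: str = "final_count",
                  t_end: float | None = None) -> list[str]:
    """The ``k`` largest trees, ranked by number of members alive at the end
    of recording (``final_count``, default) or by total cells ever born
    (``total_ever``).  Ties break by root id."""
    duration = t_end if t_end is not None else forest.dataset.meta.duration_h
    if by == "final_count":
        counts = _alive_matrix(forest, forest.roots, np.array([duration]))[:, 0]
        sizes = {r: counts[i] for i, r in enumerate(forest.roots)}
    elif by == "total_ever":
        sizes = {r: len(forest.trees[r]) for r in forest.roots}
    else:
        raise ValueError(f"unknown ranking {by!r}")
    ranked = sorted(forest.roots, key=lambda r: (-sizes[r], r))
    return ranked[:k]
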