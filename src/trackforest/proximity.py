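"""Detection of prolonged cell–cell proximity events.

Two concurrently-alive cells staying within a distance threshold for an
extended period is a proxy for physical contact, communication or material
exchange.  An event is a maximal interval during which the center-to-center
distance of a pair stays at or below the threshold, with interruptions no
longer than ``max_gap`` tolerated (a single missing or flickering frame
does not split an event).  Proximity within ``birth_exclusion`` hours of
either cell's birth is ignored — sisters are trivially adjacent right
after division — and only intervals of at least ``min_duration`` hours are
reported (defaults: 4 h minimum duration, 2 h birth exclusion).

The detector prefilters candidate pairs per frame with a k-d tree; its
output contract is exact equivalence to the brute-force all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, ParameterError
from .lineage import PedigreeForest
from .trackio import Dataset

DEFAULT_MIN_DURATION_H = 4.0
DEFAULT_BIRTH_EXCLUSION_H = 2.0

REL_SISTERS = "sisters"
REL_SAME_TREE = "same_tree"
REL_DIFFERENT_TREES = "different_trees"


@dataclass(frozen=True)
class ProximityEvent:
    """One maximal proximity interval of an unordered cell pair."""

    cell_a: str
    cell_b: str
    t_start_h: float
    t_end_h: float
    min_dist: float
    mean_dist: float
    relationship: str

    @property
    def duration_h(self) -> float:
        return self.t_end_h - self.t_start_h


def _relationship(ds: Dataset, a: str, b: str) -> str:
    cells = ds.cells.set_index("cell_id")
    pa, pb = cells.loc[a, "parent_id"], cells.loc[b, "parent_id"]
    if pa is not None and pa == pb:
        return REL_SISTERS
    # walk to roots
    def root_of(c):
        seen = set()
        while True:
            p = cells.loc[c, "parent_id"]
            if p is None or (isinstance(p, float) and np.isnan(p)) or p in seen:
                return c
            seen.add(c)
            c = p
    return REL_SAME_TREE if root_of(a) == root_of(b) else REL_DIFFERENT_TREES


def detect_proximity_events(
    ds: Dataset,
    threshold: float,
    min_duration_h: float = DEFAULT_MIN_DURATION_H,
    birth_exclusion_h: float = DEFAULT_BIRTH_EXCLUSION_H,
    max_gap_h: float | None = None,
    exclusion_mode: str = "both_births",
) -> list[ProximityEvent]:
    """Find all proximity events in a dataset from raw frame-grid positions.

    ``exclusion_mode='both_births'`` drops proximity within the exclusion
    window after either cell's birth; ``'sisters_only'`` applies the
    exclusion only to sister pairs.  Events are sorted by start time, then
    by the pair ids.
    """
    if threshold <= 0:
        raise ParameterError("distance threshold must be positive")
    if max_gap_h is None:
        max_gap_h = ds.meta.frame_interval_h
    step = ds.meta.frame_interval_h

    births = dict(zip(ds.cells["cell_id"], ds.cells["birth_time_h"]))
    parents = dict(zip(ds.cells["cell_id"], ds.cells["parent_id"]))

    # collect, per unordered pair, the frame times at which they are close
    pair_hits: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for _, frame_df in ds.tracks.groupby("frame", sort=True):
        ids = frame_df["cell_id"].to_numpy()
        if len(ids) < 2:
            continue
        xy = frame_df[["x", "y"]].to_numpy(float)
        t = float(frame_df["time_h"].iloc[0])
        tree = cKDTree(xy)
        # query radius slightly expanded so exact-threshold contacts are kept
        for i, j in tree.query_pairs(threshold * (1 + 1e-9)):
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d <= threshold * (1 + 1e-12):
                a, b = sorted((ids[i], ids[j]))
                pair_hits.setdefault((a, b), []).append((t, d))

    events: list[ProximityEvent] = []
    for (a, b), hits in pair_hits.items():
        hits.sort()
        sisters = parents.get(a) is not None and parents.get(a) == parents.get(b)
        if exclusion_mode == "both_births" or (exclusion_mode == "sisters_only" and sisters):
            t_ok = max(births[a], births[b]) + birth_exclusion_h
        else:
            t_ok = -np.inf
        hits = [(t, d) for t, d in hits if t >= t_ok - 1e-12]
        if not hits:
            continue
        rel = None
        runs: list[list[tuple[float, float]]] = [[hits[0]]]
        for t, d in hits[1:]:
            if t - runs[-1][-1][0] <= step + max_gap_h + 1e-9:
                runs[-1].append((t, d))
            else:
                runs.append([(t, d)])
        for run in runs:
            t0, t1 = run[0][0], run[-1][0]
            if t1 - t0 >= min_duration_h - 1e-9:
                dists = np.array([d for _, d in run])
                if rel is None:
                    rel = _relationship(ds, a, b)
                events.append(
                    ProximityEvent(a, b, t0, t1, float(dists.min()),
                                   float(dists.mean()), rel)
                )
    events.sort(key=lambda e: (e.t_start_h, e.cell_a, e.cell_b))
    return events


@dataclass
class ForestAnnotation:
    """Proximity events attached to the trees of a pedigree forest."""

    per_tree_events: dict[str, list[ProximityEvent]]
    within_tree_counts: dict[str, int]
    cross_tree_counts: dict[str, int]
    n_within: int
    n_cross: int


def annotate_forest(forest: PedigreeForest, events: list[ProximityEvent]) -> ForestAnnotation:
    """Attach each event to the tree(s) of its members.

    A within-tree event is attached once; a cross-tree event is attached to
    both trees, so the cross-tree attachments sum to twice the number of
    cross-tree events (conservation).
    """
    per_tree: dict[str, list[ProximityEvent]] = {r: [] for r in forest.roots}
    within = {r: 0 for r in forest.roots}
    cross = {r: 0 for r in forest.roots}
    n_within = n_cross = 0
    for ev in events:
        for cid in (ev.cell_a, ev.cell_b):
            if cid not in forest.graph.nodes:
                raise ConsistencyError(f"event references unknown cell {cid!r}")
        ra, rb = forest.tree_of(ev.cell_a), forest.tree_of(ev.cell_b)
        if ra == rb:
            per_tree[ra].append(ev)
            within[ra] += 1
            n_within += 1
        else:
            per_tree[ra].append(ev)
            per_tree[rb].append(ev)
            cross[ra] += 1
            cross[rb] += 1
            n_cross += 1
    return ForestAnnotation(per_tree, within, cross, n_within, n_cross)
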