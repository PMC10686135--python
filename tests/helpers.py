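"""Hand-built datasets and brute-force oracles shared across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from trackforest.trackio import Dataset, DatasetMeta


def make_dataset(cell_rows, track_rows, frame_interval_h=1.0, duration_h=None):
    """Build a Dataset from explicit row tuples.

    ``cell_rows``: (cell_id, parent_id, birth, end, fate);
    ``track_rows``: (cell_id, frame, time_h, x, y).
    """
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "parent_id", "birth_time_h", "end_time_h", "fate"]
    )
    tracks = pd.DataFrame(track_rows, columns=["cell_id", "frame", "time_h", "x", "y"])
    tracks = tracks.astype({"frame": np.int64, "time_h": float, "x": float, "y": float})
    if duration_h is None:
        duration_h = float(cells["end_time_h"].max()) if len(cells) else 1.0
    return Dataset(tracks, cells, DatasetMeta(frame_interval_h, duration_h))


def linear_track(cell_id, t0, t1, step, x0, y0, vx, vy, frame_offset=0):
    """Track rows for a cell moving uniformly from (x0, y0)."""
    times = np.arange(t0, t1 + step / 2, step)
    return [
        (cell_id, frame_offset + i, float(t), x0 + vx * (t - t0), y0 + vy * (t - t0))
        for i, t in enumerate(times)
    ]


def brute_force_frame_selection(x, y, n):
    """Scan every candidate scale factor for the minimal centered frame."""
    cx, cy = (x.min() + x.max()) / 2, (y.min() + y.max()) / 2
    hw, hh = (x.max() - x.min()) / 2, (y.max() - y.min()) / 2
    s = np.maximum(np.abs(x - cx) / hw, np.abs(y - cy) / hh)
    best = None
    for cand in np.sort(s):
        inside = s <= cand + 1e-12
        if inside.sum() >= n:
            best = (cand, inside)
            break
    return best


def brute_force_proximity_frames(ds, threshold):
    """All-pairs scan: per unordered pair, the frame times at distance <= threshold."""
    out = {}
    for _, g in ds.tracks.groupby("frame"):
        ids = g["cell_id"].to_numpy()
        xy = g[["x", "y"]].to_numpy(float)
        t = float(g["time_h"].iloc[0])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = float(np.hypot(*(xy[i] - xy[j])))
                if d <= threshold * (1 + 1e-12):
                    key = tuple(sorted((ids[i], ids[j])))
                    out.setdefault(key, []).append((t, d))
    return out
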