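"""Synthetic single-cell tracking datasets.

The generator emulates a time-lapse recording of an adherent monolayer:
root cells scattered uniformly over a rectangular field at time zero,
binary divisions, two death modes with constant hazards, heritable
per-lineage traits, persistent 2D motion and additive positional
measurement noise, observed on a regular frame grid.  Defaults mirror a
94 h recording at 6-min frames with enough roots (200) that a 100-cell
analysis frame can be selected.

Motion follows a persistent random walk: each velocity component is an
Ornstein–Uhlenbeck process with relaxation (persistence) time P and
stationary variance sigma_v^2, advanced with its *exact* discretization at
every step, so the mean squared displacement obeys the Fürth form

    c(t) = 4 D (t - P (1 - exp(-t/P))),   D = sigma_v^2 P,

exactly in expectation — the family presupposed by the displacement
diagnostics (flat c(t)/t for Brownian motion, a finite memory time for
persistent motion).  A ``brownian`` mode replaces this with pure diffusion
at a given constant D.

Heritability: each lineage carries a division-time trait and a
log-speed multiplier, mixed at every division as
``trait_child = w * trait_parent + (1 - w) * population_draw`` with the
heritability weight w in [0, 1].  A configurable fraction of root
lineages is "resistant" (zero death hazard), and the division-time
population can be a mixture (distinct lineage types).  Sisters can share
their initial heading (correlated initial velocities) and optionally feel
a transient mutual spring attraction after division.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParameterError
from .trackio import (
    Dataset,
    DatasetMeta,
    FATE_ALIVE_AT_END,
    FATE_DEATH_APOPTOTIC,
    FATE_DEATH_NECROTIC,
    FATE_DIVIDED,
    FATE_LOST,
)

MOTION_PRW = "prw"
MOTION_BROWNIAN = "brownian"


@dataclass
class SimConfig:
    """Parameters of the synthetic recording.

    Times are hours, lengths micrometres (or whatever ``spatial_unit``
    says).  ``speed_scale`` is the stationary per-component velocity
    standard deviation of the persistent random walk, in length units per
    hour; ``diffusion`` is only used in ``brownian`` mode.  Division times
    are drawn per cell from Normal(lineage trait, ``division_sd_h``);
    ``division_mean_h`` may be a single mean or a list of ``(mean,
    weight)`` mixture components defining distinct lineage types.
    ``math.inf`` for the division mean disables division.
    """

    duration_h: float = 94.0
    frame_interval_h: float = 0.1          # 6-min frames
    field_width: float = 1400.0
    field_height: float = 1050.0
    n_roots: int = 200
    spatial_unit: str = "um"
    exposure: str = "synthetic"

    motion: str = MOTION_PRW
    speed_scale: float = 15.0              # um/h per velocity component
    persistence_h: float = 3.0
    diffusion: float = 675.0               # um^2/h, brownian mode only

    division_mean_h: float | list = 22.0
    division_sd_h: float = 3.0
    heritability: float = 0.5
    death_hazard_apoptotic: float = 0.004  # per hour
    death_hazard_necrotic: float = 0.002
    lost_hazard: float = 0.0
    resistant_fraction: float = 0.2
    speed_mult_sd: float = 0.3             # lognormal sd of lineage speed factor

    sister_coupling: float = 0.5           # shared-heading weight, 0..1
    sister_attraction: float = 0.0         # spring rate (1/h) toward the sister
    sister_attraction_duration_h: float = 0.0
    noise_sd: float = 0.5                  # positional measurement noise
    max_generations: int | None = None     # cells of this generation never divide

    def validate(self) -> None:
        if not (0 < self.frame_interval_h < self.duration_h):
            raise ConfigError("frame interval must be positive and below the duration")
        if self.n_roots < 1:
            raise ConfigError("need at least one root cell")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ConfigError("field dimensions must be positive")
        if self.motion not in (MOTION_PRW, MOTION_BROWNIAN):
            raise ConfigError(f"unknown motion model {self.motion!r}")
        for name in ("speed_scale", "persistence_h", "diffusion", "division_sd_h",
                     "death_hazard_apoptotic", "death_hazard_necrotic", "lost_hazard",
                     "speed_mult_sd", "sister_attraction",
                     "sister_attraction_duration_h", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.motion == MOTION_PRW and self.persistence_h == 0:
            raise ConfigError("PRW persistence time must be positive")
        for name in ("heritability", "sister_coupling"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 <= self.resistant_fraction <= 1:
            raise ConfigError("resistant_fraction must be in [0, 1]")
        for mean, _ in self._division_components():
            if mean <= 0:
                raise ConfigError("division mean must be positive")

    def _division_components(self) -> list[tuple[float, float]]:
        if isinstance(self.division_mean_h, (int, float)):
            return [(float(self.division_mean_h), 1.0)]
        comps = [(float(m), float(w)) for m, w in self.division_mean_h]
        total = sum(w for _, w in comps)
        if total <= 0:
            raise ConfigError("division mixture weights must sum to > 0")
        return [(m, w / total) for m, w in comps]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if isinstance(d["division_mean_h"], list):
            d["division_mean_h"] = [list(c) for c in d["division_mean_h"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(d.get("division_mean_h"), list):
            d["division_mean_h"] = [tuple(c) for c in d["division_mean_h"]]
        return cls(**d)


@dataclass
class _Lineage:
    division_trait_h: float
    log_speed_mult: float
    resistant: bool


@dataclass
class _PendingCell:
    cell_id: str
    parent_id: str | None
    birth_h: float
    x: float
    y: float
    vx: float
    vy: float
    lineage: _Lineage
    generation: int = 0
    partner: str | None = None  # sister id, for attraction coupling


def _ou_step_coeffs(dt: float, sigma: float, P: float):
    """Exact one-step transition of an integrated OU velocity component.

    Returns (lam, pos_gain, L) with v' = lam*v + eta_v, dx = pos_gain*v +
    eta_x and (eta_v, eta_x) = L @ standard normal pair.
    """
    lam = math.exp(-dt / P)
    s2 = sigma * sigma
    svv = s2 * (1.0 - lam * lam)
    sxx = s2 * (2.0 * P * dt - P * P * (3.0 - 4.0 * lam + lam * lam))
    sxv = s2 * P * (1.0 - lam) ** 2
    l11 = math.sqrt(max(svv, 0.0))
    l21 = sxv / l11 if l11 > 0 else 0.0
    l22 = math.sqrt(max(sxx - l21 * l21, 0.0))
    return lam, P * (1.0 - lam), np.array([[l11, 0.0], [l21, l22]])


class _Simulator:
    def __init__(self, cfg: SimConfig, seed: int):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.step = cfg.frame_interval_h
        self.track_rows: list[tuple] = []
        self.cell_rows: list[tuple] = []
        self._next_id = 1

    # ---------- trait machinery ----------

    def _pop_division_trait(self) -> float:
        comps = self.cfg._division_components()
        if len(comps) == 1:
            return comps[0][0]
        means = np.array([m for m, _ in comps])
        weights = np.array([w for _, w in comps])
        return float(means[self.rng.choice(len(means), p=weights)])

    def _pop_log_speed(self) -> float:
        if self.cfg.speed_mult_sd == 0:
            return 0.0
        return float(self.rng.normal(0.0, self.cfg.speed_mult_sd))

    def _inherit(self, lin: _Lineage) -> _Lineage:
        w = self.cfg.heritability
        return _Lineage(
            division_trait_h=w * lin.division_trait_h + (1 - w) * self._pop_division_trait(),
            log_speed_mult=w * lin.log_speed_mult + (1 - w) * self._pop_log_speed(),
            resistant=lin.resistant,
        )

    def _new_id(self) -> str:
        cid = f"C{self._next_id:06d}"
        self._next_id += 1
        return cid

    # ---------- lifespan ----------

    def _waits(self, lin: _Lineage, generation: int = 0) -> tuple[float, str]:
        """Time from birth to the terminal event and its fate label."""
        cfg = self.cfg
        capped = (cfg.max_generations is not None
                  and generation >= cfg.max_generations)
        if capped or math.isinf(lin.division_trait_h):
            t_div = math.inf
        elif cfg.division_sd_h == 0:
            t_div = lin.division_trait_h
        else:
            t_div = max(float(self.rng.normal(lin.division_trait_h, cfg.division_sd_h)),
                        2 * self.step)
        draws = [(t_div, FATE_DIVIDED)]
        hazards = [
            (0.0 if lin.resistant else cfg.death_hazard_apoptotic, FATE_DEATH_APOPTOTIC),
            (0.0 if lin.resistant else cfg.death_hazard_necrotic, FATE_DEATH_NECROTIC),
            (cfg.lost_hazard, FATE_LOST),
        ]
        for h, fate in hazards:
            if h > 0:
                draws.append((max(float(self.rng.exponential(1.0 / h)), 2 * self.step), fate))
        return min(draws, key=lambda d: d[0])

    # ---------- motion ----------

    def _knots(self, birth: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """(knot times incl. birth and end, mask of knots that are frames)."""
        k0 = int(math.ceil(birth / self.step - 1e-9))
        k1 = int(math.floor(end / self.step + 1e-9))
        frames = np.arange(k0, k1 + 1) * self.step
        knots = np.concatenate(([birth], frames, [end]))
        is_frame = np.concatenate(([False], np.ones(len(frames), bool), [False]))
        # merge duplicates (birth or end on the grid)
        keep = np.concatenate(([True], np.diff(knots) > 1e-12))
        merged_frame = is_frame.copy()
        for i in np.flatnonzero(~keep):
            merged_frame[i - 1] = merged_frame[i - 1] or is_frame[i]
        return knots[keep], merged_frame[keep]

    def _prw_path(self, knots, x0, y0, vx0, vy0, sigma):
        P = self.cfg.persistence_h
        n = len(knots)
        xs = np.empty((n, 2))
        vs = np.empty((n, 2))
        xs[0] = (x0, y0)
        vs[0] = (vx0, vy0)
        for i in range(1, n):
            dt = knots[i] - knots[i - 1]
            lam, gain, L = _ou_step_coeffs(dt, sigma, P)
            eta = (L @ self.rng.standard_normal((2, 2))).T  # rows: axis, cols: (v, x)
            vs[i] = lam * vs[i - 1] + eta[:, 0]
            xs[i] = xs[i - 1] + gain * vs[i - 1] + eta[:, 1]
        return xs, vs

    def _brownian_path(self, knots, x0, y0, sigma_scale):
        D = self.cfg.diffusion * sigma_scale**2
        dts = np.diff(knots)
        steps = self.rng.standard_normal((len(dts), 2)) * np.sqrt(2 * D * dts)[:, None]
        xs = np.vstack([[x0, y0], np.cumsum(steps, axis=0) + [x0, y0]])
        return xs, np.zeros_like(xs)

    def _emit(self, cell: _PendingCell, end: float, fate: str, knots, is_frame, xs):
        n = int(is_frame.sum())
        noise = (self.rng.standard_normal((n, 2)) * self.cfg.noise_sd
                 if self.cfg.noise_sd > 0 else 0.0)
        obs = xs[is_frame] + noise
        t = knots[is_frame]
        frames = np.rint(t / self.step).astype(np.int64)
        self.track_rows.append((np.repeat(cell.cell_id, n), frames, t, obs))
        self.cell_rows.append((cell.cell_id, cell.parent_id, cell.birth_h, end, fate))

    # ---------- cell processing ----------

    def _process(self, cell: _PendingCell) -> list[_PendingCell]:
        cfg = self.cfg
        wait, fate = self._waits(cell.lineage, cell.generation)
        end = cell.birth_h + wait
        if end >= cfg.duration_h - 1e-12:
            end, fate = cfg.duration_h, FATE_ALIVE_AT_END
        knots, is_frame = self._knots(cell.birth_h, end)
        sigma = cfg.speed_scale * math.exp(cell.lineage.log_speed_mult)
        if cfg.motion == MOTION_BROWNIAN:
            xs, vs = self._brownian_path(knots, cell.x, cell.y,
                                         math.exp(cell.lineage.log_speed_mult))
        else:
            xs, vs = self._prw_path(knots, cell.x, cell.y, cell.vx, cell.vy, sigma)
        self._emit(cell, end, fate, knots, is_frame, xs)
        if fate != FATE_DIVIDED:
            return []
        return self._spawn_daughters(cell, end, xs[-1], sigma)

    def _spawn_daughters(self, cell: _PendingCell, t_div: float, pos, sigma):
        cfg = self.cfg
        c = cfg.sister_coupling
        shared = self.rng.standard_normal(2) * sigma
        daughters = []
        ids = (self._new_id(), self._new_id())
        for i in range(2):
            indep = self.rng.standard_normal(2) * sigma
            v = c * shared + math.sqrt(max(1 - c * c, 0.0)) * indep
            lin = self._inherit(cell.lineage)
            daughters.append(
                _PendingCell(ids[i], cell.cell_id, t_div, float(pos[0]), float(pos[1]),
                             float(v[0]), float(v[1]), lin,
                             generation=cell.generation + 1,
                             partner=ids[1 - i] if cfg.sister_attraction > 0 else None)
            )
        return daughters

    # ---------- attracted sister pairs ----------

    def _process_attracted_pair(self, c1: _PendingCell, c2: _PendingCell):
        """Joint simulation of two sisters with a transient mutual spring.

        During the attraction window each position is pulled toward the
        sister by rate*distance per hour (Euler coupling on top of the
        exact OU step); afterwards the cells continue independently.
        """
        cfg = self.cfg
        out = []
        waits = [self._waits(c.lineage, c.generation) for c in (c1, c2)]
        ends, fates = [], []
        for c, (w, f) in zip((c1, c2), waits):
            e = c.birth_h + w
            if e >= cfg.duration_h - 1e-12:
                e, f = cfg.duration_h, FATE_ALIVE_AT_END
            ends.append(e)
            fates.append(f)
        t_stop = min(min(ends), c1.birth_h + cfg.sister_attraction_duration_h)
        paths = []
        if t_stop > c1.birth_h + 1e-12:
            knots, is_frame = self._knots(c1.birth_h, t_stop)
            sig = [cfg.speed_scale * math.exp(c.lineage.log_speed_mult) for c in (c1, c2)]
            P = cfg.persistence_h
            xs = [np.empty((len(knots), 2)) for _ in range(2)]
            vs = [np.empty((len(knots), 2)) for _ in range(2)]
            for j, c in enumerate((c1, c2)):
                xs[j][0] = (c.x, c.y)
                vs[j][0] = (c.vx, c.vy)
            for i in range(1, len(knots)):
                dt = knots[i] - knots[i - 1]
                for j in range(2):
                    lam, gain, L = _ou_step_coeffs(dt, sig[j], P)
                    eta = (L @ self.rng.standard_normal((2, 2))).T
                    vs[j][i] = lam * vs[j][i - 1] + eta[:, 0]
                    xs[j][i] = xs[j][i - 1] + gain * vs[j][i - 1] + eta[:, 1]
                pull = cfg.sister_attraction * dt * (xs[1][i] - xs[0][i])
                xs[0][i] = xs[0][i] + pull
                xs[1][i] = xs[1][i] - pull
            paths = [(knots, is_frame, xs[0], vs[0]), (knots, is_frame, xs[1], vs[1])]
        for j, c in enumerate((c1, c2)):
            sigma = cfg.speed_scale * math.exp(c.lineage.log_speed_mult)
            if paths:
                knots, is_frame, x_j, v_j = paths[j]
                if ends[j] > t_stop + 1e-12:  # independent continuation
                    knots2, is_frame2 = self._knots(t_stop, ends[j])
                    xs2, _ = self._prw_path(knots2, x_j[-1][0], x_j[-1][1],
                                            v_j[-1][0], v_j[-1][1], sigma)
                    knots = np.concatenate([knots, knots2[1:]])
                    is_frame = np.concatenate([is_frame, is_frame2[1:]])
                    x_j = np.vstack([x_j, xs2[1:]])
                self._emit(c, ends[j], fates[j], knots, is_frame, x_j)
                end_pos = x_j[-1]
            else:
                knots, is_frame = self._knots(c.birth_h, ends[j])
                xs, _ = self._prw_path(knots, c.x, c.y, c.vx, c.vy, sigma)
                self._emit(c, ends[j], fates[j], knots, is_frame, xs)
                end_pos = xs[-1]
            if fates[j] == FATE_DIVIDED:
                out.extend(self._spawn_daughters(c, ends[j], end_pos, sigma))
        return out

    # ---------- driver ----------

    def run(self) -> Dataset:
        cfg = self.cfg
        queue: list[_PendingCell] = []
        for _ in range(cfg.n_roots):
            cid = self._new_id()
            x = float(self.rng.uniform(0, cfg.field_width))
            y = float(self.rng.uniform(0, cfg.field_height))
            lin = _Lineage(
                division_trait_h=self._pop_division_trait(),
                log_speed_mult=self._pop_log_speed(),
                resistant=bool(self.rng.random() < cfg.resistant_fraction),
            )
            sigma = cfg.speed_scale * math.exp(lin.log_speed_mult)
            v = self.rng.standard_normal(2) * sigma
            queue.append(_PendingCell(cid, None, 0.0, x, y, float(v[0]), float(v[1]), lin))
        i = 0
        while i < len(queue):
            cell = queue[i]
            if cell.partner is not None:
                partner = next(c for c in queue[i + 1:] if c.cell_id == cell.partner)
                queue.extend(self._process_attracted_pair(cell, partner))
                queue.remove(partner)
            else:
                queue.extend(self._process(cell))
            i += 1

        tracks = pd.DataFrame(
            {
                "cell_id": np.concatenate([r[0] for r in self.track_rows]),
                "frame": np.concatenate([r[1] for r in self.track_rows]),
                "time_h": np.concatenate([r[2] for r in self.track_rows]),
                "x": np.concatenate([r[3][:, 0] for r in self.track_rows]),
                "y": np.concatenate([r[3][:, 1] for r in self.track_rows]),
            }
        )
        tracks = tracks.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
        cells = pd.DataFrame(self.cell_rows,
                             columns=["cell_id", "parent_id", "birth_time_h",
                                      "end_time_h", "fate"])
        cells = cells.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
        meta = DatasetMeta(cfg.frame_interval_h, cfg.duration_h, cfg.exposure,
                           cfg.spatial_unit)
        return Dataset(tracks, cells, meta)


def simulate_forest(cfg: SimConfig, seed: int) -> Dataset:
    """Simulate a tracking dataset; reproducible given (cfg, seed)."""
    return _Simulator(cfg, seed).run()


def perturb_positions(ds: Dataset, sd: float, seed: int) -> Dataset:
    """Add i.i.d. Gaussian noise of standard deviation ``sd`` to every
    observed coordinate; lineage records are untouched.  ``sd = 0`` returns
    an identical copy."""
    if sd < 0:
        raise ParameterError("noise sd must be >= 0")
    out = ds.copy()
    if sd == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((len(out.tracks), 2)) * sd
    out.tracks["x"] = out.tracks["x"].to_numpy() + noise[:, 0]
    out.tracks["y"] = out.tracks["y"].to_numpy() + noise[:, 1]
    return out
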