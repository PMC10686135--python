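"""Forest construction, frame selection, classification and growth curves."""

import numpy as np
import pytest

from trackforest import (
    SimConfig,
    build_forest,
    classify_trees,
    fit_growth_polynomial,
    population_growth_curve,
    select_root_frame,
    simulate_forest,
)
from trackforest.errors import InsufficientCellsError, LineageError, RankError
from trackforest.lineage import GrowthCurve, MODE_FROM_START, MODE_POST_FIRST_DIVISION
from helpers import brute_force_frame_selection, make_dataset


def no_growth_config(**kw):
    base = dict(
        duration_h=20.0, frame_interval_h=1.0, n_roots=5, division_mean_h=np.inf,
        division_sd_h=0.0, death_hazard_apoptotic=0.0, death_hazard_necrotic=0.0,
        resistant_fraction=0.0, heritability=0.0, speed_mult_sd=0.0,
        field_width=200.0, field_height=150.0, noise_sd=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


# ---------- build_forest ----------

def test_forest_member_conservation(small_forest, small_dataset):
    total = sum(len(small_forest.trees[r]) for r in small_forest.roots)
    assert total == small_dataset.n_cells


def test_single_cell_and_one_division_trees():
    ds = make_dataset(
        [
            ("A", None, 0.0, 10.0, "DIVIDED"),
            ("B", "A", 10.0, 20.0, "ALIVE_AT_END"),
            ("C", "A", 10.0, 20.0, "ALIVE_AT_END"),
            ("D", None, 0.0, 20.0, "ALIVE_AT_END"),
        ],
        [(c, i, float(i), 0.0, 0.0) for c in "AD" for i in range(2)]
        + [(c, 10 + i, 10.0 + i, 0.0, 0.0) for c in "BC" for i in range(2)],
        duration_h=20.0,
    )
    forest = build_forest(ds)
    assert sorted(forest.roots) == ["A", "D"]
    assert forest.trees["A"] == ["A", "B", "C"]
    assert forest.trees["D"] == ["D"]


def test_cycle_in_parent_links_raises():
    ds = make_dataset(
        [("A", "B", 0.0, 5.0, "ALIVE_AT_END"), ("B", "A", 0.0, 5.0, "ALIVE_AT_END")],
        [("A", 0, 0.0, 0, 0), ("B", 0, 0.0, 0, 0)],
        duration_h=5.0,
    )
    with pytest.raises(LineageError):
        build_forest(ds)


# ---------- select_root_frame ----------

def _uniform_roots_dataset(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 800, n)
    y = rng.uniform(0, 600, n)
    cells = [(f"C{i:04d}", None, 0.0, 1.0, "ALIVE_AT_END") for i in range(n)]
    tracks = [(f"C{i:04d}", 0, 0.0, x[i], y[i]) for i in range(n)]
    return make_dataset(cells, tracks, duration_h=1.0), x, y


def test_frame_selection_matches_bruteforce_scan():
    ds, x, y = _uniform_roots_dataset(200, seed=7)
    rect, ids = select_root_frame(ds, n=100)
    assert len(ids) == 100  # continuous positions: ties have probability zero
    _, inside = brute_force_frame_selection(x, y, 100)
    expected = {f"C{i:04d}" for i in np.flatnonzero(inside)}
    assert set(ids) == expected
    xmin, ymin, xmax, ymax = rect
    sel = [int(c[1:]) for c in ids]
    assert (x[sel] >= xmin - 1e-9).all() and (x[sel] <= xmax + 1e-9).all()
    assert (y[sel] >= ymin - 1e-9).all() and (y[sel] <= ymax + 1e-9).all()


def test_frame_selection_all_inside_when_n_equals_total():
    ds, _, _ = _uniform_roots_dataset(50, seed=1)
    _, ids = select_root_frame(ds, n=50)
    assert len(ids) == 50


def test_frame_selection_includes_boundary_ties():
    # four roots at the corners of a square plus center: any frame reaching
    # one corner reaches all four
    cells = [(f"R{i}", None, 0.0, 1.0, "ALIVE_AT_END") for i in range(5)]
    pts = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (10.0, 10.0), (5.0, 5.0)]
    tracks = [(f"R{i}", 0, 0.0, px, py) for i, (px, py) in enumerate(pts)]
    ds = make_dataset(cells, tracks, duration_h=1.0)
    _, ids = select_root_frame(ds, n=2)
    assert len(ids) == 5  # center + all four tied corners


def test_frame_selection_insufficient_roots():
    ds, _, _ = _uniform_roots_dataset(30, seed=2)
    with pytest.raises(InsufficientCellsError):
        select_root_frame(ds, n=100)


# ---------- classify_trees ----------

def test_classification_of_hand_built_trees():
    ds = make_dataset(
        [
            ("A", None, 0.0, 20.0, "ALIVE_AT_END"),
            ("B", None, 0.0, 10.0, "DIVIDED"),
            ("B1", "B", 10.0, 20.0, "ALIVE_AT_END"),
            ("B2", "B", 10.0, 15.0, "DEATH_APOPTOTIC"),
            ("C", None, 0.0, 8.0, "DEATH_NECROTIC"),
        ],
        [("A", 0, 0.0, 0, 0), ("B", 0, 0.0, 0, 0), ("B1", 10, 10.0, 0, 0),
         ("B2", 10, 10.0, 0, 0), ("C", 0, 0.0, 0, 0)],
        duration_h=20.0,
    )
    classes = classify_trees(build_forest(ds))
    assert classes["A"].label == "NO_DEATH"
    assert classes["B"].label == "SURVIVING" and not classes["B"].no_death
    assert classes["C"].label == "EXTINCT"


def test_zero_death_hazard_gives_all_no_death():
    cfg = no_growth_config(division_mean_h=8.0, duration_h=20.0)
    ds = simulate_forest(cfg, 3)
    classes = classify_trees(build_forest(ds))
    assert all(c.no_death for c in classes.values())


def test_partition_invariant(small_forest):
    classes = classify_trees(small_forest)
    for c in classes.values():
        assert c.surviving ^ (c.label == "EXTINCT")
        if c.no_death:
            assert c.surviving


# ---------- growth curves ----------

def test_no_divisions_gives_flat_curve():
    ds = simulate_forest(no_growth_config(), 0)
    curve = population_growth_curve(build_forest(ds), mode=MODE_FROM_START)
    assert np.allclose(curve.percent, 100.0)


def test_deterministic_division_doubles_population():
    cfg = no_growth_config(division_mean_h=10.0, duration_h=30.0, frame_interval_h=0.1)
    curve = population_growth_curve(build_forest(simulate_forest(cfg, 1)),
                                    mode=MODE_FROM_START)
    t, y = curve.time_h, curve.percent

    def at(tq):
        return y[np.argmin(np.abs(t - tq))]

    assert at(0.0) == 100.0
    assert at(9.9) == 100.0
    assert at(10.0) == 200.0
    assert at(19.9) == 200.0
    assert at(20.0) == 400.0
    assert at(30.0) == 400.0  # third division lands exactly at the end


def test_post_first_division_curves_start_at_200(small_forest):
    curve = population_growth_curve(small_forest, mode=MODE_POST_FIRST_DIVISION)
    assert curve.percent[0] == 200.0


def test_growth_census_conservation(small_forest, small_dataset):
    """Count change between grid points equals births minus removals."""
    curve = population_growth_curve(small_forest, mode=MODE_FROM_START, step_h=2.0)
    counts = curve.percent * small_dataset.cells["parent_id"].isna().sum() / 100.0
    cells = small_dataset.cells
    for i in range(1, len(curve.time_h)):
        t0, t1 = curve.time_h[i - 1], curve.time_h[i]
        births = ((cells["birth_time_h"] > t0) & (cells["birth_time_h"] <= t1)).sum()
        leavers = (
            (cells["end_time_h"] > t0)
            & (cells["end_time_h"] <= t1)
            & (cells["fate"] != "ALIVE_AT_END")
        ).sum()
        assert counts[i] - counts[i - 1] == pytest.approx(births - leavers, abs=1e-9)


# ---------- cubic fit ----------

def _normal_equations_fit(t, y):
    """Independent oracle: solve the normal equations for y-100 on {t,t2,t3}."""
    X = np.column_stack([t, t**2, t**3])
    return np.linalg.solve(X.T @ X, X.T @ (y - 100.0))


def test_flat_curve_fits_to_zero_coefficients():
    t = np.arange(0.0, 50.0, 0.5)
    fit = fit_growth_polynomial(GrowthCurve(t, np.full_like(t, 100.0), MODE_FROM_START))
    assert fit.a == fit.b == fit.c == 0.0
    assert fit.rss == 0.0


def test_exact_cubic_recovered_to_six_digits():
    a, b, c = 2.0, 0.05, -0.001
    t = np.arange(0.0, 94.0, 0.5)
    y = 100.0 + a * t + b * t**2 + c * t**3
    fit = fit_growth_polynomial(GrowthCurve(t, y, MODE_FROM_START))
    assert fit.a == pytest.approx(a, rel=1e-6)
    assert fit.b == pytest.approx(b, rel=1e-6)
    assert fit.c == pytest.approx(c, rel=1e-6)
    assert fit(0.0) == 100.0


def test_fit_matches_normal_equations_on_noisy_curves():
    rng = np.random.default_rng(0)
    for _ in range(5):
        t = np.arange(0.0, 60.0, 0.25)
        y = 100 + rng.normal(0, 5, len(t)) + rng.uniform(-1, 3) * t
        fit = fit_growth_polynomial(GrowthCurve(t, y, MODE_FROM_START))
        ref = _normal_equations_fit(t, y)
        assert np.allclose([fit.a, fit.b, fit.c], ref, rtol=1e-8)


def test_degenerate_grid_raises():
    t = np.full(10, 5.0)
    with pytest.raises(RankError):
        fit_growth_polynomial(GrowthCurve(t, np.full(10, 100.0), MODE_FROM_START))
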