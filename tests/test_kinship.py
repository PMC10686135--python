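"""Sister-pair statistics, joint densities, MSD curves and memory time."""

import numpy as np
import pytest

from trackforest import SimConfig, build_forest, kinship, simulate_forest
from trackforest.errors import EmptySelectionError, UndefinedCorrelationError
from trackforest.kinship import (
    DisplacementCurves,
    SisterPair,
    estimate_memory_time,
    furth_msd,
    joint_kde,
    msd_curves,
    pair_correlation,
    sibling_cross_msd,
    sister_descendant_pairs,
    smoothed_pair_histogram,
    subtree_length_pairs,
)
from helpers import linear_track, make_dataset


def _pairs(values):
    return [SisterPair(f"m{i}", f"a{i}", f"b{i}", v1, v2, 0.0)
            for i, (v1, v2) in enumerate(values)]


# ---------- descendant counts ----------

def _division_tree_dataset(first_div, later_divs):
    """Root divides at ``first_div``; daughter A's subtree divides at the
    given absolute times (breadth-first), daughter B never divides."""
    cells = [("R", None, 0.0, first_div, "DIVIDED")]
    tracks = [("R", 0, 0.0, 0.0, 0.0), ("R", 1, 1.0, 0.0, 0.0)]
    end = 94.0
    cells += [("A", "R", first_div, later_divs[0] if later_divs else end,
               "DIVIDED" if later_divs else "ALIVE_AT_END"),
              ("B", "R", first_div, end, "ALIVE_AT_END")]
    if later_divs:
        cells += [("A1", "A", later_divs[0], end, "ALIVE_AT_END"),
                  ("A2", "A", later_divs[0], end, "ALIVE_AT_END")]
    for cid, _, birth, stop, _ in cells[1:]:
        f0 = int(np.ceil(birth))
        tracks += [(cid, f0, float(f0), 0.0, 0.0), (cid, f0 + 1, f0 + 1.0, 0.0, 0.0)]
    return make_dataset(cells, tracks, duration_h=end)


def test_descendant_counts_zero_and_two():
    ds = _division_tree_dataset(5.0, [])
    pairs = sister_descendant_pairs(build_forest(ds))
    assert len(pairs) == 1
    assert (pairs[0].value1, pairs[0].value2) == (0.0, 0.0)

    ds = _division_tree_dataset(5.0, [17.0])
    (pair,) = sister_descendant_pairs(build_forest(ds))
    assert sorted((pair.value1, pair.value2)) == [0.0, 2.0]


def test_descendant_counts_match_cell_table_oracle():
    """On a deterministic branching forest the counts equal a direct query
    of the cell table: descendants of each daughter born within the horizon."""
    cfg = SimConfig(duration_h=60.0, frame_interval_h=1.0, n_roots=4,
                    division_mean_h=12.0, division_sd_h=0.0, heritability=0.0,
                    death_hazard_apoptotic=0.0, death_hazard_necrotic=0.0,
                    resistant_fraction=0.0, speed_mult_sd=0.0, noise_sd=0.0,
                    field_width=200.0, field_height=150.0)
    ds = simulate_forest(cfg, 2)
    forest = build_forest(ds)
    horizon = 30.0
    pairs = sister_descendant_pairs(forest, horizon_h=horizon, birth_window_h=20.0)
    assert pairs, "deterministic division at 12 h must qualify"
    cells = ds.cells.set_index("cell_id")

    def oracle_count(daughter, cutoff):
        stack, n = [daughter], 0
        children = ds.cells.groupby("parent_id")["cell_id"]
        while stack:
            cur = stack.pop()
            try:
                kids = list(children.get_group(cur))
            except KeyError:
                kids = []
            for k in kids:
                if cells.loc[k, "birth_time_h"] <= cutoff + 1e-9:
                    n += 1
                    stack.append(k)
        return n

    for p in pairs:
        cutoff = p.birth_time_h + horizon
        assert p.value1 == oracle_count(p.cell_id1, cutoff)
        assert p.value2 == oracle_count(p.cell_id2, cutoff)
        # closed form: full binary tree, divisions every 12 h
        k = int(np.floor(horizon / 12.0))
        assert p.value1 == 2 ** (k + 1) - 2


# ---------- smoothed histogram ----------

def test_single_pair_gives_two_symmetric_bumps():
    jd = smoothed_pair_histogram(_pairs([(3.0, 5.0)]), bandwidth=1.5)
    assert np.allclose(jd.values, jd.values.T)
    assert jd.values[3, 5] == pytest.approx(jd.values[5, 3])
    assert jd.values[3, 5] > jd.values[0, 0]
    assert jd.integral() == pytest.approx(2.0, rel=1e-6)


def test_histogram_mass_conserved(small_forest):
    pairs = sister_descendant_pairs(small_forest, horizon_h=20.0, birth_window_h=40.0)
    if not pairs:
        pytest.skip("no qualifying sisters in fixture")
    jd = smoothed_pair_histogram(pairs)
    assert jd.integral() == pytest.approx(2.0 * len(pairs), rel=1e-6)


# ---------- subtree lengths ----------

def test_subtree_lengths_for_constant_speed_daughters():
    horizon = 20.0
    cells = [("R", None, 0.0, 2.0, "DIVIDED"),
             ("A", "R", 2.0, 40.0, "ALIVE_AT_END"),
             ("B", "R", 2.0, 40.0, "ALIVE_AT_END")]
    tracks = linear_track("R", 0.0, 2.0, 0.25, 0.0, 0.0, 0.0, 0.0)
    tracks += linear_track("A", 2.0, 40.0, 0.25, 0.0, 0.0, 3.0, 0.0, frame_offset=8)
    tracks += linear_track("B", 2.0, 40.0, 0.25, 0.0, 0.0, 0.0, 5.0, frame_offset=8)
    ds = make_dataset(cells, tracks, frame_interval_h=0.25, duration_h=40.0)
    (pair,) = subtree_length_pairs(build_forest(ds), horizon_h=horizon,
                                   birth_window_h=30.0)
    assert sorted((pair.value1, pair.value2)) == pytest.approx(
        [3.0 * horizon, 5.0 * horizon], rel=0.01
    )


def test_stationary_lineage_has_zero_lengths():
    cells = [("R", None, 0.0, 2.0, "DIVIDED"),
             ("A", "R", 2.0, 30.0, "ALIVE_AT_END"),
             ("B", "R", 2.0, 30.0, "ALIVE_AT_END")]
    tracks = []
    for cid, t0, t1 in (("R", 0.0, 2.0), ("A", 2.0, 30.0), ("B", 2.0, 30.0)):
        tracks += linear_track(cid, t0, t1, 0.5, 1.0, 1.0, 0.0, 0.0,
                               frame_offset=int(t0 * 2))
    ds = make_dataset(cells, tracks, frame_interval_h=0.5, duration_h=30.0)
    (pair,) = subtree_length_pairs(build_forest(ds))
    assert pair.value1 == pytest.approx(0.0, abs=1e-9)
    assert pair.value2 == pytest.approx(0.0, abs=1e-9)


# ---------- KDE and correlation ----------

def test_scott_kde_matches_manual_gaussian_mixture():
    """Dual route: the joint KDE equals a hand-written sum of Gaussians with
    Scott-scaled covariance at probe points, and integrates to ~1."""
    rng = np.random.default_rng(4)
    raw = rng.multivariate_normal([0, 0], [[1.0, 0.6], [0.6, 1.0]], size=400)
    pairs = _pairs([tuple(row) for row in raw])
    jd = joint_kde(pairs, grid_size=161, pad_bandwidths=5.0)
    assert jd.integral() == pytest.approx(1.0, abs=0.02)

    pts = np.vstack([raw, raw[:, ::-1]])
    n = len(pts)
    cov = np.cov(pts.T, bias=False) * n ** (-2.0 / 6.0)  # Scott, d=2
    cov_inv = np.linalg.inv(cov)
    norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(cov)))
    for probe in ([0.0, 0.0], [1.0, -0.5], [0.5, 1.5]):
        d = pts - probe
        manual = norm * np.mean(np.exp(-0.5 * np.einsum("ij,jk,ik->i", d, cov_inv, d)))
        i = np.argmin(np.abs(jd.grid1 - probe[0]))
        j = np.argmin(np.abs(jd.grid2 - probe[1]))
        assert jd.values[i, j] == pytest.approx(manual, rel=0.05)


def test_kde_mode_near_origin_for_standard_normal_sample():
    rng = np.random.default_rng(8)
    raw = rng.standard_normal((500, 2))
    jd = joint_kde(_pairs([tuple(r) for r in raw]))
    i, j = np.unravel_index(np.argmax(jd.values), jd.values.shape)
    assert abs(jd.grid1[i]) < 0.2 and abs(jd.grid2[j]) < 0.2


def test_correlation_on_diagonal_pairs_is_one():
    pairs = _pairs([(v, v) for v in (1.0, 2.0, 5.0, 9.0)])
    assert pair_correlation(pairs) == pytest.approx(1.0)


def test_correlation_invariant_to_pair_order():
    rng = np.random.default_rng(1)
    vals = [(a, a + b) for a, b in rng.normal(5, 1, (30, 2))]
    r1 = pair_correlation(_pairs(vals))
    r2 = pair_correlation(_pairs([(b, a) for a, b in vals]))
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_independent_pairs_have_near_zero_correlation():
    rng = np.random.default_rng(6)
    n = 400
    vals = list(zip(rng.normal(10, 2, n), rng.normal(10, 2, n)))
    assert abs(pair_correlation(_pairs(vals))) < 3 / np.sqrt(n)


def test_zero_variance_correlation_is_undefined():
    with pytest.raises(UndefinedCorrelationError):
        pair_correlation(_pairs([(1.0, 1.0)] * 5))


# ---------- displacement curves ----------

def _ballistic_cohort(n, speed, t_end=20.0):
    cells, tracks = [], []
    for i in range(n):
        cid = f"M{i}"
        did1, did2 = f"D{i}a", f"D{i}b"
        cells += [(cid, None, 0.0, 1.0, "DIVIDED"),
                  (did1, cid, 1.0, t_end, "ALIVE_AT_END"),
                  (did2, cid, 1.0, t_end, "ALIVE_AT_END")]
        tracks += linear_track(cid, 0.0, 1.0, 0.5, float(i) * 100, 0.0, 0.0, 0.0)
        angle = 2 * np.pi * i / n
        vx, vy = speed * np.cos(angle), speed * np.sin(angle)
        tracks += linear_track(did1, 1.0, t_end, 0.5, float(i) * 100, 0.0, vx, vy,
                               frame_offset=2)
        tracks += linear_track(did2, 1.0, t_end, 0.5, float(i) * 100, 0.0, -vx, -vy,
                               frame_offset=2)
    return make_dataset(cells, tracks, frame_interval_h=0.5, duration_h=t_end)


def test_ballistic_msd_matches_closed_form():
    speed = 4.0
    ds = _ballistic_cohort(8, speed)
    forest = build_forest(ds)
    daughters = [c for c in ds.cells["cell_id"] if c.startswith("D")]
    curves = msd_curves(forest, daughters, t_max_h=15, step_h=1.0)
    t = curves.time_h[1:]
    assert np.allclose(curves.mean_c[1:], speed**2 * t**2, rtol=0.01)
    assert np.allclose(curves.mean_c_over_t[1:], speed**2 * t, rtol=0.01)
    assert curves.mean_c[0] == 0.0


def test_mirrored_sisters_have_opposite_cross_displacement():
    ds = _ballistic_cohort(8, 3.0)
    forest = build_forest(ds)
    sisters = [(f"D{i}a", f"D{i}b") for i in range(8)]
    cross = sibling_cross_msd(forest, sisters, t_max_h=15, step_h=1.0)
    t = cross.time_h[1:]
    # r2 = -r1 exactly, so c12(t) = -c(t) = -(s t)^2
    assert np.allclose(cross.mean_c12_over_t[1:], -(3.0**2) * t, rtol=0.01)


def test_identical_sisters_have_equal_cross_displacement():
    cells = [("R", None, 0.0, 1.0, "DIVIDED"),
             ("A", "R", 1.0, 20.0, "ALIVE_AT_END"),
             ("B", "R", 1.0, 20.0, "ALIVE_AT_END")]
    tracks = linear_track("R", 0.0, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0)
    tracks += linear_track("A", 1.0, 20.0, 0.5, 0.0, 0.0, 2.0, 1.0, frame_offset=2)
    tracks += linear_track("B", 1.0, 20.0, 0.5, 0.0, 0.0, 2.0, 1.0, frame_offset=2)
    ds = make_dataset(cells, tracks, frame_interval_h=0.5, duration_h=20.0)
    forest = build_forest(ds)
    cross = sibling_cross_msd(forest, [("A", "B")], t_max_h=10, step_h=1.0)
    assert np.allclose(cross.mean_c12_over_t[1:], cross.mean_c_over_t[1:], rtol=1e-9)


def test_per_pair_cauchy_schwarz_bound(small_forest):
    sisters = kinship.first_generation_sisters(small_forest)
    if not sisters:
        pytest.skip("no sisters in fixture")
    cross = sibling_cross_msd(small_forest, [(d1, d2) for _, d1, d2, _ in sisters],
                              t_max_h=10, step_h=0.5)
    # |r1.r2| <= (|r1|^2 + |r2|^2) / 2 must hold exactly for every pair and t
    curves = msd_curves(small_forest, [d for _, d1, d2, _ in sisters for d in (d1, d2)],
                        t_max_h=10, step_h=0.5)
    for (c1, c2), c12 in cross.per_pair_c12.items():
        a = curves.per_cell_c.get(c1)
        b = curves.per_cell_c.get(c2)
        if a is None or b is None:
            continue
        ok = np.isfinite(c12) & np.isfinite(a) & np.isfinite(b)
        assert (np.abs(c12[ok]) <= 0.5 * (a[ok] + b[ok]) + 1e-9).all()


def test_attrition_reflected_in_counts():
    ds = _ballistic_cohort(4, 2.0, t_end=8.0)  # daughters die out at t=8
    forest = build_forest(ds)
    daughters = [c for c in ds.cells["cell_id"] if c.startswith("D")]
    curves = msd_curves(forest, daughters, t_max_h=15, step_h=1.0)
    assert curves.n_cells[0] == 8
    assert curves.n_cells[-1] == 0
    assert np.isnan(curves.mean_c[-1])


# ---------- memory time ----------

def test_memory_time_self_consistency_on_exact_model_data():
    t = np.arange(0.0, 15.1, 0.25)
    c = furth_msd(t, D=1.0, P=3.0)
    curves = DisplacementCurves(t, c, np.where(t > 0, c / np.maximum(t, 1e-12), 0.0),
                                np.full(len(t), 100))
    fit = estimate_memory_time(curves)
    assert fit.persistence_h == pytest.approx(3.0, rel=1e-3)
    assert fit.diffusion == pytest.approx(1.0, rel=1e-3)
    assert fit.censored is None


def test_memory_time_brownian_limit_is_censored_low():
    t = np.arange(0.0, 15.1, 0.5)
    c = 4.0 * 2.0 * t  # pure diffusion, D = 2
    curves = DisplacementCurves(t, c, np.where(t > 0, c / np.maximum(t, 1e-12), 0.0),
                                np.full(len(t), 100))
    fit = estimate_memory_time(curves)
    assert fit.censored == "low"
    assert fit.persistence_h <= 0.5 * (1 + 1e-6)


def test_memory_time_ballistic_window_is_censored_high():
    t = np.arange(0.0, 5.1, 0.5)
    c = 9.0 * t**2  # ballistic: P far beyond the window
    curves = DisplacementCurves(t, c, np.where(t > 0, c / np.maximum(t, 1e-12), 0.0),
                                np.full(len(t), 100))
    fit = estimate_memory_time(curves)
    assert fit.censored == "high"
    assert fit.persistence_h >= 5.0
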