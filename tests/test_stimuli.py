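"""Glyph rendering and display composition."""

import numpy as np
import pytest
from scipy.stats import chisquare

import sparsecrowd as sc
from sparsecrowd.glyphs import ALL_SYMBOLS, TUMBLING_T_SYMBOLS, render_glyph
from sparsecrowd.stimuli import (
    center_position,
    compose_display,
    place_random_flankers,
    single_flanker_probe_set,
)


@pytest.mark.parametrize("symbol", ALL_SYMBOLS)
def test_glyph_invariants(symbol):
    g = render_glyph(symbol, 20)
    px = g.pixels
    assert px.shape == (20, 20)
    assert set(np.unique(px)) <= {0.0, 1.0}
    assert 0 < px.sum() < px.size  # at least one on and one off pixel


def test_glyph_deterministic():
    a = render_glyph("triangle", 20).pixels
    b = render_glyph("triangle", 20).pixels
    np.testing.assert_array_equal(a, b)


def test_unknown_symbol_rejected():
    with pytest.raises(sc.UnknownSymbolError):
        render_glyph("pentagon")


def test_glyph_size_floor():
    with pytest.raises(ValueError):
        render_glyph("circle", 5)


def test_circle_ring_touches_all_edges():
    px = render_glyph("circle", 20).pixels
    assert px[0].any() and px[-1].any() and px[:, 0].any() and px[:, -1].any()
    assert px[9:11, 9:11].sum() == 0  # unfilled center


def test_hline_is_centered_band():
    px = render_glyph("hline", 20).pixels
    rows = np.flatnonzero(px.any(axis=1))
    np.testing.assert_array_equal(rows, [9, 10])
    assert px[9:11].all()


def test_tumbling_t_flip_symmetry():
    up = render_glyph("T_up").pixels
    down = render_glyph("T_down").pixels
    np.testing.assert_array_equal(up[::-1], down)
    left = render_glyph("T_left").pixels
    right = render_glyph("T_right").pixels
    np.testing.assert_array_equal(left[:, ::-1], right)


@pytest.mark.parametrize("symbol", TUMBLING_T_SYMBOLS)
def test_tumbling_t_is_two_strokes(symbol):
    # exactly one full-length horizontal and one vertical stroke of width 2
    px = render_glyph(symbol).pixels
    full_rows = np.flatnonzero(px.all(axis=1))
    full_cols = np.flatnonzero(px.all(axis=0))
    assert len(full_rows) == 2 and np.ptp(full_rows) == 1
    assert len(full_cols) == 2 and np.ptp(full_cols) == 1
    stroke_px = 2 * 20 + 2 * 20 - 4  # union of the two strokes
    assert px.sum() == stroke_px


def test_compose_centers_target():
    d = compose_display("triangle", [], 101)
    r0, c0 = center_position(101, 20)
    assert (r0, c0) == (40, 40)
    inner = d.pixels[r0 : r0 + 20, c0 : c0 + 20]
    np.testing.assert_array_equal(inner, render_glyph("triangle").pixels)
    assert d.pixels.sum() == inner.sum()  # nothing outside the target


def test_compose_max_union_pixel_count():
    g = {s: render_glyph(s).pixels.sum() for s in ("x", "circle", "triangle")}
    d = compose_display("x", [("circle", (0, 0)), ("triangle", (70, 70))], 101)
    assert d.pixels.sum() <= g["x"] + g["circle"] + g["triangle"]
    # disjoint placement: equality
    assert d.pixels.sum() == g["x"] + g["circle"] + g["triangle"]


def test_compose_flanker_offset_25px():
    r0, c0 = center_position(101, 20)
    d = compose_display("circle", [("x", (r0, c0 - 25))], 101)
    (sym, (r, c)), = d.flankers
    # bounding-box centers differ by exactly 25 px horizontally
    assert (r + 9.5) - (r0 + 9.5) == 0
    assert (c0 + 9.5) - (c + 9.5) == 25


def test_compose_out_of_bounds_flanker():
    with pytest.raises(sc.BoundsError):
        compose_display("x", [("circle", (95, 10))], 101)


def test_place_random_flankers_empty():
    rng = np.random.default_rng(0)
    assert place_random_flankers(0, 101, "x", rng, ("x", "circle", "triangle")) == []


@pytest.mark.parametrize("display_size", [101, 61, 151])
def test_random_flankers_stay_in_bounds(display_size):
    rng = np.random.default_rng(7)
    for _ in range(300):
        fl = place_random_flankers(2, display_size, "x", rng, ("x", "circle", "triangle"))
        for _, (r, c) in fl:
            assert 0 <= r <= display_size - 20
            assert 0 <= c <= display_size - 20


def test_random_flankers_do_not_overlap_target_or_each_other():
    rng = np.random.default_rng(11)
    tgt = center_position(101, 20)
    for _ in range(300):
        fl = place_random_flankers(2, 101, "x", rng, ("x", "circle", "triangle"))
        boxes = [tgt] + [p for _, p in fl]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                dr = abs(boxes[i][0] - boxes[j][0])
                dc = abs(boxes[i][1] - boxes[j][1])
                assert dr >= 20 or dc >= 20


def test_flanker_x_positions_uniform_over_valid_range():
    """Sampled x positions match a direct uniform draw over valid placements.

    Oracle: enumerate all in-bounds, non-target-overlapping top-left corners
    and compare the empirical x histogram by chi-square goodness of fit.
    """
    rng = np.random.default_rng(3)
    xs = []
    for _ in range(10_000):
        (_, (r, c)), = place_random_flankers(1, 101, "x", rng, ("x",))
        xs.append(c)
    xs = np.asarray(xs)
    # expected marginal: for each x, count of valid y rows (oracle enumeration)
    tgt = center_position(101, 20)
    expected = np.zeros(82)
    for c in range(82):
        for r in range(82):
            if abs(r - tgt[0]) >= 20 or abs(c - tgt[1]) >= 20:
                expected[c] += 1
    expected = expected / expected.sum() * len(xs)
    observed = np.bincount(xs, minlength=82)
    stat, p = chisquare(observed, expected)
    assert p > 0.01


def test_build_set_counts_and_balance(peripheral_cfg):
    rng = np.random.default_rng(5)
    s = sc.build_set(peripheral_cfg, "training", rng)
    assert len(s) == 120
    labels = s.labels()
    for sym in peripheral_cfg.symbols:
        assert labels.count(sym) == 40
    t = sc.build_set(peripheral_cfg, "test", np.random.default_rng(6))
    assert len(t) == 60


def test_zone_training_set_is_240_151px():
    cfg = sc.default_config("zone")
    s = sc.build_set(cfg, "training", np.random.default_rng(1))
    assert len(s) == 240
    assert s.items[0][0].display_size == 151


def test_probe_set_is_12_images_flanker_differs_from_target():
    s = single_flanker_probe_set(("circle", "triangle", "x"))
    assert len(s) == 12
    for d, target in s.items:
        assert len(d.flankers) == 1
        assert d.flankers[0][0] != target
    from sparsecrowd.stimuli import flanker_side

    sides = [flanker_side(d) for d, _ in s.items]
    assert sides.count("inner") == 6 and sides.count("outer") == 6


def test_set_generation_is_seed_deterministic(peripheral_cfg):
    a = sc.build_set(peripheral_cfg, "training", np.random.default_rng(42))
    b = sc.build_set(peripheral_cfg, "training", np.random.default_rng(42))
    np.testing.assert_array_equal(a.images(), b.images())
    assert a.labels() == b.labels()


def test_foveal_sets_fit_61px_display(foveal_cfg):
    rng = np.random.default_rng(9)
    s = sc.build_set(foveal_cfg, "training", rng)
    for d, _ in s.items:
        assert d.display_size == 61
        for _, (r, c) in d.flankers:
            assert 0 <= r <= 41 and 0 <= c <= 41
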