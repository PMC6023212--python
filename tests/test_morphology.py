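"""The binary morphology primitives of the cleanup chain, each against its
brute-force oracle and the documented examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from oracles import (
    bridge_slow,
    diagonal_fill_slow,
    dilate_slow,
    erode_slow,
    fill_holes_slow,
)
from spheromon.segment import (
    bridge_pixels,
    diagonal_fill,
    dilate,
    disk_element,
    erode,
    fill_holes,
    morph_cleanup,
)


def random_mask(seed: int, shape=(16, 16), p=0.4) -> np.ndarray:
    return np.random.default_rng(seed).random(shape) < p


class TestBridge:
    def test_canonical_bridge(self):
        m = np.zeros((3, 5), bool)
        m[0, 0] = m[0, 2] = True
        out = bridge_pixels(m)
        assert out[0, 1]

    def test_solid_blob_unchanged(self):
        m = np.zeros((6, 6), bool)
        m[1:5, 1:5] = True
        assert (bridge_pixels(m) == m).all()

    def test_empty(self):
        assert not bridge_pixels(np.zeros((4, 4), bool)).any()

    def test_adjacent_pair_not_bridged(self):
        # two fg neighbours that are already 8-connected: no bridging
        m = np.zeros((3, 3), bool)
        m[0, 0] = m[0, 1] = True
        out = bridge_pixels(m)
        assert out.sum() == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = random_mask(seed)
        assert (bridge_pixels(m) == bridge_slow(m)).all()


class TestDiagonalFill:
    def test_definition(self):
        m = np.zeros((2, 2), bool)
        m[0, 0] = m[1, 1] = True
        out = diagonal_fill(m)
        assert out.all()

    def test_four_connected_line_unchanged(self):
        m = np.zeros((4, 4), bool)
        m[1, :] = True
        assert (diagonal_fill(m) == m).all()

    def test_checkerboard_removes_background_diagonal_connectivity(self):
        m = np.zeros((3, 3), bool)
        m[0, 0] = m[0, 2] = m[1, 1] = m[2, 0] = m[2, 2] = True
        out = diagonal_fill(m)
        # no diagonal-only 2x2 block remains
        a, b = out[:-1, :-1], out[:-1, 1:]
        c, d = out[1:, :-1], out[1:, 1:]
        assert not (a & d & ~b & ~c).any() and not (b & c & ~a & ~d).any()
        # background component count drops (8-connected bg no longer leaks)
        _, n_before = ndimage.label(~m, structure=ndimage.generate_binary_structure(2, 1))
        _, n_after = ndimage.label(~out, structure=ndimage.generate_binary_structure(2, 1))
        assert n_after < n_before

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = random_mask(seed)
        assert (diagonal_fill(m) == diagonal_fill_slow(m)).all()


def ring_with_hole(hole_pixels: int) -> np.ndarray:
    """A rectangle with a centred rectangular hole of the requested area."""
    # hole of size a x b with a*b = hole_pixels
    a = int(np.floor(np.sqrt(hole_pixels)))
    while hole_pixels % a:
        a -= 1
    b = hole_pixels // a
    m = np.ones((a + 4, b + 4), bool)
    m[2 : 2 + a, 2 : 2 + b] = False
    return m


class TestFillHoles:
    def test_150px_hole_filled(self):
        m = ring_with_hole(150)
        assert fill_holes(m, 150).all()

    def test_151px_hole_not_filled(self):
        m = ring_with_hole(151)
        out = fill_holes(m, 150)
        assert (out == m).all()

    def test_border_touching_concavity_never_filled(self):
        m = np.ones((6, 6), bool)
        m[0:3, 2:4] = False  # notch open to the border
        assert (fill_holes(m, None) == m).all()

    def test_unlimited_fills_all(self):
        m = ring_with_hole(300)
        assert fill_holes(m, None).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = random_mask(seed, p=0.55)
        for max_area in (None, 3, 10):
            assert (fill_holes(m, max_area) == fill_holes_slow(m, max_area)).all()


class TestErodeDilate:
    def test_disk_element_has_13_pixels_at_r2(self):
        assert disk_element(2).sum() == 13

    def test_5x5_square_erodes_to_center(self):
        m = np.zeros((7, 7), bool)
        m[1:6, 1:6] = True
        out = erode(m, 2)
        expected = np.zeros((7, 7), bool)
        expected[3, 3] = True
        assert (out == expected).all()

    def test_dilate_single_pixel_gives_disk(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        assert dilate(m, 2).sum() == 13

    def test_opening_anti_extensive(self):
        yy, xx = np.mgrid[-20:21, -20:21]
        disk = xx**2 + yy**2 <= 15**2
        opened = dilate(erode(disk, 2), 2)
        assert opened.sum() <= disk.sum()
        assert not (opened & ~disk).any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = random_mask(seed)
        assert (erode(m, 2) == erode_slow(m, 2)).all()
        assert (dilate(m, 2) == dilate_slow(m, 2)).all()


class TestMorphCleanup:
    def test_step_i_small_object_thresholds(self):
        m = np.zeros((40, 90), bool)
        m[5:25, 5:30] = True  # 500 px main blob
        m[5:11, 50:55] = True  # 30 px blob: removed (> 25)
        m[30:34, 60:65] = True  # 20 px blob: retained in step i, then
        # eliminated by step iii erosion + largest-object
        out = morph_cleanup(m)
        assert out[10, 10]
        assert not out[7, 52]
        assert not out[31, 62]

    def test_100px_hole_filled_in_step_iii(self):
        m = np.ones((16, 18), bool)
        m[3:13, 4:14] = False  # 100 px hole (<= 150: filled in step iii)
        out = morph_cleanup(m)
        assert out[3:13, 4:14].all()

    def test_300px_hole_filled_in_step_iv(self):
        # 6-px-thick walls so the ring survives the step-iii r=2 erosion
        m = np.zeros((36, 31), bool)
        m[2:34, 2:29] = True
        m[8:28, 8:23] = False  # 300 px hole (> 150: filled only in step iv)
        out = morph_cleanup(m)
        assert out[8:28, 8:23].all()

    def test_single_component_or_empty(self, rng):
        for seed in range(8):
            m = random_mask(seed, shape=(32, 32), p=0.35)
            out = morph_cleanup(m)
            labels, n = ndimage.label(out, structure=np.ones((3, 3), bool))
            assert n <= 1

    def test_hole_free(self):
        for seed in range(8):
            m = random_mask(seed, shape=(32, 32), p=0.45)
            out = morph_cleanup(m)
            assert (fill_holes(out, None) == out).all()

    def test_empty_input(self):
        assert not morph_cleanup(np.zeros((10, 10), bool)).any()


@settings(max_examples=40, deadline=None, database=None)
@given(st.integers(0, 10_000), st.floats(0.2, 0.6))
def test_bridge_diagonal_properties(seed, p):
    """Bridge and diagonal fill are extensive (only add pixels) and agree
    with the brute-force oracles on random masks."""
    m = np.random.default_rng(seed).random((12, 12)) < p
    b = bridge_pixels(m)
    d = diagonal_fill(m)
    assert (b | m == b).all() and (d | m == d).all()
    assert (b == bridge_slow(m)).all()
    assert (d == diagonal_fill_slow(m)).all()
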