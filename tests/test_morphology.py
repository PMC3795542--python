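"""Flat greyscale morphology: SE construction and the four basic operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rmpenhance import (
    GreyImage,
    closing,
    dilate,
    erode,
    make_structuring_element,
    opening,
)
from .conftest import oracle_dilate, oracle_erode

SES = {
    "disc3": make_structuring_element("disc", 3),
    "disc5": make_structuring_element("disc", 5),
    "square3": make_structuring_element("square", 3),
    "line5": make_structuring_element("line", 5, 0.0),
}


class TestStructuringElements:
    def test_disc3_is_cross(self):
        se = make_structuring_element("disc", 3)
        expected = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        assert np.array_equal(se.mask, expected)
        assert se.origin == (1, 1)

    def test_square3_all_true(self):
        se = make_structuring_element("square", 3)
        assert se.mask.shape == (3, 3) and se.mask.all()

    def test_disc31_matches_lattice_enumeration(self):
        se = make_structuring_element("disc", 31)
        count = sum(
            1
            for dr in range(-15, 16)
            for dc in range(-15, 16)
            if dr * dr + dc * dc <= 15 * 15
        )
        assert se.mask.sum() == count
        assert se.mask.shape == (31, 31)

    def test_horizontal_line5_is_row(self):
        se = make_structuring_element("line", 5, 0.0)
        assert se.mask.shape == (1, 5) and se.mask.all()
        assert se.origin == (0, 2)

    def test_line_symmetric_about_origin(self):
        se = make_structuring_element("line", 7, np.pi / 3)
        offs = {tuple(o) for o in se.offsets}
        assert offs == {(-r, -c) for r, c in offs}

    @pytest.mark.parametrize("shape", ["disc", "square"])
    def test_even_size_rejected_with_parity_message(self, shape):
        with pytest.raises(ValueError, match="odd"):
            make_structuring_element(shape, 4)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_structuring_element("disc", 0)
        with pytest.raises(ValueError):
            make_structuring_element("disc", 3, angle=0.5)
        with pytest.raises(ValueError):
            make_structuring_element("hexagon", 3)


class TestDilateErode:
    def test_constant_image_fixed_point(self):
        c = GreyImage(np.full((6, 7), 42.0))
        for se in SES.values():
            assert np.array_equal(dilate(c, se).pixels, c.pixels)
            assert np.array_equal(erode(c, se).pixels, c.pixels)

    def test_single_peak_dilates_to_block(self):
        f = np.zeros((5, 5))
        f[2, 2] = 9.0
        out = dilate(GreyImage(f), SES["square3"]).pixels
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 9.0
        assert np.array_equal(out, expected)

    def test_single_pit_erodes_to_block(self):
        f = np.full((5, 5), 9.0)
        f[2, 2] = 0.0
        out = erode(GreyImage(f), SES["square3"]).pixels
        expected = np.full((5, 5), 9.0)
        expected[1:4, 1:4] = 0.0
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("name", sorted(SES))
    def test_oracle_equality_on_random_images(self, name, rng):
        se = SES[name]
        for _ in range(10):
            f = rng.integers(0, 256, (20, 20)).astype(float)
            assert np.array_equal(dilate(f, se).pixels, oracle_dilate(f, se))
            assert np.array_equal(erode(f, se).pixels, oracle_erode(f, se))

    def test_erode_is_dual_of_dilate(self, rng):
        for name, se in SES.items():
            f = rng.integers(0, 256, (20, 20)).astype(float)
            dual = -dilate(-f, se.reflected()).pixels
            assert np.array_equal(erode(f, se).pixels, dual)

    def test_asymmetric_se_offsets_honoured(self, rng):
        """An off-origin SE must follow the same offset convention as the
        oracle (this is where a footprint-flip bug would show)."""
        from rmpenhance.morphology import StructuringElement

        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = mask[1, 1] = mask[2, 2] = True
        se = StructuringElement(mask, (1, 1))
        f = rng.integers(0, 256, (15, 15)).astype(float)
        assert np.array_equal(dilate(f, se).pixels, oracle_dilate(f, se))
        assert np.array_equal(erode(f, se).pixels, oracle_erode(f, se))


class TestOpeningClosing:
    def test_constant_unchanged(self):
        c = GreyImage(np.full((8, 8), 7.0))
        assert np.array_equal(opening(c, SES["disc3"]).pixels, c.pixels)
        assert np.array_equal(closing(c, SES["disc3"]).pixels, c.pixels)

    def test_opening_removes_small_peak(self):
        f = np.zeros((7, 7))
        f[3, 3] = 5.0
        assert np.array_equal(opening(f, SES["square3"]).pixels, np.zeros((7, 7)))

    def test_closing_fills_small_pit(self):
        f = np.full((7, 7), 9.0)
        f[3, 3] = 0.0
        assert np.array_equal(closing(f, SES["square3"]).pixels, np.full((7, 7), 9.0))

    @pytest.mark.parametrize("name", sorted(SES))
    def test_idempotence(self, name, rng):
        se = SES[name]
        f = rng.integers(0, 256, (20, 20)).astype(float)
        once_o = opening(f, se).pixels
        once_c = closing(f, se).pixels
        assert np.array_equal(opening(once_o, se).pixels, once_o)
        assert np.array_equal(closing(once_c, se).pixels, once_c)

    def test_closing_is_negated_opening(self, rng):
        for name in ("disc3", "square3", "disc5"):
            se = SES[name]
            f = rng.integers(0, 256, (20, 20)).astype(float)
            assert np.array_equal(closing(f, se).pixels, -opening(-f, se).pixels)

    def test_ordering_chain(self, rng):
        """erode <= opening <= f <= closing <= dilate, pointwise, exactly."""
        for name, se in SES.items():
            f = rng.integers(0, 256, (20, 20)).astype(float)
            e = erode(f, se).pixels
            o = opening(f, se).pixels
            c = closing(f, se).pixels
            d = dilate(f, se).pixels
            assert (e <= o).all() and (o <= f).all()
            assert (f <= c).all() and (c <= d).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    f=hnp.arrays(np.float64, (8, 8), elements=st.integers(0, 100).map(float)),
    bump=hnp.arrays(np.float64, (8, 8), elements=st.integers(0, 20).map(float)),
    name=st.sampled_from(sorted(SES)),
)
def test_operators_are_increasing(f, bump, name):
    """f <= g pointwise implies op(f) <= op(g) for all four operators."""
    se = SES[name]
    g = f + bump
    for op in (dilate, erode, opening, closing):
        assert (op(f, se).pixels <= op(g, se).pixels).all()
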