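"""Writing-sample metrics: letter height, area, b value, −2 SD classification."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from micrographia.writing import (
    WritingSample,
    MicrographiaProfile,
    compute_mean_letter_height,
    compute_writing_area,
    compute_progressive_b,
    compute_drawing_area,
    compute_profile,
    derive_reference_thresholds,
    classify_micrographia,
)

positive_mm = st.floats(min_value=0.5, max_value=50.0, allow_nan=False)


@pytest.mark.parametrize(
    "heights, expected",
    [((5, 5, 5), 5.0), ((6, 3, 3), 4.0), ((4.2, 5.1, 3.9), 4.4)],
)
def test_mean_letter_height(heights, expected):
    s = WritingSample(height_T=heights[0], height_p=heights[1], height_a_umlautless=heights[2])
    assert compute_mean_letter_height(s) == pytest.approx(expected)


def test_mean_letter_height_missing_letter_gives_missing():
    s = WritingSample(height_T=5.0, height_p=None, height_a_umlautless=4.0)
    assert math.isnan(compute_mean_letter_height(s))
    profile = compute_profile(s)
    assert any("letter heights" in r for r in profile.exclusion_reasons)


@pytest.mark.parametrize(
    "heights, width, expected",
    [((5, 5, 5), 100.0, 500.0), ((4.2, 5.1, 3.9), 90.0, 396.0)],
)
def test_writing_area(heights, width, expected):
    s = WritingSample(*heights, sample_width=width)
    assert compute_writing_area(s) == pytest.approx(expected)


def test_writing_area_degenerate_width_is_missing():
    s = WritingSample(4, 4, 4, sample_width=0.0)
    assert math.isnan(compute_writing_area(s))


@pytest.mark.parametrize(
    "a_heights, expected",
    [
        ((5, 5, 5, 5, 5, 5), 0.0),
        ((6, 5, 4, 3, 2, 1), -1.0),
        # hand computation: Σ(x−x̄)(y−ȳ) = −4.85, Σ(x−x̄)² = 17.5
        ((5.0, 4.6, 4.7, 4.1, 3.9, 3.6), -4.85 / 17.5),
    ],
)
def test_progressive_b_examples(a_heights, expected):
    assert compute_progressive_b(a_heights) == pytest.approx(expected, abs=1e-12)


def test_progressive_b_requires_six_heights():
    assert math.isnan(compute_progressive_b([5, 5, 5]))
    assert math.isnan(compute_progressive_b(None))
    assert math.isnan(compute_progressive_b([5, 5, 5, 5, 5, -1]))


@given(st.lists(positive_mm, min_size=6, max_size=6))
def test_progressive_b_matches_polyfit(a_heights):
    """The b value equals the closed-form OLS slope on any 6-vector."""
    expected = np.polyfit(np.arange(1, 7), a_heights, 1)[0]
    assert compute_progressive_b(a_heights) == pytest.approx(expected, abs=1e-10)


@given(st.lists(positive_mm, min_size=6, max_size=6), st.floats(0.1, 10.0))
def test_progressive_b_shift_invariant_scale_equivariant(a_heights, c):
    b = compute_progressive_b(a_heights)
    shifted = compute_progressive_b([h + 3.0 for h in a_heights])
    scaled = compute_progressive_b([h * c for h in a_heights])
    assert shifted == pytest.approx(b, abs=1e-9)
    assert scaled == pytest.approx(b * c, rel=1e-9, abs=1e-9)


@given(
    st.tuples(positive_mm, positive_mm, positive_mm),
    st.floats(10.0, 200.0),
    st.floats(0.1, 10.0),
)
def test_scale_equivariance_of_height_and_area(heights, width, c):
    """Scaling all lengths by c scales mean height by c and area by c²."""
    s1 = WritingSample(*heights, sample_width=width)
    s2 = WritingSample(*(h * c for h in heights), sample_width=width * c)
    assert compute_mean_letter_height(s2) == pytest.approx(
        c * compute_mean_letter_height(s1), rel=1e-9
    )
    assert compute_writing_area(s2) == pytest.approx(
        c**2 * compute_writing_area(s1), rel=1e-9
    )


@pytest.mark.parametrize(
    "w, h, expected", [((5.0), 5.0, 25.0), (4.6, 5.8, 26.68)]
)
def test_drawing_area(w, h, expected):
    assert compute_drawing_area(
        WritingSample(house_width=w, house_height=h)
    ) == pytest.approx(expected)


def test_drawing_area_degenerate_is_missing():
    assert math.isnan(compute_drawing_area(WritingSample(house_width=0, house_height=5)))


def _profiles(heights, bs):
    return [
        MicrographiaProfile(mean_letter_height=h, progressive_b=b)
        for h, b in zip(heights, bs)
    ]


def test_reference_thresholds_hand_computed():
    thr = derive_reference_thresholds(_profiles([4, 5, 6], [-0.1, 0.0, 0.1]))
    assert thr.consistent_threshold == pytest.approx(3.0)   # mean 5, sample SD 1
    # b values (−0.1, 0, 0.1): mean 0, sample SD 0.1, so mean − 2·SD = −0.2
    assert thr.progressive_threshold == pytest.approx(-0.2)
    assert thr.n_reference == 3


def test_reference_thresholds_zero_variance_edge():
    thr = derive_reference_thresholds(_profiles([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]))
    assert thr.consistent_threshold == pytest.approx(5.0)
    p = classify_micrographia(
        MicrographiaProfile(mean_letter_height=4.9, progressive_b=0.0), thr
    )
    assert p.consistent_flag is True
    assert p.progressive_flag is False  # boundary equality is negative


def test_reference_thresholds_require_two_subjects():
    with pytest.raises(ValueError):
        derive_reference_thresholds(_profiles([5.0], [0.0]))


@pytest.mark.parametrize(
    "height, b, expect_cons, expect_prog",
    [
        (2.9, 0.0, True, False),    # strictly below height threshold 3.0
        (3.0, 0.0, False, False),   # boundary: strict "below"
        (5.0, -0.35, False, True),  # b more negative than −0.3
    ],
)
def test_classification_strict_inequality(height, b, expect_cons, expect_prog):
    thr = derive_reference_thresholds(_profiles([4, 5, 6], [-0.1, 0.0, 0.1]))
    p = classify_micrographia(
        MicrographiaProfile(mean_letter_height=height, progressive_b=b), thr
    )
    assert p.consistent_flag is expect_cons
    assert p.progressive_flag is expect_prog


def test_classification_flags_missing_when_metric_missing():
    thr = derive_reference_thresholds(_profiles([4, 5, 6], [-0.1, 0.0, 0.1]))
    p = classify_micrographia(MicrographiaProfile(), thr)
    assert p.consistent_flag is None and p.progressive_flag is None


def test_flag_fraction_monotone_in_sd_multiplier(rng):
    """Moving the threshold from −2 SD to −3 SD never flags more subjects."""
    hc = _profiles(rng.lognormal(np.log(5.0), 0.2, 30), rng.normal(-0.05, 0.2, 30))
    cohort = _profiles(rng.lognormal(np.log(4.3), 0.3, 200), rng.normal(-0.14, 0.2, 200))
    fractions = []
    for mult in (2.0, 2.25, 2.5, 2.75, 3.0):
        thr = derive_reference_thresholds(hc, sd_multiplier=mult)
        flagged = sum(
            classify_micrographia(p, thr).consistent_flag for p in cohort
        )
        fractions.append(flagged)
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


def test_flags_invariant_under_common_rescaling(rng):
    """Scaling subject and reference heights together leaves flags unchanged."""
    hc_h = rng.lognormal(np.log(5.0), 0.2, 25)
    hc_b = np.linspace(-0.1, 0.1, 25)
    subj_h = rng.lognormal(np.log(4.3), 0.3, 50)
    flags = {}
    for c in (1.0, 3.7):
        thr = derive_reference_thresholds(_profiles(hc_h * c, hc_b))
        flags[c] = [
            classify_micrographia(
                MicrographiaProfile(mean_letter_height=h * c, progressive_b=0.0), thr
            ).consistent_flag
            for h in subj_h
        ]
    assert flags[1.0] == flags[3.7]
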