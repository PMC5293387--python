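"""Geometry: closed-form volumes vs analytic values and brute-force oracles."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from renovol.geometry import (
    GeometryError,
    KidneyGeometry,
    ResectionSpec,
    TumorGeometry,
    ellipsoid_volume,
    functional_renal_volume,
    praiv,
    raiv,
    sphere_volume,
    spherical_cap_volume,
    volume_analysis,
)

from ._oracles import mc_cap_volume, mc_ellipsoid_volume, quad_sphere_volume


@pytest.mark.parametrize(
    "func, args, expected",
    [
        (sphere_volume, (0.0,), 0.0),
        (sphere_volume, (1.0,), 4.0 * math.pi / 3.0),
        (ellipsoid_volume, (KidneyGeometry(2, 2, 2),), 4.0 * math.pi / 3.0),
        (ellipsoid_volume, (KidneyGeometry(12, 6, 5),), math.pi / 6.0 * 360.0),
        (spherical_cap_volume, (1.0, 0.0), 0.0),
        (spherical_cap_volume, (1.0, 2.0), 4.0 * math.pi / 3.0),
        (spherical_cap_volume, (1.7, 1.5), math.pi * 1.5**2 * (3 * 1.7 - 1.5) / 3.0),
    ],
)
def test_analytic_values(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=1e-12)


def test_sphere_volume_matches_quadrature_of_cross_sections():
    assert sphere_volume(1.7) == pytest.approx(quad_sphere_volume(1.7), rel=1e-10)


def test_cap_volume_matches_point_counting_oracle(rng):
    for a, h in [(1.7, 1.5), (1.0, 0.3), (2.5, 4.0), (0.8, 0.8), (3.0, 1.2)]:
        assert spherical_cap_volume(a, h) == pytest.approx(
            mc_cap_volume(a, h, rng), rel=5e-3
        )


def test_ellipsoid_volume_matches_rejection_sampling_oracle(rng):
    kidney = KidneyGeometry(11, 6, 4.5)
    assert ellipsoid_volume(kidney) == pytest.approx(
        mc_ellipsoid_volume(11, 6, 4.5, rng), rel=5e-3
    )


@given(
    a=st.floats(0.1, 5.0),
    h1=st.floats(0.0, 12.0),
    h2=st.floats(0.0, 12.0),
)
def test_cap_volume_monotone_in_height(a, h1, h2):
    lo, hi = sorted((h1, h2))
    assert spherical_cap_volume(a, lo) <= spherical_cap_volume(a, hi) + 1e-12


@given(a1=st.floats(0.1, 5.0), a2=st.floats(0.1, 5.0), h=st.floats(0.0, 0.2))
def test_cap_volume_monotone_in_radius_below_clamp(a1, a2, h):
    # h <= 2a for both radii here, so the cap grows with the sphere
    lo, hi = sorted((a1, a2))
    assert spherical_cap_volume(lo, h) <= spherical_cap_volume(hi, h) + 1e-12


@given(a=st.floats(0.1, 5.0), excess=st.floats(0.0, 3.0))
def test_cap_volume_saturates_continuously_at_full_sphere(a, excess):
    assert spherical_cap_volume(a, 2 * a + excess) == pytest.approx(
        sphere_volume(a), rel=1e-12
    )


@given(
    radius=st.floats(0.3, 2.0),
    depth=st.floats(0.0, 4.0),
    margin=st.floats(0.0, 0.6),
)
def test_raiv_bounded_by_enlarged_sphere(radius, depth, margin):
    tumor = TumorGeometry(radius, depth)
    assert raiv(tumor, ResectionSpec(margin)) <= sphere_volume(radius + margin) + 1e-12


def test_raiv_fully_endophytic_equals_enlarged_sphere():
    # depth + margin >= 2(radius + margin): cap clamps to the whole sphere
    tumor = TumorGeometry(0.5, 1.0)
    assert raiv(tumor, ResectionSpec(0.0)) == pytest.approx(sphere_volume(0.5), rel=1e-12)
    assert raiv(tumor, ResectionSpec(0.0)) == pytest.approx(0.5236, abs=1e-4)


def test_raiv_zero_when_exophytic_with_no_margin():
    assert raiv(TumorGeometry(1.2, 0.0), ResectionSpec(0.0)) == 0.0


def test_raiv_matches_cap_oracle_at_default_margin(rng):
    tumor = TumorGeometry(1.2, 1.0)
    expected = math.pi * 1.5**2 * (3 * 1.7 - 1.5) / 3.0
    assert raiv(tumor, ResectionSpec(0.5)) == pytest.approx(expected, rel=1e-12)
    assert raiv(tumor, ResectionSpec(0.5)) == pytest.approx(
        mc_cap_volume(1.7, 1.5, rng), rel=5e-3
    )


def test_raiv_accepts_alternative_cap_strategy():
    tumor = TumorGeometry(1.0, 1.0)
    assert raiv(tumor, ResectionSpec(0.5), cap_volume=lambda a, h: a * h) == 1.5 * 1.5


def test_functional_renal_volume_composition():
    kidney = KidneyGeometry(12, 6, 5)
    tiny = functional_renal_volume(kidney, TumorGeometry(1e-9, 0.0))
    assert tiny == pytest.approx(376.99, abs=0.01)
    with_tumor = functional_renal_volume(kidney, TumorGeometry(1.7, 0.0))
    assert with_tumor == pytest.approx(tiny - sphere_volume(1.7), abs=1e-6)


def test_functional_renal_volume_rejects_tumor_exceeding_kidneys():
    kidney = KidneyGeometry(2, 2, 2)  # bilateral volume 8pi/3
    radius = (2.0) ** (1 / 3)  # sphere volume = 8pi/3 exactly
    with pytest.raises(GeometryError):
        functional_renal_volume(kidney, TumorGeometry(radius, 0.0))


def test_praiv_zero_when_nothing_resected():
    value = praiv(TumorGeometry(1.0, 0.0), KidneyGeometry(11, 6, 4.5), ResectionSpec(0.0))
    assert value == 0.0


def test_praiv_scaling_law_small_tumor_limit():
    # With negligible tumor volume, doubling all kidney axes divides PRAIV by 8
    tumor = TumorGeometry(1e-4, 1e-4)
    spec = ResectionSpec(0.5)
    small = praiv(tumor, KidneyGeometry(11, 6, 4.5), spec)
    big = praiv(tumor, KidneyGeometry(22, 12, 9), spec)
    assert small / big == pytest.approx(8.0, rel=1e-6)


def test_praiv_symmetric_in_kidney_axes():
    tumor = TumorGeometry(1.7, 1.7)
    spec = ResectionSpec(0.5)
    reference = praiv(tumor, KidneyGeometry(11, 6, 4.5), spec)
    for axes in [(6, 11, 4.5), (4.5, 6, 11), (6, 4.5, 11)]:
        assert praiv(tumor, KidneyGeometry(*axes), spec) == pytest.approx(reference, rel=1e-12)


def test_praiv_composition_against_oracles(rng):
    tumor = TumorGeometry(1.7, 1.7)
    kidney = KidneyGeometry(11, 6, 4.5)
    cap = mc_cap_volume(1.7 + 0.5, 1.7 + 0.5, rng)
    denom = 2 * mc_ellipsoid_volume(11, 6, 4.5, rng) - quad_sphere_volume(1.7)
    assert praiv(tumor, kidney, ResectionSpec(0.5)) == pytest.approx(
        100.0 * cap / denom, rel=1e-2
    )


@given(
    radius=st.floats(0.3, 2.0),
    depth=st.floats(0.0, 3.0),
    margin=st.floats(0.0, 0.6),
    length=st.floats(10.0, 13.0),
    width=st.floats(5.0, 7.0),
    height=st.floats(4.0, 5.5),
)
def test_praiv_within_percentage_bounds_for_clinical_inputs(
    radius, depth, margin, length, width, height
):
    value = praiv(
        TumorGeometry(radius, depth),
        KidneyGeometry(length, width, height),
        ResectionSpec(margin),
    )
    assert 0.0 <= value <= 100.0


def test_volume_analysis_bundles_consistently():
    result = volume_analysis(
        TumorGeometry(1.7, 1.7), KidneyGeometry(11, 6, 4.5), ResectionSpec(0.5)
    )
    assert result.praiv_pct == pytest.approx(
        100.0 * result.raiv_cm3 / result.functional_volume_cm3, rel=1e-12
    )


@pytest.mark.parametrize(
    "builder",
    [
        lambda: TumorGeometry(-1.0, 0.5),
        lambda: TumorGeometry(0.0, 0.5),
        lambda: TumorGeometry(1.0, -0.1),
        lambda: KidneyGeometry(0.0, 6, 4.5),
        lambda: KidneyGeometry(11, -6, 4.5),
        lambda: ResectionSpec(-0.5),
        lambda: sphere_volume(-1.0),
        lambda: spherical_cap_volume(-1.0, 1.0),
        lambda: spherical_cap_volume(1.0, -1.0),
    ],
)
def test_domain_errors(builder):
    with pytest.raises(GeometryError):
        builder()
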