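"""Stimulus generators: magnitude statistics, placement and dataset plumbing."""

import numpy as np
import pytest
from scipy import ndimage

from numgen import stimuli
from numgen.stimuli import (DotParams, FrameSpec, PackingError,
                            build_dataset, place_items, render_nonuniform_dots,
                            render_smoothed_squares, render_uniform_dots,
                            sample_dot_areas, smooth_and_gamma,
                            truncated_area_mean)

EIGHT = np.ones((3, 3))  # 8-connectivity for the component-count oracle


def components(img, spec):
    mask = img > (spec.intensity_levels - 1) / 2.0
    return ndimage.label(mask, structure=EIGHT)[1]


# ---------------------------------------------------------------------------
# dot-area sampling


def test_dot_area_mean_and_sd_at_n1(rng):
    """At n=1 the per-dot distribution is effectively untruncated
    Normal(150, 8^2): 10,000 draws recover both parameters."""
    params = DotParams()
    draws = np.concatenate([sample_dot_areas(1, params, rng)
                            for _ in range(10_000)])
    se_mean = params.sigma_dot / np.sqrt(draws.size)
    assert abs(draws.mean() - 150.0) < 2 * se_mean + 0.01
    se_sd = params.sigma_dot / np.sqrt(2 * (draws.size - 1))
    assert abs(draws.std(ddof=1) - 8.0) < 2 * se_sd + 0.01


def test_dot_area_zero_variance_is_exact(rng):
    areas = sample_dot_areas(3, DotParams(sigma_dot=0.0), rng)
    np.testing.assert_allclose(areas, 50.0)


def test_frame_area_expectation_at_n8(rng):
    """Monte-Carlo oracle: 5,000 frames at n=8 have mean cumulative area
    within 2 SE of the (truncation-corrected) expectation, which itself
    stays within about half a percent per dot of mu_frame."""
    params = DotParams()
    sums = np.array([sample_dot_areas(8, params, rng).sum()
                     for _ in range(5_000)])
    expected = 8 * truncated_area_mean(8, params)
    se = sums.std(ddof=1) / np.sqrt(sums.size)
    assert abs(sums.mean() - expected) < 2 * se
    assert abs(expected - 150.0) / 150.0 < 0.03  # documented truncation bias


def test_dot_area_edge_cases(rng):
    assert sample_dot_areas(0, DotParams(), rng).size == 0
    with pytest.raises(ValueError):
        sample_dot_areas(-1, DotParams(), rng)
    assert np.all(sample_dot_areas(50, DotParams(), rng)
                  >= stimuli.MIN_DOT_AREA)


# ---------------------------------------------------------------------------
# placement


def test_place_items_respects_overlap_rule(rng):
    """Brute-force pairwise check: all 28 centre distances at n=8 exceed the
    sum of the radii."""
    spec, params = FrameSpec(), DotParams()
    radii = np.full(8, params.uniform_radius)
    centers = place_items(8, radii, spec, params, rng)
    assert centers.shape == (8, 2)
    for i in range(8):
        for j in range(i + 1, 8):
            d = np.hypot(*(centers[i] - centers[j]))
            assert d >= radii[i] + radii[j]


def test_place_single_item_stays_inside_frame(rng):
    spec, params = FrameSpec(), DotParams()
    (cy, cx), = place_items(1, [2.0], spec, params, rng)
    lo = params.margin + 2.0
    assert lo <= cy <= spec.height - 1 - lo + params.margin
    assert lo <= cx <= spec.width - 1 - lo + params.margin


def test_place_items_infeasible_packing_raises(rng):
    spec, params = FrameSpec(), DotParams()
    with pytest.raises(PackingError):
        place_items(50, np.full(50, 10.0), spec, params, rng)


# ---------------------------------------------------------------------------
# renderers


def test_uniform_dots_basic_properties(rng):
    spec, params = FrameSpec(), DotParams()
    blank = render_uniform_dots(0, spec, params, rng)
    assert np.all(blank.pixels == spec.background_level)
    img = render_uniform_dots(4, spec, params, rng)
    assert img.numerosity == 4
    assert components(img.pixels, spec) == 4
    assert set(np.unique(img.pixels)) <= {spec.background_level,
                                          spec.foreground_level}


def test_uniform_dots_area_proportional_to_n(rng):
    """Fixed radius means cumulative foreground area grows linearly: the
    mean rendered area at n=8 is twice that at n=4."""
    spec, params = FrameSpec(), DotParams()
    a4 = np.mean([(render_uniform_dots(4, spec, params, rng).pixels > 127)
                  .sum() for _ in range(150)])
    a8 = np.mean([(render_uniform_dots(8, spec, params, rng).pixels > 127)
                  .sum() for _ in range(150)])
    assert abs(a8 / a4 - 2.0) < 0.05


def test_uniform_dots_area_strictly_increasing_in_n(rng):
    spec, params = FrameSpec(), DotParams()
    means = [np.mean([(render_uniform_dots(n, spec, params, rng).pixels > 127)
                      .sum() for _ in range(80)]) for n in range(1, 9)]
    assert np.all(np.diff(means) > 0)


def test_nonuniform_dots_constant_expected_area(rng):
    """The defining property of the family: rendered cumulative area has the
    same expectation at every numerosity (up to the documented truncation
    and rasterisation bias)."""
    spec, params = FrameSpec(), DotParams()
    for n in (1, 4, 8):
        areas = [(render_nonuniform_dots(n, spec, params, rng).pixels > 127)
                 .sum() for _ in range(400)]
        expected = n * truncated_area_mean(n, params)
        assert abs(np.mean(areas) - expected) / expected < 0.04, n


def test_nonuniform_dots_zero_variance_and_label(rng):
    spec = FrameSpec()
    params = DotParams(sigma_dot=0.0)
    np.testing.assert_allclose(sample_dot_areas(2, params, rng), 75.0)
    img = render_nonuniform_dots(2, spec, params, rng)
    assert img.numerosity == 2
    assert components(img.pixels, spec) == 2
    # both dots carry area 75; rasterisation jitters pixel counts by a few
    lab, _ = ndimage.label(img.pixels > 127, structure=EIGHT)
    sizes = np.bincount(lab.ravel())[1:]
    assert abs(int(sizes[0]) - int(sizes[1])) <= 5


def test_nonuniform_single_dot_area_sd(rng):
    """10,000 single-dot frames: SD of the rendered dot area tracks the
    configured sigma (rasterisation adds a little jitter)."""
    spec, params = FrameSpec(), DotParams()
    areas = np.array([(render_nonuniform_dots(1, spec, params, rng).pixels
                       > 127).sum() for _ in range(2_000)])
    assert abs(areas.std(ddof=1) - 8.0) < 1.5


def test_smoothed_squares_gamma_lifts_intensities(rng):
    """x**0.25 >= x on [0, 1]: the gamma stage can only raise the
    mean-filtered intensities."""
    hard = (rng.random((16, 16)) < 0.2).astype(float) * 255
    out = smooth_and_gamma(hard, 256)
    pre = np.rint(np.clip(
        ndimage.uniform_filter(hard / 255.0, size=3, mode="constant"),
        0, 1) * 255)
    assert np.all(out >= pre)
    blank = smooth_and_gamma(np.zeros((8, 8)), 256)
    assert np.all(blank == 0)


def test_smoothed_squares_render(rng):
    spec, params = FrameSpec(), DotParams()
    img = render_smoothed_squares(3, spec, params, rng)
    assert img.numerosity == 3
    assert components(img.pixels, spec) == 3
    # smoothing necessarily populates intermediate intensity levels
    levels = set(np.unique(img.pixels))
    assert levels - {spec.background_level, spec.foreground_level}


@pytest.mark.parametrize("family", ["uniform", "nonuniform", "squares"])
def test_label_equals_component_count(family, rng):
    spec, params = FrameSpec(), DotParams()
    for n in (1, 3, 6, 8):
        img = stimuli.render_frame(family, n, spec, params, rng)
        assert components(img.pixels, spec) == n


# ---------------------------------------------------------------------------
# dataset assembly


def test_build_dataset_sizes_and_balance():
    bundle = build_dataset("uniform", numerosities=range(1, 9),
                           split_sizes=(80, 16, 16), master_seed=5)
    assert [len(bundle.train), len(bundle.validation),
            len(bundle.test)] == [80, 16, 16]
    _, y = bundle.arrays("train")
    counts = np.bincount(y)[1:9]
    assert np.all(counts == 10)  # uniform allocation
    assert set(y) == set(range(1, 9))


def test_build_dataset_is_pure_function_of_seed():
    a = build_dataset("uniform", numerosities=(1, 2, 3),
                      split_sizes=(30, 10, 10), master_seed=9)
    b = build_dataset("uniform", numerosities=(1, 2, 3),
                      split_sizes=(30, 10, 10), master_seed=9)
    for split in ("train", "validation", "test"):
        Xa, ya = a.arrays(split)
        Xb, yb = b.arrays(split)
        assert np.array_equal(Xa, Xb) and np.array_equal(ya, yb)
    c = build_dataset("uniform", numerosities=(1, 2, 3),
                      split_sizes=(30, 10, 10), master_seed=10)
    assert not np.array_equal(a.arrays("train")[0], c.arrays("train")[0])


def test_build_dataset_mixture_interleaves():
    bundle = build_dataset("mixed", numerosities=(1, 2),
                           split_sizes=(20, 4, 4), master_seed=1,
                           spec=stimuli.TINY_SPEC, params=stimuli.TINY_PARAMS)
    fams = [im.family for im in bundle.train]
    assert fams[::2] == ["uniform_dots"] * 10
    assert fams[1::2] == ["smoothed_squares"] * 10


def test_build_dataset_rejects_bad_inputs():
    with pytest.raises(ValueError):
        build_dataset("blobs")
    with pytest.raises(ValueError):
        build_dataset("uniform", numerosities=())
    with pytest.raises(ValueError):
        build_dataset("uniform", split_sizes=(10, 0, 10))


def test_bundle_disk_roundtrip(tmp_path):
    bundle = build_dataset("uniform", numerosities=(1, 2),
                           split_sizes=(12, 4, 4), master_seed=2,
                           spec=stimuli.TINY_SPEC, params=stimuli.TINY_PARAMS)
    stimuli.save_bundle(bundle, tmp_path / "ds")
    back = stimuli.load_bundle(tmp_path / "ds")
    assert back.numerosity_set == bundle.numerosity_set
    for split in ("train", "validation", "test"):
        Xa, ya = bundle.arrays(split)
        Xb, yb = back.arrays(split)
        assert np.array_equal(Xa, Xb) and np.array_equal(ya, yb)


def test_spec_and_params_validation():
    with pytest.raises(ValueError):
        FrameSpec(intensity_levels=1)
    with pytest.raises(ValueError):
        FrameSpec(background_level=5, foreground_level=5)
    with pytest.raises(ValueError):
        DotParams(mu_frame=-1)
    with pytest.raises(ValueError):
        DotParams(uniform_radius=0.5)
    with pytest.raises(ValueError):
        DotParams(min_center_distance_policy="bogus")
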