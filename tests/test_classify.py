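"""NGRDI computation and Otsu thresholding."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowncloud.classify import (
    classify_by_cvi,
    compute_ngrdi,
    ngrdi,
    normalize_colors,
    otsu_threshold,
)
from crowncloud.pointcloud import ColoredPointCloud


def cloud_from_rgb(rgb: list[tuple[int, int, int]]) -> ColoredPointCloud:
    arr = np.array(rgb)
    n = len(arr)
    zeros = np.zeros(n)
    return ColoredPointCloud(zeros, zeros, zeros, arr[:, 0], arr[:, 1], arr[:, 2])


def brute_force_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent exhaustive maximizer of between-class variance.

    Loops over every interior bin edge of the uniform histogram, computing
    class weights and means directly from the bin counts.
    """
    counts, edges = np.histogram(values, bins=n_bins,
                                 range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    scores = []
    for k in range(n_bins - 1):  # cut after bin k
        w0 = counts[:k + 1].sum()
        w1 = counts[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k + 1] * centers[:k + 1]).sum() / w0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2  # ∝ between-class variance
        scores.append((var, edges[k + 1]))
    best_var = max(v for v, _ in scores)
    # same tie rule as the implementation: lowest edge among tied maxima
    return float(next(e for v, e in scores if v >= best_var - 1e-9 * abs(best_var)))


@pytest.mark.parametrize("rgb,expected", [
    ((255, 255, 255), (1 / 3, 1 / 3, 1 / 3)),
    ((0, 255, 0), (0.0, 1.0, 0.0)),
    ((0, 0, 0), (0.0, 0.0, 0.0)),
])
def test_normalize_colors_examples(rgb, expected):
    chroma = normalize_colors(cloud_from_rgb([rgb]))
    np.testing.assert_allclose(chroma[0], expected, atol=1e-12)


def test_chromatic_rows_sum_to_one():
    rng = np.random.default_rng(0)
    cloud = cloud_from_rgb(list(map(tuple, rng.integers(1, 256, size=(200, 3)))))
    np.testing.assert_allclose(normalize_colors(cloud).sum(axis=1), 1.0, atol=1e-12)


@pytest.mark.parametrize("rgb,expected", [
    ((100, 100, 100), 0.0),   # gray
    ((0, 255, 0), 1.0),       # pure green
    ((255, 0, 0), -1.0),      # pure red
    ((0, 0, 255), 0.0),       # pure blue: g + r = 0 rule
])
def test_ngrdi_reference_colors(rgb, expected):
    value = ngrdi(cloud_from_rgb([rgb]))[0]
    assert value == pytest.approx(expected, abs=1e-12)


@given(r=st.integers(0, 51), g=st.integers(0, 51), b=st.integers(0, 51),
       c=st.integers(1, 5))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_ngrdi_scale_invariance(r, g, b, c):
    """Uniform color scaling cancels in the chromatic coordinates, so
    pre-normalizing channels by their maximum cannot change the index."""
    base = ngrdi(cloud_from_rgb([(r, g, b)]))[0]
    scaled = ngrdi(cloud_from_rgb([(c * r, c * g, c * b)]))[0]
    assert scaled == pytest.approx(base, abs=1e-12)


def test_ngrdi_bounded():
    rng = np.random.default_rng(1)
    cloud = cloud_from_rgb(list(map(tuple, rng.integers(0, 256, size=(500, 3)))))
    values = ngrdi(cloud)
    assert np.all(values >= -1.0) and np.all(values <= 1.0)


def test_otsu_two_spikes_separates():
    values = np.concatenate([np.full(500, -0.5), np.full(500, 0.5)])
    t = otsu_threshold(values)
    assert -0.5 < t < 0.5


def test_otsu_degenerate_distribution():
    with pytest.raises(ValueError, match="degenerate"):
        otsu_threshold(np.full(100, 0.3))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_otsu_equals_brute_force(seed):
    """The vectorized threshold equals the exhaustive bin-edge maximizer on
    a bimodal Gaussian mixture (means -0.2 / +0.4, sd 0.05)."""
    rng = np.random.default_rng(seed)
    values = np.concatenate([rng.normal(-0.2, 0.05, 1000),
                             rng.normal(0.4, 0.05, 1000)])
    assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values))
    assert -0.2 < otsu_threshold(values) < 0.4


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_otsu_brute_force_on_arbitrary_inputs(seed):
    rng = np.random.default_rng(seed)
    values = rng.beta(0.5, 0.5, size=rng.integers(50, 5000)) * 2 - 1
    assert otsu_threshold(values) == pytest.approx(brute_force_otsu(values))


def test_otsu_matches_skimage_within_a_bin():
    """Cross-check against an established Otsu implementation: the two
    conventions can differ by at most one histogram bin."""
    from skimage.filters import threshold_otsu

    rng = np.random.default_rng(42)
    values = np.concatenate([rng.normal(-0.15, 0.06, 1500),
                             rng.normal(0.35, 0.08, 1500)])
    bin_width = (values.max() - values.min()) / 256
    ours = otsu_threshold(values, n_bins=256)
    theirs = threshold_otsu(values, nbins=256)
    assert abs(ours - theirs) <= bin_width + 1e-12


def test_classification_is_a_partition():
    rng = np.random.default_rng(3)
    cloud = cloud_from_rgb(list(map(tuple, rng.integers(0, 256, size=(1000, 3)))))
    veg, nonveg, fld = classify_by_cvi(cloud)
    assert len(veg) + len(nonveg) == len(cloud)
    assert set(veg.classes) <= {"vegetation"}
    assert set(nonveg.classes) <= {"nonvegetation"}
    # strict inequality: ties at the threshold fall to nonvegetation
    assert np.all(ngrdi(veg) > fld.threshold)
    assert np.all(ngrdi(nonveg) <= fld.threshold)


def test_all_green_cloud_leaves_nonvegetation_empty():
    cloud = cloud_from_rgb([(0, 255, 0)] * 10)
    veg, nonveg, _ = classify_by_cvi(cloud, threshold=0.0)
    assert len(nonveg) == 0 and len(veg) == 10


def test_synthetic_scene_recovery(small_scene):
    """≥95% of crown-origin points classify as vegetation, and ≥95% of
    ground-origin points as nonvegetation, with the generator's default
    canopy/ground color separation."""
    veg, nonveg, fld = classify_by_cvi(small_scene.cloud)
    pred_veg = fld.values > fld.threshold
    canopy = small_scene.provenance == "canopy"
    ground = small_scene.provenance == "ground"
    assert pred_veg[canopy].mean() >= 0.95
    assert (~pred_veg[ground]).mean() >= 0.95
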