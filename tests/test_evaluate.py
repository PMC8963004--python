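"""Plot clipping, detection matching, and accuracy statistics."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from crowncloud.evaluate import (
    MatchResult,
    Metrics,
    Plot,
    aggregate,
    clip_to_plot,
    compute_metrics,
    load_published_plot_counts,
    match_trees,
    metrics_from_counts,
    round_half_up,
)
from crowncloud.pointcloud import ReferenceTreeSet


def optimal_assignment(det: np.ndarray, ref: np.ndarray, max_dist: float):
    """Brute-force best one-to-one matching: maximum number of pairs, then
    minimum total distance, by enumeration (feasible for ≤8 per side)."""
    n_d, n_r = len(det), len(ref)
    dist = np.hypot(det[:, 0, None] - ref[None, :, 0],
                    det[:, 1, None] - ref[None, :, 1])
    best = (0, 0.0)
    if n_d <= n_r:
        candidates = ([(d, r) for d, r in enumerate(perm)]
                      for perm in permutations(range(n_r), n_d))
    else:
        candidates = ([(d, r) for r, d in enumerate(perm)]
                      for perm in permutations(range(n_d), n_r))
    for assignment in candidates:
        pairs = [(d, r) for d, r in assignment if dist[d, r] <= max_dist]
        total = sum(dist[d, r] for d, r in pairs)
        if (len(pairs), -total) > (best[0], -best[1]):
            best = (len(pairs), total)
    return best


def test_plot_geometry():
    plot = Plot(id=1, x=0, y=0, radius=12.7)
    assert plot.area == pytest.approx(506.7, abs=0.05)


def test_clip_boundary_rules():
    plot = Plot(id=1, x=10.0, y=10.0, radius=5.0)
    pts = np.array([[10.0, 10.0],      # center
                    [15.0, 10.0],      # exactly on the boundary
                    [15.0001, 10.0]])  # just outside
    mask = clip_to_plot(pts, plot)
    assert mask.tolist() == [True, True, False]


def test_clip_retains_geometric_fraction():
    rng = np.random.default_rng(0)
    side, r, n = 40.0, 12.7, 20000
    pts = rng.uniform(0, side, (n, 2))
    plot = Plot(id=1, x=side / 2, y=side / 2, radius=r)
    p = np.pi * r ** 2 / side ** 2
    k = clip_to_plot(pts, plot).sum()
    sigma = np.sqrt(n * p * (1 - p))
    assert abs(k - n * p) <= 3 * sigma


def test_match_identical_sets():
    pts = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
    mr = match_trees(pts, pts)
    assert (mr.tp, mr.fp, mr.fn) == (3, 0, 0)
    assert all(d == 0.0 for _, _, d in mr.pairs)


def test_match_no_detections():
    mr = match_trees(np.empty((0, 2)), np.random.default_rng(1).uniform(0, 10, (5, 2)))
    assert (mr.tp, mr.fp, mr.fn) == (0, 0, 5)


def test_match_jittered_detections():
    rng = np.random.default_rng(2)
    ref = rng.uniform(0, 50, (20, 2))
    det = ref + rng.uniform(-0.35, 0.35, (20, 2))  # jitter ≤ 0.5 m
    mr = match_trees(det, ref)
    assert (mr.tp, mr.fp, mr.fn) == (20, 0, 0)


@pytest.mark.parametrize("seed", range(6))
def test_greedy_matches_optimal_assignment_small(seed):
    """On spaced instances with ≤8 trees per side the greedy nearest-pair
    matching attains the optimum (max pairs, then min total distance)."""
    rng = np.random.default_rng(seed)
    n_ref = rng.integers(2, 8)
    n_det = rng.integers(1, 8)
    ref = rng.uniform(0, 20, (n_ref, 2))
    det = rng.uniform(0, 20, (n_det, 2))
    mr = match_trees(det, ref, max_dist=2.5)
    opt_tp, _ = optimal_assignment(det, ref, 2.5)
    assert mr.tp == opt_tp


def test_match_counts_are_consistent():
    rng = np.random.default_rng(3)
    det = rng.uniform(0, 30, (17, 2))
    ref = rng.uniform(0, 30, (23, 2))
    mr = match_trees(det, ref)
    assert mr.tp + mr.fp == 17
    assert mr.tp + mr.fn == 23


@pytest.mark.parametrize("tp,fp,fn,s,p,f", [
    (11, 2, 9, 0.55, 0.85, 0.67),  # a published plot with both error types
    (16, 0, 0, 1.00, 1.00, 1.00),  # perfect detection
    (0, 0, 3, 0.00, 0.00, 0.00),   # nothing detected: all stats zero
])
def test_metric_arithmetic(tp, fp, fn, s, p, f):
    m = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn)).rounded()
    assert (m.sensitivity, m.precision, m.fscore) == (s, p, f)


def test_metrics_need_reference_trees():
    with pytest.raises(ValueError, match="no reference"):
        compute_metrics(MatchResult(tp=0, fp=4, fn=0))


def test_fscore_between_s_and_p():
    rng = np.random.default_rng(4)
    for _ in range(50):
        tp = int(rng.integers(1, 30))
        mr = MatchResult(tp=tp, fp=int(rng.integers(0, 10)),
                         fn=int(rng.integers(0, 10)))
        m = compute_metrics(mr)
        assert min(m.sensitivity, m.precision) - 1e-12 <= m.fscore
        assert m.fscore <= max(m.sensitivity, m.precision) + 1e-12


def test_round_half_up():
    assert round_half_up(0.845, 2) == 0.85
    assert round_half_up(0.6666666, 2) == 0.67
    assert round_half_up(72.87878, 1) == 72.9


def test_published_counts_reproduce_printed_stats():
    """Every printed per-plot S/P/F cell follows from its TP/FP/FN triplet
    (±0.01 for the original report's own rounding)."""
    table = load_published_plot_counts()
    assert len(table) == 30
    for prefix in ("cvi", "tin"):
        results = metrics_from_counts(table, prefix)
        for (mr, metrics), (_, row) in zip(results, table.iterrows()):
            m = metrics.rounded()
            assert m.sensitivity == pytest.approx(row[f"{prefix}_s"], abs=0.01)
            assert m.precision == pytest.approx(row[f"{prefix}_p"], abs=0.01)
            assert m.fscore == pytest.approx(row[f"{prefix}_f"], abs=0.01)


def test_published_counts_aggregates():
    """Totals and unweighted per-plot means over the published 30 plots."""
    table = load_published_plot_counts()
    manual_total = int(table["manual"].sum())
    assert manual_total == 660
    cvi = aggregate(metrics_from_counts(table, "cvi"), total_reference=manual_total)
    tin = aggregate(metrics_from_counts(table, "tin"), total_reference=manual_total)
    assert (cvi["total_tp"], cvi["tp_percent"]) == (481, 72.9)
    assert (cvi["total_fp"], cvi["fp_percent"]) == (8, 1.2)
    assert (cvi["total_fn"], cvi["fn_percent"]) == (171, 25.9)
    assert (tin["total_tp"], tin["tp_percent"]) == (392, 59.4)
    assert cvi["mean_precision"] == 0.98
    assert cvi["mean_sensitivity"] == 0.74
    assert cvi["mean_fscore"] == 0.84
    assert tin["mean_sensitivity"] == 0.62
    assert tin["mean_fscore"] == 0.74


def test_aggregate_small_cases():
    one = [(MatchResult(tp=3, fp=1, fn=1), compute_metrics(MatchResult(3, 1, 1)))]
    agg = aggregate(one)
    assert agg["mean_sensitivity"] == round_half_up(3 / 4, 2)
    assert agg["mean_precision"] == round_half_up(3 / 4, 2)

    two = [(MatchResult(1, 0, 1), Metrics(0.5, 1.0, 2 / 3)),
           (MatchResult(2, 0, 0), Metrics(1.0, 1.0, 1.0))]
    assert aggregate(two)["mean_sensitivity"] == 0.75


def test_evaluate_plot_clips_both_sides():
    from crowncloud.evaluate import evaluate_plot

    ref = ReferenceTreeSet(pd.DataFrame({
        "id": [0, 1, 2], "x": [0.0, 1.0, 30.0], "y": [0.0, 1.0, 30.0]}))
    det = np.array([[0.1, 0.1], [30.0, 30.0], [50.0, 50.0]])
    plot = Plot(id=1, x=0.0, y=0.0, radius=12.7)
    mr, m = evaluate_plot(det, ref, plot)
    # inside the plot: refs 0,1 and detection (0.1, 0.1) only
    assert (mr.tp, mr.fp, mr.fn) == (1, 0, 1)
    assert m.sensitivity == 0.5
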