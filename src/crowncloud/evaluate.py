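"""Detection scoring against reference trees inside circular field plots.

Detections and reference stems are clipped to each circular plot (default
radius 12.7 m, i.e. about 507 m²), matched one-to-one by proximity, and the
usual detection statistics are computed:

    S = TP / (TP + FN)        sensitivity (1 - omission error)
    P = TP / (TP + FP)        precision   (1 - commission error)
    F = 2 S P / (S + P)       F-score     (harmonic mean)

The package also bundles, as a CSV fixture, the published per-plot TP/FP/FN
counts from a field validation of this workflow on a *Pinus radiata*
plantation (30 plots, 660 manually identified trees), for both the
color-index and the progressive-TIN ground-filter routes; the regression
tests recompute every printed S/P/F cell and the printed aggregates from
those counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from crowncloud.pointcloud import ReferenceTreeSet


def round_half_up(value: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (0.845 → 0.85 at 2 dp)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Plot:
    """Circular validation plot."""

    id: int
    x: float
    y: float
    radius: float = 12.7

    @property
    def area(self) -> float:
        return float(np.pi * self.radius ** 2)


@dataclass
class MatchResult:
    """Counts and matched pairs from detection-to-reference matching."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # pairs: (detection index, reference index, distance)


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, precision and F-score as exact fractions in [0, 1]."""

    sensitivity: float
    precision: float
    fscore: float

    def rounded(self, decimals: int = 2) -> "Metrics":
        return Metrics(round_half_up(self.sensitivity, decimals),
                       round_half_up(self.precision, decimals),
                       round_half_up(self.fscore, decimals))


def clip_to_plot(xy: np.ndarray, plot: Plot) -> np.ndarray:
    """Boolean mask of items whose planimetric distance to the plot center
    is <= the plot radius (boundary included)."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    d = np.hypot(xy[:, 0] - plot.x, xy[:, 1] - plot.y)
    return d <= plot.radius


def match_trees(detected: np.ndarray, reference: ReferenceTreeSet | np.ndarray,
                max_dist: float = 2.5) -> MatchResult:
    """Greedy one-to-one matching of detections to reference stems.

    Candidate pairs within ``max_dist`` (default 2.5 m, the maximum crown
    radius) are taken in ascending distance; each detection and each
    reference can be matched once.  Matched pairs count as TP, leftover
    detections as FP, leftover references as FN.
    """
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    ref = reference.xy if isinstance(reference, ReferenceTreeSet) else \
        np.asarray(reference, dtype=float).reshape(-1, 2)
    if len(det) == 0 or len(ref) == 0:
        return MatchResult(tp=0, fp=len(det), fn=len(ref))
    dist = np.hypot(det[:, 0, None] - ref[None, :, 0],
                    det[:, 1, None] - ref[None, :, 1])
    di, ri = np.nonzero(dist <= max_dist)
    order = np.lexsort((ri, di, dist[di, ri]))
    used_det = np.zeros(len(det), dtype=bool)
    used_ref = np.zeros(len(ref), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        d, r = int(di[k]), int(ri[k])
        if used_det[d] or used_ref[r]:
            continue
        used_det[d] = used_ref[r] = True
        pairs.append((d, r, float(dist[d, r])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(det) - tp, fn=len(ref) - tp, pairs=pairs)


def compute_metrics(mr: MatchResult) -> Metrics:
    """Detection statistics from TP/FP/FN counts.

    Precision is defined as 0 when there are no detections, and the F-score
    as 0 when S + P = 0.  Raises when the plot holds no reference trees.
    """
    if mr.tp + mr.fn == 0:
        raise ValueError("no reference trees: sensitivity undefined")
    s = mr.tp / (mr.tp + mr.fn)
    p = mr.tp / (mr.tp + mr.fp) if (mr.tp + mr.fp) > 0 else 0.0
    # 2SP/(S+P) simplifies to 2TP/(2TP+FP+FN), which is exact in floats
    f = 2.0 * mr.tp / (2 * mr.tp + mr.fp + mr.fn) if (s + p) > 0 else 0.0
    return Metrics(sensitivity=s, precision=p, fscore=f)


def aggregate(per_plot: list[tuple[MatchResult, Metrics]],
              total_reference: int | None = None) -> dict:
    """Summary over plots: count totals, shares of the reference total, and
    unweighted means of the per-plot statistics.

    Percentage shares are relative to the total number of reference trees
    (1 dp); means are rounded half-up to 2 dp.  ``total_reference``
    overrides the Σ(TP+FN) total — useful when scoring against an external
    manual inventory whose printed per-plot counts do not all satisfy
    TP + FN = manual count.
    """
    if not per_plot:
        raise ValueError("no plots to aggregate")
    tp = sum(mr.tp for mr, _ in per_plot)
    fp = sum(mr.fp for mr, _ in per_plot)
    fn = sum(mr.fn for mr, _ in per_plot)
    n_ref = total_reference if total_reference is not None else \
        sum(mr.tp + mr.fn for mr, _ in per_plot)
    means = {
        "mean_sensitivity": round_half_up(
            float(np.mean([m.sensitivity for _, m in per_plot])), 2),
        "mean_precision": round_half_up(
            float(np.mean([m.precision for _, m in per_plot])), 2),
        "mean_fscore": round_half_up(
            float(np.mean([m.fscore for _, m in per_plot])), 2),
    }
    shares = {
        "tp_percent": round_half_up(100.0 * tp / n_ref, 1),
        "fp_percent": round_half_up(100.0 * fp / n_ref, 1),
        "fn_percent": round_half_up(100.0 * fn / n_ref, 1),
    }
    return {"n_plots": len(per_plot), "total_reference": n_ref,
            "total_tp": tp, "total_fp": fp, "total_fn": fn, **shares, **means}


def evaluate_plot(detected_xy: np.ndarray, reference: ReferenceTreeSet,
                  plot: Plot, max_dist: float = 2.5
                  ) -> tuple[MatchResult, Metrics]:
    """Clip both sets to the plot, match, and score."""
    det = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    det_in = det[clip_to_plot(det, plot)]
    ref_xy = reference.xy
    ref_in = ref_xy[clip_to_plot(ref_xy, plot)]
    mr = match_trees(det_in, ref_in, max_dist=max_dist)
    return mr, compute_metrics(mr)


def load_published_plot_counts() -> pd.DataFrame:
    """The bundled published 30-plot validation counts.

    Columns: ``plot``, ``manual`` (manually identified trees), and
    ``tp/fp/fn/s/p/f`` for the color-index (``cvi_``) and progressive-TIN
    (``tin_``) routes, exactly as printed in the original field validation
    (including its known internal inconsistencies, e.g. rows where
    TP + FN != manual).
    """
    with resources.files("crowncloud.data").joinpath(
            "pinus_radiata_plot_counts.csv").open() as fh:
        return pd.read_csv(fh)


def metrics_from_counts(table: pd.DataFrame, prefix: str
                        ) -> list[tuple[MatchResult, Metrics]]:
    """Recompute per-plot metrics from a TP/FP/FN count table.

    ``prefix`` selects the ``cvi`` or ``tin`` column block.
    """
    out = []
    for _, row in table.iterrows():
        mr = MatchResult(tp=int(row[f"{prefix}_tp"]), fp=int(row[f"{prefix}_fp"]),
                         fn=int(row[f"{prefix}_fn"]))
        out.append((mr, compute_metrics(mr)))
    return out
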