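"""Cohort summaries and nonparametric segment comparison.

Accuracy metrics are summarised as median and range per segment.  Between-
segment differences (four related samples per pair) are tested with the
classical Friedman statistic — within-subject mid-ranks, no tie correction:

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1),   df = k - 1

Metrics with a significant Friedman test (p < 0.05) are followed up with
all six pairwise Wilcoxon signed-rank tests, Bonferroni-corrected with
m = 6.  The Wilcoxon p is exact for n <= 25 non-zero differences and uses
the normal approximation with tie and continuity corrections above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anatomy import REGISTRATION_SEGMENTS

__all__ = [
    "METRICS",
    "SegmentComparisonTable",
    "median_and_range",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni_adjust",
    "build_comparison_table",
    "reports_to_frame",
]

#: report column -> human-readable row label (Table-style layout)
METRICS = {
    "translation_mm": "Translation error (mm)",
    "rotation_deg": "Rotation error (deg)",
    "euclid_mm": "Euclidean distance (mm)",
    "euler_deg": "Euler's angle (deg)",
}

ALPHA = 0.05
N_PAIRWISE = 6  # all pairs among the four segments


def median_and_range(values) -> tuple[float, float, float]:
    """(median, min, max); the median of an even count is the mean of the
    two middle values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    return float(np.median(v)), float(v.min()), float(v.max())


def friedman_test(matrix) -> tuple[float, int, float]:
    """Classical Friedman test for n subjects x k >= 3 related samples.

    Returns (chi_square, df, p).  Ties within a subject receive mid-ranks;
    no tie correction is applied (the classical statistic).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if k < 3:
        raise ValueError("Friedman needs k >= 3 related samples; "
                         "use the Wilcoxon signed-rank test for k = 2")
    if n < 2:
        raise ValueError("Friedman needs at least 2 subjects")
    if not np.isfinite(m).all():
        raise ValueError("matrix contains missing or non-finite cells")
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((col_sums**2).sum()) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; at least 5 non-zero differences are
    required.  Returns (W, p) with W = min(W+, W-); exact p for n <= 25,
    normal approximation with tie/continuity correction above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    if len(nz) < 5:
        raise ValueError("need at least 5 non-zero differences")
    method = "exact" if len(nz) <= 25 else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, m: int) -> list[float]:
    """Elementwise ``min(1, p * m)``."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return [float(min(1.0, x * m)) for x in p]


@dataclass(frozen=True)
class SegmentComparisonTable:
    """Segment x metric comparison of restoration accuracy.

    ``summary`` holds median/min/max per (metric, segment); ``abs_medians``
    the medians of absolute errors; ``friedman`` maps metric -> (chi2, df,
    p); ``pairwise`` maps metric -> {(seg_a, seg_b): Bonferroni-adjusted p}
    for metrics whose Friedman test was significant.
    """

    summary: pd.DataFrame
    abs_medians: pd.DataFrame
    friedman: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    n_pairs: int = 0

    def formatted(self) -> pd.DataFrame:
        """Wide table with 'median (min–max)' cells, segments as columns."""
        segments = list(self.summary.index.get_level_values("segment").unique())
        rows = {}
        for metric, label in METRICS.items():
            rows[label] = {
                seg: "{:.1f} ({:.1f}–{:.1f})".format(
                    self.summary.loc[(metric, seg), "median"],
                    self.summary.loc[(metric, seg), "min"],
                    self.summary.loc[(metric, seg), "max"],
                )
                for seg in segments
            }
            if metric in self.friedman:
                rows[label]["friedman_p"] = "{:.3g}".format(self.friedman[metric][2])
        return pd.DataFrame(rows).T


def reports_to_frame(reports: dict) -> pd.DataFrame:
    """Long-form DataFrame from ``{pair_id: {SegmentName: FibulaErrorReport}}``."""
    records = []
    for pair_id, by_segment in reports.items():
        for seg, rep in by_segment.items():
            records.append({
                "pair_id": pair_id,
                "segment": str(seg),
                "translation_mm": rep.translation_error,
                "rotation_deg": rep.rotation_error,
                "euclid_mm": rep.euclidean_distance,
                "euler_deg": rep.euler_angle,
                "icp_rms_mm": rep.icp_rms,
            })
    return pd.DataFrame.from_records(records)


def build_comparison_table(reports) -> SegmentComparisonTable:
    """Build the segment-comparison table from per-pair, per-segment reports.

    ``reports`` is either the nested dict accepted by
    :func:`reports_to_frame` or an equivalent long-form DataFrame.  Every
    pair must have a report for all four registration segments; incomplete
    blocks raise with the missing combinations listed.
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    present = set(df["segment"])
    segments = [str(s) for s in REGISTRATION_SEGMENTS if str(s) in present]
    df = df[df["segment"].isin(segments)]

    missing = []
    for pair_id, grp in df.groupby("pair_id"):
        got = set(grp["segment"])
        missing += [(pair_id, s) for s in segments if s not in got]
    if missing:
        raise ValueError(f"incomplete blocks; missing pair/segment combinations: {missing}")
    if df.empty:
        raise ValueError("no reports to summarise")

    summary_rows = {}
    abs_rows = {}
    friedman: dict = {}
    pairwise: dict = {}
    pivots = {}
    for metric in METRICS:
        pivot = df.pivot(index="pair_id", columns="segment", values=metric)[segments]
        pivots[metric] = pivot
        for seg in segments:
            med, lo, hi = median_and_range(pivot[seg].to_numpy())
            summary_rows[(metric, seg)] = {"median": med, "min": lo, "max": hi}
            abs_rows[(metric, seg)] = {
                "median_abs": float(np.median(np.abs(pivot[seg].to_numpy())))
            }
        if len(pivot) >= 2 and len(segments) >= 3:
            chi2, dof, p = friedman_test(pivot.to_numpy())
            friedman[metric] = (chi2, dof, p)
            if p < ALPHA:
                raw = {}
                for sa, sb in combinations(segments, 2):
                    try:
                        _, pw = wilcoxon_signed_rank(pivot[sa].to_numpy(),
                                                     pivot[sb].to_numpy())
                    except ValueError:
                        pw = np.nan  # degenerate pair (identical columns)
                    raw[(sa, sb)] = pw
                keys = list(raw)
                finite = [k for k in keys if np.isfinite(raw[k])]
                adj = bonferroni_adjust([raw[k] for k in finite], N_PAIRWISE)
                pairwise[metric] = {
                    k: (adj[finite.index(k)] if k in finite else float("nan"))
                    for k in keys
                }

    summary = pd.DataFrame.from_dict(summary_rows, orient="index")
    summary.index = pd.MultiIndex.from_tuples(summary.index, names=["metric", "segment"])
    abs_medians = pd.DataFrame.from_dict(abs_rows, orient="index")
    abs_medians.index = pd.MultiIndex.from_tuples(abs_medians.index,
                                                  names=["metric", "segment"])
    return SegmentComparisonTable(
        summary=summary,
        abs_medians=abs_medians,
        friedman=friedman,
        pairwise=pairwise,
        n_pairs=df["pair_id"].nunique(),
    )
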