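"""Positioning-error metrics and cohort statistics.

Four signed distances (mm) quantify vertical patient positioning:

* ``BCAP = BCDL - BCGTH`` — error of the automatic (image-synthesis) method
  in finding the body centerline,
* ``BCMP = BCGTH - isocenter`` — the manual positioning error actually
  realized by the technologist (the mis-centering),
* ``LCAP`` / ``LCMP`` — the same two quantities for the lung bounding box.

Negative values mean the centerline lies below the gantry center (table too
low), positive above it.  Cohort summaries report mean ± SD with a normal
95 % CI, median/IQR, and the clinically used exceedance fractions
(>10 mm, >20 mm absolute).  Group comparisons use the Mann–Whitney test on
signed and absolute errors, normality is checked with a Lilliefors-style
Kolmogorov–Smirnov test, and size dependence with Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .centerline import CenterlineReport

__all__ = [
    "PositioningErrors",
    "CohortSummary",
    "PositioningResults",
    "positioning_errors",
    "cohort_summary",
    "evaluate_cohort",
    "mann_whitney",
    "spearman",
    "ks_normality",
]


@dataclass(frozen=True)
class PositioningErrors:
    """All four metrics (signed mm) for one case."""

    bcap: float
    bcmp: float
    lcap: Optional[float]
    lcmp: Optional[float]
    case_id: str = "case"
    body_size: Optional[float] = None

    @property
    def abs_bcap(self) -> float:
        return abs(self.bcap)

    @property
    def abs_bcmp(self) -> float:
        return abs(self.bcmp)

    @property
    def abs_lcap(self) -> Optional[float]:
        return None if self.lcap is None else abs(self.lcap)

    @property
    def abs_lcmp(self) -> Optional[float]:
        return None if self.lcmp is None else abs(self.lcmp)


def positioning_errors(report_gt: CenterlineReport, report_dl: CenterlineReport,
                       isocenter_y: float, case_id: str = "case",
                       body_size: Optional[float] = None) -> PositioningErrors:
    """Combine a ground-truth and a predicted centerline report.

    Both reports must be expressed in the same scanner frame (identical
    isocenter coordinate).
    """
    if abs(report_gt.isocenter_y - report_dl.isocenter_y) > 1e-6:
        raise ValueError("centerline reports use different scanner frames")
    bcgth, bcdl = report_gt.body_centerline, report_dl.body_centerline
    lcgth, lcdl = report_gt.lung_centerline, report_dl.lung_centerline
    lcap = None if (lcgth is None or lcdl is None) else lcdl - lcgth
    lcmp = None if lcgth is None else lcgth - isocenter_y
    return PositioningErrors(
        bcap=bcdl - bcgth,
        bcmp=bcgth - isocenter_y,
        lcap=lcap,
        lcmp=lcmp,
        case_id=case_id,
        body_size=body_size,
    )


_METRICS = ("bcap", "bcmp", "lcap", "lcmp")


def _collect(errors: Sequence[PositioningErrors], metric: str,
             absolute: bool) -> np.ndarray:
    vals = [getattr(e, metric) for e in errors]
    vals = np.array([v for v in vals if v is not None], dtype=float)
    return np.abs(vals) if absolute else vals


def _summarize(x: np.ndarray) -> dict:
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = 1.96 * sd / np.sqrt(n)
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "median": float(med),
        "iqr": float(q75 - q25),
        "frac_gt10mm": float(np.mean(np.abs(x) > 10.0)),
        "count_gt20mm": int(np.sum(np.abs(x) > 20.0)),
    }


@dataclass
class CohortSummary:
    """Per-metric signed and absolute summaries as a tidy DataFrame."""

    table: pd.DataFrame

    def row(self, metric: str, absolute: bool = False) -> pd.Series:
        kind = "absolute" if absolute else "signed"
        return self.table.loc[(metric, kind)]

    def __str__(self) -> str:
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:8.2f}".format):
            return str(self.table)


def cohort_summary(errors: Sequence[PositioningErrors]) -> CohortSummary:
    """Mean/SD/CI/median/IQR and exceedance statistics per metric.

    The 95 % CI uses the normal approximation mean ± 1.96·SD/√n.  Requires at
    least two cases.
    """
    if len(errors) < 2:
        raise ValueError("cohort summary requires at least 2 cases")
    rows = {}
    for metric in _METRICS:
        for absolute in (False, True):
            x = _collect(errors, metric, absolute)
            if x.size >= 2:
                rows[(metric, "absolute" if absolute else "signed")] = _summarize(x)
    table = pd.DataFrame(rows).T
    table.index.names = ["metric", "kind"]
    return CohortSummary(table=table)


# ---------------------------------------------------------------------------
# Statistical tests


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 exact_threshold: int = 8) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the smaller sample has at most
    ``exact_threshold`` observations and there are no ties; otherwise the
    normal approximation with tie correction.  Returns (U of sample ``a``,
    two-sided p).  Identical constant samples give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("mann_whitney: all values identical; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= exact_threshold and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_enumerated(a: Sequence[float], b: Sequence[float]
                            ) -> Tuple[float, float]:
    """Brute-force exact Mann–Whitney by enumerating all label assignments.

    Independent oracle for the exact branch of :func:`mann_whitney`; only
    usable for tiny samples (combinatorial cost).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size

    def u_of(sample, other):
        u = 0.0
        for x in sample:
            u += np.sum(x > other) + 0.5 * np.sum(x == other)
        return u

    u_obs = u_of(a, b)
    n_total = pooled.size
    us = []
    for idx in combinations(range(n_total), na):
        sel = np.zeros(n_total, dtype=bool)
        sel[list(idx)] = True
        us.append(u_of(pooled[sel], pooled[~sel]))
    us = np.array(us)
    mean_u = a.size * b.size / 2.0
    # two-sided: as extreme or more, measured from the center
    p = np.mean(np.abs(us - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)
    return float(u_obs), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks on ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires two equal-length samples, n >= 3")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def ks_normality(x: Sequence[float], n_sims: int = 500,
                 seed: int = 0) -> Tuple[float, float]:
    """Kolmogorov–Smirnov normality test with estimated mean/SD
    (Lilliefors-style), p-value by Monte-Carlo under a fixed seed.

    The null distribution of the statistic is location-scale free, so the
    simulation draws standard-normal samples, refits, and compares.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("ks_normality requires n >= 5")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return 1.0, 0.0
    d_obs = stats.kstest(x, "norm", args=(mean, sd)).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_sims):
        s = rng.standard_normal(x.size)
        d = stats.kstest(s, "norm", args=(s.mean(), s.std(ddof=1))).statistic
        if d >= d_obs:
            count += 1
    p = (count + 1) / (n_sims + 1)
    return float(d_obs), float(p)


# ---------------------------------------------------------------------------
# Cohort evaluation (results object)


@dataclass
class PositioningResults:
    """Cohort evaluation results: per-case errors, summaries, and tests."""

    errors: List[PositioningErrors]
    summary_table: CohortSummary
    tests: pd.DataFrame
    n_excluded: int = 0

    def summary(self) -> str:
        lines = [
            "Patient-positioning evaluation",
            "=" * 60,
            f"cases evaluated: {len(self.errors)}   excluded: {self.n_excluded}",
            "",
            str(self.summary_table),
            "",
            "Hypothesis tests",
            "-" * 60,
        ]
        with pd.option_context("display.width", 120):
            lines.append(str(self.tests))
        return "\n".join(lines)


def evaluate_cohort(pairs: Sequence[Tuple[CenterlineReport, CenterlineReport]],
                    isocenter_y: float = 0.0,
                    case_ids: Optional[Sequence[str]] = None,
                    body_sizes: Optional[Sequence[float]] = None,
                    seed: int = 0) -> PositioningResults:
    """Compute per-case errors from (ground-truth, predicted) report pairs and
    run the cohort statistics.

    Cases flagged as truncated in the ground-truth report are excluded, the
    automatic stand-in for the manual truncation-artifact exclusion a human
    reader would perform.
    """
    errors: List[PositioningErrors] = []
    n_excluded = 0
    for i, (rgt, rdl) in enumerate(pairs):
        if rgt.truncated:
            n_excluded += 1
            continue
        cid = case_ids[i] if case_ids is not None else f"case{i:04d}"
        bs = body_sizes[i] if body_sizes is not None else None
        errors.append(positioning_errors(rgt, rdl, isocenter_y, cid, bs))
    if len(errors) < 2:
        raise ValueError("fewer than 2 usable cases in the cohort")
    summary_tab = cohort_summary(errors)

    rows = []
    bcap = _collect(errors, "bcap", False)
    bcmp = _collect(errors, "bcmp", False)
    for name, x, y in [
        ("bcap_vs_bcmp", bcap, bcmp),
        ("abs_bcap_vs_abs_bcmp", np.abs(bcap), np.abs(bcmp)),
    ]:
        u, p = mann_whitney(x, y)
        rows.append({"test": "mann_whitney", "comparison": name,
                     "statistic": u, "p": p})
    lcap = _collect(errors, "lcap", False)
    lcmp = _collect(errors, "lcmp", False)
    if lcap.size >= 2 and lcmp.size >= 2:
        for name, x, y in [
            ("lcap_vs_lcmp", lcap, lcmp),
            ("abs_lcap_vs_abs_lcmp", np.abs(lcap), np.abs(lcmp)),
        ]:
            u, p = mann_whitney(x, y)
            rows.append({"test": "mann_whitney", "comparison": name,
                         "statistic": u, "p": p})
    if bcap.size >= 5:
        d, p = ks_normality(bcap, seed=seed)
        rows.append({"test": "ks_normality", "comparison": "bcap",
                     "statistic": d, "p": p})
    sizes = np.array([e.body_size for e in errors
                      if e.body_size is not None], dtype=float)
    if (sizes.size == len(errors) and sizes.size >= 3
            and np.ptp(sizes) > 0 and np.ptp(np.abs(bcap)) > 0):
        rho, p = spearman(sizes, np.abs(bcap))
        rows.append({"test": "spearman", "comparison": "body_size_vs_abs_bcap",
                     "statistic": rho, "p": p})
    tests = pd.DataFrame(rows)
    return PositioningResults(errors=errors, summary_table=summary_tab,
                              tests=tests, n_excluded=n_excluded)
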