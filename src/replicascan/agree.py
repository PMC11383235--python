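"""Agreement statistics on matched nuclei.

Per-nucleus measurements (area, median stain values) from two scans of
the same tissue are heteroscedastic: differences grow with magnitude.
Agreement is therefore assessed on the ratio scale — log-transform both
measurements, take per-pair differences, summarise by the median and by
empirical quantile limits of agreement (2.5% / 97.5% by default rather
than mean ± 1.96 SD, since log-differences remain non-normal), and
back-transform each summary as ``100·exp(·)`` so it reads as a ratio
percentage (100% = perfect agreement).  Uncertainty on the median and
both limits comes from bootstrap percentile intervals.

Also provides the manual-review categorization arithmetic (false /
missed / mis-segmented detections as percentages of the total) and
per-scan descriptive summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DetectionSet
from .register import MatchConfig, MatchingPercentages, match_patterns, matching_percentages

__all__ = [
    "AgreementConfig",
    "AgreementSummary",
    "CategorizationCounts",
    "CategorizationPercentages",
    "DensitySummary",
    "log_ratio_agreement",
    "bootstrap_percentile_ci",
    "categorization_percentages",
    "density_summary",
    "benchmark_compare",
]


@dataclass
class AgreementConfig:
    """Quantile and bootstrap settings for ratio-scale agreement."""

    lower_q: float = 0.025
    upper_q: float = 0.975
    n_boot: int = 2000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_q < self.upper_q < 1.0):
            raise ValueError("require 0 < lower_q < upper_q < 1")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class AgreementSummary:
    """Ratio-scale agreement for one feature across matched pairs.

    All statistics are back-transformed to ratio percentages: 100 means
    the two scans agree exactly on the typical nucleus; the limits of
    agreement bracket the central ``upper_q - lower_q`` mass of per-pair
    ratios.  Each ``ci_*`` is a (low, high) bootstrap percentile interval.
    """

    feature: str
    n_pairs: int
    median_ratio_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    ci_median: tuple[float, float]
    ci_lower: tuple[float, float]
    ci_upper: tuple[float, float]

    @property
    def loa_excludes_unity(self) -> bool:
        """True when the [lower, upper] LOA interval excludes 100% —
        a systematic shift between scans larger than the spread."""
        return self.loa_lower_pct > 100.0 or self.loa_upper_pct < 100.0

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "n_pairs": self.n_pairs,
            "median_ratio_pct": self.median_ratio_pct,
            "loa_lower_pct": self.loa_lower_pct,
            "loa_upper_pct": self.loa_upper_pct,
            "ci_median": list(self.ci_median),
            "ci_lower": list(self.ci_lower),
            "ci_upper": list(self.ci_upper),
        }


def _quantile(values: np.ndarray, q: float) -> float:
    # linear interpolation between order statistics ("type 7", the numpy default)
    return float(np.quantile(values, q))


def log_ratio_agreement(
    values_a: np.ndarray,
    values_b: np.ndarray,
    cfg: AgreementConfig | None = None,
    *,
    feature: str = "feature",
) -> AgreementSummary:
    """Ratio-scale Bland–Altman summary of paired positive measurements.

    ``d_i = ln(v_A,i) − ln(v_B,i)``; the median and the
    ``(lower_q, upper_q)`` quantiles of the ``d_i`` are each
    back-transformed as ``100·exp(·)``.  Bootstrap percentile intervals
    resample pair indices with replacement, seeded from ``cfg.seed``.
    """
    cfg = cfg or AgreementConfig()
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if va.shape != vb.shape or va.ndim != 1:
        raise ValueError("values_a and values_b must be 1-d arrays of equal length")
    if va.size < 2:
        raise ValueError("at least 2 matched pairs are required")
    bad = np.flatnonzero(~((va > 0) & (vb > 0)))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-positive measurement in pair {i}: ({va[i]}, {vb[i]}); "
            "ratio-scale agreement requires strictly positive values"
        )

    d = np.log(va) - np.log(vb)
    med = _quantile(d, 0.5)
    lo = _quantile(d, cfg.lower_q)
    hi = _quantile(d, cfg.upper_q)

    rng = np.random.default_rng(cfg.seed)
    n = d.size
    idx = rng.integers(0, n, size=(cfg.n_boot, n))
    boot = d[idx]
    boot_med = np.quantile(boot, 0.5, axis=1)
    boot_lo = np.quantile(boot, cfg.lower_q, axis=1)
    boot_hi = np.quantile(boot, cfg.upper_q, axis=1)
    alpha = 1.0 - cfg.ci_level

    def _ci(stat: np.ndarray) -> tuple[float, float]:
        a, b = np.quantile(stat, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (100.0 * float(np.exp(a)), 100.0 * float(np.exp(b)))

    return AgreementSummary(
        feature=feature,
        n_pairs=n,
        median_ratio_pct=100.0 * float(np.exp(med)),
        loa_lower_pct=100.0 * float(np.exp(lo)),
        loa_upper_pct=100.0 * float(np.exp(hi)),
        ci_median=_ci(boot_med),
        ci_lower=_ci(boot_lo),
        ci_upper=_ci(boot_hi),
    )


def bootstrap_percentile_ci(
    values: np.ndarray,
    statistic: str | tuple[str, float],
    cfg: AgreementConfig | None = None,
) -> tuple[float, float]:
    """Bootstrap percentile interval for the median or a quantile.

    ``statistic`` is ``"median"`` or ``("quantile", q)``.  Draws
    ``cfg.n_boot`` resamples with replacement, recomputes the statistic
    on each, and returns the ``(α/2, 1 − α/2)`` percentiles of the
    bootstrap distribution (α = 1 − ci_level).  Deterministic under a
    fixed ``cfg.seed``.
    """
    cfg = cfg or AgreementConfig()
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("sample must be non-empty")
    if statistic == "median":
        q = 0.5
    elif isinstance(statistic, tuple) and statistic[0] == "quantile":
        q = float(statistic[1])
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile level must be in [0, 1]")
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, v.size, size=(cfg.n_boot, v.size))
    stats = np.quantile(v[idx], q, axis=1)
    alpha = 1.0 - cfg.ci_level
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))


@dataclass(frozen=True)
class CategorizationCounts:
    """Manual-review counts over a set of algorithmic detections.

    ``n_corrected_annotations`` is the number of manual annotations that
    replaced the ``n_incorrect_segmentation`` flagged detections (an
    under-segmented detection may be replaced by several annotations).
    """

    n_total_detections: int
    n_false_detection: int
    n_missed: int
    n_incorrect_segmentation: int
    n_corrected_annotations: int

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_false_detection + self.n_incorrect_segmentation > self.n_total_detections:
            raise ValueError(
                "false + incorrectly segmented detections exceed the total detection count"
            )


@dataclass(frozen=True)
class CategorizationPercentages:
    """Review categories as percentages of total detections (full precision;
    use :meth:`rounded` for reporting precision)."""

    false_pct: float
    missed_pct: float
    incorrect_pct: float
    correct_pct: float
    detected_fraction_of_true_pct: float

    def rounded(self) -> dict:
        return {
            "false_pct": round(self.false_pct, 2),
            "missed_pct": round(self.missed_pct, 2),
            "incorrect_pct": round(self.incorrect_pct, 2),
            "correct_pct": round(self.correct_pct, 2),
            "detected_fraction_of_true_pct": round(self.detected_fraction_of_true_pct),
        }


def categorization_percentages(c: CategorizationCounts) -> CategorizationPercentages:
    """Express review categories as percentages.

    False, missed and mis-segmented counts are divided by the total
    detection count; the detected fraction of true nuclei divides the
    flagged detections by the corrected annotations that replaced them
    (how many true nuclei the flagged detections stood for).
    """
    if c.n_total_detections == 0:
        raise ZeroDivisionError("percentages undefined with zero total detections")
    total = c.n_total_detections
    false_pct = 100.0 * c.n_false_detection / total
    missed_pct = 100.0 * c.n_missed / total
    incorrect_pct = 100.0 * c.n_incorrect_segmentation / total
    if c.n_corrected_annotations == 0:
        if c.n_incorrect_segmentation:
            raise ZeroDivisionError(
                "detected fraction undefined: flagged detections but zero corrected annotations"
            )
        detected_fraction = 100.0
    else:
        detected_fraction = 100.0 * c.n_incorrect_segmentation / c.n_corrected_annotations
    return CategorizationPercentages(
        false_pct=false_pct,
        missed_pct=missed_pct,
        incorrect_pct=incorrect_pct,
        correct_pct=100.0 - false_pct - incorrect_pct,
        detected_fraction_of_true_pct=detected_fraction,
    )


@dataclass(frozen=True)
class DensitySummary:
    """Descriptive statistics of one scan's detections."""

    n_detections: int
    mean_area_um2: float
    sd_area_um2: float
    mean_hema: float
    median_hema: float
    mean_eosin: float
    median_eosin: float
    area_hist_bin_width_um2: float
    area_hist_counts: tuple[int, ...]

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["area_hist_counts"] = list(self.area_hist_counts)
        return d


def density_summary(ds: DetectionSet, bin_width_um2: float = 5.0) -> DensitySummary:
    """Count, area mean/SD (n−1 denominator), stain summaries, and an
    area histogram over half-open bins ``[k·w, (k+1)·w)``.

    An empty set yields count 0 with NaN moments (flagged, not an error).
    """
    if bin_width_um2 <= 0:
        raise ValueError("bin_width_um2 must be > 0")
    n = len(ds)
    if n == 0:
        nan = float("nan")
        return DensitySummary(0, nan, nan, nan, nan, nan, nan, bin_width_um2, ())
    area = ds.feature("area_um2")
    hema = ds.feature("hema_median")
    eosin = ds.feature("eosin_median")
    n_bins = int(np.floor(area.max() / bin_width_um2)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um2
    counts, _ = np.histogram(area, bins=edges)
    # np.histogram closes the last bin; areas exactly on the final edge
    # cannot occur since edges extend past max(area)
    return DensitySummary(
        n_detections=n,
        mean_area_um2=float(area.mean()),
        sd_area_um2=float(area.std(ddof=1)) if n > 1 else float("nan"),
        mean_hema=float(hema.mean()),
        median_hema=float(np.median(hema)),
        mean_eosin=float(eosin.mean()),
        median_eosin=float(np.median(eosin)),
        area_hist_bin_width_um2=bin_width_um2,
        area_hist_counts=tuple(int(c) for c in counts),
    )


def benchmark_compare(
    manual_A: DetectionSet,
    manual_B: DetectionSet,
    mcfg: MatchConfig | None = None,
) -> MatchingPercentages:
    """Matching percentages between two independent manual annotation sets.

    Serves as the reference line against which algorithmic inter-scan
    matching percentages are judged: two trained observers annotating
    the same region set the ceiling of attainable agreement.
    """
    if len(manual_B) == 0:
        if len(manual_A) == 0:
            raise ZeroDivisionError("both annotation sets are empty")
        return MatchingPercentages(
            matched_pct=0.0, unmatched_pct=100.0, edged_out_pct=0.0,
            matched_pct_A=0.0, matched_pct_B=float("nan"),
            unmatched_pct_A=100.0, unmatched_pct_B=float("nan"),
            edged_out_pct_A=0.0, edged_out_pct_B=float("nan"),
            n_A=len(manual_A), n_B=0,
        )
    mcfg = mcfg or MatchConfig()
    m = match_patterns(manual_A, manual_B, mcfg)
    return matching_percentages(m, len(manual_A), len(manual_B))
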