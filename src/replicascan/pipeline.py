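"""Study orchestration: replicate comparisons across scan settings.

A study mirrors the design of a scanner-profile comparison: several
scan settings, each scanned in (typically three) technical replicates,
detections exported per replicate, optionally at several analysis
resolutions.  Within every setting all unordered replicate pairs are
compared in the fixed order (1 vs 2, 1 vs 3, 2 vs 3); optionally every
replicate is also compared to a designated reference-standard scan, and
a pair of manual annotation sets provides the benchmark line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np

from . import __version__
from .agree import AgreementConfig, AgreementSummary, benchmark_compare, density_summary, log_ratio_agreement
from .io import DetectionSet, write_detections
from .register import MatchConfig, match_patterns, matching_percentages
from .synth import SyntheticScanConfig, generate_ground_truth, simulate_scan

logger = logging.getLogger(__name__)

__all__ = ["StudyDesign", "ComparisonRecord", "StudyReport", "run_study", "render_report"]

FEATURES = ("area_um2", "hema_median", "eosin_median")


@dataclass
class StudyDesign:
    """Declarative description of a replicate-comparison study.

    ``settings`` maps a setting label to its replicate
    :class:`DetectionSet` list (at least two replicates each).
    ``reference_setting`` optionally names the setting whose first
    replicate acts as the reference-standard scan; ``benchmark`` is an
    optional pair of manual annotation sets.
    """

    settings: dict[str, list[DetectionSet]]
    reference_setting: str | None = None
    benchmark: tuple[DetectionSet, DetectionSet] | None = None
    match_cfg: MatchConfig = field(default_factory=MatchConfig)
    agree_cfg: AgreementConfig = field(default_factory=AgreementConfig)

    def __post_init__(self) -> None:
        for label, reps in self.settings.items():
            if len(reps) < 2:
                raise ValueError(
                    f"setting {label!r} has {len(reps)} replicate(s); "
                    "pairwise comparison requires at least 2"
                )
        if self.reference_setting is not None and self.reference_setting not in self.settings:
            raise ValueError(f"reference_setting {self.reference_setting!r} is not a setting")


@dataclass
class ComparisonRecord:
    """One pairwise comparison: matching percentages + per-feature agreement."""

    setting: str
    scan_a: str
    scan_b: str
    kind: str  # "within" | "reference"
    percentages: dict
    agreement: list[AgreementSummary]
    transform: object

    def to_dict(self) -> dict:
        return {
            "setting": self.setting,
            "scan_a": self.scan_a,
            "scan_b": self.scan_b,
            "kind": self.kind,
            "percentages": self.percentages,
            "agreement": [a.to_dict() for a in self.agreement],
        }


@dataclass
class StudyReport:
    comparisons: list[ComparisonRecord]
    benchmark_percentages: dict | None
    scan_summaries: dict[str, dict]
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "benchmark_percentages": self.benchmark_percentages,
            "comparisons": [c.to_dict() for c in self.comparisons],
            "scan_summaries": self.scan_summaries,
        }


def _compare(
    label: str,
    A: DetectionSet,
    B: DetectionSet,
    kind: str,
    mcfg: MatchConfig,
    acfg: AgreementConfig,
) -> ComparisonRecord:
    if A.roi_id != B.roi_id:
        raise ValueError(
            f"comparison {A.scan_id} vs {B.scan_id}: mixed ROIs {A.roi_id!r} / {B.roi_id!r}"
        )
    m = match_patterns(A, B, mcfg)
    pct = matching_percentages(m, len(A), len(B))
    by_a, by_b = A.by_id(), B.by_id()
    summaries = []
    if m.n_pairs >= 2:
        for feat in FEATURES:
            va = np.array([getattr(by_a[a], feat) for a, _, _ in m.pairs])
            vb = np.array([getattr(by_b[b], feat) for _, b, _ in m.pairs])
            summaries.append(log_ratio_agreement(va, vb, acfg, feature=feat))
    logger.info(
        "%s %s vs %s [%s]: %d pairs, matched %.2f%%, transform %s",
        label, A.scan_id, B.scan_id, kind, m.n_pairs, pct.matched_pct, m.transform,
    )
    return ComparisonRecord(
        setting=label,
        scan_a=A.scan_id,
        scan_b=B.scan_id,
        kind=kind,
        percentages=vars(pct).copy(),
        agreement=summaries,
        transform=m.transform,
    )


def run_study(design: StudyDesign) -> StudyReport:
    """Run all within-setting and reference comparisons of a study.

    For every setting, replicate pairs are compared in the order
    (1 vs 2, 1 vs 3, 2 vs 3, ...); with a reference setting configured,
    every replicate of every other setting is additionally compared to
    the reference scan (the reference setting's first replicate).
    Deterministic given the design's detection sets and seeds.
    """
    comparisons: list[ComparisonRecord] = []
    for label, reps in design.settings.items():
        for i, j in combinations(range(len(reps)), 2):
            comparisons.append(
                _compare(label, reps[i], reps[j], "within", design.match_cfg, design.agree_cfg)
            )

    if design.reference_setting is not None:
        ref = design.settings[design.reference_setting][0]
        for label, reps in design.settings.items():
            if label == design.reference_setting:
                continue
            for rep in reps:
                comparisons.append(
                    _compare(label, rep, ref, "reference", design.match_cfg, design.agree_cfg)
                )

    bench = None
    if design.benchmark is not None:
        bp = benchmark_compare(design.benchmark[0], design.benchmark[1], design.match_cfg)
        bench = vars(bp).copy()

    summaries = {}
    for label, reps in design.settings.items():
        for rep in reps:
            summaries[rep.scan_id] = density_summary(rep).to_dict()

    metadata = {
        "package_version": __version__,
        "n_settings": len(design.settings),
        "n_comparisons": len(comparisons),
        "match_cfg": vars(design.match_cfg).copy(),
        "agree_cfg": vars(design.agree_cfg).copy(),
    }
    return StudyReport(
        comparisons=comparisons,
        benchmark_percentages=bench,
        scan_summaries=summaries,
        metadata=metadata,
    )


def simulate_setting(
    base_cfg: SyntheticScanConfig,
    label: str,
    n_replicates: int = 3,
    *,
    truth_seed: int | None = None,
    roi_id: str = "roi",
    shifts: list[tuple[float, float]] | None = None,
) -> list[DetectionSet]:
    """Generate one setting's technical replicates from a shared ground truth.

    One truth (seeded by ``truth_seed``, default ``base_cfg.seed``)
    degraded ``n_replicates`` times with replicate seeds derived from it.
    ``shifts`` optionally gives each replicate its own global tissue
    shift (each scan re-selects the tissue region independently);
    without it every replicate uses ``base_cfg.shift_um``.
    """
    cfg = base_cfg if truth_seed is None else replace(base_cfg, seed=truth_seed)
    if shifts is not None and len(shifts) != n_replicates:
        raise ValueError("shifts must have one entry per replicate")
    truth = generate_ground_truth(cfg)
    reps = []
    for r in range(n_replicates):
        rcfg = cfg if shifts is None else replace(cfg, shift_um=tuple(shifts[r]))
        ds, _ = simulate_scan(
            truth, rcfg, replicate_seed=cfg.seed * 1000 + r + 1,
            scan_id=f"{label}_scan{r + 1}", roi_id=roi_id,
        )
        reps.append(ds)
    return reps


def render_report(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Write the study report: percentages and LOA tables (TSV), per-scan
    summaries, and a machine-readable JSON (sorted keys; byte-identical
    across reruns with identical inputs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    p = out_dir / "comparisons.tsv"
    with open(p, "w") as fh:
        cols = [
            "setting", "scan_a", "scan_b", "kind",
            "matched_pct", "unmatched_pct", "edged_out_pct",
            "matched_pct_A", "matched_pct_B", "n_A", "n_B",
        ]
        fh.write("\t".join(cols) + "\n")
        for c in report.comparisons:
            pc = c.percentages
            fh.write(
                "\t".join(
                    [c.setting, c.scan_a, c.scan_b, c.kind]
                    + [f"{pc[k]:.2f}" for k in cols[4:9]]
                    + [str(pc["n_A"]), str(pc["n_B"])]
                )
                + "\n"
            )
    written.append(p)

    p = out_dir / "agreement.tsv"
    with open(p, "w") as fh:
        fh.write(
            "setting\tscan_a\tscan_b\tkind\tfeature\tn_pairs\tmedian_ratio_pct\t"
            "loa_lower_pct\tloa_upper_pct\tci_median_lo\tci_median_hi\t"
            "ci_lower_lo\tci_lower_hi\tci_upper_lo\tci_upper_hi\n"
        )
        for c in report.comparisons:
            for a in c.agreement:
                fh.write(
                    f"{c.setting}\t{c.scan_a}\t{c.scan_b}\t{c.kind}\t{a.feature}\t{a.n_pairs}\t"
                    f"{a.median_ratio_pct:.2f}\t{a.loa_lower_pct:.2f}\t{a.loa_upper_pct:.2f}\t"
                    f"{a.ci_median[0]:.2f}\t{a.ci_median[1]:.2f}\t"
                    f"{a.ci_lower[0]:.2f}\t{a.ci_lower[1]:.2f}\t"
                    f"{a.ci_upper[0]:.2f}\t{a.ci_upper[1]:.2f}\n"
                )
    written.append(p)

    p = out_dir / "scan_summaries.tsv"
    with open(p, "w") as fh:
        fh.write("scan_id\tn_detections\tmean_area_um2\tsd_area_um2\tmean_hema\tmean_eosin\n")
        for sid in sorted(report.scan_summaries):
            s = report.scan_summaries[sid]
            fh.write(
                f"{sid}\t{s['n_detections']}\t{s['mean_area_um2']:.4f}\t"
                f"{s['sd_area_um2']:.4f}\t{s['mean_hema']:.4f}\t{s['mean_eosin']:.4f}\n"
            )
    written.append(p)

    p = out_dir / "study.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
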