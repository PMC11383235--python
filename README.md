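# replicascan

Quantify how reproducibly a whole-slide-imaging pipeline detects and
measures cell nuclei across technical replicate scans of the same
histology slide.

Digital-pathology workflows scan an H&E slide, segment nuclei with a
deep-learning tool (e.g. StarDist inside QuPath), and export one table
of per-nucleus measurements — centroid position, area, median
hematoxylin and eosin values — per scan. Re-scanning the same slide
under identical settings does not reproduce those tables exactly: the
tissue sits at slightly different coordinates, some nuclei are missed,
small color-intensive artifacts are spuriously detected, and repeated
measurements of the same nucleus disagree. `replicascan` turns those
per-scan tables into inter-scan variability statistics, so different
scanner profiles and analysis resolutions can be compared objectively.

It is aimed at pathology image-analysis groups validating a scanner
configuration or a detection pipeline, and ships a synthetic
replicate-scan generator so the whole analysis is testable without any
slide data.

## What it computes

**Point-pattern matching.** Detections from two scans of one region of
interest (ROI) are treated as planar point patterns. A small global
tissue shift between the scans is first corrected by iterating the
component-wise median of nearest-neighbour displacements (or a
least-squares affine fit for cross-setting comparisons). Each nucleus
is then matched to its Euclidean nearest neighbour in the other pattern
within a 10 μm × 10 μm square window centered on it. When two nuclei
claim the same partner, the pair at the smallest distance wins and the
loser is considered again in a second round. Every nucleus ends up
**matched**, **unmatched**, or — if its aligned position falls outside
the overlap of the two ROI rectangles, so it never had a potential
partner — **edged-out**. Percentages are pooled over both sides, so
matched + unmatched + edged-out = 100.

**Ratio-scale agreement.** Per-nucleus measurements are heteroscedastic
(differences grow with magnitude), so agreement between matched nuclei
is assessed on log-ratios: for feature values v_A, v_B of a matched
pair, d = ln v_A − ln v_B. The median and the empirical 2.5% / 97.5%
quantiles of d (quantile limits of agreement, used instead of the
classical mean ± 1.96 SD because d remains non-normal) are each
back-transformed as 100·exp(·), giving ratio percentages where 100%
means perfect agreement. Confidence intervals for the median and both
limits are bootstrap percentile intervals over resampled pairs.

**Study orchestration.** A study runs all pairwise comparisons within
each scan setting (replicates 1 vs 2, 1 vs 3, 2 vs 3), optional
comparisons of every replicate against a reference-standard scan, and an
optional benchmark in which two independent manual annotation sets of
the same region are matched to establish the ceiling of attainable
agreement.

**Synthetic replicate scans.** The generator draws a ground-truth
nucleus population from a hard-core point process with lognormal areas
and positive stain medians, then degrades it per replicate: global
tissue shift, sub-micron positional jitter, detection drop-out, spurious
small high-stain artifacts, and multiplicative measurement noise.
Correspondence maps from true to detected nuclei let tests verify the
matcher against planted truth.

## Worked example

```python
import numpy as np
import replicascan as rs

cfg = rs.SyntheticScanConfig(seed=7)          # one 220 μm × 220 μm ROI
truth = rs.generate_ground_truth(cfg)
scan1, _ = rs.simulate_scan(truth, cfg, replicate_seed=7001, scan_id="scan1")
scan2, _ = rs.simulate_scan(truth, cfg, replicate_seed=7002, scan_id="scan2")

m = rs.match_patterns(scan1, scan2, rs.MatchConfig())
p = rs.matching_percentages(m, len(scan1), len(scan2))
print(f"matched {p.matched_pct:.2f}%  unmatched {p.unmatched_pct:.2f}%  "
      f"edged-out {p.edged_out_pct:.2f}%")

by1, by2 = scan1.by_id(), scan2.by_id()
va = np.array([by1[a].area_um2 for a, b, _ in m.pairs])
vb = np.array([by2[b].area_um2 for a, b, _ in m.pairs])
s = rs.log_ratio_agreement(va, vb, rs.AgreementConfig(seed=7), feature="area_um2")
print(f"area: median ratio {s.median_ratio_pct:.2f}%  "
      f"LOA [{s.loa_lower_pct:.2f}%, {s.loa_upper_pct:.2f}%]")
```

prints

```
matched 93.95%  unmatched 6.05%  edged-out 0.00%
area: median ratio 100.21%  LOA [87.57%, 115.27%]
```

Reading: of the 2,395 nuclei across both replicate scans, 93.95% found
a partner in the other scan. The typical nucleus is measured 0.21%
larger in scan 1 than scan 2 (no systematic bias), and 95% of matched
nuclei have an area ratio between 87.6% and 115.3% — the multiplicative
measurement noise of this simulated scanner. The edged-out share is 0%
here because both replicates carry the same global tissue shift; give
each replicate its own shift (as real scans have) and a small edged-out
percentage appears.

The same analysis is available from the shell:

```
replicascan simulate --seed 7 --n-replicates 3 --out sim/
replicascan match --a sim/scan1.tsv --b sim/scan2.tsv --out out/cmp
replicascan run-study --config study.yaml --seed 7 --out report/
```

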