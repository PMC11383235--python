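# Methods

This note documents the models, algorithms and numerical choices behind
`replicascan`, what the synthetic generator does and does not emulate,
and the design decisions taken where more than one reasonable option
existed.

## Data model

A **detection set** is all nuclei detected in one scan replicate within
one rectangular region of interest (ROI): per nucleus a centroid in
slide-frame microns (image convention, origin top-left, y downward), an
area in μm², and median hematoxylin / eosin values. ROI bounds are
inclusive on all edges so boundary containment is deterministic. The
reader normalises pixel-unit exports to microns via the scan's pixel
size; the default table dialect mimics a QuPath measurement export
(tab-delimited, `Centroid X µm`, `Nucleus: Area`, ...) and every column
name, the delimiter and the coordinate unit are remappable, since
export schemas vary between tool versions and the stain "median" may or
may not be an optical density — the dialect leaves units to the user.

## Shift correction

Scans of the same slide place the tissue at slightly different
coordinates. Before matching, side B is translated onto side A's frame
by iterating: for every B nucleus find its nearest A neighbour, discard
displacements outside the search window, take the component-wise
median, accumulate. Iteration stops when the incremental shift falls
below `align_tol_um` (default 1e-6 μm, cap 50 iterations); in practice
two or three iterations suffice for sub-window shifts. The median is
used rather than the mean so drop-out and spurious detections cannot
drag the estimate; whether one pass or an iterated scheme is used
matters only when the initial shift approaches the window half-width,
and the iterated form is strictly more robust there. If no displacement
falls inside the window at the first iteration the patterns are too far
apart and an alignment error is raised rather than returning garbage.

A least-squares affine fit (2×2 matrix + offset, normal equations via
`numpy.linalg.lstsq`) is provided for cross-setting ROI alignment,
where re-selection of the scan region can introduce slight rotation and
scale. It requires three non-collinear pairs and is bootstrapped from a
translation-aligned preliminary matching. It is off by default for
replicate comparisons: replicates differ by translation only, and
fitting an affine to noisy replicate pairs adds variance without
reducing bias.

## Matching

Matching operates in rounds (default 2). In a round, every unmatched A
nucleus proposes to its nearest unmatched B nucleus, where candidates
must satisfy |Δx| ≤ w/2 and |Δy| ≤ w/2 (the square window, default
w = 10 μm — a Chebyshev box, not a Euclidean disc) and nearest means
smallest Euclidean distance within the box. Each B nucleus accepts only
its closest proposer; losers re-propose in the next round against the
remaining candidates. Consequences asserted on every run: matching is
one-to-one, every pair distance is at most (w/2)·√2, and
|pairs| + |unmatched| + |edged-out| equals each side's record count.
Distance ties are broken lexicographically by nucleus id; ties have
probability zero under continuous coordinates but a deterministic rule
keeps reruns byte-identical. The procedure is greedy by design — it
mirrors how a reviewer would pair points — and an optimal-assignment
(Hungarian) matcher is deliberately out of scope.

Leftover nuclei whose aligned position lies outside the intersection of
the two ROI rectangles (B's rectangle mapped through the estimated
transform) are **edged-out**: the companion region was never scanned,
so counting them as disagreement would penalise the scanner for
geometry. Percentages are pooled over both sides (a pair counts twice
in the numerator, the denominator is the total nucleus count of both
sides), which makes the three categories sum to exactly 100; per-side
percentages are always emitted as well, so the per-side averaging
convention is recoverable from the same output.

## Agreement statistics

For a feature with matched values (v_A, v_B), agreement uses
d = ln v_A − ln v_B. Differences of raw values are heteroscedastic for
nucleus area and stain medians; the log-ratio removes the scale
dependence, and all statistics are invariant to rescaling both sides by
a common factor (unit changes). Summaries are the median and the
`lower_q`/`upper_q` empirical quantiles of d (defaults 0.025 / 0.975),
each back-transformed as 100·exp(·) to a ratio percentage. Quantile
limits replace the classical mean ± 1.96 SD limits because log-ratios
of segmentation outputs remain heavy-tailed: a handful of
re-segmentation events (one nucleus split or merged differently between
scans) produce outliers that would inflate an SD-based limit but move
an empirical quantile only marginally.

Quantiles use linear interpolation between order statistics (the
"type 7" rule, numpy's default); the choice is pinned by a brute-force
sort-and-interpolate oracle in the tests. Confidence intervals are
bootstrap percentile intervals: `n_boot` resamples of pair indices with
replacement (default 2000, enough to stabilise 95% percentile
endpoints to well under the reporting precision), statistic recomputed
per resample, interval = (α/2, 1 − α/2) percentiles of the bootstrap
distribution. The bootstrap is seeded and vectorised (an
`n_boot × n` index matrix), and its measured coverage for the median on
normal samples sits in the 92–98% band expected of percentile
intervals at n = 200. A comparison whose back-transformed LOA interval
excludes 100% is flagged (`loa_excludes_unity`) as a systematic shift
— e.g. a stain-color change between scans — with no inferential claim
attached.

The natural log is used for the transform; any fixed base gives
identical back-transformed results.

The manual-review categorization arithmetic expresses reviewer classes
(false detections, missed nuclei, under/over-segmented detections) as
percentages of total detections, at two-decimal reporting precision.
The "fraction of true nuclei" statistic divides flagged detections by
the corrected annotations that replaced them — an under-segmented
detection standing for several true nuclei makes this fraction fall
below 100% — and is reported at integer precision.

## Synthetic replicate scans

The generator's role is to produce detection tables with the
statistical structure the analysis assumes, with known ground truth.

* **Positions**: a hard-core point process (minimum centroid separation,
  default 3 μm) sampled by sequential dart throwing with rejection,
  budget 100×n attempts; infeasible packings raise an error reporting
  the count placed. Real nuclei do not overlap, and the hard-core gap
  is what makes sub-micron jitter unambiguous for matching.
* **Areas**: lognormal with log-mean 2.52 and log-sd 0.4, i.e. mode
  ≈ 10.6 μm² and mean ≈ 13.4 μm² — the right-skewed shape and scale
  typical of H&E nucleus segmentations at 0.11 μm/px.
* **Stains**: truncated-normal positive medians (hematoxylin 0.6 ± 0.15,
  eosin 0.3 ± 0.10, dimensionless optical values).
* **Replicate degradation**: global shift (default (1.0, −0.6) μm —
  tissue sits at slightly different coordinates each scan), isotropic
  positional jitter (sd 0.15 μm), drop-out (p_miss = 0.03), spurious
  detections as a Poisson process (0.001 /μm² ≈ 48 per default ROI)
  with small lognormal areas (mean ≈ 3.5 μm²) and elevated stain
  values — the "small color-intensive spot" artifact class — and
  multiplicative measurement noise exp(N(0, σ²)) with σ = 0.05 on area
  and both stains. Under this model the log-area difference between two
  replicates of one truth is N(0, 2σ²), which the closed-form LOA test
  exploits: the 97.5% limit must approach 100·exp(1.96·√2·σ) ≈ 114.9%.
* **Resolution series**: coarser analysis resolutions are emulated by a
  lookup resolution → (area_scale ≥ 1, p_detect_scale ≤ 1), default
  (1, 1) / (1.2, 0.92) / (1.5, 0.80) for 0.11 / 0.22 / 0.44 μm/px,
  reproducing the qualitative pattern that measured areas grow and
  detected counts shrink as pixels coarsen. The mapping is a
  configurable lookup, not a claim about any particular scanner.

Two seed streams keep replicates exchangeable: one seed fixes the
ground truth, a per-replicate seed drives its degradation. All outputs
are bit-identical under fixed seeds.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spatial clustering of nuclei beyond the
hard-core constraint (real tissue has glands, sheets and empty lamina),
correlated drop-out (real misses concentrate in blurred or pale
regions), segmentation-boundary errors that split or merge nuclei
(drop-out and artifacts are independent events here), focus maps,
compression artifacts, or any pixel-level rendering. Tests demonstrate
that the matching and agreement machinery is correct and calibrated
under the stated noise model, not that any particular scanner meets a
quality bar.

## Study design and sizes

A study maps setting labels to replicate detection sets (≥ 2 each);
within a setting all C(r, 2) unordered pairs are compared in the fixed
order 1v2, 1v3, 2v3, so three replicates give exactly three
comparisons and an eight-setting study gives 24. The default simulated
study uses one ~1,200-nucleus ROI per setting — hundreds to thousands
of nuclei per ROI is the regime these analyses operate in, and it keeps
the full suite and the acceptance script in the seconds-to-minutes
range. The machine-readable report (`study.json`, sorted keys) is
byte-identical across reruns with identical configuration and seeds.

## Known limitations

* The matcher is greedy; a globally optimal assignment could differ in
  dense regions (pair counts in random-instance tests agree with a
  brute-force re-implementation of the same greedy rule, not with an
  optimal matcher).
* Translation symmetry of `match_patterns(A, B)` vs `match_patterns(B, A)`
  is an empirical property (tested) rather than a theorem; ties or
  alignment asymmetry could in principle break it.
* Edged-out classification relies on ROI bounds being truthful; tables
  read without explicit bounds fall back to the detections' bounding
  box, which slightly overstates the overlap.
* The affine path estimates the transform from a preliminary greedy
  matching; with <3 matched pairs or collinear geometry it fails loudly
  rather than degrading.
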