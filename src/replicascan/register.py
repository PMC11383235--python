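"""Replicate-scan alignment and two-round nucleus matching.

Detections from two scans of the same region are treated as planar
point patterns.  After correcting the small global tissue shift between
scans (iterated median of nearest-neighbour displacements, or an affine
fit for cross-setting ROI alignment), each nucleus is matched to its
Euclidean nearest neighbour in the other pattern within a square search
window (default 10 μm × 10 μm centered on the nucleus).  When two nuclei
claim the same nearest neighbour, the pair at the smallest distance
wins; the losers are considered for matching a second time against the
remaining candidates.  Nuclei left over after the final round are
*unmatched*, unless their aligned position falls outside the overlap of
the two ROI rectangles, in which case they are *edged-out* and excluded
from the denominator of disagreement — they had no chance of a partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import DetectionSet

__all__ = [
    "MatchConfig",
    "MatchResult",
    "MatchingPercentages",
    "AlignmentError",
    "estimate_translation",
    "estimate_affine",
    "apply_affine",
    "match_patterns",
    "matching_percentages",
]


class AlignmentError(RuntimeError):
    """Shift estimation found no within-window neighbours, or degenerate geometry."""


@dataclass
class MatchConfig:
    """Parameters of the matching procedure.

    ``window_um`` is the side of the square search window (a Chebyshev
    box: |Δx| ≤ window/2 and |Δy| ≤ window/2); nearest neighbours inside
    it are ranked by Euclidean distance.  ``n_rounds`` repeats the
    propose/accept pass so conflict losers get a second chance.
    ``align_mode`` selects no alignment, a translation-only shift
    correction, or a full affine fit.
    """

    window_um: float = 10.0
    n_rounds: int = 2
    align_mode: str = "translation"
    align_max_iter: int = 50
    align_tol_um: float = 1e-6

    def __post_init__(self) -> None:
        if not self.window_um > 0:
            raise ValueError("window_um must be > 0")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.align_mode not in ("none", "translation", "affine"):
            raise ValueError(f"unknown align_mode {self.align_mode!r}")


@dataclass
class MatchResult:
    """Outcome of one pairwise scan comparison.

    ``pairs`` holds ``(id_A, id_B, distance_um)`` with matching one-to-one;
    ``round_of_match`` records, pair-aligned, whether the pair formed in
    round 1 or a later round.  ``transform`` is the alignment applied to
    side B expressed in A's frame: a translation vector, an
    ``(matrix, offset)`` affine pair, or ``None``.
    """

    pairs: list[tuple[str, str, float]]
    unmatched_A: set[str]
    unmatched_B: set[str]
    edged_out_A: set[str]
    edged_out_B: set[str]
    transform: object
    round_of_match: list[int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> tuple[set[str], set[str]]:
        return {a for a, _, _ in self.pairs}, {b for _, b, _ in self.pairs}

    def pair_map(self) -> dict[str, str]:
        """id_A → id_B over all matched pairs."""
        return {a: b for a, b, _ in self.pairs}


@dataclass(frozen=True)
class MatchingPercentages:
    """Matched/unmatched/edged-out percentages, pooled over both sides
    (the three pooled values sum to 100) plus the per-side breakdown."""

    matched_pct: float
    unmatched_pct: float
    edged_out_pct: float
    matched_pct_A: float
    matched_pct_B: float
    unmatched_pct_A: float
    unmatched_pct_B: float
    edged_out_pct_A: float
    edged_out_pct_B: float
    n_A: int
    n_B: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.matched_pct, self.unmatched_pct, self.edged_out_pct)


def estimate_translation(
    A: DetectionSet, B: DetectionSet, cfg: MatchConfig | None = None
) -> tuple[float, float]:
    """Estimate the global shift to add to B so it lands on A's frame.

    Iteratively: for every nucleus of (shifted) B take its nearest
    neighbour in A, keep those within the search window, and accumulate
    the component-wise median displacement until the increment drops
    below ``align_tol_um`` or the iteration cap is hit.  The median makes
    the estimate robust to drop-out and spurious detections.
    """
    cfg = cfg or MatchConfig()
    if len(A) == 0 or len(B) == 0:
        raise AlignmentError("translation estimation requires non-empty sets")
    coords_a = A.coords
    coords_b = B.coords
    tree = cKDTree(coords_a)
    half = cfg.window_um / 2.0
    shift = np.zeros(2)
    for it in range(cfg.align_max_iter):
        shifted = coords_b + shift
        _, idx = tree.query(shifted)
        disp = coords_a[idx] - shifted
        inside = (np.abs(disp[:, 0]) <= half) & (np.abs(disp[:, 1]) <= half)
        if not inside.any():
            if it == 0:
                raise AlignmentError(
                    "no nearest neighbours within the search window; "
                    "patterns too far apart for translation alignment"
                )
            break
        step = np.median(disp[inside], axis=0)
        shift += step
        if float(np.hypot(*step)) < cfg.align_tol_um:
            break
    return (float(shift[0]), float(shift[1]))


def estimate_affine(
    points_b: np.ndarray, points_a: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine transform mapping B-coordinates onto A's frame.

    Returns ``(M, t)`` with ``a ≈ M @ b + t``.  Requires at least three
    non-collinear point pairs.
    """
    points_b = np.asarray(points_b, dtype=float)
    points_a = np.asarray(points_a, dtype=float)
    if points_b.shape != points_a.shape or points_b.ndim != 2 or points_b.shape[1] != 2:
        raise ValueError("point arrays must both be (n, 2)")
    n = points_b.shape[0]
    if n < 3:
        raise AlignmentError("affine estimation requires >= 3 point pairs")
    design = np.hstack([points_b, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise AlignmentError("collinear point configuration; affine transform is degenerate")
    sol, *_ = np.linalg.lstsq(design, points_a, rcond=None)
    M = sol[:2].T
    t = sol[2]
    return M, t


def apply_affine(coords: np.ndarray, transform: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    M, t = transform
    return np.asarray(coords, dtype=float) @ M.T + t


def _greedy_rounds(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    ids_a: list[str],
    ids_b: list[str],
    window_um: float,
    n_rounds: int,
) -> tuple[list[tuple[str, str, float]], list[int], set[int], set[int]]:
    """Run the propose/accept rounds; returns pairs, rounds and leftover indices."""
    half = window_um / 2.0
    radius = half * np.sqrt(2.0)  # Euclidean ball circumscribing the square window
    free_a = set(range(len(ids_a)))
    free_b = set(range(len(ids_b)))
    pairs: list[tuple[str, str, float]] = []
    rounds: list[int] = []

    for rnd in range(1, n_rounds + 1):
        if not free_a or not free_b:
            break
        b_idx = np.fromiter(free_b, dtype=int)
        tree = cKDTree(coords_b[b_idx])
        # proposals keyed by target b: (distance, id_A, a index)
        proposals: dict[int, list[tuple[float, str, int]]] = {}
        for ia in free_a:
            cand = tree.query_ball_point(coords_a[ia], radius)
            best: tuple[float, str, int] | None = None
            for j in cand:
                ib = int(b_idx[j])
                dx = coords_b[ib, 0] - coords_a[ia, 0]
                dy = coords_b[ib, 1] - coords_a[ia, 1]
                if abs(dx) > half or abs(dy) > half:
                    continue
                d = float(np.hypot(dx, dy))
                # Euclidean nearest; ties by id_B for determinism
                key = (d, ids_b[ib])
                if best is None or key < (best[0], ids_b[best[2]]):
                    best = (d, ids_a[ia], ib)
            if best is not None:
                proposals.setdefault(best[2], []).append((best[0], best[1], ia))
        if not proposals:
            break
        for ib, plist in proposals.items():
            plist.sort()  # smallest distance first, then id_A lexicographic
            d, id_a, ia = plist[0]
            pairs.append((id_a, ids_b[ib], d))
            rounds.append(rnd)
            free_a.discard(ia)
            free_b.discard(ib)
    return pairs, rounds, free_a, free_b


def match_patterns(A: DetectionSet, B: DetectionSet, cfg: MatchConfig | None = None) -> MatchResult:
    """Match two detection point patterns with conflict resolution.

    Alignment per ``cfg.align_mode`` is applied to B first.  In each
    round every currently unmatched nucleus of A proposes to its nearest
    unmatched B nucleus within the window; each B nucleus accepts only
    its closest proposer, and losers wait for the next round.  Leftovers
    whose aligned position lies outside the intersection of the two ROI
    rectangles are classified edged-out rather than unmatched.
    """
    cfg = cfg or MatchConfig()
    ids_a, ids_b = A.ids, B.ids
    coords_a, coords_b = A.coords, B.coords
    bounds_b = np.array(B.roi_bounds, dtype=float)

    transform: object = None
    if len(A) and len(B):
        if cfg.align_mode == "translation":
            shift = estimate_translation(A, B, cfg)
            coords_b = coords_b + np.array(shift)
            bounds_b = bounds_b + np.array([shift[0], shift[1], shift[0], shift[1]])
            transform = shift
        elif cfg.align_mode == "affine":
            # bootstrap the affine fit from a translation-aligned matching
            shift = estimate_translation(A, B, cfg)
            pre_pairs, _, _, _ = _greedy_rounds(
                coords_a, coords_b + np.array(shift), ids_a, ids_b,
                cfg.window_um, cfg.n_rounds,
            )
            pos_a = A.by_id()
            pos_b = B.by_id()
            pa = np.array([[pos_a[a].x_um, pos_a[a].y_um] for a, _, _ in pre_pairs])
            pb = np.array([[pos_b[b].x_um, pos_b[b].y_um] for _, b, _ in pre_pairs])
            M, t = estimate_affine(pb, pa)
            coords_b = apply_affine(coords_b, (M, t))
            corners = np.array(
                [
                    [B.roi_bounds[0], B.roi_bounds[1]],
                    [B.roi_bounds[2], B.roi_bounds[1]],
                    [B.roi_bounds[0], B.roi_bounds[3]],
                    [B.roi_bounds[2], B.roi_bounds[3]],
                ]
            )
            tc = apply_affine(corners, (M, t))
            bounds_b = np.array([tc[:, 0].min(), tc[:, 1].min(), tc[:, 0].max(), tc[:, 1].max()])
            transform = (M, t)

    pairs, rounds, free_a, free_b = _greedy_rounds(
        coords_a, coords_b, ids_a, ids_b, cfg.window_um, cfg.n_rounds
    )

    # overlap of the two ROI rectangles in the common (A) frame
    ba = np.array(A.roi_bounds, dtype=float)
    inter = np.array(
        [
            max(ba[0], bounds_b[0]),
            max(ba[1], bounds_b[1]),
            min(ba[2], bounds_b[2]),
            min(ba[3], bounds_b[3]),
        ]
    )

    def _inside(p: np.ndarray) -> bool:
        return bool(
            inter[0] <= p[0] <= inter[2] and inter[1] <= p[1] <= inter[3]
        ) if inter[2] > inter[0] and inter[3] > inter[1] else False

    unmatched_a, edged_a = set(), set()
    for ia in free_a:
        (unmatched_a if _inside(coords_a[ia]) else edged_a).add(ids_a[ia])
    unmatched_b, edged_b = set(), set()
    for ib in free_b:
        (unmatched_b if _inside(coords_b[ib]) else edged_b).add(ids_b[ib])

    result = MatchResult(
        pairs=pairs,
        unmatched_A=unmatched_a,
        unmatched_B=unmatched_b,
        edged_out_A=edged_a,
        edged_out_B=edged_b,
        transform=transform,
        round_of_match=rounds,
    )
    _assert_one_to_one(result, len(A), len(B))
    return result


def _assert_one_to_one(m: MatchResult, n_a: int, n_b: int) -> None:
    ma, mb = m.matched_ids()
    if len(ma) != len(m.pairs) or len(mb) != len(m.pairs):
        raise AssertionError("matching is not one-to-one")
    if len(m.pairs) + len(m.unmatched_A) + len(m.edged_out_A) != n_a:
        raise AssertionError("side A accounting does not cover all records")
    if len(m.pairs) + len(m.unmatched_B) + len(m.edged_out_B) != n_b:
        raise AssertionError("side B accounting does not cover all records")


def matching_percentages(m: MatchResult, n_A: int, n_B: int) -> MatchingPercentages:
    """Matched / unmatched / edged-out percentages of the whole batch.

    The pooled convention divides by the total number of nuclei on both
    sides, so a pair counts twice in the numerator and the three pooled
    percentages sum to exactly 100.
    """
    total = n_A + n_B
    if total == 0:
        raise ZeroDivisionError("percentages undefined for two empty sets")
    if len(m.pairs) + len(m.unmatched_A) + len(m.edged_out_A) != n_A:
        raise ValueError("n_A inconsistent with MatchResult")
    if len(m.pairs) + len(m.unmatched_B) + len(m.edged_out_B) != n_B:
        raise ValueError("n_B inconsistent with MatchResult")
    k = len(m.pairs)

    def pct(x: float, denom: float) -> float:
        return 100.0 * x / denom if denom else float("nan")

    return MatchingPercentages(
        matched_pct=pct(2 * k, total),
        unmatched_pct=pct(len(m.unmatched_A) + len(m.unmatched_B), total),
        edged_out_pct=pct(len(m.edged_out_A) + len(m.edged_out_B), total),
        matched_pct_A=pct(k, n_A),
        matched_pct_B=pct(k, n_B),
        unmatched_pct_A=pct(len(m.unmatched_A), n_A),
        unmatched_pct_B=pct(len(m.unmatched_B), n_B),
        edged_out_pct_A=pct(len(m.edged_out_A), n_A),
        edged_out_pct_B=pct(len(m.edged_out_B), n_B),
        n_A=n_A,
        n_B=n_B,
    )
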