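import numpy as np
import pytest

from replicascan.io import DetectionSet, NucleusRecord


def make_set(
    coords,
    scan_id="scan",
    roi_bounds=None,
    areas=None,
    hema=None,
    eosin=None,
    id_prefix="n",
    pixel_size_um=0.11,
):
    """Build a DetectionSet from an (n, 2) coordinate array with filler features."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = len(coords)
    if roi_bounds is None:
        if n:
            roi_bounds = (
                float(coords[:, 0].min()) - 1.0,
                float(coords[:, 1].min()) - 1.0,
                float(coords[:, 0].max()) + 1.0,
                float(coords[:, 1].max()) + 1.0,
            )
        else:
            roi_bounds = (0.0, 0.0, 1.0, 1.0)
    areas = np.full(n, 15.0) if areas is None else np.asarray(areas, dtype=float)
    hema = np.full(n, 0.6) if hema is None else np.asarray(hema, dtype=float)
    eosin = np.full(n, 0.3) if eosin is None else np.asarray(eosin, dtype=float)
    recs = [
        NucleusRecord(
            id=f"{id_prefix}{i}",
            x_um=float(coords[i, 0]),
            y_um=float(coords[i, 1]),
            area_um2=float(areas[i]),
            hema_median=float(hema[i]),
            eosin_median=float(eosin[i]),
        )
        for i in range(n)
    ]
    return DetectionSet(
        scan_id=scan_id,
        roi_id="roi",
        records=recs,
        roi_bounds=roi_bounds,
        pixel_size_um=pixel_size_um,
    )


def brute_force_match(coords_a, ids_a, coords_b, ids_b, window_um=10.0, n_rounds=2):
    """Independent O(n²) re-implementation of the two-round matching.

    Round r: every free A nucleus proposes to its Euclidean-nearest free
    B nucleus within the Chebyshev box (ties by id_B); each B nucleus
    accepts the closest proposer (ties by id_A).  Returns the set of
    (id_A, id_B) pairs.
    """
    coords_a = np.asarray(coords_a, dtype=float).reshape(-1, 2)
    coords_b = np.asarray(coords_b, dtype=float).reshape(-1, 2)
    half = window_um / 2.0
    free_a = list(range(len(ids_a)))
    free_b = set(range(len(ids_b)))
    pairs = set()
    for _ in range(n_rounds):
        proposals = {}
        for ia in free_a:
            best = None
            for ib in free_b:
                dx = coords_b[ib, 0] - coords_a[ia, 0]
                dy = coords_b[ib, 1] - coords_a[ia, 1]
                if abs(dx) > half or abs(dy) > half:
                    continue
                d = float(np.hypot(dx, dy))
                if best is None or (d, ids_b[ib]) < (best[0], ids_b[best[1]]):
                    best = (d, ib)
            if best is not None:
                proposals.setdefault(best[1], []).append((best[0], ids_a[ia], ia))
        if not proposals:
            break
        for ib, plist in proposals.items():
            plist.sort()
            _, id_a, ia = plist[0]
            pairs.add((id_a, ids_b[ib]))
            free_a.remove(ia)
            free_b.discard(ib)
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
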