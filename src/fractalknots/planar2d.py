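"""Two-dimensional analogue: a planar ring is "knotted" iff it self-intersects.

In two dimensions a closed curve cannot be knotted in the topological
sense; the analogue studied here calls a conformation knotted when any
two non-adjacent segments intersect, i.e. when the polygon fails to be
simple.  Adjacent segments (sharing a bead, including across the closing
bond) are excluded, since every ring meets itself at its joints.
Grazing contacts within the tolerance count as intersections; they carry
zero probability under the Gaussian measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PlanarCall", "detect_intersection", "detect_intersection_brute", "is_simple_batch"]


@dataclass(frozen=True)
class PlanarCall:
    """Self-intersection verdict for a 2D ring."""

    is_knotted: bool
    first_pair: tuple[int, int] | None = None


def _as_2d(conformation) -> np.ndarray:
    pts = getattr(conformation, "positions", conformation)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (N, 2) coordinate array")
    if pts.shape[0] < 3:
        raise ValueError("a ring needs at least 3 beads")
    return pts


def detect_intersection(conformation, eps: float | None = None) -> PlanarCall:
    """Test all non-adjacent segment pairs of a 2D ring for intersection.

    Proper crossings are decided by orientation predicates; touching
    within ``eps`` (default 1e-12 times the diameter) also counts.
    Returns the lowest-index intersecting pair when one exists.
    """
    pts = _as_2d(conformation)
    n = pts.shape[0]
    if eps is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        eps = 1e-12 * (float(np.hypot(*span)) or 1.0)
    D = np.roll(pts, -1, axis=0) - pts
    ii, jj = np.triu_indices(n, k=2)
    keep = ~((ii == 0) & (jj == n - 1))
    ii, jj = ii[keep], jj[keep]
    d_i, d_j = D[ii], D[jj]
    rel = pts[jj] - pts[ii]
    denom = d_i[:, 0] * d_j[:, 1] - d_i[:, 1] * d_j[:, 0]
    s_num = rel[:, 0] * d_j[:, 1] - rel[:, 1] * d_j[:, 0]
    t_num = rel[:, 0] * d_i[:, 1] - rel[:, 1] * d_i[:, 0]
    scale = np.linalg.norm(d_i, axis=1) * np.linalg.norm(d_j, axis=1)
    scale = np.maximum(scale, 1e-300)
    margin = eps
    nonpar = np.abs(denom) > margin * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        s = s_num / denom
        t = t_num / denom
    lo, hi = -margin, 1.0 + margin
    hit = nonpar & (s > lo) & (s < hi) & (t > lo) & (t < hi)
    # near-parallel pairs: intersect iff collinear with overlapping spans
    par = ~nonpar
    if np.any(par):
        p = np.where(par)[0]
        off = np.abs(s_num[p]) / scale[p]
        collinear = off <= margin
        if np.any(collinear):
            for idx in p[collinear]:
                a, b = ii[idx], jj[idx]
                axis = D[a] / max(np.linalg.norm(D[a]), 1e-300)
                ta = np.array([0.0, D[a] @ axis])
                tb = (pts[[b, (b + 1) % n]] - pts[a]) @ axis
                if min(ta.max(), tb.max()) >= max(ta.min(), tb.min()) - eps:
                    hit[idx] = True
    if np.any(hit):
        first = int(np.argmax(hit))
        return PlanarCall(is_knotted=True, first_pair=(int(ii[first]), int(jj[first])))
    return PlanarCall(is_knotted=False, first_pair=None)


def _segments_cross(p1, p2, p3, p4, eps) -> bool:
    """Orientation-predicate segment intersection (inclusive within eps)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if v > eps:
            return 1
        if v < -eps:
            return -1
        return 0

    def on_segment(a, b, c):
        return (
            min(a[0], b[0]) - eps <= c[0] <= max(a[0], b[0]) + eps
            and min(a[1], b[1]) - eps <= c[1] <= max(a[1], b[1]) + eps
        )

    o1 = orient(p1, p2, p3)
    o2 = orient(p1, p2, p4)
    o3 = orient(p3, p4, p1)
    o4 = orient(p3, p4, p2)
    if o1 != o2 and o3 != o4:
        return True
    if o1 == 0 and on_segment(p1, p2, p3):
        return True
    if o2 == 0 and on_segment(p1, p2, p4):
        return True
    if o3 == 0 and on_segment(p3, p4, p1):
        return True
    return o4 == 0 and on_segment(p3, p4, p2)


def detect_intersection_brute(conformation, eps: float | None = None) -> PlanarCall:
    """Plain all-pairs loop over segments; independent reference implementation."""
    pts = _as_2d(conformation)
    n = pts.shape[0]
    if eps is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        eps = 1e-12 * (float(np.hypot(*span)) or 1.0)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_cross(
                pts[i], pts[(i + 1) % n], pts[j], pts[(j + 1) % n], eps
            ):
                return PlanarCall(is_knotted=True, first_pair=(i, j))
    return PlanarCall(is_knotted=False, first_pair=None)


def is_simple_batch(batch: np.ndarray) -> np.ndarray:
    """Vectorized simplicity test for a batch of 2D rings (n, N, 2).

    Returns a boolean array: True where the polygon has no proper
    crossing between non-adjacent segments.  Used for campaign-scale
    "unknot" counting; boundary contacts have measure zero and are
    resolved either way.
    """
    pts = np.asarray(batch, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 2:
        raise ValueError("expected a (n_samples, N, 2) array")
    n, N, _ = pts.shape
    D = np.roll(pts, -1, axis=1) - pts
    ii, jj = np.triu_indices(N, k=2)
    keep = ~((ii == 0) & (jj == N - 1))
    ii, jj = ii[keep], jj[keep]
    d_i = D[:, ii]
    d_j = D[:, jj]
    rel = pts[:, jj] - pts[:, ii]
    denom = d_i[..., 0] * d_j[..., 1] - d_i[..., 1] * d_j[..., 0]
    s_num = rel[..., 0] * d_j[..., 1] - rel[..., 1] * d_j[..., 0]
    t_num = rel[..., 0] * d_i[..., 1] - rel[..., 1] * d_i[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = s_num / denom
        t = t_num / denom
    hit = (denom != 0) & (s > 0) & (s < 1) & (t > 0) & (t < 1)
    return ~hit.any(axis=1)
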