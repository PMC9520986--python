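"""Knot detection for closed 3D polygonal curves via the Alexander invariant.

A ring conformation is typed as trivially or nontrivially knotted by:

1. topology-preserving chain simplification (KMT-style triangle elision:
   a bead is removed only when the triangle spanned with its neighbours
   is not pierced by any other chain segment),
2. generic planar projection to a crossing diagram (retrying directions
   that produce degenerate projections),
3. the knot determinant |Delta(-1)|, the Alexander polynomial evaluated
   at t = -1, computed in exact integer arithmetic.

The determinant is 1 for the unknot, 3 for the trefoil, 5 for the
figure-eight, and odd for every knot; a ring is called trivial iff the
determinant equals 1.  Composite knots yield the product determinant and
are reported as nontrivial.  Knots whose determinant happens to equal 1
(the first is 10_124 with 10 crossings) would be miscalled; such knots
are vanishingly rare in the ensembles studied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DegenerateProjection",
    "KnotDiagram",
    "KnotCall",
    "simplify_chain",
    "build_diagram",
    "alexander_determinant",
    "classify_knot",
    "classify_batch",
    "make_fixture",
    "projection_crossing_counts",
]


class DegenerateProjection(RuntimeError):
    """Raised when a projection direction produces an ambiguous diagram."""


@dataclass(frozen=True)
class KnotDiagram:
    """Crossing diagram of a ring projected along ``direction``.

    ``crossings`` holds one record per crossing:
    (over_arc, under_in_arc, under_out_arc, sign).  Arcs are the maximal
    over-strand pieces between consecutive undercrossings; a diagram
    with c >= 1 crossings has exactly c arcs.
    """

    crossings: tuple
    n_arcs: int
    direction: np.ndarray

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


@dataclass(frozen=True)
class KnotCall:
    """Result of classifying one ring conformation."""

    determinant: int
    is_trivial: bool
    crossings_after_simplification: int

    def __post_init__(self):
        if self.determinant < 1 or self.determinant % 2 == 0:
            raise ValueError("knot determinant must be an odd positive integer")
        if self.is_trivial != (self.determinant == 1):
            raise ValueError("is_trivial must mirror determinant == 1")


# ---------------------------------------------------------------------------
# KMT-style simplification
# ---------------------------------------------------------------------------


@njit(cache=False)
def _seg2d_cross(ax, ay, bx, by, cx, cy, dx, dy, eps):
    """2D segment AB vs CD intersection with inclusive tolerance."""
    o1 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    o2 = (bx - ax) * (dy - ay) - (by - ay) * (dx - ax)
    o3 = (dx - cx) * (ay - cy) - (dy - cy) * (ax - cx)
    o4 = (dx - cx) * (by - cy) - (dy - cy) * (bx - cx)
    s1 = 1 if o1 > eps else (-1 if o1 < -eps else 0)
    s2 = 1 if o2 > eps else (-1 if o2 < -eps else 0)
    s3 = 1 if o3 > eps else (-1 if o3 < -eps else 0)
    s4 = 1 if o4 > eps else (-1 if o4 < -eps else 0)
    if s1 * s2 <= 0 and s3 * s4 <= 0:
        # conservative: includes touching and collinear-overlap candidates
        if s1 == 0 and s2 == 0:
            # collinear in projection: check 1D span overlap
            lo1 = min(ax, bx) if abs(bx - ax) >= abs(by - ay) else min(ay, by)
            hi1 = max(ax, bx) if abs(bx - ax) >= abs(by - ay) else max(ay, by)
            lo2 = min(cx, dx) if abs(bx - ax) >= abs(by - ay) else min(cy, dy)
            hi2 = max(cx, dx) if abs(bx - ax) >= abs(by - ay) else max(cy, dy)
            return min(hi1, hi2) >= max(lo1, lo2) - eps
        return True
    return False


@njit(cache=False)
def _coplanar_hit(A, B, C, P, Q, tol, scale):
    """In-plane test: does segment PQ meet triangle ABC within the plane?"""
    # barycentric coordinates with respect to (B - A, C - A)
    v0x, v0y, v0z = B[0] - A[0], B[1] - A[1], B[2] - A[2]
    v1x, v1y, v1z = C[0] - A[0], C[1] - A[1], C[2] - A[2]
    dot00 = v0x * v0x + v0y * v0y + v0z * v0z
    dot01 = v0x * v1x + v0y * v1y + v0z * v1z
    dot11 = v1x * v1x + v1y * v1y + v1z * v1z
    denom = dot00 * dot11 - dot01 * dot01
    if denom <= 0.0:
        return True
    eps = tol
    inside_count = 0
    us = np.empty(2)
    vs = np.empty(2)
    for idx in range(2):
        E = P if idx == 0 else Q
        ex, ey, ez = E[0] - A[0], E[1] - A[1], E[2] - A[2]
        d20 = ex * v0x + ey * v0y + ez * v0z
        d21 = ex * v1x + ey * v1y + ez * v1z
        u = (dot11 * d20 - dot01 * d21) / denom
        v = (dot00 * d21 - dot01 * d20) / denom
        us[idx] = u
        vs[idx] = v
        if u >= -eps and v >= -eps and u + v <= 1.0 + eps:
            inside_count += 1
    if inside_count > 0:
        return True
    # neither endpoint inside: intersects iff it crosses a triangle edge
    # (in (u, v) coordinates the triangle is u>=0, v>=0, u+v<=1)
    if _seg2d_cross(us[0], vs[0], us[1], vs[1], 0.0, 0.0, 1.0, 0.0, eps):
        return True
    if _seg2d_cross(us[0], vs[0], us[1], vs[1], 0.0, 0.0, 0.0, 1.0, eps):
        return True
    return _seg2d_cross(us[0], vs[0], us[1], vs[1], 1.0, 0.0, 0.0, 1.0, eps)


@njit(cache=False)
def _segment_pierces_triangle(A, B, C, nv, nn2, P, Q, tol):
    """Does segment PQ intersect (conservatively) triangle ABC with normal nv?"""
    d1 = (
        nv[0] * (P[0] - A[0]) + nv[1] * (P[1] - A[1]) + nv[2] * (P[2] - A[2])
    )
    d2 = (
        nv[0] * (Q[0] - A[0]) + nv[1] * (Q[1] - A[1]) + nv[2] * (Q[2] - A[2])
    )
    lim = tol * math.sqrt(nn2)
    if d1 > lim and d2 > lim:
        return False
    if d1 < -lim and d2 < -lim:
        return False
    if abs(d1) <= lim and abs(d2) <= lim:
        # near-coplanar segment: decide within the triangle's plane
        return _coplanar_hit(A, B, C, P, Q, tol, lim)
    t = d1 / (d1 - d2)
    x0 = P[0] + t * (Q[0] - P[0]) - A[0]
    x1 = P[1] + t * (Q[1] - P[1]) - A[1]
    x2 = P[2] + t * (Q[2] - P[2]) - A[2]
    # barycentric coordinates of the plane intersection point
    v0x, v0y, v0z = B[0] - A[0], B[1] - A[1], B[2] - A[2]
    v1x, v1y, v1z = C[0] - A[0], C[1] - A[1], C[2] - A[2]
    dot00 = v0x * v0x + v0y * v0y + v0z * v0z
    dot01 = v0x * v1x + v0y * v1y + v0z * v1z
    dot11 = v1x * v1x + v1y * v1y + v1z * v1z
    dot20 = x0 * v0x + x1 * v0y + x2 * v0z
    dot21 = x0 * v1x + x1 * v1y + x2 * v1z
    denom = dot00 * dot11 - dot01 * dot01
    if denom <= 0.0:
        return True
    u = (dot11 * dot20 - dot01 * dot21) / denom
    v = (dot00 * dot21 - dot01 * dot20) / denom
    eps = tol
    return u >= -eps and v >= -eps and (u + v) <= 1.0 + eps


@njit(cache=False)
def _kmt_pass_mask(pts, alive, nxt, prv, count, tol):
    """One sweep of triangle elision; mutates the linked list in place."""
    n = pts.shape[0]
    removed = 0
    shrink = 1e-7
    for i in range(n):
        if count - removed <= 3:
            break
        if not alive[i]:
            continue
        p = prv[i]
        nx = nxt[i]
        A = pts[p]
        B = pts[i]
        C = pts[nx]
        # triangle normal
        e1x, e1y, e1z = B[0] - A[0], B[1] - A[1], B[2] - A[2]
        e2x, e2y, e2z = C[0] - A[0], C[1] - A[1], C[2] - A[2]
        nvx = e1y * e2z - e1z * e2y
        nvy = e1z * e2x - e1x * e2z
        nvz = e1x * e2y - e1y * e2x
        nn2 = nvx * nvx + nvy * nvy + nvz * nvz
        base2 = e2x * e2x + e2y * e2y + e2z * e2z
        leg2 = e1x * e1x + e1y * e1y + e1z * e1z
        scale2 = max(base2, leg2)
        degenerate = nn2 <= (tol * scale2) ** 2
        ok = True
        if not degenerate:
            nv = np.empty(3)
            nv[0], nv[1], nv[2] = nvx, nvy, nvz
            # triangle bounding box (slightly inflated) for fast rejection
            pad = tol * math.sqrt(scale2)
            tx0 = min(A[0], B[0], C[0]) - pad
            tx1 = max(A[0], B[0], C[0]) + pad
            ty0 = min(A[1], B[1], C[1]) - pad
            ty1 = max(A[1], B[1], C[1]) + pad
            tz0 = min(A[2], B[2], C[2]) - pad
            tz1 = max(A[2], B[2], C[2]) + pad
            j = nxt[nx]
            # walk segments (j, nxt[j]) around the ring, skipping the two
            # triangle edges (p, i) and (i, nx)
            while j != p:
                jn = nxt[j]
                P = pts[j]
                Q = pts[jn]
                if (
                    (P[0] < tx0 and Q[0] < tx0)
                    or (P[0] > tx1 and Q[0] > tx1)
                    or (P[1] < ty0 and Q[1] < ty0)
                    or (P[1] > ty1 and Q[1] > ty1)
                    or (P[2] < tz0 and Q[2] < tz0)
                    or (P[2] > tz1 and Q[2] > tz1)
                ):
                    j = jn
                    continue
                if jn == p:
                    # segment ends at triangle vertex p: shrink that end
                    Qs = np.empty(3)
                    Qs[0] = Q[0] + shrink * (P[0] - Q[0])
                    Qs[1] = Q[1] + shrink * (P[1] - Q[1])
                    Qs[2] = Q[2] + shrink * (P[2] - Q[2])
                    if _segment_pierces_triangle(A, B, C, nv, nn2, P, Qs, tol):
                        ok = False
                        break
                elif j == nx:
                    # segment starts at triangle vertex nx: shrink that end
                    Ps = np.empty(3)
                    Ps[0] = P[0] + shrink * (Q[0] - P[0])
                    Ps[1] = P[1] + shrink * (Q[1] - P[1])
                    Ps[2] = P[2] + shrink * (Q[2] - P[2])
                    if _segment_pierces_triangle(A, B, C, nv, nn2, Ps, Q, tol):
                        ok = False
                        break
                else:
                    if _segment_pierces_triangle(A, B, C, nv, nn2, P, Q, tol):
                        ok = False
                        break
                j = jn
        if ok:
            alive[i] = False
            nxt[p] = nx
            prv[nx] = p
            removed += 1
    return removed


def simplify_chain(positions: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Reduce a closed polygon to fewer beads without changing its knot type.

    Iterates triangle elision to a fixed point (or the 3-bead floor).
    Degenerate (collinear) triangles are treated as removable.  Returns
    the simplified positions; the input is not modified.
    """
    pts = np.ascontiguousarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (N, 3) coordinate array")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("a ring needs at least 3 beads")
    alive = np.ones(n, dtype=np.bool_)
    nxt = np.roll(np.arange(n), -1)
    prv = np.roll(np.arange(n), 1)
    count = n
    while count > 3:
        removed = _kmt_pass_mask(pts, alive, nxt, prv, count, tol)
        if removed == 0:
            break
        count -= removed
    return pts[alive]


# ---------------------------------------------------------------------------
# Projection to a crossing diagram
# ---------------------------------------------------------------------------


def _projection_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("projection direction must be nonzero")
    w = w / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def _pairwise_crossings(xy: np.ndarray, eps_abs: float):
    """Locate proper crossings between all non-adjacent segment pairs.

    Returns arrays (i, j, s, t) with i < j and intersection parameters
    s, t in (0, 1).  Raises DegenerateProjection on near-parallel
    overlapping pairs or crossings too close to a vertex.
    """
    n = xy.shape[0]
    P = xy
    D = np.roll(xy, -1, axis=0) - xy  # segment vectors
    ii, jj = np.triu_indices(n, k=2)
    keep = ~((ii == 0) & (jj == n - 1))  # closing bond adjacency
    ii, jj = ii[keep], jj[keep]
    d_i, d_j = D[ii], D[jj]
    denom = d_i[:, 0] * d_j[:, 1] - d_i[:, 1] * d_j[:, 0]
    rel = P[jj] - P[ii]
    s_num = rel[:, 0] * d_j[:, 1] - rel[:, 1] * d_j[:, 0]
    t_num = rel[:, 0] * d_i[:, 1] - rel[:, 1] * d_i[:, 0]
    scale = np.linalg.norm(d_i, axis=1) * np.linalg.norm(d_j, axis=1)
    parallel = np.abs(denom) <= 1e-14 * np.maximum(scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(parallel, np.nan, s_num / denom)
        t = np.where(parallel, np.nan, t_num / denom)
    margin = eps_abs
    hit = (~parallel) & (s > 0.0) & (s < 1.0) & (t > 0.0) & (t < 1.0)
    near = (
        (~parallel)
        & (s > -margin)
        & (s < 1.0 + margin)
        & (t > -margin)
        & (t < 1.0 + margin)
        & (
            (np.abs(s) < margin)
            | (np.abs(1.0 - s) < margin)
            | (np.abs(t) < margin)
            | (np.abs(1.0 - t) < margin)
        )
    )
    if np.any(near):
        raise DegenerateProjection("crossing within tolerance of a vertex")
    if np.any(parallel):
        # parallel pair: degenerate only if the supporting lines coincide
        # and the segments' parameter ranges overlap
        par = np.where(parallel)[0]
        off = np.abs(
            rel[par, 0] * d_i[par, 1] - rel[par, 1] * d_i[par, 0]
        )
        if np.any(off <= margin * np.maximum(scale[par], 1e-300)):
            raise DegenerateProjection("overlapping parallel segments")
    return ii[hit], jj[hit], s[hit], t[hit]


def build_diagram(
    positions: np.ndarray, direction, eps: float | None = None
) -> KnotDiagram:
    """Project a 3D ring along ``direction`` and extract its crossing diagram.

    Raises :class:`DegenerateProjection` when two crossings coincide, a
    crossing falls within ``eps`` of a vertex, or two projected segments
    overlap; the caller should retry with a fresh random direction.
    ``eps`` defaults to 1e-9 times the conformation diameter.
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (N, 3) coordinate array")
    n = pts.shape[0]
    u, v, w = _projection_frame(np.asarray(direction, dtype=float))
    xy = pts @ np.column_stack([u, v])
    depth = pts @ w
    span = xy.max(axis=0) - xy.min(axis=0)
    diam = float(np.hypot(*span)) or 1.0
    if eps is None:
        eps = 1e-9 * diam
    ii, jj, ss, tt = _pairwise_crossings(xy, eps / diam)
    c = ii.size
    if c == 0:
        return KnotDiagram(crossings=(), n_arcs=1, direction=w)
    pos_x = xy[ii] + ss[:, None] * (np.roll(xy, -1, axis=0) - xy)[ii]
    if c > 1:
        d2 = np.sum(
            (pos_x[:, None, :] - pos_x[None, :, :]) ** 2, axis=-1
        )
        np.fill_diagonal(d2, np.inf)
        if d2.min() < eps**2:
            raise DegenerateProjection("coincident crossing points")
    depth_next = np.roll(depth, -1)
    zi = depth[ii] + ss * (depth_next - depth)[ii]
    zj = depth[jj] + tt * (depth_next - depth)[jj]
    if np.any(np.abs(zi - zj) < eps):
        raise DegenerateProjection("ambiguous over/under assignment")
    # chain positions (segment + parameter) of each strand passage
    chain_i = ii + ss
    chain_j = jj + tt
    over_is_i = zi > zj
    under_pos = np.where(over_is_i, chain_j, chain_i)
    over_pos = np.where(over_is_i, chain_i, chain_j)
    # handedness: sign of 2D cross product (over tangent) x (under tangent)
    seg_vec = np.roll(xy, -1, axis=0) - xy
    t_over = np.where(over_is_i[:, None], seg_vec[ii], seg_vec[jj])
    t_under = np.where(over_is_i[:, None], seg_vec[jj], seg_vec[ii])
    sign = np.where(
        t_over[:, 0] * t_under[:, 1] - t_over[:, 1] * t_under[:, 0] > 0, 1, -1
    )
    # arcs are delimited by undercrossings, ordered along the chain
    order = np.argsort(under_pos)
    boundaries = under_pos[order]  # e_0 < e_1 < ... < e_{c-1}
    # arc index of a chain position: arc m runs from e_{m-1} to e_m (arc 0 wraps)
    arc_of = lambda pos: int(np.searchsorted(boundaries, pos)) % c
    crossings = []
    rank = np.empty(c, dtype=int)
    rank[order] = np.arange(c)
    for m in range(c):
        under_in = int(rank[m])  # arc arriving at this undercrossing
        under_out = (under_in + 1) % c
        over_arc = arc_of(over_pos[m])
        crossings.append((over_arc, under_in, under_out, int(sign[m])))
    return KnotDiagram(crossings=tuple(crossings), n_arcs=c, direction=w)


def projection_crossing_counts(batch: np.ndarray) -> np.ndarray:
    """Crossing counts of the z-projection for a batch of rings (n, N, 3).

    Vectorized prefilter: a diagram with fewer than 3 crossings is always
    the unknot, so rings whose z-projection shows <= 2 crossings need no
    further work.  Degeneracies are not policed here; callers needing a
    certified diagram must use :func:`build_diagram`.
    """
    pts = np.asarray(batch, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 3:
        raise ValueError("expected a (n_samples, N, 3) array")
    n, N, _ = pts.shape
    xy = pts[:, :, :2]
    D = np.roll(xy, -1, axis=1) - xy
    ii, jj = np.triu_indices(N, k=2)
    keep = ~((ii == 0) & (jj == N - 1))
    ii, jj = ii[keep], jj[keep]
    d_i = D[:, ii]
    d_j = D[:, jj]
    rel = xy[:, jj] - xy[:, ii]
    denom = d_i[..., 0] * d_j[..., 1] - d_i[..., 1] * d_j[..., 0]
    s_num = rel[..., 0] * d_j[..., 1] - rel[..., 1] * d_j[..., 0]
    t_num = rel[..., 0] * d_i[..., 1] - rel[..., 1] * d_i[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = s_num / denom
        t = t_num / denom
    hit = (denom != 0) & (s > 0) & (s < 1) & (t > 0) & (t < 1)
    return hit.sum(axis=1)


# ---------------------------------------------------------------------------
# Alexander determinant at t = -1, exact
# ---------------------------------------------------------------------------

_PRIMES: list[int] = []


def _modular_primes(count: int) -> list[int]:
    """First ``count`` primes just below 2**30 (cached)."""
    from sympy import prevprime

    while len(_PRIMES) < count:
        p = prevprime(_PRIMES[-1]) if _PRIMES else prevprime(2**30)
        _PRIMES.append(int(p))
    return _PRIMES[:count]


@njit(cache=False)
def _modpow(base, exp, p):
    result = np.int64(1)
    b = base % p
    e = exp
    while e > 0:
        if e & 1:
            result = result * b % p
        b = b * b % p
        e >>= 1
    return result


@njit(cache=False)
def _det_mod_nb(a, p):
    """Determinant mod prime p by in-place int64 Gaussian elimination."""
    n = a.shape[0]
    det = np.int64(1)
    for col in range(n):
        piv = -1
        for r in range(col, n):
            if a[r, col] != 0:
                piv = r
                break
        if piv < 0:
            return np.int64(0)
        if piv != col:
            for c in range(col, n):
                tmp = a[col, c]
                a[col, c] = a[piv, c]
                a[piv, c] = tmp
            det = (p - det) % p
        pivval = a[col, col]
        det = det * pivval % p
        inv = _modpow(pivval, p - 2, p)
        for r in range(col + 1, n):
            f = a[r, col] * inv % p
            if f != 0:
                for c in range(col, n):
                    a[r, c] = (a[r, c] - f * a[col, c]) % p
    return det


def _det_mod(mat: np.ndarray, p: int) -> int:
    """Determinant of an integer matrix modulo prime p."""
    a = np.mod(mat, p).astype(np.int64)
    return int(_det_mod_nb(a, np.int64(p)))


def bareiss_determinant(mat: np.ndarray) -> int:
    """Exact integer determinant by fraction-free (Bareiss) elimination.

    Reference implementation in pure Python integers; used as the
    independent cross-check for the faster modular/CRT route.
    """
    a = [[int(x) for x in row] for row in np.asarray(mat)]
    n = len(a)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for col in range(n - 1):
        if a[col][col] == 0:
            for r in range(col + 1, n):
                if a[r][col] != 0:
                    a[col], a[r] = a[r], a[col]
                    sign = -sign
                    break
            else:
                return 0
        for r in range(col + 1, n):
            for c in range(col + 1, n):
                a[r][c] = (a[r][c] * a[col][col] - a[r][col] * a[col][c]) // prev
            a[r][col] = 0
        prev = a[col][col]
    return sign * a[n - 1][n - 1]


def _exact_det(mat: np.ndarray, stable_extra: int = 2) -> int:
    """Exact determinant via incremental CRT over 30-bit primes.

    Primes are added until the symmetric-residue reconstruction is
    unchanged for ``stable_extra`` consecutive primes (the reconstruction
    is exact once the running modulus exceeds 2 |det|; each further
    agreeing prime multiplies the confidence by ~2^30) and in any case
    no further than the Hadamard bound, beyond which the result is
    certified.
    """
    n = mat.shape[0]
    if n == 0:
        return 1
    norms = np.sqrt(np.sum(np.asarray(mat, dtype=float) ** 2, axis=1))
    norms = np.maximum(norms, 1.0)
    log2_bound = float(np.sum(np.log2(norms)))
    max_primes = max(1, math.ceil((log2_bound + 2) / 29.0))
    modulus = 1
    value = 0
    stable = 0
    idx = 0
    while idx < max_primes:
        p = _modular_primes(idx + 1)[idx]
        r = _det_mod(mat, p)
        if modulus == 1:
            modulus = p
            value = r if r <= p // 2 else r - p
        else:
            inv = pow(modulus % p, p - 2, p)
            diff = (r - value) % p
            new = value + modulus * (diff * inv % p)
            modulus *= p
            if new > modulus // 2:
                new -= modulus
            if new == value:
                stable += 1
            else:
                stable = 0
            value = new
        idx += 1
        if stable >= stable_extra:
            break
    return int(value)


def alexander_matrix(diagram: KnotDiagram) -> np.ndarray:
    """Integer Alexander matrix at t = -1 (one row per crossing, column per arc).

    From the Wirtinger presentation with Fox calculus, at t = -1 each
    crossing contributes +2 on the over arc and -1 on the incoming and
    outgoing under arcs regardless of handedness; rows sum to zero.
    """
    c = diagram.n_crossings
    mat = np.zeros((c, c), dtype=np.int64)
    for row, (over, u_in, u_out, _sign) in enumerate(diagram.crossings):
        if not (0 <= over < c and 0 <= u_in < c and 0 <= u_out < c):
            raise ValueError("inconsistent arc bookkeeping in diagram")
        mat[row, over] += 2
        mat[row, u_in] -= 1
        mat[row, u_out] -= 1
    if c and np.any(mat.sum(axis=1)):
        raise ValueError("inconsistent diagram: rows must sum to zero")
    return mat


def alexander_determinant(diagram: KnotDiagram) -> int:
    """Knot determinant |Delta(-1)| of a crossing diagram (odd, >= 1)."""
    c = diagram.n_crossings
    if c <= 2:
        return 1
    mat = alexander_matrix(diagram)
    det = abs(_exact_det(mat[:-1, :-1]))
    if det == 0 or det % 2 == 0:
        raise ValueError(
            f"invalid knot determinant {det}: diagram is inconsistent"
        )
    return det


# ---------------------------------------------------------------------------
# Full classification pipeline
# ---------------------------------------------------------------------------


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _quick_crossing_count(pts: np.ndarray, direction: np.ndarray) -> int:
    """Crossing count of one projection, without degeneracy certification."""
    u, v, _w = _projection_frame(direction)
    xy = pts @ np.column_stack([u, v])
    n = xy.shape[0]
    D = np.roll(xy, -1, axis=0) - xy
    ii, jj = np.triu_indices(n, k=2)
    keep = ~((ii == 0) & (jj == n - 1))
    ii, jj = ii[keep], jj[keep]
    d_i, d_j = D[ii], D[jj]
    rel = xy[jj] - xy[ii]
    denom = d_i[:, 0] * d_j[:, 1] - d_i[:, 1] * d_j[:, 0]
    s_num = rel[:, 0] * d_j[:, 1] - rel[:, 1] * d_j[:, 0]
    t_num = rel[:, 0] * d_i[:, 1] - rel[:, 1] * d_i[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = s_num / denom
        t = t_num / denom
    hit = (denom != 0) & (s > 0) & (s < 1) & (t > 0) & (t < 1)
    return int(hit.sum())


def classify_knot(
    conformation,
    rng: np.random.Generator | None = None,
    simplify: bool = True,
    max_retries: int = 20,
    n_candidate_dirs: int = 3,
) -> KnotCall:
    """Classify a closed 3D ring as trivially or nontrivially knotted.

    Simplifies the chain, projects along random directions (retrying
    degenerate ones up to ``max_retries`` times), and evaluates the knot
    determinant.  The result is projection-independent; among
    ``n_candidate_dirs`` random directions the one giving the fewest
    crossings is diagrammed first, purely for speed.
    """
    pts = getattr(conformation, "positions", conformation)
    pts = np.asarray(pts, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    if simplify:
        pts = simplify_chain(pts)
    dirs = [_random_direction(rng) for _ in range(max(1, n_candidate_dirs))]
    counts = [_quick_crossing_count(pts, w) for w in dirs]
    queue = [dirs[i] for i in np.argsort(counts)]
    last_exc: Exception | None = None
    for attempt in range(max_retries):
        direction = queue[attempt] if attempt < len(queue) else _random_direction(rng)
        try:
            diagram = build_diagram(pts, direction)
        except DegenerateProjection as exc:
            last_exc = exc
            continue
        det = alexander_determinant(diagram)
        return KnotCall(
            determinant=det,
            is_trivial=det == 1,
            crossings_after_simplification=diagram.n_crossings,
        )
    raise DegenerateProjection(
        f"no generic projection found in {max_retries} attempts"
    ) from last_exc


def classify_batch(
    positions: np.ndarray,
    rng: np.random.Generator,
    simplify: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Classify a batch of rings (n, N, 3).

    Returns (is_trivial bool array, crossing-count array, determinants).
    """
    pts = np.asarray(positions, dtype=float)
    n = pts.shape[0]
    trivial = np.empty(n, dtype=bool)
    crossings = np.empty(n, dtype=np.int64)
    dets: list[int] = []
    for m in range(n):
        call = classify_knot(pts[m], rng, simplify=simplify)
        trivial[m] = call.is_trivial
        crossings[m] = call.crossings_after_simplification
        dets.append(call.determinant)
    return trivial, crossings, dets


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

_FIXTURES = ("unknot", "circle", "trefoil", "figure_eight")


def make_fixture(knot_name: str, n_beads: int) -> np.ndarray:
    """Closed polygonal curve of a named knot type from standard parametrizations.

    Supported names: "unknot"/"circle" (planar circle), "trefoil"
    (determinant 3), "figure_eight" (determinant 5).  ``n_beads`` must be
    at least 30 so that polygonalization preserves the topology.
    """
    if knot_name not in _FIXTURES:
        raise ValueError(f"unknown knot name {knot_name!r}; choose from {_FIXTURES}")
    if n_beads < 30:
        raise ValueError("n_beads must be >= 30 to preserve the topology")
    t = 2.0 * np.pi * np.arange(n_beads) / n_beads
    if knot_name in ("unknot", "circle"):
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    elif knot_name == "trefoil":
        pts = np.column_stack(
            [
                np.sin(t) + 2.0 * np.sin(2.0 * t),
                np.cos(t) - 2.0 * np.cos(2.0 * t),
                -np.sin(3.0 * t),
            ]
        )
    else:  # figure_eight
        pts = np.column_stack(
            [
                (2.0 + np.cos(2.0 * t)) * np.cos(3.0 * t),
                (2.0 + np.cos(2.0 * t)) * np.sin(3.0 * t),
                np.sin(4.0 * t),
            ]
        )
    return pts
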