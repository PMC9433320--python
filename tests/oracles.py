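"""Independent brute-force oracles used to validate the image primitives.

Each oracle deliberately re-derives the quantity from first principles
(exhaustive search, per-pixel formula evaluation, flood fill, dense
sampling) without sharing code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage


def otsu_threshold_bruteforce(img: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance argmax over histogram bins."""
    hist, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    c = hist.astype(float)
    # cumulative class moments so that splits across empty bins yield
    # bitwise-identical variances (exact ties resolved to the first split)
    cum_n = np.cumsum(c)
    cum_s = np.cumsum(c * centers)
    total_n, total_s = cum_n[-1], cum_s[-1]
    best_v, best_t = -1.0, centers[0]
    # threshold convention: the returned value is the centre of the last
    # bin assigned to the dark class (pixels strictly above are foreground)
    for k in range(1, nbins):
        n0, s0 = cum_n[k - 1], cum_s[k - 1]
        n1, s1 = total_n - n0, total_s - s0
        if n0 == 0 or n1 == 0:
            continue
        v = n0 * n1 * (s0 / n0 - s1 / n1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t


def phansalkar_bruteforce(
    img: np.ndarray, radius: int, k: float = 0.25, r: float = 0.5,
    p: float = 2.0, q: float = 10.0,
) -> np.ndarray:
    """Naive per-pixel evaluation of the Phansalkar threshold formula."""
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    sc = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    h, w = sc.shape
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if dy * dy + dx * dx <= radius * radius:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            vals.append(sc[yy, xx])
            vals = np.array(vals)
            mu, sd = vals.mean(), vals.std()
            t = mu * (1 + p * np.exp(-q * mu) + k * (sd / r - 1))
            out[y, x] = sc[y, x] > t
    return out


def maxima_bruteforce(
    img: np.ndarray, prominence: float, exclude_edges: bool = True
) -> list[tuple[int, int]]:
    """Strict local maxima with flood-fill prominence (tie-free images).

    For each strict 8-neighbourhood local maximum the key saddle is found
    by binary search over unique intensity levels: the highest threshold
    at which the maximum's connected component of ``img >= t`` contains a
    strictly higher pixel.  Prominence = peak − saddle, or peak − min for
    the global maximum.
    """
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    s8 = np.ones((3, 3), dtype=bool)
    levels = np.unique(a)
    out = []
    for y in range(h):
        for x in range(w):
            v = a[y, x]
            neigh = a[max(0, y - 1) : y + 2, max(0, x - 1) : x + 2]
            if (v > neigh).sum() != neigh.size - 1:
                continue
            if exclude_edges and (y in (0, h - 1) or x in (0, w - 1)):
                continue
            cand = levels[levels < v]

            def connected_to_higher(t: float) -> bool:
                lab, _ = ndimage.label(a >= t, structure=s8)
                comp = lab == lab[y, x]
                return a[comp].max() > v

            lo_i, hi_i = 0, len(cand) - 1
            saddle = None
            # highest level at which the component reaches a higher peak
            if len(cand) and connected_to_higher(cand[0]):
                while lo_i < hi_i:
                    mid = (lo_i + hi_i + 1) // 2
                    if connected_to_higher(cand[mid]):
                        lo_i = mid
                    else:
                        hi_i = mid - 1
                saddle = cand[lo_i]
            prom = v - (saddle if saddle is not None else a.min())
            if prom >= prominence:
                out.append((y, x))
    return sorted(out)


def mannwhitney_exact_bruteforce(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by exhaustive label permutation.

    Enumerates every assignment of the pooled values into two groups of
    the observed sizes and compares the observed U against the full null
    distribution: p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    # pairwise win matrix (0.5 for ties) so U of any subset is a gather-sum
    M = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(M, 0.5)  # self-pairs cancel in the row-sum identity below
    row_sums = M.sum(axis=1)
    combs = np.array(list(itertools.combinations(range(n), n1)))
    rs = row_sums[combs].sum(axis=1)
    sub = M[combs[:, :, None], combs[:, None, :]].sum(axis=(1, 2))
    us = rs - sub  # U against the complement group
    u_obs = float(M[:n1, n1:].sum())
    p = 2 * min((us <= u_obs + 1e-12).mean(), (us >= u_obs - 1e-12).mean())
    return u_obs, min(p, 1.0)


def clip_polyline_dense(
    polyline: np.ndarray, membership, pitch: float = 0.001
) -> tuple[float, float]:
    """Dense-sampling clipping oracle: total length of a polyline inside /
    outside a region given by a membership predicate, sampling sub-segment
    midpoints every ``pitch`` (μm)."""
    lin = lout = 0.0
    pts = np.asarray(polyline, dtype=float)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        L = float(np.linalg.norm(p1 - p0))
        if L == 0:
            continue
        n = max(int(np.ceil(L / pitch)), 1)
        ts = (np.arange(n) + 0.5) / n
        mids = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        inside = membership(mids)
        lin += L / n * np.count_nonzero(inside)
        lout += L / n * np.count_nonzero(~inside)
    return lin, lout
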