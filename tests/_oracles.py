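"""Independent reference implementations used as test oracles.

Everything here is deliberately written as per-pixel / per-point loops in
plain Python, independent of the vectorised library code paths it checks.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# scalar background-subtraction oracles (per-pixel loops)
# ---------------------------------------------------------------------------

def mog2_scalar(frames, params):
    """Per-pixel mixture-of-Gaussians recursion; returns (n, H, W) bool masks.

    Implements the documented recursion: rank by w/sigma (stable), match the
    first component within d sigma, classify against the pre-update
    background prefix (cumulative weight >= T), update matched component
    with rho = a / w_k (updated weight) and pre-update delta, or replace the
    first-minimum-weight component on no match; floor variances, then
    renormalise weights by sequential summation.
    """
    frames = np.asarray(frames)
    n, H, W = frames.shape
    K = params.n_components
    a = params.learning_rate
    d = params.match_threshold
    T = params.background_ratio
    var_init = params.sigma_init ** 2
    var_min = params.sigma_min ** 2
    out = np.zeros((n, H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            w = [0.0] * K
            mu = [0.0] * K
            var = [var_init] * K
            w[0] = 1.0
            mu[0] = float(frames[0, i, j])
            for t in range(n):
                x = float(frames[t, i, j])
                if t == 0:
                    # state was just initialised from this frame
                    pass
                sigma = [math.sqrt(v) for v in var]
                key = [w[k] / sigma[k] for k in range(K)]
                order = sorted(range(K), key=lambda k: -key[k])
                jstar = -1
                for rank, k in enumerate(order):
                    if abs(x - mu[k]) <= d * sigma[k]:
                        jstar = rank
                        break
                matched = jstar >= 0
                cum = 0.0
                in_prefix = [False] * K
                for rank, k in enumerate(order):
                    in_prefix[rank] = cum < T
                    cum += w[k]
                out[t, i, j] = (not matched) or (not in_prefix[jstar])
                if matched:
                    kstar = order[jstar]
                    w = [(1.0 - a) * wk for wk in w]
                    w[kstar] = w[kstar] + a
                    rho = a / w[kstar]
                    delta = x - mu[kstar]
                    mu[kstar] = mu[kstar] + rho * delta
                    var[kstar] = var[kstar] + rho * (delta * delta - var[kstar])
                else:
                    kmin = 0
                    for k in range(1, K):
                        if w[k] < w[kmin]:
                            kmin = k
                    w[kmin] = a
                    mu[kmin] = x
                    var[kmin] = var_init
                var = [max(v, var_min) for v in var]
                total = w[0]
                for k in range(1, K):
                    total = total + w[k]
                w = [wk / total for wk in w]
    return out


def knn_scalar(frames, params, seed):
    """Per-pixel pixel-history k-NN model.

    The library draws one uniform field and one slot field per frame from a
    generator seeded with ``seed``; the oracle reproduces the identical draw
    order and then applies the per-pixel rule in loops.
    """
    frames = np.asarray(frames)
    n, H, W = frames.shape
    N = params.n_samples
    rng = np.random.default_rng(seed)
    buffers = [[[int(frames[0, i, j])] * N for j in range(W)] for i in range(H)]
    out = np.zeros((n, H, W), dtype=bool)
    for t in range(n):
        u = rng.random((H, W))
        slots = rng.integers(0, N, size=(H, W))
        for i in range(H):
            for j in range(W):
                x = int(frames[t, i, j])
                buf = buffers[i][j]
                close = sum(
                    1 for s in buf if abs(s - x) <= params.distance_threshold
                )
                background = close >= params.k_min
                out[t, i, j] = not background
                if background and u[i, j] < params.p_update:
                    buf[slots[i, j]] = x
    return out


def cnt_scalar(frames, params):
    """Per-pixel counter-based stability model."""
    frames = np.asarray(frames)
    n, H, W = frames.shape
    out = np.zeros((n, H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            v = int(frames[0, i, j])
            c = 0
            for t in range(n):
                x = int(frames[t, i, j])
                if t > 0:
                    if abs(x - v) <= params.pixel_change_threshold:
                        c += 1
                    else:
                        c = 0
                        v = x
                out[t, i, j] = not (c >= params.min_stability)
    return out


# ---------------------------------------------------------------------------
# geometry and morphology oracles
# ---------------------------------------------------------------------------

def brute_open(mask, k):
    """Set-algebra opening: pixels whose k x k neighbourhood fits inside the
    input (outside the frame counts as empty), dilated back by the element."""
    mask = np.asarray(mask) != 0
    H, W = mask.shape
    r = k // 2
    eroded = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            fits = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < H and 0 <= jj < W and mask[ii, jj]):
                        fits = False
                        break
                if not fits:
                    break
            eroded[i, j] = fits
    opened = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            if eroded[i, j]:
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < H and 0 <= jj < W:
                            opened[ii, jj] = True
    return opened


def flood_fill_components(mask, connectivity=8):
    """Connected components by explicit flood fill.

    Returns a list of pixel lists [(y, x), ...], in discovery (row-major
    seed) order.
    """
    mask = np.asarray(mask) != 0
    H, W = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = np.zeros((H, W), dtype=bool)
    components = []
    for i in range(H):
        for j in range(W):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                pix = []
                while stack:
                    y, x = stack.pop()
                    pix.append((y, x))
                    for dy, dx in neigh:
                        yy, xx = y + dy, x + dx
                        if (0 <= yy < H and 0 <= xx < W and mask[yy, xx]
                                and not seen[yy, xx]):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                components.append(pix)
    return components


def brute_hull_vertices(points):
    """Brute-force O(n^3) hull-vertex set via the edge test.

    A directed pair (i, j) is a hull edge iff every other point lies on one
    side of the line through it; hull vertices are the edge endpoints.
    Assumes points in general position (no three collinear), which holds for
    the random float point sets this oracle is used on.
    """
    pts = sorted({tuple(map(float, p)) for p in np.asarray(points)})
    n = len(pts)
    if n <= 2:
        return set(pts)
    P = np.asarray(pts)
    vertices = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cross = ((P[j, 0] - P[i, 0]) * (P[:, 1] - P[i, 1])
                     - (P[j, 1] - P[i, 1]) * (P[:, 0] - P[i, 0]))
            if (cross >= 0).all() or (cross <= 0).all():
                vertices.add(pts[i])
                vertices.add(pts[j])
    return vertices


def disk_pixels(cx, cy, r, width, height):
    """Brute-force disk rasterisation: integer centers inside the circle."""
    out = set()
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2:
                out.add((x, y))
    return out
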