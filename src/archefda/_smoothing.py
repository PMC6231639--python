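"""Local linear kernel smoothers for pooled longitudinal scatters.

One-dimensional smoothing (mean function, diagonal variance) runs on a
binned representation of the pooled scatter: observations are assigned to
the nearest node of the output grid and each occupied bin contributes its
within-bin mean coordinate, mean response and count.  Using the mean
coordinate (rather than the node) as the design point preserves the local
linear property of reproducing constant and linear inputs exactly.

Two-dimensional surface smoothing (raw covariances) uses the exact pooled
scatter when it is small and switches to a nearest-node binned design
above a size threshold; on the tensor-product binned design all kernel
moment sums factorize into per-axis matrix products, which keeps the cost
independent of the number of raw pairs.  Binning to nodes attenuates the
linear-reproduction property by at most half a grid step; the surface
estimates it feeds are smooth on the grid scale.

Bandwidths are chosen by generalized cross-validation (GCV) over a
geometric grid of candidates, with the hat-matrix trace computed exactly
for the weighted local linear fit at the design points.
"""

from __future__ import annotations

import numpy as np

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _gauss(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / _SQRT2PI


def bin_to_grid_1d(x, y, grid):
    """Nearest-node binning of a 1-D scatter.

    Returns (design x: within-bin means, within-bin mean y, counts,
    pooled within-bin sum of squares), restricted to occupied bins.  The
    within-bin dispersion does not depend on the smoothing bandwidth but
    must enter the GCV residual sum of squares: without it the criterion
    would reward interpolating the bin means.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    step = grid[1] - grid[0]
    idx = np.clip(np.round((x - grid[0]) / step).astype(int), 0, len(grid) - 1)
    counts = np.bincount(idx, minlength=len(grid)).astype(float)
    sx = np.bincount(idx, weights=x, minlength=len(grid))
    sy = np.bincount(idx, weights=y, minlength=len(grid))
    sy2 = np.bincount(idx, weights=y * y, minlength=len(grid))
    occ = counts > 0
    ybar = sy[occ] / counts[occ]
    sse = float(np.sum(sy2[occ] - counts[occ] * ybar * ybar))
    return sx[occ] / counts[occ], ybar, counts[occ], sse


def lls_1d(xd, yd, w, xout, h):
    """Weighted local linear smooth of design points (xd, yd, weight w).

    Evaluates at ``xout``; returns (fitted, inv00) where ``inv00`` is the
    (0,0) element of the inverse local normal-equation matrix at each
    output point (used for the GCV hat trace).
    """
    xd = np.asarray(xd, float)
    u = (xd[None, :] - np.asarray(xout, float)[:, None])  # (m, nd)
    k = _gauss(u / h) / h * np.asarray(w, float)[None, :]
    s0 = k.sum(axis=1)
    s1 = (k * u).sum(axis=1)
    s2 = (k * u * u).sum(axis=1)
    t0 = (k * yd).sum(axis=1)
    t1 = (k * u * yd).sum(axis=1)
    den = s0 * s2 - s1 * s1
    tiny = np.finfo(float).tiny
    bad = den <= np.maximum(1e-300, 1e-12 * (s0 * s2 + tiny))
    if np.any(bad):
        raise np.linalg.LinAlgError(
            f"local linear fit singular at {int(bad.sum())} of {len(s0)} points; "
            f"bandwidth h={h:.4g} too small for the design"
        )
    fitted = (s2 * t0 - s1 * t1) / den
    inv00 = s2 / den
    return fitted, inv00


def gcv_select_1d(xd, yd, w, candidates, sse_within=0.0):
    """Pick the GCV-minimizing bandwidth for a 1-D local linear smooth."""
    n_raw = float(np.sum(w))
    best_h, best_score = None, np.inf
    k0 = _gauss(np.array([0.0]))[0]
    for h in candidates:
        try:
            fitted, inv00 = lls_1d(xd, yd, w, xd, h)
        except np.linalg.LinAlgError:
            continue
        trace = (k0 / h) * float(np.sum(np.asarray(w) * inv00))
        if n_raw - trace <= 1.0:
            continue
        rss = float(np.sum(np.asarray(w) * (np.asarray(yd) - fitted) ** 2))
        score = n_raw * (rss + sse_within) / (n_raw - trace) ** 2
        if score < best_score:
            best_h, best_score = h, score
    if best_h is None:
        raise np.linalg.LinAlgError("GCV failed for every candidate bandwidth")
    return best_h


def bandwidth_candidates(design_x, domain, n_candidates=10):
    """Geometric grid of bandwidths from the largest design gap to range/2."""
    xs = np.unique(np.asarray(design_x, float))
    t0, t1 = domain
    rng = t1 - t0
    if xs.size < 2:
        raise ValueError("need at least 2 distinct design points")
    h_min = max(float(np.max(np.diff(xs))), rng / 200.0)
    h_max = rng / 2.0
    if h_min >= h_max:
        h_min = h_max / 4.0
    return np.geomspace(h_min, h_max, n_candidates)


# ---------------------------------------------------------------------------
# 2-D surface smoothing


def bin_to_grid_2d(s, t, y, grid):
    """Nearest-node binning of a 2-D scatter onto the tensor grid.

    Returns (counts, mean response, pooled within-bin sum of squares);
    the matrices are G x G over grid nodes.
    """
    step = grid[1] - grid[0]
    g = len(grid)
    i = np.clip(np.round((np.asarray(s, float) - grid[0]) / step).astype(int), 0, g - 1)
    j = np.clip(np.round((np.asarray(t, float) - grid[0]) / step).astype(int), 0, g - 1)
    flat = i * g + j
    y = np.asarray(y, float)
    counts = np.bincount(flat, minlength=g * g).astype(float).reshape(g, g)
    sums = np.bincount(flat, weights=y, minlength=g * g).reshape(g, g)
    sums2 = np.bincount(flat, weights=y * y, minlength=g * g).reshape(g, g)
    ybar = np.zeros_like(sums)
    occ = counts > 0
    ybar[occ] = sums[occ] / counts[occ]
    sse = float(np.sum(sums2[occ] - counts[occ] * ybar[occ] ** 2))
    return counts, ybar, sse


def _solve_lls_2d(moments, rhs):
    """Batch-solve the 3x3 local normal equations; returns (fit, inv00)."""
    s00, s10, s01, s20, s11, s02 = moments
    t00, t10, t01 = rhs
    shape = s00.shape
    A = np.empty(shape + (3, 3))
    A[..., 0, 0] = s00
    A[..., 0, 1] = A[..., 1, 0] = s10
    A[..., 0, 2] = A[..., 2, 0] = s01
    A[..., 1, 1] = s20
    A[..., 1, 2] = A[..., 2, 1] = s11
    A[..., 2, 2] = s02
    b = np.stack([t00, t10, t01], axis=-1)
    try:
        sol = np.linalg.solve(A, b[..., None])[..., 0]
        inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "local linear surface fit singular; increase the bandwidth"
        ) from e
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError(
            "local linear surface fit produced non-finite values; "
            "increase the bandwidth"
        )
    return sol[..., 0], inv[..., 0, 0]


def lls_2d_binned(counts, ybar, grid, h):
    """Separable binned local linear surface smooth evaluated at grid nodes.

    ``counts``/``ybar`` are G x G matrices from :func:`bin_to_grid_2d`.
    Returns (fitted surface G x G, inv00 G x G).
    """
    grid = np.asarray(grid, float)
    u = grid[None, :] - grid[:, None]  # (out, in) per axis
    k = _gauss(u / h) / h
    a0, a1, a2 = k, k * u, k * u * u
    wy = counts * ybar
    moments = (
        a0 @ counts @ a0.T,
        a1 @ counts @ a0.T,
        a0 @ counts @ a1.T,
        a2 @ counts @ a0.T,
        a1 @ counts @ a1.T,
        a0 @ counts @ a2.T,
    )
    rhs = (a0 @ wy @ a0.T, a1 @ wy @ a0.T, a0 @ wy @ a1.T)
    return _solve_lls_2d(moments, rhs)


def lls_2d_exact(s, t, y, grid, h, chunk=512):
    """Unbinned 2-D local linear smooth of scatter (s, t, y) at grid nodes."""
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    g = len(grid)
    ss, tt = np.meshgrid(grid, grid, indexing="ij")
    out_s, out_t = ss.ravel(), tt.ravel()
    fit = np.empty(g * g)
    inv00 = np.empty(g * g)
    for lo in range(0, g * g, chunk):
        hi = min(lo + chunk, g * g)
        us = s[None, :] - out_s[lo:hi, None]
        ut = t[None, :] - out_t[lo:hi, None]
        k = _gauss(us / h) * _gauss(ut / h) / (h * h)
        moments = (
            k.sum(1),
            (k * us).sum(1),
            (k * ut).sum(1),
            (k * us * us).sum(1),
            (k * us * ut).sum(1),
            (k * ut * ut).sum(1),
        )
        rhs = (k @ y, (k * us) @ y, (k * ut) @ y)
        fit[lo:hi], inv00[lo:hi] = _solve_lls_2d(moments, rhs)
    return fit.reshape(g, g), inv00.reshape(g, g)


def rotated_diagonal(s, t, y, grid, h, chunk=None):
    """Covariance-surface diagonal via a rotated local fit.

    Fits, at each grid point, a polynomial that is linear along the
    diagonal direction u = (s + t)/2 and quadratic orthogonal to it
    (v = t - s), evaluated at v = 0.  The quadratic term absorbs the
    ridge curvature that a plain local linear surface smooth attenuates,
    which matters when the diagonal is subtracted to estimate the
    measurement-error variance.
    """
    u = (np.asarray(s, float) + np.asarray(t, float)) / 2.0
    v = np.asarray(t, float) - np.asarray(s, float)
    y = np.asarray(y, float)
    grid = np.asarray(grid, float)
    out = np.empty(grid.size)
    if chunk is None:  # cap the (grid chunk) x (pairs) work array at ~2e7
        chunk = max(1, int(2e7) // max(1, u.size))
    for lo in range(0, grid.size, chunk):
        hi = min(lo + chunk, grid.size)
        du = u[None, :] - grid[lo:hi, None]
        k = _gauss(du / h) * _gauss(v[None, :] / h) / (h * h)
        v2 = v[None, :] ** 2
        s00 = k.sum(1)
        s10 = (k * du).sum(1)
        s20 = (k * du * du).sum(1)
        s01 = (k * v2).sum(1)
        s11 = (k * du * v2).sum(1)
        s02 = (k * v2 * v2).sum(1)
        A = np.empty((hi - lo, 3, 3))
        A[:, 0, 0] = s00
        A[:, 0, 1] = A[:, 1, 0] = s10
        A[:, 0, 2] = A[:, 2, 0] = s01
        A[:, 1, 1] = s20
        A[:, 1, 2] = A[:, 2, 1] = s11
        A[:, 2, 2] = s02
        b = np.stack([k @ y, (k * du) @ y, (k * v2) @ y], axis=-1)
        try:
            sol = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "rotated diagonal fit singular; increase the bandwidth"
            ) from e
        out[lo:hi] = sol[:, 0]
    if not np.all(np.isfinite(out)):
        raise np.linalg.LinAlgError("rotated diagonal fit produced non-finite values")
    return out


def gcv_select_2d_binned(counts, ybar, grid, candidates, sse_within=0.0):
    """GCV bandwidth choice for the binned surface smoother."""
    n_raw = float(counts.sum())
    k0sq = _gauss(np.array([0.0]))[0] ** 2
    best_h, best_score = None, np.inf
    occ = counts > 0
    for h in candidates:
        try:
            fitted, inv00 = lls_2d_binned(counts, ybar, grid, h)
        except np.linalg.LinAlgError:
            continue
        trace = (k0sq / h / h) * float(np.sum(counts[occ] * inv00[occ]))
        if n_raw - trace <= 1.0:
            continue
        rss = float(np.sum(counts[occ] * (ybar[occ] - fitted[occ]) ** 2))
        score = n_raw * (rss + sse_within) / (n_raw - trace) ** 2
        if score < best_score:
            best_h, best_score = h, score
    if best_h is None:
        raise np.linalg.LinAlgError("GCV failed for every candidate surface bandwidth")
    return best_h
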