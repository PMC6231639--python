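"""Highest-density-region outlier detection and archetype clusters.

Subjects whose 2-D score vectors fall outside the (1 - alpha) highest
density region of a product-Gaussian kernel density estimate are flagged
as outlying, then partitioned into four quadrant-style archetype
clusters by comparing their scale-standardized coordinates: the cluster
captures whether the dominant deviation is along the first or the second
joint component and its sign.  In the growth application the four
clusters read as "Generally Large" (S1), "Catch-up" (S2), "Stunting"
(S3) and "Faltering" (S4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_ARCHETYPE_NAMES = {
    "S1": "Generally Large",
    "S2": "Catch-up",
    "S3": "Stunting",
    "S4": "Faltering",
    "normal": "normal",
}


@dataclass
class HdrModel:
    """Kernel HDR fit on a 2-D score cloud."""

    alpha: float
    bandwidths: np.ndarray       # per-coordinate h_k
    density_at_points: np.ndarray
    f_alpha: float               # density threshold
    outlier_flags: np.ndarray    # True outside the HDR

    def __post_init__(self):
        n = len(self.density_at_points)
        if np.any(self.density_at_points < 0) or self.f_alpha <= 0:
            raise ValueError("densities and threshold must be positive")
        frac = self.outlier_flags.mean()
        if frac > self.alpha + 2.0 / np.sqrt(n):
            raise ValueError(
                f"outlier fraction {frac:.3f} exceeds alpha plus empirical slack"
            )


@dataclass
class ArchetypeAssignment:
    """Per-subject archetype labels over {normal, S1..S4}."""

    labels: np.ndarray           # array of label strings
    scale: tuple                 # (scale_1, scale_2) used for the comparison
    archetype_names: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPE_NAMES))

    def members(self, label) -> np.ndarray:
        return np.where(self.labels == label)[0]

    def sizes(self) -> dict:
        return {lab: int(np.sum(self.labels == lab))
                for lab in ("normal", "S1", "S2", "S3", "S4")}


def normal_reference_bandwidths(points: np.ndarray) -> np.ndarray:
    """Per-coordinate normal-reference rule h_k = 1.06 sd_k n^(-1/5)."""
    pts = np.asarray(points, float)
    n = pts.shape[0]
    sd = pts.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate coordinate with zero variance")
    return 1.06 * sd * n ** (-0.2)


def kde_density(points: np.ndarray, bandwidths=None) -> tuple:
    """Product-Gaussian KDE evaluated at the sample points (leave-self-in).

    Returns (densities, bandwidths used).
    """
    pts = np.asarray(points, float)
    n, k = pts.shape
    if n < 1:
        raise ValueError("empty point set")
    if bandwidths is None:
        if n < 10:
            raise ValueError("need >= 10 points for data-driven bandwidths")
        bandwidths = normal_reference_bandwidths(pts)
    h = np.asarray(bandwidths, float)
    if np.any(h <= 0):
        raise ValueError("bandwidths must be positive")
    dens = np.empty(n)
    norm = 1.0 / (n * np.prod(h) * (2.0 * np.pi) ** (k / 2.0))
    chunk = max(1, int(2e7) // n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        u = (pts[lo:hi, None, :] - pts[None, :, :]) / h
        dens[lo:hi] = np.exp(-0.5 * np.sum(u * u, axis=2)).sum(axis=1) * norm
    return dens, h


def hdr_threshold(densities: np.ndarray, alpha: float) -> float:
    """Plug-in HDR density threshold: empirical alpha-quantile of densities."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.quantile(np.asarray(densities, float), alpha, method="lower"))


def fit_hdr(points: np.ndarray, alpha: float = 0.05, bandwidths=None) -> HdrModel:
    """Fit the kernel HDR at level 1 - alpha; flag points strictly below it."""
    dens, h = kde_density(points, bandwidths)
    f_alpha = hdr_threshold(dens, alpha)
    return HdrModel(
        alpha=alpha,
        bandwidths=h,
        density_at_points=dens,
        f_alpha=f_alpha,
        outlier_flags=dens < f_alpha,
    )


def _quadrant_labels(coords: np.ndarray, scale, outliers: np.ndarray) -> np.ndarray:
    """Assign S1..S4 by dominant scale-standardized coordinate and its sign.

    Ties in scaled magnitude break toward the first-coordinate clusters;
    a zero on the deciding coordinate defers to the sign of the other.
    """
    s1, s2 = scale
    if s1 <= 0 or s2 <= 0:
        raise ValueError("scales must be positive")
    z1, z2 = coords[:, 0], coords[:, 1]
    a1 = np.abs(z1) / np.sqrt(s1)
    a2 = np.abs(z2) / np.sqrt(s2)
    labels = np.full(coords.shape[0], "normal", dtype=object)
    first = a1 >= a2   # ties toward the Z1-dominant clusters
    pos1 = np.where(z1 != 0, z1 > 0, z2 > 0)
    pos2 = np.where(z2 != 0, z2 > 0, z1 > 0)
    labels[outliers & first & pos1] = "S1"
    labels[outliers & first & ~pos1] = "S3"
    labels[outliers & ~first & pos2] = "S2"
    labels[outliers & ~first & ~pos2] = "S4"
    return labels.astype(str)


def assign_joint_clusters(Z: np.ndarray, rho, hdr: HdrModel,
                          archetype_names=None) -> ArchetypeAssignment:
    """Archetype clusters of joint scores Z outside the fitted HDR.

    ``rho`` are the eigenvalues of the first two joint components; the
    comparison |Z1|/sqrt(rho1) vs |Z2|/sqrt(rho2) decides which
    component dominates.
    """
    labels = _quadrant_labels(np.asarray(Z, float), rho, hdr.outlier_flags)
    names = dict(DEFAULT_ARCHETYPE_NAMES)
    if archetype_names:
        names.update(archetype_names)
    return ArchetypeAssignment(labels=labels, scale=tuple(rho), archetype_names=names)


def assign_marginal_clusters(scores: np.ndarray, lambdas, alpha: float = 0.05,
                             bandwidths=None, archetype_names=None):
    """Per-trait archetype clusters from a trait's own first two FPC scores.

    Fits the HDR on the (xi1, xi2) cloud and applies the same quadrant
    rule with (lambda1, lambda2) as scales.  Returns
    (ArchetypeAssignment, HdrModel).
    """
    pts = np.asarray(scores, float)[:, :2]
    hdr = fit_hdr(pts, alpha=alpha, bandwidths=bandwidths)
    labels = _quadrant_labels(pts, lambdas, hdr.outlier_flags)
    names = dict(DEFAULT_ARCHETYPE_NAMES)
    if archetype_names:
        names.update(archetype_names)
    return (
        ArchetypeAssignment(labels=labels, scale=tuple(lambdas), archetype_names=names),
        hdr,
    )
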