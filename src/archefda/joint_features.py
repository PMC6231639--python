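"""Joint feature extraction across multiple longitudinal traits.

Marginal FPC scores are standardized by the square root of their
eigenvalues, stacked across traits, and reduced by conventional PCA on
the sample covariance of the stacked vector.  The first two joint
scores (Z1, Z2) summarize the shared modes of variation across traits
and are the coordinates in which archetype clusters are defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .sparse_fpca import FpcaModel, ScoreMatrix


@dataclass
class JointPcaModel:
    """PCA of stacked standardized FPC scores.

    ``loadings`` has one orthonormal eigenvector per column; ``Z`` holds
    the first two joint scores per subject (full scores available via
    :meth:`transform`).
    """

    loadings: np.ndarray       # (p, p), columns are eigenvectors
    eigenvalues: np.ndarray    # rho, descending, >= 0
    Z: np.ndarray              # (n, 2) first two joint scores
    partial_fve: np.ndarray
    cumulative_fve: np.ndarray
    feature_names: list
    center: np.ndarray         # sample mean of stacked standardized scores

    def __post_init__(self):
        p = self.loadings.shape[0]
        if not np.allclose(self.loadings.T @ self.loadings, np.eye(p), atol=1e-8):
            raise ValueError("loadings not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10) or np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative and non-increasing")

    def transform(self, standardized: np.ndarray) -> np.ndarray:
        """All p joint scores for rows of stacked standardized scores."""
        return (np.asarray(standardized, float) - self.center) @ self.loadings

    def to_json(self, path) -> None:
        doc = {
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "partial_fve": self.partial_fve.tolist(),
            "cumulative_fve": self.cumulative_fve.tolist(),
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def standardize_scores(scores: ScoreMatrix, eigenvalues) -> np.ndarray:
    """Scale each score column by 1/sqrt(lambda_k)."""
    lam = np.asarray(eigenvalues, float)
    xs = scores.scores
    if lam.size < xs.shape[1]:
        raise ValueError("fewer eigenvalues than score columns")
    lam = lam[: xs.shape[1]]
    if np.any(lam <= 0):
        raise ValueError("retained components must have positive eigenvalues")
    return xs / np.sqrt(lam)


def joint_pca(blocks, feature_names=None) -> JointPcaModel:
    """PCA of horizontally stacked standardized score blocks.

    ``blocks`` is a sequence of (n, K_j) arrays sharing the subject
    roster.  The decomposition is of the sample covariance (the blocks
    are already variance-standardized marginally per component); the
    sign of each eigenvector is fixed so its largest-magnitude loading
    is positive.
    """
    mats = [np.asarray(b, float) for b in blocks]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("blocks must share the subject roster")
    zeta = np.hstack(mats)
    p = zeta.shape[1]
    if p < 2:
        raise ValueError("need at least 2 stacked features")
    if p > n:
        raise ValueError(f"rank-deficient input: p={p} features but only n={n} subjects")
    if feature_names is None:
        feature_names = []
        for j, m in enumerate(mats):
            feature_names += [f"trait{j + 1}-FPC{k + 1}" for k in range(m.shape[1])]
    center = zeta.mean(axis=0)
    cov = np.cov(zeta, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    for k in range(p):
        jmax = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[jmax, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = (zeta - center) @ vecs
    total = vals.sum()
    return JointPcaModel(
        loadings=vecs,
        eigenvalues=vals,
        Z=scores[:, :2],
        partial_fve=vals / total,
        cumulative_fve=np.cumsum(vals) / total,
        feature_names=list(feature_names),
        center=center,
    )


def cross_covariance_check(models, standardized_blocks, trait_pair=(0, 1)):
    """Diagnostic: two reconstructions of one cross-trait covariance surface.

    (a) eigen-expansion with the empirical correlation of standardized
    scores; (b) empirical covariance of truncated trajectory
    reconstructions on the grid.  Both estimate the same population
    surface; returns the max absolute discrepancy.
    """
    j, m = trait_pair
    mj: FpcaModel = models[j]
    mm: FpcaModel = models[m]
    zj = np.asarray(standardized_blocks[j], float)
    zm = np.asarray(standardized_blocks[m], float)
    kj, km = zj.shape[1], zm.shape[1]
    lam_j, lam_m = mj.eigenvalues[:kj], mm.eigenvalues[:km]
    phi_j, phi_m = mj.eigenfunctions[:, :kj], mm.eigenfunctions[:, :km]

    n = zj.shape[0]
    zjc = zj - zj.mean(axis=0)
    zmc = zm - zm.mean(axis=0)
    czeta = zjc.T @ zmc / (n - 1)  # (kj, km) cross-covariance of zeta
    surf_a = phi_j @ (np.sqrt(np.outer(lam_j, lam_m)) * czeta) @ phi_m.T

    recon_j = zjc * np.sqrt(lam_j) @ phi_j.T  # (n, G) centered reconstructions
    recon_m = zmc * np.sqrt(lam_m) @ phi_m.T
    surf_b = recon_j.T @ recon_m / (n - 1)
    return float(np.max(np.abs(surf_a - surf_b)))
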