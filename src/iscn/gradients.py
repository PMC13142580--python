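"""Diffusion-map embedding of sparsified networks and Procrustes alignment.

Macroscale gradients are eigenvectors of the diffusion operator built from
a row-profile affinity of the sparsified covariance (or similarity) matrix.
The anisotropy parameter alpha = 0.5 approximates the Laplace-Beltrami
operator, separating manifold geometry from sampling density. Individual
gradient sets are aligned to the control-group template by orthogonal
Procrustes rotation so loadings are comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import connected_components

from .covnet import RegionMatrix


@dataclass
class GradientSet:
    """Component loadings (regions x k) with eigenvalues and metadata."""

    loadings: np.ndarray
    eigenvalues: np.ndarray
    alpha: float = 0.5
    aligned: bool = False

    @property
    def variance_explained(self) -> np.ndarray:
        lam = self.eigenvalues
        return lam / lam.sum()


def affinity(sparse: RegionMatrix, kernel: str = "normalized_angle") -> RegionMatrix:
    """Similarity between sparsified row profiles.

    Cosine similarity rho of each pair of rows, negatives clamped to 0,
    then (for the default normalized-angle kernel) a_ij = 1 - arccos(rho)/pi.
    Identical rows give 1, orthogonal rows 0.5 (normalized angle) or 0
    (cosine kernel).
    """
    X = sparse.values
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0).tolist()
        raise ValueError(f"zero row(s) in sparsified matrix: regions {bad}")
    rho = (X @ X.T) / np.outer(norms, norms)
    rho = np.clip((rho + rho.T) / 2, 0.0, 1.0)  # clamp negatives, symmetry guard
    if kernel == "normalized_angle":
        a = 1.0 - np.arccos(rho) / np.pi
    elif kernel == "cosine":
        a = rho
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    np.fill_diagonal(a, 1.0)
    return RegionMatrix(values=a, kind="affinity")


def diffusion_embedding(
    aff: RegionMatrix, alpha: float = 0.5, n_components: int = 10
) -> GradientSet:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    Anisotropic normalization W = D^-alpha A D^-alpha, Markov operator
    P = D_W^-1 W, eigendecomposition via the conjugate symmetric operator.
    The trivial constant eigenvector (eigenvalue 1) is dropped; component
    i is eigenvector_i scaled by lambda_i / (1 - lambda_i) (diffusion
    time 0). Eigenvalues are returned in descending order.
    """
    A = np.asarray(aff.values, dtype=float)
    if A.min() < 0:
        raise ValueError("affinity must be non-negative")
    n_comp_graph, labels = connected_components(A > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp_graph} components of sizes {sizes.tolist()}"
        )
    d = A.sum(axis=1)
    W = A / np.outer(d**alpha, d**alpha)
    dW = W.sum(axis=1)
    # Symmetric conjugate S = D^-1/2 W D^-1/2 shares eigenvalues with P.
    S = W / np.outer(np.sqrt(dW), np.sqrt(dW))
    S = (S + S.T) / 2
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(dW)[:, None]  # right eigenvectors of P
    lam = evals[1 : n_components + 1]
    vecs = psi[:, 1 : n_components + 1]
    # Unit-norm eigenvectors, then diffusion-time-0 scaling.
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    scale = lam / (1.0 - lam)
    loadings = vecs * scale
    return GradientSet(loadings=loadings, eigenvalues=lam, alpha=alpha)


def procrustes_align(
    individual: GradientSet, template: GradientSet, k: int = 2
) -> GradientSet:
    """Orthogonal Procrustes rotation of the first k components onto a template.

    Columns are centered; the rotation (no scaling) minimizes the
    Frobenius distance to the template's first k columns. Per-column norms
    of the centered loadings are preserved.
    """
    if k > individual.loadings.shape[1] or k > template.loadings.shape[1]:
        raise ValueError(
            f"k={k} exceeds available components "
            f"({individual.loadings.shape[1]}, {template.loadings.shape[1]})"
        )
    X = individual.loadings[:, :k]
    T = template.loadings[:, :k]
    Xc = X - X.mean(axis=0)
    Tc = T - T.mean(axis=0)
    U, _, Vt = np.linalg.svd(Xc.T @ Tc)
    R = U @ Vt
    rotated = Xc @ R
    return replace(individual, loadings=rotated, eigenvalues=individual.eigenvalues[:k], aligned=True)


def fix_template_signs(template: GradientSet) -> GradientSet:
    """Fix each column's sign so its maximum-|loading| region is positive."""
    L = template.loadings.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return replace(template, loadings=L)


def variance_explained(gs: GradientSet, top: int = 2) -> np.ndarray:
    """lambda_i / sum(lambda) over retained non-trivial components."""
    return gs.variance_explained[:top]
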