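"""Group covariance matrices, individual difference networks, sparsification.

The group-level structural covariance network is the inter-subject Pearson
correlation of residualized regional thickness. Individual networks are
built from each subject's regional z-deviations relative to the control
reference: edge similarity s_ij = exp(-|z_i - z_j|), so regions deviating
coherently are strongly connected. Sparsification retains the top
(1 - sparsity) fraction of each row's off-diagonal entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import N_REGIONS, thickness_columns

THK = thickness_columns()


@dataclass
class RegionMatrix:
    """A 68x68 region-by-region matrix with provenance.

    kind is one of {"group_covariance", "individual_similarity",
    "sparsified", "affinity"}. For sparsified matrices, `mask` holds the
    directed per-row retention mask and `union_mask` its symmetric union
    (edge kept if retained in either row), used for graph topology.
    """

    values: np.ndarray
    kind: str
    sparsity: float | None = None
    mask: np.ndarray | None = None
    union_mask: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RegionMatrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ControlReference:
    """Per-region control mean and SD (n-1 denominator)."""

    mean: np.ndarray
    sd: np.ndarray

    def zscore(self, thickness: np.ndarray) -> np.ndarray:
        return (np.asarray(thickness, dtype=float) - self.mean) / self.sd


def group_covariance(residualized: pd.DataFrame, group: int | None = None) -> RegionMatrix:
    """Inter-subject Pearson correlation of the 68 region columns.

    Parameters
    ----------
    group : 0, 1 or None
        Restrict to controls (0), cases (1), or use all rows (None).
    """
    df = residualized if group is None else residualized[residualized["dx"] == group]
    if len(df) < 3:
        raise ValueError("need at least 3 subjects for a covariance matrix")
    X = df[THK].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [THK[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return RegionMatrix(values=R, kind="group_covariance")


def control_reference(residualized_controls: pd.DataFrame) -> ControlReference:
    """Per-region mean and sample SD over controls."""
    df = residualized_controls
    if "dx" in df.columns:
        df = df[df["dx"] == 0]
    if len(df) < 2:
        raise ValueError("need at least 2 controls")
    X = df[THK].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [THK[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero control SD in region(s): {bad}")
    return ControlReference(mean=X.mean(axis=0), sd=sd)


def individual_network(
    thickness: np.ndarray,
    ref: ControlReference,
    transform: str = "exp",
) -> RegionMatrix:
    """Subject-level difference network from regional z-deviations.

    z_i = (t_i - mean_i)/sd_i against the control reference; edge
    s_ij = exp(-|z_i - z_j|) (default) or 1/(1 + |z_i - z_j|)
    (``transform="inverse"``). Symmetric, diagonal masked to 0.
    """
    t = np.asarray(thickness, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite thickness values")
    z = ref.zscore(t)
    dz = np.abs(z[:, None] - z[None, :])
    if transform == "exp":
        s = np.exp(-dz)
    elif transform == "inverse":
        s = 1.0 / (1.0 + dz)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(s, 0.0)
    return RegionMatrix(values=s, kind="individual_similarity")


def sparsify(matrix: RegionMatrix, sparsity: float) -> RegionMatrix:
    """Row-wise thresholding: keep the top (1-sparsity) off-diagonal entries.

    Per row, the k = ceil((1 - sparsity) * (n-1)) largest off-diagonal
    entries (signed value; ties broken by lower region index) are
    retained, the rest zeroed. The symmetric union mask (kept in either
    row) is attached for graph use; the raw row-sparse values feed the
    gradient affinity.

    Re-applying at the same sparsity is a no-op whenever the retained
    entries are positive (always the case for similarity matrices and for
    covariance at the analysis sparsity levels, where negatives do not
    survive thresholding).
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    A = matrix.values.copy()
    n = A.shape[0]
    k = int(np.ceil((1.0 - sparsity) * (n - 1)))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        row = A[i].copy()
        row[i] = -np.inf
        # stable sort on (-value, index): ties go to the lower region index
        order = np.lexsort((np.arange(n), -row))
        mask[i, order[:k]] = True
    values = np.where(mask, A, 0.0)
    return RegionMatrix(
        values=values,
        kind="sparsified",
        sparsity=sparsity,
        mask=mask,
        union_mask=mask | mask.T,
    )


def binary_adjacency(sparse: RegionMatrix) -> np.ndarray:
    """0/1 symmetric adjacency from the union mask of a sparsified matrix."""
    if sparse.union_mask is None:
        raise ValueError("matrix has no union mask; sparsify it first")
    adj = sparse.union_mask.astype(int)
    np.fill_diagonal(adj, 0)
    return adj


def matrix_to_frame(m: RegionMatrix, names=None) -> pd.DataFrame:
    names = list(names) if names is not None else [f"r{i}" for i in range(m.n)]
    return pd.DataFrame(m.values, index=names, columns=names)
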