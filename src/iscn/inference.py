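"""Mass-univariate case-control models, FDR, and spin-permutation nulls.

Per region, OLS models of the form ``feature ~ age + sex + DX`` (plus
optional ICV, diagnosis interactions, or illness duration) yield the
t statistic of the term of interest; the covariate-adjusted Cohen's d is
d = t (n1 + n2) / (sqrt(n1 n2) sqrt(df)). Regions are corrected by
Benjamini-Hochberg FDR within each metric. Spatial correspondence of
two cortical maps is tested against a spatial-autocorrelation-preserving
null built from random mirrored rotations of the parcel centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionAtlas

FORMULAS = ("base", "icv", "age_x_dx", "sex_x_dx", "duration")


@dataclass
class ModelResult:
    """Per-region statistics for the term of interest of one model."""

    formula: str
    term: str
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    cohens_d: np.ndarray
    p_fdr: np.ndarray
    n_cases: int
    n_controls: int
    df: int

    def to_frame(self, names=None) -> pd.DataFrame:
        idx = list(names) if names is not None else range(len(self.t))
        return pd.DataFrame(
            {"beta": self.beta, "t": self.t, "p": self.p,
             "d": self.cohens_d, "p_fdr": self.p_fdr},
            index=idx,
        )


def _design(cohort: pd.DataFrame, formula: str) -> tuple[np.ndarray, int, np.ndarray]:
    """Build the design matrix; returns (X, column index of the term, row mask)."""
    age = cohort["age"].to_numpy(dtype=float)
    sex = (cohort["sex"].to_numpy() == "M").astype(float)
    dx = cohort["dx"].to_numpy(dtype=float)
    n = len(cohort)
    mask = np.ones(n, dtype=bool)
    if formula == "base":
        X = np.column_stack([np.ones(n), age, sex, dx])
        term = 3
    elif formula == "icv":
        X = np.column_stack([np.ones(n), age, sex, cohort["icv"].to_numpy(dtype=float), dx])
        term = 4
    elif formula == "age_x_dx":
        Xc = np.column_stack([np.ones(n), age, sex, dx, (age - age.mean()) * dx])
        X, term = Xc, 4
    elif formula == "sex_x_dx":
        X = np.column_stack([np.ones(n), age, sex, dx, sex * dx])
        term = 4
    elif formula == "duration":
        mask = cohort["dx"].to_numpy() == 1
        dur = cohort["duration"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), age, sex, dur])[mask]
        term = 3
    else:
        raise ValueError(f"unknown formula {formula!r}; one of {FORMULAS}")
    return X, term, mask


def fit_region_models(
    features: np.ndarray, cohort: pd.DataFrame, formula: str = "base"
) -> ModelResult:
    """Vectorized per-region OLS; t, p, adjusted d and BH-FDR for one term.

    `features` is subjects x regions for a single metric (G1, G2, SPL or
    CC); each metric forms its own FDR family.
    """
    X, term, mask = _design(cohort, formula)
    Y = np.asarray(features, dtype=float)[mask]
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"rank-deficient design for formula {formula!r}: rank {rank} < {p} columns"
        )
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(XtX_inv[term, term] * sigma2)
    t = B[term] / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    dxv = cohort.loc[mask, "dx"].to_numpy() if formula != "duration" else None
    if dxv is not None:
        n1 = int((dxv == 1).sum())
        n2 = int((dxv == 0).sum())
    else:
        n1, n2 = int(mask.sum()), 0
    if n2 > 0:
        d = t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df))
    else:  # duration model: d on the n-based convention
        d = 2 * t / np.sqrt(df)
    return ModelResult(
        formula=formula,
        term={"base": "dx", "icv": "dx", "age_x_dx": "age:dx",
              "sex_x_dx": "sex:dx", "duration": "duration"}[formula],
        beta=B[term],
        t=t,
        p=pvals,
        cohens_d=d,
        p_fdr=fdr_bh(pvals),
        n_cases=n1,
        n_controls=n2,
        df=df,
    )


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    raw = m * p[order] / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class SpinTestResult:
    observed_r: float
    null_r: np.ndarray
    p_spin: float
    method: str


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation (QR of a Gaussian matrix, det +1)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def spin_permute(
    values: np.ndarray, atlas: RegionAtlas, rotation: np.ndarray
) -> np.ndarray:
    """Reassign parcel values after rotating centroids (mirrored across x=0).

    The rotation is applied to left-hemisphere centroids; its mirror
    conjugate M R M (M = diag(-1,1,1)) to the right, preserving the
    hemispheric symmetry of the map. Each parcel takes the value of the
    nearest rotated centroid within its own hemisphere.
    """
    M = np.diag([-1.0, 1.0, 1.0])
    out = np.empty_like(values, dtype=float)
    for hemi, R in (("L", rotation), ("R", M @ rotation @ M)):
        idx = np.flatnonzero(atlas.hemisphere_mask(hemi))
        pts = atlas.centroids[idx]
        rotated = pts @ R.T
        # parcel at original position takes value of nearest rotated source
        d2 = ((pts[:, None, :] - rotated[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        out[idx] = values[idx][nearest]
    return out


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    atlas: RegionAtlas,
    n_rot: int = 1000,
    method: str = "pearson",
    seed: int = 0,
    two_sided: bool = True,
) -> SpinTestResult:
    """Spatial-null correlation test via mirrored random parcel rotations.

    p_spin = (1 + #{|null| >= |observed|}) / (n_rot + 1) (two-sided
    default; one-sided compares signed null >= observed).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != len(atlas.names):
        raise ValueError("maps must both match the atlas length")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    observed = float(corr(a, b)[0])
    rng = np.random.default_rng(seed)
    null = np.empty(n_rot)
    for i in range(n_rot):
        rotated = spin_permute(a, atlas, _random_rotation(rng))
        null[i] = corr(rotated, b)[0]
    if two_sided:
        exceed = np.sum(np.abs(null) >= abs(observed))
    else:
        exceed = np.sum(null >= observed)
    p = (1.0 + exceed) / (n_rot + 1.0)
    return SpinTestResult(observed_r=observed, null_r=null, p_spin=float(p), method=method)


def spatial_correlation_report(
    d_map: np.ndarray,
    templates: dict,
    atlas: RegionAtlas,
    n_rot: int = 1000,
    method: str = "pearson",
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation + spin p of a Cohen's d map against template maps."""
    rows = {}
    for name, tmpl in templates.items():
        res = spin_test(d_map, np.asarray(tmpl, dtype=float), atlas,
                        n_rot=n_rot, method=method, seed=seed)
        rows[name] = {"r": res.observed_r, "p_spin": res.p_spin}
    return pd.DataFrame(rows).T
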