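"""Brain-symptom partial least squares correlation with bootstrap stability.

PLS correlation decomposes the brain x symptom cross-correlation matrix by
SVD: paired saliences (singular vectors) describe a latent dimension
linking regional network features to symptom factors, and sigma_l^2 /
sum(sigma^2) is the covariance explained by latent variable l. Loading
stability is assessed by subject bootstrap (percentile CIs after sign
alignment); latent-variable significance by row permutation of Y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DEFAULT_FACTOR_MAP, PANSS_ITEMS

log = logging.getLogger(__name__)

FACTOR_NAMES = tuple(DEFAULT_FACTOR_MAP)


def factor_scores(
    items: pd.DataFrame, mapping: dict | None = None
) -> pd.DataFrame:
    """Five-factor PANSS scores as sums of their assigned items.

    `items` must contain `panss_<item>` columns; rows with any missing
    mapped item propagate NaN. The mapping is config-driven; the default
    assigns 28 of the 30 items (positive 6, negative 8, disorganization 6,
    depression/anxiety 3, hostility 5).
    """
    mapping = mapping or DEFAULT_FACTOR_MAP
    out = {}
    for factor, its in mapping.items():
        cols = []
        for it in its:
            col = f"panss_{it}"
            if col not in items.columns:
                raise KeyError(f"factor {factor!r} needs missing item column {col}")
            cols.append(col)
        out[factor] = items[cols].sum(axis=1, skipna=False)
    return pd.DataFrame(out, index=items.index)


@dataclass
class PLSResult:
    singular_values: np.ndarray
    brain_saliences: np.ndarray  # regions x L
    symptom_saliences: np.ndarray  # factors x L
    covariance_explained: np.ndarray
    brain_ci: np.ndarray | None = None  # (regions, L, 2)
    symptom_ci: np.ndarray | None = None  # (factors, L, 2)
    lv_p_perm: np.ndarray | None = None
    n_boot: int = 0
    ci_level: float = 0.90

    def significant_brain(self, lv: int = 0) -> np.ndarray:
        """Regions whose CI for latent variable `lv` excludes zero."""
        if self.brain_ci is None:
            raise ValueError("no bootstrap CIs available")
        lo, hi = self.brain_ci[:, lv, 0], self.brain_ci[:, lv, 1]
        return (lo > 0) | (hi < 0)


def _zscore_cols(M: np.ndarray, name: str) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant column(s) in {name}: {bad}")
    return (M - M.mean(axis=0)) / sd


def pls_correlation(X: np.ndarray, Y: np.ndarray) -> PLSResult:
    """SVD of the cross-correlation matrix X'Y/(n-1) (columns z-scored)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects for PLS")
    Xz = _zscore_cols(X, "X")
    Yz = _zscore_cols(Y, "Y")
    R = Xz.T @ Yz / (X.shape[0] - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return PLSResult(
        singular_values=s,
        brain_saliences=U,
        symptom_saliences=Vt.T,
        covariance_explained=s**2 / np.sum(s**2),
    )


def bootstrap_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 5000,
    ci: float = 0.90,
    seed: int = 0,
    n_perm: int = 1000,
) -> PLSResult:
    """PLS with bootstrap loading CIs and permutation latent-variable p.

    Bootstrap: subjects resampled with replacement; each replicate's
    saliences are sign-aligned to the point estimate (dot-product sign per
    latent variable); CIs are percentile intervals at level `ci`.
    Permutation: Y rows permuted `n_perm` times; lv_p_l = (1 + #{sigma*_l
    >= sigma_l}) / (n_perm + 1).
    """
    if n_boot < 100:
        log.warning("bootstrap_pls: n_boot=%d is very small; CIs will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    point = pls_correlation(X, Y)
    n = X.shape[0]
    L = len(point.singular_values)
    bu = np.empty((n_boot, X.shape[1], L))
    bv = np.empty((n_boot, Y.shape[1], L))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            rep = pls_correlation(X[idx], Y[idx])
        except ValueError:  # constant column in a resample: redraw
            idx = rng.integers(0, n, size=n)
            rep = pls_correlation(X[idx], Y[idx])
        sign = np.sign(np.sum(rep.brain_saliences * point.brain_saliences, axis=0))
        sign[sign == 0] = 1.0
        bu[b] = rep.brain_saliences * sign
        bv[b] = rep.symptom_saliences * sign
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    brain_ci = np.stack(
        [np.percentile(bu, lo, axis=0), np.percentile(bu, hi, axis=0)], axis=-1
    )
    symptom_ci = np.stack(
        [np.percentile(bv, lo, axis=0), np.percentile(bv, hi, axis=0)], axis=-1
    )

    perm_s = np.empty((n_perm, L))
    for i in range(n_perm):
        perm_s[i] = pls_correlation(X, Y[rng.permutation(n)]).singular_values
    lv_p = (1.0 + np.sum(perm_s >= point.singular_values, axis=0)) / (n_perm + 1.0)

    point.brain_ci = brain_ci
    point.symptom_ci = symptom_ci
    point.lv_p_perm = lv_p
    point.n_boot = n_boot
    point.ci_level = ci
    return point


def panss_item_matrix(cohort: pd.DataFrame, mapping: dict | None = None) -> pd.DataFrame:
    """The 28 mapped PANSS item columns (item-level PLS variant)."""
    mapping = mapping or DEFAULT_FACTOR_MAP
    mapped = [it for its in mapping.values() for it in its]
    cols = [f"panss_{it}" for it in PANSS_ITEMS if it in mapped]
    return cohort[cols]
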