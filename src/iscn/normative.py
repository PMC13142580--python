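"""GAM normative models of cortical thickness and deviation profiling.

A penalized-spline GAM (smooth age term, sex factor, linear ICV) is fitted
in controls for mean cortical thickness and each region. An individual's
deviation score is

    z = (observed - predicted) * 4 / (upper - lower 95% PI)

where the interval is the 95% *prediction* interval for a new observation
(mean CI plus residual variance). Under Gaussian residuals the width is
about 2 * 1.96 * sigma, so control z-scores have SD close to
4 / (2 * 1.96) = 1.02. Heterogeneity is the fraction of a group with
|z| > 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines

from .atlas import dk_atlas_fixture, thickness_columns
from .inference import fdr_bh, spatial_correlation_report

log = logging.getLogger(__name__)

THK = thickness_columns()
MEAN_COL = "mean_thickness"

DURATION_BINS = ((0, 1), (1, 5), (5, 10), (10, 20), (20, 55))
AGE_BINS = ((15, 25), (25, 35), (35, 45), (45, 55), (55, 65))


@dataclass
class _TargetFit:
    params: np.ndarray
    cov_params: np.ndarray  # covariance of the fitted mean's coefficients
    sigma2: float
    edf: float


@dataclass
class NormativeModel:
    """Fitted normative GAM for mean thickness and (optionally) each region."""

    smoother: BSplines
    alpha: float  # spline penalty weight (shared across targets)
    fits: dict  # target name -> _TargetFit
    age_ref: tuple
    icv_center: float

    @property
    def targets(self) -> list:
        return list(self.fits)


def _linear_design(cohort: pd.DataFrame, icv_center: float) -> np.ndarray:
    sex = (cohort["sex"].to_numpy() == "M").astype(float)
    icv = cohort["icv"].to_numpy(dtype=float) - icv_center
    return np.column_stack([np.ones(len(cohort)), sex, icv])


def _with_mean_column(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out[MEAN_COL] = out[THK].to_numpy(dtype=float).mean(axis=1)
    return out


def _penalized_fit(D: np.ndarray, P: np.ndarray, y: np.ndarray) -> _TargetFit:
    """Penalized least squares with sandwich covariance of the mean."""
    n = len(y)
    A = D.T @ D + P
    A_inv = np.linalg.inv(A)
    params = A_inv @ D.T @ y
    # edf = trace of the hat matrix D A^-1 D'
    edf = float(np.trace(A_inv @ (D.T @ D)))
    resid = y - D @ params
    sigma2 = float(resid @ resid / max(n - edf, 1.0))
    cov = sigma2 * A_inv @ (D.T @ D) @ A_inv
    return _TargetFit(params=params, cov_params=cov, sigma2=sigma2, edf=edf)


def _gcv_alpha(D: np.ndarray, S: np.ndarray, pen_cols: slice, y: np.ndarray) -> float:
    """Spline penalty weight minimizing generalized cross-validation.

    GCV(alpha) = n * RSS / (n - edf)^2 over a log-spaced alpha grid.
    """
    n = len(y)
    DtD = D.T @ D
    Dty = D.T @ y
    best, best_alpha = np.inf, 1.0
    for alpha in np.logspace(-4, 6, 21):
        P = np.zeros_like(DtD)
        P[pen_cols, pen_cols.start : pen_cols.stop] = alpha * S
        A_inv = np.linalg.inv(DtD + P)
        params = A_inv @ Dty
        edf = float(np.trace(A_inv @ DtD))
        resid = y - D @ params
        gcv = n * float(resid @ resid) / (n - edf) ** 2
        if gcv < best:
            best, best_alpha = gcv, alpha
    return best_alpha


def fit_normative(
    controls: pd.DataFrame,
    targets: str = "all",
    df_spline: int = 20,
    degree: int = 3,
) -> NormativeModel:
    """Fit the normative GAM on controls.

    Age enters as a penalized B-spline (default 20 basis functions,
    second-difference penalty); sex and centered ICV as linear terms. The
    penalty weight is chosen once by GCV on the mean-thickness model and
    shared across regions (regions share the same age-sampling design, so
    a shared smoothness is both stable and fast). ``targets="mean"`` fits
    only mean thickness, for analyses that need no regional profiles.
    """
    ctr = controls[controls["dx"] == 0] if "dx" in controls.columns else controls
    if len(ctr) < 100:
        log.warning("fit_normative: only %d controls; the age smooth may be unstable", len(ctr))
    ctr = _with_mean_column(ctr)
    age = ctr[["age"]].to_numpy(dtype=float)
    icv_center = float(ctr["icv"].mean())
    X = _linear_design(ctr, icv_center)
    smoother = BSplines(age, df=[df_spline], degree=[degree], include_intercept=False)
    S = smoother.penalty_matrices[0]
    D = np.hstack([X, smoother.basis])
    pen = slice(X.shape[1], D.shape[1])

    y_mean = ctr[MEAN_COL].to_numpy(dtype=float)
    alpha = _gcv_alpha(D, S, pen, y_mean)
    P = np.zeros((D.shape[1], D.shape[1]))
    P[pen, pen.start : pen.stop] = alpha * S

    names = [MEAN_COL] + (THK if targets == "all" else [])
    fits = {
        name: _penalized_fit(D, P, ctr[name].to_numpy(dtype=float)) for name in names
    }
    return NormativeModel(
        smoother=smoother,
        alpha=alpha,
        fits=fits,
        age_ref=(float(age.min()), float(age.max())),
        icv_center=icv_center,
    )


def _full_design(model: NormativeModel, cohort: pd.DataFrame) -> np.ndarray:
    age = np.clip(
        cohort["age"].to_numpy(dtype=float), model.age_ref[0], model.age_ref[1]
    )
    basis = model.smoother.transform(age[:, None])
    X = _linear_design(cohort, model.icv_center)
    return np.hstack([X, basis])


def predict_interval(
    model: NormativeModel, cohort: pd.DataFrame, target: str = MEAN_COL,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted mean and prediction-interval bounds for a new observation."""
    fit = model.fits[target]
    D = _full_design(model, cohort)
    pred = D @ fit.params
    var_mean = np.einsum("ij,jk,ik->i", D, fit.cov_params, D)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(var_mean + fit.sigma2)
    return pd.DataFrame(
        {"predicted": pred, "lower": pred - half, "upper": pred + half},
        index=cohort.index,
    )


def deviation_scores(
    model: NormativeModel, cohort: pd.DataFrame
) -> pd.DataFrame:
    """z = (observed - predicted) * 4 / (upper - lower 95% PI), per target.

    Returns a subjects x targets table (mean thickness first). The scale
    factor 4 / width approximates a z-score: width ~ 2 * 1.96 * sigma, so
    z ~ residual / (0.98 * sigma).
    """
    cohort = _with_mean_column(cohort)
    out = {}
    for target in model.targets:
        pi = predict_interval(model, cohort, target)
        width = (pi["upper"] - pi["lower"]).to_numpy()
        if np.any(width <= 0):
            raise ValueError(f"zero-width prediction interval for {target}")
        obs = cohort[target].to_numpy(dtype=float)
        out[target] = (obs - pi["predicted"].to_numpy()) * 4.0 / width
    return pd.DataFrame(out, index=cohort.index)


def heterogeneity(dev: pd.DataFrame, mask=None, target: str = MEAN_COL) -> float:
    """Fraction of the (masked) group with |z| > 2 on the given target."""
    z = dev[target]
    if mask is not None:
        z = z[np.asarray(mask, dtype=bool)]
    if len(z) == 0:
        raise ValueError("empty group")
    return float((z.abs() > 2).mean())


def subtype_profile_compare(
    dev: pd.DataFrame,
    labels: np.ndarray,
    templates: dict | None = None,
    n_rot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Welch t per region between subtypes S1 and S2, FDR, Cohen's d map.

    `dev` must hold the regional z columns for the patients being
    compared; `labels` gives 1/2 per row. If `templates` maps names to
    68-length group maps (G1, G2, SPL, CC), the d map is Spearman-
    correlated with each, with spin p from the mirrored-rotation null.
    """
    labels = np.asarray(labels)
    z = dev[THK].to_numpy(dtype=float)
    a, b = z[labels == 1], z[labels == 2]
    if min(len(a), len(b)) < 2:
        raise ValueError("each subtype needs at least 2 members")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    n1, n2 = len(a), len(b)
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1, axis=0) + (n2 - 1) * b.var(ddof=1, axis=0)) / (n1 + n2 - 2))
    d = (a.mean(axis=0) - b.mean(axis=0)) / sp
    table = pd.DataFrame(
        {"t": t, "p": p, "p_fdr": fdr_bh(p), "d": d}, index=THK
    )
    report = None
    if templates:
        report = spatial_correlation_report(
            d, templates, dk_atlas_fixture(), n_rot=n_rot, method="spearman", seed=seed
        )
    return table, report


def stratified_compare(
    dev: pd.DataFrame,
    labels: np.ndarray,
    cohort: pd.DataFrame,
    strata: str = "duration",
) -> dict:
    """Per-bin subtype comparisons over duration or age strata.

    Bins are half-open [lo, hi) with the final bin closed. Returns
    {(lo, hi): (n1, n2, table)}; bins with a subtype below 2 members are
    skipped with a warning.
    """
    bins = DURATION_BINS if strata == "duration" else AGE_BINS
    v = cohort[strata].to_numpy(dtype=float)
    labels = np.asarray(labels)
    out = {}
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        m = (v >= lo) & ((v <= hi) if last else (v < hi))
        n1 = int(((labels == 1) & m).sum())
        n2 = int(((labels == 2) & m).sum())
        if min(n1, n2) < 2:
            log.warning("stratified_compare: bin [%s, %s%s skipped (n1=%d, n2=%d)",
                        lo, hi, "]" if last else ")", n1, n2)
            continue
        table, _ = subtype_profile_compare(dev.loc[m], labels[m])
        out[(lo, hi)] = (n1, n2, table)
    return out


def assign_bin(value: float, strata: str = "duration"):
    """Bin assignment rule: half-open [lo, hi), final bin closed."""
    bins = DURATION_BINS if strata == "duration" else AGE_BINS
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        if value >= lo and (value <= hi if last else value < hi):
            return (lo, hi)
    return None
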