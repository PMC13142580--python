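"""Imputation, multi-site harmonization and covariate residualization.

The preprocessing chain mirrors standard consortium practice for pooled
regional-thickness tables:

1. subjects with >= 10% missing regions are dropped; remaining missing
   cells are filled by round-robin chained regression (each region on all
   others, iterated to convergence);
2. site batch effects in location and scale are removed by parametric
   empirical-Bayes harmonization (the ComBat model) while preserving
   diagnosis, age and sex effects;
3. age and sex are regressed out of each region by OLS before covariance
   construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

from .atlas import dk_atlas_fixture, thickness_columns

log = logging.getLogger(__name__)

THK = thickness_columns()


def _thickness_matrix(cohort: pd.DataFrame) -> np.ndarray:
    return cohort[THK].to_numpy(dtype=float)


def impute_missing(
    cohort: pd.DataFrame, max_missing_frac: float = 0.10
) -> pd.DataFrame:
    """Drop heavily missing subjects; chained-regression impute the rest.

    Subjects missing at least `max_missing_frac` of their 68 regions are
    removed (count logged). Remaining missing cells are filled by
    iterative round-robin linear regression of each region on all others
    (mean-initialized, fixed region order, tolerance 1e-3, at most 10
    sweeps). Observed cells are never altered.
    """
    X = _thickness_matrix(cohort)
    n_missing = np.isnan(X).sum(axis=1)
    all_nan_regions = np.isnan(X).all(axis=0)
    if all_nan_regions.any():
        names = [THK[i] for i in np.flatnonzero(all_nan_regions)]
        raise ValueError(f"region(s) entirely missing: {names}")
    keep = n_missing < max_missing_frac * X.shape[1]
    if (~keep).any():
        log.info("impute_missing: dropping %d subjects with >=%.0f%% missing regions",
                 int((~keep).sum()), 100 * max_missing_frac)
    out = cohort.loc[keep].reset_index(drop=True)
    X = _thickness_matrix(out)
    if not np.isnan(X).any():
        return out
    imputer = IterativeImputer(
        estimator=LinearRegression(),
        max_iter=10,
        tol=1e-3,
        initial_strategy="mean",
        imputation_order="roman",  # fixed atlas order each sweep
        sample_posterior=False,
        random_state=0,
    )
    filled = imputer.fit_transform(X)
    observed = ~np.isnan(X)
    filled[observed] = X[observed]  # guard: observed cells untouched
    out.loc[:, THK] = filled
    return out


@dataclass
class HarmonizationModel:
    """Fitted parametric empirical-Bayes site-harmonization model."""

    sites: list
    gamma_star: np.ndarray  # (n_sites, 68) additive site effects (standardized scale)
    delta_star_sq: np.ndarray  # (n_sites, 68) multiplicative site variances
    grand_mean: np.ndarray  # (68,)
    pooled_var: np.ndarray  # (68,)
    beta: np.ndarray  # preserved-covariate coefficients (p, 68)
    design_cols: list


def _preserve_design(cohort: pd.DataFrame, preserve: tuple) -> tuple[np.ndarray, list]:
    cols, names = [], []
    for name in ("dx", "age", "sex"):
        if name not in preserve:
            continue
        v = (
            (cohort["sex"].to_numpy() == "M").astype(float)
            if name == "sex"
            else cohort[name].to_numpy(dtype=float)
        )
        if np.ptp(v) == 0:  # e.g. a controls-only cohort: nothing to preserve
            log.info("combat_harmonize: preserved covariate %r is constant, dropped", name)
            continue
        cols.append(v)
        names.append(name)
    if not cols:
        return np.empty((len(cohort), 0)), []
    return np.column_stack(cols), names


def combat_harmonize(
    cohort: pd.DataFrame,
    batch: str = "site",
    preserve: tuple = ("dx", "age", "sex"),
) -> tuple[pd.DataFrame, HarmonizationModel]:
    """Remove site location/scale batch effects, empirical-Bayes style.

    Standard parametric ComBat: per region, standardize on the grand mean
    plus preserved-covariate fit; estimate per-site location/scale;
    shrink them toward pooled priors (normal prior for location,
    inverse-gamma for scale, moment-matched hyperparameters, iterated
    conditional modes); remove the shrunken site effects and restore the
    covariate fit. A single site passes through unchanged.
    """
    sites = list(pd.unique(cohort[batch]))
    counts = cohort[batch].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"site(s) with a single subject: {bad}")
    Y = _thickness_matrix(cohort)
    n, p = Y.shape
    site_idx = cohort[batch].map({s: i for i, s in enumerate(sites)}).to_numpy()
    n_sites = len(sites)
    one_hot = np.eye(n_sites)[site_idx]
    Z, names = _preserve_design(cohort, preserve)

    # Design: site indicators (sum-to-weighted-zero via proportions) + covariates.
    X = np.hstack([one_hot, Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: preserved covariates collinear with site")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    site_means = B[:n_sites]  # (n_sites, 68)
    beta = B[n_sites:]
    props = np.bincount(site_idx, minlength=n_sites) / n
    grand = props @ site_means  # (68,)
    fitted_cov = Z @ beta if Z.size else np.zeros_like(Y)
    resid = Y - one_hot @ site_means - fitted_cov
    pooled_var = (resid**2).sum(axis=0) / n
    pooled_sd = np.sqrt(pooled_var)

    Zs = (Y - grand - fitted_cov) / pooled_sd  # standardized data

    gamma_hat = np.vstack(
        [Zs[site_idx == i].mean(axis=0) for i in range(n_sites)]
    )
    delta_hat_sq = np.vstack(
        [Zs[site_idx == i].var(axis=0, ddof=1) for i in range(n_sites)]
    )
    delta_hat_sq = np.maximum(delta_hat_sq, 1e-12)

    # Moment-matched EB hyperparameters (per site, across regions).
    gamma_bar = gamma_hat.mean(axis=1, keepdims=True)
    tau_sq = gamma_hat.var(axis=1, ddof=1, keepdims=True)
    d_bar = delta_hat_sq.mean(axis=1, keepdims=True)
    d_var = delta_hat_sq.var(axis=1, ddof=1, keepdims=True)
    lam = (2 * d_var + d_bar**2) / np.maximum(d_var, 1e-12)  # IG shape
    theta = (d_bar * d_var + d_bar**3) / np.maximum(d_var, 1e-12)  # IG scale

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    for i in range(n_sites):
        ni = int((site_idx == i).sum())
        Zi = Zs[site_idx == i]
        g, dsq = gamma_hat[i].copy(), delta_hat_sq[i].copy()
        for _ in range(100):  # iterated conditional modes
            g_new = (ni * tau_sq[i] * gamma_hat[i] + dsq * gamma_bar[i]) / (
                ni * tau_sq[i] + dsq
            )
            ss = ((Zi - g_new) ** 2).sum(axis=0)
            dsq_new = (theta[i] + 0.5 * ss) / (ni / 2 + lam[i] - 1)
            if np.max(np.abs(g_new - g)) < 1e-8 and np.max(np.abs(dsq_new - dsq)) < 1e-8:
                g, dsq = g_new, dsq_new
                break
            g, dsq = g_new, dsq_new
        gamma_star[i] = g
        delta_star_sq[i] = np.maximum(dsq, 1e-12)

    if n_sites == 1:
        adjusted = Y.copy()
    else:
        adj = (Zs - gamma_star[site_idx]) / np.sqrt(delta_star_sq[site_idx])
        adjusted = adj * pooled_sd + grand + fitted_cov

    out = cohort.copy()
    out.loc[:, THK] = adjusted
    model = HarmonizationModel(
        sites=sites,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        grand_mean=np.asarray(grand),
        pooled_var=pooled_var,
        beta=beta,
        design_cols=names,
    )
    return out, model


@dataclass
class ResidualizationModel:
    coef: np.ndarray  # (p, 68)
    design_cols: list


def residualize(
    cohort: pd.DataFrame,
    covariates: tuple = ("age", "sex"),
    sample: str = "pooled",
) -> tuple[pd.DataFrame, ResidualizationModel]:
    """Regress covariates out of every region by OLS; residuals replace thickness.

    The regression is fitted on the pooled sample by default (diagnosis is
    never in the design, so case-control differences survive); set
    ``sample="controls"`` to fit coefficients on controls only and apply
    them to everyone.
    """
    Y = _thickness_matrix(cohort)
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for c in covariates:
        v = (
            (cohort["sex"].to_numpy() == "M").astype(float)
            if c == "sex"
            else cohort[c].to_numpy(dtype=float)
        )
        if np.ptp(v) == 0:
            log.warning("residualize: covariate %r is constant, dropped", c)
            continue
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)
    if sample == "controls":
        mask = cohort["dx"].to_numpy() == 0
        B, *_ = np.linalg.lstsq(X[mask], Y[mask], rcond=None)
        resid = Y - X @ B
        # Keep residual interpretation: center on the pooled mean of the fit.
        resid -= resid[mask].mean(axis=0)
    else:
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ B
    out = cohort.copy()
    out.loc[:, THK] = resid
    return out, ResidualizationModel(coef=B, design_cols=names)
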