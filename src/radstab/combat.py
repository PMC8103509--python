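"""Parametric empirical-Bayes ComBat harmonization of feature tables.

The location/scale model is Y_ij = alpha + beta X_ij + gamma_i + delta_i
eps_ij for feature value Y of sample j in batch i: alpha is the grand
(batch-size-weighted) mean, X optional covariates, gamma_i and delta_i
additive and multiplicative batch effects, eps ~ N(0, sigma^2). Batch
effects are estimated per feature, shrunk toward parametric priors
(normal for gamma, inverse-gamma for delta^2) by iterating the coupled
EB posterior equations, and removed as

    Y* = sigma_hat * (Z - gamma*) / sqrt(delta*) + alpha_hat + beta_hat X

with Z the standardized residual. delta* is carried as a variance, so
the division uses its square root. Here each scan is a batch and the
phantom has no biologic covariates, so X is empty by default.

Features with near-zero variance (the same value in >= 95% of rows)
must be removed before fitting; ``nzv_filter`` does that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NzvReport",
    "CombatModel",
    "nzv_filter",
    "combat_fit",
    "combat_apply",
    "harmonize",
]


@dataclass(frozen=True)
class NzvReport:
    removed: list[str]
    retained: list[str]
    modal_fraction: dict[str, float]


def _feature_columns(df: pd.DataFrame) -> list[str]:
    meta = {"scan_id", "roi_label", "batch"}
    return [c for c in df.columns if c not in meta]


def nzv_filter(
    df: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, NzvReport]:
    """Drop features whose most frequent value (after rounding to 12
    significant digits) occurs in >= ``threshold`` of the rows."""
    if len(df) < 2:
        raise ValueError("need >= 2 rows")
    feats = _feature_columns(df)
    removed, retained, frac = [], [], {}
    for c in feats:
        v = df[c].to_numpy(dtype=np.float64)
        r = v.copy()
        nz = v != 0
        if nz.any():
            mag = np.floor(np.log10(np.abs(v[nz])))
            factor = 10.0 ** (mag - 11)
            r[nz] = np.round(v[nz] / factor) * factor
        _, counts = np.unique(r, return_counts=True)
        f = counts.max() / len(r)
        frac[c] = float(f)
        (removed if f >= threshold else retained).append(c)
    return df.drop(columns=removed), NzvReport(removed, retained, frac)


@dataclass
class CombatModel:
    """Fitted ComBat parameters for a fixed feature set and batch set."""

    features: list[str]
    batches: list[str]
    alpha: np.ndarray          # (F,) grand intercept per feature
    beta: np.ndarray           # (F, C) covariate coefficients
    sigma: np.ndarray          # (F,) pooled residual sd
    gamma_star: np.ndarray     # (B, F) EB additive effects (standardized units)
    delta_star: np.ndarray     # (B, F) EB multiplicative effects (variances), > 0
    passthrough: list[str]     # zero-variance features left unharmonized


def _design(batch_labels: np.ndarray, batches: list[str], covariates) -> tuple[np.ndarray, np.ndarray]:
    B = np.column_stack([(batch_labels == b).astype(np.float64) for b in batches])
    if covariates is None:
        X = np.zeros((len(batch_labels), 0))
    else:
        X = np.asarray(covariates, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        keep = [k for k in range(X.shape[1]) if np.ptp(X[:, k]) > 0]
        X = X[:, keep]  # drop degenerate (constant) covariate columns
    return B, X


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (n * t2 * g_hat + d_star * g_bar) / (n * t2 + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, maxit=500):
    """Iterate the coupled EB posterior equations for one batch."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(maxit):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-30)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-30)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _aprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2 if s2 > 0 else 100.0


def _bprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else (_aprior(d_hat) - 1) * m


def combat_fit(
    df: pd.DataFrame,
    batch_col: str = "batch",
    covariates=None,
    parametric: bool = True,
    eb_tol: float = 1e-4,
    eb_maxit: int = 500,
) -> CombatModel:
    """Fit parametric EB ComBat on the feature columns of ``df``.

    Requires >= 2 batches with >= 2 rows each. Features with zero pooled
    variance cannot be standardized; they are flagged and passed through
    unharmonized by :func:`combat_apply`.
    """
    if not parametric:
        raise NotImplementedError("only parametric priors are implemented")
    feats = _feature_columns(df)
    feats = [f for f in feats if f != batch_col]
    labels = df[batch_col].astype(str).to_numpy()
    batches = sorted(set(labels))
    sizes = {b: int((labels == b).sum()) for b in batches}
    small = [b for b, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"batches with < 2 rows: {small}")

    Y = df[feats].to_numpy(dtype=np.float64)  # (N, F)
    N, F = Y.shape
    B, X = _design(labels, batches, covariates)
    D = np.column_stack([B, X])
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    nb = len(batches)
    batch_int = coef[:nb, :]          # (B, F) per-batch intercepts
    beta = coef[nb:, :].T             # (F, C)
    w = np.array([sizes[b] for b in batches], dtype=np.float64) / N
    alpha = w @ batch_int             # batch-size-weighted grand mean

    resid = Y - D @ coef
    var_pooled = (resid**2).mean(axis=0)  # (F,), 1/N
    passthrough = [feats[k] for k in np.nonzero(var_pooled <= 0)[0]]
    ok = var_pooled > 0
    sigma = np.sqrt(np.where(ok, var_pooled, 1.0))

    stand_mean = alpha[None, :] + X @ beta.T
    Z = (Y - stand_mean) / sigma[None, :]

    gamma_star = np.zeros((nb, F))
    delta_star = np.ones((nb, F))
    if nb == 1:
        # a single batch carries no batch effect: harmonization is the identity
        return CombatModel(
            features=list(feats), batches=batches, alpha=alpha, beta=beta,
            sigma=sigma, gamma_star=gamma_star, delta_star=delta_star,
            passthrough=passthrough,
        )
    g_hat = np.vstack([Z[labels == b].mean(axis=0) for b in batches])
    d_hat = np.vstack([Z[labels == b].var(axis=0, ddof=1) for b in batches])
    for i, b in enumerate(batches):
        g_bar, t2 = g_hat[i].mean(), g_hat[i].var(ddof=1)
        a_pr, b_pr = _aprior(d_hat[i]), _bprior(d_hat[i])
        g, d = _it_sol(
            Z[labels == b][:, ok],
            g_hat[i][ok],
            d_hat[i][ok],
            g_bar,
            t2 if t2 > 0 else 1e-12,
            a_pr,
            b_pr,
            conv=eb_tol,
            maxit=eb_maxit,
        )
        gamma_star[i, ok] = g
        delta_star[i, ok] = np.maximum(d, 1e-30)

    return CombatModel(
        features=[f for f in feats],
        batches=batches,
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=delta_star,
        passthrough=passthrough,
    )


def combat_apply(model: CombatModel, df: pd.DataFrame, batch_col: str = "batch") -> pd.DataFrame:
    """Remove the fitted batch effects; row order and labels preserved."""
    labels = df[batch_col].astype(str).to_numpy()
    unseen = sorted(set(labels) - set(model.batches))
    if unseen:
        raise ValueError(f"unseen batch labels: {unseen}")
    out = df.copy()
    Y = df[model.features].to_numpy(dtype=np.float64)
    bidx = np.array([model.batches.index(b) for b in labels])
    X = np.zeros((len(df), model.beta.shape[1]))
    stand_mean = model.alpha[None, :] + X @ model.beta.T
    Z = (Y - stand_mean) / model.sigma[None, :]
    adj = (Z - model.gamma_star[bidx]) / np.sqrt(model.delta_star[bidx])
    Ystar = adj * model.sigma[None, :] + stand_mean
    for k, f in enumerate(model.features):
        if f in model.passthrough:
            continue
        out[f] = Ystar[:, k]
    return out


def harmonize(
    df: pd.DataFrame,
    batch_col: str = "batch",
    nzv_threshold: float = 0.95,
) -> tuple[pd.DataFrame, NzvReport]:
    """NZV-filter then fit-and-apply ComBat on one table; convenience for
    the pairwise runs of the pipeline."""
    filtered, report = nzv_filter(df, nzv_threshold)
    model = combat_fit(filtered, batch_col=batch_col)
    return combat_apply(model, filtered, batch_col=batch_col), report
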