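"""ComBat harmonization: parametric empirical-Bayes location-scale adjustment.

Per feature v, subject j at site i, the model is

    Y_ijv = alpha_v + X_ij beta_v + gamma_iv + delta_iv eps_ijv,
    eps_ijv ~ N(0, sigma_v^2),

with additive (gamma) and multiplicative (delta) site effects.  The data are
standardized feature-wise, site effects are estimated per (site, feature) and
shrunk across features by empirical Bayes under the parametric priors
gamma_iv ~ N(gamma_bar_i, tau_i^2) and delta_iv^2 ~ InverseGamma(lambda_i,
theta_i), and the standardized data are adjusted with the shrunken estimates:

    Y*_ijv = sigma_v * (Z_ijv - gamma*_iv) / delta*_iv + alpha_v + X_ij beta_v.

The robust variant fits every quantity on a caller-supplied subset of rows
(typically the non-outliers) and then applies the adjustment to all rows,
outliers included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from combatsim._errors import DegenerateFeatureError, ValidationError

__all__ = [
    "CombatFit",
    "standardize",
    "eb_hyperparameters",
    "eb_posteriors",
    "apply_adjustment",
    "harmonize",
]

EB_TOL = 1e-4
EB_MAX_ITER = 100


@dataclass
class CombatFit:
    """Everything estimated during a ComBat fit.

    Shapes: P features, S sites, C covariates.  ``gamma_hat``/``delta_hat_sq``
    are the raw per-(site, feature) location/scale effects on the standardized
    scale; ``gamma_star``/``delta_star`` are their EB-shrunken versions
    (identical when ``eb_enabled`` is false).
    """

    sites: list = field(default_factory=list)
    site_sizes: np.ndarray | None = None
    alpha_hat: np.ndarray | None = None      # (P,)
    beta_hat: np.ndarray | None = None       # (C, P)
    sigma_hat: np.ndarray | None = None      # (P,) pooled residual SD
    gamma_hat: np.ndarray | None = None      # (S, P)
    delta_hat_sq: np.ndarray | None = None   # (S, P)
    gamma_bar: np.ndarray | None = None      # (S,)
    tau_sq: np.ndarray | None = None         # (S,)
    lam: np.ndarray | None = None            # (S,) inverse-gamma shape
    theta: np.ndarray | None = None          # (S,) inverse-gamma scale
    gamma_star: np.ndarray | None = None     # (S, P)
    delta_star: np.ndarray | None = None     # (S, P)
    eb_enabled: bool = True
    converged: bool = False
    n_iterations: int = 0

    def to_json(self, path) -> None:
        def enc(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {k: enc(v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CombatFit":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {
            "site_sizes", "alpha_hat", "beta_hat", "sigma_hat", "gamma_hat",
            "delta_hat_sq", "gamma_bar", "tau_sq", "lam", "theta",
            "gamma_star", "delta_star",
        }
        for k in arrays:
            if payload.get(k) is not None:
                payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


def _site_indicator(sites_arr: np.ndarray, site_order: list) -> np.ndarray:
    return np.column_stack([(sites_arr == s).astype(float) for s in site_order])


def standardize(
    Y: np.ndarray,
    sites: np.ndarray,
    X: np.ndarray | None = None,
    ml_variance: bool = True,
) -> tuple[CombatFit, np.ndarray]:
    """Feature-wise standardization of the location-scale model.

    Fits, per feature, the intercept alpha_v, covariate effects beta_v and raw
    site effects gamma_iv by least squares under the sample-size-weighted
    constraint ``sum_i n_i gamma_iv = 0`` (which makes alpha_v the weighted
    grand mean), then rescales residual variation to unit pooled variance:
    ``Z = (Y - alpha - X beta) / sigma_hat``.  ``sigma_hat**2`` pools squared
    residuals over all N rows (maximum-likelihood denominator N by default;
    ``ml_variance=False`` uses N - rank(design)).

    Returns a partially populated :class:`CombatFit` (through ``gamma_hat`` /
    ``delta_hat_sq``) and the standardized matrix Z.
    """
    Y = np.asarray(Y, dtype=float)
    sites_arr = np.asarray(sites)
    n, p = Y.shape
    _, first_idx = np.unique(sites_arr, return_index=True)
    site_order = [sites_arr[i] for i in np.sort(first_idx)]
    n_i = np.array([(sites_arr == s).sum() for s in site_order], dtype=float)
    if np.any(n_i < 2):
        raise ValidationError("every site needs at least 2 rows")

    D = _site_indicator(sites_arr, site_order)  # (N, S), rows sum to 1
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.hstack([D, X])
    else:
        design = D
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError("design matrix is singular (covariates collinear with sites?)")

    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)  # (S + C, P)
    s = len(site_order)
    site_coef = coef[:s]                      # per-site feature means net of covariates
    beta_hat = coef[s:] if X is not None else np.zeros((0, p))
    alpha_hat = (n_i / n) @ site_coef         # weighted grand mean
    gamma_hat = site_coef - alpha_hat         # satisfies sum_i n_i gamma_iv = 0

    fitted = design @ coef
    resid = Y - fitted
    denom = n if ml_variance else n - rank
    if denom <= 0:
        raise ValidationError("not enough rows for unbiased variance denominator")
    sigma_sq = (resid**2).sum(axis=0) / denom
    if np.any(sigma_sq <= 0):
        bad = int(np.argmax(sigma_sq <= 0))
        raise DegenerateFeatureError(f"zero residual variance for feature index {bad}")
    sigma_hat = np.sqrt(sigma_sq)

    stand_mean = alpha_hat[None, :] + (X @ beta_hat if X is not None else 0.0)
    Z = (Y - stand_mean) / sigma_hat[None, :]

    # raw site effects on the standardized scale
    gamma_hat_z = np.vstack([Z[sites_arr == s_].mean(axis=0) for s_ in site_order])
    delta_hat_sq = np.vstack([Z[sites_arr == s_].var(axis=0, ddof=1) for s_ in site_order])
    if np.any(delta_hat_sq <= 0):
        raise DegenerateFeatureError("zero within-site variance on the standardized scale")

    fit = CombatFit(
        sites=site_order,
        site_sizes=n_i,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        sigma_hat=sigma_hat,
        gamma_hat=gamma_hat_z,
        delta_hat_sq=delta_hat_sq,
    )
    return fit, Z


def eb_hyperparameters(fit: CombatFit) -> CombatFit:
    """Method-of-moments hyperpriors from the across-feature spread of site effects.

    gamma_bar_i / tau_i^2 are the mean and variance (ddof=1) of gamma_hat_iv
    over features; (lambda_i, theta_i) invert the inverse-gamma mean m and
    variance s2 of delta_hat_sq_iv: lambda = m^2/s2 + 2, theta = m (lambda - 1).
    """
    if fit.gamma_hat is None or fit.delta_hat_sq is None:
        raise ValidationError("standardize() must run first")
    s, p = fit.gamma_hat.shape
    if p < 3:
        raise ValidationError("need at least 3 features to estimate hyperpriors")
    fit.gamma_bar = fit.gamma_hat.mean(axis=1)
    fit.tau_sq = fit.gamma_hat.var(axis=1, ddof=1)
    m = fit.delta_hat_sq.mean(axis=1)
    s2 = fit.delta_hat_sq.var(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        lam = np.where(s2 > 0, m**2 / np.where(s2 > 0, s2, 1.0) + 2.0, np.inf)
    fit.lam = lam
    fit.theta = np.where(np.isfinite(lam), m * (lam - 1.0), m)
    return fit


def eb_posteriors(
    Z: np.ndarray,
    sites: np.ndarray,
    fit: CombatFit,
    tol: float = EB_TOL,
    max_iter: int = EB_MAX_ITER,
) -> CombatFit:
    """Iterate the coupled conditional-posterior-mean updates to convergence.

        gamma*_iv = (n_i tau_i^2 gamma_hat_iv + delta*_iv^2 gamma_bar_i)
                    / (n_i tau_i^2 + delta*_iv^2)
        delta*_iv^2 = (theta_i + 0.5 sum_j (Z_ijv - gamma*_iv)^2)
                      / (n_i / 2 + lambda_i - 1)

    Starting from the raw estimates, iteration stops when the maximum relative
    change across both parameter sets falls below ``tol``; non-convergence at
    ``max_iter`` is recorded, not fatal.
    """
    if fit.gamma_bar is None:
        raise ValidationError("eb_hyperparameters() must run first")
    sites_arr = np.asarray(sites)
    gamma_star = fit.gamma_hat.copy()
    delta_sq_star = fit.delta_hat_sq.copy()
    n_iter_max = 0
    for i, site in enumerate(fit.sites):
        block = Z[sites_arr == site]
        n_i = block.shape[0]
        g_hat = fit.gamma_hat[i]
        d_hat_sq = fit.delta_hat_sq[i]
        g_bar, t2, lam, th = fit.gamma_bar[i], fit.tau_sq[i], fit.lam[i], fit.theta[i]
        g, d_sq = g_hat.copy(), d_hat_sq.copy()
        sum_sq0 = (block**2).sum(axis=0)
        col_sum = block.sum(axis=0)
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (n_i * t2 * g_hat + d_sq * g_bar) / (n_i * t2 + d_sq)
            # sum_j (z - g)^2 = sum z^2 - 2 g sum z + n g^2
            ss = sum_sq0 - 2.0 * g_new * col_sum + n_i * g_new**2
            if np.isfinite(lam):
                d_new = (th + 0.5 * ss) / (n_i / 2.0 + lam - 1.0)
            else:
                d_new = d_sq  # variance shrinkage disabled (flat delta_hat_sq)
            change = max(
                np.max(np.abs(g_new - g) / (np.abs(g) + 1e-12)),
                np.max(np.abs(d_new - d_sq) / (np.abs(d_sq) + 1e-12)),
            )
            g, d_sq = g_new, d_new
            if change < tol:
                break
        n_iter_max = max(n_iter_max, it)
        gamma_star[i] = g
        delta_sq_star[i] = d_sq
    fit.gamma_star = gamma_star
    fit.delta_star = np.sqrt(delta_sq_star)
    fit.n_iterations = n_iter_max
    fit.converged = n_iter_max < max_iter
    fit.eb_enabled = True
    return fit


def apply_adjustment(
    Z: np.ndarray,
    sites: np.ndarray,
    fit: CombatFit,
    X: np.ndarray | None = None,
) -> np.ndarray:
    """Remove shrunken site effects and restore the original location/scale.

    Per (site, feature) the map is affine with strictly positive slope
    ``sigma_v / delta*_iv``, so within-site Pearson and Spearman correlations
    with any external variable are preserved exactly.
    """
    sites_arr = np.asarray(sites)
    out = np.empty_like(Z, dtype=float)
    for i, site in enumerate(fit.sites):
        rows = sites_arr == site
        out[rows] = (Z[rows] - fit.gamma_star[i]) / fit.delta_star[i]
    out = out * fit.sigma_hat[None, :] + fit.alpha_hat[None, :]
    if X is not None and fit.beta_hat is not None and fit.beta_hat.size:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = out + X @ fit.beta_hat
    return out


def harmonize(
    Y: np.ndarray,
    sites: np.ndarray,
    X: np.ndarray | None = None,
    eb: bool = True,
    exclude_mask: np.ndarray | None = None,
    ml_variance: bool = True,
    tol: float = EB_TOL,
    max_iter: int = EB_MAX_ITER,
) -> tuple[np.ndarray, CombatFit]:
    """Full ComBat pass: standardize, shrink site effects, adjust.

    ``exclude_mask`` (subject-level booleans, true = leave out of the fit)
    selects the robust variant: every fitted quantity — standardization,
    raw site effects, hyperpriors, posteriors — is estimated on the unflagged
    rows only, and the resulting transform is then applied to every row,
    flagged ones included.  With an all-false mask the result is bit-identical
    to the plain fit.
    """
    Y = np.asarray(Y, dtype=float)
    sites_arr = np.asarray(sites)
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != (Y.shape[0],):
            raise ValidationError("exclude_mask must be one flag per row")
        keep = ~exclude_mask
        for s in np.unique(sites_arr):
            if (keep & (sites_arr == s)).sum() < 2:
                raise ValidationError(
                    f"robust mode infeasible: site {s} retains < 2 unflagged rows"
                )
        Y_fit = Y[keep]
        sites_fit = sites_arr[keep]
        X_fit = None if X is None else np.asarray(X, dtype=float)[keep]
    else:
        Y_fit, sites_fit, X_fit = Y, sites_arr, X

    fit, Z_fit = standardize(Y_fit, sites_fit, X_fit, ml_variance=ml_variance)
    if eb:
        fit = eb_hyperparameters(fit)
        fit = eb_posteriors(Z_fit, sites_fit, fit, tol=tol, max_iter=max_iter)
    else:
        fit.gamma_star = fit.gamma_hat.copy()
        fit.delta_star = np.sqrt(fit.delta_hat_sq)
        fit.eb_enabled = False
        fit.converged = True

    # transform ALL rows with the fitted parameters
    if X is not None:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        stand_mean = fit.alpha_hat[None, :] + Xa @ fit.beta_hat
    else:
        Xa = None
        stand_mean = fit.alpha_hat[None, :]
    Z_all = (Y - stand_mean) / fit.sigma_hat[None, :]
    Y_combat = apply_adjustment(Z_all, sites_arr, fit, X=Xa)
    return Y_combat, fit
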