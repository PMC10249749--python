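"""Multisite synthetic IDP data generation.

Each acquisition site is modeled as a multivariate normal with its own mean
vector and covariance matrix over P imaging-derived phenotypes (IDPs).  Site
heterogeneity follows ComBat's own location-scale form: per-site additive mean
offsets plus a multiplicative rescaling of a shared base covariance.  A
behavioral variable is coupled to one designated "target" IDP as its per-site
z-score plus Gaussian noise, so it carries true brain-behavior signal but no
site effect.

Feature naming is 1-based ("IDP-187" is column index 186); internal indices
are 0-based and contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from combatsim._errors import CovarianceError, DegenerateFeatureError, ValidationError

__all__ = [
    "SiteModel",
    "SiteEffectSpec",
    "MultisiteDataset",
    "default_base_moments",
    "hub_correlation_matrix",
    "build_site_models",
    "generate_normal_dataset",
    "generate_behavior",
    "make_default_dataset",
]

#: Default design: 3 sites x 1,000 subjects x 273 IDPs, target IDP-187,
#: behavioral noise variance 0.04.
DEFAULT_N_SITES = 3
DEFAULT_N_PER_SITE = 1000
DEFAULT_N_FEATURES = 273
DEFAULT_TARGET_IDP = 186  # 0-based column of "IDP-187"
DEFAULT_NOISE_VARIANCE = 0.04

_SYM_RTOL = 1e-10
_EIG_RTOL = 1e-8


def _check_covariance(sigma: np.ndarray, name: str = "sigma") -> None:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise CovarianceError(f"{name} must be square, got shape {sigma.shape}")
    scale = max(np.abs(sigma).max(), 1.0)
    if np.abs(sigma - sigma.T).max() > _SYM_RTOL * scale:
        raise CovarianceError(f"{name} is not symmetric")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] < -_EIG_RTOL * max(eigvals[-1], 0.0):
        raise CovarianceError(
            f"{name} is not positive semidefinite (min eigenvalue {eigvals[0]:.3g})"
        )


@dataclass(frozen=True)
class SiteModel:
    """Generating moments of one site: mean vector, covariance, planned size."""

    site_id: str
    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.n < 2:
            raise ValidationError(f"site {self.site_id}: need n >= 2, got {self.n}")
        _check_covariance(self.sigma, f"sigma[{self.site_id}]")
        if self.mu.shape != (self.sigma.shape[0],):
            raise ValidationError(
                f"site {self.site_id}: mu length {self.mu.shape} does not match "
                f"sigma shape {self.sigma.shape}"
            )

    @property
    def n_features(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class SiteEffectSpec:
    """Parametric site-effect model around shared base moments.

    Site i gets mean ``base_mu + a_i`` where ``a_i`` is drawn per feature with
    standard deviation ``additive_shift_scale * sqrt(diag(base_sigma))``, and
    covariance ``m_i**2 * base_sigma`` with ``m_i`` uniform on
    ``multiplicative_scale_range``.  This is exactly the additive/multiplicative
    structure ComBat models, so parameter recovery is testable.
    """

    base_mu: np.ndarray
    base_sigma: np.ndarray
    additive_shift_scale: float = 1.0
    multiplicative_scale_range: tuple[float, float] = (0.7, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_mu", np.asarray(self.base_mu, dtype=float))
        object.__setattr__(self, "base_sigma", np.asarray(self.base_sigma, dtype=float))
        lo, hi = self.multiplicative_scale_range
        if not (0.0 < lo <= hi):
            raise ValidationError(
                f"multiplicative_scale_range bounds must be positive, got ({lo}, {hi})"
            )
        if self.additive_shift_scale < 0:
            raise ValidationError("additive_shift_scale must be nonnegative")
        _check_covariance(self.base_sigma, "base_sigma")


@dataclass
class MultisiteDataset:
    """Subject x IDP values with site labels, behavior and outlier bookkeeping.

    ``outlier_mask`` marks injected outlier *values* (all-false for freshly
    generated data).  ``site_models`` carries the generating moments so that
    sample-size balancing during injection can draw fresh normal rows.
    """

    values: np.ndarray
    site_labels: np.ndarray
    behavior: np.ndarray | None = None
    outlier_mask: np.ndarray | None = None
    covariates: np.ndarray | None = None
    feature_ids: list[str] | None = None
    subject_ids: list[str] | None = None
    site_models: list[SiteModel] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.site_labels = np.asarray(self.site_labels)
        n, p = self.values.shape
        if self.site_labels.shape != (n,):
            raise ValidationError("site_labels length must match number of rows")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros((n, p), dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
            if self.outlier_mask.shape != (n, p):
                raise ValidationError("outlier_mask shape must match values")
        if self.behavior is not None:
            self.behavior = np.asarray(self.behavior, dtype=float)
            if self.behavior.shape != (n,):
                raise ValidationError("behavior length must match number of rows")
            if not np.all(np.isfinite(self.behavior)):
                raise ValidationError("behavior contains non-finite values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        for s in self.sites:
            if (self.site_labels == s).sum() < 2:
                raise ValidationError(f"site {s} has fewer than 2 rows")
        if self.feature_ids is None:
            self.feature_ids = [f"IDP-{v + 1:d}" for v in range(p)]
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i + 1:05d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sites(self) -> list:
        # stable order of first appearance (site-blocked generation order)
        _, idx = np.unique(self.site_labels, return_index=True)
        return [self.site_labels[i] for i in np.sort(idx)]

    def site_rows(self, site) -> np.ndarray:
        return np.flatnonzero(self.site_labels == site)

    @property
    def outlier_rows(self) -> np.ndarray:
        """Subject-level ground-truth flag: true if any value in the row is injected."""
        return self.outlier_mask.any(axis=1)

    def copy(self) -> "MultisiteDataset":
        return MultisiteDataset(
            values=self.values.copy(),
            site_labels=self.site_labels.copy(),
            behavior=None if self.behavior is None else self.behavior.copy(),
            outlier_mask=self.outlier_mask.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
            feature_ids=list(self.feature_ids),
            subject_ids=list(self.subject_ids),
            site_models=self.site_models,
        )

    def to_frame(self) -> pd.DataFrame:
        width = len(str(self.n_features))
        cols = [f"IDP_{v + 1:0{max(width, 4)}d}" for v in range(self.n_features)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "site", self.site_labels)
        df.insert(2, "behavior", self.behavior if self.behavior is not None else np.nan)
        return df


def hub_correlation_matrix(
    n_features: int,
    hub_index: int = DEFAULT_TARGET_IDP,
    hub_strength: float = 0.9,
    loading_range: tuple[float, float] = (0.2, 0.7),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Correlation matrix from a one-factor model with a designated hub feature.

    Feature v satisfies ``x_v = l_v * f + sqrt(1 - l_v**2) * e_v`` with a shared
    factor f, so ``corr(u, v) = l_u * l_v`` and the matrix is positive definite
    by construction.  The hub gets loading ``hub_strength``; the rest draw
    uniformly from ``loading_range``, making the hub correlate appreciably with
    every other feature — the property that qualifies it as the representative
    IDP coupled to behavior.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0.0 < hub_strength < 1.0:
        raise ValidationError("hub_strength must lie in (0, 1)")
    loadings = rng.uniform(*loading_range, size=n_features)
    loadings[hub_index] = hub_strength
    corr = np.outer(loadings, loadings)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_base_moments(
    n_features: int = DEFAULT_N_FEATURES,
    hub_index: int = DEFAULT_TARGET_IDP,
    hub_strength: float = 0.9,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Volume-like base mean vector and hub-structured base covariance.

    Means are uniform on [5, 15] and per-feature SDs uniform on [0.5, 2]
    (arbitrary volume-like units, roughly regional grey-matter-volume scale
    heterogeneity); covariance is D @ R @ D with R from
    :func:`hub_correlation_matrix`.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(5.0, 15.0, size=n_features)
    sds = rng.uniform(0.5, 2.0, size=n_features)
    corr = hub_correlation_matrix(n_features, hub_index, hub_strength, rng=rng)
    sigma = corr * np.outer(sds, sds)
    return mu, sigma


def build_site_models(
    spec: SiteEffectSpec,
    n_sites: int = DEFAULT_N_SITES,
    n_per_site: int = DEFAULT_N_PER_SITE,
) -> list[SiteModel]:
    """Derive per-site generating moments from the base moments and effect spec."""
    if n_sites < 2:
        raise ValidationError("need at least 2 sites")
    if n_per_site < 2:
        raise ValidationError("need at least 2 subjects per site")
    rng = np.random.default_rng(spec.seed)
    base_sd = np.sqrt(np.diag(spec.base_sigma))
    lo, hi = spec.multiplicative_scale_range
    models = []
    for i in range(n_sites):
        shift = rng.normal(0.0, 1.0, size=spec.base_mu.shape[0])
        mu_i = spec.base_mu + spec.additive_shift_scale * base_sd * shift
        m_i = rng.uniform(lo, hi)
        sigma_i = (m_i**2) * spec.base_sigma
        models.append(SiteModel(site_id=f"Site {i + 1}", mu=mu_i, sigma=sigma_i, n=n_per_site))
    return models


def _mvn(rng: np.random.Generator, mu: np.ndarray, sigma: np.ndarray, n: int) -> np.ndarray:
    try:
        return rng.multivariate_normal(mu, sigma, size=n, method="eigh")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numpy raises rarely here
        raise CovarianceError(f"covariance factorization failed: {exc}") from exc


def generate_normal_dataset(
    site_models: list[SiteModel], seed: int = 0
) -> MultisiteDataset:
    """Draw each site's block from its multivariate normal; no outliers.

    Rows are site-blocked in model order; all downstream code keys on site
    labels rather than row order.
    """
    p = site_models[0].n_features
    if any(m.n_features != p for m in site_models):
        raise ValidationError("all site models must share the same number of features")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for m in site_models:
        blocks.append(_mvn(rng, m.mu, m.sigma, m.n))
        labels.extend([m.site_id] * m.n)
    return MultisiteDataset(
        values=np.vstack(blocks),
        site_labels=np.asarray(labels, dtype=object),
        site_models=site_models,
    )


def generate_behavior(
    dataset: MultisiteDataset,
    target_idp: int = DEFAULT_TARGET_IDP,
    noise_variance: float = DEFAULT_NOISE_VARIANCE,
    seed: int = 0,
) -> np.ndarray:
    """Per-site z-score of the target IDP plus Gaussian noise.

    The behavioral variable correlates with the target IDP (analytically
    ``1/sqrt(1 + noise_variance)`` within site) and, through it, with the
    hub-correlated features; per-site standardization removes any site effect
    from the behavior itself.  Uses the sample SD (ddof=1).
    """
    if noise_variance < 0:
        raise ValidationError("noise_variance must be nonnegative")
    if not 0 <= target_idp < dataset.n_features:
        raise ValidationError(f"target_idp {target_idp} out of range")
    rng = np.random.default_rng(seed)
    behavior = np.empty(dataset.n_subjects)
    for site in dataset.sites:
        rows = dataset.site_rows(site)
        x = dataset.values[rows, target_idp]
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateFeatureError(
                f"target IDP has zero spread in site {site}; behavior undefined"
            )
        z = (x - x.mean()) / sd
        behavior[rows] = z + rng.normal(0.0, np.sqrt(noise_variance), size=rows.size)
    return behavior


def make_default_dataset(
    n_sites: int = DEFAULT_N_SITES,
    n_per_site: int = DEFAULT_N_PER_SITE,
    n_features: int = DEFAULT_N_FEATURES,
    target_idp: int = DEFAULT_TARGET_IDP,
    noise_variance: float = DEFAULT_NOISE_VARIANCE,
    additive_shift_scale: float = 1.0,
    multiplicative_scale_range: tuple[float, float] = (0.7, 1.5),
    hub_strength: float = 0.9,
    seed: int = 0,
) -> MultisiteDataset:
    """One-call construction of the study's normal (outlier-free) dataset.

    Derives three sub-seeds from ``seed`` for base moments/site effects,
    the normal draws, and the behavioral noise.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    base_mu, base_sigma = default_base_moments(
        n_features, hub_index=target_idp, hub_strength=hub_strength, seed=seeds[0]
    )
    spec = SiteEffectSpec(
        base_mu=base_mu,
        base_sigma=base_sigma,
        additive_shift_scale=additive_shift_scale,
        multiplicative_scale_range=multiplicative_scale_range,
        seed=seeds[0],
    )
    models = build_site_models(spec, n_sites=n_sites, n_per_site=n_per_site)
    ds = generate_normal_dataset(models, seed=seeds[1])
    ds.behavior = generate_behavior(
        ds, target_idp=target_idp, noise_variance=noise_variance, seed=seeds[2]
    )
    return ds
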