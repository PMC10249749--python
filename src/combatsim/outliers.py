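"""Outlier scoring, Tukey-fence detection, and scenario-based injection.

The deviation of a value x from the bulk of a distribution is measured by the
outlier score ``min(|x - Q1|, |x - Q3|) / IQR``; values at least 3 IQR beyond
a quartile (score >= 3, Tukey's "far out" fences with k = 3) are outliers.

Injection appends clouds of extreme rows to one or two sites, drawn
multivariate-normal around ``Q3 + score * IQR`` (upper side) or
``Q1 - score * IQR`` (lower side) per feature with a tight covariance
``cloud_sd**2 * R`` (R the site's normal-data correlation matrix), under six
scenarios varying which sites and which sides receive the outliers.  Every
non-target site receives an equal number of fresh *normal* rows so all sites
keep equal sample sizes, and all appended rows get behavioral values from the
normal generating mechanism — the behavioral variable never receives outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from combatsim._errors import CovarianceError, DegenerateFeatureError, ValidationError
from combatsim.datasets import MultisiteDataset

__all__ = [
    "TUKEY_K",
    "QuartileSummary",
    "Scenario",
    "OutlierSpec",
    "GridCell",
    "compute_quartiles",
    "outlier_score",
    "detect_outliers",
    "DetectionResult",
    "make_outlier_block",
    "inject_outliers",
    "build_sweep_grid",
    "DEFAULT_QUANTITIES",
    "DEFAULT_SCORES",
]

TUKEY_K = 3.0
DEFAULT_QUANTITIES = (0.002, 0.006, 0.01, 0.05, 0.10)
DEFAULT_SCORES = (3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0)
#: Fixed upper-side score in the "one-site different" scenario.
DIFFERENT_UPPER_SCORE = 40.0
DEFAULT_CLOUD_SD = 0.003


class Scenario(str, Enum):
    """The six outlier placement scenarios."""

    ONE_SITE_UNILATERAL = "one_site_unilateral"
    ONE_SITE_BILATERAL = "one_site_bilateral"
    ONE_SITE_DIFFERENT = "one_site_different"
    TWO_SITE_UNILATERAL = "two_site_unilateral"
    TWO_SITE_BILATERAL = "two_site_bilateral"
    TWO_SITE_DIFFERENT = "two_site_different"

    @property
    def one_site(self) -> bool:
        return self in (
            Scenario.ONE_SITE_UNILATERAL,
            Scenario.ONE_SITE_BILATERAL,
            Scenario.ONE_SITE_DIFFERENT,
        )

    @property
    def contaminated_sites(self) -> tuple[int, ...]:
        """0-based indices (in site order) of the sites that receive outliers."""
        return (0,) if self.one_site else (0, 1)


@dataclass(frozen=True)
class QuartileSummary:
    """Quartiles, IQR, and the k=3 Tukey fences of one sample."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_fence(self) -> float:
        return self.q1 - TUKEY_K * self.iqr

    @property
    def upper_fence(self) -> float:
        return self.q3 + TUKEY_K * self.iqr


def compute_quartiles(values: np.ndarray) -> QuartileSummary:
    """Q1/Q3 by linear interpolation between order statistics (quantile type 7)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValidationError("need at least 4 finite values for quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    if q3 - q1 <= 0:
        raise DegenerateFeatureError("zero IQR: outlier scores are undefined")
    return QuartileSummary(q1=float(q1), q3=float(q3))


def outlier_score(x: float, q: QuartileSummary) -> float:
    """Deviation of x in IQR units beyond the nearer quartile; 0 inside [Q1, Q3].

    A score of exactly 3 places x on a Tukey fence, so ``score >= 3`` is
    equivalent to the k=3 fence rule (inclusive).
    """
    if not np.isfinite(x):
        raise ValidationError("outlier score undefined for non-finite values")
    if q.iqr <= 0:
        raise DegenerateFeatureError("zero IQR: outlier score undefined")
    if q.q1 <= x <= q.q3:
        return 0.0
    return min(abs(x - q.q1), abs(x - q.q3)) / q.iqr


@dataclass
class DetectionResult:
    """Per-value mask, subject-level flags, and per-(site, feature) counts."""

    mask: np.ndarray
    subject_flags: np.ndarray
    counts: pd.DataFrame  # index: site, columns: feature ids

    @property
    def n_flagged_subjects(self) -> int:
        return int(self.subject_flags.sum())


def detect_outliers(dataset: MultisiteDataset) -> DetectionResult:
    """Tukey-fence detection per site and per IDP (k = 3, inclusive).

    Fences are computed from each site's own per-feature quartiles.  A subject
    is flagged if any of its values is an outlier on any IDP.
    """
    n, p = dataset.values.shape
    mask = np.zeros((n, p), dtype=bool)
    counts = {}
    for site in dataset.sites:
        rows = dataset.site_rows(site)
        if rows.size < 4:
            raise ValidationError(f"site {site} has fewer than 4 rows")
        block = dataset.values[rows]
        q1, q3 = np.quantile(block, [0.25, 0.75], axis=0, method="linear")
        iqr = q3 - q1
        if np.any(iqr <= 0):
            bad = dataset.feature_ids[int(np.argmax(iqr <= 0))]
            raise DegenerateFeatureError(f"zero IQR for feature {bad} in site {site}")
        site_mask = (block <= q1 - TUKEY_K * iqr) | (block >= q3 + TUKEY_K * iqr)
        mask[rows] = site_mask
        counts[site] = site_mask.sum(axis=0)
    counts_df = pd.DataFrame.from_dict(counts, orient="index", columns=dataset.feature_ids)
    return DetectionResult(mask=mask, subject_flags=mask.any(axis=1), counts=counts_df)


def _psd_correlation(values: np.ndarray) -> np.ndarray:
    """Correlation matrix of the rows of ``values``, clipped to PSD."""
    corr = np.corrcoef(values, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise CovarianceError("correlation matrix undefined (constant feature?)")
    corr = (corr + corr.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] < -1e-8 * max(eigvals[-1], 1.0):
        # numerically indefinite beyond roundoff: rebuild from clipped spectrum
        eigvals = np.clip(eigvals, 0.0, None)
        corr = (eigvecs * eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def make_outlier_block(
    normal_values: np.ndarray,
    n_out: int,
    score: float,
    side: str,
    cloud_sd: float = DEFAULT_CLOUD_SD,
    seed: int = 0,
) -> np.ndarray:
    """Draw an n_out x P cloud of outlier rows for one site and one side.

    Per feature the cloud mean is ``Q3 + score * IQR`` (upper) or
    ``Q1 - score * IQR`` (lower) of the site's normal values; the covariance is
    ``cloud_sd**2`` times the normal data's correlation matrix, giving a tight,
    correlation-preserving cluster whose score is controlled to within a few
    ``cloud_sd``.
    """
    if n_out < 1:
        raise ValidationError("n_out must be >= 1")
    if side not in ("upper", "lower"):
        raise ValidationError(f"side must be 'upper' or 'lower', got {side!r}")
    normal_values = np.asarray(normal_values, dtype=float)
    q1, q3 = np.quantile(normal_values, [0.25, 0.75], axis=0, method="linear")
    iqr = q3 - q1
    if np.any(iqr <= 0):
        raise DegenerateFeatureError("zero IQR in normal values; cannot place outliers")
    mean = q3 + score * iqr if side == "upper" else q1 - score * iqr
    cov = (cloud_sd**2) * _psd_correlation(normal_values)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(mean, cov, size=n_out, method="eigh")


@dataclass(frozen=True)
class OutlierSpec:
    """Scenario, contamination fraction, score(s) and cloud spread of one injection.

    ``quantity_fraction`` is the TOTAL outlier count per affected site as a
    fraction of that site's pre-injection size (bilateral scenarios split it
    across the two sides, upper side taking the extra row on odd counts); set
    ``per_side=True`` to add the full count on each side instead.
    ``lower_score`` applies only to the "one-site different" scenario, whose
    upper side is fixed at score 40.
    """

    scenario: Scenario
    quantity_fraction: float
    score: float
    lower_score: float | None = None
    cloud_sd: float = DEFAULT_CLOUD_SD
    per_side: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if not 0 <= self.quantity_fraction < 0.5:
            raise ValidationError("quantity_fraction must lie in [0, 0.5)")
        if self.score < TUKEY_K:
            raise ValidationError(
                f"score {self.score} < {TUKEY_K}: not an outlier by the fence definition"
            )
        if self.scenario is Scenario.ONE_SITE_DIFFERENT:
            if self.lower_score is None:
                raise ValidationError("one_site_different requires lower_score")
            if self.lower_score < TUKEY_K:
                raise ValidationError("lower_score must be >= 3")
        if self.cloud_sd <= 0:
            raise ValidationError("cloud_sd must be positive")


def _split_bilateral(n_out: int) -> tuple[int, int]:
    upper = (n_out + 1) // 2
    return upper, n_out - upper


def _site_side_plan(spec: OutlierSpec) -> dict[int, list[tuple[str, float]]]:
    """Map contaminated-site index -> list of (side, score) cloud assignments."""
    s = spec.scenario
    if s is Scenario.ONE_SITE_UNILATERAL:
        return {0: [("upper", spec.score)]}
    if s is Scenario.ONE_SITE_BILATERAL:
        return {0: [("upper", spec.score), ("lower", spec.score)]}
    if s is Scenario.ONE_SITE_DIFFERENT:
        return {0: [("upper", DIFFERENT_UPPER_SCORE), ("lower", spec.lower_score)]}
    if s is Scenario.TWO_SITE_UNILATERAL:
        return {0: [("upper", spec.score)], 1: [("upper", spec.score)]}
    if s is Scenario.TWO_SITE_BILATERAL:
        return {
            0: [("upper", spec.score), ("lower", spec.score)],
            1: [("upper", spec.score), ("lower", spec.score)],
        }
    if s is Scenario.TWO_SITE_DIFFERENT:
        return {0: [("upper", spec.score)], 1: [("lower", spec.score)]}
    raise ValidationError(f"unknown scenario {s!r}")


def inject_outliers(
    dataset: MultisiteDataset,
    spec: OutlierSpec,
    target_idp: int | None = None,
    noise_variance: float = 0.04,
) -> MultisiteDataset:
    """Append outlier rows per the scenario, keeping all site sizes equal.

    Contaminated sites gain ``n_out = round(fraction * site size)`` outlier
    rows (split across sides for bilateral scenarios); every other site gains
    the same number of fresh normal rows drawn from its generating model.  All
    appended rows receive behavioral values built by the normal mechanism —
    z-score of a normal target-IDP value against the site's normal-sample
    statistics plus noise — so injection never adds behavioral outliers.
    ``outlier_mask`` is true exactly on the injected outlier values.
    """
    if dataset.behavior is not None and target_idp is None:
        raise ValidationError("target_idp required when the dataset has behavior")
    if dataset.site_models is None:
        raise ValidationError("dataset must carry site_models for balanced injection")

    sites = dataset.sites
    plan = _site_side_plan(spec)
    rng = np.random.default_rng(spec.seed)

    site_n = {site: dataset.site_rows(site).size for site in sites}
    n_out_by_site = {}
    for idx in plan:
        n_out = round(spec.quantity_fraction * site_n[sites[idx]])
        if spec.per_side:
            n_out *= len(plan[idx])
        n_out_by_site[idx] = n_out
    if all(n == 0 for n in n_out_by_site.values()):
        warnings.warn("quantity yields zero outliers; returning dataset unchanged")
        return dataset.copy()
    rows_to_add = max(n_out_by_site.values())

    models = {m.site_id: m for m in dataset.site_models}
    new_values, new_labels, new_mask, new_behavior, new_ids = [], [], [], [], []
    counter = 0
    for idx, site in enumerate(sites):
        pre_rows = dataset.site_rows(site)
        block = dataset.values[pre_rows]
        model = models[site]
        appended, is_outlier = [], []

        if idx in plan:
            assignments = plan[idx]
            n_out = n_out_by_site[idx]
            if spec.per_side or len(assignments) == 1:
                counts = [n_out // len(assignments)] * len(assignments)
            else:
                counts = list(_split_bilateral(n_out))
            for (side, score), k in zip(assignments, counts):
                if k == 0:
                    continue
                sub = int(rng.integers(0, 2**31))
                appended.append(
                    make_outlier_block(block, k, score, side, spec.cloud_sd, seed=sub)
                )
                is_outlier.append(np.ones(k, dtype=bool))
            n_normal = rows_to_add - sum(len(a) for a in appended)
        else:
            n_normal = rows_to_add
        if n_normal > 0:
            sub = np.random.default_rng(int(rng.integers(0, 2**31)))
            appended.append(
                sub.multivariate_normal(model.mu, model.sigma, size=n_normal, method="eigh")
            )
            is_outlier.append(np.zeros(n_normal, dtype=bool))

        app_values = np.vstack(appended)
        app_flags = np.concatenate(is_outlier)
        new_values.append(app_values)
        new_labels.extend([site] * len(app_values))
        new_mask.append(np.broadcast_to(app_flags[:, None], app_values.shape).copy())
        for _ in range(len(app_values)):
            counter += 1
            new_ids.append(f"inj-{counter:05d}")

        if dataset.behavior is not None:
            x_norm = block[:, target_idp]
            mu_n, sd_n = x_norm.mean(), x_norm.std(ddof=1)
            # outlier rows get a FRESH normal target-IDP draw (their own value
            # is extreme); normal rows use their own drawn value, as in the
            # normal generating mechanism
            t_draw = app_values[:, target_idp].copy()
            n_fresh = int(app_flags.sum())
            if n_fresh:
                t_draw[app_flags] = rng.normal(
                    model.mu[target_idp],
                    np.sqrt(model.sigma[target_idp, target_idp]),
                    size=n_fresh,
                )
            b = (t_draw - mu_n) / sd_n + rng.normal(
                0.0, np.sqrt(noise_variance), size=len(app_values)
            )
            new_behavior.append(b)

    # rebuild site-blocked: each site's original rows, then its appended rows
    values_parts, label_parts, mask_parts, behav_parts, id_parts = [], [], [], [], []
    offset = 0
    for idx, site in enumerate(sites):
        pre_rows = dataset.site_rows(site)
        values_parts.append(dataset.values[pre_rows])
        values_parts.append(new_values[idx])
        label_parts.extend([site] * (len(pre_rows) + len(new_values[idx])))
        mask_parts.append(dataset.outlier_mask[pre_rows])
        mask_parts.append(new_mask[idx])
        id_parts.extend([dataset.subject_ids[i] for i in pre_rows])
        n_app = len(new_values[idx])
        id_parts.extend(new_ids[offset : offset + n_app])
        offset += n_app
        if dataset.behavior is not None:
            behav_parts.append(dataset.behavior[pre_rows])
            behav_parts.append(new_behavior[idx])

    return MultisiteDataset(
        values=np.vstack(values_parts),
        site_labels=np.asarray(label_parts, dtype=object),
        behavior=np.concatenate(behav_parts) if dataset.behavior is not None else None,
        outlier_mask=np.vstack(mask_parts),
        feature_ids=list(dataset.feature_ids),
        subject_ids=id_parts,
        site_models=dataset.site_models,
    )


@dataclass(frozen=True)
class GridCell:
    """One sweep-grid condition: scenario x quantity x score."""

    scenario: Scenario
    quantity_fraction: float
    score: float
    lower_score: float | None = None

    def to_spec(self, cloud_sd: float = DEFAULT_CLOUD_SD, seed: int = 0,
                per_side: bool = False) -> OutlierSpec:
        return OutlierSpec(
            scenario=self.scenario,
            quantity_fraction=self.quantity_fraction,
            score=self.score,
            lower_score=self.lower_score,
            cloud_sd=cloud_sd,
            per_side=per_side,
            seed=seed,
        )


def build_sweep_grid(
    scenarios: list[Scenario] | None = None,
    quantities: tuple[float, ...] = DEFAULT_QUANTITIES,
    scores: tuple[float, ...] = DEFAULT_SCORES,
) -> list[GridCell]:
    """Full Cartesian sweep: per scenario, every quantity x score pair.

    The "one-site different" scenario sweeps the score grid on its LOWER side
    with the upper side pinned at 40, so every scenario contributes
    ``len(quantities) * len(scores)`` cells (35 under the default grids).
    """
    if scenarios is None:
        scenarios = list(Scenario)
    if not scenarios or not quantities or not scores:
        raise ValidationError("scenarios, quantities and scores must be non-empty")
    cells = []
    for scn in scenarios:
        scn = Scenario(scn)
        for q in quantities:
            for s in scores:
                if scn is Scenario.ONE_SITE_DIFFERENT:
                    cells.append(
                        GridCell(scn, q, score=DIFFERENT_UPPER_SCORE, lower_score=s)
                    )
                else:
                    cells.append(GridCell(scn, q, score=s))
    return cells
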