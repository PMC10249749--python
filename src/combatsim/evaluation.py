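"""Assessment battery for harmonization quality and outlier damage.

Covers: top-2 PCA embeddings for site-separation visualization; within-site
and pooled ("combined site", mega-analysis) Pearson/Spearman IDP-behavior
correlations; intraclass correlation (two-way random effects, absolute
agreement, single measure by default) of correlation vectors between sites
and between each site and the combined site, with the conventional
consistency bands (high >= 0.80, moderate, good, poor, none < 0.10); counts
of high correlations (r >= 0.6); and mean/variance tracking of a
representative IDP over the normal (non-outlier) samples, the study's core
readout of harmonization distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from combatsim._errors import ValidationError
from combatsim.datasets import MultisiteDataset
from combatsim.outliers import Scenario

__all__ = [
    "COMBINED_SITE",
    "pca_first_two",
    "correlations_by_site",
    "icc",
    "consistency_band",
    "count_high_correlations",
    "normal_sample_moments",
    "scenario_consistency_table",
    "CellMetrics",
    "EvaluationReport",
]

COMBINED_SITE = "combined"
HIGH_R_THRESHOLD = 0.6


def pca_first_two(values: np.ndarray) -> np.ndarray:
    """Scores on the first two principal components of the column-centered data.

    Sign convention: within each component, the loading of largest magnitude is
    made positive, so embeddings are deterministic across linear-algebra
    backends.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n < 3 or p < 2:
        raise ValidationError("PCA needs at least 3 rows and 2 features")
    centered = values - values.mean(axis=0)
    if not np.any(centered):
        raise ValidationError("rank-0 input: all rows identical")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(centered)
    for k in range(2):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1.0
    return scores


def _corr_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 3:
        raise ValidationError("need at least 3 rows per group for correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in a group: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic  # average ranks for ties
    return float(r), float(rho)


def correlations_by_site(
    dataset: MultisiteDataset,
    feature: int,
    values: np.ndarray | None = None,
    rows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson r and Spearman rho of (IDP, behavior), per site and pooled.

    ``values`` substitutes a harmonized matrix for the dataset's raw values;
    ``rows`` restricts the computation to a row subset (e.g. normal samples).
    The "combined" row pools raw subject rows across sites (mega-analysis).
    """
    if dataset.behavior is None:
        raise ValidationError("dataset has no behavioral variable")
    vals = dataset.values if values is None else np.asarray(values, dtype=float)
    keep = np.ones(dataset.n_subjects, dtype=bool) if rows is None else np.asarray(rows)
    records = []
    for site in dataset.sites:
        sel = (dataset.site_labels == site) & keep
        r, rho = _corr_pair(vals[sel, feature], dataset.behavior[sel])
        records.append({"site": site, "pearson_r": r, "spearman_rho": rho})
    r, rho = _corr_pair(vals[keep, feature], dataset.behavior[keep])
    records.append({"site": COMBINED_SITE, "pearson_r": r, "spearman_rho": rho})
    return pd.DataFrame.from_records(records).set_index("site")


def all_feature_correlations(
    dataset: MultisiteDataset,
    values: np.ndarray | None = None,
    rows: np.ndarray | None = None,
    kind: str = "pearson",
) -> pd.DataFrame:
    """IDP-behavior correlations for every feature, per site and combined.

    Returns a (features x groups) frame; used for the violin-box/ICC analysis
    over all P features.
    """
    if dataset.behavior is None:
        raise ValidationError("dataset has no behavioral variable")
    vals = dataset.values if values is None else np.asarray(values, dtype=float)
    keep = np.ones(dataset.n_subjects, dtype=bool) if rows is None else np.asarray(rows)
    b = dataset.behavior
    out = {}
    groups = [(s, (dataset.site_labels == s) & keep) for s in dataset.sites]
    groups.append((COMBINED_SITE, keep))
    for name, sel in groups:
        block = vals[sel]
        bb = b[sel]
        if kind == "pearson":
            bc = bb - bb.mean()
            xc = block - block.mean(axis=0)
            denom = np.sqrt((xc**2).sum(axis=0) * (bc**2).sum())
            out[name] = (xc * bc[:, None]).sum(axis=0) / denom
        elif kind == "spearman":
            br = stats.rankdata(bb)
            xr = np.apply_along_axis(stats.rankdata, 0, block)
            bc = br - br.mean()
            xc = xr - xr.mean(axis=0)
            denom = np.sqrt((xc**2).sum(axis=0) * (bc**2).sum())
            out[name] = (xc * bc[:, None]).sum(axis=0) / denom
        else:
            raise ValidationError(f"unknown correlation kind {kind!r}")
    return pd.DataFrame(out, index=dataset.feature_ids)


def icc(*raters: np.ndarray, kind: str = "absolute") -> float:
    """Intraclass correlation of k paired measurement vectors over n targets.

    Two-way random-effects, single-measure ICC from the ANOVA mean squares of
    the n x k table (targets x raters).  ``kind='absolute'`` is ICC(2,1)
    (absolute agreement — sensitive to constant offsets between raters);
    ``kind='consistency'`` is ICC(3,1).
    """
    data = np.column_stack([np.asarray(r, dtype=float) for r in raters])
    n, k = data.shape
    if k < 2:
        raise ValidationError("ICC needs at least 2 measurement vectors")
    if n < 3:
        raise ValidationError("ICC needs at least 3 paired observations")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-targets
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise ValidationError("zero total variance: ICC undefined")
    if kind == "absolute":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if kind == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValidationError(f"unknown ICC kind {kind!r}")


def consistency_band(value: float) -> str:
    """Conventional qualitative band for an ICC value."""
    if not np.isfinite(value):
        raise ValidationError("ICC must be finite")
    if value >= 0.80:
        return "high"
    if value >= 0.60:
        return "moderate"
    if value >= 0.40:
        return "good"
    if value >= 0.10:
        return "poor"
    return "none"


def count_high_correlations(r_values: np.ndarray, threshold: float = HIGH_R_THRESHOLD) -> int:
    """Number of correlations at or above the threshold (default r >= 0.6)."""
    r_values = np.asarray(r_values, dtype=float)
    return int(np.sum(r_values >= threshold))


def normal_sample_moments(
    dataset: MultisiteDataset,
    feature: int,
    values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and variance of one IDP over the normal samples, per site and pooled.

    Normal samples are the rows whose subject-level ground-truth outlier flag
    is false; the variance uses ddof=1.
    """
    vals = dataset.values if values is None else np.asarray(values, dtype=float)
    normal = ~dataset.outlier_rows
    records = []
    for site in dataset.sites:
        sel = (dataset.site_labels == site) & normal
        if sel.sum() < 2:
            raise ValidationError(f"site {site} has < 2 normal rows")
        x = vals[sel, feature]
        records.append({"site": site, "mean": x.mean(), "var": x.var(ddof=1)})
    x = vals[normal, feature]
    records.append({"site": COMBINED_SITE, "mean": x.mean(), "var": x.var(ddof=1)})
    return pd.DataFrame.from_records(records).set_index("site")


@dataclass
class CellMetrics:
    """Metrics of one sweep-grid cell, per site/phase/harmonization mode."""

    scenario: Scenario
    quantity_fraction: float
    score: float
    lower_score: float | None
    #: rows: (site, phase, mode) -> dict of metric values
    records: list[dict] = field(default_factory=list)
    failed: bool = False
    failure_reason: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_records(self.records)
        df.insert(0, "scenario", self.scenario.value)
        df.insert(1, "quantity_fraction", self.quantity_fraction)
        df.insert(2, "score", self.score)
        df.insert(3, "lower_score",
                  np.nan if self.lower_score is None else float(self.lower_score))
        return df


@dataclass
class EvaluationReport:
    """All per-cell metrics of a sweep plus scenario-consistency ICC tables."""

    cells: list[CellMetrics] = field(default_factory=list)
    icc_tables: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if not self.cells:
            return pd.DataFrame()
        return pd.concat([c.to_frame() for c in self.cells], ignore_index=True)

    def cell_correlation_vector(
        self,
        scenario: Scenario,
        site: str,
        phase: str,
        metric: str = "pearson_r",
        mode: str = "naive",
    ) -> np.ndarray:
        """The grid-ordered vector of one correlation metric for one scenario."""
        df = self.to_frame()
        sel = (
            (df["scenario"] == Scenario(scenario).value)
            & (df["site"] == site)
            & (df["phase"] == phase)
            & (df["mode"] == mode)
        )
        sub = df[sel].sort_values(["quantity_fraction", "score", "lower_score"])
        return sub[metric].to_numpy()


def scenario_consistency_table(
    report: EvaluationReport,
    metric: str = "pearson_r",
    mode: str = "naive",
    icc_kind: str = "absolute",
) -> pd.DataFrame:
    """ICC of the per-scenario sweep correlation vectors across scenarios.

    Quantifies whether outlier *location* (unilateral vs bilateral vs
    different-sides) matters: for the one-site scenario pair (unilateral,
    bilateral) and the two-site scenario triple (unilateral, bilateral,
    different), the 35-long correlation vectors over the quantity x score grid
    are compared by ICC, per contaminated site and for the combined site,
    before and after harmonization.  The "one-site different" scenario is
    excluded (it differs in score, not only location).
    """
    groups = {
        "one_site": [Scenario.ONE_SITE_UNILATERAL, Scenario.ONE_SITE_BILATERAL],
        "two_site": [
            Scenario.TWO_SITE_UNILATERAL,
            Scenario.TWO_SITE_BILATERAL,
            Scenario.TWO_SITE_DIFFERENT,
        ],
    }
    df = report.to_frame()
    present = set(df["scenario"].unique())
    records = []
    for phase in ("before", "after"):
        for gname, scns in groups.items():
            if not all(s.value in present for s in scns):
                continue
            sites = ["Site 1", COMBINED_SITE] if gname == "one_site" else [
                "Site 1", "Site 2", COMBINED_SITE,
            ]
            for site in sites:
                vectors = [
                    report.cell_correlation_vector(s, site, phase, metric, mode)
                    for s in scns
                ]
                lengths = {len(v) for v in vectors}
                if len(lengths) != 1 or 0 in lengths:
                    raise ValidationError(
                        f"incomplete grid for {gname}/{site}/{phase}: lengths {lengths}"
                    )
                records.append(
                    {
                        "phase": phase,
                        "group": gname,
                        "site": site,
                        "metric": metric,
                        "icc": icc(*vectors, kind=icc_kind),
                        "n_cells": len(vectors[0]),
                    }
                )
    return pd.DataFrame.from_records(records)
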