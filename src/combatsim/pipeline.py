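"""Experiment orchestration: generate, inject, harmonize, evaluate, report.

Runs the full sweep — six outlier scenarios over a quantity x score grid —
against one normal multisite dataset per master seed.  Each grid cell gets a
stable sub-seed derived from (master_seed, scenario, quantity index, score
index), so any cell can be re-run in isolation and reproduce its row exactly.
Both the naive fit (all rows) and the robust fit-on-normals variant can be
run per cell; failed cells are recorded with a reason and never abort the
sweep.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from combatsim._errors import SchemaError, ValidationError
from combatsim.datasets import (
    DEFAULT_N_FEATURES,
    DEFAULT_N_PER_SITE,
    DEFAULT_N_SITES,
    DEFAULT_NOISE_VARIANCE,
    DEFAULT_TARGET_IDP,
    MultisiteDataset,
    make_default_dataset,
)
from combatsim.outliers import (
    DEFAULT_CLOUD_SD,
    DEFAULT_QUANTITIES,
    DEFAULT_SCORES,
    GridCell,
    Scenario,
    build_sweep_grid,
    detect_outliers,
    inject_outliers,
)
from combatsim.combat import harmonize
from combatsim.evaluation import (
    COMBINED_SITE,
    CellMetrics,
    EvaluationReport,
    all_feature_correlations,
    correlations_by_site,
    count_high_correlations,
    icc,
    normal_sample_moments,
    scenario_consistency_table,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "evaluate_normal_dataset",
    "cell_seed",
    "write_dataset",
    "read_dataset",
]

logger = logging.getLogger("combatsim")


def _pkg_version() -> str:
    import combatsim

    return combatsim.__version__


def cell_seed(master_seed: int, scenario: Scenario, q_index: int, s_index: int) -> int:
    """Stable sub-seed for one grid cell; independent of sweep order."""
    key = f"{master_seed}|{Scenario(scenario).value}|{q_index}|{s_index}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """All knobs of one study run; defaults reproduce the full design."""

    n_sites: int = DEFAULT_N_SITES
    n_per_site: int = DEFAULT_N_PER_SITE
    n_features: int = DEFAULT_N_FEATURES
    target_idp: int = DEFAULT_TARGET_IDP  # 0-based column index
    noise_variance: float = DEFAULT_NOISE_VARIANCE
    additive_shift_scale: float = 1.0
    multiplicative_scale_low: float = 0.7
    multiplicative_scale_high: float = 1.5
    hub_strength: float = 0.9
    scenarios: list[str] = field(default_factory=lambda: [s.value for s in Scenario])
    quantities: list[float] = field(default_factory=lambda: list(DEFAULT_QUANTITIES))
    scores: list[float] = field(default_factory=lambda: list(DEFAULT_SCORES))
    cloud_sd: float = DEFAULT_CLOUD_SD
    per_side: bool = False
    run_naive: bool = True
    run_robust: bool = True
    eb: bool = True
    master_seed: int = 0
    output_dir: str = "combatsim_out"
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not self.scenarios or not self.quantities or not self.scores:
            raise ValidationError("scenarios, quantities and scores must be non-empty")
        if not 0 <= self.target_idp < self.n_features:
            raise ValidationError("target_idp out of range")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def make_dataset(self) -> MultisiteDataset:
        return make_default_dataset(
            n_sites=self.n_sites,
            n_per_site=self.n_per_site,
            n_features=self.n_features,
            target_idp=self.target_idp,
            noise_variance=self.noise_variance,
            additive_shift_scale=self.additive_shift_scale,
            multiplicative_scale_range=(
                self.multiplicative_scale_low,
                self.multiplicative_scale_high,
            ),
            hub_strength=self.hub_strength,
            seed=self.master_seed,
        )


# ---------------------------------------------------------------------------
# dataset CSV schema


def _idp_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("IDP_")]


def write_dataset(dataset: MultisiteDataset, path, spec_info: dict | None = None) -> None:
    """Write the dataset CSV plus the 0/1 outlier-mask companion CSV.

    ``<path>`` holds subject_id, site, behavior and one column per IDP;
    ``<path stem>.mask.csv`` holds the same grid of 0/1 mask entries; an
    optional ``<path stem>.spec.json`` records injection provenance.
    """
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round-trip
    mask_df = pd.DataFrame(
        dataset.outlier_mask.astype(int), columns=_idp_columns(df)
    )
    mask_df.insert(0, "subject_id", dataset.subject_ids)
    mask_df.to_csv(path.with_suffix(".mask.csv"), index=False)
    if spec_info is not None:
        with open(path.with_suffix(".spec.json"), "w") as fh:
            json.dump(spec_info, fh, indent=2, sort_keys=True)


def read_dataset(path) -> MultisiteDataset:
    """Read a dataset CSV (and mask companion if present) back into memory."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("site", "behavior"):
        if col not in df.columns:
            raise SchemaError(f"dataset CSV lacks required column '{col}'")
    idp_cols = _idp_columns(df)
    if not idp_cols:
        raise SchemaError("dataset CSV has no IDP_* columns")
    values = df[idp_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("dataset CSV contains non-finite IDP values")
    behavior = df["behavior"].to_numpy(dtype=float)
    if np.all(np.isnan(behavior)):
        behavior = None
    mask = None
    mask_path = path.with_suffix(".mask.csv")
    if mask_path.exists():
        mdf = pd.read_csv(mask_path)
        if _idp_columns(mdf) != idp_cols or len(mdf) != len(df):
            raise ValidationError("outlier-mask companion does not match dataset shape")
        mask = mdf[idp_cols].to_numpy(dtype=int).astype(bool)
    return MultisiteDataset(
        values=values,
        site_labels=df["site"].to_numpy(dtype=object),
        behavior=behavior,
        outlier_mask=mask,
        subject_ids=[str(s) for s in df["subject_id"]],
    )


# ---------------------------------------------------------------------------
# evaluation of the outlier-free dataset


def evaluate_normal_dataset(
    dataset: MultisiteDataset, eb: bool = True
) -> tuple[dict, np.ndarray]:
    """Harmonization-effectiveness summary on the outlier-free dataset.

    Computes all-feature IDP-behavior correlations per site and combined,
    ICCs of those correlation vectors (site pairs, and each site vs the
    combined site), and high-correlation counts, before and after
    harmonization.  Returns the summary dict and the harmonized matrix.
    """
    harmonized, _ = harmonize(dataset.values, dataset.site_labels, eb=eb)
    summary: dict = {"phase": {}}
    for phase, vals in (("before", None), ("after", harmonized)):
        corr = all_feature_correlations(dataset, values=vals, kind="pearson")
        site_cols = [c for c in corr.columns if c != COMBINED_SITE]
        pair_iccs = {
            f"{a}|{b}": icc(corr[a], corr[b])
            for i, a in enumerate(site_cols)
            for b in site_cols[i + 1 :]
        }
        combined_iccs = {
            f"{a}|{COMBINED_SITE}": icc(corr[a], corr[COMBINED_SITE]) for a in site_cols
        }
        high = {c: count_high_correlations(corr[c]) for c in corr.columns}
        n_high_all_sites = count_high_correlations(corr[site_cols].min(axis=1))
        summary["phase"][phase] = {
            "median_within_site_r": float(corr[site_cols].median().median()),
            "median_combined_r": float(corr[COMBINED_SITE].median()),
            "icc_between_sites": pair_iccs,
            "icc_site_vs_combined": combined_iccs,
            "n_high_r": high,
            "n_high_r_all_sites": n_high_all_sites,
        }
    return summary, harmonized


# ---------------------------------------------------------------------------
# sweep


def _cell_records(
    injected: MultisiteDataset,
    target_idp: int,
    phase: str,
    mode: str,
    values: np.ndarray | None,
) -> list[dict]:
    moments = normal_sample_moments(injected, target_idp, values=values)
    corr_all = correlations_by_site(injected, target_idp, values=values)
    corr_norm = correlations_by_site(
        injected, target_idp, values=values, rows=~injected.outlier_rows
    )
    records = []
    for site in moments.index:
        records.append(
            {
                "site": site,
                "phase": phase,
                "mode": mode,
                "mean_normal": float(moments.loc[site, "mean"]),
                "var_normal": float(moments.loc[site, "var"]),
                "pearson_r": float(corr_all.loc[site, "pearson_r"]),
                "spearman_rho": float(corr_all.loc[site, "spearman_rho"]),
                "pearson_r_normal": float(corr_norm.loc[site, "pearson_r"]),
                "spearman_rho_normal": float(corr_norm.loc[site, "spearman_rho"]),
            }
        )
    return records


def evaluate_cell(
    dataset: MultisiteDataset,
    cell: GridCell,
    config: ExperimentConfig,
    seed: int,
) -> CellMetrics:
    """Inject one grid cell, harmonize (naive and/or robust), collect metrics."""
    metrics = CellMetrics(
        scenario=cell.scenario,
        quantity_fraction=cell.quantity_fraction,
        score=cell.score,
        lower_score=cell.lower_score,
    )
    spec = cell.to_spec(cloud_sd=config.cloud_sd, seed=seed, per_side=config.per_side)
    injected = inject_outliers(
        dataset, spec, target_idp=config.target_idp, noise_variance=config.noise_variance
    )
    n_injected = int(injected.outlier_rows.sum())
    detection = detect_outliers(injected)

    before = _cell_records(injected, config.target_idp, "before", "naive", None)
    for rec in before:
        rec["n_outliers_injected"] = n_injected
        rec["n_outliers_detected"] = detection.n_flagged_subjects
    modes = []
    if config.run_naive:
        modes.append(("naive", None))
    if config.run_robust:
        modes.append(("robust", detection.subject_flags))
    all_records = []
    for mode, exclude in modes:
        all_records.extend([{**r, "mode": mode} for r in before])
        harmonized, _ = harmonize(
            injected.values, injected.site_labels, eb=config.eb, exclude_mask=exclude
        )
        all_records.extend(
            _cell_records(injected, config.target_idp, "after", mode, harmonized)
        )
    metrics.records = all_records
    logger.info(
        "cell %s q=%g score=%g lower=%s seed=%d: injected=%d detected=%d",
        cell.scenario.value, cell.quantity_fraction, cell.score,
        cell.lower_score, seed, n_injected, detection.n_flagged_subjects,
    )
    return metrics


def run_experiment(config: ExperimentConfig) -> EvaluationReport:
    """Run the full study and write report files under ``config.output_dir``.

    Emits: ``report.csv`` (tidy, one row per cell x site x phase x mode),
    ``scenario_icc.csv`` (Table-1-style location-consistency ICCs),
    ``normal_summary.json`` (outlier-free effectiveness summary),
    ``manifest.json`` (config, seeds, version) and ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        dataset = config.make_dataset()
        logger.info(
            "normal dataset: %d sites x %d subjects x %d IDPs (master seed %d)",
            config.n_sites, config.n_per_site, config.n_features, config.master_seed,
        )
        normal_summary, harmonized_normal = evaluate_normal_dataset(dataset, eb=config.eb)

        # outlier-free reference row for the target IDP
        ref_records = _cell_records(dataset, config.target_idp, "before", "none", None)
        ref_records += _cell_records(
            dataset, config.target_idp, "after", "none", harmonized_normal
        )
        normal_summary["target_idp_reference"] = ref_records

        scenarios = [Scenario(s) for s in config.scenarios]
        cells = build_sweep_grid(
            scenarios, tuple(config.quantities), tuple(config.scores)
        )
        report = EvaluationReport()
        seeds = {}
        for cell in cells:
            qi = config.quantities.index(cell.quantity_fraction)
            swept = cell.lower_score if cell.scenario is Scenario.ONE_SITE_DIFFERENT else cell.score
            si = config.scores.index(swept)
            seed = cell_seed(config.master_seed, cell.scenario, qi, si)
            seeds[f"{cell.scenario.value}|{cell.quantity_fraction}|{swept}"] = seed
            try:
                metrics = evaluate_cell(dataset, cell, config, seed)
            except Exception as exc:  # failed cells never abort the sweep
                logger.warning("cell failed (%s): %s", cell, exc)
                metrics = CellMetrics(
                    scenario=cell.scenario,
                    quantity_fraction=cell.quantity_fraction,
                    score=cell.score,
                    lower_score=cell.lower_score,
                    failed=True,
                    failure_reason=f"{type(exc).__name__}: {exc}",
                )
            report.cells.append(metrics)

        tidy = report.to_frame()
        tidy.to_csv(out / "report.csv", index=False)

        icc_frames = []
        for metric in ("pearson_r", "spearman_rho"):
            try:
                icc_frames.append(scenario_consistency_table(report, metric=metric))
            except ValidationError as exc:
                logger.warning("scenario ICC table skipped for %s: %s", metric, exc)
        if icc_frames:
            icc_table = pd.concat(icc_frames, ignore_index=True)
            icc_table.to_csv(out / "scenario_icc.csv", index=False)
            report.icc_tables = {
                metric: df for metric, df in zip(("pearson_r", "spearman_rho"), icc_frames)
            }

        with open(out / "normal_summary.json", "w") as fh:
            json.dump(normal_summary, fh, indent=2, sort_keys=True)
        manifest = {
            "config": asdict(config),
            "cell_seeds": seeds,
            "n_cells": len(cells),
            "n_failed": sum(c.failed for c in report.cells),
            "version": _pkg_version(),
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if config.make_figures:
            _make_figures(dataset, harmonized_normal, tidy, out)
        logger.info("sweep complete: %d cells in %.1f s", len(cells), time.time() - t0)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def _make_figures(dataset, harmonized, tidy, out: Path) -> None:
    """Optional overview figures: density + PCA before/after, sweep lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from combatsim.evaluation import pca_first_two

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for row, (vals, label) in enumerate(
        [(dataset.values, "before"), (harmonized, "after")]
    ):
        ax = axes[row, 0]
        for site in dataset.sites:
            block = vals[dataset.site_labels == site]
            ax.hist(block.ravel(), bins=80, histtype="step", density=True, label=str(site))
        ax.set_title(f"IDP value density ({label})")
        ax.legend(fontsize=7)
        ax = axes[row, 1]
        scores = pca_first_two(vals)
        for site in dataset.sites:
            sel = dataset.site_labels == site
            ax.scatter(scores[sel, 0], scores[sel, 1], s=4, alpha=0.4, label=str(site))
        ax.set_title(f"first two PCs ({label})")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(out / "normal_overview.png", dpi=110)
    plt.close(fig)

    sub = tidy[(tidy["site"] == COMBINED_SITE) & (tidy["phase"] == "after")]
    if len(sub):
        fig, ax = plt.subplots(figsize=(7, 5))
        for (scn, q), grp in sub[sub["mode"] == "naive"].groupby(
            ["scenario", "quantity_fraction"]
        ):
            grp = grp.sort_values("score")
            ax.plot(grp["score"], grp["pearson_r"], alpha=0.6, label=f"{scn} q={q}")
        ax.set_xlabel("outlier score")
        ax.set_ylabel("combined-site Pearson r (after)")
        ax.legend(fontsize=5, ncol=2)
        fig.tight_layout()
        fig.savefig(out / "sweep_combined_r.png", dpi=110)
        plt.close(fig)
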