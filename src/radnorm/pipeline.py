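"""End-to-end experiment orchestration and reporting.

Two experiments quantify feature robustness on a cohort of (synthetic)
scans:

* the voxel-size experiment expands every subject into the original plus 10
  resampled data sets, extracts the feature panel at a fixed gray-level
  count (default 64) in non-normalized and voxel-normalized variants, and
  correlates each feature with the number of voxels N across all data sets
  (|Spearman r_s|);
* the gray-level experiment extracts the texture-feature panel from each
  original scan at every gray-level count in {8, 16, 32, 64, 128, 256}, in
  non-normalized and GL-normalized variants, and scores each feature's
  stability across gray levels with the two-way consistency ICC.

With the default 18-subject cohort and 8 phantom scans these produce
198, 88 and 108 data-set rows respectively.  Reports are written as CSV,
JSON (with a config echo) and paired bar charts (black = non-normalized,
gray = normalized).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discretize import discretize
from .features import (
    GL_PANEL,
    VOXEL_PANEL,
    FeatureRecord,
    apply_gl_normalization,
    apply_voxel_normalization,
    extract_features,
    features_from_discretized,
)
from .resample import ResamplingGrid, expand_grid
from .stats import RobustnessReport, categorize_icc, categorize_rs, icc, spearman_abs
from .synthetic import CohortSpec, Subject, generate_phantom_scans, generate_tumor_cohort
from .volume import extract_voi

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_voxel_experiment",
    "run_gl_experiment",
    "run_experiment",
    "write_report",
]

logger = logging.getLogger("radnorm")

_META_COLUMNS = [
    "subject", "dataset", "variant", "pixel_size", "slice_thickness",
    "n_gray_levels", "n_voxels", "voi_volume",
]


def _is_power_of_two(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the voxel-size and gray-level experiments."""

    mode: str = "both"                       # voxel | gl | both
    cohort: CohortSpec = field(default_factory=CohortSpec)
    grid: ResamplingGrid = field(default_factory=ResamplingGrid)
    gl_levels: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    d_voxel: int = 64
    include_phantom: bool = True
    n_scanners: int = 8
    outdir: str | None = None
    seed: int | None = None                  # overrides cohort.seed when set

    def __post_init__(self) -> None:
        if self.mode not in ("voxel", "gl", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        levels = tuple(int(d) for d in self.gl_levels)
        if not levels:
            raise ValueError("gl_levels must be nonempty")
        for d in levels:
            if not (_is_power_of_two(d) and 8 <= d <= 256):
                raise ValueError(f"gray-level counts must be powers of two in [8, 256], got {d}")
        object.__setattr__(self, "gl_levels", levels)

    def effective_cohort(self) -> CohortSpec:
        if self.seed is None:
            return self.cohort
        return dataclasses.replace(self.cohort, seed=self.seed)


@dataclass
class ExperimentResult:
    """Feature table plus robustness report for one experiment arm."""

    name: str
    features: pd.DataFrame
    report: RobustnessReport

    @property
    def n_datasets(self) -> int:
        """Number of distinct data sets (non-normalized rows)."""
        return int((self.features.variant == "non_normalized").sum())


def _record_row(record: FeatureRecord, dataset: str) -> dict:
    row = {
        "subject": record.subject,
        "dataset": dataset,
        "variant": record.variant,
        "pixel_size": record.pixel_size,
        "slice_thickness": record.slice_thickness,
        "n_gray_levels": record.n_gray_levels,
        "n_voxels": record.n_voxels,
        "voi_volume": record.n_voxels * record.pixel_size ** 2 * record.slice_thickness,
    }
    row.update(record.values)
    return row


def run_voxel_experiment(config: ExperimentConfig,
                         subjects: list[Subject] | None = None,
                         name: str = "voxel") -> ExperimentResult:
    """Voxel-size robustness experiment over the resampling design.

    Expands every subject into the original plus resampled data sets,
    extracts the 24 features at ``config.d_voxel`` gray levels, applies the
    voxel-count normalization, and correlates each 10-panel feature with N
    across all data sets in both variants.
    """
    t0 = time.time()
    if subjects is None:
        subjects = generate_tumor_cohort(config.effective_cohort())
    rows: list[dict] = []
    for s in subjects:
        for ds in expand_grid(s.volume, s.mask, config.grid):
            rec = extract_features(ds.volume, ds.mask, d=config.d_voxel, subject=s.subject_id)
            rows.append(_record_row(rec, ds.label))
            rows.append(_record_row(apply_voxel_normalization(rec), ds.label))
    df = pd.DataFrame(rows)
    n_sets = int((df.variant == "non_normalized").sum())
    logger.info("voxel experiment [%s]: %d subjects, %d data sets, extraction %.1f s",
                name, len(subjects), n_sets, time.time() - t0)

    report_rows: list[dict] = []
    for variant in ("non_normalized", "voxel_normalized"):
        sub = df[df.variant == variant]
        if len(sub) < 4:
            raise ValueError(
                f"insufficient data for correlation: {len(sub)} data sets (need >= 4)"
            )
        for feat in VOXEL_PANEL:
            res = spearman_abs(sub["n_voxels"].to_numpy(), sub[feat].to_numpy())
            report_rows.append({
                "feature": feat, "variant": variant, "statistic": "spearman_abs",
                "value": res.abs_rs, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "category": categorize_rs(res.abs_rs), "n": res.n,
            })
    return ExperimentResult(name=name, features=df, report=RobustnessReport(report_rows))


def run_gl_experiment(config: ExperimentConfig,
                      subjects: list[Subject] | None = None,
                      name: str = "gl") -> ExperimentResult:
    """Gray-level robustness experiment across discretization levels.

    Extracts the features from each original scan at every gray-level count,
    applies the gray-level normalization, assembles a subjects x levels
    matrix per feature and scores it with the consistency ICC in both
    variants.
    """
    if len(config.gl_levels) < 2:
        raise ValueError("ICC undefined: need at least 2 gray-level counts")
    t0 = time.time()
    if subjects is None:
        subjects = generate_tumor_cohort(config.effective_cohort())
    rows: list[dict] = []
    for s in subjects:
        voi = extract_voi(s.volume, s.mask)
        for d in config.gl_levels:
            dvoi = discretize(voi, d)
            values = features_from_discretized(voi, dvoi)
            rec = FeatureRecord(
                subject=s.subject_id, variant="non_normalized",
                pixel_size=s.volume.pixel_size,
                slice_thickness=s.volume.slice_thickness,
                n_gray_levels=d, n_voxels=voi.n_voxels, values=values,
            )
            rows.append(_record_row(rec, f"GL{d}"))
            rows.append(_record_row(apply_gl_normalization(rec), f"GL{d}"))
    df = pd.DataFrame(rows)
    n_sets = int((df.variant == "non_normalized").sum())
    logger.info("gl experiment [%s]: %d subjects x %d levels = %d data sets, %.1f s",
                name, len(subjects), len(config.gl_levels), n_sets, time.time() - t0)

    report_rows: list[dict] = []
    for variant in ("non_normalized", "gl_normalized"):
        sub = df[df.variant == variant]
        for feat in GL_PANEL:
            table = sub.pivot(index="subject", columns="n_gray_levels", values=feat)
            table = table[list(config.gl_levels)]
            res = icc(table.to_numpy())
            report_rows.append({
                "feature": feat, "variant": variant, "statistic": "icc",
                "value": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "category": categorize_icc(res.icc),
                "n": res.n_subjects * res.n_levels,
            })
    return ExperimentResult(name=name, features=df, report=RobustnessReport(report_rows))


def run_experiment(config: ExperimentConfig) -> dict[str, ExperimentResult]:
    """Run the configured arms; cohort and phantom share the config seed.

    Returns a dict keyed by arm name ("voxel", "voxel_phantom", "gl").
    Writes reports when ``config.outdir`` is set.
    """
    results: dict[str, ExperimentResult] = {}
    if config.mode in ("voxel", "both"):
        results["voxel"] = run_voxel_experiment(config)
        if config.include_phantom:
            seed = config.seed if config.seed is not None else config.cohort.seed
            phantom = generate_phantom_scans(n_scanners=config.n_scanners, seed=seed + 1)
            results["voxel_phantom"] = run_voxel_experiment(
                config, subjects=phantom, name="voxel_phantom"
            )
    if config.mode in ("gl", "both"):
        results["gl"] = run_gl_experiment(config)
    if config.outdir is not None:
        write_report(results, config.outdir, config)
    return results


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"]) if d["outdir"] is not None else None
    return d


def _plot_report(report: RobustnessReport, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.table
    variants = list(dict.fromkeys(table.variant))
    raw = table[table.variant == variants[0]].set_index("feature")
    norm = table[table.variant == variants[1]].set_index("feature") if len(variants) > 1 else None
    feats = list(raw.index)
    x = np.arange(len(feats))
    width = 0.4
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(feats)), 4))
    ax.bar(x - width / 2, raw.value.abs(), width, color="black", label=variants[0])
    if norm is not None:
        ax.bar(x + width / 2, norm.value.abs(), width, color="0.6", label=variants[1])
    stat = raw.statistic.iloc[0]
    ax.set_ylabel("|r_s|" if stat == "spearman_abs" else "ICC")
    ax.set_xticks(x)
    ax.set_xticklabels(feats, rotation=60, ha="right", fontsize=8)
    ax.legend(fontsize=8)
    ax.set_title(f"{title} (synthetic data)", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(results: dict[str, ExperimentResult], outdir: str | Path,
                 config: ExperimentConfig) -> list[Path]:
    """Write feature tables, robustness CSV/JSON, a config echo and plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    cfg = _config_dict(config)
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    paths.append(cfg_path)

    payload = {"config": cfg, "results": {}}
    for name, result in results.items():
        fpath = outdir / f"features_{name}.csv"
        result.features.to_csv(fpath, index=False)
        paths.append(fpath)
        rpath = outdir / f"robustness_{name}.csv"
        result.report.to_csv(rpath)
        paths.append(rpath)
        ppath = outdir / f"robustness_{name}.png"
        _plot_report(result.report, ppath, f"Feature robustness: {name}")
        paths.append(ppath)
        payload["results"][name] = {
            "n_datasets": result.n_datasets,
            "robustness": result.report.to_records(),
        }
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(payload, indent=2))
    paths.append(jpath)
    return paths
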