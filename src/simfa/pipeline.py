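"""End-to-end orchestration: simulate -> group stats -> factor fit ->
bootstrap inference -> classification, with reproducible, provenance-stamped
table outputs.

One global seed is fanned out deterministically to the stages; re-running
with an identical config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import modality_comparison
from .data_model import (
    DataModelError,
    MultiModalDataset,
    standardize_dataset,
)
from .group_stats import demographics_table, group_difference_table
from .inference import bootstrap_coefficients, significant_factor_report
from .sifa import (
    SIFARanks,
    em_fit,
    select_ranks_lcv,
    sparsify_loadings,
    variance_explained,
)
from .synthetic import SimulationConfig, simulate_sifa_dataset

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (
    ("HC", "S_FEP"),
    ("HC", "M_FEP"),
    ("S_FEP", "M_FEP"),
)


@dataclass
class PipelineConfig:
    """Single-document configuration for a full run (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "results"
    # simulation (the packaged data source; reduced dimensions by default)
    simulation: dict = field(
        default_factory=lambda: {
            "n": 150,
            "p": (40, 20, 20, 60),
            "r0": 2,
            "r": (1, 1, 1, 1),
            "snr": 2.0,
            "group_beta": 1.0,
        }
    )
    contrasts: tuple = DEFAULT_CONTRASTS
    q_level: float = 0.05
    standardize: bool = True
    # SIFA settings
    ranks: dict | None = None  # {"r0": int, "r": [ints]}; None -> LCV
    lcv: dict = field(
        default_factory=lambda: {"r0_grid": (0, 1, 2, 3), "rk_grid": (0, 1, 2),
                                 "n_folds": 5}
    )
    sparsify: str | float = "cv"
    # bootstrap
    n_boot: int = 200
    ci_level: float = 0.95
    # classification
    classifiers: tuple = ("logistic", "svm-linear", "svm-poly", "svm-radial")
    classify_mode: str = "transductive"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig, ds: MultiModalDataset | None = None
) -> dict:
    """Execute every stage in order and write the report tables.

    Returns a dict of in-memory results; files land under ``config.out_dir``:
    demographics, per-contrast group-difference tables, factor loading
    tables, coefficient CI table, variance-explained table, and the
    classification AUC grid, plus ``run_info.json`` with provenance.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    results: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()
        return name

    try:
        stage("simulate")
        if ds is None:
            sim = SimulationConfig(**config.simulation, seed=seed)
            ds, truth = simulate_sifa_dataset(sim)
            results["truth"] = truth
            demo = truth.demographics
        else:
            demo = None
        timings["simulate"] = time.time() - timings["simulate"]

        stage("demographics")
        if demo is not None:
            present = set(ds.covariates.group_labels)
            contrasts = [c for c in config.contrasts
                         if c[0] in present and c[1] in present]
            demo_tab = demographics_table(demo, contrasts)
            _write(demo_tab, out / "table_demographics.csv")
            results["demographics"] = demo_tab
        else:
            contrasts = list(config.contrasts)
        timings["demographics"] = time.time() - timings["demographics"]

        stage("group_stats")
        sds = standardize_dataset(ds) if config.standardize else ds
        gd_frames = []
        for contrast in contrasts:
            for blk in ds.blocks:
                tab = group_difference_table(
                    ds, contrast, blk.modality, q_level=config.q_level
                )
                t = tab.table.copy()
                t.insert(0, "modality", blk.modality)
                t.insert(0, "contrast", f"{contrast[0]} vs {contrast[1]}")
                gd_frames.append(t)
        group_diff = pd.concat(gd_frames, ignore_index=True)
        _write(group_diff, out / "table_group_differences.csv")
        results["group_differences"] = group_diff
        timings["group_stats"] = time.time() - timings["group_stats"]

        stage("fit")
        if config.ranks is not None:
            ranks = SIFARanks(config.ranks["r0"], tuple(config.ranks["r"]))
            lcv_table = None
        else:
            ranks, lcv_table = select_ranks_lcv(
                sds, seed=seed + 1, **config.lcv
            )
            _write(lcv_table, out / "table_lcv_ranks.csv")
        fit = em_fit(sds, ranks, seed=seed + 2)
        fit = sparsify_loadings(fit, sds, penalty=config.sparsify, seed=seed + 3)
        ve = variance_explained(fit, sds)
        _write(ve, out / "table_variance_explained.csv")
        loading_rows = []
        for k, blk in enumerate(sds.blocks):
            for j in range(ranks.r0):
                col = fit.model.V0k[k][:, j]
                for i in np.flatnonzero(col != 0.0):
                    loading_rows.append(
                        {"factor": f"joint{j + 1}", "modality": blk.modality,
                         "feature": blk.feature_names[i], "loading": col[i]}
                    )
        loadings = pd.DataFrame(
            loading_rows, columns=["factor", "modality", "feature", "loading"]
        )
        _write(loadings, out / "table_joint_loadings.csv")
        results.update(fit=fit, ranks=ranks, lcv=lcv_table,
                       variance_explained=ve, loadings=loadings)
        timings["fit"] = time.time() - timings["fit"]

        stage("infer")
        boot, _ = bootstrap_coefficients(
            sds, ranks, point_fit=fit, n_boot=config.n_boot,
            level=config.ci_level, seed=seed + 4,
        )
        _write(boot.ci, out / "table_coefficient_ci.csv")
        report = significant_factor_report(boot, fit, sds)
        _write(report, out / "table_significant_factors.csv")
        results.update(bootstrap=boot, factor_report=report)
        timings["infer"] = time.time() - timings["infer"]

        stage("classify")
        grids = []
        for contrast in contrasts:
            grid, _ = modality_comparison(
                sds, ranks, contrast, classifiers=config.classifiers,
                mode=config.classify_mode, seed=seed + 5,
            )
            grid.insert(0, "contrast", f"{contrast[0]} vs {contrast[1]}")
            grids.append(grid)
        auc_grid = pd.concat(grids, ignore_index=True)
        _write(auc_grid, out / "table_classification_auc.csv")
        results["classification"] = auc_grid
        timings["classify"] = time.time() - timings["classify"]
    except Exception as exc:
        failed = [k for k, v in timings.items() if not isinstance(v, float)]
        stage_name = failed[-1] if failed else "unknown"
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    info = {
        "config_digest": config.digest(),
        "seed": seed,
        "simfa_version": __version__,
        "elapsed_s": round(time.time() - t_start, 2),
        "stage_seconds": {k: round(v, 2) for k, v in timings.items()},
        "tables": sorted(p.name for p in out.glob("table_*.csv")),
    }
    with open(out / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    results["run_info"] = info
    return results
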