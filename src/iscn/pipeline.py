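"""One-command orchestration: simulate/ingest -> build -> metrics -> stats.

Every run writes a ``manifest.json`` capturing the configuration, seed,
package and library versions, and the FDR family sizes actually used, so a
rerun with the same configuration and seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import destrieux_registry
from .cohort import CohortTable
from .errors import ISCNError
from .io import (
    read_cohort,
    write_cohort,
    write_comparison_table,
    write_correlation_table,
    write_json,
    write_matrix,
    write_reference,
)
from .metrics import metrics_tables
from .network import build_cohort_scns
from .simulate import GROUP_A, GROUP_B, SimulationConfig, simulate_cohort
from .stats import compare_global, compare_nodal, correlation_screen

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Default per-group covariate sets for the correlation screen: medication
#: and illness duration are partialled out in patient groups only.
DEFAULT_SCREEN_COVARIATES = {
    GROUP_A: ["medication_dose", "illness_duration"],
    GROUP_B: ["medication_dose", "illness_duration"],
}


@dataclass
class RunConfig:
    out_dir: str | Path = "iscn_run"
    # either a simulation config ...
    simulation: SimulationConfig | None = None
    # ... or input files
    thickness_path: str | Path | None = None
    metadata_path: str | Path | None = None
    seed: int = 0
    group_covariate: str = "premorbid_iq"
    screen_covariates: dict[str, list[str]] = field(
        default_factory=lambda: {g: list(c) for g, c in DEFAULT_SCREEN_COVARIATES.items()}
    )
    alpha: float = 0.05
    n_boot: int = 5000
    normalization: str = "two_stage"
    reference_scoring: str = "leave_one_out"
    write_matrices: bool = True

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.thickness_path is not None or self.metadata_path is not None
        if has_sim == has_files:
            raise ISCNError(
                "config must specify exactly one of: a simulation block, "
                "or thickness/metadata paths"
            )
        if has_files and (self.thickness_path is None or self.metadata_path is None):
            raise ISCNError("both thickness_path and metadata_path are required")

    def to_jsonable(self) -> dict:
        """Config as JSON-safe dict; excludes out_dir so that the manifest
        (and its config hash) depends only on what was computed, not where
        it was written."""
        d = dataclasses.asdict(self)
        del d["out_dir"]
        if self.thickness_path is not None:
            d["thickness_path"] = str(self.thickness_path)
        if self.metadata_path is not None:
            d["metadata_path"] = str(self.metadata_path)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["affected_regions"] = {
                g: (v if isinstance(v, (str, int)) else [int(i) for i in v])
                for g, v in sim["affected_regions"].items()
            }
            d["simulation"] = sim
        return d


@dataclass
class PipelineResult:
    cohort: CohortTable
    global_metrics: pd.DataFrame
    nodal_metrics: pd.DataFrame
    global_comparison: list
    nodal_comparison: list
    correlations: list
    manifest: dict
    out_dir: Path


def _stage(name: str):
    logger.info("stage %s", name)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = destrieux_registry()

    _stage("1-ingest")
    try:
        if config.simulation is not None:
            sim = simulate_cohort(config.simulation)
            cohort = sim.cohort
            atlas = cohort.atlas
            write_cohort(cohort, out / "thickness.tsv", out / "metadata.tsv")
        else:
            cohort = read_cohort(config.thickness_path, config.metadata_path, atlas)
    except ISCNError as exc:
        raise ISCNError(f"stage 1-ingest: {exc}") from exc

    _stage("2-build")
    try:
        matrices, reference = build_cohort_scns(
            cohort,
            normalization=config.normalization,
            reference_scoring=config.reference_scoring,
        )
        write_reference(reference, atlas, out / "reference_model.tsv")
        if config.write_matrices:
            mat_dir = out / "matrices"
            mat_dir.mkdir(exist_ok=True)
            for m in matrices:
                write_matrix(m, mat_dir / f"{m.subject_id}.tsv")
    except ISCNError as exc:
        raise ISCNError(f"stage 2-build: {exc}") from exc

    _stage("3-metrics")
    try:
        global_df, nodal_df = metrics_tables(matrices)
        global_df.index.name = "subject_id"
        nodal_df.index.name = "subject_id"
        global_df.to_csv(out / "metrics.tsv", sep="\t", float_format="%.17g")
        nodal_df.to_csv(out / "nodal.tsv", sep="\t", float_format="%.17g")
    except ISCNError as exc:
        raise ISCNError(f"stage 3-metrics: {exc}") from exc

    _stage("4-stats")
    try:
        groups = cohort.groups
        covariate = cohort.covariate_vector(config.group_covariate)
        if not np.isfinite(covariate).all():
            raise ISCNError(
                f"covariate {config.group_covariate!r} has missing values"
            )
        global_results = compare_global(global_df, groups, covariate, config.alpha)
        nodal_results, excluded = compare_nodal(
            nodal_df, groups, covariate, config.alpha
        )
        sig_regions = [
            r.index_name for r in nodal_results if r.p_fdr is not None and r.p_fdr < config.alpha
        ]
        screen_indices = pd.concat(
            [global_df, nodal_df[sig_regions]], axis=1
        )
        meta = cohort.metadata_frame()
        score_cols = [
            c
            for c in meta.columns
            if c != "group"
            and c not in covariateset(config)
            and pd.api.types.is_numeric_dtype(meta[c])
        ]
        correlations = correlation_screen(
            screen_indices,
            meta[score_cols],
            groups,
            config.screen_covariates,
            covariate_table=meta,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        write_comparison_table(global_results, out / "global_comparison.tsv")
        write_comparison_table(nodal_results, out / "nodal_comparison.tsv")
        write_correlation_table(correlations, out / "correlations.tsv")
    except ISCNError as exc:
        raise ISCNError(f"stage 4-stats: {exc}") from exc

    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "iscn_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_subjects": len(cohort),
        "n_regions": atlas.n_regions,
        "fdr_family_sizes": {
            "global": len(global_results),
            "nodal": len(nodal_results),
        },
        "excluded_regions": excluded,
        "fdr_significant_global": [
            r.index_name for r in global_results if r.p_fdr < config.alpha
        ],
        "fdr_significant_nodal": sig_regions,
        "n_boot": config.n_boot,
    }
    write_json(manifest, out / "manifest.json")
    return PipelineResult(
        cohort=cohort,
        global_metrics=global_df,
        nodal_metrics=nodal_df,
        global_comparison=global_results,
        nodal_comparison=nodal_results,
        correlations=correlations,
        manifest=manifest,
        out_dir=out,
    )


def covariateset(config: RunConfig) -> set[str]:
    names = {config.group_covariate}
    for cols in config.screen_covariates.values():
        names.update(cols)
    return names
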