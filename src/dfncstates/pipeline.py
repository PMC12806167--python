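"""End-to-end orchestration: exclusion -> denoise -> dFNC -> states -> metrics -> inference.

A single master seed deterministically derives every stage's seed, so two
invocations with the same configuration and inputs produce identical
results tables.  High-motion subjects (mean framewise displacement
strictly above the threshold, default 0.3 mm) are excluded before any
estimation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .connectivity import FNCConfig, estimate_run_fnc, regress_covariates
from .containers import CONDITIONS, StateSequence
from .denoise import DenoiseConfig, denoise_run
from .inference import InferenceConfig, InferenceResults, run_full_inference
from .metrics import metrics_table
from .simulate import Cohort, CohortConfig, simulate_cohort
from .states import (
    ClusterQuality,
    StateModel,
    assign_windows,
    elbow_select_k,
    kmeans_manhattan,
    labels_to_sequences,
    pool_windows,
    select_exemplars,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic stage seed: pure function of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; defaults match the emulated study design."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    fnc: FNCConfig = field(default_factory=FNCConfig)
    k: int | None = 4
    k_range: list[int] | None = None
    cluster_replicates: int = 500
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    fd_exclusion_mm: float = 0.3
    master_seed: int = 0
    apply_denoise: bool = True
    apply_covariate_regression: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                if key == "cohort" and "n_per_cell" in value:
                    value["n_per_cell"] = {
                        tuple(k.split("/")): v for k, v in value["n_per_cell"].items()
                    }
                setattr(cfg, key, dataclasses.replace(current, **value))
            else:
                setattr(cfg, key, value)
        return cfg


@dataclass
class ResultsBundle:
    config: dict
    seeds: dict
    metadata: pd.DataFrame
    exclusions: pd.DataFrame
    lambda_by_run: pd.DataFrame
    state_model: StateModel
    quality: ClusterQuality | None
    sequences: list[StateSequence]
    metrics: pd.DataFrame
    inference: InferenceResults


def exclude_high_motion(
    metadata: pd.DataFrame, threshold_mm: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects whose mean FD strictly exceeds the threshold (boundary retained)."""
    if "mean_fd" not in metadata.columns:
        raise ValueError("metadata missing mean_fd column")
    excluded = metadata[metadata["mean_fd"] > threshold_mm].copy()
    retained = metadata[metadata["mean_fd"] <= threshold_mm].copy()
    if len(excluded):
        per_group = excluded.groupby("group").size().to_dict() if "group" in excluded else {}
        logger.info(
            "excluded %d subjects with mean FD > %.3g mm (%s)",
            len(excluded),
            threshold_mm,
            per_group,
        )
    return retained, excluded


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    cohort: Cohort | None = None,
) -> ResultsBundle:
    """Run the whole analysis on a (simulated or supplied) cohort.

    Stage seeds derive from ``config.master_seed``; with ``out_dir`` set,
    every intermediate table is persisted as delimited text (arrays as
    ``.npz`` with JSON sidecars).
    """
    config = config or PipelineConfig()
    seeds = {name: stage_seed(config.master_seed, name) for name in
             ("simulate", "cluster", "inference")}
    if cohort is None:
        cohort = simulate_cohort(config.cohort, seed=seeds["simulate"])
    metadata = cohort.metadata()
    retained_meta, excluded = exclude_high_motion(metadata, config.fd_exclusion_mm)
    retained_ids = set(retained_meta["subject_id"])
    subjects = [s for s in cohort.subjects if s.subject_id in retained_ids]

    wfncs_by_condition: dict[str, list] = {c: [] for c in CONDITIONS}
    lam_rows = []
    for subject in subjects:
        for cond, tc in subject.runs.items():
            if config.apply_denoise:
                tc, _ = denoise_run(tc, None, config.denoise)
            wfnc = estimate_run_fnc(tc, config.fnc)
            wfncs_by_condition[cond].append(wfnc)
            lam_rows.append(
                {"subject_id": subject.subject_id, "condition": cond, "lambda": wfnc.lambda_used}
            )
    if config.apply_covariate_regression:
        for cond in CONDITIONS:
            if wfncs_by_condition[cond]:
                wfncs_by_condition[cond] = regress_covariates(
                    wfncs_by_condition[cond], retained_meta
                )
    all_wfncs = [w for cond in CONDITIONS for w in wfncs_by_condition[cond]]

    exemplars = select_exemplars(all_wfncs)
    pooled = pool_windows(all_wfncs)
    quality: ClusterQuality | None = None
    if config.k_range is not None:
        quality = elbow_select_k(
            exemplars.vectors,
            config.k_range,
            seed=seeds["cluster"],
            n_replicates=config.cluster_replicates,
        )
        k = quality.chosen_k
        exemplar_model = quality.models[k]
    else:
        if config.k is None:
            raise ValueError("config must set k or k_range")
        k = config.k
        exemplar_model = kmeans_manhattan(
            exemplars.vectors, k, n_replicates=config.cluster_replicates, seed=seeds["cluster"]
        )
    model, labels = assign_windows(exemplar_model, pooled.vectors)
    sequences = labels_to_sequences(labels, pooled.provenance)
    mtable = metrics_table(
        sequences, k, tr_seconds=cohort.config.tr_seconds, step=config.fnc.step
    )
    inf_config = dataclasses.replace(config.inference, seed=seeds["inference"])
    inference = run_full_inference(mtable, retained_meta, inf_config)

    bundle = ResultsBundle(
        config=config.to_dict(),
        seeds=seeds,
        metadata=retained_meta,
        exclusions=excluded,
        lambda_by_run=pd.DataFrame(lam_rows),
        state_model=model,
        quality=quality,
        sequences=sequences,
        metrics=mtable,
        inference=inference,
    )
    if out_dir is not None:
        persist_bundle(bundle, all_wfncs, out_dir)
    return bundle


def persist_bundle(bundle: ResultsBundle, wfncs, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dict(bundle.config)
    cohort_cfg = cfg.get("cohort", {})
    if isinstance(cohort_cfg.get("n_per_cell"), dict):
        cohort_cfg["n_per_cell"] = {"/".join(k): v for k, v in cohort_cfg["n_per_cell"].items()}
    (out_dir / "config_snapshot.yaml").write_text(
        yaml.safe_dump({"config": _yaml_safe(cfg), "seeds": bundle.seeds})
    )
    dio.write_table(bundle.metadata, out_dir / "metadata_retained.tsv")
    dio.write_table(bundle.exclusions, out_dir / "exclusion_log.tsv")
    dio.write_table(bundle.lambda_by_run, out_dir / "lambda_by_run.tsv")
    dio.write_table(bundle.metrics, out_dir / "temporal_metrics.tsv")
    dio.write_table(bundle.inference.results, out_dir / "inference_results.tsv")
    (out_dir / "report.txt").write_text(bundle.inference.report + "\n")
    dio.write_sequences(bundle.sequences, out_dir / "state_sequences.tsv")
    for s in range(bundle.state_model.k):
        np.savetxt(
            out_dir / f"state_{s + 1}_centroid_edges.tsv",
            bundle.state_model.centroids[s][None, :],
            delimiter="\t",
        )
    if bundle.quality is not None:
        dio.write_table(
            pd.DataFrame(
                {
                    "k": bundle.quality.k_candidates,
                    "validity_index": bundle.quality.validity_index,
                }
            ),
            out_dir / "cluster_quality.tsv",
        )
    fnc_dir = out_dir / "windowed_fnc"
    for w in wfncs:
        dio.write_wfnc(w, fnc_dir)
    return out_dir


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
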