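"""End-to-end orchestration: generate or ingest a cohort, preprocess,
extract features, compare scenes, build coherence summaries, discover
subgroups and write a report bundle.

Every run writes a manifest carrying the seed, the full parameter set and
a configuration hash; two runs with equal hashes and seeds produce equal
machine-readable outputs.  The feature-extraction stage is cached on disk
keyed by the config hash, since spectral features and especially the
surrogate-masked coherence matrices dominate runtime.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coherence import (
    ANALYSIS_BAND,
    coherence_matrix,
    group_mean_and_deviation,
    plot_coherence_heatmap,
)
from .compare import build_comparison_table
from .features import features_table
from .io_formats import (
    read_actions_csv,
    read_edf,
    reject_noisy_segments,
    select_channels,
)
from .subgroups import build_vectors, select_clustering, subgroup_reports
from .synthetic import CohortConfig, CohortRecord, SceneSpec, generate_cohort

logger = logging.getLogger("vrphobia")

__all__ = ["PipelineConfig", "validate_config", "config_hash", "run_pipeline"]

_ALLOWED_KEYS = {
    "mode", "input_dir", "out_dir", "seed", "cohort",
    "surrogate_count", "alpha_level", "coherence_band",
    "noise_threshold", "min_clean_fraction", "include_iha",
    "include_hurst", "k_values", "verbosity",
}


@dataclass
class PipelineConfig:
    """Validated, normalized configuration of one pipeline run."""

    mode: str = "synthetic"                  # "synthetic" | "files"
    input_dir: str | None = None             # files mode: manifest.csv directory
    out_dir: str = "vrphobia_out"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    surrogate_count: int = 100
    alpha_level: float = 0.05
    coherence_band: tuple[float, float] = ANALYSIS_BAND
    noise_threshold: float = 200.0           # µV
    min_clean_fraction: float = 0.5
    include_iha: bool = False                # extend clustering vectors with IHA
    include_hurst: bool = True
    k_values: tuple[int, ...] = (2, 3)
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        if not 0 <= self.min_clean_fraction <= 1:
            raise ValueError("min_clean_fraction must be in [0, 1]")
        if self.noise_threshold <= 0:
            raise ValueError("noise_threshold must be positive")
        if not all(k >= 2 for k in self.k_values):
            raise ValueError("cluster counts must be >= 2")
        self.k_values = tuple(self.k_values)
        self.coherence_band = tuple(self.coherence_band)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d


def validate_config(source) -> PipelineConfig:
    """Parse and normalize a config from YAML/JSON path, mapping or
    PipelineConfig; unknown keys and out-of-range values raise.  The
    operation is idempotent: normalizing a normalized config is a no-op."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        import yaml

        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
    else:
        raw = dict(source or {})
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cohort_raw = raw.pop("cohort", {})
    if isinstance(cohort_raw, CohortConfig):
        cohort = cohort_raw
    else:
        cohort_raw = dict(cohort_raw)
        scenes = cohort_raw.pop("scenes", None)
        if scenes is not None:
            cohort_raw["scenes"] = tuple(
                s if isinstance(s, SceneSpec) else SceneSpec(**s) for s in scenes
            )
        cohort = CohortConfig(**cohort_raw)
    return PipelineConfig(cohort=cohort, **raw)


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the scientific parameters (output paths excluded)."""
    payload = config.to_dict()
    payload.pop("out_dir", None)
    payload.pop("verbosity", None)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_file_cohort(input_dir: Path) -> list[CohortRecord]:
    manifest = input_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"cohort manifest not found: {manifest}")
    rows = pd.read_csv(manifest)
    records = []
    for _, row in rows.iterrows():
        edf_path = input_dir / str(row["edf_path"]) if row.get("edf_path") else None
        if edf_path is not None and not edf_path.exists():
            raise FileNotFoundError(f"EDF file missing: {edf_path}")
        actions = read_actions_csv(input_dir / str(row["actions_path"]))
        scene = SceneSpec(
            scene_id=int(row["scene_id"]),
            exercise=str(row["exercise"]),
            environment=str(row["environment"]),
            n_actions=max(1, actions.n_actions),
        )
        eeg = read_edf(edf_path) if edf_path is not None else None
        records.append(CohortRecord(
            participant_id=str(row["participant_id"]),
            scene=scene, eeg=eeg, actions=actions,
            abnormal=bool(row.get("abnormal", 0)),
        ))
    return records


@dataclass
class PipelineResult:
    out_dir: Path
    features: pd.DataFrame
    manifest: dict
    rejected_records: list[str]


def _stage(name):
    """Log a stage boundary with timing; failures abort with the stage name."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                return False
            logger.info("stage %s: done in %.1fs", name, dt)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig | dict | str | Path) -> PipelineResult:
    """Execute the full experimental design and write the report bundle.

    Outputs under ``out_dir``: the tidy features table, per-exercise scene
    comparison tables (CSV/Markdown/JSON), per-scene mean coherence
    matrices (CSV + PNG heatmaps), the clustering p-value grid, subgroup
    assignments and per-subgroup comparison/IHA tables, and a manifest.
    Deterministic given the seed.
    """
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    root_ss = np.random.SeedSequence(config.seed)
    coh_ss, cluster_ss = root_ss.spawn(2)
    cluster_seed = int(cluster_ss.generate_state(1)[0] % (2**31))

    with _stage("ingest"):
        if config.mode == "synthetic":
            cohort = config.cohort
            if cohort.seed != config.seed:
                cohort = replace(cohort, seed=config.seed)
            records = generate_cohort(cohort)
        else:
            records = _load_file_cohort(Path(config.input_dir))

    rejected: list[str] = []

    def preprocess(eeg):
        picked = select_channels(eeg)
        result = reject_noisy_segments(
            picked, amplitude_threshold=config.noise_threshold,
            min_clean_fraction=config.min_clean_fraction,
        )
        if result.rejected:
            rejected.append(f"{eeg.participant_id}/scene{eeg.scene_id}")
            logger.warning(
                "record %s scene %s rejected: clean fraction %.2f",
                eeg.participant_id, eeg.scene_id, result.clean_fraction,
            )
            return None
        return result.record

    with _stage("features"):
        cache_dir = out / "cache"
        cache_dir.mkdir(exist_ok=True)
        cache_file = cache_dir / f"features-{chash}.csv"
        if cache_file.exists():
            feats = pd.read_csv(cache_file)
            logger.info("features loaded from cache %s", cache_file.name)
        else:
            feats = features_table(
                records, include_hurst=config.include_hurst, preprocess=preprocess
            )
            feats.to_csv(cache_file, index=False)
        feats.to_csv(out / "features.csv", index=False)

    exercises = sorted({r.scene.exercise for r in records})

    with _stage("scene-comparisons"):
        have_eeg = any(r.eeg is not None for r in records)
        metric_list = None if have_eeg else ("T", "A", "S")
        for ex in exercises:
            ex_df = feats[feats["exercise"] == ex]
            kwargs = {} if metric_list is None else {"metrics": metric_list}
            report = build_comparison_table(
                ex_df, group_col="environment",
                grouping_name=f"{ex} scenes",
                group_order=["norm", "arachnophobia", "acrophobia"],
                **kwargs,
            )
            stem = out / f"scene_comparison_{ex.lower()}"
            report.to_csv(stem.with_suffix(".csv"))
            stem.with_suffix(".md").write_text(report.to_markdown())
            stem.with_suffix(".json").write_text(report.to_json())

    with _stage("coherence"):
        if any(r.eeg is not None for r in records):
            by_scene: dict[int, list] = {}
            coh_children = coh_ss.spawn(len(records))
            for rec, child in zip(records, coh_children):
                if rec.eeg is None:
                    continue
                eeg = preprocess(rec.eeg)
                if eeg is None:
                    continue
                mat = coherence_matrix(
                    eeg, surrogate_count=config.surrogate_count,
                    alpha_level=config.alpha_level,
                    band=config.coherence_band,
                    rng=np.random.default_rng(child),
                )
                by_scene.setdefault(rec.scene.scene_id, []).append(mat)
            for sid, mats in sorted(by_scene.items()):
                summary = group_mean_and_deviation(mats)
                mean_df = pd.DataFrame(
                    summary.mean.values,
                    index=list(summary.mean.channels),
                    columns=list(summary.mean.channels),
                )
                mean_df.to_csv(out / f"coherence_mean_scene{sid}.csv")
                plot_coherence_heatmap(
                    summary.mean, out / f"coherence_mean_scene{sid}.png",
                    title=f"scene {sid} group mean",
                )

    with _stage("subgroups"):
        grids = []
        for ex in exercises:
            vectors = build_vectors(feats, ex, include_iha=config.include_iha)
            assignment = select_clustering(
                vectors, feats, k_values=config.k_values, seed=cluster_seed
            )
            grid = assignment.p_grid.copy()
            grid.insert(0, "exercise", ex)
            grids.append(grid)
            (out / f"subgroup_assignment_{ex.lower()}.json").write_text(
                assignment.to_json()
            )
            if assignment.feasible:
                bundle = subgroup_reports(assignment, feats)
                for sid, rep in bundle.scene_reports.items():
                    stem = out / f"subgroup_comparison_{ex.lower()}_scene{sid}"
                    rep.to_csv(stem.with_suffix(".csv"))
                    stem.with_suffix(".md").write_text(rep.to_markdown())
                    stem.with_suffix(".json").write_text(rep.to_json())
                if len(bundle.iha_table):
                    bundle.iha_table.to_csv(
                        out / f"subgroup_iha_{ex.lower()}.csv", index=False
                    )
        pd.concat(grids, ignore_index=True).to_csv(
            out / "clustering_p_grid.csv", index=False
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": config.to_dict(),
        "n_records": len(records),
        "rejected_records": rejected,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return PipelineResult(
        out_dir=out, features=feats, manifest=manifest, rejected_records=rejected
    )
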