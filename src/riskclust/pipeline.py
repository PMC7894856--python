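"""End-to-end orchestration: synthetic cohort -> features -> stratified
samples -> per-set t-SNE -> OPTICS tuning on the training sets -> final
clustering of the validation set -> ridge profiling -> outcome reports.

Every stage is deterministic given the config seed (stage-specific
sub-seeds are derived by fixed offsets) and writes its artifacts plus a
JSON manifest when an output directory is configured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clustering, embedding, features, profiling, reporting, sampling, synthgen
from .errors import ConfigurationError, PipelineError

STAGES = (
    "synth",
    "features",
    "sample",
    "embed",
    "tune",
    "cluster",
    "profile",
    "report",
)


@dataclass
class PipelineConfig:
    """Flat key-value configuration; every tunable parameter of the
    pipeline appears here and is echoed into the run manifest."""

    seed: int
    outdir: str | None = None
    # synthetic cohort
    n_total: int = 3000
    n_subgroups: int = 12
    background_fraction: float = 0.25
    missing_rate_labs: float = 0.15
    missing_rate_vitals: float = 0.08
    missing_rate_pharmacy: float = 0.05
    missing_rate_sociodemographic: float = 0.02
    missingness_mechanism: str = "MAR_on_utilization"
    # feature engineering
    min_variance: float = 0.0099
    r_max: float = 0.80
    fcs_cycles: int = 10
    adherence_weighting: str = "days_supplied"
    # sampling
    n_sets: int = 5
    set_size: int | None = None  # default: n_total // n_sets
    stratum_width: int = 5
    high_risk_threshold: int = 75
    validation_index: int = 0
    # t-SNE
    perplexity: float = 30.0
    tsne_iterations: int = 1000
    exaggeration_factor: float = 12.0
    exaggeration_duration: int = 250
    learning_rate: float = 200.0
    momentum_initial: float = 0.5
    momentum_final: float = 0.8
    momentum_switch: int = 250
    # OPTICS tuning; min_pts defaults to ~1-2.5% of the set size
    grid_min_pts: tuple[int, ...] | None = None
    grid_min_pts_fractions: tuple[float, ...] = (0.010, 0.017, 0.025)
    grid_xi: tuple[float, ...] = (0.03, 0.05)
    grid_cut_quantiles: tuple[float, ...] = (0.65, 0.70, 0.75, 0.85)
    noise_target: float = 0.25
    noise_penalty: float = 0.5
    # ridge profiling
    n_penalties: int = 100
    penalty_lo: float = 1e-4
    penalty_hi: float = 1e4

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("a seed is required")
        if self.set_size is None:
            self.set_size = self.n_total // self.n_sets

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in raw:
            raise ConfigurationError("config missing required key 'seed'")
        for key in ("grid_min_pts", "grid_xi", "grid_cut_quantiles"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def manifest(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def tsne_config(self, seed: int) -> embedding.TsneConfig:
        return embedding.TsneConfig(
            perplexity=self.perplexity,
            n_iterations=self.tsne_iterations,
            early_exaggeration_factor=self.exaggeration_factor,
            early_exaggeration_duration=self.exaggeration_duration,
            learning_rate=self.learning_rate,
            momentum_initial=self.momentum_initial,
            momentum_final=self.momentum_final,
            momentum_switch_iteration=self.momentum_switch,
            seed=seed,
        )

    def optics_grid(self) -> list[clustering.OpticsConfig]:
        if self.grid_min_pts is not None:
            min_pts_values = tuple(self.grid_min_pts)
        else:
            raw = {
                max(5, int(round(f * self.set_size)))
                for f in self.grid_min_pts_fractions
            }
            min_pts_values = tuple(sorted(raw))
        grid = []
        for mp in min_pts_values:
            for xi in self.grid_xi:
                grid.append(clustering.OpticsConfig(min_pts=mp, xi=xi))
            for q in self.grid_cut_quantiles:
                grid.append(
                    clustering.OpticsConfig(min_pts=mp, xi=None, cut_quantile=q)
                )
        return grid

    def penalty_grid(self) -> np.ndarray:
        return profiling.default_penalty_grid(
            self.n_penalties, self.penalty_lo, self.penalty_hi
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    structure: synthgen.PlantedStructure
    cohort: synthgen.CohortTable
    feature_matrix: features.FeatureMatrix
    sample_sets: list[sampling.SampleSet]
    tuned_config: clustering.OpticsConfig
    score_table: pd.DataFrame
    validation_ids: list[str]
    validation_embedding: embedding.Embedding
    validation_result: clustering.ReachabilityResult
    labels: pd.Series  # validation patients -> cluster id / noise
    profiles: list[profiling.ClusterProfile]
    importance: pd.DataFrame | None
    evidence: list[dict]
    outcome_summary: pd.DataFrame
    baseline: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def true_labels(self) -> pd.Series:
        return self.cohort.data.loc[self.validation_ids, "true_label"]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; any stage error aborts with the stage
    name. Idempotent given the seed."""
    outdir = Path(config.outdir) if config.outdir else None
    manifest: dict[str, Any] = {"config": config.manifest(), "stages": {}}

    def finish_stage(name: str, info: dict) -> None:
        manifest["stages"][name] = info
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def fail(name: str, exc: Exception) -> PipelineError:
        finish_stage(name, {"error": str(exc)})
        return PipelineError(f"stage {name!r} failed: {exc}")

    seed = config.seed
    # --- synth ------------------------------------------------------------
    try:
        structure = synthgen.demo_structure(
            config.n_total, config.n_subgroups, config.background_fraction, seed
        )
        cohort = synthgen.generate_cohort(structure, config.n_total, seed=seed)
        rates = {
            "labs": config.missing_rate_labs,
            "vitals": config.missing_rate_vitals,
            "pharmacy": config.missing_rate_pharmacy,
            "sociodemographic": config.missing_rate_sociodemographic,
        }
        cohort = synthgen.inject_missingness(
            cohort, rates, config.missingness_mechanism, seed=seed + 1
        )
        measures = synthgen.generate_repeated_measures(cohort, seed=seed + 2)
        targets = {
            k: g.adherence
            for k, g in enumerate(structure.subgroups)
            if g.adherence is not None
        }
        fills = synthgen.generate_fill_histories(
            cohort, adherence_targets=targets or None, seed=seed + 3
        )
        if outdir is not None:
            synthgen.write_cohort(cohort, outdir / "synth", measures, fills)
        finish_stage(
            "synth",
            {
                "n_total": config.n_total,
                "n_subgroups": structure.n_subgroups,
                "subgroup_sizes": structure.subgroup_sizes,
                "seed": seed,
            },
        )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail("synth", exc)

    # --- features ----------------------------------------------------------
    try:
        fm = features.build_features(
            cohort.data,
            cohort.dictionary,
            measures,
            fills,
            min_variance=config.min_variance,
            r_max=config.r_max,
            n_cycles=config.fcs_cycles,
            seed=seed + 4,
            weighting=config.adherence_weighting,
        )
        if outdir is not None:
            features.write_features(fm, outdir / "features")
        finish_stage(
            "features",
            {
                "n_original": fm.report.n_original,
                "n_retained": fm.values.shape[1],
                "removed_low_variance": len(fm.report.removed_low_variance),
                "removed_correlated": len(fm.report.removed_correlated),
                "fcs_cycles": config.fcs_cycles,
            },
        )
    except Exception as exc:
        raise fail("features", exc)

    # --- sample ------------------------------------------------------------
    try:
        population = pd.DataFrame(
            {
                "patient_id": cohort.data.index,
                "risk_percentile": cohort.data["risk_percentile"].to_numpy(),
            }
        )
        plan = sampling.SamplePlan(
            n_sets=config.n_sets,
            set_size=config.set_size,
            stratum_width=config.stratum_width,
            high_risk_threshold=config.high_risk_threshold,
            validation_index=config.validation_index,
            seed=seed + 5,
        )
        sets = sampling.stratified_sample(population, plan)
        if outdir is not None:
            sampling.write_samples(sets, plan, outdir / "samples")
        finish_stage(
            "sample",
            {"n_sets": config.n_sets, "set_size": config.set_size,
             "stratum_width": config.stratum_width},
        )
    except Exception as exc:
        raise fail("sample", exc)

    # --- embed (training sets + validation set) ----------------------------
    try:
        train_coords = []
        val_emb = None
        val_ids: list[str] = []
        for k, s in enumerate(sets):
            Z = fm.values.loc[s.patient_ids]
            emb = embedding.embed_features(Z, config.tsne_config(seed + 10 + k))
            if outdir is not None:
                embedding.write_embedding(
                    emb, outdir / "embeddings", f"set_{k:02d}_{s.role}"
                )
            if s.role == "train":
                train_coords.append(emb.coordinates)
            else:
                val_emb = emb
                val_ids = list(s.patient_ids)
        finish_stage(
            "embed",
            {"n_sets": len(sets), "perplexity": config.perplexity,
             "iterations": config.tsne_iterations},
        )
    except Exception as exc:
        raise fail("embed", exc)

    # --- tune ---------------------------------------------------------------
    try:
        tuned, score_table = clustering.tune_hyperparameters(
            train_coords,
            config.optics_grid(),
            noise_target=config.noise_target,
            noise_penalty=config.noise_penalty,
        )
        if outdir is not None:
            (outdir / "tuning").mkdir(parents=True, exist_ok=True)
            score_table.to_json(
                outdir / "tuning" / "score_table.json", orient="records", indent=1
            )
            (outdir / "tuning" / "chosen.json").write_text(
                json.dumps(dataclasses.asdict(tuned), default=str, indent=1)
            )
        finish_stage("tune", {"chosen": tuned.describe()})
    except Exception as exc:
        raise fail("tune", exc)

    # --- cluster (validation set) -------------------------------------------
    try:
        result = clustering.cluster_embedding(val_emb.coordinates, tuned)
        labels = pd.Series(result.labels, index=pd.Index(val_ids, name="patient_id"))
        if outdir is not None:
            clustering.write_clustering(result, val_ids, outdir / "clusters")
        finish_stage(
            "cluster",
            {
                "n_clusters": int(len(set(result.labels)) - (clustering.NOISE in result.labels)),
                "noise_fraction": result.noise_fraction(),
            },
        )
    except Exception as exc:
        raise fail("cluster", exc)

    # --- profile --------------------------------------------------------------
    try:
        Xval = fm.values.loc[val_ids]
        profiles = profiling.profile_all_clusters(
            Xval, result.labels, config.penalty_grid()
        )
        importance = (
            profiling.importance_ranges(profiles) if len(profiles) >= 2 else None
        )
        evidence = profiling.suggest_labels(profiles, fm.domains)
        if outdir is not None and importance is not None:
            profiling.write_profiles(profiles, importance, evidence, outdir / "profiles")
        finish_stage("profile", {"n_profiles": len(profiles)})
    except Exception as exc:
        raise fail("profile", exc)

    # --- report ----------------------------------------------------------------
    try:
        summary = reporting.summarize_outcomes(labels, cohort.data)
        baseline = reporting.baseline_table(cohort.data, cohort.dictionary)
        if outdir is not None:
            rep = outdir / "report"
            rep.mkdir(parents=True, exist_ok=True)
            summary.to_csv(rep / "outcomes_by_cluster.csv", index=False)
            reporting.format_outcome_summary(summary).to_csv(
                rep / "outcomes_by_cluster_formatted.csv", index=False
            )
            baseline.to_csv(rep / "baseline_table.csv", index=False)
        finish_stage("report", {"n_rows": len(summary)})
    except Exception as exc:
        raise fail("report", exc)

    return PipelineResult(
        config=config,
        structure=structure,
        cohort=cohort,
        feature_matrix=fm,
        sample_sets=sets,
        tuned_config=tuned,
        score_table=score_table,
        validation_ids=val_ids,
        validation_embedding=val_emb,
        validation_result=result,
        labels=labels,
        profiles=profiles,
        importance=importance,
        evidence=evidence,
        outcome_summary=summary,
        baseline=baseline,
        manifest=manifest,
    )
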