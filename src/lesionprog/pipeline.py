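"""End-to-end orchestration: simulate → encode → select → transfer →
ensemble → associations → report.

Each stage persists flat TSV/JSON/NIfTI artefacts into the run directory
as it completes, so a failed run keeps everything before the failing
stage and any stage can be re-run or inspected on its own.  A manifest
(config, seeds, file hashes) is written at the end; re-running the same
config reproduces every output hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import encoding, selection, simulate, transfer


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    All randomness is controlled by explicit seeds; ``n_perm = 0``
    disables permutation thresholding (the shift table is then marked
    uncorrected and flagged at the nominal alpha).
    """

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    input_dir: str | None = None  # read a cohort from disk instead of simulating
    tasks: list[str] | None = None
    criterion: str = "mae"
    seed_features: tuple[str, ...] = selection.DEFAULT_SEED_FEATURES
    alpha: float = 0.05
    n_perm: int = 1000
    permutation_seed: int = 1
    n_random_models: int = 2000
    random_size_range: tuple[int, int] = (2, 40)
    ensemble_seed: int = 2
    strong_threshold: float = 10.0
    associations_flagged_only: bool = True
    bf_epsrel: float = 1e-8

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if sim_raw.get("true_weights") is not None:
            sim_raw["true_weights"] = tuple(
                simulate.TaskWeights(
                    intercept=w["intercept"],
                    region_weights=np.asarray(w["region_weights"], dtype=float),
                    time_weight=w.get("time_weight", 0.0),
                    age_weight=w.get("age_weight", 0.0),
                    sex_weight=w.get("sex_weight", 0.0),
                    volume_weight=w.get("volume_weight", 0.0),
                )
                for w in sim_raw["true_weights"]
            )
        for key in ("grid_dims", "divergent_regions"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        for key in ("weight_magnitude_range", "volume_range_mm3"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = tuple(sim_raw[key])
        sim = simulate.SimulationConfig(**sim_raw)
        for key in ("seed_features", "random_size_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "tasks" in raw and raw["tasks"] is not None:
            raw["tasks"] = list(raw["tasks"])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    cohort: simulate.Cohort
    table_a: pd.DataFrame
    table_b: pd.DataFrame
    models: dict[str, selection.PrognosticModel]
    records: pd.DataFrame
    null: transfer.PermutationNull | None
    shift_table: pd.DataFrame
    corrected_alpha: float
    ensemble: transfer.EnsembleResult | None
    associations: pd.DataFrame
    screen: assoc.ConvergenceScreen | None
    slopes: assoc.SlopeComparison | None
    history: tuple[pd.DataFrame, list[str]] | None
    model_frequency: pd.Series
    shared_frequency: pd.Series | None
    manifest: dict


# ---------------------------------------------------------------------------
# Region frequency maps
# ---------------------------------------------------------------------------

def region_frequency(
    source: Mapping[str, selection.PrognosticModel | Sequence[str]] | pd.DataFrame,
    region_names: Sequence[str],
) -> pd.Series:
    """Count, per region, the number of tasks implicating it.

    ``source`` is either a mapping task → model/feature-set (counting
    membership in the best models) or a convergence-screen case table
    with ``region``/``task`` columns (counting shared strong
    associations).  Counts lie in [0, n_tasks].
    """
    counts = pd.Series(0, index=pd.Index(region_names, name="region"), dtype=int)
    known = set(region_names)
    if isinstance(source, pd.DataFrame):
        pairs = source[["region", "task"]].drop_duplicates()
        for region in pairs["region"]:
            if region not in known:
                raise ValueError(f"unknown region label {region!r}")
        vc = pairs["region"].value_counts()
        counts.loc[vc.index] = vc.astype(int)
    else:
        for task, model in source.items():
            feats = model.features if isinstance(model, selection.PrognosticModel) else list(model)
            for f in feats:
                if f in known:
                    counts.loc[f] += 1
                elif f not in encoding.DEMOGRAPHIC_COLUMNS:
                    raise ValueError(f"unknown region label {f!r} in task {task!r}")
    return counts


def paint_frequency_map(freq: pd.Series, atlas: encoding.Atlas) -> np.ndarray:
    """Paint per-region counts into the atlas grid (max over overlapping
    regions at each voxel)."""
    vol = np.zeros(int(np.prod(atlas.grid_dims)), dtype=float)
    for name, idx in atlas.regions:
        c = float(freq.get(name, 0))
        vol[idx] = np.maximum(vol[idx], c)
    return vol.reshape(atlas.grid_dims)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def split_tables(cohort: simulate.Cohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Predictor tables and score tables for the two groups."""
    table = encoding.build_predictor_table(cohort.loads, cohort.lesion_volume, cohort.demographics)
    ia = cohort.group_index(simulate.GROUP_A)
    ib = cohort.group_index(simulate.GROUP_B)
    return table.loc[ia], table.loc[ib], cohort.scores.loc[ia], cohort.scores.loc[ib]


def select_models(
    table_a: pd.DataFrame,
    scores_a: pd.DataFrame,
    tasks: Sequence[str],
    criterion: str = "mae",
    seed_features: Sequence[str] = selection.DEFAULT_SEED_FEATURES,
) -> dict[str, selection.PrognosticModel]:
    return {
        task: selection.select_features(
            table_a, scores_a[task], seed_features=seed_features, criterion=criterion, task=task
        )
        for task in tasks
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis and persist stage artefacts under ``outdir``."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, **kw) -> None:
        if out is not None:
            path = out / name
            df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
            written.append(path)

    def save_json(obj, name: str) -> None:
        if out is not None:
            path = out / name
            path.write_text(json.dumps(obj, indent=1, default=_json_default))
            written.append(path)

    # --- simulate / load ---
    try:
        if config.input_dir is not None:
            cohort = simulate.read_cohort(config.input_dir)
        else:
            cohort = simulate.generate_cohort(config.simulation)
    except Exception as exc:
        raise PipelineStageError("simulate", exc)

    # --- encode ---
    try:
        table_a, table_b, scores_a, scores_b = split_tables(cohort)
        tasks = list(config.tasks) if config.tasks else list(cohort.scores.columns)
        save_tsv(pd.concat([table_a, table_b]), "predictor_table.tsv", index=True)
    except Exception as exc:
        raise PipelineStageError("encode", exc)

    # --- select ---
    try:
        models = select_models(
            table_a, scores_a, tasks, criterion=config.criterion, seed_features=config.seed_features
        )
        if out is not None:
            mdir = out / "models"
            mdir.mkdir(exist_ok=True)
            for task, model in models.items():
                path = mdir / f"{task}.json"
                model.to_json(path)
                written.append(path)
    except Exception as exc:
        raise PipelineStageError("select", exc)

    # --- transfer + permutation threshold ---
    try:
        records = transfer.transfer_predict(models, table_a, scores_a, table_b, scores_b)
        errs = transfer.errors_by_task(records)
        if config.n_perm > 0:
            null = transfer.permutation_familywise_threshold(
                errs,
                cohort.demographics["group"],
                n_perm=config.n_perm,
                seed=config.permutation_seed,
                alpha=config.alpha,
            )
            corrected_alpha = null.corrected_alpha
            save_json(
                {
                    "n_perm": null.n_perm,
                    "seed": null.seed,
                    "alpha": null.alpha,
                    "corrected_alpha": null.corrected_alpha,
                },
                "permutation.json",
            )
        else:
            null = None
            corrected_alpha = config.alpha
            save_json({"n_perm": 0, "marker": "uncorrected", "alpha": config.alpha}, "permutation.json")
        shift = transfer.shift_tests(records, corrected_alpha=corrected_alpha)
        save_tsv(shift, "shift_tests.tsv")
        save_tsv(records, "prediction_records.tsv")
    except Exception as exc:
        raise PipelineStageError("transfer", exc)

    flagged = list(shift.loc[shift["significant"] == True, "task"])  # noqa: E712

    # --- random-model ensemble ---
    ensemble = None
    try:
        if config.n_random_models > 0 and flagged:
            sets = selection.sample_random_feature_sets(
                config.n_random_models,
                config.random_size_range,
                list(table_a.columns),
                seed=config.ensemble_seed,
            )
            ensemble = transfer.random_model_consistency(
                sets, table_a, scores_a, table_b, scores_b, flagged, threshold_alpha=corrected_alpha
            )
            save_tsv(ensemble.per_task, "ensemble_per_task.tsv")
            save_json(
                {
                    "fraction_consistent": ensemble.fraction_consistent,
                    "n_tests": ensemble.n_tests,
                    "n_significant_positive": ensemble.n_significant_positive,
                    "n_significant_negative": ensemble.n_significant_negative,
                    "seed": config.ensemble_seed,
                },
                "ensemble.json",
            )
    except Exception as exc:
        raise PipelineStageError("ensemble", exc)

    # --- region associations / convergence screen ---
    screen = None
    slopes = None
    try:
        assoc_tasks = flagged if (config.associations_flagged_only and flagged) else tasks
        table = assoc.region_association_table(
            cohort.loads, cohort.scores, cohort.demographics["group"], tasks=assoc_tasks
        )
        save_tsv(table, "region_associations.tsv")
        if not table.empty:
            screen = assoc.convergence_screen(table, strong_threshold=config.strong_threshold)
            save_tsv(screen.cases, "screen_cases.tsv")
            save_json(screen.divergent.to_dict(orient="records"), "divergent_cases.json")
            shared = screen.cases[screen.cases["shared"]]
            if len(shared) >= 2:
                slopes = assoc.slope_comparison(shared)
                save_json(dataclasses.asdict(slopes), "slope_comparison.json")
    except Exception as exc:
        raise PipelineStageError("associations", exc)

    # --- history screen ---
    history = None
    try:
        if cohort.history is not None and flagged:
            b_idx = cohort.group_index(simulate.GROUP_B)
            errs_b = {
                t: s.loc[s.index.intersection(b_idx)] for t, s in errs.items() if t in flagged
            }
            history = transfer.history_screen(cohort.history.loc[b_idx], errs_b, flagged)
            save_tsv(history[0], "history_screen.tsv")
    except Exception as exc:
        raise PipelineStageError("history", exc)

    # --- report: region frequency maps + manifest ---
    try:
        model_freq = region_frequency(models, cohort.atlas.region_names)
        save_tsv(model_freq.rename("count").reset_index(), "region_frequency_models.tsv")
        shared_freq = None
        if screen is not None and screen.n_shared > 0:
            shared_cases = screen.cases[screen.cases["shared"]]
            shared_freq = region_frequency(shared_cases, cohort.atlas.region_names)
            save_tsv(shared_freq.rename("count").reset_index(), "region_frequency_shared.tsv")
        if out is not None:
            import nibabel as nib

            vol = paint_frequency_map(model_freq, cohort.atlas)
            aff = np.eye(4) * (cohort.atlas.voxel_volume ** (1 / 3))
            aff[3, 3] = 1.0
            path = out / "region_frequency_models.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(path))
        manifest = {
            "config": config.to_dict(),
            "tasks": tasks,
            "flagged_tasks": flagged,
            "corrected_alpha": corrected_alpha,
            "outputs": {p.name: _sha256(p) for p in written},
        }
        if out is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_json_default))
    except Exception as exc:
        raise PipelineStageError("report", exc)

    return PipelineResult(
        cohort=cohort,
        table_a=table_a,
        table_b=table_b,
        models=models,
        records=records,
        null=null,
        shift_table=shift,
        corrected_alpha=corrected_alpha,
        ensemble=ensemble,
        associations=table,
        screen=screen,
        slopes=slopes,
        history=history,
        model_frequency=model_freq,
        shared_frequency=shared_freq,
        manifest=manifest,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
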