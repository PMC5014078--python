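"""Synthetic two-group stroke cohorts with a known lesion-deficit structure.

Generates toy left-hemisphere parcellations, territory-structured focal
lesions, and task score tables that follow the linear lesion-load model the
downstream analysis assumes: each task score is an affine function of
region lesion loads (negative weights: damage lowers scores), time
post-stroke and optionally age, plus Gaussian noise, standardized to a
T-score scale against a simulated aphasic reference sample.

Two knobs create controlled group differences between the reference group
("a", the native-speaker analogue) and the transfer group ("b", the
non-native analogue):

``lambda_sensitivity``
    multiplies the lesion-load weights for group b — "enhanced sensitivity
    to damage" in a shared network;
``intercept_shift``
    adds a constant to group-b expected scores — a premorbid-proficiency
    style main effect of group.

A third, ``divergent_regions``/``divergent_weight``, gives group b loading
on regions that carry no weight for group a, emulating neural divergence.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .encoding import Atlas, LesionMask, lesion_load

GROUP_A = "a"  # reference (native-speaker analogue) group
GROUP_B = "b"  # transfer (non-native analogue) group

#: Canonical task battery (22 language tasks of a comprehensive aphasia
#: assessment, by construct); sliced when fewer tasks are simulated.
TASK_NAMES = (
    "fluency",
    "comp_spoken_words",
    "comp_spoken_sentences",
    "comp_spoken_paragraphs",
    "comp_written_words",
    "comp_written_sentences",
    "repeat_words",
    "repeat_complex_words",
    "repeat_nonwords",
    "repeat_digits",
    "repeat_sentences",
    "naming_objects",
    "naming_actions",
    "spoken_picture_description",
    "reading_words",
    "reading_complex_words",
    "reading_function_words",
    "reading_nonwords",
    "writing_copying",
    "writing_picture_naming",
    "writing_dictation",
    "written_picture_description",
)

#: Tasks for which group-b patients also receive native-language scores.
NATIVE_TASKS = (
    "fluency",
    "repeat_digits",
    "naming_objects",
    "naming_actions",
    "spoken_picture_description",
    "writing_picture_naming",
    "written_picture_description",
)

HISTORY_FIELDS = (
    "n_languages",
    "age_of_bilingualism",
    "age_learned_l2",
    "years_l2_used",
    "self_rated_proficiency",
    "pct_l2_use_pre",
    "pct_l2_use_post",
)


def task_names(n_tasks: int) -> list[str]:
    if n_tasks <= len(TASK_NAMES):
        return list(TASK_NAMES[:n_tasks])
    extra = [f"task_{i:02d}" for i in range(len(TASK_NAMES), n_tasks)]
    return list(TASK_NAMES) + extra


@dataclass(frozen=True)
class TaskWeights:
    """True generative coefficients for one task, on the raw score scale."""

    intercept: float
    region_weights: np.ndarray  # one per region; <= 0 by default
    time_weight: float = 0.0  # per month
    age_weight: float = 0.0  # per year
    sex_weight: float = 0.0
    volume_weight: float = 0.0  # per mm^3

    def active_regions(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.region_weights))


@dataclass(frozen=True)
class ScoreScale:
    """T-score standardization for one task.

    ``reference_mean``/``reference_sd`` come from a simulated aphasic
    reference sample (default size 60); ``impairment_cutoff`` is the raw
    score at the 5th percentile of a simulated neurologically normal
    control sample (default size 27).  T = 50 + 10 * (x - mean) / sd.
    """

    reference_mean: float
    reference_sd: float
    impairment_cutoff: float

    def __post_init__(self) -> None:
        if self.reference_sd <= 0:
            raise ValueError("reference_sd must be positive")

    def to_t(self, raw: np.ndarray | float) -> np.ndarray | float:
        return 50.0 + 10.0 * (np.asarray(raw, dtype=float) - self.reference_mean) / self.reference_sd

    @property
    def impairment_cutoff_t(self) -> float:
        return float(self.to_t(self.impairment_cutoff))


@dataclass
class TerritoryParams:
    """Lesion-geometry controls: where lesions seed and how large they grow."""

    count: int = 2
    spread: float = 2.0  # SD, in voxels, of seed placement around a centre
    volume_range_mm3: tuple[float, float] = (1000.0, 250_000.0)
    log_volume_sd: float = 0.8
    log_volume_position: float = 0.55  # median's position within the log-range
    centers: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("territory count must be >= 1")
        if self.volume_range_mm3[0] < 1000.0:
            raise ValueError("minimum lesion volume must be >= 1000 mm^3 (1 cm^3)")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-group cohort.

    Defaults mirror the cohort structure the analysis was designed around:
    174 + 33 patients, 199 overlapping left-hemisphere regions, 22 task
    scores, territory-structured focal lesions, and mild per-task
    missingness.  ``lambda_sensitivity`` (λ), ``intercept_shift`` (δ, T
    units) and ``noise_sd`` (σ, ≈ T units) default to the null: λ = 1,
    δ = 0.
    """

    n_group_a: int = 174
    n_group_b: int = 33
    n_regions: int = 199
    n_tasks: int = 22
    # --- geometry ---
    grid_dims: tuple[int, int, int] = (16, 20, 16)
    voxel_volume: float = 125.0  # 5 mm isotropic
    atlas_overlap: float = 0.25
    territory_count: int = 2
    territory_spread: float = 2.0
    # --- generative score model ---
    true_weights: tuple[TaskWeights, ...] | None = None
    n_active_regions: int = 8
    weight_magnitude_range: tuple[float, float] = (0.06, 0.18)  # per % load
    prevalence_sharpness: float = 2.0  # exponent biasing active regions to lesioned territory
    time_weight: float = 0.02  # per month: slow recovery with time
    age_task_fraction: float = 0.25  # share of tasks with an age effect
    age_weight: float = -0.05  # per year, where active
    intercept: float = 60.0
    lambda_sensitivity: float = 1.0
    intercept_shift: float = 0.0
    noise_sd: float = 3.0  # task-specific noise
    noise_shared_sd: float = 5.0  # patient-level severity noise common to all tasks
    missing_rate: float = 0.03
    divergent_regions: tuple[int, ...] = ()
    divergent_weight: float = 0.0
    # --- standardization samples ---
    n_reference: int = 60
    n_controls: int = 27
    # --- native-language scores and history (group b only) ---
    native_shift: float = -0.8
    native_sd: float = 1.5
    native_missing_rate: float = 0.35
    history_missing_rate: float = 0.2
    history_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_regions", "n_tasks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0 or self.noise_shared_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.lambda_sensitivity < 0:
            raise ValueError("lambda_sensitivity must be >= 0")

    def task_names(self) -> list[str]:
        return task_names(self.n_tasks)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.true_weights is not None:
            d["true_weights"] = [
                {**asdict(w), "region_weights": np.asarray(w.region_weights).tolist()}
                for w in self.true_weights
            ]
        return d


@dataclass
class Cohort:
    """An in-memory synthetic cohort: both groups, encoded and scored."""

    demographics: pd.DataFrame  # group, sex, age_at_stroke_years, time_post_stroke_months
    loads: pd.DataFrame  # patients x regions, percent
    lesion_volume: pd.Series  # mm^3
    scores: pd.DataFrame  # patients x tasks, T-scores, NaN = missing
    atlas: Atlas
    native_scores: pd.DataFrame | None = None
    history: pd.DataFrame | None = None
    masks: np.ndarray | None = None  # (n_patients, *grid), uint8
    config: SimulationConfig | None = None
    true_weights: tuple[TaskWeights, ...] | None = None
    scales: tuple[ScoreScale, ...] | None = None
    seed: int | None = None

    @property
    def patients(self) -> pd.Index:
        return self.demographics.index

    def group_index(self, group: str) -> pd.Index:
        return self.demographics.index[self.demographics["group"] == group]

    @property
    def tasks(self) -> list[str]:
        return list(self.scores.columns)


# ---------------------------------------------------------------------------
# Atlas generation
# ---------------------------------------------------------------------------

def generate_atlas(
    grid_dims: tuple[int, int, int] = (16, 20, 16),
    n_regions: int = 199,
    overlap_fraction: float = 0.25,
    seed: int = 0,
    voxel_volume: float = 125.0,
    hemisphere_tag: str = "L",
) -> Atlas:
    """Generate a toy parcellation covering the grid.

    Seeds ``n_regions`` voxels and assigns every voxel to its nearest seed
    (a Voronoi partition), guaranteeing non-empty disjoint base regions;
    with ``overlap_fraction`` > 0 each region then annexes boundary voxels
    of its neighbours with that probability, emulating the overlapping
    union of several published atlases.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dims = tuple(int(d) for d in grid_dims)
    n_vox = int(np.prod(dims))
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > n_vox:
        raise ValueError(
            f"grid with {n_vox} voxels cannot host {n_regions} region seeds"
        )
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")

    seeds = rng.choice(n_vox, size=n_regions, replace=False)
    coords = np.stack(np.unravel_index(np.arange(n_vox), dims), axis=1).astype(float)
    seed_coords = coords[seeds]
    # nearest seed per voxel; ties resolved to the lowest region index
    assignment = np.empty(n_vox, dtype=int)
    chunk = 4096
    for start in range(0, n_vox, chunk):
        d2 = ((coords[start : start + chunk, None, :] - seed_coords[None, :, :]) ** 2).sum(-1)
        assignment[start : start + chunk] = np.argmin(d2, axis=1)

    base = [np.flatnonzero(assignment == i) for i in range(n_regions)]
    label = assignment.reshape(dims)
    regions: list[tuple[str, np.ndarray]] = []
    width = max(3, len(str(n_regions)))
    for i in range(n_regions):
        idx = base[i]
        if overlap_fraction > 0:
            ring = _boundary_ring(label, i, dims)
            if ring.size:
                take = rng.random(ring.size) < overlap_fraction
                idx = np.union1d(idx, ring[take])
        regions.append((f"{hemisphere_tag}_region_{i:0{width}d}", np.sort(idx)))
    return Atlas(
        grid_dims=dims,  # type: ignore[arg-type]
        voxel_volume=voxel_volume,
        regions=tuple(regions),
        hemisphere_tag=hemisphere_tag,
    )


def _boundary_ring(label: np.ndarray, i: int, dims: tuple[int, ...]) -> np.ndarray:
    """Flat indices of voxels 6-adjacent to region ``i`` but outside it."""
    inside = label == i
    ring = np.zeros_like(inside)
    for axis in range(3):
        ring |= np.roll(inside, 1, axis=axis)
        ring |= np.roll(inside, -1, axis=axis)
    ring &= ~inside
    return np.flatnonzero(ring.ravel())


# ---------------------------------------------------------------------------
# Lesion generation
# ---------------------------------------------------------------------------

def generate_lesion_masks(
    atlas: Atlas,
    n_patients: int,
    territory_params: TerritoryParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Grow one focal lesion per patient, clustered in vascular-territory
    analogues.

    Each lesion is grown voxel-by-voxel from a seed point near a territory
    centre, so it is a single connected component by construction, and its
    target size is drawn log-normally within ``volume_range_mm3`` (floor
    1 cm^3, the cohort inclusion threshold).  Returns a
    (n_patients, *grid) uint8 array.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = territory_params or TerritoryParams()
    rng = np.random.default_rng(seed)
    dims = atlas.grid_dims
    n_vox = int(np.prod(dims))

    centers = _territory_centers(dims, params, rng)

    min_vox = int(np.ceil(params.volume_range_mm3[0] / atlas.voxel_volume))
    max_vox = min(
        int(params.volume_range_mm3[1] / atlas.voxel_volume), int(0.5 * n_vox)
    )
    max_vox = max(max_vox, min_vox)

    masks = np.zeros((n_patients,) + tuple(dims), dtype=np.uint8)
    log_lo, log_hi = np.log(min_vox), np.log(max_vox)
    for p in range(n_patients):
        territory = int(rng.integers(params.count))
        center = centers[territory]
        start = np.clip(
            np.rint(center + rng.normal(0.0, params.spread, size=3)).astype(int),
            0,
            np.asarray(dims) - 1,
        )
        mid = log_lo + params.log_volume_position * (log_hi - log_lo)
        target = int(np.clip(np.rint(np.exp(rng.normal(mid, params.log_volume_sd))), min_vox, max_vox))
        masks[p] = _grow_lesion(tuple(start), target, dims, rng)
    return masks


def _territory_centers(
    dims: tuple[int, ...], params: TerritoryParams, rng: np.random.Generator
) -> np.ndarray:
    if params.centers is not None:
        centers = np.asarray(params.centers, dtype=int)
        if centers.shape != (params.count, 3):
            raise ValueError("centers must be one (x, y, z) triple per territory")
        if np.any(centers < 0) or np.any(centers >= np.asarray(dims)):
            raise ValueError(f"territory centre outside grid {dims}")
        return centers
    # keep centres away from the faces so seeds mostly land in-grid
    lo = np.maximum(1, (np.asarray(dims) * 0.2).astype(int))
    hi = np.asarray(dims) - 1 - lo
    return np.stack(
        [rng.integers(lo[k], hi[k] + 1, size=params.count) for k in range(3)], axis=1
    )


def _grow_lesion(
    start: tuple[int, int, int],
    target_voxels: int,
    dims: tuple[int, int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic 6-connected region growth to an exact voxel count."""
    grown = np.zeros(dims, dtype=np.uint8)
    grown[start] = 1
    frontier: list[tuple[int, int, int]] = []
    seen = {start}

    def push_neighbours(v: tuple[int, int, int]) -> None:
        x, y, z = v
        for nb in ((x - 1, y, z), (x + 1, y, z), (x, y - 1, z), (x, y + 1, z), (x, y, z - 1), (x, y, z + 1)):
            if (
                0 <= nb[0] < dims[0]
                and 0 <= nb[1] < dims[1]
                and 0 <= nb[2] < dims[2]
                and nb not in seen
            ):
                seen.add(nb)
                frontier.append(nb)

    push_neighbours(start)
    size = 1
    while size < target_voxels and frontier:
        j = int(rng.integers(len(frontier)))
        frontier[j], frontier[-1] = frontier[-1], frontier[j]
        v = frontier.pop()
        grown[v] = 1
        size += 1
        push_neighbours(v)
    return grown


# ---------------------------------------------------------------------------
# Score generation
# ---------------------------------------------------------------------------

def draw_task_weights(
    config: SimulationConfig,
    rng: np.random.Generator,
    region_prevalence: np.ndarray | None = None,
) -> tuple[TaskWeights, ...]:
    """Draw one sparse negative lesion-weight vector per task.

    Magnitudes are drawn once per (task, region) from
    ``weight_magnitude_range`` and negated: damage lowers scores.  When
    ``region_prevalence`` (e.g. mean lesion load per region) is given,
    active regions are sampled proportionally to it, mirroring the fact
    that the deficit-relevant language network lies inside the vascular
    territories the cohort's lesions actually strike.  A configured
    fraction of tasks also carries a (negative) age effect.
    """
    lo, hi = config.weight_magnitude_range
    p = None
    if region_prevalence is not None:
        prev = np.asarray(region_prevalence, dtype=float)
        if prev.shape != (config.n_regions,):
            raise ValueError("region_prevalence must have one entry per region")
        p = prev**config.prevalence_sharpness
        p = p + 1e-6 * max(p.max(), 1.0)  # floor keeps every region eligible
        p = p / p.sum()
    weights = []
    n_age_tasks = int(round(config.age_task_fraction * config.n_tasks))
    age_tasks = set(rng.choice(config.n_tasks, size=n_age_tasks, replace=False).tolist())
    for t in range(config.n_tasks):
        w = np.zeros(config.n_regions)
        k = min(config.n_active_regions, config.n_regions)
        active = rng.choice(config.n_regions, size=k, replace=False, p=p)
        w[active] = -rng.uniform(lo, hi, size=k)
        weights.append(
            TaskWeights(
                intercept=config.intercept,
                region_weights=w,
                time_weight=config.time_weight,
                age_weight=config.age_weight if t in age_tasks else 0.0,
            )
        )
    return tuple(weights)


def _expected_raw(
    loads: np.ndarray,
    demographics: pd.DataFrame,
    w: TaskWeights,
    config: SimulationConfig,
) -> np.ndarray:
    """Noise-free expected raw score for one task, honouring λ, δ and any
    divergent group-b-only region loading."""
    is_b = (demographics["group"] == GROUP_B).to_numpy()
    rw = np.asarray(w.region_weights, dtype=float)
    base = loads @ rw
    scaled = loads @ (rw * config.lambda_sensitivity)
    lesion_term = np.where(is_b, scaled, base)
    if config.divergent_weight != 0.0 and len(config.divergent_regions):
        div = loads[:, list(config.divergent_regions)].sum(axis=1) * config.divergent_weight
        lesion_term = lesion_term + np.where(is_b, div, 0.0)
    raw = (
        w.intercept
        + lesion_term
        + w.time_weight * demographics["time_post_stroke_months"].to_numpy()
        + w.age_weight * demographics["age_at_stroke_years"].to_numpy()
        + w.sex_weight * demographics["sex"].to_numpy()
        + np.where(is_b, config.intercept_shift, 0.0)
    )
    if w.volume_weight:
        raise ValueError("volume_weight requires lesion volumes; use generate_cohort")
    return raw


def generate_scores(
    lesion_loads: pd.DataFrame,
    demographics: pd.DataFrame,
    config: SimulationConfig,
    scale: Sequence[ScoreScale] | None = None,
    seed: int | None = None,
    weights: Sequence[TaskWeights] | None = None,
) -> pd.DataFrame:
    """Generate the task x patient score table from lesion loads.

    Expected raw score = intercept + Σ weight·predictor, with group-b
    lesion weights multiplied by λ and expected scores shifted by δ.
    Gaussian noise has two components: a patient-level draw shared by all
    tasks (``noise_shared_sd``, the general-severity factor that makes a
    patient's scores correlate across an aphasia battery) plus a
    task-specific draw (``noise_sd``).  Scores are T-standardized via
    ``scale`` (or returned on the raw scale when ``scale`` is None), and
    entries are deleted independently at ``missing_rate``.
    """
    if weights is None:
        weights = config.true_weights
    if weights is None:
        raise ValueError("no true_weights: pass weights or set config.true_weights")
    loads = np.asarray(lesion_loads, dtype=float)
    if loads.shape[0] != len(demographics):
        raise ValueError("lesion_loads rows must match demographics rows")
    if loads.shape[1] != len(weights[0].region_weights):
        raise ValueError(
            f"lesion_loads has {loads.shape[1]} regions but weights expect "
            f"{len(weights[0].region_weights)}"
        )
    if len(weights) != config.n_tasks:
        raise ValueError("one TaskWeights per task required")
    if scale is not None and len(scale) != config.n_tasks:
        raise ValueError("one ScoreScale per task required")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = config.task_names()
    n = loads.shape[0]
    shared = rng.normal(0.0, config.noise_shared_sd, size=n) if config.noise_shared_sd > 0 else 0.0
    out = np.empty((n, config.n_tasks))
    for t, w in enumerate(weights):
        raw = _expected_raw(loads, demographics, w, config)
        raw = raw + shared + rng.normal(0.0, config.noise_sd, size=raw.shape)
        out[:, t] = scale[t].to_t(raw) if scale is not None else raw
    if config.missing_rate > 0:
        drop = rng.random(out.shape) < config.missing_rate
        out[drop] = np.nan
    index = demographics.index if isinstance(demographics, pd.DataFrame) else None
    return pd.DataFrame(out, index=index, columns=names)


def _reference_batch(
    atlas: Atlas,
    config: SimulationConfig,
    rng: np.random.Generator,
    params: TerritoryParams | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Demographics and lesion loads of the aphasic reference sample."""
    if params is None:
        params = TerritoryParams(count=config.territory_count, spread=config.territory_spread)
    ref_demo = _draw_demographics(config.n_reference, GROUP_A, rng)
    ref_masks = generate_lesion_masks(
        atlas,
        config.n_reference,
        params,
        seed=int(rng.integers(2**31)),
    )
    ref_loads = np.array([lesion_load(m, atlas) for m in ref_masks])
    return ref_demo, ref_loads


def build_score_scales(
    atlas: Atlas,
    weights: Sequence[TaskWeights],
    config: SimulationConfig,
    seed: int,
    reference: tuple[pd.DataFrame, np.ndarray] | None = None,
) -> tuple[ScoreScale, ...]:
    """Simulate the standardization samples and build per-task scales.

    The reference sample is ``n_reference`` lesioned (aphasic-analogue)
    patients scored through the same generative model with group-a
    parameters; the control sample is ``n_controls`` lesion-free patients
    whose 5th percentile defines the impairment cutoff.  A precomputed
    ``(demographics, loads)`` reference batch may be supplied.
    """
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = _reference_batch(atlas, config, rng)
    ref_demo, ref_loads = reference
    ctl_demo = _draw_demographics(config.n_controls, GROUP_A, rng)
    ctl_loads = np.zeros((config.n_controls, atlas.n_regions))
    ref_shared = rng.normal(0.0, config.noise_shared_sd, size=config.n_reference) if config.noise_shared_sd > 0 else 0.0
    ctl_shared = rng.normal(0.0, config.noise_shared_sd, size=config.n_controls) if config.noise_shared_sd > 0 else 0.0
    scales = []
    for w in weights:
        ref_raw = _expected_raw(ref_loads, ref_demo, w, config)
        ref_raw = ref_raw + ref_shared + rng.normal(0.0, config.noise_sd, size=ref_raw.shape)
        ctl_raw = _expected_raw(ctl_loads, ctl_demo, w, config)
        ctl_raw = ctl_raw + ctl_shared + rng.normal(0.0, config.noise_sd, size=ctl_raw.shape)
        sd = float(np.std(ref_raw, ddof=1))
        if sd <= 0:  # degenerate noiseless homogeneous sample
            sd = 1.0
        scales.append(
            ScoreScale(
                reference_mean=float(np.mean(ref_raw)),
                reference_sd=sd,
                impairment_cutoff=float(np.percentile(ctl_raw, 5.0)),
            )
        )
    return tuple(scales)


def _draw_demographics(n: int, group: str, rng: np.random.Generator, start: int = 0) -> pd.DataFrame:
    """Demographics analogue: age ≈ N(53, 12.5) years, time post-stroke
    ≈ 3 + lognormal months, sex ≈ 63% male."""
    age = np.clip(rng.normal(53.0, 12.5, size=n), 18.0, 90.0)
    time = 3.0 + rng.lognormal(3.4, 0.9, size=n)
    sex = (rng.random(n) < 0.63).astype(int)
    ids = [f"{group}{start + i:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "group": group,
            "sex": sex,
            "age_at_stroke_years": age,
            "time_post_stroke_months": time,
        },
        index=pd.Index(ids, name="patient"),
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig, keep_masks: bool = False) -> Cohort:
    """Generate a complete two-group cohort under ``config``.

    Produces the atlas, per-patient lesion masks, encoded region loads and
    lesion volumes, T-standardized task scores with missingness,
    native-language scores on seven tasks for group b, and Table-style
    language-history fields for group b.  Byte-identical given the same
    config (all randomness flows from ``config.seed``).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(9)]
    atlas = generate_atlas(
        config.grid_dims,
        config.n_regions,
        config.atlas_overlap,
        seed=seeds[0],
        voxel_volume=config.voxel_volume,
    )
    # territory anatomy is a cohort-level constant shared by the reference
    # sample and both patient groups
    rng_terr = np.random.default_rng(seeds[2])
    base_params = TerritoryParams(count=config.territory_count, spread=config.territory_spread)
    centers = _territory_centers(atlas.grid_dims, base_params, rng_terr)
    params = TerritoryParams(
        count=config.territory_count,
        spread=config.territory_spread,
        centers=tuple(map(tuple, centers.tolist())),
    )
    # reference batch doubles as the lesion-prevalence source, so the
    # deficit-relevant regions fall inside the simulated territories
    reference = _reference_batch(atlas, config, rng_terr, params)
    prevalence = reference[1].mean(axis=0)
    rng_w = np.random.default_rng(seeds[1])
    weights = config.true_weights or draw_task_weights(config, rng_w, prevalence)
    scales = build_score_scales(atlas, weights, config, seed=seeds[8], reference=reference)

    rng_demo = np.random.default_rng(seeds[3])
    demo = pd.concat(
        [
            _draw_demographics(config.n_group_a, GROUP_A, rng_demo),
            _draw_demographics(config.n_group_b, GROUP_B, rng_demo),
        ]
    )
    n_total = config.n_group_a + config.n_group_b
    masks = generate_lesion_masks(atlas, n_total, params, seed=seeds[4])
    loads = pd.DataFrame(
        np.array([lesion_load(m, atlas) for m in masks]),
        index=demo.index,
        columns=atlas.region_names,
    )
    volumes = pd.Series(
        masks.reshape(n_total, -1).sum(axis=1).astype(float) * atlas.voxel_volume,
        index=demo.index,
        name="lesion_volume_mm3",
    )
    scores = generate_scores(loads, demo, config, scale=scales, seed=seeds[5], weights=weights)

    rng_nat = np.random.default_rng(seeds[6])
    native = _native_scores(scores, demo, config, rng_nat)
    rng_hist = np.random.default_rng(seeds[7])
    history = _history_table(demo, scores, config, rng_hist)

    return Cohort(
        demographics=demo,
        loads=loads,
        lesion_volume=volumes,
        scores=scores,
        atlas=atlas,
        native_scores=native,
        history=history,
        masks=masks if keep_masks else None,
        config=config,
        true_weights=weights,
        scales=scales,
        seed=config.seed,
    )


def _native_scores(
    scores: pd.DataFrame,
    demo: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Native-language (L1) scores for group b on the seven narrative and
    naming tasks: English score + shift + noise, with missingness."""
    tasks = [t for t in NATIVE_TASKS if t in scores.columns]
    b_idx = demo.index[demo["group"] == GROUP_B]
    native = pd.DataFrame(np.nan, index=demo.index, columns=tasks)
    for t in tasks:
        vals = scores.loc[b_idx, t] + config.native_shift + rng.normal(0.0, config.native_sd, size=len(b_idx))
        drop = rng.random(len(b_idx)) < config.native_missing_rate
        vals[drop] = np.nan
        native.loc[b_idx, t] = vals
    return native


def _history_table(
    demo: pd.DataFrame,
    scores: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Language-history fields for group b.

    Independent of scores by default (a true null for the history screen);
    ``history_effect`` couples self-rated proficiency to the patients'
    mean score deviation for power testing.
    """
    b_idx = demo.index[demo["group"] == GROUP_B]
    n = len(b_idx)
    hist = pd.DataFrame(np.nan, index=demo.index, columns=list(HISTORY_FIELDS))
    hist.loc[b_idx, "n_languages"] = 2 + rng.poisson(1.3, size=n)
    hist.loc[b_idx, "age_of_bilingualism"] = np.clip(rng.gamma(2.0, 3.0, size=n), 0, 20)
    hist.loc[b_idx, "age_learned_l2"] = np.clip(2 + rng.gamma(2.5, 3.5, size=n), 2, 45)
    hist.loc[b_idx, "years_l2_used"] = np.clip(rng.normal(40.0, 15.0, size=n), 5, 80)
    prof = np.clip(9.0 - rng.exponential(0.9, size=n), 1.0, 9.0)
    if config.history_effect != 0.0:
        dev = (scores.loc[b_idx] - scores.loc[b_idx].mean()).mean(axis=1).fillna(0.0)
        sd = float(dev.std(ddof=1)) or 1.0
        prof = np.clip(prof + config.history_effect * (dev.to_numpy() / sd), 1.0, 9.0)
    hist.loc[b_idx, "self_rated_proficiency"] = prof
    hist.loc[b_idx, "pct_l2_use_pre"] = np.clip(rng.normal(74.0, 18.0, size=n), 10, 100)
    hist.loc[b_idx, "pct_l2_use_post"] = np.clip(rng.normal(65.0, 22.0, size=n), 5, 100)
    if config.history_missing_rate > 0:
        drop = rng.random((n, len(HISTORY_FIELDS))) < config.history_missing_rate
        block = hist.loc[b_idx].to_numpy()
        block[drop] = np.nan
        hist.loc[b_idx, :] = block
    return hist


# ---------------------------------------------------------------------------
# On-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as NIfTI masks + TSV tables + YAML config.

    Layout: ``masks/<patient>.nii.gz``, ``atlas/`` (per-region masks and
    manifest), ``demographics.tsv``, ``scores.tsv``, ``native_scores.tsv``,
    ``history.tsv``, ``config.yaml`` (includes the seed).
    """
    from . import encoding

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort.masks is None:
        raise ValueError("cohort has no masks (generate with keep_masks=True)")
    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for i, pid in enumerate(cohort.patients):
        lm = LesionMask(cohort.masks[i], voxel_volume=cohort.atlas.voxel_volume)
        encoding.write_mask_nifti(lm, mask_dir / f"{pid}.nii.gz")
    encoding.write_atlas(cohort.atlas, outdir / "atlas")
    cohort.demographics.to_csv(outdir / "demographics.tsv", sep="\t")
    cohort.scores.to_csv(outdir / "scores.tsv", sep="\t")
    if cohort.native_scores is not None:
        cohort.native_scores.to_csv(outdir / "native_scores.tsv", sep="\t")
    if cohort.history is not None:
        cohort.history.to_csv(outdir / "history.tsv", sep="\t")
    meta = {"seed": cohort.seed}
    if cohort.config is not None:
        meta["config"] = cohort.config.to_dict()
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (masks re-encoded)."""
    from . import encoding

    indir = Path(indir)
    atlas = encoding.read_atlas(indir / "atlas")
    demo = pd.read_csv(indir / "demographics.tsv", sep="\t", index_col="patient")
    scores = pd.read_csv(indir / "scores.tsv", sep="\t", index_col="patient")
    native = None
    if (indir / "native_scores.tsv").exists():
        native = pd.read_csv(indir / "native_scores.tsv", sep="\t", index_col="patient")
    history = None
    if (indir / "history.tsv").exists():
        history = pd.read_csv(indir / "history.tsv", sep="\t", index_col="patient")
    masks = []
    for pid in demo.index:
        lm = encoding.read_mask_nifti(indir / "masks" / f"{pid}.nii.gz")
        masks.append(lm.data)
    masks_arr = np.stack(masks)
    loads = pd.DataFrame(
        np.array([lesion_load(m, atlas) for m in masks_arr]),
        index=demo.index,
        columns=atlas.region_names,
    )
    volumes = pd.Series(
        masks_arr.reshape(len(demo), -1).sum(axis=1).astype(float) * atlas.voxel_volume,
        index=demo.index,
        name="lesion_volume_mm3",
    )
    with open(indir / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    return Cohort(
        demographics=demo,
        loads=loads,
        lesion_volume=volumes,
        scores=scores,
        atlas=atlas,
        native_scores=native,
        history=history,
        masks=masks_arr,
        seed=meta.get("seed"),
    )
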