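"""Region-wise encoding of binary lesion masks.

Converts binary lesion images in a shared (MNI-like) voxel grid into
per-region lesion loads (percentage of each region destroyed), applies the
automatable cohort inclusion rules (time post-stroke >= 3 months; largest
contiguous lesion component >= 1 cm^3), and assembles the predictor table
used by the prognostic models: one column per region plus total lesion
volume, time post-stroke, sex and age.

Masks and parcellation must share one voxel grid; no resampling is done.
Regions may overlap (the parcellation may be a union of several atlases),
and nothing downstream assumes disjointness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: The four non-region predictors, in fixed column order after the regions.
DEMOGRAPHIC_COLUMNS = (
    "lesion_volume_mm3",
    "time_post_stroke_months",
    "sex",
    "age_at_stroke_years",
)

#: Sex encoding used throughout: 0 = female, 1 = male.
SEX_FEMALE, SEX_MALE = 0, 1

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


class GridMismatchError(ValueError):
    """Mask and atlas (or two masks) do not share a voxel grid."""


@dataclass(frozen=True)
class Atlas:
    """A parcellation: named voxel-index sets on a common 3D grid.

    Regions are stored as flat (raveled, C-order) voxel indices.  They may
    overlap; each must be non-empty and names must be unique.
    """

    grid_dims: tuple[int, int, int]
    voxel_volume: float  # mm^3 per voxel
    regions: tuple[tuple[str, np.ndarray], ...]
    hemisphere_tag: str = "L"

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(int(d) <= 0 for d in self.grid_dims):
            raise ValueError(f"grid_dims must be 3 positive ints, got {self.grid_dims}")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        n_vox = int(np.prod(self.grid_dims))
        names = [name for name, _ in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for name, idx in self.regions:
            idx = np.asarray(idx)
            if idx.size == 0:
                raise ValueError(f"region {name!r} is empty")
            if idx.min() < 0 or idx.max() >= n_vox:
                raise ValueError(f"region {name!r} has voxel indices outside the grid")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_names(self) -> list[str]:
        return [name for name, _ in self.regions]

    def region_sizes(self) -> np.ndarray:
        return np.array([idx.size for _, idx in self.regions])

    def membership_matrix(self) -> np.ndarray:
        """Boolean (n_regions, n_voxels) matrix of region membership."""
        n_vox = int(np.prod(self.grid_dims))
        m = np.zeros((self.n_regions, n_vox), dtype=bool)
        for i, (_, idx) in enumerate(self.regions):
            m[i, idx] = True
        return m


@dataclass(frozen=True)
class LesionMask:
    """A binary lesion image on a 3D grid (1 = lesioned voxel)."""

    data: np.ndarray
    voxel_volume: float = 1.0
    space_label: str = "MNI"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("lesion mask must be a 3D array")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("lesion mask must be binary (values in {0, 1})")
        object.__setattr__(self, "data", data.astype(np.uint8))

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def volume(self) -> float:
        """Total lesioned volume in mm^3 (all components)."""
        return float(self.data.sum()) * self.voxel_volume


def _as_mask_array(mask: LesionMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, LesionMask):
        return mask.data
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("mask must be binary")
    return arr.astype(np.uint8)


def lesion_load(mask: LesionMask | np.ndarray, atlas: Atlas) -> np.ndarray:
    """Percentage of each atlas region destroyed by the lesion.

    For region R: ``100 * |lesion ∩ R| / |R|``, so 0 when the region is
    fully preserved and 100 when it is completely destroyed.  Returns one
    value per region, in atlas order.
    """
    arr = _as_mask_array(mask)
    if tuple(arr.shape) != tuple(atlas.grid_dims):
        raise GridMismatchError(
            f"mask grid {arr.shape} does not match atlas grid {atlas.grid_dims}"
        )
    flat = arr.ravel()
    loads = np.empty(atlas.n_regions)
    for i, (_, idx) in enumerate(atlas.regions):
        loads[i] = 100.0 * flat[idx].sum() / idx.size
    return loads


def largest_component_volume(
    mask: LesionMask | np.ndarray,
    voxel_volume: float | None = None,
    connectivity: int = 26,
) -> float:
    """Volume (mm^3) of the largest connected lesion component.

    ``connectivity`` is 6, 18 or 26 (neighbours sharing a face, edge or
    corner).  Returns 0 for an empty mask.
    """
    arr = _as_mask_array(mask)
    if voxel_volume is None:
        voxel_volume = mask.voxel_volume if isinstance(mask, LesionMask) else 1.0
    try:
        struct = _CONNECTIVITY_STRUCTS[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labels, n = ndimage.label(arr, structure=struct)
    if n == 0:
        return 0.0
    counts = np.bincount(labels.ravel())[1:]
    return float(counts.max()) * float(voxel_volume)


#: Exclusion reason codes written to the inclusion log.
EXCLUDE_LT3MONTHS = "lt3months"
EXCLUDE_SUB_CM3 = "sub_cm3"


def apply_inclusion_criteria(
    time_post_stroke: Sequence[float] | pd.Series,
    masks: Sequence[LesionMask | np.ndarray],
    voxel_volume: float | None = None,
    *,
    min_months: float = 3.0,
    min_volume_mm3: float = 1000.0,
    connectivity: int = 26,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the automatable inclusion rules to a raw patient list.

    Excludes patients assessed less than ``min_months`` post-stroke and
    patients whose largest contiguous lesion component is below
    ``min_volume_mm3`` (default 1 cm^3).  Returns a boolean keep-mask
    aligned with the input order and a log with one reason code per
    excluded patient (a patient failing both rules is logged once per
    rule).
    """
    times = pd.Series(time_post_stroke)
    if len(times) != len(masks):
        raise ValueError("time_post_stroke and masks must have equal length")
    keep = np.ones(len(times), dtype=bool)
    rows = []
    for i, (pid, t) in enumerate(times.items()):
        mask = masks[i]
        if mask is None:
            raise ValueError(f"patient {pid!r} has no lesion mask")
        if t < min_months:
            keep[i] = False
            rows.append({"patient": pid, "code": EXCLUDE_LT3MONTHS})
        vol = largest_component_volume(mask, voxel_volume, connectivity=connectivity)
        if vol < min_volume_mm3:
            keep[i] = False
            rows.append({"patient": pid, "code": EXCLUDE_SUB_CM3})
    log = pd.DataFrame(rows, columns=["patient", "code"])
    return keep, log


def build_predictor_table(
    loads: pd.DataFrame,
    lesion_volume_mm3: pd.Series,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the patients x (regions + 4) predictor table.

    Columns are the region loads in atlas order followed by total lesion
    volume, time post-stroke (months), sex (0 = female, 1 = male) and age
    at stroke (years).  With the 199-region parcellation this is the
    203-predictor encoding.
    """
    required = {"time_post_stroke_months", "sex", "age_at_stroke_years"}
    missing = required - set(demographics.columns)
    if missing:
        raise ValueError(f"demographics table lacks columns: {sorted(missing)}")
    if not loads.index.equals(demographics.index):
        raise ValueError("loads and demographics must be indexed by the same patients")
    if set(DEMOGRAPHIC_COLUMNS) & set(loads.columns):
        raise ValueError("region names collide with reserved demographic column names")
    table = loads.copy()
    table["lesion_volume_mm3"] = pd.Series(lesion_volume_mm3, index=loads.index)
    table["time_post_stroke_months"] = demographics["time_post_stroke_months"]
    table["sex"] = demographics["sex"]
    table["age_at_stroke_years"] = demographics["age_at_stroke_years"]
    if table.columns.duplicated().any():
        raise ValueError("duplicate predictor labels")
    return table


def encode_cohort(
    masks: Sequence[LesionMask | np.ndarray],
    atlas: Atlas,
    demographics: pd.DataFrame,
) -> pd.DataFrame:
    """Encode masks against ``atlas`` and build the full predictor table."""
    if len(masks) != len(demographics):
        raise ValueError("one mask per patient required")
    load_rows = np.array([lesion_load(m, atlas) for m in masks])
    loads = pd.DataFrame(load_rows, index=demographics.index, columns=atlas.region_names)
    vols = pd.Series(
        [float(_as_mask_array(m).sum()) * atlas.voxel_volume for m in masks],
        index=demographics.index,
    )
    return build_predictor_table(loads, vols, demographics)


# ---------------------------------------------------------------------------
# NIfTI / TSV interfaces
# ---------------------------------------------------------------------------

def _affine(voxel_volume: float) -> np.ndarray:
    size = float(voxel_volume) ** (1.0 / 3.0)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = size
    return aff


def write_mask_nifti(mask: LesionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_volume))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path, space_label: str = "MNI") -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel_volume = float(abs(np.linalg.det(img.affine[:3, :3])))
    data = (data > 0.5).astype(np.uint8)
    return LesionMask(data=data, voxel_volume=voxel_volume, space_label=space_label)


def write_atlas(atlas: Atlas, directory: str | Path) -> None:
    """Write an atlas as per-region binary NIfTI masks plus a TSV manifest.

    Region masks are stored individually (``region_000.nii.gz`` ...) so
    overlapping parcellations round-trip exactly; the manifest maps file
    names to region names.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (name, idx) in enumerate(atlas.regions):
        vol = np.zeros(int(np.prod(atlas.grid_dims)), dtype=np.uint8)
        vol[idx] = 1
        fname = f"region_{i:03d}.nii.gz"
        img = nib.Nifti1Image(vol.reshape(atlas.grid_dims), _affine(atlas.voxel_volume))
        nib.save(img, str(directory / fname))
        rows.append({"file": fname, "region": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "regions.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        [
            {
                "grid_dims": "x".join(str(d) for d in atlas.grid_dims),
                "voxel_volume": atlas.voxel_volume,
                "hemisphere_tag": atlas.hemisphere_tag,
            }
        ]
    )
    meta.to_csv(directory / "atlas_meta.tsv", sep="\t", index=False)


def read_atlas(directory: str | Path) -> Atlas:
    """Read an atlas written by :func:`write_atlas`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "regions.tsv", sep="\t")
    meta = pd.read_csv(directory / "atlas_meta.tsv", sep="\t").iloc[0]
    grid_dims = tuple(int(d) for d in str(meta["grid_dims"]).split("x"))
    regions = []
    for _, row in manifest.iterrows():
        img = nib.load(str(directory / row["file"]))
        data = np.asarray(img.dataobj) > 0.5
        regions.append((str(row["region"]), np.flatnonzero(data.ravel())))
    return Atlas(
        grid_dims=grid_dims,  # type: ignore[arg-type]
        voxel_volume=float(meta["voxel_volume"]),
        regions=tuple(regions),
        hemisphere_tag=str(meta["hemisphere_tag"]),
    )


def read_label_atlas(
    path: str | Path,
    names: Mapping[int, str] | None = None,
    hemisphere_tag: str = "L",
) -> Atlas:
    """Build an atlas from an integer label image (one region per label > 0).

    A label image cannot represent overlapping regions; use the
    directory-of-masks layout (:func:`read_atlas`) for multi-atlas unions.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(int)
    voxel_volume = float(abs(np.linalg.det(img.affine[:3, :3])))
    labels = np.unique(data)
    labels = labels[labels > 0]
    flat = data.ravel()
    regions = []
    for lab in labels:
        name = names[int(lab)] if names else f"label_{int(lab):03d}"
        regions.append((name, np.flatnonzero(flat == lab)))
    return Atlas(
        grid_dims=tuple(data.shape),  # type: ignore[arg-type]
        voxel_volume=voxel_volume,
        regions=tuple(regions),
        hemisphere_tag=hemisphere_tag,
    )


def write_predictor_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="patient")


def read_predictor_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient")
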