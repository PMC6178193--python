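"""Reading and writing volumes and clinical tables; grid checks; masks.

Volumes are NIfTI-1 (via nibabel), clinical tables are tab-delimited UTF-8
with a header row.  A cohort is valid only if every map shares one grid shape
and affine and joins 1:1 with the clinical table on ``subject_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import CohortError, MaskError, TableError
from .synthetic import SyntheticAtlas

REQUIRED_COLUMNS = ("subject_id", "group", "sara", "cerebrum_volume")


@dataclass
class GrayMatterMap:
    """One subject's modulated gray-matter intensity volume."""

    subject_id: str
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise CohortError(f"{self.subject_id}: map must be 3-D, got {self.data.ndim}-D")
        if np.any(self.data < 0):
            raise CohortError(f"{self.subject_id}: negative gray-matter intensities")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class MaskDefinition:
    """Boolean analysis mask plus a record of how it was derived."""

    source: str                      # "atlas-cortical" | "intensity-threshold"
    mask: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise MaskError(f"empty mask from source {self.source!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def save_map(gm: GrayMatterMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(gm.data.astype(np.float32), gm.affine), str(path))


def load_map(path: str | Path, subject_id: str | None = None) -> GrayMatterMap:
    img = nib.load(str(path))
    sid = subject_id or Path(path).name.split(".")[0]
    return GrayMatterMap(sid, np.asarray(img.get_fdata(), dtype=float), img.affine)


def save_atlas(atlas: SyntheticAtlas, path: str | Path) -> None:
    """Write the label volume as NIfTI and the region table as a sidecar TSV."""
    path = Path(path)
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), atlas.affine), str(path))
    sidecar = path.parent / (path.name.split(".")[0] + "_regions.tsv")
    atlas.region_table.to_csv(sidecar, sep="\t", index=False)


def load_atlas(path: str | Path) -> SyntheticAtlas:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.parent / (path.name.split(".")[0] + "_regions.tsv")
    if not sidecar.exists():
        raise CohortError(f"atlas region table not found: {sidecar}")
    table = pd.read_csv(sidecar, sep="\t")
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    return SyntheticAtlas(labels, table, img.affine)


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TableError(f"clinical table missing columns {missing}")
    if table[list(REQUIRED_COLUMNS)].isna().any().any():
        raise TableError("missing values in required clinical columns")
    if table.subject_id.duplicated().any():
        dup = table.subject_id[table.subject_id.duplicated()].tolist()
        raise TableError(f"duplicate subject ids: {dup}")
    bad = table[(table.sara < 0) | (table.sara > 40)]
    if len(bad):
        raise TableError(f"sara outside [0, 40] for subjects {bad.subject_id.tolist()}")
    return table


def validate_cohort(maps: Sequence[GrayMatterMap], table: pd.DataFrame) -> None:
    """Enforce common grid and a complete 1:1 join on subject_id."""
    if not len(maps):
        raise CohortError("no maps supplied")
    ref = maps[0]
    for m in maps[1:]:
        if m.shape != ref.shape:
            raise CohortError(
                f"shape mismatch for {m.subject_id}: {m.shape} vs {ref.shape}")
        if not np.allclose(m.affine, ref.affine):
            raise CohortError(f"affine mismatch for {m.subject_id}")
    map_ids = {m.subject_id for m in maps}
    table_ids = set(table.subject_id)
    if map_ids - table_ids:
        raise TableError(f"maps without a table row: {sorted(map_ids - table_ids)}")
    if table_ids - map_ids:
        raise TableError(f"table rows without a map: {sorted(table_ids - map_ids)}")


def load_cohort(map_paths: Iterable[str | Path], table_path: str | Path,
                atlas_path: str | Path | None = None,
                ) -> tuple[list[GrayMatterMap], pd.DataFrame, SyntheticAtlas | None]:
    """Load maps + clinical table (+ optional atlas) and validate consistency."""
    maps = [load_map(p) for p in map_paths]
    table = load_table(table_path)
    validate_cohort(maps, table)
    atlas = None
    if atlas_path is not None:
        atlas = load_atlas(atlas_path)
        if atlas.label_volume.shape != maps[0].shape:
            raise CohortError(
                f"atlas grid {atlas.label_volume.shape} does not match maps {maps[0].shape}")
    # order maps as in the table for downstream positional alignment
    by_id = {m.subject_id: m for m in maps}
    maps = [by_id[s] for s in table.subject_id]
    return maps, table, atlas


def gm_mask(maps: Sequence[GrayMatterMap] | None = None,
            atlas: SyntheticAtlas | None = None,
            source: str = "atlas-cortical",
            threshold: float = 0.1,
            control_ids: Iterable[str] | None = None) -> MaskDefinition:
    """Define the gray-matter analysis mask.

    ``atlas-cortical`` (default): union of cortical atlas labels.
    ``intensity-threshold``: voxels whose control-group mean intensity exceeds
    ``threshold`` (all maps if ``control_ids`` is None).
    """
    if source == "atlas-cortical":
        if atlas is None:
            raise MaskError("atlas-cortical mask requested but no atlas given")
        return MaskDefinition(source, atlas.cortical_mask())
    if source == "intensity-threshold":
        if not maps:
            raise MaskError("intensity-threshold mask requested but no maps given")
        sel = maps
        if control_ids is not None:
            wanted = set(control_ids)
            sel = [m for m in maps if m.subject_id in wanted]
            if not sel:
                raise MaskError("no control maps found for threshold mask")
        mean = np.mean([m.data for m in sel], axis=0)
        return MaskDefinition(source, mean > threshold, threshold=threshold)
    raise MaskError(f"unknown mask source {source!r}")
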