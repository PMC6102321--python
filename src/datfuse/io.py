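"""Cohort container and on-disk formats.

A cohort on disk is a directory with a YAML manifest tying everything
together:

.. code-block:: yaml

    cohort: phantom
    classes: [HC, PD]
    atlas: atlas.nii.gz
    subjects:
      - {id: HC001, label: HC, volume: volumes/HC001.nii.gz}
      - ...
    sources:
      CSF: sources/CSF.csv
    provenance: {seed: 7, package: datfuse 0.1.0}

Volumes are NIfTI (float), the atlas integer NIfTI on the same grid.
Biomarker tables are comma-separated UTF-8 CSV with a mandatory header row
``subject_id,<test>,...``; an empty cell is a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grids import GridMismatchError, IntensityVolume, ROILabelMap

__all__ = ["Cohort", "ManifestError", "write_cohort", "load_cohort"]


class ManifestError(ValueError):
    """A manifest is malformed or references missing/inconsistent files."""


@dataclass
class Cohort:
    """In-memory cohort: volumes + atlas + biomarker tables + labels.

    ``labels`` is indexed by subject id; ``sources`` maps a source name to a
    subjects × tests DataFrame (NaN = missing) indexed the same way.
    """

    volumes: dict[str, IntensityVolume]
    atlas: ROILabelMap
    sources: dict[str, pd.DataFrame]
    labels: pd.Series
    name: str = "cohort"
    classes: tuple[str, ...] = ("HC", "PD")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate subject ids in labels")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {sorted(unknown)}")
        vol_ids = set(self.volumes)
        if vol_ids and vol_ids != set(self.labels.index):
            raise ValueError("volumes and labels cover different subjects")
        for vol in self.volumes.values():
            self.atlas.check_same_grid(vol)
        for name, table in self.sources.items():
            extra = set(table.index) - set(self.labels.index)
            if extra:
                raise ValueError(
                    f"source {name!r} has unknown subjects: {sorted(extra)[:5]}"
                )

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.labels.index)

    def __len__(self) -> int:
        return len(self.labels)


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort to ``directory``; returns the manifest path.

    Layout: ``atlas.nii.gz``, ``volumes/<id>.nii.gz``, ``sources/<name>.csv``
    and ``manifest.yaml``. Volumes are stored as float32 (the documented
    storage precision of the round-trip).
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    try:
        (directory / "volumes").mkdir(parents=True, exist_ok=True)
        (directory / "sources").mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create cohort directory {directory}: {err}") from err

    vx = next(iter(cohort.volumes.values())).voxel_size_mm if cohort.volumes else 1.0
    nib.save(
        nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), _affine(vx)),
        directory / "atlas.nii.gz",
    )
    subjects = []
    for sid in cohort.subject_ids:
        entry = {"id": str(sid), "label": str(cohort.labels[sid])}
        if sid in cohort.volumes:
            vol = cohort.volumes[sid]
            rel = f"volumes/{sid}.nii.gz"
            nib.save(
                nib.Nifti1Image(
                    vol.data.astype(np.float32), _affine(vol.voxel_size_mm)
                ),
                directory / rel,
            )
            entry["volume"] = rel
        subjects.append(entry)

    source_entries = {}
    for name, table in cohort.sources.items():
        rel = f"sources/{name}.csv"
        out = table.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(directory / rel, index=False)
        source_entries[name] = rel

    manifest = {
        "cohort": cohort.name,
        "classes": list(cohort.classes),
        "atlas": "atlas.nii.gz",
        "voxel_size_mm": float(vx),
        "subjects": subjects,
        "sources": source_entries,
        "provenance": cohort.provenance,
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def _load_volume(path: Path) -> IntensityVolume:
    img = nib.load(path)
    voxel = float(img.header.get_zooms()[0])
    return IntensityVolume(np.asarray(img.dataobj, dtype=np.float64), voxel)


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from its YAML manifest, validating grids and labels."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    spec = yaml.safe_load(manifest_path.read_text())
    for key in ("classes", "atlas", "subjects"):
        if key not in spec:
            raise ManifestError(f"manifest missing required key {key!r}")

    atlas_path = root / spec["atlas"]
    if not atlas_path.exists():
        raise ManifestError(f"atlas file missing: {atlas_path}")
    atlas_img = nib.load(atlas_path)
    atlas = ROILabelMap(np.asarray(atlas_img.dataobj).astype(np.int64))

    labels: dict[str, str] = {}
    volumes: dict[str, IntensityVolume] = {}
    for entry in spec["subjects"]:
        sid, label = str(entry["id"]), str(entry["label"])
        labels[sid] = label
        if "volume" in entry:
            vol_path = root / entry["volume"]
            if not vol_path.exists():
                raise ManifestError(f"volume file missing: {vol_path}")
            volumes[sid] = _load_volume(vol_path)

    sources: dict[str, pd.DataFrame] = {}
    for name, rel in (spec.get("sources") or {}).items():
        csv_path = root / rel
        if not csv_path.exists():
            raise ManifestError(f"source table missing: {csv_path}")
        table = pd.read_csv(csv_path, dtype={"subject_id": str})
        if "subject_id" not in table.columns:
            raise ManifestError(f"source {name!r} lacks a subject_id column")
        sources[name] = table.set_index("subject_id")

    try:
        return Cohort(
            volumes=volumes,
            atlas=atlas,
            sources=sources,
            labels=pd.Series(labels, name="label"),
            name=str(spec.get("cohort", "cohort")),
            classes=tuple(spec["classes"]),
            provenance=dict(spec.get("provenance") or {}),
        )
    except (ValueError, GridMismatchError) as err:
        raise ManifestError(f"inconsistent cohort at {manifest_path}: {err}") from err
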