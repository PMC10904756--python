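"""Reading and writing specimens as NIfTI / multi-page TIFF plus CSV tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .phantom import (MODALITIES, AnnotationSet, LabelVolume,
                      MultimodalVolume, PhantomSpec, SpecimenRecord,
                      SymptomHistory)


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(array: np.ndarray, spacing: Sequence[float], path: Path,
                fmt: str = "nifti") -> Path:
    """Write one 3D grid as ``.nii.gz`` or a z-stack ``.tiff``."""
    path = Path(path)
    if fmt == "nifti":
        if not path.name.endswith((".nii", ".nii.gz")):
            path = path.with_name(path.name + ".nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(array), _affine(spacing)), str(path))
    elif fmt == "tiff":
        path = path.with_name(path.name + ".tiff") if not path.suffix else path
        tifffile.imwrite(str(path), np.transpose(np.asarray(array), (2, 1, 0)),
                         metadata={"spacing_mm": list(spacing)})
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def load_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return np.asarray(img.dataobj), spacing
    if path.suffix in (".tif", ".tiff"):
        data = np.transpose(tifffile.imread(str(path)), (2, 1, 0))
        return data, (1.0, 1.0, 1.0)
    raise ValueError(f"unrecognized volume file {path.name!r}")


def save_specimen(record: SpecimenRecord, outdir: Path, fmt: str = "nifti") -> dict[str, Path]:
    """Write a specimen's modality volumes, labels and annotations CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spacing = record.volume.spacing
    written = {}
    for m in record.volume.modalities:
        written[m] = save_volume(record.volume.get(m), spacing,
                                 outdir / f"{record.specimen_id}_{m}", fmt)
    written["labels"] = save_volume(record.labels.data, spacing,
                                    outdir / f"{record.specimen_id}_labels", fmt)
    meta = {
        "specimen_id": record.specimen_id,
        "trunk_head_position": list(record.trunk_head_position),
        "reference_point": list(record.reference_point),
        "spec": dataclasses.asdict(record.spec),
    }
    meta_path = outdir / f"{record.specimen_id}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written["meta"] = meta_path
    return written


def load_specimen_volumes(outdir: Path, specimen_id: str) -> tuple[MultimodalVolume, LabelVolume]:
    outdir = Path(outdir)
    channels = {}
    spacing = None
    for m in MODALITIES:
        for candidate in (f"{specimen_id}_{m}.nii.gz", f"{specimen_id}_{m}.tiff"):
            p = outdir / candidate
            if p.exists():
                channels[m], spacing = load_volume(p)
                break
    if not channels:
        raise FileNotFoundError(f"no modality volumes for {specimen_id!r} in {outdir}")
    for candidate in (f"{specimen_id}_labels.nii.gz", f"{specimen_id}_labels.tiff"):
        p = outdir / candidate
        if p.exists():
            label_data, _ = load_volume(p)
            break
    else:
        raise FileNotFoundError(f"no label volume for {specimen_id!r} in {outdir}")
    return (MultimodalVolume(channels=channels, spacing=spacing),
            LabelVolume(data=label_data, spacing=spacing))


def save_annotations(annotations: AnnotationSet, path: Path) -> Path:
    path = Path(path)
    annotations.table.to_csv(path, index=False)
    return path


def load_annotations(path: Path) -> AnnotationSet:
    return AnnotationSet(table=pd.read_csv(path))


def save_cohort_history(histories: Iterable[SymptomHistory], path: Path) -> Path:
    rows = []
    for h in histories:
        for year in h.years:
            rows.append({"vine_id": h.vine_id, "year": year, "symptom": int(h.flags[year]),
                         "apoplexy": int(h.apoplexy_year == year) if h.apoplexy_year else 0})
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    return Path(path)


def load_cohort_history(path: Path) -> dict[str, SymptomHistory]:
    frame = pd.read_csv(path)
    histories = {}
    for vine_id, group in frame.groupby("vine_id"):
        flags = {int(r.year): bool(r.symptom) for r in group.itertuples()}
        apoplexy = [int(r.year) for r in group.itertuples() if getattr(r, "apoplexy", 0)]
        histories[str(vine_id)] = SymptomHistory(vine_id=str(vine_id), flags=flags,
                                                 apoplexy_year=apoplexy[0] if apoplexy else None)
    return histories


def save_phantom_config(spec: PhantomSpec, path: Path, extra: Optional[Mapping] = None) -> Path:
    payload = {"spec": dataclasses.asdict(spec), **(dict(extra) if extra else {})}
    Path(path).write_text(json.dumps(payload, indent=2))
    return Path(path)
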