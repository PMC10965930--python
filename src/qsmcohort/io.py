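"""NIfTI and sidecar IO for volumes, multi-echo data, atlases, and tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .recon import MultiEchoGRE
from .roi import VOIAtlas


def _affine(voxel_size_mm):
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(path, volume, voxel_size_mm=(1.0, 1.0, 1.0), dtype=np.float32):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume).astype(dtype), _affine(voxel_size_mm))
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def save_gre(prefix, data: MultiEchoGRE):
    """Write 4D magnitude/phase NIfTIs plus a JSON sidecar with acquisition
    metadata. ``prefix`` is a path stem (e.g. out/sub01)."""
    prefix = Path(prefix)
    save_volume(prefix.with_suffix("").as_posix() + "_mag.nii.gz",
                data.magnitude, data.voxel_size_mm)
    save_volume(prefix.with_suffix("").as_posix() + "_phase.nii.gz",
                data.phase, data.voxel_size_mm)
    meta = {
        "te_ms": list(data.te_ms),
        "b0_tesla": data.b0_tesla,
        "b0_direction": list(data.b0_direction),
        "voxel_size_mm": list(data.voxel_size_mm),
    }
    meta_path = Path(prefix.with_suffix("").as_posix() + "_meta.json")
    meta_path.write_text(json.dumps(meta, indent=2))
    return meta_path


def load_gre(prefix=None, mag_path=None, phase_path=None, meta_path=None) -> MultiEchoGRE:
    if prefix is not None:
        stem = Path(prefix).with_suffix("").as_posix()
        mag_path = stem + "_mag.nii.gz"
        phase_path = stem + "_phase.nii.gz"
        meta_path = stem + "_meta.json"
    meta = json.loads(Path(meta_path).read_text())
    mag, voxel = load_volume(mag_path)
    phase, _ = load_volume(phase_path)
    return MultiEchoGRE(
        magnitude=mag, phase=np.clip(phase, -np.pi, np.pi),
        te_ms=meta["te_ms"],
        voxel_size_mm=tuple(meta.get("voxel_size_mm", voxel)),
        b0_tesla=meta.get("b0_tesla", 3.0),
        b0_direction=tuple(meta.get("b0_direction", (0.0, 0.0, 1.0))),
    )


def save_atlas(path, atlas: VOIAtlas, labels_json=None):
    path = Path(path)
    save_volume(path, atlas.labels, atlas.voxel_size_mm, dtype=np.int16)
    labels_json = Path(labels_json) if labels_json else path.with_name(
        path.name.split(".")[0] + "_labels.json")
    labels_json.write_text(json.dumps(atlas.label_map, indent=2))
    return labels_json


def load_atlas(path, labels_json) -> VOIAtlas:
    labels, voxel = load_volume(path)
    label_map = json.loads(Path(labels_json).read_text())
    return VOIAtlas(labels.astype(np.int16), label_map, voxel)
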