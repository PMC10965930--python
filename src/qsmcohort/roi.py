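"""VOI-based susceptibility and volume measurements.

Measurement conventions:

* susceptibility of a structure = mean chi over the VOI after a 2-pixel
  in-plane (per axial slice) erosion, computed per hemisphere and then
  averaged left/right (unweighted) — the erosion limits partial-volume
  contamination at structure boundaries;
* volume of a structure = voxel count of the *uneroded* VOI times the voxel
  volume, per hemisphere, averaged left/right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical subcortical structure names used throughout the package
STRUCTURES = (
    "red_nucleus",
    "substantia_nigra",
    "caudate",
    "putamen",
    "thalamus",
    "hippocampus",
    "nucleus_accumbens",
    "amygdala",
    "globus_pallidus_externa",
    "globus_pallidus_interna",
)

HEMISPHERES = ("left", "right")

#: column schema shared by simulated and image-derived cohort tables
COHORT_COLUMNS = (
    "subject_id",
    "group",
    "region",
    "susceptibility_ppm",
    "volume_mm3",
    "sex",
    "handedness",
    "iq",
    "illness_duration_y",
    "severity",
    "med_dose",
)


@dataclass
class VOIAtlas:
    """Labeled subcortical atlas: integer label volume plus a name map.

    ``label_map`` maps structure name -> {"left": int, "right": int};
    0 is background.
    """

    labels: np.ndarray
    label_map: dict
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D integer volume")
        seen = {}
        for name, hemis in self.label_map.items():
            for hemi, value in hemis.items():
                if hemi not in HEMISPHERES:
                    raise ValueError(f"unknown hemisphere {hemi!r} for {name!r}")
                if value in seen:
                    raise ValueError(
                        f"label value {value} assigned to both {seen[value]!r} "
                        f"and {(name, hemi)!r}"
                    )
                seen[value] = (name, hemi)

    @property
    def structures(self):
        return tuple(self.label_map)

    def mask(self, structure, hemisphere=None):
        """Boolean mask of a structure (one hemisphere, or both combined)."""
        if structure not in self.label_map:
            raise KeyError(f"structure {structure!r} not in atlas")
        hemis = self.label_map[structure]
        if hemisphere is not None:
            return self.labels == hemis[hemisphere]
        out = np.zeros(self.labels.shape, dtype=bool)
        for value in hemis.values():
            out |= self.labels == value
        return out


@dataclass
class RegionMeasurement:
    structure: str
    susceptibility_ppm: float
    volume_mm3: float
    n_voxels_used: dict
    flags: list = field(default_factory=list)


def _cross_structure(connectivity: int) -> np.ndarray:
    """2D structuring element embedded in 3D so erosion acts per axial slice."""
    if connectivity == 4:
        se2d = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    elif connectivity == 8:
        se2d = np.ones((3, 3), dtype=bool)
    else:
        raise ValueError("connectivity must be 4 or 8")
    return se2d[:, :, None]


def erode_inplane(mask, n_pixels=2, connectivity=4):
    """Erode a boolean mask slice-by-slice (axial = fixed z) by n_pixels.

    Each iteration applies one 2D binary erosion with the 4-connected cross
    (or 8-connected square) within every axial slice independently.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D (x, y, z)")
    if n_pixels < 0:
        raise ValueError("n_pixels must be nonnegative")
    if n_pixels == 0:
        return mask.copy()
    return ndimage.binary_erosion(
        mask, structure=_cross_structure(connectivity), iterations=n_pixels
    )


def erode_voi_inplane(atlas: VOIAtlas, structure: str, n_pixels=2, connectivity=4):
    """Eroded bilateral mask of one structure; error if empty in both hemispheres."""
    eroded = erode_inplane(atlas.mask(structure), n_pixels, connectivity)
    if not eroded.any():
        raise ValueError(
            f"eroded VOI for {structure!r} is empty in both hemispheres "
            f"(n_pixels={n_pixels}); structure too small for this erosion"
        )
    return eroded


def extract_measurements(chi, atlas: VOIAtlas, n_erode=2, connectivity=4):
    """Per-structure susceptibility (eroded VOI mean) and volume (uneroded).

    Parameters
    ----------
    chi : SusceptibilityMap or 3D ndarray of chi in ppm
    atlas : VOIAtlas on the same grid

    Returns
    -------
    list of RegionMeasurement, one per structure in the atlas.
    """
    chi_vol = np.asarray(getattr(chi, "chi_ppm", chi), dtype=float)
    if chi_vol.shape != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: chi {chi_vol.shape} vs atlas {atlas.labels.shape}"
        )
    voxel_volume = float(np.prod(atlas.voxel_size_mm))

    results = []
    for structure in atlas.structures:
        flags = []
        chi_by_hemi = {}
        vol_by_hemi = {}
        n_used = {}
        for hemi in atlas.label_map[structure]:
            full = atlas.mask(structure, hemi)
            vol_by_hemi[hemi] = int(full.sum()) * voxel_volume
            eroded = erode_inplane(full, n_erode, connectivity)
            n_used[hemi] = int(eroded.sum())
            if n_used[hemi] == 0:
                flags.append(f"empty_eroded_voi_{hemi}")
            else:
                chi_by_hemi[hemi] = float(chi_vol[eroded].mean())
        if not chi_by_hemi:
            raise ValueError(
                f"eroded VOI for {structure!r} is empty in both hemispheres"
            )
        if flags:
            logger.warning("structure %s: %s", structure, "; ".join(flags))
        results.append(
            RegionMeasurement(
                structure=structure,
                susceptibility_ppm=float(np.mean(list(chi_by_hemi.values()))),
                volume_mm3=float(np.mean(list(vol_by_hemi.values()))),
                n_voxels_used=n_used,
                flags=flags,
            )
        )
    return results


def cohort_extract(subjects: Iterable, n_erode=2, connectivity=4):
    """Batch VOI extraction over a cohort.

    Parameters
    ----------
    subjects : iterable of (subject_id, group, chi, atlas) or
        (subject_id, group, chi, atlas, covariates-dict)

    Returns
    -------
    (table, exclusions) : a long-format DataFrame with the shared cohort
        schema, and a list of {"subject_id", "error"} records for subjects
        whose extraction failed (excluded, never silently dropped).
    """
    rows = []
    exclusions = []
    n_ok = 0
    for entry in subjects:
        subject_id, group, chi, atlas = entry[:4]
        covariates = entry[4] if len(entry) > 4 else {}
        try:
            measurements = extract_measurements(chi, atlas, n_erode, connectivity)
        except Exception as exc:  # noqa: BLE001 - contract: log and exclude
            logger.error("subject %s excluded: %s", subject_id, exc)
            exclusions.append({"subject_id": subject_id, "error": str(exc)})
            continue
        n_ok += 1
        for m in measurements:
            row = {
                "subject_id": subject_id,
                "group": group,
                "region": m.structure,
                "susceptibility_ppm": m.susceptibility_ppm,
                "volume_mm3": m.volume_mm3,
            }
            for col in COHORT_COLUMNS[5:]:
                row[col] = covariates.get(col, np.nan)
            rows.append(row)
    if n_ok == 0:
        raise ValueError("no subject could be measured")
    table = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return table, exclusions
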