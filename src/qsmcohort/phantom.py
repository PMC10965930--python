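"""Digital susceptibility phantoms, forward GRE simulation, synthetic cohorts.

Three simulators live here:

* :func:`build_phantom` rasterizes a geometric scene (ellipsoidal
  "subcortical" structures, a CSF-like ventricle pair, air-like external
  sources) into ground-truth chi / R2* volumes with masks and a VOI atlas;
* :func:`simulate_gre` forward-models a 3 T multi-echo gradient-echo
  acquisition (8 echoes, TE1 = 3.6 ms, spacing 5.91 ms by default) from that
  ground truth, including the background field of external sources, R2*
  magnitude decay, phase wrapping, and complex Gaussian noise;
* :func:`simulate_cohort` draws per-subject, per-region susceptibility and
  volume tables with configurable group means/SDs and a configurable
  group-specific standardized volume-susceptibility slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .dipole import dipole_kernel, forward_field  # noqa: F401  (re-exported)
from .recon import GAMMA_MHZ_PER_T, MultiEchoGRE
from .roi import COHORT_COLUMNS, STRUCTURES, VOIAtlas

GROUPS = ("HC", "MDD", "SCZ")

#: per-region susceptibility in ppm: group -> (mean, sd), reference cohort values
SUSCEPTIBILITY_PPM = {
    "red_nucleus": {"HC": (0.094, 0.039), "MDD": (0.099, 0.036), "SCZ": (0.097, 0.035)},
    "substantia_nigra": {"HC": (0.11, 0.029), "MDD": (0.102, 0.029), "SCZ": (0.092, 0.031)},
    "caudate": {"HC": (0.019, 0.010), "MDD": (0.023, 0.011), "SCZ": (0.020, 0.011)},
    "putamen": {"HC": (0.035, 0.017), "MDD": (0.038, 0.016), "SCZ": (0.040, 0.019)},
    "thalamus": {"HC": (0.0011, 0.011), "MDD": (0.0019, 0.011), "SCZ": (0.00010, 0.0088)},
    "hippocampus": {"HC": (-0.012, 0.0079), "MDD": (-0.0078, 0.0098), "SCZ": (-0.0088, 0.0093)},
    "nucleus_accumbens": {"HC": (0.0063, 0.0089), "MDD": (0.015, 0.015), "SCZ": (0.012, 0.015)},
    "amygdala": {"HC": (-0.014, 0.0092), "MDD": (-0.0073, 0.011), "SCZ": (-0.0097, 0.011)},
    "globus_pallidus_externa": {"HC": (0.11, 0.029), "MDD": (0.117, 0.024), "SCZ": (0.112, 0.023)},
    "globus_pallidus_interna": {"HC": (0.11, 0.030), "MDD": (0.109, 0.025), "SCZ": (0.107, 0.019)},
}

#: per-region volume in mm^3: group -> (mean, sd), reference cohort values
VOLUME_MM3 = {
    "red_nucleus": {"HC": (185, 17), "MDD": (181, 15), "SCZ": (177, 15)},
    "substantia_nigra": {"HC": (480, 45), "MDD": (471, 38), "SCZ": (461, 39)},
    "caudate": {"HC": (3044, 311), "MDD": (3073, 251), "SCZ": (2976, 389)},
    "putamen": {"HC": (2991, 321), "MDD": (3032, 268), "SCZ": (2920, 334)},
    "thalamus": {"HC": (5542, 471), "MDD": (5476, 450), "SCZ": (5234, 564)},
    "hippocampus": {"HC": (2682, 217), "MDD": (2624, 198), "SCZ": (2519, 215)},
    "nucleus_accumbens": {"HC": (316, 33), "MDD": (310, 27), "SCZ": (304, 38)},
    "amygdala": {"HC": (1125, 101), "MDD": (1112, 89), "SCZ": (1075, 105)},
    "globus_pallidus_externa": {"HC": (1143, 110), "MDD": (1149, 88), "SCZ": (1127, 103)},
    "globus_pallidus_interna": {"HC": (369, 35), "MDD": (366, 28), "SCZ": (362, 32)},
}

N_PER_GROUP = {"HC": 50, "MDD": 49, "SCZ": 24}

#: sex (male, female) and handedness (right, mixed, left) counts per group
SEX_COUNTS = {"HC": (25, 25), "MDD": (21, 28), "SCZ": (13, 11)}
HANDEDNESS_COUNTS = {"HC": (38, 9, 3), "MDD": (48, 0, 1), "SCZ": (22, 0, 2)}
IQ_STATS = {"HC": (108, 7, 20), "MDD": (112, 6, 25), "SCZ": (102, 11, 2)}  # mean, sd, n missing
ILLNESS_DURATION_Y = {"MDD": (9, 7), "SCZ": (14, 10)}
SEVERITY = {"MDD": (15.8, 4.8), "SCZ": (26.5, 8.0)}  # HAMD-17 / PANSS general
MED_DOSE = {"MDD": (217.9, 29.3), "SCZ": (406.7, 376.2)}  # imipramine / CPZ eq. mg


# ---------------------------------------------------------------------------
# geometric scene types


@dataclass
class Shape:
    """One rasterizable structure: sphere, ellipsoid, or box."""

    geometry: str
    center_vox: tuple
    radii_vox: tuple
    chi_ppm: float
    r2star_per_s: float = 20.0
    label: str = "background"
    hemisphere: str | None = None

    def __post_init__(self):
        if self.geometry not in ("sphere", "ellipsoid", "box"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        self.center_vox = tuple(float(c) for c in self.center_vox)
        radii = np.atleast_1d(np.asarray(self.radii_vox, dtype=float))
        if radii.size == 1:
            radii = np.repeat(radii, 3)
        if radii.size != 3 or (radii <= 0).any():
            raise ValueError("radii_vox must be 1 or 3 positive values")
        self.radii_vox = tuple(radii)
        if self.r2star_per_s < 0:
            raise ValueError("r2star_per_s must be nonnegative")
        if not np.isfinite(self.chi_ppm):
            raise ValueError("chi_ppm must be finite")


@dataclass
class ExternalSource:
    """Spherical susceptibility source outside the brain (e.g. air cavity)."""

    center_vox: tuple
    radius_vox: float
    chi_ppm: float = 9.0


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    shapes: Sequence[Shape] = ()
    external_sources: Sequence[ExternalSource] = ()
    brain_margin_vox: int = 6
    background_r2star_per_s: float = 15.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(n <= 0 for n in self.grid_shape) or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("grid_shape and voxel_size_mm must be positive")
        if self.brain_margin_vox < 0:
            raise ValueError("brain_margin_vox must be nonnegative")


@dataclass
class GroundTruth:
    chi_true_ppm: np.ndarray
    r2star_per_s: np.ndarray
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    voi_atlas: VOIAtlas | None
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)


@dataclass
class AcquisitionParams:
    """Multi-echo GRE protocol (3 T, 8 echoes by default)."""

    te_first_ms: float = 3.6
    echo_spacing_ms: float = 5.91
    n_echoes: int = 8
    b0_tesla: float = 3.0
    gamma_mhz_per_t: float = GAMMA_MHZ_PER_T
    flip_deg: float = 15.0  # metadata only, not used by the signal model
    snr: float = np.inf
    b0_direction: tuple = (0.0, 0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_echoes < 2:
            raise ValueError("n_echoes must be >= 2")
        if self.echo_spacing_ms <= 0 or self.te_first_ms <= 0:
            raise ValueError("echo times must be positive and strictly increasing")
        if not self.snr > 0:
            raise ValueError("snr must be positive (use inf for noiseless)")

    @property
    def te_ms(self):
        return tuple(self.te_first_ms + i * self.echo_spacing_ms
                     for i in range(self.n_echoes))


# ---------------------------------------------------------------------------
# rasterization


def _coords(grid_shape):
    return np.meshgrid(*[np.arange(n, dtype=float) for n in grid_shape],
                       indexing="ij")


def _rasterize(shape: Shape, grid_shape):
    gx, gy, gz = _coords(grid_shape)
    cx, cy, cz = shape.center_vox
    rx, ry, rz = shape.radii_vox
    if shape.geometry == "box":
        return ((np.abs(gx - cx) <= rx) & (np.abs(gy - cy) <= ry)
                & (np.abs(gz - cz) <= rz))
    # sphere is an ellipsoid with equal radii
    return (((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2
            + ((gz - cz) / rz) ** 2) <= 1.0


def brain_mask_for(spec: PhantomSpec):
    """Ellipsoidal brain mask: semi-axes = grid/2 - margin, centered."""
    gx, gy, gz = _coords(spec.grid_shape)
    center = [(n - 1) / 2.0 for n in spec.grid_shape]
    semi = [n / 2.0 - spec.brain_margin_vox for n in spec.grid_shape]
    if any(s <= 0 for s in semi):
        raise ValueError("brain_margin_vox too large for this grid")
    return (((gx - center[0]) / semi[0]) ** 2 + ((gy - center[1]) / semi[1]) ** 2
            + ((gz - center[2]) / semi[2]) ** 2) <= 1.0


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize a scene into ground-truth chi, R2*, masks, and a VOI atlas.

    Deterministic given the spec. Raises on overlapping shapes (naming the
    colliding labels), shapes outside the grid, structures outside the brain
    mask, or external sources inside it.
    """
    shape3 = spec.grid_shape
    for s in spec.shapes:
        if not all(0 <= c < n for c, n in zip(s.center_vox, shape3)):
            raise ValueError(f"shape {s.label!r} center {s.center_vox} outside grid {shape3}")

    brain = brain_mask_for(spec)
    chi = np.zeros(shape3, dtype=float)
    r2s = np.where(brain, spec.background_r2star_per_s, 0.0)
    labels = np.zeros(shape3, dtype=np.int16)
    ventricle = np.zeros(shape3, dtype=bool)
    occupied = np.zeros(shape3, dtype=np.int32)  # 1-based index into shape list

    label_map: dict = {}
    structure_keys = []
    for s in spec.shapes:
        if s.label not in ("background", "ventricle"):
            key = (s.label, s.hemisphere)
            if key in structure_keys:
                raise ValueError(f"duplicate structure {key!r}")
            structure_keys.append(key)

    next_label = 1
    for i, s in enumerate(spec.shapes):
        mask = _rasterize(s, shape3)
        if not mask.any():
            raise ValueError(f"shape {s.label!r} rasterizes to zero voxels")
        collision = mask & (occupied > 0)
        if collision.any():
            idx = tuple(int(v[0]) for v in np.nonzero(collision))
            other = spec.shapes[int(occupied[idx]) - 1].label
            raise ValueError(
                f"shapes {other!r} and {s.label!r} overlap at voxel {idx}"
            )
        occupied[mask] = i + 1

        chi[mask] = s.chi_ppm
        r2s[mask] = s.r2star_per_s
        if s.label == "ventricle":
            ventricle |= mask
            if not (mask <= brain).all():
                raise ValueError("ventricle extends outside the brain mask")
        elif s.label != "background":
            if not (mask <= brain).all():
                raise ValueError(f"structure {s.label!r} extends outside the brain mask")
            hemi = s.hemisphere or "left"
            labels[mask] = next_label
            label_map.setdefault(s.label, {})[hemi] = next_label
            next_label += 1

    for src in spec.external_sources:
        mask = _rasterize(
            Shape("sphere", src.center_vox, (src.radius_vox,) * 3, src.chi_ppm),
            shape3,
        )
        if (mask & brain).any():
            raise ValueError(
                f"external source at {src.center_vox} intersects the brain mask"
            )

    atlas = VOIAtlas(labels, label_map, spec.voxel_size_mm) if label_map else None
    return GroundTruth(chi, r2s, brain, ventricle, atlas, spec.voxel_size_mm)


def external_chi(spec: PhantomSpec):
    """Susceptibility volume of the external (background) sources alone."""
    chi = np.zeros(spec.grid_shape, dtype=float)
    for src in spec.external_sources:
        mask = _rasterize(
            Shape("sphere", src.center_vox, (src.radius_vox,) * 3, src.chi_ppm),
            spec.grid_shape,
        )
        chi[mask] = src.chi_ppm
    return chi


# ---------------------------------------------------------------------------
# canned scenes


def two_sphere_scene(grid=64, margin=6):
    """Reference validation scene: a paramagnetic and a diamagnetic bilateral
    sphere pair spanning the measured subcortical chi range, a CSF-like
    ventricle pair at chi = 0, and four air-like external sources.

    The sources sit in the grid corners, far enough from the brain that the
    background phase gradient stays below pi/voxel at the last echo (so the
    wrapped phase remains spatially resolvable, as a shimmed scan's would be)
    while still dominating low spatial frequencies inside the mask.
    """
    c = (grid - 1) / 2.0
    shapes = [
        Shape("sphere", (c - 12, c, c), (8,), 0.10, 30.0,
              "paramagnetic_nucleus", "left"),
        Shape("sphere", (c + 12, c, c), (8,), 0.10, 30.0,
              "paramagnetic_nucleus", "right"),
        Shape("sphere", (c, c - 14, c), (6,), -0.015, 18.0,
              "diamagnetic_nucleus", "left"),
        Shape("sphere", (c, c + 14, c), (6,), -0.015, 18.0,
              "diamagnetic_nucleus", "right"),
        Shape("ellipsoid", (c - 3, c, c + 12), (2.5, 2.5, 6.0), 0.0, 5.0,
              "ventricle", "left"),
        Shape("ellipsoid", (c + 3, c, c + 12), (2.5, 2.5, 6.0), 0.0, 5.0,
              "ventricle", "right"),
    ]
    lo, hi = 10.0 * grid / 64.0, grid - 11.0 * grid / 64.0
    sources = [
        ExternalSource((lo, lo, 4.0), 3.0, 9.0),
        ExternalSource((hi, hi, grid - 5.0), 3.0, 9.0),
        ExternalSource((lo, hi, grid - 5.0), 3.0, 9.0),
        ExternalSource((hi, lo, 4.0), 3.0, 9.0),
    ]
    return PhantomSpec(grid_shape=(grid,) * 3, shapes=shapes,
                       external_sources=sources, brain_margin_vox=margin)


def phantom_recon_config(**overrides):
    """Reconstruction settings scaled to the 64-voxel phantom geometry.

    The in-vivo kernel schedule (radii up to 29 mm) assumes a whole-head mask
    ~75 mm in radius; on the 26 mm phantom brain a single 4 mm SMV kernel with
    a lower deconvolution truncation keeps the valid region large while
    preserving the deep tissue field (chosen by noiseless pilot runs).
    """
    from .recon import ReconConfig

    kwargs = dict(vsharp_radii_mm=(4.0,), deconv_threshold=0.02,
                  lsqr_max_iter=50, lsqr_tol=1e-4, pad_vox=8)
    kwargs.update(overrides)
    return ReconConfig(**kwargs)


def cohort_scene(grid=48, chi_by_structure=None, rng=None, radius_jitter_sd=0.2):
    """Scene with all 10 bilateral subcortical structures plus ventricles.

    ``chi_by_structure`` maps structure name -> chi (ppm); defaults to the
    HC group means. With an ``rng``, in-plane/through-plane semi-axes are
    jittered to create per-subject volume variability.
    """
    if chi_by_structure is None:
        chi_by_structure = {s: SUSCEPTIBILITY_PPM[s]["HC"][0] for s in STRUCTURES}
    c = (grid - 1) / 2.0
    slots = ([(y, -8) for y in (-12, -4, 4, 12)]
             + [(y, 8) for y in (-12, -4, 4, 12)]
             + [(-12, 0), (12, 0)])
    shapes = []
    base_radii = np.array([4.0, 3.0, 3.0])
    for structure, (dy, dz) in zip(STRUCTURES, slots):
        for hemi, dx in (("left", -8.0), ("right", 8.0)):
            radii = base_radii.copy()
            if rng is not None:
                radii = np.clip(radii + rng.normal(0, radius_jitter_sd, 3),
                                base_radii - 0.5, base_radii + 0.5)
            shapes.append(Shape(
                "ellipsoid", (c + dx, c + dy, c + dz), tuple(radii),
                float(chi_by_structure[structure]), 25.0, structure, hemi,
            ))
    for hemi, dx in (("left", -3.5), ("right", 3.5)):
        shapes.append(Shape("ellipsoid", (c + dx, c, c), (2.0, 2.0, 5.0),
                            0.0, 5.0, "ventricle", hemi))
    lo, hi = 5.0 * grid / 48.0, grid - 6.0 * grid / 48.0
    sources = [
        ExternalSource((lo, lo, 2.0), 2.0, 9.0),
        ExternalSource((hi, hi, grid - 3.0), 2.0, 9.0),
        ExternalSource((lo, hi, grid - 3.0), 2.0, 9.0),
        ExternalSource((hi, lo, 2.0), 2.0, 9.0),
    ]
    return PhantomSpec(grid_shape=(grid,) * 3, shapes=shapes,
                       external_sources=sources, brain_margin_vox=3)


# ---------------------------------------------------------------------------
# forward GRE simulation


def simulate_gre(truth: GroundTruth, acq: AcquisitionParams,
                 background_chi=None) -> MultiEchoGRE:
    """Forward-model a multi-echo GRE acquisition from a ground-truth scene.

    Per echo i: signal = M0 exp(-TE_i R2*) exp(j phi_i) + complex Gaussian
    noise, where phi_i = 2 pi f0 field_ppm 1e-6 TE_i and the field is the
    forward dipole field of (chi + background sources). M0 = 1 inside the
    brain mask. SNR is defined on the first-echo magnitude within the brain
    mask; the stored phase is wrapped to (-pi, pi].
    """
    chi_total = truth.chi_true_ppm.copy()
    if background_chi is not None:
        bg = np.asarray(background_chi, dtype=float)
        if bg.shape != chi_total.shape:
            raise ValueError("background chi grid mismatch")
        chi_total = chi_total + bg

    kernel = dipole_kernel(chi_total.shape, truth.voxel_size_mm, acq.b0_direction)
    field_ppm = forward_field(chi_total, kernel)

    f0_hz = acq.gamma_mhz_per_t * 1e6 * acq.b0_tesla
    m0 = truth.brain_mask.astype(float)
    te_s = np.asarray(acq.te_ms) / 1000.0

    mags, phases = [], []
    rng = np.random.default_rng(acq.seed)
    sigma = 0.0
    for i, te in enumerate(te_s):
        mag = m0 * np.exp(-te * truth.r2star_per_s)
        phi = 2.0 * np.pi * f0_hz * field_ppm * 1e-6 * te
        signal = mag * np.exp(1j * phi)
        if np.isfinite(acq.snr):
            if i == 0:
                sigma = float(mag[truth.brain_mask].mean()) / acq.snr
            noise = rng.normal(0.0, sigma, signal.shape) \
                + 1j * rng.normal(0.0, sigma, signal.shape)
            signal = signal + noise
        mags.append(np.abs(signal))
        phases.append(np.angle(signal))

    return MultiEchoGRE(
        magnitude=np.stack(mags, axis=-1),
        phase=np.stack(phases, axis=-1),
        te_ms=acq.te_ms,
        voxel_size_mm=truth.voxel_size_mm,
        b0_tesla=acq.b0_tesla,
        b0_direction=acq.b0_direction,
    )


# ---------------------------------------------------------------------------
# synthetic cohort tables


@dataclass
class CohortSpec:
    """Statistical structure of the synthetic cohort.

    ``slopes`` maps (group, region) -> standardized volume-susceptibility
    slope, on the pooled-sample standardized scale used by the group x volume
    GLM (so a generated slope is the quantity that model estimates).
    """

    n_per_group: dict = dc_field(default_factory=lambda: dict(N_PER_GROUP))
    susceptibility: dict = dc_field(default_factory=lambda: {
        r: dict(v) for r, v in SUSCEPTIBILITY_PPM.items()})
    volume: dict = dc_field(default_factory=lambda: {
        r: dict(v) for r, v in VOLUME_MM3.items()})
    slopes: dict = dc_field(default_factory=lambda: {("MDD", "nucleus_accumbens"): 0.58})
    seed: int = 0

    def __post_init__(self):
        for group, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {group!r} needs n >= 2, got {n}")
        for table, name in ((self.susceptibility, "susceptibility"),
                            (self.volume, "volume")):
            for region, per_group in table.items():
                for group, (mean, sd) in per_group.items():
                    if not sd > 0:
                        raise ValueError(
                            f"{name} SD for {region}/{group} must be positive, got {sd}")
        for key, slope in self.slopes.items():
            if not np.isfinite(slope):
                raise ValueError(f"slope for {key} must be finite")

    @property
    def regions(self):
        return tuple(self.susceptibility)


def pooled_sd(per_group: dict, n_per_group: dict) -> float:
    """Population SD of the group mixture implied by per-group (mean, sd)."""
    groups = list(per_group)
    n = np.array([n_per_group[g] for g in groups], dtype=float)
    means = np.array([per_group[g][0] for g in groups])
    sds = np.array([per_group[g][1] for g in groups])
    w = n / n.sum()
    grand = float(w @ means)
    var = float(w @ (sds ** 2) + w @ (means - grand) ** 2)
    return np.sqrt(var)


def simulate_cohort(spec: CohortSpec | None = None, seed=None) -> pd.DataFrame:
    """Draw a long-format cohort table (one row per subject x region).

    Volume ~ Normal(group mean, group SD). Susceptibility couples to the
    group-centered volume with the configured pooled-standardized slope, with
    residual noise scaled so the marginal susceptibility SD matches the spec:

        chi = mu_c + slope * (sigma_c / sigma_v) * (vol - mu_v) + eps

    where sigma_c, sigma_v are the pooled (mixture) SDs. Reproducible given
    the seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    pooled_c = {r: pooled_sd(spec.susceptibility[r], spec.n_per_group)
                for r in spec.regions}
    pooled_v = {r: pooled_sd(spec.volume[r], spec.n_per_group)
                for r in spec.regions}

    rows = []
    for group, n in spec.n_per_group.items():
        sex_counts = SEX_COUNTS.get(group, (1, 1))
        hand_counts = HANDEDNESS_COUNTS.get(group, (1, 0, 0))
        iq_mean, iq_sd, iq_missing = IQ_STATS.get(group, (100.0, 10.0, 0))
        p_iq_missing = min(1.0, iq_missing / max(n, 1))
        for s in range(n):
            subject_id = f"{group}_{s + 1:03d}"
            sex = rng.choice(["male", "female"],
                             p=np.array(sex_counts) / sum(sex_counts))
            handedness = rng.choice(["right", "mixed", "left"],
                                    p=np.array(hand_counts) / sum(hand_counts))
            iq = np.nan if rng.random() < p_iq_missing \
                else float(rng.normal(iq_mean, iq_sd))
            if group in ILLNESS_DURATION_Y:
                duration = max(0.0, float(rng.normal(*ILLNESS_DURATION_Y[group])))
                severity = max(0.0, float(rng.normal(*SEVERITY[group])))
                med = max(0.0, float(rng.normal(*MED_DOSE[group])))
            else:
                duration = severity = med = np.nan

            for region in spec.regions:
                mu_v, sd_v = spec.volume[region][group]
                mu_c, sd_c = spec.susceptibility[region][group]
                slope = spec.slopes.get((group, region), 0.0)
                coupling = slope * pooled_c[region] / pooled_v[region]
                resid_var = sd_c ** 2 - (coupling * sd_v) ** 2
                if resid_var < 0:
                    raise ValueError(
                        f"slope {slope} too large for {group}/{region}: implied "
                        "coupling exceeds the marginal susceptibility SD")
                vol = float(rng.normal(mu_v, sd_v))
                chi = mu_c + coupling * (vol - mu_v) \
                    + float(rng.normal(0.0, np.sqrt(resid_var)))
                rows.append({
                    "subject_id": subject_id, "group": group, "region": region,
                    "susceptibility_ppm": chi, "volume_mm3": vol,
                    "sex": sex, "handedness": handedness, "iq": iq,
                    "illness_duration_y": duration, "severity": severity,
                    "med_dose": med,
                })
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
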