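"""Susceptibility map reconstruction from multi-echo gradient-echo data.

Pipeline (per subject): Laplacian phase unwrapping per echo -> V-SHARP
background field removal per echo -> conversion to field in ppm ->
R2*-weighted echo combination -> two-stage iterative least-squares dipole
inversion with streaking-artifact correction -> zero-referencing to the
lateral ventricles.

Sign convention shared with the simulator: positive phase accumulation
corresponds to a positive (paramagnetic) local field and chi > 0. All
spectral operators treat the grid as periodic; the mask is zero-padded
(``ReconConfig.pad_vox``) to suppress wrap-around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.fft
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, lsqr

from .dipole import dipole_kernel

logger = logging.getLogger(__name__)

#: gyromagnetic ratio of the proton, MHz per tesla
GAMMA_MHZ_PER_T = 42.577


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultiEchoGRE:
    """Multi-echo gradient-echo acquisition: 4D magnitude/phase + geometry."""

    magnitude: np.ndarray
    phase: np.ndarray
    te_ms: Sequence[float]
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    b0_tesla: float = 3.0
    b0_direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.te_ms = tuple(float(t) for t in self.te_ms)
        if self.magnitude.ndim != 4 or self.phase.shape != self.magnitude.shape:
            raise ValueError("magnitude and phase must be matching 4D (x,y,z,echo) arrays")
        if self.magnitude.shape[-1] != len(self.te_ms):
            raise ValueError("echo dimension must match len(te_ms)")
        if len(self.te_ms) >= 2 and not np.all(np.diff(self.te_ms) > 0):
            raise ValueError("echo times must be strictly increasing")
        if (self.magnitude < 0).any():
            raise ValueError("magnitude must be nonnegative")
        if (np.abs(self.phase) > np.pi + 1e-9).any():
            raise ValueError("phase must lie in (-pi, pi]")

    @property
    def n_echoes(self):
        return len(self.te_ms)

    @property
    def larmor_hz(self):
        """Larmor frequency of the main field in Hz."""
        return GAMMA_MHZ_PER_T * 1e6 * self.b0_tesla


@dataclass
class LocalFieldMap:
    """Tissue local field in ppm, valid on the V-SHARP-eroded brain mask."""

    field_ppm: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self):
        self.field_ppm = np.asarray(self.field_ppm, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.field_ppm.shape != self.valid_mask.shape:
            raise ValueError("field and valid_mask must share a grid")
        if not np.all(np.isfinite(self.field_ppm[self.valid_mask])):
            raise ValueError("field must be finite inside valid_mask")


@dataclass
class SusceptibilityMap:
    """Zero-referenced susceptibility volume in ppm."""

    chi_ppm: np.ndarray
    valid_mask: np.ndarray
    reference_region: str = "lateral_ventricles"
    reference_offset_ppm: float = 0.0

    def __post_init__(self):
        self.chi_ppm = np.asarray(self.chi_ppm, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.chi_ppm.shape != self.valid_mask.shape:
            raise ValueError("chi and valid_mask must share a grid")


@dataclass
class ReconConfig:
    """Tunable reconstruction parameters (defaults set by phantom pilot runs)."""

    vsharp_radii_mm: tuple = tuple(range(1, 30, 2))
    deconv_threshold: float = 0.05
    lsqr_max_iter: int = 50
    lsqr_tol: float = 1e-4
    streak_kernel_threshold: float = 0.1
    r2star_floor_per_s: float = 0.0
    pad_vox: int = 8

    def __post_init__(self):
        radii = tuple(float(r) for r in self.vsharp_radii_mm)
        if not radii or any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("vsharp_radii_mm must be positive and ascending")
        self.vsharp_radii_mm = radii
        for name in ("deconv_threshold", "streak_kernel_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lsqr_max_iter < 1 or self.lsqr_tol <= 0:
            raise ValueError("lsqr_max_iter >= 1 and lsqr_tol > 0 required")
        if self.r2star_floor_per_s < 0 or self.pad_vox < 0:
            raise ValueError("r2star_floor_per_s and pad_vox must be nonnegative")


@dataclass
class ReconResult:
    """Full reconstruction output with intermediates for diagnostics."""

    chi: SusceptibilityMap
    local_field: LocalFieldMap
    r2star_per_s: np.ndarray
    converged: bool
    per_echo_field_ppm: np.ndarray | None = None


# ---------------------------------------------------------------------------
# spectral helpers


def _k2_grid(shape, voxel_size_mm):
    axes = [
        (2.0 * np.pi * np.fft.fftfreq(int(n), d=float(d))) ** 2
        for n, d in zip(shape, voxel_size_mm)
    ]
    kx2, ky2, kz2 = np.meshgrid(*axes, indexing="ij")
    return kx2 + ky2 + kz2


def _pad(vol, pad, mode="constant"):
    if pad == 0:
        return vol
    return np.pad(vol, pad, mode=mode)


def _crop(vol, pad):
    if pad == 0:
        return vol
    sl = tuple(slice(pad, n - pad) for n in vol.shape)
    return vol[sl]


# ---------------------------------------------------------------------------
# stage 1: Laplacian unwrapping


def laplacian_unwrap(phase_wrapped, voxel_size_mm=(1.0, 1.0, 1.0),
                     congruent=True, mirror=True):
    """Unwrap phase via the Laplacian identity, solved spectrally.

    Computes Lap(phi) = cos(phi_w)*Lap(sin(phi_w)) - sin(phi_w)*Lap(cos(phi_w))
    and inverts the Laplacian in k-space (k = 0 term set to 0), so the result
    is defined up to an additive constant and contains no 2*pi jumps where the
    true phase gradient is below pi per voxel.

    With ``mirror`` (default), the volume is symmetrically extended before the
    spectral solve — the Poisson problem is then solved under Neumann rather
    than periodic boundary conditions, so non-periodic phase (e.g. a global
    ramp) is representable and box-edge Gibbs artifacts vanish.

    With ``congruent`` (default), the wrapped residual between input and the
    spectral estimate is added back, making the output exactly congruent with
    the measured phase modulo 2*pi. Wherever the spectral estimate is within
    pi of the true phase this recovers it exactly, removing the smooth
    discretization error of the spectral Laplacian (which otherwise grows
    with the phase amplitude, i.e. with echo time).
    """
    phase = np.asarray(phase_wrapped, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("wrapped phase must be finite")
    if mirror:
        p = np.pad(phase, [(0, n) for n in phase.shape], mode="symmetric")
    else:
        p = phase
    k2 = _k2_grid(p.shape, voxel_size_mm)

    def lap(a):
        return scipy.fft.ifftn(-k2 * scipy.fft.fftn(a)).real

    s, c = np.sin(p), np.cos(p)
    rhs = c * lap(s) - s * lap(c)
    spec = scipy.fft.fftn(rhs)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = spec / (-k2)
    spec[k2 == 0] = 0.0
    out = scipy.fft.ifftn(spec).real
    if mirror:
        out = out[tuple(slice(0, n) for n in phase.shape)]
    if congruent:
        out = out + np.angle(np.exp(1j * (phase - out)))
    return out


# ---------------------------------------------------------------------------
# stage 2: V-SHARP background removal

_SMV_CACHE: dict = {}


def _smv_kernel_ft(shape, voxel_size_mm, radius_mm):
    """FT of a normalized sphere of given radius, centered at the origin of
    the periodic grid (real by symmetry). Boundary voxels get linear
    partial-volume weights, which makes small kernels much better
    approximations of the continuous spherical mean."""
    key = (tuple(shape), tuple(voxel_size_mm), float(radius_mm))
    if key in _SMV_CACHE:
        return _SMV_CACHE[key]
    axes = []
    for n, d in zip(shape, voxel_size_mm):
        idx = np.arange(int(n))
        axes.append(np.minimum(idx, n - idx) * float(d))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    dist = np.sqrt(gx * gx + gy * gy + gz * gz)
    h = min(voxel_size_mm)
    sphere = np.clip((radius_mm + h / 2.0 - dist) / h, 0.0, 1.0)
    sphere /= sphere.sum()
    ft = scipy.fft.fftn(sphere).real
    if len(_SMV_CACHE) > 64:
        _SMV_CACHE.clear()
    _SMV_CACHE[key] = ft
    return ft


def vsharp(phase_or_field, brain_mask, config: ReconConfig | None = None,
           voxel_size_mm=(1.0, 1.0, 1.0)):
    """V-SHARP background removal by variable-radius SMV filtering.

    Each voxel is high-pass filtered with (I - S_r) using the largest sphere
    radius r that fits inside the brain mask at that voxel; the result is
    deconvolved spectrally by (I - S_rmax) with truncation where
    |1 - S_rmax(k)| < ``deconv_threshold``. Harmonic fields from sources
    outside the mask are suppressed; the valid region is the mask eroded by
    the smallest radius.
    """
    config = config or ReconConfig()
    mask = np.asarray(brain_mask, dtype=bool)
    data = np.asarray(phase_or_field, dtype=float)
    if data.shape != mask.shape:
        raise ValueError("input and mask must share a grid")
    if not mask.any():
        raise ValueError("brain mask is empty")

    pad = config.pad_vox
    f = _pad(data * mask, pad)
    m = _pad(mask, pad)
    dist = ndimage.distance_transform_edt(m, sampling=voxel_size_mm)

    radii = [r for r in config.vsharp_radii_mm if (dist >= r).any()]
    if not radii:
        raise ValueError(
            "mask too thin for the smallest V-SHARP radius "
            f"({config.vsharp_radii_mm[0]} mm); configure smaller radii"
        )
    r_min, r_max = radii[0], radii[-1]

    spec = scipy.fft.fftn(f)
    hp = np.zeros_like(f)
    # ascending radii: larger admissible radii overwrite smaller ones
    for r in radii:
        smv = scipy.fft.ifftn(_smv_kernel_ft(f.shape, voxel_size_mm, r) * spec).real
        admissible = dist >= r
        hp[admissible] = f[admissible] - smv[admissible]

    valid = dist >= r_min
    h = 1.0 - _smv_kernel_ft(f.shape, voxel_size_mm, r_max)
    hp_spec = scipy.fft.fftn(hp * valid)
    keep = np.abs(h) >= config.deconv_threshold
    inv = np.zeros_like(hp_spec)
    inv[keep] = hp_spec[keep] / h[keep]
    local = scipy.fft.ifftn(inv).real * valid

    return LocalFieldMap(_crop(local, pad), _crop(valid, pad))


# ---------------------------------------------------------------------------
# stage 3: R2* fit and echo combination


def estimate_r2star(magnitude, te_ms, floor_per_s=0.0, return_flags=False):
    """Voxelwise R2* (s^-1): negated slope of the log-linear fit of
    ln(magnitude) against TE, clipped below at ``floor_per_s``.

    All-zero voxels get R2* = 0 and are flagged.
    """
    mag = np.asarray(magnitude, dtype=float)
    te = np.asarray(te_ms, dtype=float) / 1000.0
    if mag.ndim != 4 or mag.shape[-1] != te.size:
        raise ValueError("magnitude must be 4D with echo as last axis matching te_ms")
    if te.size < 2:
        raise ValueError("at least 2 echoes required")

    all_zero = (mag <= 0).all(axis=-1)
    logm = np.log(np.clip(mag, 1e-30, None))
    tec = te - te.mean()
    slope = np.tensordot(logm, tec, axes=([-1], [0])) / (tec @ tec)
    r2s = np.clip(-slope, floor_per_s, None)
    r2s[all_zero] = 0.0
    if all_zero.any():
        logger.warning("R2* fit: %d all-zero voxels flagged", int(all_zero.sum()))
    if return_flags:
        return r2s, all_zero
    return r2s


def combine_echo_fields(field_maps: Sequence[LocalFieldMap], te_ms, r2star_per_s):
    """R2*-based weighted average of per-echo local field maps (ppm).

    Weights per voxel: w_i proportional to TE_i * exp(-TE_i * R2*), normalized
    to sum 1. Voxels with zero weight sum fall back to an unweighted mean.
    """
    te = np.asarray(te_ms, dtype=float) / 1000.0
    if len(field_maps) != te.size:
        raise ValueError("one field map per echo time required")
    fields = np.stack([fm.field_ppm for fm in field_maps], axis=-1)
    valid = np.logical_and.reduce([fm.valid_mask for fm in field_maps])
    r2s = np.asarray(r2star_per_s, dtype=float)[..., None]

    w = te * np.exp(-te * r2s)
    wsum = w.sum(axis=-1)
    degenerate = wsum <= 0
    if degenerate.any():
        logger.warning(
            "echo combination: %d voxels with zero weight sum, "
            "falling back to unweighted mean", int(degenerate.sum()),
        )
        w = np.where(degenerate[..., None], 1.0, w)
        wsum = w.sum(axis=-1)
    combined = (w * fields).sum(axis=-1) / wsum
    return LocalFieldMap(combined * valid, valid)


# ---------------------------------------------------------------------------
# stage 4: dipole inversion (iLSQR-style, two stages)


def _projected_operator(kernel_like, data_mask, support):
    """LinearOperator y = M . IFFT(K . FFT(S . x)) on flattened real volumes
    (K real and even-symmetric, so the operator is its own transpose up to
    the two projections)."""
    shape = kernel_like.shape
    n = int(np.prod(shape))

    def matvec(x):
        chi = x.reshape(shape) * support
        f = scipy.fft.ifftn(kernel_like * scipy.fft.fftn(chi)).real
        return (f * data_mask).ravel()

    def rmatvec(y):
        yv = y.reshape(shape) * data_mask
        out = scipy.fft.ifftn(kernel_like * scipy.fft.fftn(yv)).real
        return (out * support).ravel()

    return LinearOperator((n, n), matvec=matvec, rmatvec=rmatvec)


def dipole_inversion_ilsqr(field, kernel, config: ReconConfig | None = None,
                           chi_support=None, return_info=False):
    """Two-stage iterative least-squares dipole inversion.

    Stage 1 solves argmin_chi || M (IFFT(D FFT(chi)) - f) ||_2 with LSQR
    (M = valid mask), stopping at ``lsqr_tol`` or ``lsqr_max_iter``. The
    susceptibility is constrained to ``chi_support`` (default: the valid
    mask, i.e. the region where field data exists) — without a support
    constraint the masked problem is underdetermined and the minimum-norm
    iterate systematically underestimates chi; voxels inside a wider support
    but outside the data region would likewise absorb signal from real
    structures. Stage 2 estimates streaking
    artifacts — high-frequency content of the stage-1 map whose spectrum
    lives in the ill-conditioned cone {|D(k)| < streak_kernel_threshold} —
    by a short least-squares fit and subtracts them. Voxels outside the
    support are exactly 0.
    """
    config = config or ReconConfig()
    if isinstance(field, LocalFieldMap):
        f, mask = field.field_ppm, field.valid_mask
    else:
        f = np.asarray(field, dtype=float)
        mask = np.isfinite(f)
    if f.shape != kernel.shape:
        raise ValueError("field and kernel must share a grid")
    support = mask if chi_support is None else np.asarray(chi_support, dtype=bool)
    if support.shape != f.shape:
        raise ValueError("chi_support and field must share a grid")

    b = (f * mask).ravel()
    if not b.any():
        chi = np.zeros_like(f)
        return (chi, {"converged": True, "n_iter": 0}) if return_info else chi

    op = _projected_operator(kernel, mask, support)
    sol = lsqr(op, b, atol=config.lsqr_tol, btol=config.lsqr_tol,
               iter_lim=config.lsqr_max_iter)
    chi1 = sol[0].reshape(f.shape) * support
    n_iter = int(sol[2])
    converged = sol[1] in (1, 2) or n_iter < config.lsqr_max_iter
    if not converged:
        logger.warning("LSQR reached iteration limit (%d); returning best iterate",
                       config.lsqr_max_iter)

    # stage 2: streaking-artifact estimation restricted to the dipole cone.
    # Streaks are high-frequency content of the stage-1 map whose spectrum
    # lives in the ill-conditioned cone; they are estimated in *smooth*
    # regions only (edge voxels excluded by a gradient gate, scale-invariant
    # so the whole inversion stays homogeneous) and subtracted everywhere.
    cone = np.abs(kernel) < config.streak_kernel_threshold
    grad = ndimage.gaussian_gradient_magnitude(chi1, sigma=1.0)
    gate = np.median(grad[mask]) * 2.0 if mask.any() else 0.0
    edges = grad > gate
    # guard band: inversion ringing hugs structure boundaries, so the edge
    # exclusion is dilated before fitting the streak component
    edges = ndimage.binary_dilation(edges, iterations=3)
    smooth_region = mask & ~edges
    highpass = chi1 - ndimage.gaussian_filter(chi1, sigma=2.0)
    b2 = (highpass * smooth_region).ravel()
    op2 = _projected_operator(cone.astype(float), smooth_region,
                              np.ones_like(support))
    sol2 = lsqr(op2, b2, atol=config.lsqr_tol, btol=config.lsqr_tol,
                iter_lim=min(10, config.lsqr_max_iter))
    artifact = scipy.fft.ifftn(
        cone * scipy.fft.fftn(sol2[0].reshape(f.shape))).real

    chi = (chi1 - artifact) * support
    if return_info:
        return chi, {"converged": converged, "n_iter": n_iter,
                     "lsqr_stop": int(sol[1])}
    return chi


# ---------------------------------------------------------------------------
# stage 5: zero-referencing


def zero_reference(chi, ventricle_mask, valid_mask=None,
                   reference_region="lateral_ventricles"):
    """Subtract the mean susceptibility over the reference region.

    QSM determines chi only up to a constant; referencing to ventricular CSF
    fixes the absolute scale.
    """
    chi = np.asarray(chi, dtype=float)
    vmask = np.asarray(ventricle_mask, dtype=bool)
    if chi.shape != vmask.shape:
        raise ValueError("chi and ventricle mask must share a grid")
    if valid_mask is not None:
        valid = np.asarray(valid_mask, dtype=bool)
        vmask = vmask & valid
    else:
        valid = np.ones(chi.shape, dtype=bool)
    if not vmask.any():
        raise ValueError("reference (ventricle) mask is empty within the valid region")
    offset = float(chi[vmask].mean())
    out = (chi - offset) * valid
    return SusceptibilityMap(out, valid, reference_region, offset)


# ---------------------------------------------------------------------------
# full pipeline


def reconstruct_qsm(data: MultiEchoGRE, brain_mask, ventricle_mask,
                    config: ReconConfig | None = None, return_intermediates=False):
    """Full reconstruction: unwrap -> V-SHARP -> field (ppm) -> R2*-weighted
    combination -> dipole inversion -> ventricle zero-referencing."""
    config = config or ReconConfig()
    mask = np.asarray(brain_mask, dtype=bool)
    if data.magnitude.shape[:3] != mask.shape:
        raise ValueError("data and brain mask must share a grid")
    if not (data.magnitude[mask] > 0).any():
        raise ValueError("zero signal inside the brain mask; nothing to reconstruct")

    scale = 2.0 * np.pi * data.larmor_hz * 1e-6  # rad per (ppm * s)
    per_echo = []
    for e, te in enumerate(data.te_ms):
        logger.info("echo %d/%d: unwrap + V-SHARP", e + 1, data.n_echoes)
        unwrapped = laplacian_unwrap(data.phase[..., e], data.voxel_size_mm)
        local = vsharp(unwrapped, mask, config, data.voxel_size_mm)
        te_s = te / 1000.0
        per_echo.append(LocalFieldMap(local.field_ppm / (scale * te_s),
                                      local.valid_mask))

    logger.info("R2* fit and echo combination")
    r2star = estimate_r2star(data.magnitude, data.te_ms, config.r2star_floor_per_s)
    combined = combine_echo_fields(per_echo, data.te_ms, r2star)

    logger.info("dipole inversion (iLSQR, max %d iterations)", config.lsqr_max_iter)
    pad = config.pad_vox
    f_pad = _pad(combined.field_ppm, pad)
    m_pad = _pad(combined.valid_mask, pad)
    kernel = dipole_kernel(f_pad.shape, data.voxel_size_mm, data.b0_direction)
    chi_pad, info = dipole_inversion_ilsqr(
        LocalFieldMap(f_pad, m_pad), kernel, config, return_info=True)
    chi = _crop(chi_pad, pad)

    logger.info("zero-referencing to ventricles")
    chi_map = zero_reference(chi, ventricle_mask, combined.valid_mask)

    if return_intermediates:
        return ReconResult(chi_map, combined, r2star, info["converged"],
                           np.stack([fm.field_ppm for fm in per_echo], axis=-1))
    return chi_map
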