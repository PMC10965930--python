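"""Unit dipole response and forward field computation in k-space.

The induced local field (in ppm) of a susceptibility distribution chi (ppm)
is the convolution of chi with the unit dipole response, evaluated here as a
pointwise multiplication in k-space:

    field = IFFT( D(k) * FFT(chi) ),   D(k) = 1/3 - (k . b0_hat)^2 / |k|^2

D vanishes on the cone at ~54.7 deg to the main field, which is what makes
the inverse problem (dipole inversion) ill-posed.
"""

from __future__ import annotations

import numpy as np
import scipy.fft


def _freq_grids(grid_shape, voxel_size_mm):
    axes = [
        np.fft.fftfreq(int(n), d=float(d))
        for n, d in zip(grid_shape, voxel_size_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def dipole_kernel(grid_shape, voxel_size_mm=(1.0, 1.0, 1.0), b0_direction=(0.0, 0.0, 1.0)):
    """k-space unit dipole kernel D(k) = 1/3 - (k.b0)^2/|k|^2 on the FFT grid.

    The k = 0 term is set to 0 by convention, so the forward field of any
    uniform susceptibility is zero and reconstructed maps are mean-free
    before zero-referencing.

    Parameters
    ----------
    grid_shape : tuple of 3 ints
    voxel_size_mm : tuple of 3 floats
    b0_direction : 3-vector, direction of the main field (need not be
        normalized, but must have nonzero norm).

    Returns
    -------
    ndarray, real, same shape as ``grid_shape``, laid out on the numpy FFT
    frequency grid.
    """
    b0 = np.asarray(b0_direction, dtype=float)
    norm = np.linalg.norm(b0)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("b0_direction must be a finite vector with nonzero norm")
    b0 = b0 / norm

    kx, ky, kz = _freq_grids(grid_shape, voxel_size_mm)
    k2 = kx * kx + ky * ky + kz * kz
    kb = kx * b0[0] + ky * b0[1] + kz * b0[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (kb * kb) / k2
    d[k2 == 0] = 0.0
    return d


def forward_field(chi_ppm, kernel):
    """Local field (ppm) induced by a susceptibility volume (ppm).

    Grids are treated as periodic; callers who care about wrap-around should
    pad before calling.
    """
    chi = np.asarray(chi_ppm, dtype=float)
    if chi.shape != kernel.shape:
        raise ValueError(
            f"grid mismatch: chi has shape {chi.shape}, kernel {kernel.shape}"
        )
    if not np.all(np.isfinite(chi)):
        raise ValueError("chi must be finite everywhere")
    return scipy.fft.ifftn(kernel * scipy.fft.fftn(chi)).real
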