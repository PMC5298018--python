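"""GRAPPA reconstruction for 1-D phase-encode undersampling.

Missing ky lines are interpolated from acquired neighbours with kernels
calibrated on the fully sampled autocalibration (ACS) block by regularized
least squares.  The kernel spans ``kernel_ky`` acquired ky lines (on the
acceleration grid) and ``kernel_kx`` readout columns, across all coils.
Arrays are (n_coils, nx, ny) with ky the last axis and k-space centred.
"""

from __future__ import annotations

import numpy as np

__all__ = ["grappa_weights", "grappa_reconstruct"]


def _source_offsets(d: int, accel: int, kernel_ky: int) -> np.ndarray:
    """ky offsets (relative to the target line) of the acquired source lines.

    The target sits ``d`` lines above an acquired grid line; sources are the
    ``kernel_ky`` grid lines bracketing it (two below, two above for the
    default kernel_ky=4).
    """
    base = -d + accel * (np.arange(kernel_ky) - (kernel_ky // 2 - 1))
    return base


def grappa_weights(
    acs: np.ndarray,
    accel: int,
    kernel_ky: int = 4,
    kernel_kx: int = 5,
    tikhonov: float = 1e-4,
) -> dict[int, np.ndarray]:
    """Calibrate GRAPPA kernels on the ACS block.

    ``acs`` is (n_coils, nx, n_acs) fully sampled.  Returns one weight
    matrix of shape (n_coils*kernel_ky*kernel_kx, n_coils) per line offset
    d in 1..accel-1.
    """
    nc, nx, nacs = acs.shape
    hx = kernel_kx // 2
    weights: dict[int, np.ndarray] = {}
    for d in range(1, accel):
        offs = _source_offsets(d, accel, kernel_ky)
        t_lo = max(0, -offs.min())
        t_hi = nacs - max(0, offs.max())
        if t_hi <= t_lo or nx <= 2 * hx:
            raise ValueError("ACS region too small for the kernel")
        targets = []
        sources = []
        for ky in range(t_lo, t_hi):
            tgt = acs[:, hx : nx - hx, ky]  # (nc, nx-2hx)
            src = np.stack(
                [
                    acs[:, hx + dx : nx - hx + dx, ky + dy]
                    for dy in offs
                    for dx in range(-hx, hx + 1)
                ],
                axis=0,
            )  # (ky*kx, nc, nx-2hx)
            targets.append(tgt.T)  # (npts, nc)
            sources.append(src.reshape(kernel_ky * kernel_kx * nc, -1).T)
        T = np.concatenate(targets, axis=0)
        S = np.concatenate(sources, axis=0)
        sh = S.conj().T @ S
        lam = tikhonov * np.trace(sh).real / sh.shape[0]
        W = np.linalg.solve(sh + lam * np.eye(sh.shape[0]), S.conj().T @ T)
        weights[d] = W
    return weights


def grappa_reconstruct(
    kspace: np.ndarray,
    line_mask: np.ndarray,
    accel: int,
    weights: dict[int, np.ndarray],
    kernel_ky: int = 4,
    kernel_kx: int = 5,
) -> np.ndarray:
    """Fill missing ky lines of undersampled k-space with calibrated kernels.

    Acquired lines (including ACS) are kept untouched.  Edge targets use
    zero padding outside the matrix.
    """
    nc, nx, ny = kspace.shape
    hx = kernel_kx // 2
    grid = np.nonzero(line_mask)[0]
    if grid.size == 0:
        raise ValueError("no acquired lines")
    # regular acceleration grid phase (ACS lines included in line_mask)
    center = ny // 2
    phase = center % accel

    pad_y = accel * kernel_ky
    kp = np.pad(kspace, ((0, 0), (hx, hx), (pad_y, pad_y)))
    out = kspace.copy()
    for ky in range(ny):
        if line_mask[ky]:
            continue
        below = ((ky - phase) // accel) * accel + phase
        d = ky - below
        offs = _source_offsets(d, accel, kernel_ky)
        src = np.stack(
            [
                kp[:, dx + hx : dx + hx + nx, ky + dy + pad_y]
                for dy in offs
                for dx in range(-hx, hx + 1)
            ],
            axis=0,
        )  # (ky*kx, nc, nx)
        S = src.reshape(kernel_ky * kernel_kx * nc, nx).T  # (nx, features)
        out[:, :, ky] = (S @ weights[d]).T
    return out
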