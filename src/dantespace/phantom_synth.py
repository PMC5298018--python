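"""Synthetic vessel phantoms and multi-coil k-space acquisitions.

Builds an annular vessel phantom (lumen / wall / CSF ring / background)
with area-weighted partial volume at compartment boundaries, smooth complex
coil sensitivities with a correlated-noise model, and undersampled
multi-coil k-space acquisitions plus an RF-free noise-only companion — the
inputs every quantification stage needs, generated entirely in code.

Geometry is in millimetres; image arrays are indexed ``(nx, ny, nz)`` with
the phase-encode direction along y.  K-space is centred (DC at the matrix
centre) and Fourier transforms are orthonormal, so noise levels are
preserved between domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "CoilModel",
    "SyntheticAcquisition",
    "make_vessel_phantom",
    "make_coil_model",
    "synthesize_acquisition",
    "estimate_noise_covariance",
    "sampling_mask",
    "preset_compartment_values",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of the annular vessel phantom.

    The vessel axis runs along z; in-plane geometry is a disc of lumen
    surrounded by a wall annulus and a CSF ring, embedded in background.
    ``wall_thickness_mm`` may be below the voxel size — sub-voxel walls are
    the regime of interest for vessel-wall imaging.
    """

    matrix: tuple[int, int, int] = (64, 64, 1)
    voxel_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    lumen_radius_mm: float = 2.0
    wall_thickness_mm: float = 0.6
    csf_ring_mm: float = 1.5
    compartment_values: dict = field(
        default_factory=lambda: {"wall": 0.7, "csf": 1.0, "lumen": 0.1, "background": 0.0}
    )

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0 or self.csf_ring_mm <= 0:
            raise ValueError("radii must be positive")
        if self.wall_thickness_mm < 0:
            raise ValueError("wall thickness must be non-negative")
        r_out = self.lumen_radius_mm + self.wall_thickness_mm + self.csf_ring_mm
        fov_x = self.matrix[0] * self.voxel_mm[0] / 2.0
        fov_y = self.matrix[1] * self.voxel_mm[1] / 2.0
        if r_out >= min(fov_x, fov_y):
            raise ValueError("vessel geometry does not fit inside the matrix")

    @property
    def radii(self) -> tuple[float, float, float]:
        """(lumen, wall outer, CSF outer) radii in mm."""
        r1 = self.lumen_radius_mm
        r2 = r1 + self.wall_thickness_mm
        r3 = r2 + self.csf_ring_mm
        return r1, r2, r3


@dataclass(frozen=True)
class CoilModel:
    """Receive array: smooth complex sensitivities and a noise covariance."""

    sensitivities: np.ndarray  # (n_coils, nx, ny) complex
    noise_cov: np.ndarray  # (n_coils, n_coils) Hermitian positive definite

    def __post_init__(self) -> None:
        n = self.sensitivities.shape[0]
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise covariance does not match coil count")
        if not np.allclose(self.noise_cov, self.noise_cov.conj().T):
            raise ValueError("noise covariance must be Hermitian")
        if np.any(np.linalg.eigvalsh(self.noise_cov) <= 0):
            raise ValueError("noise covariance must be positive definite")

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]


@dataclass(frozen=True)
class SyntheticAcquisition:
    """Undersampled multi-coil k-space with its RF-free noise companion.

    ``kspace`` is (n_coils, nx, ny) with zeros on unacquired phase-encode
    lines; ``line_mask`` marks acquired ky lines; ``noise_only`` is the
    fully sampled RF-free companion (pure correlated noise, same covariance).
    """

    kspace: np.ndarray
    line_mask: np.ndarray
    accel: int
    acs_lines: int
    seed: int
    noise_only: np.ndarray

    def __post_init__(self) -> None:
        ny = self.kspace.shape[2]
        if self.line_mask.shape != (ny,):
            raise ValueError("line mask must have one entry per ky line")


def _subgrid_labels(spec: PhantomSpec, sub: int) -> np.ndarray:
    """Compartment labels on a sub-voxel grid (0 lumen, 1 wall, 2 csf, 3 bg)."""
    nx, ny, _ = spec.matrix
    dx, dy, _ = spec.voxel_mm
    xs = (np.arange(nx * sub) + 0.5) / sub - nx / 2.0
    ys = (np.arange(ny * sub) + 0.5) / sub - ny / 2.0
    X, Y = np.meshgrid(xs * dx, ys * dy, indexing="ij")
    r = np.hypot(X, Y)
    r1, r2, r3 = spec.radii
    labels = np.full(r.shape, 3, dtype=np.int8)
    labels[r < r3] = 2
    labels[r < r2] = 1
    labels[r < r1] = 0
    return labels


_COMPARTMENTS = ("lumen", "wall", "csf", "background")


def make_vessel_phantom(
    spec: PhantomSpec,
    psf=None,
    subsample: int = 8,
):
    """Rasterize the annular phantom with partial volume; optionally blur.

    The analytic geometry is sampled on a ``subsample`` x ``subsample``
    sub-voxel grid per in-plane voxel; averaging the sub-cells gives
    area-weighted partial-volume fractions at every boundary voxel.  When a
    :class:`~dantespace.psf_analysis.PSFProfile` is supplied, the
    fine-resolution image is convolved along the phase-encode (y) axis with
    the PSF before voxel averaging, emulating echo-train blurring.

    Returns ``(volume, masks, fractions)``: the image volume, boolean
    voxel-centre masks per compartment (an exact partition), and the
    partial-volume fraction maps (summing to 1 per voxel).
    """
    nx, ny, nz = spec.matrix
    labels = _subgrid_labels(spec, subsample)
    values = np.array([spec.compartment_values[c] for c in _COMPARTMENTS], dtype=float)
    fine = values[labels]

    if psf is not None:
        kernel = _psf_kernel(psf, subsample)
        fine = _convolve_y(fine, kernel)

    # voxel averaging of the fine grid
    plane = fine.reshape(nx, subsample, ny, subsample).mean(axis=(1, 3))
    volume = np.repeat(plane[:, :, None], nz, axis=2)

    # fractions from sub-cell label counts
    onehot = labels[None, :, :] == np.arange(4, dtype=np.int8)[:, None, None]
    frac_plane = onehot.reshape(4, nx, subsample, ny, subsample).mean(axis=(2, 4))
    fractions = {
        c: np.repeat(frac_plane[i][:, :, None], nz, axis=2) for i, c in enumerate(_COMPARTMENTS)
    }

    # voxel-centre classification: exact partition of the matrix
    center_labels = _subgrid_labels(spec, 1)
    masks = {
        c: np.repeat((center_labels == i)[:, :, None], nz, axis=2)
        for i, c in enumerate(_COMPARTMENTS)
    }
    return volume, masks, fractions


def _psf_kernel(psf, subsample: int) -> np.ndarray:
    """Resample a PSF magnitude profile onto the sub-voxel grid, unit area."""
    x = psf.positions_px
    step = 1.0 / subsample
    grid = np.arange(x[0], x[-1] + step / 2, step)
    k = np.interp(grid, x, psf.magnitude)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate PSF kernel")
    return k / s


def _convolve_y(fine: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve1d

    return convolve1d(fine, kernel, axis=1, mode="nearest")


def make_coil_model(
    n_coils: int = 8,
    matrix: tuple[int, int] = (64, 64),
    seed: int = 0,
    noise_sigma: float = 1.0,
    coupling: float = 0.2,
) -> CoilModel:
    """Build smooth perimeter coil sensitivities and a correlated covariance.

    Coils are Gaussian sensitivity lobes placed on a circle around the FOV
    with a smooth low-order phase; the noise covariance is
    ``sigma^2 * (I + coupling * C)`` with a seeded random Hermitian coupling,
    guaranteed positive definite.
    """
    nx, ny = matrix
    rng = np.random.default_rng(seed)
    x = (np.arange(nx) - nx / 2.0) / nx
    y = (np.arange(ny) - ny / 2.0) / ny
    X, Y = np.meshgrid(x, y, indexing="ij")
    angles = 2 * np.pi * np.arange(n_coils) / n_coils
    radius = 0.6
    width = 0.45
    sens = np.empty((n_coils, nx, ny), dtype=complex)
    for c, a in enumerate(angles):
        cx, cy = radius * np.cos(a), radius * np.sin(a)
        mag = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2))
        phase = 2 * np.pi * (0.3 * (X * np.cos(a) + Y * np.sin(a)) + 0.05 * c)
        sens[c] = mag * np.exp(1j * phase)

    a = rng.standard_normal((n_coils, n_coils)) + 1j * rng.standard_normal((n_coils, n_coils))
    corr = a @ a.conj().T
    corr /= np.abs(np.diag(corr)).mean()
    cov = noise_sigma**2 * (np.eye(n_coils) + coupling * corr)
    # symmetrize against round-off
    cov = 0.5 * (cov + cov.conj().T)
    return CoilModel(sensitivities=sens, noise_cov=cov)


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2-D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Centred orthonormal 2-D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def sampling_mask(ny: int, accel: int, acs_lines: int) -> np.ndarray:
    """Phase-encode line mask: every ``accel``-th line plus a centred ACS block."""
    if accel < 1:
        raise ValueError("acceleration factor must be >= 1")
    if acs_lines > ny:
        raise ValueError("ACS block larger than the matrix")
    mask = np.zeros(ny, dtype=bool)
    center = ny // 2
    mask[center % accel :: accel] = True
    lo = center - acs_lines // 2
    mask[lo : lo + acs_lines] = True
    return mask


def _coloured_noise(rng, chol, shape):
    """Correlated complex Gaussian noise, coil axis first."""
    n_coils = chol.shape[0]
    white = rng.standard_normal((n_coils, *shape)) + 1j * rng.standard_normal((n_coils, *shape))
    white /= np.sqrt(2.0)  # unit variance per complex sample
    return np.einsum("ij,j...->i...", chol, white)


def synthesize_acquisition(
    image: np.ndarray,
    coils: CoilModel,
    accel: int = 1,
    seed: int = 0,
    acs_lines: int = 24,
    noise_scale: float = 1.0,
) -> SyntheticAcquisition:
    """Simulate a multi-coil acquisition of a 2-D image slice.

    Coil-weighted images are Fourier transformed, sampled on the
    acceleration mask, and corrupted with correlated Gaussian noise drawn
    through the Cholesky factor of the coil covariance.  The RF-free
    companion contains the same noise statistics with no signal and full
    sampling.  Deterministic given ``seed``.
    """
    if image.ndim == 3:
        if image.shape[2] != 1:
            raise ValueError("pass a single slice (nx, ny) or (nx, ny, 1)")
        image = image[:, :, 0]
    nx, ny = image.shape
    if coils.sensitivities.shape[1:] != (nx, ny):
        raise ValueError("coil maps do not match the image matrix")

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(coils.noise_cov) * noise_scale
    ksp = fft2c(coils.sensitivities * image[None])
    mask = sampling_mask(ny, accel, acs_lines)
    noise = _coloured_noise(rng, chol, (nx, ny))
    ksp = (ksp + noise) * mask[None, None, :]
    noise_only = _coloured_noise(rng, chol, (nx, ny))
    return SyntheticAcquisition(
        kspace=ksp,
        line_mask=mask,
        accel=accel,
        acs_lines=acs_lines,
        seed=seed,
        noise_only=noise_only,
    )


def estimate_noise_covariance(noise_kspace: np.ndarray) -> np.ndarray:
    """Sample coil covariance from RF-free k-space data (coil axis first)."""
    x = noise_kspace.reshape(noise_kspace.shape[0], -1)
    return (x @ x.conj().T) / x.shape[1]


_SCHEME_CACHE: dict = {}


def preset_compartment_values(
    mode: str,
    flip_deg: float = 10.0,
    n_pulses: int = 300,
    lumen_flow_suppression: float = 0.1,
    timing=None,
) -> dict:
    """Compartment intensities derived from the sequence simulations.

    ``mode`` is ``"space"`` (no preparation, CSF bright) or ``"dante-space"``
    (DANTE-prepared, CSF crushed).  Each compartment value is

        rho0 * |Mz at the end of the preparation| * MTF(k=0)

    with the MTF simulated from the wall-optimized flip-angle scheme for the
    compartment's relaxation times.  The static echo-train simulation cannot
    produce the readout's intrinsic black-blood effect (flow-induced
    dephasing during the train), so the lumen value carries an explicit
    flow-suppression factor in both presets.  Values are normalized so the
    SPACE-mode CSF value is 1.
    """
    from . import dante_bloch as db
    from . import flipangle_design as fa
    from .psf_analysis import KSpaceMapping

    if mode not in ("space", "dante-space"):
        raise ValueError("mode must be 'space' or 'dante-space'")
    if timing is None:
        timing = fa.SequenceTiming.protocol_7t()

    if timing not in _SCHEME_CACHE:
        target = fa.prescribed_evolution(timing)
        _SCHEME_CACHE[timing] = fa.design_flip_angles(target, fa.VESSEL_WALL_7T, timing)
    scheme = _SCHEME_CACHE[timing]
    k0 = KSpaceMapping.from_timing(timing).center_index

    tissues = {
        "wall": (fa.VESSEL_WALL_7T, db.STATIC_TISSUE),
        "csf": (fa.CSF_7T, db.CSF_FLOW),
        "lumen": (fa.ARTERIAL_BLOOD_7T, db.BLOOD_FLOW),
    }
    values = {}
    for name, (tissue, flow) in tissues.items():
        mtf_k0 = fa.epg_echo_train(scheme, tissue, timing).m_perp[k0]
        if mode == "dante-space":
            prep = db.DantePrep.protocol_7t(flip_deg=flip_deg, n_pulses=n_pulses)
            mz = db.simulate_dante(prep, tissue, flow).mz_abs[-1]
        else:
            mz = 1.0
        values[name] = tissue.rho0 * mz * mtf_k0
    values["lumen"] *= lumen_flow_suppression
    values["background"] = 0.0

    # normalize to the unprepared CSF level so presets share one scale
    csf_space = fa.CSF_7T.rho0 * fa.epg_echo_train(scheme, fa.CSF_7T, timing).m_perp[k0]
    return {k: v / csf_space for k, v in values.items()}
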