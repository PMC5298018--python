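"""Isochromat Bloch simulation of the DANTE flow-spoiling preparation.

A DANTE module is a train of short, nonselective, low-flip RF pulses, each
followed by a strong gradient lobe.  Static spins approach a steady state of
longitudinal magnetization; moving spins accrue a velocity-dependent phase
between pulses and their transverse coherence pathways interfere
destructively, crushing |<Mz>| of the ensemble.  The phase accrued over
pulse interval n is

    dphi(n) = gamma * G . r0 * tau_g  +  gamma * (n - 1/2) * G . v * tau_g**2

where the first (position) term is constant per interval and the second
(velocity) term grows linearly with pulse number.  The wall/fluid contrast
after n pulses is the spin-density weighted difference

    dMz = rho_wall * Mz_wall(n) - rho_fluid * |Mz_fluid(n)|

with the moving compartment taken in magnitude because the image displays
magnitude while the fluid Mz can undershoot below zero on its way to the
steady state.

Units: times in ms, gradients in mT/m, velocities in cm/s, positions in mm;
everything is converted to SI inside the phase computation.  The default
gyromagnetic ratio is 267.513e6 rad s^-1 T^-1 (proton).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flipangle_design import TissueRelaxation

__all__ = [
    "GAMMA_PROTON",
    "DantePrep",
    "VelocityModel",
    "IsochromatState",
    "MzTrajectory",
    "ContrastCurve",
    "STATIC_TISSUE",
    "CSF_FLOW",
    "BLOOD_FLOW",
    "phase_increment",
    "simulate_dante",
    "contrast_curve",
    "dante_sweep",
    "first_crossing",
]

GAMMA_PROTON = 267.513e6  # rad s^-1 T^-1


@dataclass(frozen=True)
class DantePrep:
    """DANTE pulse-train parameters.

    flip_deg : pulse flip angle (degrees)
    n_pulses : number of pulses in the train
    tau_d    : interpulse time (ms)
    tau_g    : gradient duration within each interval (ms)
    gradient : (G_AP, G_RL, G_HF) amplitudes in mT/m
    """

    flip_deg: float
    n_pulses: int
    tau_d: float = 1.6
    tau_g: float = 1.4
    gradient: tuple[float, float, float] = (28.0, 20.0, 40.0)
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        if not (0 < self.tau_g <= self.tau_d):
            raise ValueError("require 0 < tau_g <= tau_d")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be non-negative")
        if self.flip_deg < 0:
            raise ValueError("flip_deg must be non-negative")

    @classmethod
    def protocol_7t(cls, flip_deg: float = 10.0, n_pulses: int = 300) -> "DantePrep":
        """The 7T protocol prep: tau_d 1.6 ms, tau_g 1.4 ms, G = (28, 20, 40) mT/m."""
        return cls(flip_deg=flip_deg, n_pulses=n_pulses)


@dataclass(frozen=True)
class VelocityModel:
    """Moving-spin ensemble of a voxel.

    ``mean_velocity`` is (v_AP, v_RL, v_HF) in cm/s; each axis is uniformly
    dispersed over mean * (1 +- fractional_spread).  The dynamics depend on
    velocity only through the scalar G.v, so the ensemble is sampled with
    ``n_velocity_samples`` equal-probability quantiles of the exact
    distribution of G.v (the convolution of the per-axis uniforms).
    Intravoxel position is represented by ``n_phase_samples`` uniformly
    spaced values of the constant phase term in [0, 2pi) — the gradient
    lobes wind many full cycles across a voxel, so only the phase modulo
    2pi matters.
    """

    mean_velocity: tuple[float, float, float]
    fractional_spread: float = 0.025
    n_velocity_samples: int = 513
    n_phase_samples: int = 128

    def __post_init__(self) -> None:
        if self.fractional_spread < 0:
            raise ValueError("fractional_spread must be non-negative")
        if self.n_velocity_samples < 1 or self.n_phase_samples < 1:
            raise ValueError("sample counts must be at least 1")

    def gv_quantiles(self, gradient) -> np.ndarray:
        """Equal-probability samples of G.v (units T/m * m/s).

        The per-axis contributions g_i * v_i are independent uniforms; their
        sum's density is built by numerical convolution and sampled at the
        midpoint quantiles (j + 1/2)/N of its CDF.
        """
        g = np.asarray(gradient, dtype=float) * 1e-3  # T/m
        v = np.asarray(self.mean_velocity, dtype=float) * 1e-2  # m/s
        centers = g * v
        widths = np.abs(centers) * 2.0 * self.fractional_spread
        total = centers.sum()
        active = widths > 0
        if not active.any() or self.n_velocity_samples == 1:
            return np.array([total])
        half = widths.sum() / 2.0
        m = 4096
        xs = np.linspace(-half, half, m)
        dx = xs[1] - xs[0]
        dens = None
        for w in widths[active]:
            box = ((np.abs(xs) <= w / 2.0).astype(float)) / w
            dens = box if dens is None else np.convolve(dens, box, mode="same") * dx
        cdf = np.cumsum(dens) * dx
        cdf /= cdf[-1]
        q = (np.arange(self.n_velocity_samples) + 0.5) / self.n_velocity_samples
        return total + np.interp(q, cdf, xs)


STATIC_TISSUE = VelocityModel(mean_velocity=(0.0, 0.0, 0.0))
# CSF near the MCA: slow pulsatile flow, dominated by the head-feet axis
CSF_FLOW = VelocityModel(mean_velocity=(0.5, 0.5, 2.0))
# arterial blood: fast head-feet flow
BLOOD_FLOW = VelocityModel(mean_velocity=(0.0, 0.0, 20.0))


@dataclass
class IsochromatState:
    """A single spin isochromat: position (mm), velocity (cm/s), magnetization."""

    position: np.ndarray
    velocity: np.ndarray
    magnetization: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if np.linalg.norm(self.magnetization) > 1 + 1e-9:
            raise ValueError("|M| must not exceed unit equilibrium")


@dataclass(frozen=True)
class MzTrajectory:
    """Ensemble <Mz> after each DANTE pulse; index 0 is the equilibrium start."""

    mz_signed: np.ndarray
    mz_abs: np.ndarray
    flip_deg: float

    def __post_init__(self) -> None:
        if self.mz_signed.shape != self.mz_abs.shape:
            raise ValueError("signed and absolute trajectories must align")

    def __len__(self) -> int:
        return self.mz_signed.size


@dataclass(frozen=True)
class ContrastCurve:
    """Spin-density weighted longitudinal contrast per pulse count."""

    delta_mz: np.ndarray
    flip_deg: float


def phase_increment(
    prep: DantePrep,
    position_mm,
    velocity_cm_s,
    pulse_index: int,
) -> float:
    """Phase (rad) accrued during pulse interval ``pulse_index`` (1-based).

    Sum of the constant position term gamma*G.r0*tau_g and the velocity term
    gamma*(n-1/2)*G.v*tau_g^2, with per-axis contributions summed.
    """
    if pulse_index < 1:
        raise ValueError("pulse_index is 1-based")
    g = np.asarray(prep.gradient, dtype=float) * 1e-3  # T/m
    r0 = np.asarray(position_mm, dtype=float) * 1e-3  # m
    v = np.asarray(velocity_cm_s, dtype=float) * 1e-2  # m/s
    tau_g = prep.tau_g * 1e-3  # s
    const = prep.gamma * float(g @ r0) * tau_g
    vel = prep.gamma * (pulse_index - 0.5) * float(g @ v) * tau_g**2
    return const + vel


def _ensemble(prep: DantePrep, flow: VelocityModel):
    """Phase parametrization of the isochromat grid.

    Position advances continuously between pulses, so the phase accrued in
    interval n is

        phi(n) = phi0 + gamma*G.v*tau_g * ((n-1)*tau_d + tau_g/2)

    i.e. the constant term evaluated at the position reached after n-1
    interpulse periods plus the within-lobe velocity phase.  This reduces to
    the tau_g^2 closed form of :func:`phase_increment` when tau_d == tau_g.
    Returns (phi0, offset, slope) with theta_n = phi0 + offset + (n-1)*slope.
    """
    phi0 = 2.0 * np.pi * (np.arange(flow.n_phase_samples) + 0.5) / flow.n_phase_samples
    tau_g = prep.tau_g * 1e-3
    tau_d = prep.tau_d * 1e-3
    gv = flow.gv_quantiles(prep.gradient)  # T/m * m/s
    slope = prep.gamma * gv * tau_g * tau_d  # rad per interpulse period
    offset = prep.gamma * gv * tau_g**2 / 2.0  # within-lobe velocity phase
    p0 = np.repeat(phi0, slope.size)
    sl = np.tile(slope, phi0.size)
    off = np.tile(offset, phi0.size)
    return p0, off, sl


def simulate_dante(
    prep: DantePrep,
    tissue: TissueRelaxation,
    flow: VelocityModel = STATIC_TISSUE,
    ideal_spoiling: bool = False,
) -> MzTrajectory:
    """Bloch-simulate the DANTE train and return the ensemble Mz trajectory.

    Each pulse is an instantaneous rotation by ``prep.flip_deg`` about the x
    axis (constant RF phase).  Between pulses every isochromat precesses by
    its interval phase (constant position term plus the growing velocity
    term) and relaxes over ``tau_d``.  The ensemble average runs over
    deterministic stratified grids of intravoxel phase and velocity; no
    randomness is involved.

    With ``ideal_spoiling`` the transverse magnetization is zeroed before
    every pulse, which reduces the static case to the spoiled gradient-echo
    steady state (1-E1)/(1-E1*cos(alpha)).
    """
    if tissue.T1 <= 0 or tissue.T2 <= 0:
        raise ValueError("relaxation times must be positive")
    phi0, offset, slope = _ensemble(prep, flow)
    n_iso = phi0.size
    if n_iso == 0:
        raise ValueError("empty isochromat ensemble")

    alpha = np.deg2rad(prep.flip_deg)
    ca, sa = np.cos(alpha), np.sin(alpha)
    e1 = np.exp(-prep.tau_d / tissue.T1)
    e2 = np.exp(-prep.tau_d / tissue.T2)

    mx = np.zeros(n_iso)
    my = np.zeros(n_iso)
    mz = np.ones(n_iso)
    out = np.empty(prep.n_pulses + 1)
    out[0] = 1.0
    for n in range(1, prep.n_pulses + 1):
        if ideal_spoiling:
            mx[:] = 0.0
            my[:] = 0.0
        # RF rotation about x
        my, mz = ca * my + sa * mz, ca * mz - sa * my
        # free precession about z by the interval phase
        theta = phi0 + offset + (n - 1) * slope
        ct, st = np.cos(theta), np.sin(theta)
        mx, my = ct * mx - st * my, st * mx + ct * my
        # relaxation over tau_d
        mx *= e2
        my *= e2
        mz = mz * e1 + (1.0 - e1)
        out[n] = mz.mean()
    return MzTrajectory(mz_signed=out, mz_abs=np.abs(out), flip_deg=prep.flip_deg)


def contrast_curve(
    traj_static: MzTrajectory,
    rho_static: float,
    traj_moving: MzTrajectory,
    rho_moving: float,
) -> ContrastCurve:
    """Spin-density weighted contrast between a static and a moving compartment.

    The static compartment keeps its sign; the moving compartment enters in
    magnitude because its Mz may undershoot while the image shows magnitude.
    """
    if len(traj_static) != len(traj_moving):
        raise ValueError("trajectory length mismatch")
    delta = rho_static * traj_static.mz_signed - rho_moving * traj_moving.mz_abs
    return ContrastCurve(delta_mz=delta, flip_deg=traj_static.flip_deg)


def dante_sweep(
    prep_template: DantePrep | None = None,
    tissues: dict[str, tuple[TissueRelaxation, VelocityModel]] | None = None,
    flip_deg_range=None,
    n_max: int = 700,
) -> dict[float, dict[str, object]]:
    """Sweep the DANTE simulation over a range of flip angles.

    Returns, per flip angle, the Mz trajectories of every compartment and the
    wall/CSF and wall/blood contrast curves (when those compartments are
    present).  Defaults reproduce the published exploration: flip angles 7-12
    degrees, up to 700 pulses, wall/CSF/blood compartments at 7T.
    """
    if prep_template is None:
        prep_template = DantePrep.protocol_7t()
    if tissues is None:
        from .flipangle_design import ARTERIAL_BLOOD_7T, CSF_7T, VESSEL_WALL_7T

        tissues = {
            "wall": (VESSEL_WALL_7T, STATIC_TISSUE),
            "csf": (CSF_7T, CSF_FLOW),
            "blood": (ARTERIAL_BLOOD_7T, BLOOD_FLOW),
        }
    if flip_deg_range is None:
        flip_deg_range = np.arange(7.0, 12.5, 1.0)
    flips = np.atleast_1d(np.asarray(flip_deg_range, dtype=float))
    if flips.size == 0:
        raise ValueError("empty flip angle range")

    results: dict[float, dict[str, object]] = {}
    for flip in flips:
        prep = DantePrep(
            flip_deg=float(flip),
            n_pulses=n_max,
            tau_d=prep_template.tau_d,
            tau_g=prep_template.tau_g,
            gradient=prep_template.gradient,
            gamma=prep_template.gamma,
        )
        trajs = {
            name: simulate_dante(prep, tissue, flow)
            for name, (tissue, flow) in tissues.items()
        }
        entry: dict[str, object] = {"trajectories": trajs}
        if "wall" in trajs:
            wall_rho = tissues["wall"][0].rho0
            for other in ("csf", "blood"):
                if other in trajs:
                    entry[f"contrast_wall_{other}"] = contrast_curve(
                        trajs["wall"], wall_rho, trajs[other], tissues[other][0].rho0
                    )
        results[float(flip)] = entry
    return results


def first_crossing(traj: MzTrajectory, level: float) -> int | None:
    """Smallest pulse count with |<Mz>| below ``level``, or None if never."""
    below = np.nonzero(traj.mz_abs < level)[0]
    return int(below[0]) if below.size else None
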