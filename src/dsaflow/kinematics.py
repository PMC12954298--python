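"""Kinematic biomarkers from flow fields: displacement velocity (mm/cycle),
oscillation angle theta (degrees vs the vessel axis) and strain rate (1/s)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optical_flow import FlowField
from .preprocess import Mask


@dataclass
class KinematicProfile:
    displacement_velocity: float      # mm/cycle
    theta_deg: float                  # [0, 90]
    strain_rate: float                # 1/s
    per_frame_vectors: list[tuple[float, float]]   # (dx, dy) mm/frame
    frames_per_cycle: int

    def __post_init__(self) -> None:
        if self.displacement_velocity < 0:
            raise ValueError("displacement_velocity must be >= 0")
        if not 0 <= self.theta_deg <= 90:
            raise ValueError("theta_deg must be in [0, 90]")
        if not math.isfinite(self.strain_rate):
            raise ValueError("strain_rate must be finite")


def displacement_vectors(flows: list[FlowField], thrombus_mask: Mask,
                         pixel_spacing: float) -> list[tuple[float, float]]:
    """Mean in-mask flow vector per frame pair, scaled to mm/frame."""
    if not flows:
        raise ValueError("flows must be nonempty")
    m = thrombus_mask.data
    if not m.any():
        raise ValueError("thrombus mask is empty")
    out = []
    for f in flows:
        if f.u.shape != m.shape:
            raise ValueError("mask shape does not match flow field shape")
        out.append((float(f.u[m].mean()) * pixel_spacing,
                    float(f.v[m].mean()) * pixel_spacing))
    return out


def displacement_velocity(vectors: list[tuple[float, float]],
                          frames_per_cycle: int,
                          mode: str = "path") -> float:
    """Per-cycle thrombus motion in mm/cycle.

    mode "path" (default): mean over complete cycle windows of the summed
    per-frame path length, so pure oscillation contributes.  mode "net":
    mean per-cycle net displacement magnitude.
    """
    if frames_per_cycle < 1:
        raise ValueError("frames_per_cycle must be >= 1")
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("vectors must be a sequence of (dx, dy) pairs")
    n_cycles = v.shape[0] // frames_per_cycle
    if n_cycles < 1:
        raise ValueError(
            f"need at least {frames_per_cycle} vectors (one full cycle), "
            f"got {v.shape[0]}"
        )
    totals = []
    for c in range(n_cycles):
        window = v[c * frames_per_cycle:(c + 1) * frames_per_cycle]
        if mode == "path":
            totals.append(np.hypot(window[:, 0], window[:, 1]).sum())
        elif mode == "net":
            totals.append(np.hypot(*window.sum(axis=0)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(totals))


def phase_average(vectors: list[tuple[float, float]],
                  frames_per_cycle: int) -> list[tuple[float, float]]:
    """Average vectors occupying the same phase of the motion cycle.

    For periodic thrombus motion the per-frame displacement is a function
    of cycle phase, so averaging frames `i % frames_per_cycle` across
    cycles suppresses measurement noise without attenuating the motion.
    Returns one vector per cycle phase.
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape[0] < frames_per_cycle:
        raise ValueError("need at least one full cycle of vectors")
    phases = np.arange(v.shape[0]) % frames_per_cycle
    return [tuple(v[phases == k].mean(axis=0)) for k in range(frames_per_cycle)]


def residual_noise_cov(vectors: list[tuple[float, float]],
                       frames_per_cycle: int) -> np.ndarray:
    """Covariance of the measurement noise on per-frame vectors, estimated
    from the residuals around the cycle-phase average."""
    v = np.asarray(vectors, dtype=float)
    phases = np.arange(v.shape[0]) % frames_per_cycle
    resid = np.empty_like(v)
    for k in range(frames_per_cycle):
        sel = phases == k
        resid[sel] = v[sel] - v[sel].mean(axis=0)
    dof = v.shape[0] - frames_per_cycle
    if dof < 1:
        return np.zeros((2, 2))
    return resid.T @ resid / dof


def oscillation_angle(vectors: list[tuple[float, float]],
                      vessel_axis_angle: float,
                      noise_cov: np.ndarray | None = None) -> float:
    """Angle (degrees, folded into [0, 90]) between the principal axis of
    the displacement vectors and the vessel axis.

    The principal axis is the leading eigenvector of the *uncentred* second
    moment matrix: an oscillating thrombus has near-zero mean displacement,
    so centring would erase the signal.  `noise_cov`, when given, is the
    total noise second moment summed over the supplied vectors; subtracting
    it removes the bias that anisotropic measurement noise exerts on the
    principal axis (errors-in-variables correction).
    """
    v = np.asarray(vectors, dtype=float)
    if v.size == 0 or not np.any(np.hypot(v[:, 0], v[:, 1]) > 0):
        raise ValueError("oscillation angle undefined for all-zero vectors")
    m = v.T @ v
    if noise_cov is not None:
        m = m - noise_cov
    w, vecs = np.linalg.eigh(m)
    px, py = vecs[:, int(np.argmax(w))]
    principal = math.degrees(math.atan2(py, px))
    diff = abs(principal - vessel_axis_angle) % 180.0
    return float(min(diff, 180.0 - diff))


def strain_rate(flow: FlowField, thrombus_mask: Mask, frame_rate: float) -> float:
    """Mean in-mask Frobenius norm of the symmetric velocity-gradient
    tensor, scaled by frame_rate (units 1/s)."""
    m = thrombus_mask.data
    if not m.any():
        raise ValueError("thrombus mask is empty")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    dudy, dudx = np.gradient(flow.u)
    dvdy, dvdx = np.gradient(flow.v)
    e_xy = 0.5 * (dudy + dvdx)
    frob = np.sqrt(dudx ** 2 + dvdy ** 2 + 2.0 * e_xy ** 2)
    return float(frob[m].mean()) * frame_rate


def kinematic_profile(flows: list[FlowField], thrombus_mask: Mask,
                      pixel_spacing: float, frame_rate: float,
                      vessel_axis_angle: float, frames_per_cycle: int,
                      use_phase_average: bool = True) -> KinematicProfile:
    """Convenience wrapper computing the full kinematic biomarker set.

    With `use_phase_average` (default) and more than one observed cycle,
    velocity and angle are computed from cycle-phase-averaged vectors,
    which suppresses noise in small-amplitude motion.
    """
    vectors = displacement_vectors(flows, thrombus_mask, pixel_spacing)
    basis = vectors
    noise_cov = None
    if use_phase_average and len(vectors) >= 2 * frames_per_cycle:
        basis = phase_average(vectors, frames_per_cycle)
        # noise second moment of the phase means: Cov_eps * sum_k 1/n_k
        v = np.asarray(vectors)
        phases = np.arange(v.shape[0]) % frames_per_cycle
        counts = np.bincount(phases, minlength=frames_per_cycle)
        noise_cov = (residual_noise_cov(vectors, frames_per_cycle)
                     * float((1.0 / counts[counts > 0]).sum()))
    velocity = displacement_velocity(basis, frames_per_cycle)
    theta = oscillation_angle(basis, vessel_axis_angle, noise_cov=noise_cov)
    sr = float(np.mean([strain_rate(f, thrombus_mask, frame_rate) for f in flows]))
    return KinematicProfile(displacement_velocity=velocity, theta_deg=theta,
                            strain_rate=sr, per_frame_vectors=vectors,
                            frames_per_cycle=frames_per_cycle)
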