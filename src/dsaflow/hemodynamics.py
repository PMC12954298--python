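"""Time-intensity-curve hemodynamics.

Transit time Delta-t across the thrombus, the linear pressure-gradient
surrogate Delta-P = kappa * Delta-t (kappa defaults to 1.05 mmHg/s), mean
flow velocity from optical flow, the venous quantitative flow ratio and
the collateral flow index.

The raw velocity/pressure ratio is not dimensionless; it is normalized by
a configurable reference ratio (the value an unobstructed segment would
attain) and clamped to [0, 1] so the 0.80 operating threshold is
meaningful.  A zero pressure gradient maps to 1 by convention
(no gradient = unobstructed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .optical_flow import FlowField
from .preprocess import DSASequence, Mask, PHASE_COLLATERAL

logger = logging.getLogger(__name__)

DEFAULT_KAPPA = 1.05          # mmHg/s
DEFAULT_REFERENCE_RATIO = 10.0  # (mm/s)/mmHg; repo normalization convention


@dataclass
class TimeIntensityCurve:
    times: np.ndarray
    intensities: np.ndarray
    roi_tag: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class HemodynamicProfile:
    v_mean: float       # mm/s
    delta_t: float      # s
    kappa: float        # mmHg/s
    delta_p: float      # mmHg
    vqfr_raw: float     # (mm/s)/mmHg
    vqfr: float         # dimensionless, [0, 1]

    def __post_init__(self) -> None:
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")
        if not math.isclose(self.delta_p, self.kappa * self.delta_t,
                            rel_tol=0, abs_tol=1e-12):
            raise ValueError("delta_p must equal kappa * delta_t exactly")
        if not 0 <= self.vqfr <= 1:
            raise ValueError("vqfr must lie in [0, 1]")
        if self.vqfr_raw < 0:
            raise ValueError("vqfr_raw must be >= 0")


@dataclass
class CollateralProfile:
    n_collaterals: int
    thrombus_length: float   # cm
    cfi: float               # collaterals/cm

    def __post_init__(self) -> None:
        if self.n_collaterals < 0:
            raise ValueError("n_collaterals must be >= 0")
        if self.thrombus_length <= 0:
            raise ValueError("thrombus_length must be > 0")
        if not math.isclose(self.cfi, self.n_collaterals / self.thrombus_length):
            raise ValueError("cfi must equal n_collaterals / thrombus_length")


def time_intensity_curve(seq: DSASequence, roi: Mask) -> TimeIntensityCurve:
    """Per-frame mean intensity inside the ROI; times = index / frame_rate."""
    m = roi.data
    if not m.any():
        raise ValueError("ROI is empty")
    if m.shape != seq.frame_shape:
        raise ValueError("ROI shape does not match the frames")
    vals = seq.frames[:, m].mean(axis=1)
    return TimeIntensityCurve(seq.times, vals, roi.role)


def _first_half_max_crossing(curve: TimeIntensityCurve) -> float:
    """Time of the first upslope crossing of half-maximum, with linear
    interpolation between the bracketing samples."""
    y = curve.intensities
    level = 0.5 * (y.min() + y.max())
    above = np.flatnonzero(y >= level)
    i = int(above[0])
    if i == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def transit_time(proximal: TimeIntensityCurve, distal: TimeIntensityCurve,
                 method: str = "time_to_peak") -> float:
    """Contrast transit-time difference distal minus proximal, in seconds.

    time_to_peak uses the time of the first sample attaining the curve
    maximum; arrival_half_max uses the first upslope crossing of
    half-maximum.  Negative differences are clamped to 0 with a warning.
    """
    for c in (proximal, distal):
        if np.ptp(c.intensities) == 0:
            raise ValueError(f"constant {c.roi_tag} curve: transit time undefined")
    if method == "time_to_peak":
        tp = float(proximal.times[int(np.argmax(proximal.intensities))])
        td = float(distal.times[int(np.argmax(distal.intensities))])
    elif method == "arrival_half_max":
        tp = _first_half_max_crossing(proximal)
        td = _first_half_max_crossing(distal)
    else:
        raise ValueError(f"unknown transit-time method {method!r}")
    dt = td - tp
    if dt < 0:
        logger.warning("negative transit time (%.3f s) clamped to 0; "
                       "check ROI placement", dt)
        dt = 0.0
    return dt


def pressure_gradient(delta_t: float, kappa: float = DEFAULT_KAPPA) -> float:
    """Linear surrogate Delta-P = kappa * Delta-t (mmHg)."""
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return kappa * delta_t


def mean_flow_velocity(flows: list[FlowField], lumen_roi: Mask,
                       pixel_spacing: float, frame_rate: float) -> float:
    """Time-average of the in-ROI mean flow magnitude, in mm/s."""
    if not flows:
        raise ValueError("flows must be nonempty")
    m = lumen_roi.data
    if not m.any():
        raise ValueError("lumen ROI is empty")
    per_frame = [float(f.magnitude[m].mean()) for f in flows]
    return float(np.mean(per_frame)) * pixel_spacing * frame_rate


def vqfr(v_mean: float, delta_p: float,
         reference_ratio: float = DEFAULT_REFERENCE_RATIO) -> tuple[float, float]:
    """(vqfr_raw, vqfr): raw velocity/pressure ratio and its normalized,
    clamped value in [0, 1].  delta_p = 0 yields vqfr = 1 (unobstructed)."""
    if v_mean < 0 or delta_p < 0:
        raise ValueError("v_mean and delta_p must be >= 0")
    if reference_ratio <= 0:
        raise ValueError("reference_ratio must be > 0")
    if delta_p == 0:
        return math.inf if v_mean > 0 else 0.0, 1.0
    raw = v_mean / delta_p
    return raw, min(1.0, raw / reference_ratio)


def hemodynamic_profile(v_mean: float, delta_t: float,
                        kappa: float = DEFAULT_KAPPA,
                        reference_ratio: float = DEFAULT_REFERENCE_RATIO
                        ) -> HemodynamicProfile:
    delta_p = pressure_gradient(delta_t, kappa)
    raw, ratio = vqfr(v_mean, delta_p, reference_ratio)
    return HemodynamicProfile(v_mean=v_mean, delta_t=delta_t, kappa=kappa,
                              delta_p=delta_p,
                              vqfr_raw=0.0 if math.isinf(raw) else raw,
                              vqfr=ratio)


def _axis_span(mask: np.ndarray, ex: float, ey: float) -> float:
    rows, cols = np.nonzero(mask)
    s = cols * ex + rows * ey
    return float(s.max() - s.min())


def count_collaterals(seq: DSASequence, thrombus_mask: Mask, lumen_mask: Mask,
                      vessel_axis_angle: float, lumen_margin_px: int = 2,
                      min_pixels: int = 5,
                      intensity_fraction: float = 0.5) -> int:
    """Count opacified collateral channels bypassing >50% of the thrombus.

    Connected bright components of the mean collateral-phase frame lying
    outside the (dilated) lumen are counted when their projection onto the
    vessel axis spans more than half the thrombus's axis-projected extent.
    """
    if not thrombus_mask.data.any() or not lumen_mask.data.any():
        raise ValueError("masks must be nonempty")
    idx = seq.phase_indices(PHASE_COLLATERAL)
    if idx.size == 0:
        raise ValueError("sequence has no collateral-phase frames")
    img = seq.frames[idx].mean(axis=0)
    outside = ~ndimage.binary_dilation(lumen_mask.data,
                                       iterations=lumen_margin_px)
    vals = img[outside]
    vmax = vals.max()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    noise_floor = med + 6.0 * 1.4826 * mad
    # absolute floor vs in-lumen opacification: soft vessel-edge tails must
    # not masquerade as channels when no collateral exists
    thr = max(intensity_fraction * vmax, noise_floor, 0.1 * img.max())
    bright = outside & (img > thr)
    labels, n = ndimage.label(bright)
    if n == 0:
        return 0
    ang = math.radians(vessel_axis_angle)
    ex, ey = math.cos(ang), math.sin(ang)
    extent = _axis_span(thrombus_mask.data, ex, ey)
    count = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_pixels:
            continue
        if _axis_span(comp, ex, ey) > 0.5 * extent:
            count += 1
    return count


def thrombus_length_cm(thrombus_mask: Mask, vessel_axis_angle: float,
                       pixel_spacing: float) -> float:
    """Axis-projected thrombus extent, converted px -> cm."""
    ang = math.radians(vessel_axis_angle)
    span = _axis_span(thrombus_mask.data, math.cos(ang), math.sin(ang))
    return span * pixel_spacing / 10.0


def collateral_flow_index(n_collaterals: int, thrombus_length: float) -> float:
    """CFI = number of qualifying collaterals / thrombus length (cm)."""
    if thrombus_length <= 0:
        raise ValueError("thrombus_length must be > 0")
    if n_collaterals < 0:
        raise ValueError("n_collaterals must be >= 0")
    return n_collaterals / thrombus_length


def collateral_profile(n_collaterals: int, thrombus_length: float) -> CollateralProfile:
    return CollateralProfile(n_collaterals=n_collaterals,
                             thrombus_length=thrombus_length,
                             cfi=collateral_flow_index(n_collaterals, thrombus_length))
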