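"""Synthetic dynamic-DSA phantoms with known ground truth.

A phantom is a contrast-opacified straight vein rendered on a pixel grid.
It contains:

* a thrombus, rendered as a smooth-edged intensity deficit (filling defect)
  that oscillates sinusoidally along a fixed direction at a configurable
  angle to the vessel axis;
* a contrast bolus whose arrival at the distal side of the thrombus lags
  the proximal side by a configurable transit delay;
* optional thin curved collateral channels that opacify only during the
  late ("collateral") phase;
* optional advected lumen texture encoding a known mean flow velocity,
  additive Gaussian noise and frame-wise baseline drift.

All generating parameters are returned as ground truth so that analysis
code can be tested for parameter recovery.

Coordinate convention (used package-wide): x = column index, y = row index,
origin top-left; axis angles are measured in degrees from the +x axis
toward +y.  Physical positions are in millimetres relative to the image
centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import (DSASequence, Mask, PHASE_BASELINE, PHASE_COLLATERAL,
                         PHASE_FILLING)

_DEFICIT_DEPTH = 0.9     # fractional intensity drop at the thrombus centre
_DEFICIT_HALO = 1.3      # deficit support extends this factor past the mask
_CHANNEL_INTENSITY = 0.8
_CHANNEL_HALF_WIDTH = 1.2   # px
_ROI_WIDTH = 6              # px, proximal/distal ROI extent along the axis


@dataclass(frozen=True)
class PhantomConfig:
    """Generating parameters of a synthetic dynamic-DSA sequence.

    All `*_true` fields are the ground-truth counterparts of quantities the
    analysis modules estimate.  Lengths are physical (mm or cm as noted);
    the "cycle" of the displacement velocity is `frames_per_cycle` frames.
    """

    image_shape: tuple[int, int] = (96, 128)        # (H, W) pixels
    n_frames: int = 48
    frame_rate: float = 15.0                        # frames/s, >= 7.5
    pixel_spacing: float = 0.5                      # mm/pixel
    vessel_axis_angle: float = 0.0                  # degrees from +x axis
    vessel_width: float = 10.0                      # mm (full width)
    thrombus_length: float = 2.0                    # cm
    thrombus_center: tuple[float, float] = (0.0, 0.0)  # mm from image centre
    thrombus_width_fraction: float = 0.35           # of vessel_width (half)
    displacement_velocity_true: float = 0.0         # mm/cycle (path length)
    oscillation_angle_true: float = 0.0             # degrees vs vessel axis
    frames_per_cycle: int = 8
    bolus_transit_delay_true: float = 1.0           # s, proximal -> distal
    mean_flow_velocity_true: float = 0.0            # mm/s (needs texture)
    n_collaterals_true: int = 0
    collateral_bypass_fraction: float = 0.8         # of thrombus length
    noise_sd: float = 0.0                           # intensity units
    baseline_drift: float = 0.0                     # intensity/frame
    flow_texture_amp: float = 0.0                   # relative amplitude
    n_baseline_frames: int = 4
    fill_rise_time: float = 0.4                     # s
    collateral_fraction: float = 0.25               # last fraction of frames
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate < 7.5:
            raise ValueError("frame_rate must be >= 7.5 frames/s")
        if min(self.image_shape) < 16 or self.n_frames < 2:
            raise ValueError("image too small or too few frames")
        for name in ("pixel_spacing", "vessel_width", "thrombus_length",
                     "fill_rise_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.displacement_velocity_true < 0 or self.mean_flow_velocity_true < 0:
            raise ValueError("velocities must be >= 0")
        if not 0 <= self.oscillation_angle_true <= 90:
            raise ValueError("oscillation_angle_true must be in [0, 90] degrees")
        if self.frames_per_cycle < 2:
            raise ValueError("frames_per_cycle must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bolus_transit_delay_true < 0:
            raise ValueError("bolus_transit_delay_true must be >= 0")
        if self.n_collaterals_true < 0:
            raise ValueError("n_collaterals_true must be >= 0")
        if not 0 < self.collateral_bypass_fraction <= 1:
            raise ValueError("collateral_bypass_fraction must be in (0, 1]")
        if not 1 <= self.n_baseline_frames < self.n_frames:
            raise ValueError("n_baseline_frames out of range")
        if not 0 <= self.collateral_fraction < 1:
            raise ValueError("collateral_fraction must be in [0, 1)")
        if not 0 < self.thrombus_width_fraction < 0.5:
            raise ValueError("thrombus_width_fraction must be in (0, 0.5) "
                             "so the thrombus fits inside the lumen")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a generated sequence."""

    config: PhantomConfig
    thrombus_mask: np.ndarray          # (n_frames, H, W) bool
    lumen_mask: Mask
    collateral_masks: list[Mask]
    proximal_roi: Mask
    distal_roi: Mask
    displacement_px: np.ndarray        # (n_frames, 2) true (dx, dy) offsets

    def thrombus_mask_frame(self, k: int) -> Mask:
        return Mask(self.thrombus_mask[k], "thrombus")


def _cycle_path_factor(frames_per_cycle: int) -> float:
    """Discrete per-cycle path length of a unit-amplitude sampled sinusoid."""
    k = np.arange(frames_per_cycle + 1)
    s = np.sin(2 * np.pi * k / frames_per_cycle)
    return float(np.abs(np.diff(s)).sum())


def generate_sequence(config: PhantomConfig) -> tuple[DSASequence, PhantomTruth]:
    """Render a phantom sequence and its ground truth.

    Deterministic for a given config (the only randomness — noise and
    texture phases — is driven by ``config.seed``).
    """
    config.validate()
    h, w = config.image_shape
    sp = config.pixel_spacing
    rng = np.random.default_rng(config.seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ang = math.radians(config.vessel_axis_angle)
    ex, ey = math.cos(ang), math.sin(ang)           # axis unit vector
    # axis (s) and perpendicular (p) coordinates in pixels
    s_grid = (xx - cx) * ex + (yy - cy) * ey
    p_grid = -(xx - cx) * ey + (yy - cy) * ex

    halfwidth = config.vessel_width / 2.0 / sp
    lumen_soft = 1.0 / (1.0 + np.exp(-(halfwidth - np.abs(p_grid)) / 0.8))
    lumen_mask = np.abs(p_grid) <= halfwidth

    # thrombus geometry
    tc_mm = np.asarray(config.thrombus_center, dtype=float)
    tcx, tcy = cx + tc_mm[0] / sp, cy + tc_mm[1] / sp
    s_center = (tcx - cx) * ex + (tcy - cy) * ey
    a_px = config.thrombus_length * 10.0 / 2.0 / sp     # half length, px
    b_px = config.thrombus_width_fraction * config.vessel_width / sp  # half thickness
    s0, s1 = s_center - a_px, s_center + a_px

    # oscillation waveform: amplitude calibrated so the discrete per-cycle
    # path length equals displacement_velocity_true exactly
    amp_px = 0.0
    if config.displacement_velocity_true > 0:
        amp_px = (config.displacement_velocity_true
                  / _cycle_path_factor(config.frames_per_cycle) / sp)
    osc = math.radians(config.vessel_axis_angle + config.oscillation_angle_true)
    ox, oy = math.cos(osc), math.sin(osc)
    frames_idx = np.arange(config.n_frames)
    disp = amp_px * np.sin(2 * np.pi * frames_idx / config.frames_per_cycle)
    displacement_px = np.stack([disp * ox, disp * oy], axis=1)

    # field-of-view check: thrombus plus flanking ROIs must fit in the lumen
    s_lumen = s_grid[lumen_mask]
    gap = max(3.0, math.ceil(amp_px) + 2.0)
    need_lo = s0 - gap - _ROI_WIDTH
    need_hi = s1 + gap + _ROI_WIDTH
    if need_lo <= s_lumen.min() + 1 or need_hi >= s_lumen.max() - 1:
        raise ValueError(
            "invalid geometry: thrombus (plus flanking ROIs) does not fit in "
            f"the field of view (needs axis range [{need_lo:.1f}, {need_hi:.1f}] px, "
            f"lumen spans [{s_lumen.min():.1f}, {s_lumen.max():.1f}] px); "
            "shorten the thrombus or enlarge the image"
        )

    # bolus arrival time: proximal side fills at t_fill, distal side lags by
    # the configured transit delay, with a linear ramp across the thrombus
    t_fill = (config.n_baseline_frames + 1) / config.frame_rate
    frac = np.clip((s_grid - s0) / max(s1 - s0, 1e-9), 0.0, 1.0)
    arrival = t_fill + config.bolus_transit_delay_true * frac

    # phase labels
    n_coll = int(round(config.collateral_fraction * config.n_frames))
    coll_start = config.n_frames - n_coll if n_coll > 0 else config.n_frames
    labels = []
    for k in range(config.n_frames):
        if k < config.n_baseline_frames:
            labels.append(PHASE_BASELINE)
        elif k >= coll_start:
            labels.append(PHASE_COLLATERAL)
        else:
            labels.append(PHASE_FILLING)
    t_coll = coll_start / config.frame_rate

    # advected lumen texture (sum of axial sinusoids moving at the true
    # mean flow velocity; band-limited so sub-pixel shifts stay smooth)
    wavelengths = np.array([14.0, 23.0, 37.0])
    phases = rng.uniform(0, 2 * np.pi, size=wavelengths.size)
    v_px_per_s = config.mean_flow_velocity_true / sp

    # collateral channel geometry
    coll_geoms = []
    for j in range(config.n_collaterals_true):
        side = 1.0 if j % 2 == 0 else -1.0
        clear = 5.0 + 6.0 * (j // 2)
        half_span = config.collateral_bypass_fraction * a_px
        coll_geoms.append((side, clear, s_center - half_span, s_center + half_span))

    def channel_profile(side, clear, sa, sb):
        u = (s_grid - sa) / max(sb - sa, 1e-9)
        in_span = (u >= 0) & (u <= 1)
        ramp = np.clip(np.sin(np.pi * np.clip(u, 0, 1)) / 0.2, 0.0, 1.0)
        offset = side * (halfwidth - 1.0 + clear * ramp)
        dist = np.abs(p_grid - offset)
        tube = 1.0 / (1.0 + np.exp(-(_CHANNEL_HALF_WIDTH - dist) / 0.4))
        return np.where(in_span, tube, 0.0), in_span & (dist <= _CHANNEL_HALF_WIDTH)

    channels = [channel_profile(*g) for g in coll_geoms]
    collateral_masks = [Mask(m, "collateral") for _, m in channels]

    # base thrombus mask (frame 0) on the integer grid; per-frame masks are
    # integer translations so the pixel count is conserved exactly
    r0 = np.sqrt(((s_grid - s_center) / a_px) ** 2 + (p_grid / b_px) ** 2)
    base_mask = r0 <= 1.0

    frames = np.empty((config.n_frames, h, w), dtype=float)
    thrombus_masks = np.empty((config.n_frames, h, w), dtype=bool)
    times = frames_idx / config.frame_rate
    rise = config.fill_rise_time

    for k in range(config.n_frames):
        t = times[k]
        fill = np.clip((t - arrival) / rise, 0.0, 1.0)
        dx, dy = displacement_px[k]
        s_c = s_center + dx * ex + dy * ey
        p_c = -dx * ey + dy * ex
        r2 = (((s_grid - s_c) / a_px) ** 2 + ((p_grid - p_c) / b_px) ** 2)
        # parabolic dome with a faint halo extending _DEFICIT_HALO beyond
        # the nominal extent: every mask pixel keeps a substantial intensity
        # gradient (a flat-top or hard-edged profile leaves the mask rim and
        # interior untrackable by optical flow); the truth mask (r <= 1) is
        # the region where the defect exceeds ~40% of its peak depth
        deficit = _DEFICIT_DEPTH * np.clip(1.0 - r2 / _DEFICIT_HALO ** 2,
                                           0.0, None)
        img = fill * (1.0 - deficit)
        if config.flow_texture_amp > 0:
            tex = np.zeros_like(s_grid)
            for lam, ph in zip(wavelengths, phases):
                tex += np.sin(2 * np.pi * (s_grid - v_px_per_s * t) / lam + ph)
            img *= 1.0 + config.flow_texture_amp * tex / wavelengths.size
        img *= lumen_soft
        if labels[k] == PHASE_COLLATERAL or t >= t_coll:
            c_fill = np.clip((t - t_coll) / rise, 0.0, 1.0)
            for tube, _ in channels:
                img = np.maximum(img, _CHANNEL_INTENSITY * c_fill * tube)
        img = img + config.baseline_drift * k
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[k] = img
        shift = (int(round(dy)), int(round(dx)))
        thrombus_masks[k] = (base_mask if shift == (0, 0)
                             else ndimage.shift(base_mask.astype(np.uint8), shift,
                                                order=0, mode="constant",
                                                cval=0).astype(bool))

    proximal = Mask(lumen_mask & (s_grid >= s0 - gap - _ROI_WIDTH)
                    & (s_grid <= s0 - gap), "proximal")
    distal = Mask(lumen_mask & (s_grid >= s1 + gap)
                  & (s_grid <= s1 + gap + _ROI_WIDTH), "distal")

    seq = DSASequence(frames, config.frame_rate, sp, labels)
    truth = PhantomTruth(config=config, thrombus_mask=thrombus_masks,
                         lumen_mask=Mask(lumen_mask, "lumen"),
                         collateral_masks=collateral_masks,
                         proximal_roi=proximal, distal_roi=distal,
                         displacement_px=displacement_px)
    return seq, truth


# ---------------------------------------------------------------------------
# synthetic feature/outcome cohorts
# ---------------------------------------------------------------------------

DEFAULT_CLASS_PARAMS: dict[str, dict] = {
    "high": dict(fraction=0.5, velocity=(2.8, 0.5), theta=(60.0, 12.0),
                 vqfr=(0.62, 0.12), cfi=(0.45, 0.15), d_dimer=(7.5, 2.5),
                 wells=(6.0, 2.0), p_iliac=0.8),
    "low": dict(fraction=0.5, velocity=(1.3, 0.4), theta=(30.0, 12.0),
                vqfr=(0.88, 0.08), cfi=(0.18, 0.10), d_dimer=(3.0, 1.5),
                wells=(2.5, 1.5), p_iliac=0.5),
}

DEFAULT_EVENT_RATES: dict[str, dict] = {
    "high": {"pe": 0.30, "pts": 0.21},
    "low": {"pe": 0.03, "pts": 0.08},
}

COHORT_COLUMNS = ["case_id", "risk_class", "displacement_velocity_mm_per_cycle",
                  "theta_deg", "vqfr", "cfi", "d_dimer", "wells_score",
                  "location", "pe_event", "pts_event"]


def generate_feature_cohort(n_cases: int,
                            class_params: dict[str, dict] | None = None,
                            event_rates: dict[str, dict] | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Draw a tabular synthetic cohort of imaging + clinical features.

    Features are drawn per risk class from truncated normal distributions;
    binary PE / severe-PTS outcomes follow class-conditional Bernoulli
    rates.  Fully seeded and reproducible.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    class_params = class_params if class_params is not None else DEFAULT_CLASS_PARAMS
    event_rates = event_rates if event_rates is not None else DEFAULT_EVENT_RATES
    fracs = {c: p["fraction"] for c, p in class_params.items()}
    total = sum(fracs.values())
    if total <= 0:
        raise ValueError("class fractions must sum to a positive value")
    names = sorted(class_params)
    counts = {c: int(round(n_cases * fracs[c] / total)) for c in names}
    counts[names[-1]] += n_cases - sum(counts.values())
    for c, n in counts.items():
        if n <= 0:
            raise ValueError(f"degenerate class {c!r}: zero cases at n={n_cases}")
    for c in names:
        for key in ("pe", "pts"):
            p = event_rates[c][key]
            if not 0 <= p <= 1:
                raise ValueError(f"event rate {c}/{key} outside [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    for c in names:
        p = class_params[c]
        n = counts[c]
        vel = np.clip(rng.normal(*p["velocity"], n), 0.0, None)
        theta = np.clip(rng.normal(*p["theta"], n), 0.0, 90.0)
        vqfr = np.clip(rng.normal(*p["vqfr"], n), 0.0, 1.0)
        cfi = np.clip(rng.normal(*p["cfi"], n), 0.0, None)
        dd = np.clip(rng.normal(*p["d_dimer"], n), 0.0, None)
        wells = np.clip(np.round(rng.normal(*p["wells"], n)), 0, None).astype(int)
        loc = np.where(rng.random(n) < p.get("p_iliac", 0.5), "iliac", "femoral")
        pe = (rng.random(n) < event_rates[c]["pe"]).astype(int)
        pts = (rng.random(n) < event_rates[c]["pts"]).astype(int)
        for i in range(n):
            rows.append((f"case_{cid:05d}", c, vel[i], theta[i], vqfr[i],
                         cfi[i], dd[i], wells[i], loc[i], pe[i], pts[i]))
            cid += 1
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
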