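"""Sequence/mask containers and classical DSA preprocessing.

The preprocessing chain is baseline subtraction -> optional Gaussian
denoising -> intensity normalization.  Thrombus segmentation is a classical
threshold + connected-component proxy (pixels darker than an intensity
quantile inside the opacified lumen); callers may always supply their own
masks instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

PHASE_BASELINE = "baseline"
PHASE_FILLING = "filling"
PHASE_COLLATERAL = "collateral"
PHASES = (PHASE_BASELINE, PHASE_FILLING, PHASE_COLLATERAL)

MASK_ROLES = ("thrombus", "lumen", "proximal", "distal", "collateral")


@dataclass
class DSASequence:
    """A 2D+t intensity stack with acquisition metadata.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Ordered intensity frames (float).
    frame_rate : float
        Frames per second (> 0).
    pixel_spacing : float
        Millimetres per pixel (> 0).
    phase_labels : list of str, optional
        Per-frame label in {"baseline", "filling", "collateral"}.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: float
    phase_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (n, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.phase_labels is not None:
            if len(self.phase_labels) != self.n_frames:
                raise ValueError("phase_labels length must match n_frames")
            bad = set(self.phase_labels) - set(PHASES)
            if bad:
                raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame_index / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def phase_indices(self, phase: str) -> np.ndarray:
        if self.phase_labels is None:
            raise ValueError("sequence carries no phase labels")
        return np.flatnonzero(np.asarray(self.phase_labels) == phase)

    def with_frames(self, frames: np.ndarray) -> "DSASequence":
        """Copy of this sequence with replaced pixel data, metadata untouched."""
        labels = list(self.phase_labels) if self.phase_labels is not None else None
        return DSASequence(np.asarray(frames, dtype=float), self.frame_rate,
                           self.pixel_spacing, labels)


@dataclass
class Mask:
    """Binary 2D region with a semantic role tag."""

    data: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")
        if self.role in ("thrombus", "lumen") and not self.data.any():
            raise ValueError(f"{self.role} mask must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())


def subtract_baseline(seq: DSASequence, baseline_frames: int) -> DSASequence:
    """Subtract the mean of the first `baseline_frames` frames from every frame."""
    if not 1 <= baseline_frames < seq.n_frames:
        raise ValueError(
            f"baseline_frames must be in [1, {seq.n_frames - 1}], got {baseline_frames}"
        )
    baseline = seq.frames[:baseline_frames].mean(axis=0)
    return seq.with_frames(seq.frames - baseline)


def denoise(seq: DSASequence, sigma=1.0) -> DSASequence:
    """Per-frame Gaussian smoothing; sigma in pixels, 0 is a no-op.

    `sigma` may be a (row, column) pair for anisotropic smoothing — e.g.
    smoothing along the vessel axis only, which suppresses noise without
    smearing static vessel walls into the moving thrombus.
    """
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    if np.any(sig < 0):
        raise ValueError("sigma must be >= 0")
    if not np.any(sig > 0):
        return seq.with_frames(seq.frames.copy())
    s = tuple(sig) if sig.size > 1 else float(sig[0])
    out = np.stack([ndimage.gaussian_filter(f, s) for f in seq.frames])
    return seq.with_frames(out)


def normalize_intensity(seq: DSASequence, method: str = "zscore") -> DSASequence:
    """Global intensity normalization over the whole stack.

    zscore -> mean 0, SD 1; minmax -> range [0, 1].  Constant stacks are
    rejected (both normalizations are undefined).
    """
    x = seq.frames
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValueError("zscore normalization undefined for a constant stack")
        return seq.with_frames((x - x.mean()) / sd)
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("minmax normalization undefined for a constant stack")
        return seq.with_frames((x - lo) / (hi - lo))
    raise ValueError(f"unknown normalization method {method!r}")


def _opacified_mean_frame(seq: DSASequence, phase: str) -> np.ndarray:
    """Mean over the better-opacified half of the frames in `phase`.

    Guards against early filling frames where the contrast bolus has not yet
    crossed the field of view.
    """
    idx = seq.phase_indices(phase)
    if idx.size == 0:
        raise ValueError(f"sequence has no {phase!r} frames")
    totals = seq.frames[idx].sum(axis=(1, 2))
    keep = idx[totals >= np.median(totals)]
    return seq.frames[keep].mean(axis=0)


def steady_filling_indices(seq: DSASequence, rel_tol: float = 0.01) -> np.ndarray:
    """Filling-phase frames in which opacification has reached a plateau.

    Brightness-constancy motion analysis is only valid once the bolus has
    stopped sweeping the field of view, so kinematics should be computed on
    this window: frames whose total intensity is within `rel_tol` of the
    filling-phase maximum.
    """
    idx = seq.phase_indices(PHASE_FILLING)
    if idx.size == 0:
        raise ValueError("sequence has no filling frames")
    totals = seq.frames[idx].sum(axis=(1, 2))
    lo = totals.min()
    # robust plateau level: median of the top quartile, so single noisy
    # frames neither raise the bar nor get excluded
    top = np.sort(totals)[-max(1, totals.size // 4):]
    hi = np.median(top)
    above = totals >= hi - rel_tol * max(hi - lo, 1e-12)
    if not above.any():
        raise ValueError("no steady opacification plateau found; "
                         "acquire more filling frames")
    # contiguous run from the first plateau frame: frame-pair flow must not
    # silently span gaps, and noise dips below threshold are still plateau
    keep = idx[int(np.argmax(above)):]
    if keep.size < 2:
        raise ValueError("no steady opacification plateau found; "
                         "acquire more filling frames")
    return keep


def segment_lumen(seq: DSASequence, phase: str = PHASE_FILLING,
                  threshold_fraction: float = 0.5) -> Mask:
    """Opacified-lumen mask: bright pixels of the well-filled frames, holes
    (filling defects) closed, largest connected component kept."""
    img = _opacified_mean_frame(seq, phase)
    thr = img.min() + threshold_fraction * (img.max() - img.min())
    bright = img > thr
    bright = ndimage.binary_fill_holes(bright)
    labels, n = ndimage.label(bright)
    if n == 0:
        raise ValueError("no opacified region found; lower threshold_fraction")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return Mask(labels == (1 + int(np.argmax(sizes))), "lumen")


def segment_thrombus(seq: DSASequence, phase: str = PHASE_FILLING,
                     threshold_quantile: float = 0.2,
                     lumen: Mask | None = None, edge_erosion_px: int = 2) -> Mask:
    """Largest intra-lumen filling defect.

    Pixels inside the lumen that fall below the `threshold_quantile` of the
    in-lumen intensity distribution are candidate defect pixels; the largest
    connected component is returned.  The lumen is eroded by
    `edge_erosion_px` first so partial-volume wall pixels are not mistaken
    for defect.
    """
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    if lumen is None:
        lumen = segment_lumen(seq, phase=phase)
    interior = lumen.data
    if edge_erosion_px > 0:
        eroded = ndimage.binary_erosion(interior, iterations=edge_erosion_px)
        if eroded.any():
            interior = eroded
    img = _opacified_mean_frame(seq, phase)
    vals = img[interior]
    cut = np.quantile(vals, threshold_quantile)
    candidates = interior & (img < cut)
    labels, n = ndimage.label(candidates)
    if n == 0:
        raise ValueError(
            "no filling defect found inside the lumen; "
            "try a higher threshold_quantile or supply a mask"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return Mask(labels == (1 + int(np.argmax(sizes))), "thrombus")


def estimate_vessel_axis(lumen: Mask) -> float:
    """Vessel axis angle (degrees from the +x/column axis, toward +y/rows)
    from the principal axis of the lumen pixel coordinates."""
    rows, cols = np.nonzero(lumen.data)
    pts = np.stack([cols - cols.mean(), rows - rows.mean()])
    cov = pts @ pts.T
    w, vecs = np.linalg.eigh(cov)
    vx, vy = vecs[:, int(np.argmax(w))]
    ang = np.degrees(np.arctan2(vy, vx)) % 180.0
    return float(ang if ang <= 90 else ang - 180)
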