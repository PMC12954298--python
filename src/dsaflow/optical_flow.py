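"""Dense Horn-Schunck optical flow.

Implemented from scratch: brightness constancy plus an alpha^2-weighted
smoothness penalty, solved by Jacobi-style averaging iterations.  Spatial
and temporal derivatives use averaged forward differences over the 2x2x2
cube spanned by the two frames, with edge replication at the borders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import DSASequence

# weights of the neighbourhood average in the iterative update
_AVG_KERNEL = np.array([[1.0, 2.0, 1.0],
                        [2.0, 0.0, 2.0],
                        [1.0, 2.0, 1.0]]) / 12.0


@dataclass
class FlowField:
    """Per-pixel displacement between two consecutive frames.

    u is the x (column) displacement, v the y (row) displacement, both in
    pixels/frame and positive toward increasing index.
    """

    u: np.ndarray
    v: np.ndarray
    alpha: float
    n_iterations_run: int
    final_update_norm: float
    residual_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow field contains non-finite values")
        if self.n_iterations_run < 1:
            raise ValueError("n_iterations_run must be >= 1")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class HSParams:
    """Horn-Schunck solver settings (all exposed in pipeline config)."""

    alpha: float = 1.0
    max_iter: int = 300
    tol: float = 1e-4
    smooth_sigma: float = 0.0  # optional Gaussian pre-smoothing of the frames
    n_warp: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.n_warp < 1:
            raise ValueError("n_warp must be >= 1")


def _cube_derivatives(a: np.ndarray, b: np.ndarray):
    """Averaged forward differences over the 2x2x2 cube of frames a, b."""
    ap = np.pad(a, ((0, 1), (0, 1)), mode="edge")
    bp = np.pad(b, ((0, 1), (0, 1)), mode="edge")
    ex = 0.25 * ((ap[:-1, 1:] - ap[:-1, :-1]) + (ap[1:, 1:] - ap[1:, :-1])
                 + (bp[:-1, 1:] - bp[:-1, :-1]) + (bp[1:, 1:] - bp[1:, :-1]))
    ey = 0.25 * ((ap[1:, :-1] - ap[:-1, :-1]) + (ap[1:, 1:] - ap[:-1, 1:])
                 + (bp[1:, :-1] - bp[:-1, :-1]) + (bp[1:, 1:] - bp[:-1, 1:]))
    et = 0.25 * ((bp[:-1, :-1] - ap[:-1, :-1]) + (bp[1:, :-1] - ap[1:, :-1])
                 + (bp[:-1, 1:] - ap[:-1, 1:]) + (bp[1:, 1:] - ap[1:, 1:]))
    return ex, ey, et


def _hs_increment(a: np.ndarray, b: np.ndarray, alpha: float, max_iter: int,
                  tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One linearized Horn-Schunck solve (Jacobi averaging iterations)."""
    ex, ey, et = _cube_derivatives(a, b)
    denom = alpha ** 2 + ex ** 2 + ey ** 2
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    trace: list[float] = []
    for _ in range(max_iter):
        ubar = ndimage.convolve(u, _AVG_KERNEL, mode="nearest")
        vbar = ndimage.convolve(v, _AVG_KERNEL, mode="nearest")
        t = (ex * ubar + ey * vbar + et) / denom
        u_new = ubar - ex * t
        v_new = vbar - ey * t
        update = float(np.mean(np.hypot(u_new - u, v_new - v)))
        u, v = u_new, v_new
        trace.append(update)
        if update < tol:
            break
    return u, v, trace


def _warp(img: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    rows, cols = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
    return ndimage.map_coordinates(img, [rows + v, cols + u], order=3,
                                   mode="nearest")


def horn_schunck(frame_a: np.ndarray, frame_b: np.ndarray,
                 alpha: float = 1.0, max_iter: int = 300,
                 tol: float = 1e-4, n_warp: int = 1) -> FlowField:
    """Estimate dense flow carrying frame_a onto frame_b.

    Parameters
    ----------
    alpha : float
        Smoothness weight; larger values give spatially smoother fields.
    max_iter, tol : int, float
        Each linearized solve stops at `max_iter` Jacobi iterations or when
        the mean per-pixel update norm drops below `tol` (pixels).
    n_warp : int
        Number of linearizations.  1 (default) is the plain Horn-Schunck
        solution; values > 1 re-linearize around the current estimate by
        warping frame_b back, reducing the bias for motions approaching a
        pixel per frame.

    Returns
    -------
    FlowField with the iteration count, final update norm and the residual
    trace (mean update norm per Jacobi iteration of the final solve).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2D")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("frames contain non-finite values")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_warp < 1:
        raise ValueError("n_warp must be >= 1")

    u = np.zeros_like(a)
    v = np.zeros_like(a)
    n_run = 0
    for w in range(n_warp):
        b_cur = b if w == 0 else _warp(b, u, v)
        du, dv, trace = _hs_increment(a, b_cur, alpha, max_iter, tol)
        u = u + du
        v = v + dv
        n_run += len(trace)
    return FlowField(u=u, v=v, alpha=alpha, n_iterations_run=n_run,
                     final_update_norm=trace[-1], residual_trace=trace)


def flow_sequence(seq: DSASequence, params: HSParams = HSParams(),
                  frame_indices: np.ndarray | None = None) -> list[FlowField]:
    """Flow fields between consecutive frames of a sequence.

    `frame_indices` restricts the computation to a contiguous run of frames
    (e.g. the filling phase); defaults to all frames.  Returns len - 1 fields.
    """
    idx = np.arange(seq.n_frames) if frame_indices is None else np.asarray(frame_indices)
    if idx.size < 2:
        raise ValueError("need at least 2 frames to compute flow")
    frames = seq.frames[idx]
    if params.smooth_sigma > 0:
        frames = np.stack([ndimage.gaussian_filter(f, params.smooth_sigma)
                           for f in frames])
    fields = []
    for k in range(frames.shape[0] - 1):
        try:
            fields.append(horn_schunck(frames[k], frames[k + 1],
                                       alpha=params.alpha,
                                       max_iter=params.max_iter,
                                       tol=params.tol,
                                       n_warp=params.n_warp))
        except ValueError as exc:  # pragma: no cover - defensive context
            raise ValueError(f"optical flow failed at frame pair "
                             f"({idx[k]}, {idx[k + 1]}): {exc}") from exc
    return fields


def save_flow(flow: FlowField, path: str | Path) -> None:
    """Serialize to a compressed .npz plus a .json header alongside."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), u=flow.u, v=flow.v)
    header = {"alpha": flow.alpha,
              "n_iterations_run": flow.n_iterations_run,
              "final_update_norm": flow.final_update_norm}
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_flow(path: str | Path) -> FlowField:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    header = json.loads(path.with_suffix(".json").read_text())
    return FlowField(u=arrays["u"], v=arrays["v"], alpha=header["alpha"],
                     n_iterations_run=header["n_iterations_run"],
                     final_update_norm=header["final_update_norm"])
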