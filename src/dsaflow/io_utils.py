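"""Reading/writing sequences (multi-frame TIFF + JSON sidecar), masks and
ground-truth records."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .phantom import PhantomTruth
from .preprocess import DSASequence, Mask


def write_sequence(seq: DSASequence, directory: str | Path, stem: str,
                   extra_meta: dict | None = None) -> Path:
    """Write `<stem>.tif` plus `<stem>.json` sidecar; returns the TIFF path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif = directory / f"{stem}.tif"
    tifffile.imwrite(tif, seq.frames.astype(np.float32))
    meta = {"frame_rate": seq.frame_rate,
            "pixel_spacing": seq.pixel_spacing,
            "phase_labels": seq.phase_labels}
    if extra_meta:
        meta.update(extra_meta)
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return tif


def read_sequence(tif_path: str | Path) -> tuple[DSASequence, dict]:
    """Read a multi-frame TIFF and its JSON sidecar; returns (sequence, meta)."""
    tif_path = Path(tif_path)
    frames = np.asarray(tifffile.imread(tif_path), dtype=float)
    if frames.ndim == 2:
        raise ValueError(f"{tif_path} holds a single frame, not a sequence")
    sidecar = tif_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    seq = DSASequence(frames, meta["frame_rate"], meta["pixel_spacing"],
                      meta.get("phase_labels"))
    return seq, meta


def write_mask(mask: Mask, path: str | Path) -> None:
    """Store as 0/255 single-frame TIFF."""
    tifffile.imwrite(Path(path), (mask.data.astype(np.uint8) * 255))


def read_mask(path: str | Path, role: str) -> Mask:
    data = np.asarray(tifffile.imread(Path(path)))
    return Mask(data > 0, role)


def write_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Ground-truth generating parameters as JSON (masks are stored via
    write_mask if needed; the JSON carries the scalar truth)."""
    cfg = asdict(truth.config)
    cfg["image_shape"] = list(cfg["image_shape"])
    cfg["thrombus_center"] = list(cfg["thrombus_center"])
    Path(path).write_text(json.dumps(cfg, indent=2))


def read_truth_params(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
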