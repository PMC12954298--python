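"""End-to-end feature-extraction and reporting pipeline.

Coordinate convention (stated once, used everywhere): row-major pixel
grids, origin top-left, 0-based indices; axis angles in degrees from the
+x (column) axis toward +y (rows).

The feature CSV is the single interchange format between the imaging and
statistics halves; every row carries the configuration hash so reruns are
provenance-exact.  Per-case failures are quarantined to an errors sidecar
and the run continues; the run only fails if every case fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hemodynamics as hd
from . import kinematics as kin
from . import preprocess as pp
from . import stats as st
from . import stratify as strat
from .io_utils import read_mask, read_sequence
from .optical_flow import HSParams, flow_sequence

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

FEATURE_COLUMNS = ["case_id", "displacement_velocity_mm_per_cycle", "theta_deg",
                   "strain_rate_per_s", "v_mean_mm_s", "delta_t_s",
                   "delta_p_mmHg", "vqfr", "n_collaterals",
                   "thrombus_length_cm", "cfi", "wells_score", "d_dimer",
                   "location", "schema_version", "config_hash"]


@dataclass
class PipelineConfig:
    """Validated parameter blocks for the extraction pipeline."""

    input_dir: str = "."
    output_dir: str = "out"
    clinical_csv: str | None = None
    baseline_frames: int = 4
    denoise_sigma: float = 1.0
    threshold_quantile: float = 0.2
    hs_alpha: float = 1.0
    hs_max_iter: int = 300
    hs_tol: float = 1e-4
    hs_smooth_sigma: float = 0.0
    transit_method: str = "time_to_peak"
    kappa: float = hd.DEFAULT_KAPPA
    reference_ratio: float = hd.DEFAULT_REFERENCE_RATIO
    frames_per_cycle: int = 8
    thresholds: strat.RiskThresholds = field(default_factory=strat.RiskThresholds)
    fusion_weights: dict = field(default_factory=lambda: dict(strat.DEFAULT_WEIGHTS))
    fusion_intercept: float = strat.DEFAULT_INTERCEPT
    stratify_cutoff: float = strat.DEFAULT_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        # delegate numeric validation to the module constructors
        HSParams(self.hs_alpha, self.hs_max_iter, self.hs_tol, self.hs_smooth_sigma)
        if isinstance(self.thresholds, dict):
            self.thresholds = strat.RiskThresholds(**self.thresholds)
        if self.transit_method not in ("time_to_peak", "arrival_half_max"):
            raise ValueError(f"unknown transit_method {self.transit_method!r}")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        if self.frames_per_cycle < 2:
            raise ValueError("frames_per_cycle must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters only — filesystem paths are
        excluded so reruns in different locations stay provenance-equal."""
        d = self.to_dict()
        for key in ("input_dir", "output_dir", "clinical_csv"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_case(seq: pp.DSASequence, meta: dict, config: PipelineConfig,
                 thrombus: pp.Mask | None = None,
                 lumen: pp.Mask | None = None) -> dict:
    """Full feature extraction for one sequence.

    Masks are segmented classically when not supplied.  The vessel axis
    angle and frames-per-cycle come from the sidecar metadata when present,
    otherwise the axis is estimated from the lumen and the config default
    cycle is used.
    """
    work = pp.subtract_baseline(seq, config.baseline_frames)
    if config.denoise_sigma > 0:
        work = pp.denoise(work, config.denoise_sigma)

    if lumen is None:
        lumen = pp.segment_lumen(work)
    if thrombus is None:
        thrombus = pp.segment_thrombus(work, threshold_quantile=config.threshold_quantile,
                                       lumen=lumen)
    axis_angle = meta.get("vessel_axis_angle")
    if axis_angle is None:
        axis_angle = pp.estimate_vessel_axis(lumen)
    frames_per_cycle = int(meta.get("frames_per_cycle", config.frames_per_cycle))

    hs = HSParams(config.hs_alpha, config.hs_max_iter, config.hs_tol,
                  config.hs_smooth_sigma)
    fill_idx = pp.steady_filling_indices(work)
    flows = flow_sequence(work, hs, frame_indices=fill_idx)

    profile = kin.kinematic_profile(flows, thrombus, work.pixel_spacing,
                                    work.frame_rate, axis_angle, frames_per_cycle)

    prox, dist = _flank_rois(lumen, thrombus, axis_angle)
    tic_p = hd.time_intensity_curve(work, prox)
    tic_d = hd.time_intensity_curve(work, dist)
    delta_t = hd.transit_time(tic_p, tic_d, method=config.transit_method)
    v_mean = hd.mean_flow_velocity(flows, lumen, work.pixel_spacing, work.frame_rate)
    hemo = hd.hemodynamic_profile(v_mean, delta_t, config.kappa,
                                  config.reference_ratio)

    length_cm = hd.thrombus_length_cm(thrombus, axis_angle, work.pixel_spacing)
    labels = work.phase_labels or []
    if pp.PHASE_COLLATERAL in labels:
        n_coll = hd.count_collaterals(work, thrombus, lumen, axis_angle)
        cfi = hd.collateral_flow_index(n_coll, length_cm)
    else:
        n_coll, cfi = np.nan, np.nan

    return {"displacement_velocity_mm_per_cycle": profile.displacement_velocity,
            "theta_deg": profile.theta_deg,
            "strain_rate_per_s": profile.strain_rate,
            "v_mean_mm_s": hemo.v_mean,
            "delta_t_s": hemo.delta_t,
            "delta_p_mmHg": hemo.delta_p,
            "vqfr": hemo.vqfr,
            "n_collaterals": n_coll,
            "thrombus_length_cm": length_cm,
            "cfi": cfi}


def _flank_rois(lumen: pp.Mask, thrombus: pp.Mask, axis_angle: float,
                gap_px: int = 3, width_px: int = 6) -> tuple[pp.Mask, pp.Mask]:
    """In-lumen ROIs flanking the thrombus along the vessel axis."""
    import math
    ang = math.radians(axis_angle)
    ex, ey = math.cos(ang), math.sin(ang)
    yy, xx = np.mgrid[0:lumen.data.shape[0], 0:lumen.data.shape[1]]
    s = xx * ex + yy * ey
    sthr = s[thrombus.data]
    s0, s1 = sthr.min(), sthr.max()
    prox = lumen.data & (s >= s0 - gap_px - width_px) & (s <= s0 - gap_px)
    dist = lumen.data & (s >= s1 + gap_px) & (s <= s1 + gap_px + width_px)
    if not prox.any() or not dist.any():
        raise ValueError("cannot place flanking ROIs: thrombus touches the "
                         "field-of-view boundary")
    return pp.Mask(prox, "proximal"), pp.Mask(dist, "distal")


def run_extract(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract features for every `*.tif` case under `config.input_dir`.

    Writes `features.csv` (and `errors.csv` when cases fail) under
    `config.output_dir`; per-stage timings go to the log.  Raises only if
    every case fails.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_suffixes = ("_thrombus", "_lumen", "_proximal", "_distal", "_collateral")
    cases = sorted(p for p in in_dir.glob("*.tif")
                   if not p.stem.endswith(mask_suffixes))
    if not cases:
        raise FileNotFoundError(f"no .tif sequences under {in_dir}")
    clinical = None
    if config.clinical_csv:
        clinical = pd.read_csv(config.clinical_csv).set_index("case_id")

    rows, errors = [], []
    for tif in cases:
        case_id = tif.stem
        t0 = time.perf_counter()
        try:
            seq, meta = read_sequence(tif)
            masks = {}
            for role in ("thrombus", "lumen"):
                mpath = tif.with_name(f"{case_id}_{role}.tif")
                if mpath.exists():
                    masks[role] = read_mask(mpath, role)
            row = extract_case(seq, meta, config,
                               thrombus=masks.get("thrombus"),
                               lumen=masks.get("lumen"))
        except Exception as exc:
            logger.warning("case %s quarantined: %s", case_id, exc)
            errors.append({"case_id": case_id, "error": str(exc)})
            continue
        row["case_id"] = case_id
        if clinical is not None and case_id in clinical.index:
            for col in ("wells_score", "d_dimer", "location"):
                if col in clinical.columns:
                    row[col] = clinical.loc[case_id, col]
        row.setdefault("wells_score", np.nan)
        row.setdefault("d_dimer", np.nan)
        row.setdefault("location", "NA")
        row["schema_version"] = SCHEMA_VERSION
        row["config_hash"] = config.config_hash
        rows.append(row)
        logger.info("case %s extracted in %.2f s", case_id,
                    time.perf_counter() - t0)

    errors_df = pd.DataFrame(errors, columns=["case_id", "error"])
    if not rows:
        errors_df.to_csv(out_dir / "errors.csv", index=False)
        raise RuntimeError("all cases failed feature extraction")
    features = pd.DataFrame(rows)[FEATURE_COLUMNS]
    features.to_csv(out_dir / "features.csv", index=False)
    if not errors_df.empty:
        errors_df.to_csv(out_dir / "errors.csv", index=False)
    return features, errors_df


def run_report(features: pd.DataFrame, assessments: pd.DataFrame,
               outcomes: pd.DataFrame | None, out_dir: str | Path,
               seed: int = 0, n_boot: int = 1000) -> dict:
    """Diagnostic-performance and outcome-comparison report (JSON + Markdown).

    Joins on case_id; mismatches are listed explicitly.  The outcome section
    is marked skipped when no outcomes are supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    merged = features.merge(assessments, on="case_id", how="inner",
                            suffixes=("", "_assess"))
    unmatched = sorted(set(features["case_id"]) ^ set(assessments["case_id"]))
    report: dict = {"seed": seed, "n_cases": int(len(merged)),
                    "unmatched_case_ids": unmatched,
                    "software_version": _version()}

    if outcomes is not None:
        outcome_cols = [c for c in outcomes.columns if c != "case_id"]
        merged = merged.drop(columns=[c for c in outcome_cols if c in merged])
        merged = merged.merge(outcomes, on="case_id", how="inner")
        y = merged["pe_event"].to_numpy(dtype=int)
        scores = merged["score"].to_numpy(dtype=float)
        if len(np.unique(y)) == 2:
            auc = st.roc_auc(scores, y)
            ci = st.bootstrap_ci(lambda s, l: st.roc_auc(s, l)
                                 if len(np.unique(l)) == 2 else None,
                                 (scores, y), n_boot=n_boot, seed=seed)
            report["diagnostic"] = {"auc": auc, "auc_ci": list(ci),
                                    **st.diagnostic_metrics(
                                        merged["stratum"] == "high", y)}
        outcome_rows = {}
        high = merged["stratum"] == "high"
        for col in ("pe_event", "pts_event"):
            if col not in merged:
                continue
            t = st.TwoByTwo(int(merged.loc[high, col].sum()), int(high.sum()),
                            int(merged.loc[~high, col].sum()), int((~high).sum()))
            entry = {"events_high": t.events_a, "n_high": t.n_a,
                     "events_low": t.events_b, "n_low": t.n_b,
                     "pct_high": st.rate_percent(t.events_a, t.n_a),
                     "pct_low": st.rate_percent(t.events_b, t.n_b)}
            try:
                rr, lo, hi = st.relative_risk(t)
                entry.update({"rr": rr, "rr_ci": [lo, hi]})
            except ValueError as exc:
                entry["rr"] = str(exc)
            outcome_rows[col] = entry
        report["outcomes"] = outcome_rows
    else:
        report["outcomes"] = "skipped: no outcome table supplied"

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "report.md").write_text(_markdown_report(report))
    return report


def _version() -> str:
    from . import __version__
    return __version__


def _markdown_report(report: dict) -> str:
    lines = ["# Risk stratification report", "",
             f"- cases: {report['n_cases']}",
             f"- seed: {report['seed']}",
             f"- software: dsaflow {report['software_version']}", ""]
    if "diagnostic" in report:
        d = report["diagnostic"]
        lines += ["## Diagnostic performance", "",
                  f"- AUC: {d['auc']:.3f} "
                  f"(95% CI {d['auc_ci'][0]:.3f}-{d['auc_ci'][1]:.3f})",
                  f"- sensitivity: {d['sensitivity']:.1f}%",
                  f"- specificity: {d['specificity']:.1f}%", ""]
    if isinstance(report.get("outcomes"), dict):
        lines += ["## Outcomes by stratum", "",
                  "| outcome | high, n (%) | low, n (%) | RR (95% CI) |",
                  "|---|---|---|---|"]
        for name, e in report["outcomes"].items():
            rr = e.get("rr")
            if isinstance(rr, float):
                rr_txt = f"{rr:.2f} ({e['rr_ci'][0]:.2f}-{e['rr_ci'][1]:.2f})"
            else:
                rr_txt = str(rr)
            lines.append(f"| {name} | {e['events_high']} ({e['pct_high']:.1f}) "
                         f"| {e['events_low']} ({e['pct_low']:.1f}) | {rr_txt} |")
        lines.append("")
    else:
        lines += ["## Outcomes", "", str(report.get("outcomes")), ""]
    if report.get("unmatched_case_ids"):
        lines += ["## Join mismatches", ""]
        lines += [f"- {cid}" for cid in report["unmatched_case_ids"]]
    return "\n".join(lines) + "\n"
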