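"""Threshold flags, clinical covariates, transparent logistic score fusion
and high/low risk assignment.

Boundary semantics follow the published operating thresholds exactly:
velocity >= 2.1 mm/cycle, theta > 45 degrees, vqfr <= 0.80,
CFI > 0.3 collaterals/cm, D-dimer > 5.0 ug/mL; Wells bands 0-1 / 2-6 / >=7.

The fusion rule is a documented logistic combination of the flags — a
deterministic, auditable stand-in for a trained network; it makes no claim
of reproducing any trained model's outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

FLAG_NAMES = ("velocity_high", "theta_high", "vqfr_low", "cfi_high",
              "d_dimer_high", "wells_moderate", "wells_high")

#: default fusion weights (log-odds per flag); a repo convention, documented
#: in the README and calibratable on synthetic cohorts via fit_risk_weights.
DEFAULT_WEIGHTS: dict[str, float] = {
    "velocity_high": 1.2,
    "theta_high": 1.0,
    "vqfr_low": 1.0,
    "cfi_high": 0.6,
    "d_dimer_high": 0.8,
    "wells_moderate": 0.4,
    "wells_high": 1.0,
}
DEFAULT_INTERCEPT = -2.5
DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class ClinicalProfile:
    wells_score: float
    d_dimer: float            # ug/mL
    location: str             # {"iliac", "femoral"}

    def __post_init__(self) -> None:
        if self.wells_score < 0:
            raise ValueError("wells_score must be >= 0")
        if self.d_dimer < 0:
            raise ValueError("d_dimer must be >= 0")
        if self.location not in ("iliac", "femoral"):
            raise ValueError("location must be 'iliac' or 'femoral'")


@dataclass(frozen=True)
class RiskThresholds:
    velocity_cut: float = 2.1     # mm/cycle, flag when velocity >= cut
    theta_cut: float = 45.0       # degrees, flag when theta > cut
    vqfr_cut: float = 0.80        # flag when vqfr <= cut
    cfi_cut: float = 0.3          # collaterals/cm, flag when cfi > cut
    d_dimer_cut: float = 5.0      # ug/mL, flag when d_dimer > cut

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RiskAssessment:
    flags: dict[str, bool]
    score: float
    stratum: str              # {"high", "low"}
    cutoff: float

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1:
            raise ValueError("score must be a probability")
        expected = "high" if self.score >= self.cutoff else "low"
        if self.stratum != expected:
            raise ValueError("stratum inconsistent with score and cutoff")


def wells_band(score: float) -> str:
    """Wells pre-test probability band: 0-1 low, 2-6 moderate, >=7 high."""
    if score < 0:
        raise ValueError("Wells score must be >= 0")
    if score < 2:
        return "low"
    if score < 7:
        return "moderate"
    return "high"


def feature_flags(velocity: float, theta_deg: float, vqfr: float, cfi: float,
                  clinical: ClinicalProfile,
                  thresholds: RiskThresholds = RiskThresholds()) -> dict[str, bool]:
    """Threshold flags with the printed boundary semantics (>=, >, <=, >, >)."""
    for name, val in (("velocity", velocity), ("theta_deg", theta_deg),
                      ("vqfr", vqfr), ("cfi", cfi)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite")
    band = wells_band(clinical.wells_score)
    return {
        "velocity_high": velocity >= thresholds.velocity_cut,
        "theta_high": theta_deg > thresholds.theta_cut,
        "vqfr_low": vqfr <= thresholds.vqfr_cut,
        "cfi_high": cfi > thresholds.cfi_cut,
        "d_dimer_high": clinical.d_dimer > thresholds.d_dimer_cut,
        "wells_moderate": band == "moderate",
        "wells_high": band == "high",
    }


def risk_score(flags: dict[str, bool],
               weights: dict[str, float] | None = None,
               intercept: float = DEFAULT_INTERCEPT) -> float:
    """Logistic fusion: sigmoid(intercept + sum of weight * flag)."""
    weights = weights if weights is not None else DEFAULT_WEIGHTS
    if not all(math.isfinite(w) for w in weights.values()) or not math.isfinite(intercept):
        raise ValueError("weights and intercept must be finite")
    z = intercept + sum(weights.get(name, 0.0) * bool(flags.get(name, False))
                        for name in weights)
    return 1.0 / (1.0 + math.exp(-z))


def stratify(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """'high' iff score >= cutoff (boundary assigned to high)."""
    if not 0 <= score <= 1 or not 0 <= cutoff <= 1:
        raise ValueError("score and cutoff must lie in [0, 1]")
    return "high" if score >= cutoff else "low"


def assess(velocity: float, theta_deg: float, vqfr: float, cfi: float,
           clinical: ClinicalProfile,
           thresholds: RiskThresholds = RiskThresholds(),
           weights: dict[str, float] | None = None,
           intercept: float = DEFAULT_INTERCEPT,
           cutoff: float = DEFAULT_CUTOFF) -> RiskAssessment:
    flags = feature_flags(velocity, theta_deg, vqfr, cfi, clinical, thresholds)
    score = risk_score(flags, weights, intercept)
    return RiskAssessment(flags=flags, score=score,
                          stratum=stratify(score, cutoff), cutoff=cutoff)


def flags_frame(features: pd.DataFrame,
                thresholds: RiskThresholds = RiskThresholds()) -> pd.DataFrame:
    """Vectorized flags for a feature table (cohort CSV schema)."""
    wells = features["wells_score"].astype(float)
    out = pd.DataFrame({
        "velocity_high": features["displacement_velocity_mm_per_cycle"]
                         >= thresholds.velocity_cut,
        "theta_high": features["theta_deg"] > thresholds.theta_cut,
        "vqfr_low": features["vqfr"] <= thresholds.vqfr_cut,
        "cfi_high": features["cfi"] > thresholds.cfi_cut,
        "d_dimer_high": features["d_dimer"] > thresholds.d_dimer_cut,
        "wells_moderate": (wells >= 2) & (wells < 7),
        "wells_high": wells >= 7,
    })
    return out.astype(bool)


def assess_frame(features: pd.DataFrame,
                 thresholds: RiskThresholds = RiskThresholds(),
                 weights: dict[str, float] | None = None,
                 intercept: float = DEFAULT_INTERCEPT,
                 cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Per-case flags, fused score and stratum for a feature table."""
    weights = weights if weights is not None else DEFAULT_WEIGHTS
    flags = flags_frame(features, thresholds)
    z = np.full(len(flags), float(intercept))
    for name, w in weights.items():
        if name in flags:
            z += w * flags[name].to_numpy(dtype=float)
    score = 1.0 / (1.0 + np.exp(-z))
    out = flags.copy()
    if "case_id" in features:
        out.insert(0, "case_id", features["case_id"].to_numpy())
    out["score"] = score
    out["stratum"] = np.where(score >= cutoff, "high", "low")
    return out


def fit_risk_weights(flags: pd.DataFrame, outcomes: np.ndarray
                     ) -> tuple[dict[str, float], float, pd.DataFrame]:
    """Calibrate fusion weights by maximum-likelihood logistic regression.

    Returns (weights, intercept, fit table with coefficients and standard
    errors) so recovered log-odds can be compared against a generating
    model.
    """
    x = sm.add_constant(flags.astype(float), has_constant="add")
    model = sm.Logit(np.asarray(outcomes, dtype=float), x)
    res = model.fit(disp=False)
    params = res.params
    table = pd.DataFrame({"coef": res.params, "se": res.bse})
    weights = {k: float(v) for k, v in params.items() if k != "const"}
    return weights, float(params["const"]), table
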