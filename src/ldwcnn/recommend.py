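"""Clinical reference-range banding, severity levels, and recommendations.

Markers with published reference ranges are banded (normal / borderline /
high / very_high / low); the classifier's disease probability is combined
with a capped risk boost from the bands into a severity level, which maps
through fixed intervals to a recommendation tier:

    disease none        -> normal        "Patient is normal"
    level < 0           -> none          "No R_ec"
    0 <= level < 0.5    -> exercise      "Need normal exercise"
    0.5 <= level < 1    -> visit_doctor  "Need to visit a doctor"
    level >= 1          -> hospitalize   "Need to get hospitalized and have
                                          proper treatment"

The reference ranges ship as an editable plain-text (YAML) config; the
defaults below mirror the published liver-enzyme, renal and cardiovascular
bands.  The potassium band edges (medium 5.3-5.5, high 5.5-6, very high
above 6) are declared in the config and overridable.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

logger = logging.getLogger(__name__)

NORMAL, BORDERLINE, HIGH, VERY_HIGH, LOW = "normal", "borderline", "high", "very_high", "low"

#: Bands that contribute to the risk boost: life-threateningly elevated
#: markers and out-of-range-low readings.
RISKY_BANDS = frozenset({VERY_HIGH, LOW})

DEFAULT_REFERENCE_RANGES: dict = {
    "liver": {
        # enzyme: [normal upper bound (range top), absolute maximum]
        "ast": {"range_top": 35.0, "maximum": 40.0, "unit": "IU/L"},
        "alt": {"range_top": 45.0, "maximum": 56.0, "unit": "IU/L"},
    },
    "kidney": {
        "serum": {"male": [60.0, 120.0], "female": [50.0, 110.0], "unit": "umol/L"},
        "potassium": {"medium": [5.3, 5.5], "high_max": 6.0, "unit": "mmol/L"},
    },
    "heart": {
        "bp_low": [90.0, 60.0],    # at or below either -> low (high risk)
        "bp_high": [140.0, 90.0],  # at or above either -> high
        "cholesterol": {"normal_max": 129.0, "borderline_max": 159.0,
                        "high_max": 189.0, "unit": "mg/dL"},
    },
}


def load_reference_ranges(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_reference_ranges(ranges: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(ranges, sort_keys=False))


@dataclass(frozen=True)
class MarkerFlag:
    marker: str
    band: str
    value: float
    unit: str | None = None


@dataclass
class RiskFlags:
    flags: tuple[MarkerFlag, ...]

    def band(self, marker: str) -> str:
        for f in self.flags:
            if f.marker == marker:
                return f.band
        raise KeyError(marker)

    @property
    def n_markers(self) -> int:
        return len(self.flags)

    @property
    def n_risky(self) -> int:
        return sum(1 for f in self.flags if f.band in RISKY_BANDS)


@dataclass
class SeverityAssessment:
    disease: str          # heart | liver | kidney | none
    probability: float
    risk_boost: float
    level: float


@dataclass
class Recommendation:
    tier: str    # none | normal | exercise | visit_doctor | hospitalize
    message: str
    level: float


# ---------------------------------------------------------------------------
# Banding
# ---------------------------------------------------------------------------

def _check_non_negative(**values: float) -> None:
    for name, v in values.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def band_liver(ast: float, alt: float, ranges: Mapping | None = None) -> RiskFlags:
    """Band AST and ALT: normal within range, high up to the maximum,
    very_high above it (AST > 40, ALT > 56 by default)."""
    _check_non_negative(ast=ast, alt=alt)
    r = (ranges or DEFAULT_REFERENCE_RANGES)["liver"]
    flags = []
    for marker, value in (("ast", ast), ("alt", alt)):
        cfg = r[marker]
        if value <= cfg["range_top"]:
            band = NORMAL
        elif value <= cfg["maximum"]:
            band = HIGH
        else:
            band = VERY_HIGH
        flags.append(MarkerFlag(marker, band, value, cfg.get("unit")))
    return RiskFlags(tuple(flags))


def band_kidney(serum: float, potassium: float, sex: str,
                ranges: Mapping | None = None) -> RiskFlags:
    """Band serum creatinine (sex-specific inclusive range) and potassium."""
    _check_non_negative(serum=serum, potassium=potassium)
    sex = sex.lower()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    r = (ranges or DEFAULT_REFERENCE_RANGES)["kidney"]
    lo, hi = r["serum"][sex]
    if serum < lo:
        serum_band = LOW
    elif serum > hi:
        serum_band = HIGH
    else:
        serum_band = NORMAL
    pm_lo, pm_hi = r["potassium"]["medium"]
    if potassium < pm_lo:
        pot_band = NORMAL
    elif potassium <= pm_hi:
        pot_band = BORDERLINE  # "medium"
    elif potassium <= r["potassium"]["high_max"]:
        pot_band = HIGH
    else:
        pot_band = VERY_HIGH
    return RiskFlags((MarkerFlag("serum", serum_band, serum, r["serum"].get("unit")),
                      MarkerFlag("potassium", pot_band, potassium,
                                 r["potassium"].get("unit"))))


def band_heart(bp_sys: float, bp_dia: float, cholesterol: float,
               ranges: Mapping | None = None) -> RiskFlags:
    """Band blood pressure (low <= 90/60, high >= 140/90) and cholesterol."""
    _check_non_negative(bp_sys=bp_sys, bp_dia=bp_dia, cholesterol=cholesterol)
    r = (ranges or DEFAULT_REFERENCE_RANGES)["heart"]
    lo_s, lo_d = r["bp_low"]
    hi_s, hi_d = r["bp_high"]
    if bp_sys <= lo_s or bp_dia <= lo_d:
        bp_band = LOW
    elif bp_sys >= hi_s or bp_dia >= hi_d:
        bp_band = HIGH
    else:
        bp_band = NORMAL
    c = r["cholesterol"]
    if cholesterol <= c["normal_max"]:
        chol_band = NORMAL
    elif cholesterol <= c["borderline_max"]:
        chol_band = BORDERLINE
    elif cholesterol <= c["high_max"]:
        chol_band = HIGH
    else:
        chol_band = VERY_HIGH
    return RiskFlags((MarkerFlag("bp", bp_band, bp_sys, "mmHg"),
                      MarkerFlag("cholesterol", chol_band, cholesterol, c.get("unit"))))


# ---------------------------------------------------------------------------
# Severity level and recommendation
# ---------------------------------------------------------------------------

def severity_level(probability: float, flags: RiskFlags | None,
                   disease: str = "none") -> SeverityAssessment:
    """Combine classifier probability with a capped reference-range boost.

    risk_boost = 0.5 * (risky markers) / (evaluated markers); the level is
    probability + risk_boost, hence bounded by 1.5.  With no evaluated
    markers the boost is zero (logged).
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {probability}")
    if flags is None or flags.n_markers == 0:
        logger.info("severity_level: no evaluated markers; risk boost 0")
        boost = 0.0
    else:
        boost = 0.5 * flags.n_risky / flags.n_markers
    return SeverityAssessment(disease, probability, boost, probability + boost)


_MESSAGES = {
    "none": "No R_ec",
    "normal": "Patient is normal",
    "exercise": "Need normal exercise",
    "visit_doctor": "Need to visit a doctor",
    "hospitalize": "Need to get hospitalized and have proper treatment",
}


def recommend(level: float, disease: str) -> Recommendation:
    """Map a severity level to a recommendation tier.

    A ``disease='none'`` verdict always yields the normal tier.  Otherwise
    the level falls through half-open intervals: negative -> no
    recommendation, [0, 0.5) -> exercise, [0.5, 1) -> visit a doctor,
    >= 1 -> hospitalize.
    """
    level = float(level)
    if not math.isfinite(level):
        raise ValueError(f"level must be finite, got {level}")
    if disease not in ("heart", "liver", "kidney", "none"):
        raise ValueError(f"unknown disease {disease!r}")
    if disease == "none":
        tier = "normal"
    elif level < 0:
        tier = "none"
    elif level < 0.5:
        tier = "exercise"
    elif level < 1.0:
        tier = "visit_doctor"
    else:
        tier = "hospitalize"
    return Recommendation(tier, _MESSAGES[tier], level)


def recommendation_record(patient_id, disease: str,
                          assessment: SeverityAssessment) -> str:
    """One JSON record per patient, as emitted by the pipeline."""
    rec = recommend(assessment.level, disease)
    return json.dumps({"id": patient_id, "disease": disease,
                       "level": assessment.level, "tier": rec.tier,
                       "message": rec.message})
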