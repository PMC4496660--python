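"""Traffic-light verdicts, consumer profile bands and report rendering.

The verdict depends only on the multiset of pair relations:

* RED    — at least one Exact pair: the product contains an ingredient the
           consumer is intolerant to (or one of its synonyms);
* YELLOW — no Exact pair but at least one Plugin/Subsume pair: a related
           ingredient is present, professional advice is warranted;
* GREEN  — all pairs Dissimilar: no related ingredient found.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .cme import MatchResult, PairMatch, Relation
from .rules import Atom

__all__ = [
    "Verdict",
    "traffic_light",
    "classify_bands",
    "bmi_band",
    "bmr_band",
    "activity_band",
    "blood_pressure_band",
    "Report",
    "render_report",
    "YELLOW_ADVISORY",
]

YELLOW_ADVISORY = (
    "A possible issue was found; the consumer should seek professional "
    "medical advice before consuming this product."
)


@dataclass(frozen=True)
class Verdict:
    color: str  # RED | YELLOW | GREEN
    reasons: tuple[str, ...]


def traffic_light(result: MatchResult) -> Verdict:
    """Verdict from the pair relations alone (score magnitude is ignored)."""
    reasons = []
    worst = Relation.DISSIMILAR
    for pair in result.pairs:
        if pair.relation is Relation.DISSIMILAR:
            continue
        worst = max(worst, pair.relation)
        reasons.append(
            f"{pair.c_concept} vs {pair.p_concept}: {pair.relation} "
            f"(weight {pair.d_weight:.3f}, distance {pair.distance})"
        )
    if worst is Relation.EXACT:
        color = "RED"
    elif worst is Relation.DISSIMILAR:
        color = "GREEN"
        reasons = ["no related ingredient found"]
    else:
        color = "YELLOW"
        reasons.append(YELLOW_ADVISORY)
    return Verdict(color, tuple(reasons))


# ---------------------------------------------------------------------
# profile bands
# ---------------------------------------------------------------------
#
# Ranges are printed with touching or overlapping endpoints in the source
# tables, so one convention is required: each band is closed at its lower
# bound and open at the next band's lower bound; the last band is
# open-ended.  A value below the first lower bound is "unclassified".

_BMI_BANDS = [
    (19.0, "normal overweight"),
    (25.0, "very overweight"),
    (30.0, "class I obese"),
    (35.0, "class II obese"),
    (45.0, "class III obese"),
]
_BMR_BANDS = [
    (0.0, "sedentary"),
    (800.0, "lightly active"),
    (1400.0, "moderately active"),
    (1600.0, "very active"),
    (1900.0, "extremely active"),
]
_ACTIVITY_BANDS = [
    (1.0, "very light"),
    (3.0, "light"),
    (5.0, "activity medium"),
    (7.0, "heavy"),
    (9.0, "very heavy"),
]
_BP_VALUES = [
    "optimal blood pressure",
    "normal blood pressure",
    "high-normal blood pressure",
    "degree I hypertension",
    "degree II hypertension",
    "degree III hypertension",
]
_BP_LOW_BOUNDS = [0.0, 81.0, 86.0, 91.0, 100.0, 110.0]
_BP_HIGH_BOUNDS = [80.0, 121.0, 131.0, 140.0, 160.0, 180.0]

UNCLASSIFIED = "unclassified"


def _band(value: float, bands: Sequence[tuple[float, str]]) -> str:
    if value < bands[0][0]:
        return UNCLASSIFIED
    label = bands[0][1]
    for lower, name in bands:
        if value >= lower:
            label = name
    return label


def bmi_band(value: float) -> str:
    """Body-mass-index band, e.g. 26.0 -> "very overweight"."""
    return _band(value, _BMI_BANDS)


def bmr_band(value: float) -> str:
    """Basal-metabolic-rate band, e.g. 1500 -> "moderately active"."""
    return _band(value, _BMR_BANDS)


def activity_band(value: float) -> str:
    """Physical-activity-level band on the 1-10 scale."""
    return _band(value, _ACTIVITY_BANDS)


def blood_pressure_band(low: float, high: float) -> str:
    """Blood-pressure category from the (diastolic, systolic) pair.

    Each component maps onto its own band column; the reported category is
    the worse (higher) of the two, the usual clinical convention.
    """
    if low < 0 or high < _BP_HIGH_BOUNDS[0]:
        return UNCLASSIFIED
    i_low = max(i for i, b in enumerate(_BP_LOW_BOUNDS) if low >= b)
    i_high = max(i for i, b in enumerate(_BP_HIGH_BOUNDS) if high >= b)
    return _BP_VALUES[max(i_low, i_high)]


def classify_bands(
    bmi: Optional[float] = None,
    bmr: Optional[float] = None,
    activity_level: Optional[float] = None,
    blood_pressure: Optional[tuple[float, float]] = None,
) -> dict[str, str]:
    """Band labels for whichever profile values are present."""
    out: dict[str, str] = {}
    if bmi is not None:
        out["bmi"] = bmi_band(bmi)
    if bmr is not None:
        out["bmr"] = bmr_band(bmr)
    if activity_level is not None:
        out["activity_level"] = activity_band(activity_level)
    if blood_pressure is not None:
        out["blood_pressure"] = blood_pressure_band(*blood_pressure)
    return out


# ---------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------


@dataclass
class Report:
    """Serializable summary of one consumer/product evaluation."""

    ingredients: list[str]
    pairs: list[dict]
    m: float
    l: int
    d_j: float
    d_w: float
    score: float
    percentage: int
    color: str
    reasons: list[str]
    risks: list[str] = field(default_factory=list)
    bands: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ingredients": self.ingredients,
            "pairs": self.pairs,
            "m": self.m,
            "l": self.l,
            "d_j": self.d_j,
            "d_w": self.d_w,
            "score": self.score,
            "percentage": self.percentage,
            "color": self.color,
            "reasons": self.reasons,
            "risks": self.risks,
            "bands": self.bands,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: Mapping) -> "Report":
        return cls(**{k: data[k] for k in cls.__dataclass_fields__ if k in data})

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls.from_dict(json.loads(text))

    def render_text(self) -> str:
        lines = [
            f"verdict: {self.color}   intolerance {self.percentage}%"
            f"   score {self.score:.3f}",
            f"m={self.m:g}  l={self.l}  d_j={self.d_j:.4f}  d_w={self.d_w:.4f}",
            "ingredients: " + (", ".join(self.ingredients) or "(none)"),
            "pairs:",
        ]
        for p in self.pairs:
            lines.append(
                f"  {p['c'] or '-':<24} {p['p'] or '-':<24} "
                f"{p['relation']:<10} term={p['term']:.4f}"
            )
        if self.risks:
            lines.append("inferred risks:")
            lines.extend(f"  {r}" for r in self.risks)
        for reason in self.reasons:
            lines.append(f"note: {reason}")
        if self.bands:
            lines.append("profile bands: " + ", ".join(f"{k}={v}" for k, v in self.bands.items()))
        return "\n".join(lines)


def render_report(
    result: MatchResult,
    verdict: Verdict,
    inferred: Iterable[Atom] = (),
    bands: Optional[Mapping[str, str]] = None,
    ingredients: Optional[Sequence[str]] = None,
) -> Report:
    """Assemble the report record for one evaluation."""
    pair_rows = [
        {
            "c": str(p.c_concept) if p.c_concept else None,
            "p": str(p.p_concept) if p.p_concept else None,
            "relation": str(p.relation),
            "d_weight": p.d_weight,
            "distance": p.distance,
            "term": p.term,
        }
        for p in result.pairs
    ]
    if ingredients is None:
        ingredients = [str(p.p_concept) for p in result.pairs if p.p_concept]
    return Report(
        ingredients=list(ingredients),
        pairs=pair_rows,
        m=result.m,
        l=result.l,
        d_j=result.d_j,
        d_w=result.d_w,
        score=result.score,
        percentage=result.percentage,
        color=verdict.color,
        reasons=list(verdict.reasons),
        risks=[str(a) for a in sorted(inferred, key=str)],
        bands=dict(bands or {}),
    )
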