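"""Clinical risk scores: CHADS2, CHA2DS2-VASc, GNRI and the abdominal aortic
calcification score (AACS).

CHADS2 assigns 1 point each for age >= 75 years, hypertension, diabetes
mellitus and congestive heart failure, and 2 points for a history of stroke
or transient ischemic attack (range 0-6). CHA2DS2-VASc assigns 1 point each
for congestive heart failure, hypertension, diabetes, female sex, vascular
disease and age 65-74, and 2 points each for prior stroke and age >= 75
(range 0-9); the two age bands are mutually exclusive. A total score of
0-1 defines the low-risk group, >= 2 the high-risk group.

GNRI (Geriatric Nutritional Risk Index) = 14.89 x albumin (g/dl)
+ 41.7 x (actual/ideal body weight). Albumin must be in g/dl; laboratory
reports in g/L should be divided by 10 first (see
:func:`albumin_g_per_l_to_g_per_dl`).

The AACS grades calcified-plaque length on the anterior and posterior
abdominal-aortic walls at lumbar levels L1-L4 (eight wall segments). Each
segment scores 0 for no calcification, 1 for calcification under one third
of the wall length, 2 for one third to two thirds, 3 for more than two
thirds; the total ranges 0-24.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import InputError

__all__ = [
    "PatientRecord",
    "chads2_score",
    "cha2ds2_vasc_score",
    "risk_group",
    "gnri",
    "albumin_g_per_l_to_g_per_dl",
    "aac_segment_score",
    "aacs_total",
]

_SEXES = ("male", "female")


@dataclass(frozen=True)
class PatientRecord:
    """Inputs to the clinical scoring functions.

    ``weight_ratio`` is actual/ideal body weight (ideal weight is an input,
    not computed here). ``aac_fractions`` lists the calcified fraction of
    the eight aortic wall segments in the fixed order anterior L1-L4 then
    posterior L1-L4; each fraction must lie in [0, 1].
    """

    age: float
    sex: str
    chf: bool = False
    hypertension: bool = False
    diabetes: bool = False
    stroke_or_tia: bool = False
    vascular_disease: bool = False
    albumin_g_dl: float | None = None
    weight_ratio: float | None = None
    aac_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise InputError(f"age must be nonnegative, got {self.age}")
        if self.sex not in _SEXES:
            raise InputError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.aac_fractions is not None:
            fr = tuple(float(f) for f in self.aac_fractions)
            if len(fr) != 8:
                raise InputError(f"aac_fractions needs exactly 8 entries, got {len(fr)}")
            for f in fr:
                if not 0.0 <= f <= 1.0:
                    raise InputError(f"aac fraction {f} outside [0, 1]")
            object.__setattr__(self, "aac_fractions", fr)


def chads2_score(p: PatientRecord) -> int:
    """CHADS2 stroke-risk score, range 0-6."""
    score = 0
    score += 1 if p.age >= 75 else 0
    score += 1 if p.hypertension else 0
    score += 1 if p.diabetes else 0
    score += 1 if p.chf else 0
    score += 2 if p.stroke_or_tia else 0
    return score


def cha2ds2_vasc_score(p: PatientRecord) -> int:
    """CHA2DS2-VASc stroke-risk score, range 0-9."""
    score = 0
    score += 1 if p.chf else 0
    score += 1 if p.hypertension else 0
    score += 1 if p.diabetes else 0
    score += 1 if p.sex == "female" else 0
    score += 1 if p.vascular_disease else 0
    if p.age >= 75:
        score += 2
    elif p.age >= 65:
        score += 1
    score += 2 if p.stroke_or_tia else 0
    return score


def risk_group(score: int) -> str:
    """Dichotomize a stroke score: 0-1 -> ``"low"``, >= 2 -> ``"high"``."""
    if score < 0:
        raise InputError(f"score must be nonnegative, got {score}")
    return "low" if score <= 1 else "high"


def albumin_g_per_l_to_g_per_dl(albumin_g_l: float) -> float:
    """Convert serum albumin from g/L (common lab units) to the g/dl GNRI expects."""
    return albumin_g_l / 10.0


def gnri(albumin_g_dl: float, weight_ratio: float) -> float:
    """Geriatric Nutritional Risk Index: 14.89 x albumin(g/dl) + 41.7 x weight ratio.

    Warns if albumin exceeds 10 g/dl — physiologically implausible and
    usually a sign the value is still in g/L.
    """
    if albumin_g_dl < 0 or weight_ratio < 0:
        raise InputError("albumin and weight ratio must be nonnegative")
    if albumin_g_dl > 10.0:
        warnings.warn(
            f"albumin {albumin_g_dl} g/dl is implausibly high; was it passed in g/L?",
            stacklevel=2,
        )
    return 14.89 * albumin_g_dl + 41.7 * weight_ratio


def aac_segment_score(fraction: float) -> int:
    """Band one wall segment's calcified-length fraction to 0-3 points.

    Boundary fractions of exactly 1/3 and 2/3 fall in the middle band
    (score 2): the band wording (under one third / one third to two
    thirds / over two thirds) leaves the boundaries open, and the closed
    middle interval is the documented choice.
    """
    if not 0.0 <= fraction <= 1.0:
        raise InputError(f"calcified fraction {fraction} outside [0, 1]")
    if fraction == 0.0:
        return 0
    if fraction < 1.0 / 3.0:
        return 1
    if fraction <= 2.0 / 3.0:
        return 2
    return 3


def aacs_total(p: PatientRecord) -> int:
    """Total abdominal aortic calcification score over 8 wall segments, range 0-24."""
    if p.aac_fractions is None:
        raise InputError("patient record has no aac_fractions")
    return sum(aac_segment_score(f) for f in p.aac_fractions)
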