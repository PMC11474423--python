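"""Clinical severity-score calculators: modified GCS, AVPU, MEWS, qSOFA, UVA.

Three bedside scores are implemented exactly as used for febrile adults in
low-resource settings:

* **MEWS** (Modified Early Warning Score): points from temperature, heart
  rate, respiratory rate, systolic blood pressure and the AVPU consciousness
  level.
* **qSOFA** (quick Sequential Organ Failure Assessment): one point each for
  respiratory rate >= 22 /min, systolic BP <= 100 mmHg and GCS < 15.
* **UVA** (Universal Vital Assessment): vitals, oxygen saturation, reduced
  consciousness and HIV serostatus, developed for sub-Saharan African
  inpatient cohorts.

Consciousness is assessed with a *modified* Glasgow Coma Scale whose motor
component is restricted to three categories (spontaneous/verbal movement -> 6
points, movement to pain only -> 3, none -> 1), reflecting simplified limb
movement data collection; the modified GCS is converted to AVPU for the MEWS
calculation.

All band tables and weights are data-driven (:class:`ScoreBandTable`) and
serialise to/from JSON, so the default instruments can be pinned bit-exactly
and alternative published parameterisations expressed.  Non-integer inputs
are rounded half-up to each measurement's resolution before banding.

Note on ranges: the published instrument descriptions state MEWS 0-11 and
UVA 0-12, but the component bands as tabulated sum to maxima of 14 and 13
respectively; this package scores the components literally, so MEWS is in
[0, 14] and UVA in [0, 13] under the default tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence


class ValidationError(ValueError):
    """An input field is outside its physiologically valid range."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"{fld}: {message}")


def _round_half_up(x: float, resolution: float) -> float:
    """Round to the nearest multiple of ``resolution``, ties away from zero-ward."""
    scaled = x / resolution
    return math.floor(scaled + 0.5) * resolution


class MotorCategory(str, Enum):
    """Motor response categories of the modified GCS."""

    SPONTANEOUS_OR_VERBAL = "spontaneous_or_verbal"
    PAIN_ONLY = "pain_only"
    NONE = "none"


#: Modified-GCS motor points per category.
MOTOR_POINTS: Mapping[MotorCategory, int] = {
    MotorCategory.SPONTANEOUS_OR_VERBAL: 6,
    MotorCategory.PAIN_ONLY: 3,
    MotorCategory.NONE: 1,
}


class AVPULevel(str, Enum):
    """Alert / responds to Voice / responds to Pain / Unresponsive."""

    A = "A"
    V = "V"
    P = "P"
    U = "U"


class HIVStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


# (name, resolution, valid lo, valid hi)
_VITAL_SPECS = (
    ("temperature", 0.1, 25.0, 45.0),
    ("heart_rate", 1, 0, 300),
    ("resp_rate", 1, 0, 90),
    ("sbp", 1, 0, 300),
    ("spo2", 1, 0, 100),
)


@dataclass(frozen=True)
class VitalSigns:
    """One participant's physiological measurements at enrolment.

    Values are rounded half-up to the measurement's resolution on
    construction (0.1 degC for temperature, integers otherwise) and then
    range-checked.
    """

    temperature: float  # degrees Celsius
    heart_rate: int  # beats/min
    resp_rate: int  # breaths/min
    sbp: int  # systolic blood pressure, mmHg
    spo2: int  # oxygen saturation, %

    def __post_init__(self):
        for name, res, lo, hi in _VITAL_SPECS:
            raw = getattr(self, name)
            try:
                val = _round_half_up(float(raw), res)
            except (TypeError, ValueError):
                raise ValidationError(name, f"not a number: {raw!r}")
            if res == 1:
                val = int(val)
            else:
                val = round(val, 1)
            if not (lo <= val <= hi):
                raise ValidationError(name, f"{val} outside [{lo}, {hi}]")
            object.__setattr__(self, name, val)


@dataclass(frozen=True)
class ConsciousnessAssessment:
    """Eye and verbal GCS components plus the simplified motor category."""

    eye_response: int  # 1-4
    verbal_response: int  # 1-5
    motor_category: MotorCategory

    def __post_init__(self):
        if self.eye_response not in (1, 2, 3, 4):
            raise ValidationError("eye_response", f"{self.eye_response} not in 1-4")
        if self.verbal_response not in (1, 2, 3, 4, 5):
            raise ValidationError(
                "verbal_response", f"{self.verbal_response} not in 1-5"
            )
        object.__setattr__(
            self, "motor_category", MotorCategory(self.motor_category)
        )


def modified_gcs(c: ConsciousnessAssessment) -> int:
    """Modified Glasgow Coma Scale: eye + verbal + {6, 3, 1} motor points.

    Range 3-15; sums unreachable with the restricted motor component simply
    never occur.
    """
    return c.eye_response + c.verbal_response + MOTOR_POINTS[c.motor_category]


def avpu_from_gcs(gcs: int) -> AVPULevel:
    """Convert a (modified) GCS total to the AVPU scale.

    Mapping: 15 -> A, 9-14 -> V, 4-8 -> P, 3 -> U — the standard teaching
    correspondence (A ~ 15, V ~ 12, P ~ 8, U ~ 3).
    """
    if not isinstance(gcs, (int,)) or not 3 <= gcs <= 15:
        raise ValidationError("gcs", f"{gcs} not in 3-15")
    if gcs == 15:
        return AVPULevel.A
    if gcs >= 9:
        return AVPULevel.V
    if gcs >= 4:
        return AVPULevel.P
    return AVPULevel.U


def gcs_to_avpu(c: ConsciousnessAssessment) -> AVPULevel:
    """AVPU level derived from a consciousness assessment via the modified GCS."""
    return avpu_from_gcs(modified_gcs(c))


# ---------------------------------------------------------------------------
# Data-driven band tables


@dataclass(frozen=True)
class Band:
    """Half-bounded interval with explicit open/closed flags, and its points.

    ``lo``/``hi`` of ``None`` mean unbounded on that side.
    """

    points: int
    lo: float | None = None
    hi: float | None = None
    lo_closed: bool = True
    hi_closed: bool = True

    def contains(self, x: float) -> bool:
        if self.lo is not None:
            if x < self.lo or (x == self.lo and not self.lo_closed):
                return False
        if self.hi is not None:
            if x > self.hi or (x == self.hi and not self.hi_closed):
                return False
        return True


@dataclass(frozen=True)
class BandedComponent:
    """One measurement's ordered bands; bands must tile the valid range."""

    vital: str  # attribute name on VitalSigns, or "gcs"
    resolution: float
    valid_lo: float
    valid_hi: float
    bands: tuple[Band, ...]

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        # disjoint cover at the measurement's resolution grid
        n = int(round((self.valid_hi - self.valid_lo) / self.resolution))
        for k in range(n + 1):
            x = round(self.valid_lo + k * self.resolution, 10)
            hits = [b for b in self.bands if b.contains(x)]
            if len(hits) != 1:
                raise ValueError(
                    f"{self.vital}: value {x} covered by {len(hits)} bands"
                )

    def points_for(self, x: float) -> int:
        x = _round_half_up(float(x), self.resolution)
        if not (self.valid_lo <= x <= self.valid_hi):
            raise ValidationError(self.vital, f"{x} outside "
                                  f"[{self.valid_lo}, {self.valid_hi}]")
        for b in self.bands:
            if b.contains(x):
                return b.points
        raise AssertionError("unreachable: bands tile the valid range")


@dataclass(frozen=True)
class CategoricalComponent:
    """A component scored from a discrete level (AVPU, HIV status)."""

    vital: str
    points: Mapping[str, int]

    def points_for(self, level: str) -> int:
        key = getattr(level, "value", level)
        if key not in self.points:
            raise ValidationError(self.vital, f"unknown level {level!r}")
        return self.points[key]


@dataclass(frozen=True)
class ScoreBandTable:
    """A full score definition: named, component-wise band tables + weights."""

    name: str
    components: tuple[BandedComponent | CategoricalComponent, ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def max_points(self) -> int:
        total = 0
        for comp in self.components:
            if isinstance(comp, BandedComponent):
                total += max(b.points for b in comp.bands)
            else:
                total += max(comp.points.values())
        return total

    def to_json(self) -> str:
        def enc(comp):
            if isinstance(comp, BandedComponent):
                return {
                    "kind": "banded",
                    "vital": comp.vital,
                    "resolution": comp.resolution,
                    "valid_lo": comp.valid_lo,
                    "valid_hi": comp.valid_hi,
                    "bands": [
                        {
                            "points": b.points,
                            "lo": b.lo,
                            "hi": b.hi,
                            "lo_closed": b.lo_closed,
                            "hi_closed": b.hi_closed,
                        }
                        for b in comp.bands
                    ],
                }
            return {"kind": "categorical", "vital": comp.vital,
                    "points": dict(comp.points)}

        return json.dumps(
            {"name": self.name, "components": [enc(c) for c in self.components]},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreBandTable":
        obj = json.loads(text)
        comps = []
        for c in obj["components"]:
            if c["kind"] == "banded":
                comps.append(
                    BandedComponent(
                        vital=c["vital"],
                        resolution=c["resolution"],
                        valid_lo=c["valid_lo"],
                        valid_hi=c["valid_hi"],
                        bands=tuple(Band(**b) for b in c["bands"]),
                    )
                )
            else:
                comps.append(CategoricalComponent(c["vital"], c["points"]))
        return cls(name=obj["name"], components=tuple(comps))


def _mews_table() -> ScoreBandTable:
    return ScoreBandTable(
        name="MEWS",
        components=(
            BandedComponent(
                "temperature", 0.1, 25.0, 45.0,
                (
                    Band(2, hi=35.0, hi_closed=False),
                    Band(0, lo=35.0, hi=38.5, hi_closed=False),
                    Band(2, lo=38.5),
                ),
            ),
            BandedComponent(
                "heart_rate", 1, 0, 300,
                (
                    Band(2, hi=40),
                    Band(1, lo=41, hi=50),
                    Band(0, lo=51, hi=100),
                    Band(1, lo=101, hi=110),
                    Band(2, lo=111, hi=129),
                    Band(3, lo=130),
                ),
            ),
            BandedComponent(
                "resp_rate", 1, 0, 90,
                (
                    Band(2, hi=8),
                    Band(0, lo=9, hi=14),
                    Band(1, lo=15, hi=20),
                    Band(2, lo=21, hi=29),
                    Band(3, lo=30),
                ),
            ),
            BandedComponent(
                "sbp", 1, 0, 300,
                (
                    Band(3, hi=70),
                    Band(2, lo=71, hi=80),
                    Band(1, lo=81, hi=100),
                    Band(0, lo=101, hi=199),
                    Band(2, lo=200),
                ),
            ),
            CategoricalComponent("avpu", {"A": 0, "V": 1, "P": 2, "U": 3}),
        ),
    )


def _uva_table() -> ScoreBandTable:
    return ScoreBandTable(
        name="UVA",
        components=(
            BandedComponent(
                "temperature", 0.1, 25.0, 45.0,
                (Band(2, hi=36.0, hi_closed=False), Band(0, lo=36.0)),
            ),
            BandedComponent(
                "heart_rate", 1, 0, 300,
                (Band(0, hi=120, hi_closed=False), Band(1, lo=120)),
            ),
            BandedComponent(
                "resp_rate", 1, 0, 90,
                (Band(0, hi=30, hi_closed=False), Band(1, lo=30)),
            ),
            BandedComponent(
                "sbp", 1, 0, 300,
                (Band(1, hi=90, hi_closed=False), Band(0, lo=90)),
            ),
            BandedComponent(
                "spo2", 1, 0, 100,
                (Band(2, hi=92, hi_closed=False), Band(0, lo=92)),
            ),
            BandedComponent(
                "gcs", 1, 3, 15,
                (Band(4, hi=15, hi_closed=False), Band(0, lo=15)),
            ),
            CategoricalComponent(
                "hiv", {"positive": 2, "negative": 0, "unknown": 0}
            ),
        ),
    )


#: Default MEWS band table (component maxima sum to 14).
MEWS_TABLE: ScoreBandTable = _mews_table()
#: Default UVA band table (component maxima sum to 13).
UVA_TABLE: ScoreBandTable = _uva_table()


def score_mews(
    v: VitalSigns, avpu: AVPULevel, table: ScoreBandTable | None = None
) -> int:
    """MEWS total from vital signs and the AVPU consciousness level."""
    table = MEWS_TABLE if table is None else table
    total = 0
    for comp in table.components:
        if comp.vital == "avpu":
            total += comp.points_for(AVPULevel(avpu))
        else:
            total += comp.points_for(getattr(v, comp.vital))
    return total


def score_qsofa(v: VitalSigns, gcs: int) -> int:
    """qSOFA: respiratory rate >= 22, systolic BP <= 100, GCS < 15 — one point each."""
    if not 3 <= gcs <= 15:
        raise ValidationError("gcs", f"{gcs} not in 3-15")
    return int(v.resp_rate >= 22) + int(v.sbp <= 100) + int(gcs < 15)


def score_uva(
    v: VitalSigns,
    gcs: int,
    hiv: HIVStatus,
    table: ScoreBandTable | None = None,
) -> int:
    """UVA total from vital signs, modified GCS and HIV serostatus.

    HIV-unknown scores 0 points, identically to HIV-negative.
    """
    if not 3 <= gcs <= 15:
        raise ValidationError("gcs", f"{gcs} not in 3-15")
    table = UVA_TABLE if table is None else table
    total = 0
    for comp in table.components:
        if comp.vital == "hiv":
            total += comp.points_for(HIVStatus(hiv))
        elif comp.vital == "gcs":
            total += comp.points_for(gcs)
        else:
            total += comp.points_for(getattr(v, comp.vital))
    return total


def score_plus_hiv(base_score: int, hiv: HIVStatus, hiv_points: int = 2) -> int:
    """Exploratory score variant: add ``hiv_points`` when HIV-positive.

    The weight defaults to 2 (the UVA instrument's HIV weight) and is
    exposed as a parameter.  Unknown status is treated as non-positive.
    """
    if base_score < 0:
        raise ValidationError("base_score", f"{base_score} is negative")
    if hiv_points < 0:
        raise ValidationError("hiv_points", f"{hiv_points} is negative")
    return base_score + (hiv_points if HIVStatus(hiv) is HIVStatus.POSITIVE else 0)
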