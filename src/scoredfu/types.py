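"""Core domain types: label codes, areas, probabilities, weights, score breakdown.

Label-map code semantics (single channel, uint8):

====  =================  ==========================================
code  subcategory        meaning
====  =================  ==========================================
0     background/normal  healthy skin or non-foot background
1     Ulcer1             superficial ulcer
2     Ulcer2             deep ulcer
3     Infection1         soft-tissue infection
4     Infection2         deep abscess / osteomyelitis
5     Gangrene1          localized gangrene
6     Gangrene2          extensive (whole-foot) gangrene
====  =================  ==========================================

Each lesion family i (ulcer, infection, gangrene) has two depth levels;
``S_i = S_i1 + S_i2`` is the family's total pixel area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

from scoredfu.errors import ValidationError

PROB_TOL = 1e-6


class Subcategory(IntEnum):
    """Six lesion subcategories; integer values are the label-map codes."""

    ULCER1 = 1
    ULCER2 = 2
    INFECTION1 = 3
    INFECTION2 = 4
    GANGRENE1 = 5
    GANGRENE2 = 6

    @property
    def family(self) -> "Severity":
        return _FAMILY[self]

    @property
    def level(self) -> int:
        """Depth level, 1 (superficial/localized) or 2 (deep/extensive)."""
        return 1 if self in (Subcategory.ULCER1, Subcategory.INFECTION1, Subcategory.GANGRENE1) else 2


class Severity(Enum):
    """Image-level severity classes, ordered by clinical escalation."""

    NORMAL = "normal"
    INFECTION = "infection"
    ULCER = "ulcer"
    GANGRENE = "gangrene"

    @classmethod
    def from_name(cls, name: str) -> "Severity":
        name = name.strip().lower()
        if name == "necrosis":  # accepted alias for the most severe class
            return cls.GANGRENE
        return cls(name)

    @property
    def rank(self) -> int:
        return _SEVERITY_RANK[self]


_SEVERITY_RANK = {
    Severity.NORMAL: 0,
    Severity.INFECTION: 1,
    Severity.ULCER: 2,
    Severity.GANGRENE: 3,
}

_FAMILY = {
    Subcategory.ULCER1: Severity.ULCER,
    Subcategory.ULCER2: Severity.ULCER,
    Subcategory.INFECTION1: Severity.INFECTION,
    Subcategory.INFECTION2: Severity.INFECTION,
    Subcategory.GANGRENE1: Severity.GANGRENE,
    Subcategory.GANGRENE2: Severity.GANGRENE,
}

#: Canonical ordering of the four classes in probability vectors and heads.
SEVERITY_ORDER = (Severity.NORMAL, Severity.INFECTION, Severity.ULCER, Severity.GANGRENE)

N_CODES = 7  # 0..6


@dataclass(frozen=True)
class LesionAreas:
    """Pixel areas of the six lesion subcategories (S_i1, S_i2 per family)."""

    ulcer1: int = 0
    ulcer2: int = 0
    infection1: int = 0
    infection2: int = 0
    gangrene1: int = 0
    gangrene2: int = 0

    def __post_init__(self):
        for name in ("ulcer1", "ulcer2", "infection1", "infection2", "gangrene1", "gangrene2"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"area {name} must be >= 0, got {v}")

    @property
    def ulcer(self) -> int:
        return self.ulcer1 + self.ulcer2

    @property
    def infection(self) -> int:
        return self.infection1 + self.infection2

    @property
    def gangrene(self) -> int:
        return self.gangrene1 + self.gangrene2

    @property
    def total(self) -> int:
        return self.ulcer + self.infection + self.gangrene

    def as_dict(self) -> dict:
        return {
            "ulcer1": int(self.ulcer1),
            "ulcer2": int(self.ulcer2),
            "infection1": int(self.infection1),
            "infection2": int(self.infection2),
            "gangrene1": int(self.gangrene1),
            "gangrene2": int(self.gangrene2),
        }

    def by_code(self, code: int) -> int:
        """Area for a label-map code 1..6."""
        return (
            self.ulcer1,
            self.ulcer2,
            self.infection1,
            self.infection2,
            self.gangrene1,
            self.gangrene2,
        )[code - 1]


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax output of the stratifier over the four severity classes."""

    normal: float
    infection: float
    ulcer: float
    gangrene: float

    def __post_init__(self):
        vals = (self.normal, self.infection, self.ulcer, self.gangrene)
        for v in vals:
            if not (-PROB_TOL <= v <= 1 + PROB_TOL):
                raise ValidationError(f"probability {v} outside [0, 1]")
        if abs(sum(vals) - 1.0) > PROB_TOL:
            raise ValidationError(f"probabilities sum to {sum(vals)}, expected 1")

    @classmethod
    def from_vector(cls, p) -> "ClassProbabilities":
        p = np.asarray(p, dtype=float)
        if p.shape != (4,):
            raise ValidationError(f"expected a 4-vector, got shape {p.shape}")
        return cls(*(float(x) for x in p))

    @classmethod
    def from_dict(cls, d: dict) -> "ClassProbabilities":
        d = {k.strip().lower(): v for k, v in d.items()}
        if "necrosis" in d and "gangrene" not in d:
            d["gangrene"] = d.pop("necrosis")
        return cls(d["normal"], d["infection"], d["ulcer"], d["gangrene"])

    def as_vector(self) -> np.ndarray:
        return np.array([self.normal, self.infection, self.ulcer, self.gangrene])

    @property
    def argmax(self) -> Severity:
        return SEVERITY_ORDER[int(np.argmax(self.as_vector()))]

    def for_severity(self, s: Severity) -> float:
        return {
            Severity.NORMAL: self.normal,
            Severity.INFECTION: self.infection,
            Severity.ULCER: self.ulcer,
            Severity.GANGRENE: self.gangrene,
        }[s]


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the scoring formula.

    ``w_<family>`` are the per-family weights W_i, ``w_<family>1/2`` the
    per-level weights W_i1/W_i2, ``scale`` the range constant C and
    ``epsilon`` the additive adjustment.

    The shipped defaults (gangrene weighted 1.5x, deep level weighted 2x,
    C = 100 for a nominal 0-100 scale, epsilon = 0) respect the clinical
    severity ordering but are NOT calibrated against any published weight
    set; treat them as a starting point.
    """

    w_ulcer: float = 1.0
    w_infection: float = 1.0
    w_gangrene: float = 1.5
    w_ulcer1: float = 1.0
    w_ulcer2: float = 2.0
    w_infection1: float = 1.0
    w_infection2: float = 2.0
    w_gangrene1: float = 1.0
    w_gangrene2: float = 2.0
    scale: float = 100.0
    epsilon: float = 0.0

    def __post_init__(self):
        for name in (
            "w_ulcer", "w_infection", "w_gangrene",
            "w_ulcer1", "w_ulcer2", "w_infection1", "w_infection2",
            "w_gangrene1", "w_gangrene2",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"weight {name} must be >= 0")
        if self.scale <= 0:
            raise ValidationError("scale constant C must be > 0")

    def family(self, s: Severity) -> tuple[float, float, float]:
        """(W_i, W_i1, W_i2) for a lesion family."""
        if s == Severity.ULCER:
            return self.w_ulcer, self.w_ulcer1, self.w_ulcer2
        if s == Severity.INFECTION:
            return self.w_infection, self.w_infection1, self.w_infection2
        if s == Severity.GANGRENE:
            return self.w_gangrene, self.w_gangrene1, self.w_gangrene2
        raise ValidationError(f"no weights for severity {s}")

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreWeights":
        known = set(cls.__dataclass_fields__)
        extra = set(d) - known
        if extra:
            raise ValidationError(f"unknown weight fields: {sorted(extra)}")
        return cls(**d)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Feature ratios a_i, feature scores X_i, and the total score V."""

    a_ulcer: float
    a_infection: float
    a_gangrene: float
    x_ulcer: float
    x_infection: float
    x_gangrene: float
    v: float
    no_lesion: bool = False

    def as_dict(self) -> dict:
        return {
            "a_ulcer": self.a_ulcer,
            "a_infection": self.a_infection,
            "a_gangrene": self.a_gangrene,
            "x_ulcer": self.x_ulcer,
            "x_infection": self.x_infection,
            "x_gangrene": self.x_gangrene,
            "v": self.v,
            "no_lesion": self.no_lesion,
        }


def validate_labelmap(labelmap: np.ndarray) -> np.ndarray:
    """Check a label map carries only codes 0..6; return it as uint8."""
    lm = np.asarray(labelmap)
    if lm.ndim != 2:
        raise ValidationError(f"label map must be 2-D, got shape {lm.shape}")
    if lm.size and (lm.min() < 0 or lm.max() >= N_CODES):
        raise ValidationError(
            f"label codes must be in 0..{N_CODES - 1}, got range "
            f"[{lm.min()}, {lm.max()}]"
        )
    return lm.astype(np.uint8, copy=False)
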