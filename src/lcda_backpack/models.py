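"""The LCDA backpacking equation family and resting metabolic rate.

The model predicts mass-specific metabolic rate (W per kg of *body* mass,
carried load excluded from the denominator) during standing and walking
with backpack loads:

    M  =  (M_rest + a + eta * (b * S**p + d * S**4) + M_grade) * (1 + x * L**y)

where ``S`` is walking speed (m/s), ``L`` is backpack mass as a fraction of
body mass, ``G`` is treadmill grade as decimal rise/run, ``eta`` is a
terrain coefficient (1.0 for treadmill or pavement), and ``M_rest`` is the
resting metabolic rate estimated from lean body mass.  With ``eta = 1`` and
``G = 0`` the expression reduces exactly to the level-walking backpacking
equation; the graded-walking cost ``M_grade`` and terrain scaling are
modular extensions.

All operations accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

__all__ = [
    "Participant",
    "Condition",
    "ModelCoefficients",
    "LCDA_BACKPACKING_2022",
    "TERRAIN_COEFFICIENTS",
    "KCAL_PER_DAY_TO_WATT",
    "resting_metabolic_rate",
    "level_walking_terms",
    "load_multiplier",
    "grade_cost",
    "predict_metabolic_rate",
    "predict_for_condition",
    "to_absolute_watts",
    "GradeOutOfWindowWarning",
    "ExtrapolationWarning",
]

# 1 kcal = 4184 J; 86400 s per day
KCAL_PER_DAY_TO_WATT = 4184.0 / 86400.0

#: Multiplicative terrain factors for the speed-dependent walking cost.
#: Transcribed from the classic dismounted-movement terrain-factor literature
#: (treadmill walking defines 1.0).  Values are transcriptions, not fits
#: performed by this package.
TERRAIN_COEFFICIENTS: dict[str, float] = {
    "treadmill": 1.0,
    "blacktop": 1.0,
    "dirt_road": 1.1,
    "light_brush": 1.2,
    "heavy_brush": 1.5,
    "swampy_bog": 1.8,
    "loose_sand": 2.1,
}


class GradeOutOfWindowWarning(UserWarning):
    """Grade outside the window the graded-walking term was developed for."""


class ExtrapolationWarning(UserWarning):
    """Speed or load outside the fitted domain of the model."""


@dataclass(frozen=True)
class Participant:
    """Anthropometrics for one study participant.

    ``lean_mass`` drives the resting metabolic rate; ``body_mass`` is the
    denominator of every mass-specific rate.
    """

    id: str
    sex: str  # "female" | "male"
    age: float  # yr
    height: float  # m
    body_mass: float  # kg
    lean_mass: float  # kg
    body_fat_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not 0 < self.lean_mass <= self.body_mass * (1 + 1e-9):
            raise ValueError("lean_mass must be in (0, body_mass]")
        if self.body_fat_fraction is not None:
            if not 0 <= self.body_fat_fraction < 1:
                raise ValueError("body_fat_fraction must be in [0, 1)")
            implied = self.body_mass * (1.0 - self.body_fat_fraction)
            if abs(implied - self.lean_mass) > 0.05 * self.body_mass:
                raise ValueError(
                    "lean_mass inconsistent with body_mass * (1 - body_fat_fraction)"
                )

    @property
    def resting_rate(self) -> float:
        """Resting metabolic rate in W/kg body mass."""
        return float(resting_metabolic_rate(self.lean_mass, self.body_mass))


@dataclass(frozen=True)
class Condition:
    """One walking (or standing) condition: the model's independent variables."""

    speed: float  # m/s
    load_fraction: float = 0.0  # backpack mass / body mass
    grade: float = 0.0  # decimal rise/run
    terrain_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.load_fraction < 0:
            raise ValueError("load_fraction must be >= 0")
        if self.terrain_coefficient <= 0:
            raise ValueError("terrain_coefficient must be > 0")


@dataclass(frozen=True)
class ModelCoefficients:
    """The six parameters of the backpacking equation.

    ``p`` is the exponent applied to speed in the fractional term (the model
    is sometimes written with its reciprocal ``c = 1/p``; only ``p`` is
    stored).  ``x`` and ``y`` parameterize the load multiplier
    ``1 + x * L**y``.
    """

    a: float  # W/kg, constant term
    b: float  # W/kg, fractional-speed coefficient
    p: float  # speed exponent (in (0, 1])
    d: float  # W/kg, quartic-speed coefficient
    x: float  # load multiplier scale
    y: float  # load exponent
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("speed exponent p must be in (0, 1]")

    @property
    def c(self) -> float:
        """Reciprocal speed exponent, for display alongside the 1/c notation."""
        return 1.0 / self.p

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.p, self.d, self.x, self.y])

    @classmethod
    def from_array(cls, theta: np.ndarray, name: str = "", provenance: str = "") -> "ModelCoefficients":
        a, b, p, d, x, y = (float(v) for v in theta)
        return cls(a=a, b=b, p=p, d=d, x=x, y=y, name=name, provenance=provenance)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelCoefficients":
        with open(path) as fh:
            return cls(**json.load(fh))


#: Published coefficient set for heavy backpacking (loads up to 66% body
#: mass, speeds up to ~2 m/s).
LCDA_BACKPACKING_2022 = ModelCoefficients(
    a=0.19,
    b=1.78,
    p=0.58,
    d=0.27,
    x=1.96,
    y=1.36,
    name="lcda_backpacking_2022",
    provenance="published LCDA backpacking equation coefficient set",
)

_FITTED_SPEED_MAX = 2.0  # m/s; above this the gait transition is not modelled
_FITTED_LOAD_MAX = 1.0  # fraction of body mass


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def resting_metabolic_rate(lean_mass, body_mass):
    """Resting metabolic rate (W/kg body mass) from lean body mass.

    Uses the Cunningham estimate RMR[kcal/day] = 500 + 22 * LBM[kg]
    (transcribed from its original source), converted with 1 kcal = 4184 J
    over 86400 s and divided by body mass.
    """
    lean = np.asarray(lean_mass, dtype=float)
    bm = np.asarray(body_mass, dtype=float)
    scalar = lean.ndim == 0 and bm.ndim == 0
    if np.any(lean <= 0) or np.any(bm <= 0):
        raise ValueError("masses must be positive")
    if np.any(lean > bm * (1 + 1e-9)):
        raise ValueError("lean_mass cannot exceed body_mass")
    rmr_w = (500.0 + 22.0 * lean) * KCAL_PER_DAY_TO_WATT
    return _maybe_scalar(rmr_w / bm, scalar)


def _speed_terms(speed: np.ndarray, coeffs: ModelCoefficients) -> np.ndarray:
    # single expression so level and composed forms agree bit-for-bit
    return coeffs.b * speed**coeffs.p + coeffs.d * speed**4


def level_walking_terms(speed, coeffs: ModelCoefficients = LCDA_BACKPACKING_2022):
    """Speed-dependent walking cost ``a + b*S**p + d*S**4`` (W/kg), excluding rest."""
    s = np.asarray(speed, dtype=float)
    scalar = s.ndim == 0
    if np.any(s < 0):
        raise ValueError("speed must be >= 0")
    if np.any(s > _FITTED_SPEED_MAX):
        warnings.warn(
            f"speed above {_FITTED_SPEED_MAX} m/s is outside the fitted walking domain",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return _maybe_scalar(coeffs.a + _speed_terms(s, coeffs), scalar)


def load_multiplier(load_fraction, coeffs: ModelCoefficients = LCDA_BACKPACKING_2022):
    """Multiplicative cost of backpack load: ``1 + x * L**y`` (dimensionless)."""
    load = np.asarray(load_fraction, dtype=float)
    scalar = load.ndim == 0
    if np.any(load < 0):
        raise ValueError("load_fraction must be >= 0")
    if np.any(load > _FITTED_LOAD_MAX):
        warnings.warn(
            "loads above 100% body mass are outside the fitted domain",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return _maybe_scalar(1.0 + coeffs.x * load**coeffs.y, scalar)


def grade_cost(speed, grade, grade_window: float = 0.4):
    """Graded-walking cost term (W/kg) for decimal grades.

    ``34 * S * G * (1 - 1.05**(1 - 1.1**(100*G + 32)))``.  Exactly zero when
    either the speed or the grade is zero.  The term was developed for
    moderate slopes; grades with ``|G| > grade_window`` trigger a warning
    rather than an error.
    """
    s = np.asarray(speed, dtype=float)
    g = np.asarray(grade, dtype=float)
    scalar = s.ndim == 0 and g.ndim == 0
    if np.any(s < 0):
        raise ValueError("speed must be >= 0")
    if np.any(np.abs(g) > grade_window):
        warnings.warn(
            f"grade outside |G| <= {grade_window}: the graded-walking term is "
            "extrapolating beyond the slopes it was developed on",
            GradeOutOfWindowWarning,
            stacklevel=2,
        )
    damping = 1.0 - 1.05 ** (1.0 - 1.1 ** (100.0 * g + 32.0))
    out = 34.0 * s * g * damping
    # multiplicative structure guarantees exact zeros; enforce despite any
    # floating noise in the damping factor
    out = np.where((s == 0) | (g == 0), 0.0, out)
    return _maybe_scalar(out, scalar)


def predict_metabolic_rate(
    m_rest,
    speed,
    load_fraction=0.0,
    grade=0.0,
    terrain_coefficient=1.0,
    coeffs: ModelCoefficients = LCDA_BACKPACKING_2022,
    include_rest_in_multiplier: bool = True,
    grade_window: float = 0.4,
):
    """Predicted metabolic rate (W/kg body mass) for standing or walking.

    Parameters
    ----------
    m_rest
        Resting metabolic rate, W/kg body mass (see :func:`resting_metabolic_rate`).
    speed, load_fraction, grade, terrain_coefficient
        Condition variables; scalars or broadcastable arrays.
    coeffs
        Coefficient set; defaults to the published backpacking set.
    include_rest_in_multiplier
        By default the load multiplier scales the full bracket including the
        resting rate, as the equation's parenthesization dictates.  Setting
        this False applies the multiplier to the walking cost only
        (a research variant, not the published model).
    """
    mr = np.asarray(m_rest, dtype=float)
    s = np.asarray(speed, dtype=float)
    load = np.asarray(load_fraction, dtype=float)
    g = np.asarray(grade, dtype=float)
    eta = np.asarray(terrain_coefficient, dtype=float)
    scalar = all(v.ndim == 0 for v in (mr, s, load, g, eta))
    if np.any(mr < 0):
        raise ValueError("m_rest must be >= 0")
    if np.any(eta <= 0):
        raise ValueError("terrain_coefficient must be > 0")

    mgrade = grade_cost(s, g, grade_window=grade_window)
    # grouping chosen so eta=1, G=0 reduces bit-identically to
    # (m_rest + level_walking_terms) * load_multiplier
    inner = coeffs.a + eta * _speed_terms(s, coeffs) + mgrade
    mult = load_multiplier(load, coeffs)
    if include_rest_in_multiplier:
        out = (mr + inner) * mult
    else:
        out = mr + inner * mult
    return _maybe_scalar(out, scalar)


def predict_for_condition(
    m_rest: float,
    cond: Condition,
    coeffs: ModelCoefficients = LCDA_BACKPACKING_2022,
    **kwargs,
) -> float:
    """Convenience wrapper evaluating :func:`predict_metabolic_rate` for a Condition."""
    return predict_metabolic_rate(
        m_rest,
        cond.speed,
        load_fraction=cond.load_fraction,
        grade=cond.grade,
        terrain_coefficient=cond.terrain_coefficient,
        coeffs=coeffs,
        **kwargs,
    )


def to_absolute_watts(rate_w_per_kg, body_mass):
    """Convert a mass-specific rate (W/kg body mass) to absolute watts."""
    return np.asarray(rate_w_per_kg, dtype=float) * np.asarray(body_mass, dtype=float)
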