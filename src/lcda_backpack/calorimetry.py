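"""Indirect calorimetry and steady-state quality control.

Metabolic rate is computed from steady-state oxygen uptake and carbon
dioxide production with a linear energy-equivalent formula, and each trial
is screened with the same steady-state checks used during data collection:
the between-half-minute coefficient of variation of each gas must be below
10% and the respiratory exchange ratio must lie in the respiratory-quotient
range [0.7, 1.0].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GasExchangeSample",
    "QCResult",
    "ENERGY_EQUIVALENTS",
    "respiratory_exchange_ratio",
    "metabolic_rate_from_gas",
    "m_from_vo2_assumed_rer",
    "invert_gas",
    "steady_state_qc",
    "lpm_to_mls",
    "RER_MIN",
    "RER_MAX",
    "CV_LIMIT_PERCENT",
]

#: Energy equivalents of O2 and CO2 for steady-state aerobic exercise,
#: W per (mL/s) STPD.  Transcribed from the published energy-expenditure
#: formula derived from the updated nonprotein respiratory-quotient table;
#: kept in this single block so the transcription has one point of
#: verification.
ENERGY_EQUIVALENTS = {
    "o2_w_per_ml_s": 16.58,
    "co2_w_per_ml_s": 4.51,
    "provenance": "published indirect-calorimetry energy-equivalent "
    "coefficients (nonprotein respiratory quotient)",
}

RER_MIN = 0.7
RER_MAX = 1.0
CV_LIMIT_PERCENT = 10.0


def lpm_to_mls(value_l_per_min):
    """Convert a gas flow from L/min to the package-internal mL/s."""
    return np.asarray(value_l_per_min, dtype=float) * (1000.0 / 60.0)


@dataclass(frozen=True)
class GasExchangeSample:
    """Steady-state gas exchange averaged over one measurement window."""

    vo2: float  # mL/s STPD
    vco2: float  # mL/s STPD
    window_label: str = "final_minute"  # first_30s | second_30s | final_minute

    def __post_init__(self) -> None:
        if self.vo2 <= 0:
            raise ValueError("vo2 must be positive")
        if self.vco2 < 0:
            raise ValueError("vco2 must be >= 0")


@dataclass(frozen=True)
class QCResult:
    cv_vo2: float  # percent
    cv_vco2: float  # percent
    rer: float
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def respiratory_exchange_ratio(sample: GasExchangeSample) -> float:
    """RER = VCO2 / VO2."""
    return sample.vco2 / sample.vo2


def metabolic_rate_from_gas(
    sample: GasExchangeSample,
    body_mass: float,
    check_rer: bool = True,
) -> float:
    """Metabolic rate (W/kg body mass) from a steady-state gas sample.

    Linear and homogeneous in (VO2, VCO2).  Samples whose RER falls outside
    [0.7, 1.0] are rejected (such trials are excluded from analysis), unless
    ``check_rer`` is disabled for exploratory use.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    rer = respiratory_exchange_ratio(sample)
    if check_rer and not RER_MIN <= rer <= RER_MAX:
        raise ValueError(
            f"RER {rer:.3f} outside [{RER_MIN}, {RER_MAX}]: trial fails the "
            "steady-state aerobic screen"
        )
    watts = (
        ENERGY_EQUIVALENTS["o2_w_per_ml_s"] * sample.vo2
        + ENERGY_EQUIVALENTS["co2_w_per_ml_s"] * sample.vco2
    )
    return watts / body_mass


def m_from_vo2_assumed_rer(
    vo2: float,
    body_mass: float,
    rer: float = 0.85,
) -> float:
    """Metabolic rate when only VO2 was reported, assuming an RER (default 0.85)."""
    if not RER_MIN <= rer <= RER_MAX:
        raise ValueError(f"assumed RER {rer} outside [{RER_MIN}, {RER_MAX}]")
    sample = GasExchangeSample(vo2=vo2, vco2=rer * vo2)
    return metabolic_rate_from_gas(sample, body_mass)


def invert_gas(m_w_per_kg: float, rer: float, body_mass: float) -> GasExchangeSample:
    """Back-compute the (VO2, VCO2) pair yielding a given rate at a given RER.

    Exact algebraic inverse of :func:`metabolic_rate_from_gas`; used by the
    synthetic study generator to emit gas traces.
    """
    if m_w_per_kg <= 0:
        raise ValueError("metabolic rate must be positive")
    if not RER_MIN <= rer <= RER_MAX:
        raise ValueError(f"RER {rer} outside [{RER_MIN}, {RER_MAX}]")
    denom = ENERGY_EQUIVALENTS["o2_w_per_ml_s"] + ENERGY_EQUIVALENTS["co2_w_per_ml_s"] * rer
    vo2 = m_w_per_kg * body_mass / denom
    return GasExchangeSample(vo2=vo2, vco2=rer * vo2)


def _two_point_cv_percent(x1: float, x2: float) -> float:
    # sample (n-1) SD of two points is |x1 - x2| / sqrt(2)
    mean = 0.5 * (x1 + x2)
    if mean <= 0:
        raise ValueError("window means must be positive")
    return abs(x1 - x2) / np.sqrt(2.0) / mean * 100.0


def steady_state_qc(first: GasExchangeSample, second: GasExchangeSample) -> QCResult:
    """Screen the two 30-s halves of a trial's final minute.

    CV per gas is the two-point sample SD over the mean (x100); RER is
    computed on the pooled final minute.  Pass requires both CVs < 10% and
    pooled RER in [0.7, 1.0] (bounds inclusive).  Symmetric in the two
    windows.
    """
    cv_vo2 = _two_point_cv_percent(first.vo2, second.vo2)
    cv_vco2 = _two_point_cv_percent(first.vco2, second.vco2)
    rer = (first.vco2 + second.vco2) / (first.vo2 + second.vo2)
    reasons: list[str] = []
    if cv_vo2 >= CV_LIMIT_PERCENT:
        reasons.append("cv_vo2_exceeds_limit")
    if cv_vco2 >= CV_LIMIT_PERCENT:
        reasons.append("cv_vco2_exceeds_limit")
    if not RER_MIN <= rer <= RER_MAX:
        reasons.append("rer_out_of_range")
    return QCResult(
        cv_vo2=cv_vo2,
        cv_vco2=cv_vco2,
        rer=rer,
        passed=not reasons,
        reasons=tuple(reasons),
    )
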