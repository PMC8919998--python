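"""Comparator load-carriage models used as validation baselines.

Both formulas are transcriptions from their original publications; this
package only evaluates them head-to-head against the backpacking equation.
Each constant block carries a provenance note and is pinned by unit tests to
hand-computed values of the transcribed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PandolfInputs",
    "pandolf_metabolic_rate",
    "minimum_mechanics_metabolic_rate",
    "MINIMUM_MECHANICS_LEVEL_WALKING",
]


@dataclass(frozen=True)
class PandolfInputs:
    """Inputs to the Pandolf load-carriage equation (its native units)."""

    body_mass: float  # kg (W)
    load_mass: float  # kg (L)
    speed: float  # m/s (V)
    grade: float = 0.0  # percent
    terrain_factor: float = 1.0  # eta

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.load_mass < 0 or self.speed < 0:
            raise ValueError("load_mass and speed must be >= 0")


def pandolf_metabolic_rate(
    body_mass,
    load_mass,
    speed,
    grade=0.0,
    terrain_factor=1.0,
):
    """Pandolf equation prediction, returned as W/kg of body mass.

    Transcription (absolute watts; W body mass kg, L load kg, V speed m/s,
    G grade percent, eta terrain factor):

        M = 1.5 W + 2.0 (W + L) (L / W)**2 + eta (W + L) (1.5 V**2 + 0.35 V G)

    The downhill correction published later is deliberately excluded: the
    comparison here is level walking only.
    """
    w = np.asarray(body_mass, dtype=float)
    load = np.asarray(load_mass, dtype=float)
    v = np.asarray(speed, dtype=float)
    g = np.asarray(grade, dtype=float)
    eta = np.asarray(terrain_factor, dtype=float)
    scalar = all(a.ndim == 0 for a in (w, load, v, g, eta))
    if np.any(w <= 0):
        raise ValueError("body_mass must be positive")
    if np.any(load < 0) or np.any(v < 0):
        raise ValueError("load_mass and speed must be >= 0")
    watts = (
        1.5 * w
        + 2.0 * (w + load) * (load / w) ** 2
        + eta * (w + load) * (1.5 * v**2 + 0.35 * v * g)
    )
    out = watts / w
    return float(out) if scalar else out


def pandolf_for_inputs(inp: PandolfInputs) -> float:
    return pandolf_metabolic_rate(
        inp.body_mass, inp.load_mass, inp.speed, inp.grade, inp.terrain_factor
    )


#: Gross standing-and-level-walking cost per kilogram of *supported* mass,
#: W/kg: constant, fractional-speed, and quartic-speed coefficients.
#: Transcribed from the published level-walking cost model the
#: minimum-mechanics comparison builds on.
MINIMUM_MECHANICS_LEVEL_WALKING = {
    "a": 1.44,  # W/kg
    "b": 1.94,  # W/kg
    "p": 0.43,
    "d": 0.24,  # W/kg
    "provenance": "published level-walking gross cost model; load applied as "
    "linearly scaled total mass per the minimum-mechanics premise",
}


def minimum_mechanics_metabolic_rate(body_mass, load_mass, speed):
    """Minimum-mechanics comparator prediction, W/kg of body mass.

    The premise is that body mass and carried mass raise absolute metabolic
    rate by the same linear factor, so the gross level-walking cost per
    kilogram of supported mass is applied to body + load and re-expressed
    per kilogram of body mass:

        M [W/kg body] = (a + b S**p + d S**4) * (body + load) / body
    """
    w = np.asarray(body_mass, dtype=float)
    load = np.asarray(load_mass, dtype=float)
    v = np.asarray(speed, dtype=float)
    scalar = all(a.ndim == 0 for a in (w, load, v))
    if np.any(w <= 0):
        raise ValueError("body_mass must be positive")
    if np.any(load < 0) or np.any(v < 0):
        raise ValueError("load_mass and speed must be >= 0")
    mm = MINIMUM_MECHANICS_LEVEL_WALKING
    per_kg_total = mm["a"] + mm["b"] * v ** mm["p"] + mm["d"] * v**4
    out = per_kg_total * (w + load) / w
    return float(out) if scalar else out
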