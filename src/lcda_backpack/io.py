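"""Trial CSV reading/writing with a versioned schema, plus run records.

The trial table is plain CSV preceded by one comment line identifying the
schema version (``# lcda-trials-v1``).  Speeds are stored in m/s, loads as
decimal fractions of body mass, grades as decimal rise/run, and gas flows
in mL/s STPD — the units are spelled out in the column names so nothing is
guessed on read.  Readers reject unknown schema versions and unknown
columns outright.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calorimetry import GasExchangeSample, metabolic_rate_from_gas, steady_state_qc

__all__ = [
    "TRIAL_SCHEMA_V1",
    "read_trials",
    "write_trials",
    "percent_to_decimal_grade",
    "load_kg_to_fraction",
    "write_run_record",
]

SCHEMA_TAG = "# lcda-trials-v1"

#: Versioned trial schema: required and optional columns.
TRIAL_SCHEMA_V1 = {
    "required": (
        "participant_id",
        "body_mass_kg",
        "load_fraction",
        "speed_mps",
        "grade_decimal",
    ),
    "optional": (
        "sex",
        "lean_mass_kg",
        "vo2_first30_ml_s",
        "vo2_second30_ml_s",
        "vco2_first30_ml_s",
        "vco2_second30_ml_s",
        "m_wkg",
    ),
}

_GAS_COLS = (
    "vo2_first30_ml_s",
    "vo2_second30_ml_s",
    "vco2_first30_ml_s",
    "vco2_second30_ml_s",
)


def percent_to_decimal_grade(grade_percent):
    """Percent grade -> decimal rise/run."""
    return np.asarray(grade_percent, dtype=float) / 100.0


def load_kg_to_fraction(load_kg, body_mass_kg):
    """Absolute backpack mass (kg) -> fraction of body mass."""
    return np.asarray(load_kg, dtype=float) / np.asarray(body_mass_kg, dtype=float)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table with the schema tag as the first line."""
    unknown = set(trials.columns) - set(TRIAL_SCHEMA_V1["required"]) - set(
        TRIAL_SCHEMA_V1["optional"]
    )
    if unknown:
        raise ValueError(f"columns not in the trial schema: {sorted(unknown)}")
    missing = set(TRIAL_SCHEMA_V1["required"]) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing required columns: {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(SCHEMA_TAG + "\n")
        trials.to_csv(fh, index=False, lineterminator="\n")


def read_trials(
    path,
    apply_qc: bool = False,
    assume_rer: float | None = None,
) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Gas-bearing rows get ``qc_passed``/``qc_reasons`` columns from the
    steady-state screen and, where ``m_wkg`` is absent, a rate computed by
    indirect calorimetry on the pooled final minute.  Rows failing QC are
    flagged, not dropped, unless ``apply_qc`` is set.  When VCO2 columns are
    absent, ``assume_rer`` enables the assumed-RER calorimetry path.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != SCHEMA_TAG:
            raise ValueError(
                f"unsupported trial schema header {first!r}; expected {SCHEMA_TAG!r}"
            )
        trials = pd.read_csv(fh)
    known = set(TRIAL_SCHEMA_V1["required"]) | set(TRIAL_SCHEMA_V1["optional"])
    unknown = set(trials.columns) - known
    if unknown:
        raise ValueError(f"unknown columns {sorted(unknown)} in {path}")
    missing = set(TRIAL_SCHEMA_V1["required"]) - set(trials.columns)
    if missing:
        raise ValueError(f"missing required columns {sorted(missing)} in {path}")

    has_full_gas = all(c in trials.columns for c in _GAS_COLS)
    has_vo2_only = (
        "vo2_first30_ml_s" in trials.columns
        and "vo2_second30_ml_s" in trials.columns
        and not has_full_gas
    )
    if has_full_gas:
        qc_passed, qc_reasons, m_gas = [], [], []
        for row in trials.itertuples(index=False):
            first_w = GasExchangeSample(
                row.vo2_first30_ml_s, row.vco2_first30_ml_s, "first_30s"
            )
            second_w = GasExchangeSample(
                row.vo2_second30_ml_s, row.vco2_second30_ml_s, "second_30s"
            )
            qc = steady_state_qc(first_w, second_w)
            qc_passed.append(qc.passed)
            qc_reasons.append(";".join(qc.reasons))
            pooled = GasExchangeSample(
                0.5 * (first_w.vo2 + second_w.vo2),
                0.5 * (first_w.vco2 + second_w.vco2),
                "final_minute",
            )
            m_gas.append(
                metabolic_rate_from_gas(pooled, row.body_mass_kg, check_rer=False)
            )
        trials = trials.assign(qc_passed=qc_passed, qc_reasons=qc_reasons)
        if "m_wkg" not in trials.columns:
            trials["m_wkg"] = m_gas
    elif has_vo2_only:
        if assume_rer is None:
            raise ValueError(
                "VO2-only trial file: pass assume_rer to compute metabolic rates"
            )
        vo2 = 0.5 * (trials["vo2_first30_ml_s"] + trials["vo2_second30_ml_s"])
        from .calorimetry import m_from_vo2_assumed_rer

        if "m_wkg" not in trials.columns:
            trials["m_wkg"] = [
                m_from_vo2_assumed_rer(v, bm, rer=assume_rer)
                for v, bm in zip(vo2, trials["body_mass_kg"])
            ]
        trials = trials.assign(qc_passed=True, qc_reasons="")
    if apply_qc and "qc_passed" in trials.columns:
        trials = trials[trials["qc_passed"]].reset_index(drop=True)
    return trials


def write_run_record(path, config: dict, seed: int | None) -> dict:
    """Write a machine-readable run record (seed, config, config hash)."""
    payload = {"seed": seed, "config": config}
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
    print(f"run record: {path} (hash {payload['config_hash']})", file=sys.stderr)
    return payload
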