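"""Packaged study data: flow-meter readings, injected activities, modelled flows.

The study published its measurements only as printed tables; those tables are
transcribed here as plain CSV package data so that every reported statistic
can be recomputed offline:

* ``table2_flowmeters.csv`` — pump setting, constriction, nominal and measured
  Qcyl/Qtube per measurement x system x session (48 records);
* ``table3_activities.csv`` — injected activities (MBq) with the printed
  signed test-retest differences and their printed decimal precision
  (24 records);
* ``table5_flows.csv`` — modelled Qin and Qout per measurement x system,
  test and retest (48 records).

``load_fixtures`` validates a sha256 manifest and the internal consistency of
the activity table (recomputed signed differences must round to the printed
values) before returning anything.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .frames import default_frame_spec
from .metrics import repeatability_error

__all__ = ["PaperFixtures", "FixtureError", "load_fixtures", "MEASUREMENT_IDS", "SYSTEMS"]

MEASUREMENT_IDS: Tuple[str, ...] = tuple(
    f"{q}-{c}" for q in (150, 200, 250) for c in (20, 40, 60, 80)
)
SYSTEMS: Tuple[str, str] = ("DMI-20", "Vision-600")

_EXPECTED_ROWS = {"table2_flowmeters.csv": 48, "table3_activities.csv": 24, "table5_flows.csv": 48}


class FixtureError(RuntimeError):
    """Raised when packaged study data fails validation."""


@dataclass(frozen=True)
class PaperFixtures:
    """Validated study tables plus the fixed protocol constants."""

    table2: pd.DataFrame
    table3: pd.DataFrame
    table5: pd.DataFrame
    protocol: Dict[str, object] = field(
        default_factory=lambda: {
            "frame_spec": default_frame_spec(),
            "requested_activity_MBq": 500.0,
            "vcyl_ml": 160.0,
            "v_input_ml": 15.7,
        }
    )


def _data_bytes(name: str) -> bytes:
    return resources.files("flowphantom.data").joinpath(name).read_bytes()


def _read_csv(name: str) -> pd.DataFrame:
    import io

    return pd.read_csv(io.BytesIO(_data_bytes(name)))


def _verify_manifest() -> None:
    manifest = json.loads(_data_bytes("MANIFEST.json"))
    for name, meta in manifest.items():
        raw = _data_bytes(name)
        digest = hashlib.sha256(raw).hexdigest()
        if digest != meta["sha256"]:
            raise FixtureError(f"checksum mismatch for packaged fixture {name}")
        rows = raw.decode().count("\n") - 1
        if rows != meta["rows"] or rows != _EXPECTED_ROWS[name]:
            raise FixtureError(f"row count mismatch for packaged fixture {name}: {rows}")


def _validate_table2(t2: pd.DataFrame) -> None:
    required = {
        "measurement_id", "system", "session", "qpump_ml_min", "constriction_fraction",
        "qcyl_nominal_ml_min", "qcyl_measured_ml_min", "qtube_nominal_ml_min", "qtube_measured_ml_min",
    }
    missing = required - set(t2.columns)
    if missing:
        raise FixtureError(f"table2 missing columns: {sorted(missing)}")
    if set(t2["measurement_id"]) != set(MEASUREMENT_IDS):
        raise FixtureError("table2 must contain exactly the 12 protocol measurement ids")
    if len(t2) != 48:
        raise FixtureError(f"table2 must have 48 records, found {len(t2)}")
    for col in ("qpump_ml_min", "qcyl_measured_ml_min", "qtube_measured_ml_min"):
        if (t2[col] <= 0).any():
            raise FixtureError(f"table2 field {col} must be positive everywhere")
    nominal = t2["qpump_ml_min"] * t2["constriction_fraction"]
    if not (abs(nominal - t2["qcyl_nominal_ml_min"]) < 1e-9).all():
        raise FixtureError("table2 field qcyl_nominal_ml_min inconsistent with qpump x constriction")


def _validate_table3(t3: pd.DataFrame) -> None:
    required = {"measurement_id", "system", "test_MBq", "retest_MBq",
                "printed_difference_percent", "printed_decimals", "inconsistent"}
    missing = required - set(t3.columns)
    if missing:
        raise FixtureError(f"table3 missing columns: {sorted(missing)}")
    if (t3["test_MBq"] <= 0).any() or (t3["retest_MBq"] <= 0).any():
        raise FixtureError("table3 activities must be positive")
    for _, row in t3.iterrows():
        if row["inconsistent"]:
            continue
        recomputed = repeatability_error(row["test_MBq"], row["retest_MBq"], signed=True)
        printed = float(row["printed_difference_percent"])
        if round(recomputed, int(row["printed_decimals"])) != printed:
            raise FixtureError(
                f"table3 printed_difference_percent mismatch for "
                f"{row['measurement_id']}/{row['system']}: recomputed {recomputed:.4f} "
                f"vs printed {printed}"
            )


def _validate_table5(t5: pd.DataFrame, t2: pd.DataFrame) -> None:
    required = {"measurement_id", "system", "quantity", "test_ml_min", "retest_ml_min"}
    missing = required - set(t5.columns)
    if missing:
        raise FixtureError(f"table5 missing columns: {sorted(missing)}")
    if len(t5) != 48:
        raise FixtureError(f"table5 must have 48 records, found {len(t5)}")
    if set(t5["quantity"]) != {"Qin", "Qout"}:
        raise FixtureError("table5 field quantity must be Qin or Qout")
    keys2 = set(zip(t2["measurement_id"], t2["system"]))
    for mid, system in zip(t5["measurement_id"], t5["system"]):
        if (mid, system) not in keys2:
            raise FixtureError(f"table5 record ({mid}, {system}) has no table2 counterpart")
    if (t5["test_ml_min"] <= 0).any() or (t5["retest_ml_min"] <= 0).any():
        raise FixtureError("table5 flow values must be positive")


def load_fixtures() -> PaperFixtures:
    """Load and validate the packaged study tables. Fails loudly on any defect."""
    _verify_manifest()
    t2 = _read_csv("table2_flowmeters.csv")
    t3 = _read_csv("table3_activities.csv")
    t5 = _read_csv("table5_flows.csv")
    _validate_table2(t2)
    _validate_table3(t3)
    _validate_table5(t5, t2)
    return PaperFixtures(table2=t2, table3=t3, table5=t5)
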