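"""File formats: the TAC CSV dialect and the run configuration file.

TAC CSV dialect (UTF-8, header required)::

    # decay_corrected=true reference_time=0.0      <- optional metadata comment
    frame_start_s,frame_duration_s,value_kBq_ml
    0.0,5.0,12.34
    ...

Frames must be contiguous and non-overlapping; malformed rows are rejected
with their line number. The optional leading comment carries the
decay-correction state so that write -> read round-trips the full TAC.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .frames import FrameSchedule, SampledTAC, ScheduleError

__all__ = ["TACParseError", "read_tac_csv", "write_tac_csv", "RunConfig", "load_config"]

logger = logging.getLogger("flowphantom")

_COLUMNS = ("frame_start_s", "frame_duration_s", "value_kBq_ml")


class TACParseError(ValueError):
    """Raised for malformed TAC CSV files, carrying the offending line number."""


def write_tac_csv(tac: SampledTAC, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(
            f"# decay_corrected={'true' if tac.decay_corrected else 'false'} "
            f"reference_time={tac.reference_time!r}\n"
        )
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for start, dur, value in zip(tac.schedule.frame_starts, tac.schedule.frame_durations, tac.values):
            writer.writerow([repr(float(start)), repr(float(dur)), repr(float(value))])


def read_tac_csv(path: Union[str, Path]) -> SampledTAC:
    path = Path(path)
    decay_corrected = False
    reference_time = 0.0
    starts, durs, values = [], [], []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            for token in stripped.lstrip("#").split():
                if token.startswith("decay_corrected="):
                    decay_corrected = token.split("=", 1)[1].lower() == "true"
                elif token.startswith("reference_time="):
                    reference_time = float(token.split("=", 1)[1])
            continue
        cells = [c.strip() for c in stripped.split(",")]
        if not header_seen:
            if tuple(cells) != _COLUMNS:
                raise TACParseError(
                    f"{path}:{lineno}: header must be {','.join(_COLUMNS)}, got {stripped!r}"
                )
            header_seen = True
            continue
        if len(cells) != 3:
            raise TACParseError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        try:
            start, dur, value = (float(c) for c in cells)
        except ValueError as exc:
            raise TACParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        starts.append(start)
        durs.append(dur)
        values.append(value)
    if not header_seen:
        raise TACParseError(f"{path}: empty file (header row required)")
    if not starts:
        raise TACParseError(f"{path}: no data rows")
    try:
        schedule = FrameSchedule(np.asarray(starts), np.asarray(durs))
    except ScheduleError as exc:
        raise TACParseError(f"{path}: invalid frame schedule: {exc}") from None
    return SampledTAC(schedule, np.asarray(values), decay_corrected=decay_corrected,
                      reference_time=reference_time)


class RunConfig(BaseModel):
    """Flat run configuration mirroring the simulator and fitter knobs.

    Unknown keys are rejected (typo guard); absent keys take these defaults.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    noise_scale: float = 2.5
    qpump: float = 150.0               # ml/min
    constriction_fraction: float = 0.2
    vcyl: float = 160.0                # ml
    v_input: float = 15.7              # ml
    flowmeter_calibration: float = 1.0
    requested_activity_MBq: float = 500.0
    dispense_error_fraction: float = 0.0
    half_life_s: float = 122.24
    isf_true: float = 0.1
    delay_true_s: float = 5.0
    spillover_mode: str = "additive"
    delay_grid_max_s: float = 30.0
    delay_grid_step_s: float = 1.0
    qin_max: float = 10.0              # min^-1, fit bound
    qout_max: float = 10.0
    rounding_decimals: int = 2

    @field_validator("spillover_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("additive", "scaled"):
            raise ValueError("spillover_mode must be 'additive' or 'scaled'")
        return v


class _DuplicateKeyLoader(yaml.SafeLoader):
    """YAML loader that warns on duplicate mapping keys; the last value wins."""


def _construct_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            warnings.warn(f"duplicate config key {key!r}; last value wins", stacklevel=2)
            logger.warning("duplicate config key %r; last value wins", key)
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_DuplicateKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load a YAML-style flat config; ``None`` or an empty file -> all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    raw = yaml.load(path.read_text(encoding="utf-8"), Loader=_DuplicateKeyLoader)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return RunConfig(**raw)
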