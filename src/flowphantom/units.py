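"""Physical constants and unit conversions.

All internal computation uses seconds for time and kBq/ml for activity
concentration. Flows are expressed in ml/min and rate constants in min^-1 at
module boundaries (the units the field reports) and converted here, in one
place, when entering second-based numerics.
"""

import math

#: Physical half-life of oxygen-15 in seconds.
O15_HALF_LIFE_S = 122.24

SECONDS_PER_MINUTE = 60.0


def decay_constant(half_life_s: float) -> float:
    """Decay constant lambda = ln 2 / T_half in s^-1. ``inf`` half-life -> 0."""
    if half_life_s <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_s}")
    if math.isinf(half_life_s):
        return 0.0
    return math.log(2.0) / half_life_s


def ml_min_to_ml_s(flow_ml_min: float) -> float:
    return flow_ml_min / SECONDS_PER_MINUTE


def ml_s_to_ml_min(flow_ml_s: float) -> float:
    return flow_ml_s * SECONDS_PER_MINUTE


def per_min_to_per_s(rate_per_min: float) -> float:
    return rate_per_min / SECONDS_PER_MINUTE


def per_s_to_per_min(rate_per_s: float) -> float:
    return rate_per_s * SECONDS_PER_MINUTE
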