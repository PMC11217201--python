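"""Recomputing the study's Results from the packaged tables.

Aggregates the metric primitives into the complete analysis: the signed
activity-difference column, flow-meter and activity QC, per-system
test-retest repeatability statistics for Qin and Qout, threshold counts,
between-system Bland-Altman agreement and correlation lines — together with
pass/fail checks at the tolerances these quantities support (rounded printed
inputs reproduce unrounded-source summary statistics only to within rounding
propagation; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .fixtures import PaperFixtures, SYSTEMS
from .metrics import (
    activity_qc,
    bland_altman,
    count_exceeding,
    flowmeter_qc,
    linear_fit,
    repeatability_error,
    summarize,
)

__all__ = ["CheckResult", "study_report", "paper_checks", "repeatability_table"]

#: Protocol-wide relative tolerance limit (percent) for both QC checks.
QC_LIMIT_PERCENT = 15.0
#: Repeatability threshold (percent) used for the exceedance count.
REPEATABILITY_THRESHOLD = 15.0
#: Tolerance for summary means recomputed from rounded printed values (pp / ml/min).
ROUNDING_TOLERANCE_MEAN = 0.5


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def repeatability_table(table5: pd.DataFrame) -> pd.DataFrame:
    """Absolute Eq.-style repeatability error per (measurement, system, quantity)."""
    out = table5.copy()
    out["repeatability_percent"] = [
        repeatability_error(t, r) for t, r in zip(out["test_ml_min"], out["retest_ml_min"])
    ]
    return out


def study_report(fixtures: PaperFixtures) -> Dict[str, object]:
    """Every reported statistic, recomputed from the packaged tables."""
    t2, t3, t5 = fixtures.table2, fixtures.table3, fixtures.table5
    requested = float(fixtures.protocol["requested_activity_MBq"])

    # --- Table 3: signed differences and activity QC -----------------------
    diffs = []
    for _, row in t3.iterrows():
        recomputed = repeatability_error(row["test_MBq"], row["retest_MBq"], signed=True)
        diffs.append(
            {
                "measurement_id": row["measurement_id"],
                "system": row["system"],
                "recomputed_percent": recomputed,
                "printed_percent": float(row["printed_difference_percent"]),
                "matches_printed": bool(
                    row["inconsistent"]
                    or round(recomputed, int(row["printed_decimals"]))
                    == float(row["printed_difference_percent"])
                ),
            }
        )
    table3_diffs = pd.DataFrame(diffs)
    activities = np.concatenate([t3["test_MBq"].to_numpy(float), t3["retest_MBq"].to_numpy(float)])
    activity_devs = [activity_qc(a, requested, QC_LIMIT_PERCENT) for a in activities]

    # --- Table 2: flow-meter conservation QC --------------------------------
    qc = t2.copy()
    qc["qc_percent"] = [
        flowmeter_qc(c, u, p, QC_LIMIT_PERCENT).observed_percent
        for c, u, p in zip(qc["qcyl_measured_ml_min"], qc["qtube_measured_ml_min"], qc["qpump_ml_min"])
    ]

    # --- Table 5: repeatability ---------------------------------------------
    rep = repeatability_table(t5)
    rep_stats = {
        (system, quantity): summarize(
            rep[(rep["system"] == system) & (rep["quantity"] == quantity)]["repeatability_percent"]
        )
        for system in SYSTEMS
        for quantity in ("Qin", "Qout")
    }
    counts_over = {
        system: count_exceeding(
            rep[rep["system"] == system]["repeatability_percent"], REPEATABILITY_THRESHOLD
        )
        for system in SYSTEMS
    }
    max_err = {
        system: float(rep[rep["system"] == system]["repeatability_percent"].max())
        for system in SYSTEMS
    }

    # --- Between-system agreement (test and retest sessions pooled) ---------
    ba = {}
    lines = {}
    for quantity in ("Qin", "Qout"):
        sub = t5[t5["quantity"] == quantity].set_index(["measurement_id", "system"])
        a, b = [], []
        for mid in t5["measurement_id"].unique():
            for col in ("test_ml_min", "retest_ml_min"):
                a.append(float(sub.loc[(mid, "DMI-20"), col]))
                b.append(float(sub.loc[(mid, "Vision-600"), col]))
        ba[quantity] = bland_altman(a, b)
        lines[quantity] = linear_fit(a, b)

    return {
        "table3_diffs": table3_diffs,
        "activity_max_deviation_percent": max(r.observed_percent for r in activity_devs),
        "activity_all_within_limit": all(r.passed for r in activity_devs),
        "flowmeter_qc": qc,
        "flowmeter_qc_max_abs_percent": float(qc["qc_percent"].abs().max()),
        "repeatability": rep,
        "repeatability_stats": rep_stats,
        "repeatability_counts_over_15": counts_over,
        "repeatability_max_percent": max_err,
        "bland_altman": ba,
        "correlation_lines": lines,
    }


def paper_checks(report: Dict[str, object]) -> List[CheckResult]:
    """Pass/fail verdicts for the study's reported findings."""
    checks: List[CheckResult] = []
    t3 = report["table3_diffs"]
    n_match = int(t3["matches_printed"].sum())
    checks.append(
        CheckResult(
            "activity-differences-reproduced",
            n_match == len(t3),
            f"{n_match}/{len(t3)} printed signed differences reproduced at printed precision",
        )
    )
    amax = report["activity_max_deviation_percent"]
    checks.append(
        CheckResult(
            "activities-within-15-percent",
            bool(report["activity_all_within_limit"]),
            f"max |injected-500|/500 = {amax:.1f}% (limit {QC_LIMIT_PERCENT}%)",
        )
    )
    fmax = report["flowmeter_qc_max_abs_percent"]
    checks.append(
        CheckResult(
            "flowmeter-qc-within-15-percent",
            fmax <= QC_LIMIT_PERCENT,
            f"max |Qcyl+Qtube-Qpump|/Qpump = {fmax:.1f}% (limit {QC_LIMIT_PERCENT}%)",
        )
    )
    dmax = report["repeatability_max_percent"]["DMI-20"]
    checks.append(
        CheckResult(
            "dmi20-repeatability-below-15-percent",
            dmax <= REPEATABILITY_THRESHOLD,
            f"max DMI-20 repeatability error = {dmax:.1f}%",
        )
    )
    stats = report["repeatability_stats"]
    for quantity, printed in (("Qin", 10.0), ("Qout", 11.0)):
        mean = stats[("Vision-600", quantity)].mean
        checks.append(
            CheckResult(
                f"vision600-{quantity.lower()}-mean-repeatability",
                round(mean) == printed,
                f"Vision-600 {quantity} mean = {mean:.2f}% (reported {printed:.0f}%)",
            )
        )
    for quantity, printed in (("Qin", 2.1), ("Qout", 3.3)):
        mean = stats[("DMI-20", quantity)].mean
        checks.append(
            CheckResult(
                f"dmi20-{quantity.lower()}-mean-repeatability",
                abs(mean - printed) <= ROUNDING_TOLERANCE_MEAN,
                f"DMI-20 {quantity} mean = {mean:.2f}% (reported {printed}%, "
                f"tolerance {ROUNDING_TOLERANCE_MEAN} pp)",
            )
        )
    n_over = report["repeatability_counts_over_15"]["Vision-600"]
    checks.append(
        CheckResult(
            "vision600-count-over-15-percent",
            n_over == 7,
            f"Vision-600 errors > 15%: {n_over}/24 (reported 7/24)",
        )
    )
    for quantity, printed in (("Qin", 1.59), ("Qout", -17.3)):
        mean = report["bland_altman"][quantity].mean_difference
        checks.append(
            CheckResult(
                f"bland-altman-{quantity.lower()}-mean-difference",
                abs(mean - printed) <= ROUNDING_TOLERANCE_MEAN,
                f"{quantity} mean difference DMI-20 - Vision-600 = {mean:.2f} ml/min "
                f"(reported {printed} ml/min, tolerance {ROUNDING_TOLERANCE_MEAN} ml/min)",
            )
        )
    return checks
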