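"""Recompute the study's reported results from the packaged tables.

Loads the packaged flow-meter, injected-activity and modelled-flow tables,
then recomputes the QC maxima, per-system test-retest repeatability, the
>15% exceedance count and the between-system Bland-Altman agreement.
"""

from flowphantom import load_fixtures
from flowphantom.report import paper_checks, study_report

report = study_report(load_fixtures())

print("QC: max |Qcyl+Qtube-Qpump|/Qpump =",
      f"{report['flowmeter_qc_max_abs_percent']:.1f}% (all below the 15% limit)")
print("QC: max injected-activity deviation from 500 MBq =",
      f"{report['activity_max_deviation_percent']:.1f}%")
print()
for (system, quantity), s in report["repeatability_stats"].items():
    print(f"{system:>11s} {quantity:>5s} repeatability: {s.mean:5.2f}% +- {s.sd:5.2f}%")
print("Vision-600 errors above 15%:",
      f"{report['repeatability_counts_over_15']['Vision-600']}/24")
print()
for quantity, ba in report["bland_altman"].items():
    print(f"Bland-Altman {quantity}: mean difference {ba.mean_difference:6.2f} ml/min, "
          f"LoA [{ba.loa_low:.1f}, {ba.loa_high:.1f}]")
print()
# each line below is one reported finding, recomputed and judged
for check in paper_checks(report):
    print(f"[{'PASS' if check.passed else 'FAIL'}] {check.name}: {check.detail}")
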