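"""The central experiment: does harmonization rescue the worst hospital?

Trains two federations on a deliberately heterogeneous two-hospital cohort
(disjoint intensity ranges, opposite photometric conventions, labels and
clips at hospital 1): condition A applies metadata harmonization only,
condition B adds breast-area cleaning and shared normalization statistics.
At the default scale this takes about three minutes on one CPU core.
"""

from fedmammo import harmonization_ablation

report = harmonization_ablation(seed=0)

for name, cond in report.items():
    f1s = ", ".join(f"{h}: {v:.3f}" for h, v in cond["per_hospital_f1"].items())
    print(f"{name:14s} per-hospital F1 [{f1s}]  "
          f"worst {cond['worst_f1']:.3f}  spread {cond['spread']:.3f}")

a, b = report["minimal"], report["full_pipeline"]
print(
    "\nThe full pipeline lifts the worst hospital by "
    f"{b['worst_f1'] - a['worst_f1']:+.3f} F1. Printed labels and clips are "
    "invisible to metadata-only harmonization; removing the non-breast "
    "region is what aligns the hospitals' inputs."
)
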