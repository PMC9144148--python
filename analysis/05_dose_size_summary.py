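"""Dose-size safety summary: the headline trade-off.

Aggregates the per-group safety labels from 02_lsci_flow_safety.py and
reports the relative change in diameter and dose between the largest
safe doses of the two capsule sizes.  Writes
results/dose_size_summary.csv.  Run 02 first.
"""

from pathlib import Path

import pandas as pd

from renoperf.pipeline import DoseGroupSummary, dose_size_summary

OUT = Path(__file__).resolve().parents[1] / "results"

flow = pd.read_csv(OUT / "flow_safety.csv")
flow = flow.dropna(subset=["diameter_um"])  # control/sham carry no dose

groups = [
    DoseGroupSummary(
        capsule_diameter_um=row["diameter_um"],
        dose_count=row["dose"],
        flow_percent={"15 min": row["percent_15min"], "24 h": row["percent_24h"]},
        safety_label=row["safety_label"],
    )
    for _, row in flow.iterrows()
]

table, headline = dose_size_summary(groups)
table.to_csv(OUT / "dose_size_summary.csv", index=False)
print(table.to_string(index=False))
print(
    f"\nBetween the largest safe doses of the two sizes: diameter "
    f"{headline['diameter_change_percent']:+.0f}%, dose "
    f"{headline['dose_change_percent']:+.0f}% — growing the capsules by "
    f"roughly a third of their diameter forces at least a halving of the "
    f"dose to keep kidney perfusion safe."
)
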