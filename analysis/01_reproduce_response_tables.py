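"""Recompute the cohort's response assessments from the printed sums.

From the packaged study tables (per-patient target-lesion sums at both CT
visits), recompute every change rate and RECIST category — manual caliper
measurements (10 patients) and 3D volumetry (10 patients x 2 metrics x
2 selection modes) — and compare against the published cells.  Writes the
recomputed tables under results/.
"""

from pathlib import Path

import pandas as pd

from pulmhet.core import change_rate
from pulmhet.io import load_manual_assessment_table, load_volumetry_assessment_table
from pulmhet.response import classify, Metric

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    manual = load_manual_assessment_table()
    manual["recomputed_change_percent"] = [
        round(change_rate(a, b), 1) for a, b in zip(manual.sum1_cm, manual.sum2_cm)
    ]
    manual["recomputed_response"] = [
        classify(Metric.DIAMETER, change_rate(a, b)).value
        for a, b in zip(manual.sum1_cm, manual.sum2_cm)
    ]
    ok = (manual.recomputed_change_percent == manual.change_percent).all() and (
        manual.recomputed_response == manual.response
    ).all()
    manual.to_csv(RESULTS / "manual_assessment_recomputed.csv", index=False)
    print(f"manual table: {len(manual)} patients, all cells reproduced: {ok}")
    print(f"  all categories SD: {(manual.recomputed_response == 'SD').all()}")

    vol = load_volumetry_assessment_table()
    n_match = 0
    for prefix, metric, unit in (("diam", Metric.DIAMETER, "cm"), ("vol", Metric.VOLUME, "cm3")):
        ch = [
            change_rate(a, b)
            for a, b in zip(vol[f"{prefix}_sum1_{unit}"], vol[f"{prefix}_sum2_{unit}"])
        ]
        vol[f"{prefix}_recomputed_change"] = [round(c, 1) for c in ch]
        vol[f"{prefix}_recomputed_response"] = [classify(metric, c).value for c in ch]
        n_match += (vol[f"{prefix}_recomputed_change"] == vol[f"{prefix}_change_percent"]).sum()
    vol.to_csv(RESULTS / "volumetry_assessment_recomputed.csv", index=False)
    cats = pd.concat([vol.diam_recomputed_response, vol.vol_recomputed_response])
    print(f"volumetry table: {n_match}/40 change cells reproduced to 1 decimal")
    print(f"  categories: {cats.value_counts().to_dict()} "
          f"(the single PR is patient 4, diameter, two largest)")


if __name__ == "__main__":
    main()
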