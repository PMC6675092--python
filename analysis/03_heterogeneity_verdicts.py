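"""Apply the overall heterogeneity decision rule to the published p-values.

The combination test's per-metric minimum p-values are published per patient;
the per-nodule raw rates are not, so the p-values themselves are not
recomputable here (the synthetic pipeline exercises that path instead —
see 04/05).  This driver applies the min(min(p)) < 0.05 rule and checks the
resulting verdicts.  Writes results/heterogeneity_verdicts.csv.
"""

from pathlib import Path

from pulmhet.heterogeneity import overall_verdict
from pulmhet.io import load_heterogeneity_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    table = load_heterogeneity_table()
    mm, verdicts = [], []
    for _, row in table.iterrows():
        m, v = overall_verdict(row.min_p_diameter, row.min_p_volume)
        mm.append(m)
        verdicts.append(v)
    table["recomputed_min_min_p"] = mm
    table["recomputed_heterogeneous"] = verdicts
    table.to_csv(RESULTS / "heterogeneity_verdicts.csv", index=False)
    het = table[table.recomputed_heterogeneous].patient_id.tolist()
    print(f"heterogeneous patients: {het} ({len(het)} of {len(table)})")
    print(f"verdicts match published: {(table.recomputed_heterogeneous == table.heterogeneous).all()}")
    print(f"min(min(p)) matches published: {(table.recomputed_min_min_p == table.min_min_p).all()}")


if __name__ == "__main__":
    main()
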