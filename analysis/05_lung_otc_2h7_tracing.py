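"""Compare glycogen turnover in cancerous vs non-cancerous lung slices.

Runs the simulate-mode pipeline on the paired organotypic-culture scenarios
labeled with 2H7-glucose: the cancerous slice holds more total glycogen but
a smaller fully labeled fraction (about 15% vs 27% enrichment), i.e. slower
turnover, with light 2H2-2H4 scrambling from pentose-phosphate activity in
both. The dual 13C6-2H7 spike keeps the standard mass-resolved from every
single-tracer analyte.

Writes results/otc_enrichment.csv.
"""

from pathlib import Path

import pandas as pd

from glycotrace.glycogen import fractional_enrichment
from glycotrace.pipeline import RunConfig, run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 144


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for scenario, tissue in (
        ("otc_cancer_like", "cancerous"),
        ("otc_noncancer_like", "non-cancerous"),
    ):
        report, artifacts = run_pipeline(
            RunConfig(mode="simulate", scenario=scenario, seed=SEED)
        )
        total = report.corrected_glycogen_ug
        full = total * report.split_percent["fully_labeled"] / 100.0
        rows.append(
            {
                "tissue": tissue,
                "total_glycogen_ug": round(total, 1),
                "fully_labeled_ug": round(full, 1),
                "enrichment_percent": round(
                    fractional_enrichment(full, total - full)
                ),
                "scrambled_percent": round(report.split_percent["scrambled"], 1),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "otc_enrichment.csv", index=False)

    print("2H7-glucose tracing in paired lung tissue slices (simulate mode):")
    print(table.to_string(index=False))
    ca, nc = table.iloc[0], table.iloc[1]
    print(f"\nThe cancerous slice stores more glycogen "
          f"({ca.total_glycogen_ug} vs {nc.total_glycogen_ug} ug) but at lower "
          f"2H7 enrichment ({ca.enrichment_percent}% vs {nc.enrichment_percent}%), "
          f"consistent with slower glycogen turnover in the tumor tissue.")
    print("Scrambled 2H2-2H4 isotopologues report pentose-phosphate-derived "
          "glucose re-entering glycogen in both tissues.")


if __name__ == "__main__":
    main()
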