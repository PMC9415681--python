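"""Resolve direct vs scrambled 13C6-glucose incorporation in liver glycogen.

Runs the simulate-mode pipeline on the tumor-bearing-mouse liver scenario:
glycogen whose hydrolysate is roughly 46% unlabeled, 38% fully 13C6-labeled
and 16% scrambled (13C1-13C5, from pentose-phosphate / gluconeogenic
rearrangement), with 85% of total glycogen visible to solution NMR before
hydrolysis. The report shows the FTMS isotopologue split, the headline 13C
fractional enrichment, and the NMR-visible fraction obtained by comparing
the intact-extract NMR quantification with the hydrolysis total.

Writes results/pdtx_liver_report.json and results/pdtx_liver_split.csv.
"""

import json
from pathlib import Path

import pandas as pd

from glycotrace.pipeline import RunConfig, run_pipeline
from glycotrace.scenarios import get_scenario

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 760


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report, artifacts = run_pipeline(
        RunConfig(mode="simulate", scenario="pdtx_liver_like", seed=SEED)
    )
    (RESULTS / "pdtx_liver_report.json").write_text(
        json.dumps(report.rounded(), indent=2, sort_keys=True, default=str) + "\n"
    )

    truth = get_scenario("pdtx_liver_like")["labeling"]
    split = pd.DataFrame(
        [
            {
                "component": name,
                "true_percent": 100 * truth[key],
                "measured_percent": round(report.split_percent[name], 1),
            }
            for name, key in (
                ("unlabeled", "f_unlabeled"),
                ("fully_labeled", "f_direct"),
                ("scrambled", "f_scrambled"),
            )
        ]
    )
    split.to_csv(RESULTS / "pdtx_liver_split.csv", index=False)

    print("Liver glycogen after 13C6-glucose feeding (simulate mode):")
    print(split.to_string(index=False))
    print(f"\nTotal glycogen (corrected): {report.corrected_glycogen_ug:.1f} ug "
          f"vs {artifacts['stages']['truth']['glycogen_ug']:.1f} ug ground truth.")
    print(f"13C fractional enrichment of hydrolyzed glycogen: "
          f"{report.enrichment_percent:.1f}%.")
    print(f"NMR-visible glycogen: {report.nmr_visible_percent:.0f}% of the "
          f"hydrolysis-determined total (mobile outer branches only; the "
          f"immobile core is silent in solution NMR).")
    pre_nmr = artifacts["stages"]["pre_nmr"]
    print(f"Intact-extract 13C enrichment at H1 (NMR satellites): "
          f"{100 * pre_nmr['F_glycogen']:.0f}% for glycogen, "
          f"{100 * pre_nmr['F_glucose_H1b']:.0f}% for free glucose.")


if __name__ == "__main__":
    main()
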