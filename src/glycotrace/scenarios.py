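"""Bundled simulation scenarios emulating the study systems.

Each scenario fixes the biological ground truth for one synthetic run:
glycogen content, free glucose, tracer and its incorporation split,
hydrolysis condition, spike level, and NMR acquisition constants. Values
mirror the measured systems they are named after (a primary bronchial cell
line grown in unlabeled glucose; tumor-bearing mouse liver after 13C6-glucose
feeding; cancerous and non-cancerous lung organotypic slices after
2H7-glucose labeling).
"""

from __future__ import annotations

import copy

__all__ = ["SCENARIOS", "get_scenario"]

SCENARIOS: dict[str, dict] = {
    # Unlabeled bronchial epithelial cell culture: modest glycogen store,
    # measurable free glucose, 13C6 spike (valid because no 13C tracer).
    "beas2b_like": {
        "name": "beas2b_like",
        "tracer": None,
        "labeling": None,
        "glycogen_ug": 24.0,
        "free_glucose_nmol": 29.1,
        "protein_mg": 0.61,
        "nmr_visible_fraction": 0.9,
        "hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "standard_hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "spike_nmol": 50.0,
        "dss_mM": 0.5,
        "volume_uL": 50.0,
        "normalization": "protein",
    },
    # Liver of a tumor-bearing mouse fed 13C6-glucose: roughly 46% unlabeled,
    # 38% fully labeled, 16% scrambled glucose in hydrolyzed glycogen, with
    # 85% of total glycogen NMR-visible before hydrolysis.
    "pdtx_liver_like": {
        "name": "pdtx_liver_like",
        "tracer": "13C6",
        "labeling": {
            "f_unlabeled": 0.463,
            "f_direct": 0.376,
            "f_scrambled": 0.161,
            "scramble_retention": 0.5,
        },
        "glucose_labeling": {
            "f_unlabeled": 0.12,
            "f_direct": 0.85,
            "f_scrambled": 0.03,
            "scramble_retention": 0.5,
        },
        "glycogen_ug": 44.8,
        "free_glucose_nmol": 40.0,
        "protein_mg": 1.0,
        "nmr_visible_fraction": 0.855,
        "hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "standard_hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "spike_nmol": 100.0,
        "dss_mM": 0.5,
        "volume_uL": 50.0,
        "normalization": "residue_weight",
    },
    # Cancerous lung organotypic slice culture in 2H7-glucose: 6.3 of 43.3
    # ug/mg fully labeled (15% enrichment), light scrambling via PPP.
    "otc_cancer_like": {
        "name": "otc_cancer_like",
        "tracer": "2H7",
        "labeling": {
            "f_unlabeled": 0.8245,
            "f_direct": 0.1455,
            "f_scrambled": 0.03,
            "scramble_retention": 0.4,
        },
        "glucose_labeling": {
            "f_unlabeled": 0.25,
            "f_direct": 0.72,
            "f_scrambled": 0.03,
            "scramble_retention": 0.4,
        },
        "glycogen_ug": 43.3,
        "free_glucose_nmol": 25.0,
        "protein_mg": 1.0,
        "nmr_visible_fraction": 0.8,
        "hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "standard_hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "spike_nmol": 80.0,
        "dss_mM": 0.5,
        "volume_uL": 50.0,
        "normalization": "protein",
    },
    # Matched non-cancerous slice: less total glycogen, higher turnover
    # (5.9 of 21.3 ug/mg fully labeled, 27% enrichment), more scrambling.
    "otc_noncancer_like": {
        "name": "otc_noncancer_like",
        "tracer": "2H7",
        "labeling": {
            "f_unlabeled": 0.683,
            "f_direct": 0.277,
            "f_scrambled": 0.04,
            "scramble_retention": 0.4,
        },
        "glucose_labeling": {
            "f_unlabeled": 0.25,
            "f_direct": 0.71,
            "f_scrambled": 0.04,
            "scramble_retention": 0.4,
        },
        "glycogen_ug": 21.3,
        "free_glucose_nmol": 20.0,
        "protein_mg": 1.0,
        "nmr_visible_fraction": 0.8,
        "hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "standard_hydrolysis": {"temperature_C": 110.0, "time_min": 10.0},
        "spike_nmol": 80.0,
        "dss_mM": 0.5,
        "volume_uL": 50.0,
        "normalization": "protein",
    },
}


def get_scenario(name: str) -> dict:
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    return copy.deepcopy(SCENARIOS[name])
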