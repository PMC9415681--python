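"""End-to-end orchestration: synthetic or file-based runs, reports, QC.

``run_pipeline`` realizes the workflow order of the wet protocol: NMR on the
intact extract, then acid hydrolysis, then FTMS (and optionally NMR) on the
hydrolysate, then the glycogen computation chain. Runs are deterministic
given config + seed; every numeric parameter used lands in the run log.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import glycogen as gly
from .ftms import QuantResult, quantify_spectrum
from .isotopes import IsotopologueSpecies, enumerate_species
from .nmr import (
    ShiftWindow,
    ShiftWindowSet,
    WindowCollisionError,
    fraction_13C,
    integrate_pool,
    integrate_window,
    quantify_vs_dss,
)
from .scenarios import get_scenario
from .spectra import Spectrum, read_mzml, read_peak_csv
from .synth import (
    DEFAULT_HYDROLYSIS_MODEL,
    GLUCOSE_PER_GLYCOGEN_NMOL_PER_UG,
    HydrolysisModel,
    LabelingScenario,
    SpectrumSynthConfig,
    TRACERS,
    simulate_hydrolysis,
    simulate_labeling,
    synthesize_ftms_spectrum,
    synthesize_nmr_spectrum,
)

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "run_pipeline",
    "qc_summary",
]

DUAL_STANDARD = IsotopologueSpecies(n13C=6, n2H=7)
C13_STANDARD = IsotopologueSpecies(n13C=6)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and sample id."""

    def __init__(self, stage: str, sample: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {original}")
        self.stage = stage
        self.sample = sample
        self.original = original


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``mode`` is 'simulate' (scenario-driven synthetic run; seed mandatory)
    or 'analyze' (file-based; all referenced paths must exist).
    """

    mode: str = "simulate"
    scenario: str | dict | None = "beas2b_like"
    inputs: dict | None = None
    out_dir: str | Path | None = None
    seed: int | None = None
    synth: SpectrumSynthConfig = field(default_factory=SpectrumSynthConfig)
    hydrolysis_model: HydrolysisModel = field(
        default_factory=lambda: DEFAULT_HYDROLYSIS_MODEL
    )
    tolerance_ppm: float = 5.0
    snr_threshold: float = 5.0
    standard_glycogen_ug: float = 100.0
    write_spectra: bool = False

    def resolved_scenario(self) -> dict:
        if isinstance(self.scenario, dict):
            return dict(self.scenario)
        if isinstance(self.scenario, str):
            if self.scenario.endswith(".json"):
                path = Path(self.scenario)
                if not path.exists():
                    raise FileNotFoundError(f"scenario file not found: {path}")
                return json.loads(path.read_text())
            return get_scenario(self.scenario)
        raise ValueError("simulate mode requires a scenario")


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def _labeling_fractions(
    tracer: str | None, labeling: dict | None
) -> tuple[list[IsotopologueSpecies], np.ndarray]:
    if tracer is None:
        return enumerate_species(set()), np.array([1.0])
    scenario = LabelingScenario(tracer=tracer, **labeling)
    return simulate_labeling(scenario)


def _f_at_c1(tracer: str | None, species, fractions) -> float:
    """13C fraction at C1 implied by an isotopologue distribution (uniform
    positional placement within each isotopologue)."""
    if tracer != "13C6":
        return 0.0
    n = TRACERS[tracer]["n_positions"]
    return float(sum(f * sp.n13C / n for sp, f in zip(species, fractions)))


def _h1_visible_fraction(tracer: str | None, species, fractions) -> float:
    """Fraction of molecules still carrying a proton (not 2H) at H1; 2H at
    the anomeric position removes the molecule from the 1H anomeric signal."""
    if tracer != "2H7":
        return 1.0
    n = TRACERS[tracer]["n_positions"]
    return float(sum(f * (1.0 - sp.n2H / n) for sp, f in zip(species, fractions)))


def _windows_for(config: RunConfig) -> ShiftWindowSet:
    return ShiftWindowSet(
        windows={
            "glycogen_H1a": ShiftWindow(5.41, 0.022),
            "glucose_H1a": ShiftWindow(5.22, 0.022),
            "glucose_H1b": ShiftWindow(4.64, 0.022),
            "dss": ShiftWindow(0.0, 0.022),
        },
        jch_hz=config.synth.jch_hz,
        spectrometer_mhz=config.synth.spectrometer_mhz,
    )


def _quantify_nmr(
    spectrum: Spectrum,
    windows: ShiftWindowSet,
    dss_mM: float,
    volume_uL: float,
) -> dict:
    """Window integrals -> per-pool amounts (nmol) and enrichments."""
    expanded = windows.expanded()
    dss_integral = integrate_window(spectrum, expanded["dss"])
    out: dict = {"dss_integral": dss_integral}
    glyc = integrate_pool(spectrum, windows, "glycogen_H1a")
    alpha = integrate_pool(spectrum, windows, "glucose_H1a")
    beta = integrate_pool(spectrum, windows, "glucose_H1b")
    out["glycogen_nmol"] = quantify_vs_dss(
        glyc.I_12C + glyc.I_13C, 1, dss_integral, dss_mM, volume_uL
    )
    # Anomeric windows each see one proton of their anomer sub-pool
    # (alpha:beta = 1:2 at equilibrium), so total glucose is 3x the alpha
    # amount or 1.5x the beta amount.
    glucose_alpha = quantify_vs_dss(
        alpha.I_12C + alpha.I_13C, 1, dss_integral, dss_mM, volume_uL
    )
    glucose_beta = quantify_vs_dss(
        beta.I_12C + beta.I_13C, 1, dss_integral, dss_mM, volume_uL
    )
    out["glucose_nmol_from_H1a"] = 3.0 * glucose_alpha
    out["glucose_nmol_from_H1b"] = 1.5 * glucose_beta
    out["anomer_ratio"] = (
        (alpha.I_12C + alpha.I_13C) / (beta.I_12C + beta.I_13C)
        if (beta.I_12C + beta.I_13C) > 0
        else float("nan")
    )
    for name, integ in (("glycogen", glyc), ("glucose_H1a", alpha), ("glucose_H1b", beta)):
        try:
            out[f"F_{name}"] = fraction_13C(integ)
        except ValueError:
            out[f"F_{name}"] = float("nan")
    return out


def _simulate_stages(config: RunConfig) -> dict:
    if config.seed is None:
        raise ValueError("simulate mode requires a seed")
    scen = config.resolved_scenario()
    sample = scen.get("name", "scenario")
    seeds = _child_seeds(config.seed, 4)
    tracer = scen.get("tracer")
    synth = config.synth

    glyc_species, glyc_fracs = _labeling_fractions(tracer, scen.get("labeling"))
    glc_species, glc_fracs = _labeling_fractions(
        tracer, scen.get("glucose_labeling") or scen.get("labeling")
    )
    spike_species = C13_STANDARD if tracer is None else DUAL_STANDARD
    spike_nmol = float(scen["spike_nmol"])
    volume = float(scen.get("volume_uL", 50.0))
    dss_mM = float(scen.get("dss_mM", 0.5))

    # --- pre-hydrolysis FTMS: free glucose only ---
    free_glucose = float(scen.get("free_glucose_nmol", 0.0))
    pre_amounts = {
        sp: free_glucose * f for sp, f in zip(glc_species, glc_fracs) if f > 0
    }
    pre_cfg = dataclasses.replace(synth, seed=seeds[0])
    pre_spectrum = synthesize_ftms_spectrum(pre_amounts, (spike_species, spike_nmol), pre_cfg)
    pre_quant = quantify_spectrum(
        pre_spectrum,
        glc_species,
        spike_species,
        spike_nmol,
        resolving_power=synth.resolving_power,
        reference_mz=synth.reference_mz,
        snr_threshold=config.snr_threshold,
        tolerance_ppm=config.tolerance_ppm,
        stage="pre_hydrolysis",
    )

    # --- pre-hydrolysis NMR: intact (NMR-visible) glycogen + free glucose ---
    visible_frac = float(scen.get("nmr_visible_fraction", 1.0))
    glycogen_ug = float(scen["glycogen_ug"])
    glyc_visible_nmol = (
        visible_frac * glycogen_ug * GLUCOSE_PER_GLYCOGEN_NMOL_PER_UG
    )
    nmr_cfg = dataclasses.replace(synth, seed=seeds[1])
    pre_nmr_spectrum = synthesize_nmr_spectrum(
        {
            "glycogen": {
                "conc_mM": glyc_visible_nmol
                * _h1_visible_fraction(tracer, glyc_species, glyc_fracs)
                / volume,
                "F": _f_at_c1(tracer, glyc_species, glyc_fracs),
            },
            "glucose": {
                "conc_mM": free_glucose
                * _h1_visible_fraction(tracer, glc_species, glc_fracs)
                / volume,
                "F": _f_at_c1(tracer, glc_species, glc_fracs),
            },
        },
        dss_mM,
        nmr_cfg,
    )
    windows = _windows_for(config)
    pre_nmr = _quantify_nmr(pre_nmr_spectrum, windows, dss_mM, volume)

    # --- hydrolysis-efficiency standard run ---
    hyd_cond = scen.get("standard_hydrolysis", scen["hydrolysis"])
    standard = simulate_hydrolysis(
        config.standard_glycogen_ug,
        hyd_cond["temperature_C"],
        hyd_cond["time_min"],
        config.hydrolysis_model,
    )
    efficiency = standard["recovery_fraction"]

    # --- sample hydrolysis and post-hydrolysis FTMS ---
    hyd = simulate_hydrolysis(
        glycogen_ug,
        scen["hydrolysis"]["temperature_C"],
        scen["hydrolysis"]["time_min"],
        config.hydrolysis_model,
    )
    released = hyd["glucose_nmol"]
    post_species = glyc_species if tracer is not None else glc_species
    post_amounts: dict[IsotopologueSpecies, float] = {}
    for sp, f in zip(glc_species, glc_fracs):
        if f > 0:
            post_amounts[sp] = post_amounts.get(sp, 0.0) + free_glucose * f
    for sp, f in zip(glyc_species, glyc_fracs):
        if f > 0:
            post_amounts[sp] = post_amounts.get(sp, 0.0) + released * f
    post_cfg = dataclasses.replace(synth, seed=seeds[2])
    post_spectrum = synthesize_ftms_spectrum(
        post_amounts, (spike_species, spike_nmol), post_cfg
    )
    post_quant = quantify_spectrum(
        post_spectrum,
        post_species,
        spike_species,
        spike_nmol,
        resolving_power=synth.resolving_power,
        reference_mz=synth.reference_mz,
        snr_threshold=config.snr_threshold,
        tolerance_ppm=config.tolerance_ppm,
        stage="post_hydrolysis",
    )

    # --- post-hydrolysis NMR: all glucose, no glycogen left ---
    post_total_true = free_glucose + released
    combined_fracs = np.zeros(len(post_species))
    for i, sp in enumerate(post_species):
        combined_fracs[i] = post_amounts.get(sp, 0.0) / post_total_true
    post_nmr_cfg = dataclasses.replace(synth, seed=seeds[3])
    post_nmr_spectrum = synthesize_nmr_spectrum(
        {
            "glucose": {
                "conc_mM": post_total_true
                * _h1_visible_fraction(tracer, post_species, combined_fracs)
                / volume,
                "F": _f_at_c1(tracer, post_species, combined_fracs),
            },
        },
        dss_mM,
        post_nmr_cfg,
    )
    post_nmr = _quantify_nmr(post_nmr_spectrum, windows, dss_mM, volume)

    return {
        "sample": sample,
        "tracer": tracer,
        "scenario": scen,
        "seeds": seeds,
        "efficiency": efficiency,
        "pre_quant": pre_quant,
        "post_quant": post_quant,
        "pre_nmr": pre_nmr,
        "post_nmr": post_nmr,
        "spike_nmol": spike_nmol,
        "protein_mg": scen.get("protein_mg"),
        "normalization": scen.get("normalization", "protein"),
        "spectra": {
            "ftms_pre": pre_spectrum,
            "ftms_post": post_spectrum,
            "nmr_pre": pre_nmr_spectrum,
            "nmr_post": post_nmr_spectrum,
        },
        "truth": {
            "glycogen_ug": glycogen_ug,
            "recovery_fraction": hyd["recovery_fraction"],
            "released_nmol": released,
        },
    }


def _read_spectrum(path: str | Path, kind: str) -> Spectrum:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input spectrum not found: {path}")
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    return read_peak_csv(path, kind=kind)


def _analyze_stages(config: RunConfig) -> dict:
    inputs = config.inputs or {}
    for key in ("ftms_pre", "ftms_post"):
        if key not in inputs:
            raise ValueError(f"analyze mode requires input path {key!r}")
    tracer = inputs.get("tracer")
    spike_nmol = float(inputs["spike_nmol"])
    spike_species = C13_STANDARD if tracer is None else DUAL_STANDARD
    species = (
        enumerate_species(set())
        if tracer is None
        else enumerate_species({TRACERS[tracer]["element"]})
    )
    quants = {}
    spectra = {}
    for stage, key in (("pre_hydrolysis", "ftms_pre"), ("post_hydrolysis", "ftms_post")):
        spectrum = _read_spectrum(inputs[key], "mz")
        spectra[key] = spectrum
        quants[stage] = quantify_spectrum(
            spectrum,
            species,
            spike_species,
            spike_nmol,
            resolving_power=config.synth.resolving_power,
            reference_mz=config.synth.reference_mz,
            snr_threshold=config.snr_threshold,
            tolerance_ppm=config.tolerance_ppm,
            stage=stage,
        )
    windows = _windows_for(config)
    nmr_results = {}
    for key in ("nmr_pre", "nmr_post"):
        if key in inputs:
            spectrum = _read_spectrum(inputs[key], "ppm")
            spectra[key] = spectrum
            nmr_results[key] = _quantify_nmr(
                spectrum,
                windows,
                float(inputs.get("dss_mM", 0.5)),
                float(inputs.get("volume_uL", 50.0)),
            )
    return {
        "sample": inputs.get("sample", "sample"),
        "tracer": tracer,
        "scenario": None,
        "seeds": [],
        "efficiency": float(inputs["hydrolysis_efficiency"]),
        "pre_quant": quants["pre_hydrolysis"],
        "post_quant": quants["post_hydrolysis"],
        "pre_nmr": nmr_results.get("nmr_pre"),
        "post_nmr": nmr_results.get("nmr_post"),
        "spike_nmol": spike_nmol,
        "protein_mg": inputs.get("protein_mg"),
        "normalization": inputs.get("normalization", "protein"),
        "spectra": spectra,
        "truth": None,
    }


def _full_label(tracer: str | None) -> str | None:
    if tracer is None:
        return None
    n = TRACERS[tracer]["n_positions"]
    return f"13C{n}" if tracer == "13C6" else f"2H{n}"


def _report_from_stages(stages: dict) -> gly.GlycogenReport:
    pre: QuantResult = stages["pre_quant"]
    post: QuantResult = stages["post_quant"]
    net = gly.net_glucose(post.total_nmol, pre.total_nmol)
    report = gly.glycogen_from_glucose(
        net,
        stages["efficiency"],
        stages["protein_mg"],
        normalization=stages["normalization"],
    )

    # Species-wise glycogen-derived split: post minus pre, clipped at zero.
    tracer = stages["tracer"]
    if tracer is not None:
        pre_by_label = {sp.label: a for sp, a in zip(pre.species, pre.amounts_nmol)}
        net_by_label = {
            sp.label: max(a - pre_by_label.get(sp.label, 0.0), 0.0)
            for sp, a in zip(post.species, post.amounts_nmol)
        }
        total = sum(net_by_label.values())
        full = _full_label(tracer)
        if total > 0:
            unlabeled = net_by_label.get("M0", 0.0)
            direct = net_by_label.get(full, 0.0)
            scrambled = total - unlabeled - direct
            report.split_percent = {
                "unlabeled": 100.0 * unlabeled / total,
                "fully_labeled": 100.0 * direct / total,
                "scrambled": 100.0 * scrambled / total,
            }
            report.enrichment_percent = gly.fractional_enrichment(
                total - unlabeled, unlabeled
            )

    pre_nmr = stages.get("pre_nmr")
    if pre_nmr is not None and report.corrected_glycogen_ug > 0:
        visible_ug = pre_nmr["glycogen_nmol"] / gly.glucose_equivalent_constant()
        report.nmr_visible_percent = gly.nmr_visible_fraction(
            visible_ug, report.corrected_glycogen_ug
        )
    return report


def qc_summary(
    report: gly.GlycogenReport,
    stages: dict,
    anomer_tolerance: float = 0.2,
    spike_ratio_limits: tuple[float, float] = (0.1, 10.0),
) -> pd.DataFrame:
    """Quality-control checks; flags problems, never aborts.

    Checks: anomer integral ratio within 20% of the equilibrium 1:2; spike
    within 10-fold of the tallest analyte signal; non-negative net glucose;
    satellite windows free of collisions.
    """
    rows = []
    for key in ("pre_nmr", "post_nmr"):
        nmr = stages.get(key)
        if not nmr:
            continue
        ratio = nmr.get("anomer_ratio")
        if ratio is not None and np.isfinite(ratio) and ratio > 0:
            dev = abs(ratio - 0.5) / 0.5
            rows.append(
                {
                    "check": f"anomer_ratio_{key}",
                    "value": ratio,
                    "flag": bool(dev > anomer_tolerance),
                    "detail": "alpha/beta integral ratio vs equilibrium 0.5",
                }
            )
    for key in ("pre_quant", "post_quant"):
        quant: QuantResult = stages[key]
        tallest = float(quant.amounts_nmol.max()) if quant.amounts_nmol.size else 0.0
        if tallest > 0:
            ratio = stages["spike_nmol"] / tallest
            rows.append(
                {
                    "check": f"spike_ratio_{key}",
                    "value": ratio,
                    "flag": bool(
                        not spike_ratio_limits[0] <= ratio <= spike_ratio_limits[1]
                    ),
                    "detail": "spike nmol / tallest analyte nmol, target within 10-fold",
                }
            )
    rows.append(
        {
            "check": "net_glucose_nonnegative",
            "value": report.net_glucose_nmol,
            "flag": bool(report.net_glucose_nmol < 0),
            "detail": "post minus pre hydrolysis glucose",
        }
    )
    try:
        _windows_for_stage = ShiftWindowSet(
            windows={
                "glycogen_H1a": ShiftWindow(5.41, 0.022),
                "glucose_H1a": ShiftWindow(5.22, 0.022),
                "glucose_H1b": ShiftWindow(4.64, 0.022),
                "dss": ShiftWindow(0.0, 0.022),
            }
        )
        collision = False
    except WindowCollisionError:
        collision = True
    rows.append(
        {
            "check": "satellite_window_collision",
            "value": float(collision),
            "flag": collision,
            "detail": "integration windows intersect after satellite expansion",
        }
    )
    return pd.DataFrame(rows, columns=["check", "value", "flag", "detail"])


def _table_frame(report: gly.GlycogenReport, stages: dict) -> pd.DataFrame:
    pre: QuantResult = stages["pre_quant"]
    post: QuantResult = stages["post_quant"]
    rows = {
        "Pre-Hydrolysis Glucose (nmol)": pre.total_nmol,
        "Post-Hydrolysis Glucose (nmol)": post.total_nmol,
        "Average Glycogen (ug)": report.glycogen_ug,
        "Average Hydrolysis Efficiency (%)": 100.0 * report.hydrolysis_efficiency,
        "Corrected Glycogen (ug)": report.corrected_glycogen_ug,
    }
    if report.glycogen_per_mg_ug is not None:
        rows["Glycogen per mg protein (ug/mg)"] = report.glycogen_per_mg_ug
    return pd.DataFrame(
        {"quantity": list(rows), "FTMS": [round(v, 1) for v in rows.values()]}
    )


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> tuple[gly.GlycogenReport, dict]:
    """Execute one run and return (report, artifacts).

    Artifacts hold the per-stage quantification results, QC table, run log
    and (in simulate mode) the synthetic spectra. When ``config.out_dir``
    is set, the report (JSON + Table-shaped CSV), per-stage quant tables,
    QC table and log are written there; spectra too when
    ``config.write_spectra`` is enabled.
    """
    if config.mode not in ("simulate", "analyze"):
        raise ValueError(f"unknown mode {config.mode!r}")
    stage_fn = _simulate_stages if config.mode == "simulate" else _analyze_stages
    sample = "unknown"
    try:
        if config.mode == "simulate" and isinstance(config.scenario, (str, dict)):
            resolved = (
                config.scenario.get("name", "scenario")
                if isinstance(config.scenario, dict)
                else config.scenario
            )
            sample = str(resolved)
        stages = stage_fn(config)
        sample = stages["sample"]
    except (PipelineStageError,):
        raise
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context added
        raise PipelineStageError("acquisition", sample, exc) from exc

    try:
        report = _report_from_stages(stages)
        qc = qc_summary(report, stages)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("glycogen_calc", sample, exc) from exc

    log = {
        "sample": sample,
        "mode": config.mode,
        "seed": config.seed,
        "child_seeds": stages["seeds"],
        "tolerance_ppm": config.tolerance_ppm,
        "snr_threshold": config.snr_threshold,
        "standard_glycogen_ug": config.standard_glycogen_ug,
        "glucose_equivalent_umol_per_mg": gly.glucose_equivalent_constant(),
        "synth": dataclasses.asdict(config.synth),
        "hydrolysis_model": dataclasses.asdict(config.hydrolysis_model),
        "scenario": stages["scenario"],
        "hydrolysis_efficiency": stages["efficiency"],
        "spike_nmol": stages["spike_nmol"],
        "protein_mg": stages["protein_mg"],
    }
    artifacts = {
        "stages": stages,
        "qc": qc,
        "log": log,
        "report_dict": report.rounded(),
        "table": _table_frame(report, stages),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(_json_ready(report.rounded()), indent=2, sort_keys=True) + "\n"
        )
        artifacts["table"].to_csv(out / "report_table.csv", index=False)
        stages["pre_quant"].to_frame().to_csv(out / "quant_pre.csv", index=False)
        stages["post_quant"].to_frame().to_csv(out / "quant_post.csv", index=False)
        qc.to_csv(out / "qc.csv", index=False)
        (out / "log.json").write_text(
            json.dumps(_json_ready(log), indent=2, sort_keys=True) + "\n"
        )
        if config.write_spectra:
            for name, spectrum in stages.get("spectra", {}).items():
                spectrum.to_csv(out / f"{name}.csv")
    return report, artifacts
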