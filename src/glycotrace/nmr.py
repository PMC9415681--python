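"""1D 1H-NMR integration, 13C-satellite fractional enrichment, and absolute
quantification against the DSS reference.

Windows follow the anomeric-region assignments: glycogen H1-alpha at
5.41 ppm, free glucose (+ Glc-6-P) H1-alpha at 5.22 ppm and H1-beta at
4.64 ppm (equilibrium ratio 1:2), DSS at 0 ppm. Each 13C-attached proton is
flanked by satellite doublets at +/- 1J_CH / 2; the fractional enrichment is
F = I(13C) / [I(13C) + I(12C)].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum

__all__ = [
    "ShiftWindow",
    "ShiftWindowSet",
    "NMRSatelliteIntegrals",
    "WindowCollisionError",
    "DEFAULT_WINDOWS",
    "integrate_window",
    "fraction_13C",
    "quantify_vs_dss",
    "satellite_windows",
    "integrate_pool",
]

DSS_PROTONS = 9  # trimethyl reference


class WindowCollisionError(ValueError):
    """Integration windows intersect after satellite expansion."""


@dataclass(frozen=True)
class ShiftWindow:
    center_ppm: float
    halfwidth_ppm: float

    @property
    def lo(self) -> float:
        return self.center_ppm - self.halfwidth_ppm

    @property
    def hi(self) -> float:
        return self.center_ppm + self.halfwidth_ppm

    def overlaps(self, other: "ShiftWindow") -> bool:
        return self.lo < other.hi and other.lo < self.hi

    def shifted(self, delta_ppm: float) -> "ShiftWindow":
        return ShiftWindow(self.center_ppm + delta_ppm, self.halfwidth_ppm)


@dataclass
class ShiftWindowSet:
    """Named central windows plus derived satellite windows.

    Satellite windows sit at +/- 1J_CH / (2 * spectrometer frequency) around
    each anomeric center with the same halfwidth. Construction fails if any
    windows intersect after satellite expansion (overlapping satellites, e.g.
    glycogen vs glucose H1-alpha at low field, need 2D methods that are out
    of scope here).
    """

    windows: dict[str, ShiftWindow]
    jch_hz: float = 170.0
    spectrometer_mhz: float = 600.0
    satellite_parents: tuple[str, ...] = (
        "glycogen_H1a",
        "glucose_H1a",
        "glucose_H1b",
    )

    def __post_init__(self) -> None:
        expanded = self.expanded()
        names = list(expanded)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if expanded[a].overlaps(expanded[b]):
                    raise WindowCollisionError(
                        f"windows {a} ({expanded[a].lo:.3f}-{expanded[a].hi:.3f} ppm) and "
                        f"{b} ({expanded[b].lo:.3f}-{expanded[b].hi:.3f} ppm) intersect"
                    )

    @property
    def satellite_offset_ppm(self) -> float:
        return 0.5 * self.jch_hz / self.spectrometer_mhz

    def expanded(self) -> dict[str, ShiftWindow]:
        out = dict(self.windows)
        for name in self.satellite_parents:
            if name not in self.windows:
                continue
            center = self.windows[name]
            out[f"{name}_sat_lo"] = center.shifted(-self.satellite_offset_ppm)
            out[f"{name}_sat_hi"] = center.shifted(+self.satellite_offset_ppm)
        return out


DEFAULT_WINDOWS = ShiftWindowSet(
    windows={
        "glycogen_H1a": ShiftWindow(5.41, 0.022),
        "glucose_H1a": ShiftWindow(5.22, 0.022),
        "glucose_H1b": ShiftWindow(4.64, 0.022),
        "dss": ShiftWindow(0.0, 0.022),
    }
)


@dataclass(frozen=True)
class NMRSatelliteIntegrals:
    """Central and summed-satellite integrals for one anomeric window."""

    I_12C: float
    I_13C: float
    window: str

    def __post_init__(self) -> None:
        if self.I_12C < 0 or self.I_13C < 0:
            raise ValueError("integrals must be non-negative")


def integrate_window(spectrum: Spectrum, window: ShiftWindow) -> float:
    """Trapezoidal integral over a window after subtracting the linear
    baseline through the window endpoints.

    Each baseline anchor is the mean of the outermost ~10% of window points
    (at least 3), not a single sample: a lone noisy endpoint would be
    multiplied by the full window width and dominate the integral error.
    """
    if spectrum.kind != "ppm":
        raise ValueError("NMR integration requires a ppm-axis spectrum")
    axis = spectrum.axis
    if window.lo < axis[0] or window.hi > axis[-1]:
        raise ValueError(
            f"window {window.lo:.3f}-{window.hi:.3f} ppm outside spectrum "
            f"range {axis[0]:.3f}-{axis[-1]:.3f} ppm"
        )
    lo = np.searchsorted(axis, window.lo)
    hi = np.searchsorted(axis, window.hi, side="right")
    x = axis[lo:hi]
    y = spectrum.intensity[lo:hi]
    if x.size < 2:
        return 0.0
    edge = max(3, x.size // 10)
    edge = min(edge, x.size // 2)
    if edge >= 1:
        x_lo, y_lo = float(x[:edge].mean()), float(y[:edge].mean())
        x_hi, y_hi = float(x[-edge:].mean()), float(y[-edge:].mean())
    else:
        x_lo, y_lo, x_hi, y_hi = float(x[0]), float(y[0]), float(x[-1]), float(y[-1])
    slope = (y_hi - y_lo) / (x_hi - x_lo) if x_hi != x_lo else 0.0
    baseline = y_lo + slope * (x - x_lo)
    return float(np.trapezoid(y - baseline, x))


def satellite_windows(
    window: ShiftWindow, jch_hz: float, spectrometer_mhz: float
) -> tuple[ShiftWindow, ShiftWindow]:
    off = 0.5 * jch_hz / spectrometer_mhz
    return window.shifted(-off), window.shifted(+off)


def integrate_pool(
    spectrum: Spectrum,
    window_set: ShiftWindowSet,
    name: str,
) -> NMRSatelliteIntegrals:
    """Central + satellite integrals for one named anomeric window.

    Noise can push an integral slightly negative after baseline
    subtraction; values are floored at zero since the integrals feed the
    non-negative enrichment ratio.
    """
    expanded = window_set.expanded()
    central = integrate_window(spectrum, expanded[name])
    sat = 0.0
    for suffix in ("_sat_lo", "_sat_hi"):
        key = f"{name}{suffix}"
        if key in expanded:
            sat += integrate_window(spectrum, expanded[key])
    return NMRSatelliteIntegrals(
        I_12C=max(central, 0.0), I_13C=max(sat, 0.0), window=name
    )


def fraction_13C(integrals: NMRSatelliteIntegrals) -> float:
    """Satellite-based fractional enrichment F = I(13C)/[I(13C)+I(12C)]."""
    total = integrals.I_12C + integrals.I_13C
    if total <= 0:
        raise ValueError(
            f"window {integrals.window}: both integrals zero; enrichment undefined"
        )
    return integrals.I_13C / total


def quantify_vs_dss(
    analyte_integral: float,
    n_protons: int,
    dss_integral: float,
    dss_mM: float,
    volume_uL: float,
) -> float:
    """Absolute amount (nmol) from the per-proton integral ratio to DSS.

    concentration = dss_mM * (I_analyte / n_protons) / (I_dss / 9);
    nmol = concentration (mM) x volume (uL).
    """
    if dss_integral <= 0:
        raise ValueError("DSS integral must be positive")
    if n_protons <= 0 or dss_mM <= 0 or volume_uL <= 0:
        raise ValueError("proton count, DSS concentration and volume must be positive")
    conc_mM = dss_mM * (analyte_integral / n_protons) / (dss_integral / DSS_PROTONS)
    return conc_mM * volume_uL
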