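"""Glycogen content and enrichment computation chain.

net glucose = post-hydrolysis glucose - pre-hydrolysis glucose
glycogen (ug) = net glucose (nmol) / 6.17 (nmol glucose per ug glycogen)
corrected glycogen = glycogen / hydrolysis efficiency (glycogen standard run)
per-protein = corrected glycogen / mg protein

The 6.17 constant is the glucose-residue equivalent of glycogen: one
polymerized residue weighs glucose (180.06 g/mol) minus water (18.01 g/mol)
= 162.05 g/mol, i.e. 1000/162.05 = 6.17 umol glucose per mg glycogen.
Enrichment summaries (12C vs fully labeled vs scrambled split, percent
enrichment, NMR-visible fraction) are derived alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GlycogenQuantInput",
    "GlycogenReport",
    "GLUCOSE_MW",
    "WATER_MW",
    "glucose_equivalent_constant",
    "glucose_equivalent_unrounded",
    "net_glucose",
    "glycogen_from_glucose",
    "fractional_enrichment",
    "nmr_visible_fraction",
]

GLUCOSE_MW = 180.06  # g/mol
WATER_MW = 18.01  # g/mol


def glucose_equivalent_constant() -> float:
    """umol glucose per mg glycogen, rounded to 2 decimals: 6.17."""
    return round(glucose_equivalent_unrounded(), 2)


def glucose_equivalent_unrounded() -> float:
    return 1000.0 / (GLUCOSE_MW - WATER_MW)


def net_glucose(
    post_nmol: float, pre_nmol: float, pre_below_loq: bool = False
) -> float:
    """Glycogen-derived glucose released by hydrolysis.

    A pre-hydrolysis value flagged below the limit of quantification is
    treated as zero. A negative result is allowed (the caller flags it);
    it is never clipped silently.
    """
    if pre_below_loq:
        pre_nmol = 0.0
    return post_nmol - pre_nmol


@dataclass(frozen=True)
class GlycogenQuantInput:
    """Inputs to the glycogen computation chain for one sample."""

    pre_hydrolysis_glucose_nmol: float
    post_hydrolysis_glucose_nmol: float
    hydrolysis_efficiency: float
    protein_mg: float | None = None
    pre_below_loq: bool = False
    normalization: str = "protein"  # or "residue_weight"

    def __post_init__(self) -> None:
        if not 0 < self.hydrolysis_efficiency <= 1.2:
            raise ValueError(
                "hydrolysis efficiency must be in (0, 1.2]; values above 1 "
                "reflect standard-run variability and are allowed with a flag"
            )
        if self.protein_mg is not None and self.protein_mg <= 0:
            raise ValueError("protein mass must be positive when given")

    @property
    def efficiency_above_unity(self) -> bool:
        return self.hydrolysis_efficiency > 1.0


@dataclass
class GlycogenReport:
    """The computation-chain outputs plus enrichment summaries.

    Masses in ug, enrichments as percent. ``flags`` collects warnings
    (negative net glucose, efficiency above 1, pre below LoQ) rather than
    silently altering values.
    """

    net_glucose_nmol: float
    glycogen_ug: float
    corrected_glycogen_ug: float
    glycogen_per_mg_ug: float | None
    normalization: str
    hydrolysis_efficiency: float
    split_percent: dict[str, float] = field(default_factory=dict)
    enrichment_percent: float | None = None
    nmr_visible_percent: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.split_percent:
            total = sum(self.split_percent.values())
            if abs(total - 100.0) > 0.1:
                raise ValueError(f"split percentages sum to {total}, expected 100")

    def rounded(self) -> dict:
        """Table-style view: masses and percentages at 1 decimal."""
        out = {
            "net_glucose_nmol": round(self.net_glucose_nmol, 1),
            "glycogen_ug": round(self.glycogen_ug, 1),
            "corrected_glycogen_ug": round(self.corrected_glycogen_ug, 1),
            "hydrolysis_efficiency_percent": round(100 * self.hydrolysis_efficiency, 1),
            "normalization": self.normalization,
            "flags": list(self.flags),
        }
        if self.glycogen_per_mg_ug is not None:
            out["glycogen_per_mg_ug"] = round(self.glycogen_per_mg_ug, 1)
        if self.split_percent:
            out["split_percent"] = {
                k: round(v, 1) for k, v in self.split_percent.items()
            }
        if self.enrichment_percent is not None:
            out["enrichment_percent"] = round(self.enrichment_percent, 1)
        if self.nmr_visible_percent is not None:
            out["nmr_visible_percent"] = round(self.nmr_visible_percent)
        return out


def glycogen_from_glucose(
    net_nmol: float,
    efficiency: float,
    protein_mg: float | None = None,
    normalization: str = "protein",
) -> GlycogenReport:
    """Run the chain net glucose -> glycogen -> efficiency correction ->
    per-mg normalization. Negative net glucose propagates with a flag."""
    if efficiency <= 0:
        raise ValueError("hydrolysis efficiency must be positive")
    const = glucose_equivalent_constant()
    glycogen_ug = net_nmol / const
    corrected = glycogen_ug / efficiency
    per_mg = corrected / protein_mg if protein_mg else None
    flags = []
    if net_nmol < 0:
        flags.append("negative_net_glucose")
    if efficiency > 1.0:
        flags.append("efficiency_above_unity")
    return GlycogenReport(
        net_glucose_nmol=net_nmol,
        glycogen_ug=glycogen_ug,
        corrected_glycogen_ug=corrected,
        glycogen_per_mg_ug=per_mg,
        normalization=normalization,
        hydrolysis_efficiency=efficiency,
        flags=flags,
    )


def fractional_enrichment(labeled: float, unlabeled: float) -> float:
    """Percent of the pool carrying tracer label: 100 * L / (L + U)."""
    total = labeled + unlabeled
    if total <= 0:
        raise ValueError("labeled + unlabeled must be positive")
    if labeled < 0 or unlabeled < 0:
        raise ValueError("amounts must be non-negative")
    return 100.0 * labeled / total


def nmr_visible_fraction(visible_ug: float, total_ug: float) -> float:
    """Percent of total (hydrolysis-determined) glycogen that is mobile
    enough to be seen by solution NMR before hydrolysis."""
    if total_ug <= 0:
        raise ValueError("total glycogen must be positive")
    if visible_ug < 0:
        raise ValueError("NMR-visible glycogen must be non-negative")
    return 100.0 * visible_ug / total_ug
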