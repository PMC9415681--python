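"""Multi-tracer glucose isotopologues: enumeration, exact masses, isotopic
fine structure and mass-spectrometric resolvability.

Glucose (C6H12O6) carries 6 labelable carbons but only 7 labelable hydrogens:
the 5 hydroxyl protons exchange with aqueous solvent during workup and can
never retain a deuterium label, which is why the heaviest deuterated tracer
species is 2H7-glucose. 13C and 2H substitutions shift the monoisotopic mass
by +1.0033548 and +1.0062767 Da respectively; the resulting 2.9 mDa gap
between 13C1 and 2H1 isotopologues is what ultra-high resolving power FTMS
separates.

Isotope masses and abundances are a fixed IUPAC-2021 table embedded below so
every derived number in this package is reproducible from source.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

from scipy.stats import binom

__all__ = [
    "ElementIsotopeTable",
    "IsotopologueSpecies",
    "FineStructureLine",
    "FineStructure",
    "UnsupportedTracerError",
    "DEFAULT_ISOTOPE_TABLE",
    "FORMULAS",
    "LABELABLE_POSITIONS",
    "ADDUCT_MASSES",
    "MASS_SHIFT_13C",
    "MASS_SHIFT_2H",
    "enumerate_species",
    "exact_mass",
    "natural_abundance_fine_structure",
    "resolvable",
    "fwhm_at",
    "min_resolving_power",
]


class UnsupportedTracerError(ValueError):
    """Raised when a tracer element outside {13C, 2H} is requested."""


@dataclass(frozen=True)
class ElementIsotopeTable:
    """Per-element (isotope mass Da, natural abundance) entries.

    Invariants enforced at construction: abundances sum to 1 within 1e-9 per
    element, and isotope masses are strictly increasing.
    """

    isotopes: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for element, entries in self.isotopes.items():
            total = sum(a for _, a in entries)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{element}: abundances sum to {total!r}, expected 1"
                )
            masses = [m for m, _ in entries]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"{element}: isotope masses not increasing")

    def monoisotopic(self, element: str) -> float:
        return self.isotopes[element][0][0]

    def abundances(self, element: str) -> tuple[float, ...]:
        return tuple(a for _, a in self.isotopes[element])

    def __getitem__(self, element: str) -> tuple[tuple[float, float], ...]:
        return self.isotopes[element]


# IUPAC 2021 atomic masses (Da) and representative natural abundances.
DEFAULT_ISOTOPE_TABLE = ElementIsotopeTable(
    {
        "C": ((12.0, 0.9893), (13.003354835, 0.0107)),
        "H": ((1.0078250319, 0.999885), (2.0141017781, 0.000115)),
        "O": (
            (15.9949146196, 0.99757),
            (16.9991317565, 0.00038),
            (17.9991596129, 0.00205),
        ),
        "N": ((14.0030740044, 0.99636), (15.0001088989, 0.00364)),
        "P": ((30.9737619986, 1.0),),
    }
)

PROTON_MASS = 1.007276466621
ELECTRON_MASS = 0.000548579909
_NA_MASS = 22.9897692820

MASS_SHIFT_13C = DEFAULT_ISOTOPE_TABLE["C"][1][0] - DEFAULT_ISOTOPE_TABLE["C"][0][0]
MASS_SHIFT_2H = DEFAULT_ISOTOPE_TABLE["H"][1][0] - DEFAULT_ISOTOPE_TABLE["H"][0][0]
MASS_SHIFT_15N = DEFAULT_ISOTOPE_TABLE["N"][1][0] - DEFAULT_ISOTOPE_TABLE["N"][0][0]
_MASS_SHIFT_17O = DEFAULT_ISOTOPE_TABLE["O"][1][0] - DEFAULT_ISOTOPE_TABLE["O"][0][0]
_MASS_SHIFT_18O = DEFAULT_ISOTOPE_TABLE["O"][2][0] - DEFAULT_ISOTOPE_TABLE["O"][0][0]

# Charge-carrier mass differences for singly charged ions.
ADDUCT_MASSES = {
    "M+H": PROTON_MASS,
    "M+Na": _NA_MASS - ELECTRON_MASS,
    "M-H": -PROTON_MASS,
}

# The four metabolites this package quantifies or monitors; no general
# formula decomposition is attempted.
FORMULAS: dict[str, dict[str, int]] = {
    "glucose": {"C": 6, "H": 12, "O": 6},
    "udp_glucose": {"C": 15, "H": 24, "N": 2, "O": 17, "P": 2},
    "hmf": {"C": 6, "H": 6, "O": 3},
    "levulinic_acid": {"C": 5, "H": 8, "O": 3},
}

# (labelable carbons, labelable non-exchangeable hydrogens) per metabolite.
LABELABLE_POSITIONS: dict[str, tuple[int, int]] = {
    "glucose": (6, 7),
    "udp_glucose": (15, 14),
    "hmf": (6, 5),
    "levulinic_acid": (5, 7),
}

_TRACER_ELEMENTS = {"13C", "2H"}


@dataclass(frozen=True, order=True)
class IsotopologueSpecies:
    """One glucose (or related metabolite) labeling state.

    ``n13C``/``n2H`` count tracer-derived heavy atoms; ``n2H`` counts only
    non-exchangeable (C-bound) positions. ``exact_mass`` is the adduct ion
    mass computed by :func:`exact_mass`.
    """

    sort_index: float = field(init=False, repr=False)
    n13C: int = 0
    n2H: int = 0
    n15N: int = 0
    adduct: str = "M+H"
    formula: str = "glucose"

    def __post_init__(self) -> None:
        n_c, n_h = LABELABLE_POSITIONS[self.formula]
        if not 0 <= self.n13C <= n_c:
            raise ValueError(f"n13C={self.n13C} outside 0..{n_c} for {self.formula}")
        if not 0 <= self.n2H <= n_h:
            raise ValueError(f"n2H={self.n2H} outside 0..{n_h} for {self.formula}")
        if self.n15N < 0 or self.n15N > FORMULAS[self.formula].get("N", 0):
            raise ValueError(f"n15N={self.n15N} invalid for {self.formula}")
        if self.adduct not in ADDUCT_MASSES:
            raise ValueError(f"unknown adduct {self.adduct!r}")
        object.__setattr__(self, "sort_index", exact_mass(self))

    @property
    def exact_mass(self) -> float:
        return self.sort_index

    @property
    def label(self) -> str:
        parts = []
        if self.n13C:
            parts.append(f"13C{self.n13C}")
        if self.n2H:
            parts.append(f"2H{self.n2H}")
        if self.n15N:
            parts.append(f"15N{self.n15N}")
        return "+".join(parts) if parts else "M0"


def _neutral_monoisotopic(formula: str, table: ElementIsotopeTable) -> float:
    return sum(
        n * table.monoisotopic(el) for el, n in FORMULAS[formula].items()
    )


def exact_mass(
    species: IsotopologueSpecies,
    table: ElementIsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> float:
    """Exact ion mass (Da) of a labeled species: neutral monoisotopic mass
    plus heavy-atom shifts plus the adduct mass."""
    mass = _neutral_monoisotopic(species.formula, table)
    mass += species.n13C * MASS_SHIFT_13C
    mass += species.n2H * MASS_SHIFT_2H
    mass += species.n15N * MASS_SHIFT_15N
    return mass + ADDUCT_MASSES[species.adduct]


def enumerate_species(
    tracer_elements: set[str] | frozenset[str],
    adduct: str = "M+H",
    formula: str = "glucose",
) -> list[IsotopologueSpecies]:
    """All isotopologues reachable from the given tracer elements.

    The enumeration is the full cartesian product over labelable positions
    ((n_C + 1) x (n_H + 1) species when both elements are traced), sorted by
    exact mass.
    """
    unsupported = set(tracer_elements) - _TRACER_ELEMENTS
    if unsupported:
        raise UnsupportedTracerError(
            f"unsupported tracer element(s) {sorted(unsupported)}; "
            f"supported: {sorted(_TRACER_ELEMENTS)}"
        )
    n_c, n_h = LABELABLE_POSITIONS[formula]
    c_range = range(n_c + 1) if "13C" in tracer_elements else range(1)
    h_range = range(n_h + 1) if "2H" in tracer_elements else range(1)
    species = [
        IsotopologueSpecies(n13C=nc, n2H=nh, adduct=adduct, formula=formula)
        for nc, nh in itertools.product(c_range, h_range)
    ]
    return sorted(species, key=lambda s: s.exact_mass)


@dataclass(frozen=True)
class FineStructureLine:
    """One natural-abundance line of a species: heavy-isotope composition at
    the non-tracer positions, its exact mass, and its probability."""

    composition: tuple[tuple[str, int], ...]
    mass: float
    probability: float


@dataclass(frozen=True)
class FineStructure:
    """Floored natural-abundance fine structure of one species."""

    species: IsotopologueSpecies
    lines: tuple[FineStructureLine, ...]
    dropped_probability: float
    renormalized: bool

    def total_probability(self) -> float:
        return sum(line.probability for line in self.lines)


def _binom_pmf(n: int, p: float) -> list[float]:
    return [float(binom.pmf(k, n, p)) for k in range(n + 1)]


def natural_abundance_fine_structure(
    species: IsotopologueSpecies,
    probability_floor: float = 1e-6,
    renormalize: bool = False,
    table: ElementIsotopeTable = DEFAULT_ISOTOPE_TABLE,
) -> FineStructure:
    """Natural-abundance fine structure of one labeled species.

    Tracer-substituted positions are fixed; the remaining C, H (including
    exchangeable H), O and N positions vary multinomially with natural
    abundances. Lines below ``probability_floor`` are dropped; the dropped
    probability mass is reported and, only when ``renormalize`` is set, the
    kept lines are rescaled to sum to 1.
    """
    if not 0 < probability_floor < 1:
        raise ValueError("probability_floor must be in (0, 1)")
    formula = FORMULAS[species.formula]
    free = {
        "C": formula.get("C", 0) - species.n13C,
        "H": formula.get("H", 0) - species.n2H,
        "O": formula.get("O", 0),
        "N": formula.get("N", 0) - species.n15N,
    }
    base_mass = species.exact_mass

    # Per-element distributions over heavy-substitution counts.
    per_element: list[list[tuple[tuple[tuple[str, int], ...], float, float]]] = []
    ab_c = table.abundances("C")
    per_element.append(
        [
            ((("13C", k),) if k else (), p, k * MASS_SHIFT_13C)
            for k, p in enumerate(_binom_pmf(free["C"], ab_c[1]))
        ]
    )
    ab_h = table.abundances("H")
    per_element.append(
        [
            ((("2H", k),) if k else (), p, k * MASS_SHIFT_2H)
            for k, p in enumerate(_binom_pmf(free["H"], ab_h[1]))
        ]
    )
    if free["N"]:
        ab_n = table.abundances("N")
        per_element.append(
            [
                ((("15N", k),) if k else (), p, k * MASS_SHIFT_15N)
                for k, p in enumerate(_binom_pmf(free["N"], ab_n[1]))
            ]
        )
    # Oxygen: three isotopes, trinomial over (n16, n17, n18).
    n_o = free["O"]
    ab_o = table.abundances("O")
    o_terms = []
    for k17 in range(n_o + 1):
        for k18 in range(n_o + 1 - k17):
            k16 = n_o - k17 - k18
            p = (
                math.comb(n_o, k17)
                * math.comb(n_o - k17, k18)
                * ab_o[0] ** k16
                * ab_o[1] ** k17
                * ab_o[2] ** k18
            )
            comp = []
            if k17:
                comp.append(("17O", k17))
            if k18:
                comp.append(("18O", k18))
            o_terms.append((tuple(comp), p, k17 * _MASS_SHIFT_17O + k18 * _MASS_SHIFT_18O))
    per_element.append(o_terms)

    lines: list[FineStructureLine] = []
    dropped = 0.0
    for combo in itertools.product(*per_element):
        prob = math.prod(term[1] for term in combo)
        if prob < probability_floor:
            dropped += prob
            continue
        comp = tuple(item for term in combo for item in term[0])
        mass = base_mass + sum(term[2] for term in combo)
        lines.append(FineStructureLine(comp, mass, prob))
    lines.sort(key=lambda ln: ln.mass)
    if renormalize and lines:
        kept = sum(ln.probability for ln in lines)
        lines = [replace(ln, probability=ln.probability / kept) for ln in lines]
    return FineStructure(
        species=species,
        lines=tuple(lines),
        dropped_probability=dropped,
        renormalized=renormalize,
    )


def fwhm_at(mz: float, resolving_power: float, reference_mz: float = 200.0) -> float:
    """Peak FWHM (Da) at a given m/z for an FT analyzer whose resolving power
    is quoted at ``reference_mz`` and falls off as 1/sqrt(m/z) (Orbitrap
    convention): FWHM(m) = m / (R_ref * sqrt(ref/m))."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    return mz / (resolving_power * math.sqrt(reference_mz / mz))


def resolvable(
    m1: float,
    m2: float,
    resolving_power: float,
    reference_mz: float = 200.0,
) -> bool:
    """True iff two masses are separated by at least one FWHM at their mean."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    delta = abs(m1 - m2)
    if delta == 0:
        return False
    return delta >= fwhm_at(0.5 * (m1 + m2), resolving_power, reference_mz)


def min_resolving_power(
    m1: float, m2: float, reference_mz: float = 200.0
) -> float:
    """Smallest reference-m/z resolving power that separates two masses
    (closed form of the :func:`resolvable` threshold)."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    delta = abs(m1 - m2)
    if delta == 0:
        return math.inf
    mean = 0.5 * (m1 + m2)
    return mean**1.5 / (delta * math.sqrt(reference_mz))
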