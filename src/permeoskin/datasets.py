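"""Published permeability tables and permeant descriptors used as inputs.

These are literature values for transdermal permeation of metronidazole,
caffeine and naproxen with different permeation enhancers: log10 K_P (cm/h)
from in vitro measurements and from stacked-bilayer-model calculations,
with one standard error where reported, plus the enhancement ratios (ER)
printed alongside them. They serve as worked-example inputs for the ER
arithmetic; the package does not recompute the underlying free-energy
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TableRow:
    """One formulation row of a permeability table.

    ``log_kp``/``stderr`` in log10(cm/h); ``er_printed`` is the published
    enhancement ratio relative to the table's reference row (None when not
    reported). ``is_reference`` marks the formulation ERs are taken against.
    """

    formulation: str
    log_kp: float
    stderr: float | None
    er_printed: float | None
    is_reference: bool = False


#: Calculated metronidazole permeabilities, saturated aqueous formulations.
METRONIDAZOLE_CALCULATED = [
    TableRow("water", -3.79, 0.24, 1, is_reference=True),
    TableRow("lauric acid (16 inserted)", -3.73, 0.23, 1),
    TableRow("lauric acid (24 inserted)", -2.97, 0.30, 7),
    TableRow("geraniol", -2.74, 0.21, 11),
    TableRow("stearic acid", -3.79, 0.24, 1),
    TableRow("thymol", -1.39, 0.26, 256),
]

#: In vitro metronidazole permeabilities for the same formulations (the
#: thymol measurement never reached steady state and is reported only as a
#: bound, so it is omitted here).
METRONIDAZOLE_IN_VITRO = [
    TableRow("water", -2.89, 0.03, 1, is_reference=True),
    TableRow("lauric acid (16 inserted)", -1.78, 0.07, 13),
    TableRow("geraniol", -2.17, 0.04, 5),
    TableRow("stearic acid", -2.80, 0.03, 1),
]

#: Calculated caffeine permeabilities; reference is pure water.
CAFFEINE_CALCULATED = [
    TableRow("water", -3.00, 0.21, 1, is_reference=True),
    TableRow("water/ethanol", -2.28, 0.24, 5),
    TableRow("oleic acid (18 inserted)", -1.92, 0.18, 12),
    TableRow("oleic acid (36 inserted)", -2.21, 0.20, 6),
    TableRow("eucalyptol (26 inserted)", -2.64, 0.23, 2),
    TableRow("eucalyptol (52 inserted)", -2.00, 0.25, 10),
]

#: In vitro caffeine permeabilities.
CAFFEINE_IN_VITRO = [
    TableRow("water", -4.15, 0.04, 1.0, is_reference=True),
    TableRow("water/ethanol", -3.50, 0.02, 4.5),
    TableRow("oleic acid (18 inserted)", -1.91, 0.02, 175),
    TableRow("eucalyptol (26 inserted)", -1.99, 0.01, 148),
]

#: Calculated naproxen permeabilities; reference is the 40/60 water/ethanol
#: vehicle.
NAPROXEN_CALCULATED = [
    TableRow("water/ethanol", -2.85, 0.10, 1, is_reference=True),
    TableRow("oleic acid (18 inserted)", -2.39, 0.13, 3),
    TableRow("oleic acid (36 inserted)", -1.68, 0.11, 15),
    TableRow("eucalyptol (26 inserted)", -2.46, 0.11, 3),
    TableRow("eucalyptol (52 inserted)", -2.02, 0.17, 7),
]

#: In vitro naproxen permeabilities.
NAPROXEN_IN_VITRO = [
    TableRow("water/ethanol", -3.34, 0.07, 1.0, is_reference=True),
    TableRow("oleic acid (18 inserted)", -1.73, 0.02, 41),
    TableRow("eucalyptol (26 inserted)", -2.44, 0.04, 7.9),
]

ALL_TABLES: dict[str, list[TableRow]] = {
    "metronidazole_calculated": METRONIDAZOLE_CALCULATED,
    "metronidazole_in_vitro": METRONIDAZOLE_IN_VITRO,
    "caffeine_calculated": CAFFEINE_CALCULATED,
    "caffeine_in_vitro": CAFFEINE_IN_VITRO,
    "naproxen_calculated": NAPROXEN_CALCULATED,
    "naproxen_in_vitro": NAPROXEN_IN_VITRO,
}

#: Aqueous pKa of naproxen (weak acid) and the pH span of the studied
#: formulations.
NAPROXEN_PKA = 4.19
NAPROXEN_FORMULATION_PH_RANGE = (2.9, 4.8)

#: Pure liquid thymol: density (g/cm^3) and molar mass (g/mol); the number
#: density of the pure liquid is a reference concentration for local
#: enhancer packing.
THYMOL_DENSITY = 0.97
THYMOL_MOLAR_MASS = 150.22

#: Water bookkeeping of the skin bilayer model: waters inserted from a pure
#: water vehicle, and waters already resident in the model.
WATERS_INSERTED_FROM_PURE_WATER = 100
WATERS_RESIDENT = 90

#: Formulation-referenced PMF minima (kJ/mol) of two permeants in water,
#: used by the flux-design worked examples.
NAPROXEN_WATER_PMF_MIN = -5.4
CAFFEINE_WATER_PMF_MIN = -13.0

#: Stepwise insertion escalation series actually simulated.
LAURIC_ACID_SERIES = (16, 24)     # +50% per step
OLEIC_ACID_SERIES = (18, 36, 54)  # x2, x3 of the planned 18
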