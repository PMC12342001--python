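"""Flush and perfusate media.

Two media are bundled: a reduced University of Wisconsin (UW) flush
(adenosine + glutathione + water) used before static cold storage, and a
reduced Williams Medium E (WME) used during machine perfusion.  Component
rows carry both the published per-cell amounts and the mass-concentration /
molar-mass data they were derived from; where a published molarity is not
reproducible from g/L divided by molar mass the row is stored as printed
and flagged ``as_printed`` rather than silently corrected, and the
recomputed value remains available through
:func:`molarity_from_mass_conc`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

__all__ = [
    "MediumComponent",
    "Medium",
    "molarity_from_mass_conc",
    "uw_solution",
    "williams_medium_e",
    "save_medium_tsv",
    "load_medium_tsv",
]

#: UW per-cell conversion implied by its table: amount/concentration, nmol/(cell mM)
UW_PERCELL_VOLUME = 1e-4
#: WME per-cell conversion implied by its table, nmol/(cell mM)
WME_PERCELL_VOLUME = 1.0 / 9.0


def molarity_from_mass_conc(mass_conc: float, mw: float) -> float:
    """Molarity (mM) from a mass concentration (g/L) and molar mass (g/mol):
    1000 * mass_conc / mw."""
    if mw <= 0:
        raise ValueError(f"molar mass must be positive, got {mw}")
    if mass_conc < 0:
        raise ValueError(f"mass concentration must be nonnegative, got {mass_conc}")
    return 1000.0 * mass_conc / mw


@dataclass(frozen=True)
class MediumComponent:
    species: str  # chemical name resolved against Species.name in the network
    amount: float  # nmol/cell actually supplied to the simulation
    molarity: Optional[float] = None  # mM, as published
    mass_conc: Optional[float] = None  # g/L
    mw: Optional[float] = None  # g/mol
    as_printed: bool = False  # published molarity disagrees with g/L / MW


@dataclass
class Medium:
    """A named medium: component list plus its own amount<->concentration
    conversion factor (the two source tables imply different factors, so
    each medium carries its own)."""

    name: str
    components: List[MediumComponent] = field(default_factory=list)
    percell_volume: float = WME_PERCELL_VOLUME  # nmol per (cell mM)

    def amount(self, species: str) -> float:
        for c in self.components:
            if c.species == species:
                return c.amount
        return 0.0

    def amounts(self) -> Dict[str, float]:
        return {c.species: c.amount for c in self.components}

    def with_amount(self, species: str, amount: float) -> "Medium":
        """Copy of the medium with one component's amount replaced (adding
        the component if absent).  Used for supplementation studies."""
        comps = []
        found = False
        for c in self.components:
            if c.species == species:
                comps.append(MediumComponent(species=species, amount=amount))
                found = True
            else:
                comps.append(c)
        if not found:
            comps.append(MediumComponent(species=species, amount=amount))
        return Medium(self.name, comps, self.percell_volume)


def uw_solution() -> Medium:
    """Reduced University of Wisconsin flush: adenosine and glutathione
    (the functionally important constituents) in water."""
    return Medium(
        name="UW",
        percell_volume=UW_PERCELL_VOLUME,
        components=[
            MediumComponent("glutathione", amount=0.0003, molarity=3.0),
            MediumComponent("adenosine", amount=0.0005, molarity=5.0),
            MediumComponent("water", amount=5.54),
        ],
    )


def williams_medium_e() -> Medium:
    """Reduced Williams Medium E perfusate, rows as published.

    ``as_printed=True`` marks rows whose published molarity is not equal
    (to table precision) to 1000*g/L / MW; both values are preserved.
    """
    rows = [
        # species, g/L, MW, amount nmol/cell, molarity mM, as_printed
        ("glucose", 2.0, 180.06, 1.2340, 11.074, True),
        ("glutamine", 0.292, 146.07, 0.2221, 1.9990, False),
        ("glutathione", 0.00005, 307.08, 2.22e-5, 0.00247, True),
        ("L-serine", 0.01, 105.04, 0.1057, 0.9520, True),
        ("glycine", 0.05, 75.03, 0.0740, 0.6664, False),
        ("L-alanine", 0.09, 89.09, 0.1122, 1.0102, False),
        ("L-arginine", 0.05, 174.11, 0.0319, 0.2872, False),
        ("L-aspartate", 0.03, 133.04, 0.0250, 0.2254, True),
        ("L-cysteine", 0.04, 121.02, 0.0367, 0.3306, True),
        ("bicarbonate", 2.0, 60.99, 3.6432, 32.6943, True),
    ]
    comps = [
        MediumComponent(
            species=s, amount=amt, molarity=mol, mass_conc=gl, mw=mw, as_printed=flag
        )
        for s, gl, mw, amt, mol, flag in rows
    ]
    # solvent: sized so mole fractions track molarities (55.5 M water)
    comps.append(MediumComponent("water", amount=55.5e3 * WME_PERCELL_VOLUME))
    # perfusate gases: oxygenated (~0.5 mM dissolved O2) and equilibrated
    # with a low-CO2 sweep gas (~0.4 mM), held at set-point by the circuit
    comps.append(MediumComponent("oxygen", amount=0.5 * WME_PERCELL_VOLUME, molarity=0.5))
    comps.append(MediumComponent("co2", amount=0.4 * WME_PERCELL_VOLUME, molarity=0.4))
    return Medium("WME", comps, WME_PERCELL_VOLUME)


_TSV_FIELDS = ["species", "mass_conc_g_L", "mw_g_mol", "amount_nmol_cell", "molarity_mM", "as_printed"]


def save_medium_tsv(medium: Medium, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["# medium", medium.name, "percell_volume", repr(medium.percell_volume)])
        w.writerow(_TSV_FIELDS)
        for c in medium.components:
            w.writerow(
                [
                    c.species,
                    "" if c.mass_conc is None else repr(c.mass_conc),
                    "" if c.mw is None else repr(c.mw),
                    repr(c.amount),
                    "" if c.molarity is None else repr(c.molarity),
                    int(c.as_printed),
                ]
            )


def load_medium_tsv(path: str | Path) -> Medium:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header = rows[0]
    name, percell = header[1], float(header[3])
    comps = []
    for row in rows[2:]:
        if not row:
            continue
        comps.append(
            MediumComponent(
                species=row[0],
                mass_conc=float(row[1]) if row[1] else None,
                mw=float(row[2]) if row[2] else None,
                amount=float(row[3]),
                molarity=float(row[4]) if row[4] else None,
                as_printed=bool(int(row[5])),
            )
        )
    return Medium(name, comps, percell)
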