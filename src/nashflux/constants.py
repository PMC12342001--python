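"""Physical constants and unit conversions shared across the package.

Internal unit conventions:

* formation energies/enthalpies: kJ/mol at the reference temperature ``T0``
* species amounts: nmol per cell
* temperature: kelvin internally, degrees Celsius at user interfaces
* concentrations: mM at interfaces, molar (M) for ROS bands
"""

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Reference temperature for formation data, K.
T0 = 298.0

#: 0 degrees Celsius in kelvin.
CELSIUS_OFFSET = 273.15

#: Molar concentration of pure water, mM (55.5 M). Used to size the solvent
#: pool so that mole fractions map onto molarities in dilute compartments.
WATER_MM = 55.5e3


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


def energy_per_cell(kj_per_mol: float, nmol_per_cell: float) -> float:
    """Energy turnover per cell (kJ/cell) for a molar reaction energy
    applied to a per-cell amount.

    1 nmol = 1e-9 mol, so ``kJ/mol * nmol/cell`` carries a factor 1e-9.
    """
    return kj_per_mol * nmol_per_cell * 1e-9
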