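"""Reduced liver metabolic network with self-consistent fixture
thermodynamics.

The network is a deliberately small, fully balanced stand-in for a
whole-liver reconstruction.  It covers every pathway the perfusion
analysis touches:

* lumped glycolysis (glucose -> lactate, net ATP),
* lumped Krebs cycle (lactate oxidation to CO2 with substrate-level ATP
  and NADH export) and oxidative phosphorylation (O2-consuming ATP
  synthesis from NADH),
* purine degradation (adenosine -> hypoxanthine -> xanthine -> urate)
  whose xanthine-oxidase steps release superoxide during hypoxia,
* the superoxide dismutase / catalase / glutathione-peroxidase redox
  triad, written exactly in its textbook stoichiometry,
* glutathione transport and regeneration (disulfide reduction),
* malonyl-unit synthesis (irreversible committed step) and a lumped
  fatty-acid synthesis step that consumes ATP,
* mevalonate synthesis (the bile-production proxy),
* the adenylate pool (adenylate kinase + an ATP-consuming maintenance
  load) and a CO2/bicarbonate buffer that carries pH.

Formation energies are fixture data: a handful of species carry
literature-scale anchor values and every other species is derived from a
target standard reaction energy, so the network is thermodynamically
self-consistent by construction and key anchors (glutathione-peroxidase
reaction enthalpy of -196 kJ/mol, ATP hydrolysis near -30 kJ/mol) hold
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .network import MetabolicNetwork, NetworkNode
from .thermo import Reaction, Species, parse_formula, reaction_delta

__all__ = ["ReactionTargets", "build_reduced_liver_network", "build_initial_amounts"]


#: Transformed-convention proton potential (kJ/mol): mu0 such that the
#: proton's standard term cancels its ideal-mixing term at pH 7.4 in a
#: 55.5 M aqueous pool.  This is the mole-fraction analogue of transformed
#: (pH-buffered) biochemical formation energies; all reaction targets below
#: are then physiological driving forces at the pH 7.4 operating point.
import math as _math

from .constants import R_GAS as _R, T0 as _T0, WATER_MM as _WATER_MM

PROTON_MU0 = -_R * 1e-3 * _T0 * _math.log(10 ** (-7.4) * 1e3 / _WATER_MM)


@dataclass(frozen=True)
class ReactionTargets:
    """Target standard reaction energies (kJ/mol at 298 K) used to derive
    fixture formation data.  Each pair is (DeltaG0, DeltaH0)."""

    glycolysis: Tuple[float, float] = (-80.0, -120.0)
    atp_hydrolysis: Tuple[float, float] = (-30.0, -20.0)
    adenylate_kinase: Tuple[float, float] = (0.5, -5.0)
    nadh_oxidation: Tuple[float, float] = (-220.0, -240.0)
    pdh: Tuple[float, float] = (-15.0, -25.0)
    catalase: Tuple[float, float] = (-190.0, -196.0)
    sod: Tuple[float, float] = (-116.0, -80.0)
    gpx: Tuple[float, float] = (-100.0, -196.0)
    acc: Tuple[float, float] = (-25.0, -15.0)
    fas: Tuple[float, float] = (-60.0, -90.0)
    mevalonate: Tuple[float, float] = (-100.0, -180.0)
    xo_step: Tuple[float, float] = (-30.0, -50.0)
    #: CO2 + H2O = HCO3- + H+ in the transformed convention; sets pH
    bicarbonate_buffer: Tuple[float, float] = (-6.9, -13.0)


#: anchor formation data (dGf0, dHf0, kJ/mol): literature-scale values for
#: common species, arbitrary-but-fixed anchors for large cofactors whose
#: absolute formation energies never matter (only reaction deltas do).
_ANCHORS: Dict[str, Tuple[float, float]] = {
    "water": (-237.2, -285.8),
    "oxygen": (0.0, 0.0),
    # set after module constants: transformed (pH-buffered) convention
    "proton": (None, 0.0),  # type: ignore[dict-item]
    "co2": (-394.4, -393.5),
    "glucose": (-917.0, -1264.0),
    "phosphate": (-1096.0, -1299.0),
    "adp": (-1906.0, -2000.0),
    "nad": (-1000.0, -1100.0),
    "glutathione": (-900.0, -1200.0),
    "adenosine": (-194.0, -621.0),
    "hypoxanthine": (89.5, -110.8),
    "ribose": (-742.0, -1047.0),
    "ammonia": (-26.5, -80.3),
    # inert medium amino acids (no reactions; values only for completeness)
    "glutamine": (-529.0, -805.0),
    "L-serine": (-510.0, -730.0),
    "glycine": (-370.0, -530.0),
    "L-alanine": (-371.0, -560.0),
    "L-arginine": (-240.0, -620.0),
    "L-aspartate": (-700.0, -945.0),
    "L-cysteine": (-340.0, -530.0),
}
_ANCHORS["proton"] = (0.0, 0.0)

#: chemical name -> (formula, charge)
_CHEMS: Dict[str, Tuple[str, int]] = {
    "water": ("H2O", 0),
    "oxygen": ("O2", 0),
    "proton": ("H", 1),
    "co2": ("CO2", 0),
    "bicarbonate": ("CHO3", -1),
    "glucose": ("C6H12O6", 0),
    "lactate": ("C3H5O3", -1),
    "phosphate": ("HO4P", -2),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "amp": ("C10H12N5O7P", -2),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "glutathione": ("C10H18N3O6S", 1),
    "gssg": ("C20H34N6O12S2", 2),
    "superoxide": ("O2", -1),
    "h2o2": ("H2O2", 0),
    "adenosine": ("C10H13N5O4", 0),
    "hypoxanthine": ("C5H4N4O", 0),
    "xanthine": ("C5H4N4O2", 0),
    "urate": ("C5H3N4O3", -1),
    "ribose": ("C5H10O5", 0),
    "ammonia": ("H3N", 0),
    "acetate": ("C2H3O2", -1),
    "malonate": ("C3H2O4", -2),
    "octanoate": ("C8H15O2", -1),
    "mevalonate": ("C6H11O4", -1),
    "glutamine": ("C5H10N2O3", 0),
    "L-serine": ("C3H7NO3", 0),
    "glycine": ("C2H5NO2", 0),
    "L-alanine": ("C3H7NO2", 0),
    "L-arginine": ("C6H14N4O2", 0),
    "L-aspartate": ("C4H7NO4", 0),
    "L-cysteine": ("C3H7NO2S", 0),
}


def _derive_formation(targets: ReactionTargets) -> Dict[str, Tuple[float, float]]:
    """Derive formation data for non-anchor chemicals from the target
    standard reaction energies, one unknown chemical per target."""
    f = dict(_ANCHORS)

    def g(n):  # noqa: ANN001 - local shorthand
        return f[n][0]

    def h(n):
        return f[n][1]

    def solve(name, dG, dH):
        f[name] = (dG, dH)

    # 2 H2O2 = 2 H2O + O2  (catalase)
    dG, dH = targets.catalase
    solve("h2o2", (2 * g("water") + g("oxygen") - dG) / 2, (2 * h("water") + h("oxygen") - dH) / 2)
    # 2 O2- + 2 H+ = H2O2 + O2  (superoxide dismutase)
    dG, dH = targets.sod
    solve(
        "superoxide",
        (g("h2o2") + g("oxygen") - dG) / 2 - g("proton"),
        (h("h2o2") + h("oxygen") - dH) / 2 - h("proton"),
    )
    # 2 GSH + H2O2 = GSSG + 2 H2O  (glutathione peroxidase; dH anchored -196)
    dG, dH = targets.gpx
    solve(
        "gssg",
        dG + 2 * g("glutathione") + g("h2o2") - 2 * g("water"),
        dH + 2 * h("glutathione") + h("h2o2") - 2 * h("water"),
    )
    # ATP + H2O = ADP + Pi + H+  (hydrolysis approx -30 kJ/mol)
    dG, dH = targets.atp_hydrolysis
    solve(
        "atp",
        g("adp") + g("phosphate") + g("proton") - g("water") - dG,
        h("adp") + h("phosphate") + h("proton") - h("water") - dH,
    )
    # 2 ADP = ATP + AMP  (adenylate kinase)
    dG, dH = targets.adenylate_kinase
    solve("amp", 2 * g("adp") - g("atp") + dG, 2 * h("adp") - h("atp") + dH)
    # NADH + H+ + 1/2 O2 = NAD+ + H2O
    dG, dH = targets.nadh_oxidation
    solve(
        "nadh",
        g("nad") + g("water") - g("proton") - dG,
        h("nad") + h("water") - h("proton") - dH,
    )
    # glucose + 2 ADP + 2 Pi = 2 lactate + 2 ATP + 2 H2O
    dG, dH = targets.glycolysis
    solve(
        "lactate",
        (dG + g("glucose") + 2 * g("adp") + 2 * g("phosphate") - 2 * g("atp") - 2 * g("water")) / 2,
        (dH + h("glucose") + 2 * h("adp") + 2 * h("phosphate") - 2 * h("atp") - 2 * h("water")) / 2,
    )
    # lactate + H2O + 2 NAD+ = acetate + CO2 + 2 NADH + 2 H+
    dG, dH = targets.pdh
    solve(
        "acetate",
        dG + g("lactate") + g("water") + 2 * g("nad") - g("co2") - 2 * g("nadh") - 2 * g("proton"),
        dH + h("lactate") + h("water") + 2 * h("nad") - h("co2") - 2 * h("nadh") - 2 * h("proton"),
    )
    # acetate + HCO3- + ATP = malonate + ADP + Pi + H+   (needs bicarbonate first)
    dG, dH = targets.bicarbonate_buffer
    solve(
        "bicarbonate",
        g("co2") + g("water") + dG - g("proton"),
        h("co2") + h("water") + dH - h("proton"),
    )
    dG, dH = targets.acc
    solve(
        "malonate",
        dG + g("acetate") + g("bicarbonate") + g("atp") - g("adp") - g("phosphate") - g("proton"),
        dH + h("acetate") + h("bicarbonate") + h("atp") - h("adp") - h("phosphate") - h("proton"),
    )
    # 4 malonate + 6 NADH + 4 ATP + 9 H+ = octanoate + 4 CO2 + 6 NAD+ + 2 H2O + 4 ADP + 4 Pi
    dG, dH = targets.fas
    solve(
        "octanoate",
        dG
        + 4 * g("malonate") + 6 * g("nadh") + 4 * g("atp") + 9 * g("proton")
        - 4 * g("co2") - 6 * g("nad") - 2 * g("water") - 4 * g("adp") - 4 * g("phosphate"),
        dH
        + 4 * h("malonate") + 6 * h("nadh") + 4 * h("atp") + 9 * h("proton")
        - 4 * h("co2") - 6 * h("nad") - 2 * h("water") - 4 * h("adp") - 4 * h("phosphate"),
    )
    # 3 acetate + 2 NADH + 4 H+ = mevalonate + 2 NAD+ + 2 H2O
    dG, dH = targets.mevalonate
    solve(
        "mevalonate",
        dG + 3 * g("acetate") + 2 * g("nadh") + 4 * g("proton") - 2 * g("nad") - 2 * g("water"),
        dH + 3 * h("acetate") + 2 * h("nadh") + 4 * h("proton") - 2 * h("nad") - 2 * h("water"),
    )
    # hypoxanthine + H2O + 2 O2 = xanthine + 2 O2- + 2 H+
    dG, dH = targets.xo_step
    solve(
        "xanthine",
        dG + g("hypoxanthine") + g("water") - 2 * g("superoxide") - 2 * g("proton"),
        dH + h("hypoxanthine") + h("water") - 2 * h("superoxide") - 2 * h("proton"),
    )
    # xanthine + H2O + 2 O2 = urate- + 2 O2- + 3 H+
    solve(
        "urate",
        dG + g("xanthine") + g("water") - 2 * g("superoxide") - 3 * g("proton"),
        dH + h("xanthine") + h("water") - 2 * h("superoxide") - 3 * h("proton"),
    )
    # Apply the transformed-convention proton potential *after* the chain:
    # every target above is then the driving force of its reaction at the
    # pH 7.4 operating point, where the proton's standard and ideal-mixing
    # terms cancel exactly.
    f["proton"] = (PROTON_MU0, 0.0)
    return f


# species ids are "<chem key>_<compartment letter>"
def _sid(chem: str, comp: str) -> str:
    short = {
        "water": "h2o", "oxygen": "o2", "proton": "h", "glutathione": "gsh",
        "phosphate": "pi", "glucose": "glc", "lactate": "lac", "adenosine": "ado",
        "hypoxanthine": "hx", "xanthine": "xan", "urate": "ura", "ribose": "rib",
        "ammonia": "nh3", "acetate": "ac", "malonate": "mal", "octanoate": "octa",
        "mevalonate": "mev", "superoxide": "sox", "bicarbonate": "hco3",
        "glutamine": "gln", "L-serine": "ser", "glycine": "gly", "L-alanine": "ala",
        "L-arginine": "arg", "L-aspartate": "asp", "L-cysteine": "cys",
    }.get(chem, chem)
    return f"{short}_{comp}"


def build_reduced_liver_network(targets: ReactionTargets | None = None) -> MetabolicNetwork:
    """Deterministic reduced liver network (3 compartments, 10 nodes,
    ~30 reactions including transport edges), validated at build time."""
    targets = targets or ReactionTargets()
    formation = _derive_formation(targets)

    # (chem, compartments it lives in)
    placement = [
        ("water", "ecm"), ("oxygen", "ecm"), ("proton", "cm"),
        ("glucose", "ec"), ("lactate", "c"), ("phosphate", "c"),
        ("atp", "c"), ("adp", "c"), ("amp", "c"),
        ("nad", "m"), ("nadh", "m"), ("co2", "em"), ("bicarbonate", "ec"),
        ("glutathione", "ecm"), ("gssg", "m"),
        ("superoxide", "cm"), ("h2o2", "m"),
        ("adenosine", "ec"), ("hypoxanthine", "c"), ("xanthine", "c"),
        ("urate", "c"), ("ribose", "c"), ("ammonia", "c"),
        ("acetate", "c"), ("malonate", "c"), ("octanoate", "c"), ("mevalonate", "c"),
        ("glutamine", "e"), ("L-serine", "e"), ("glycine", "e"), ("L-alanine", "e"),
        ("L-arginine", "e"), ("L-aspartate", "e"), ("L-cysteine", "e"),
    ]
    comp_name = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}
    species: Dict[str, Species] = {}
    for chem, comps in placement:
        formula, charge = _CHEMS[chem]
        dG, dH = formation[chem]
        for letter in comps:
            sid = _sid(chem, letter)
            species[sid] = Species(
                id=sid, name=chem, composition=parse_formula(formula), charge=charge,
                dGf0=dG, dHf0=dH, compartment=comp_name[letter],
                buffered=(chem == "proton"),
            )

    def rxn(rid, enzyme, eq_stoich, node, irreversible=False, transport=False, max_rate=None):
        return Reaction(rid, enzyme, eq_stoich, node, irreversible, transport, max_rate)

    reactions = [
        # --- glycolysis node ---------------------------------------------
        rxn("T_glc", "GLUT2 transport", {"glc_e": -1, "glc_c": 1}, "glycolysis",
            transport=True, max_rate=0.5),
        rxn("R_glyc", "glycolysis (lumped)",
            {"glc_c": -1, "adp_c": -2, "pi_c": -2, "lac_c": 2, "atp_c": 2, "h2o_c": 2},
            "glycolysis", max_rate=0.05),
        # --- purine degradation node -------------------------------------
        rxn("T_ado", "nucleoside transport", {"ado_e": -1, "ado_c": 1}, "purine",
            transport=True, max_rate=0.01),
        rxn("R_ado_hx", "adenosine deaminase + nucleosidase (lumped)",
            {"ado_c": -1, "h2o_c": -2, "hx_c": 1, "rib_c": 1, "nh3_c": 1},
            "purine", max_rate=0.01),
        # xanthine-oxidase steps: hypoxia-driven, applied as forced extents
        # during static cold storage (dehydrogenase form, no superoxide, in
        # normoxia -> free extent held at zero)
        rxn("R_xo1", "xanthine oxidase (EC 1.17.3.2)",
            {"hx_c": -1, "h2o_c": -1, "o2_c": -2, "xan_c": 1, "sox_c": 2, "h_c": 2},
            "purine", irreversible=True, max_rate=0.0),
        rxn("R_xo2", "xanthine oxidase (EC 1.17.3.2)",
            {"xan_c": -1, "h2o_c": -1, "o2_c": -2, "ura_c": 1, "sox_c": 2, "h_c": 3},
            "purine", irreversible=True, max_rate=0.0),
        # --- ROS node (textbook stoichiometry) ---------------------------
        rxn("T_sox", "superoxide carrier", {"sox_c": -1, "sox_m": 1}, "ros",
            transport=True, max_rate=1e-4),
        rxn("R_sod", "superoxide dismutase (EC 1.15.1.1)",
            {"sox_m": -2, "h_m": -2, "h2o2_m": 1, "o2_m": 1}, "ros",
            irreversible=True, max_rate=1e-3),
        rxn("R_cat", "catalase (EC 1.11.1.6)",
            {"h2o2_m": -2, "h2o_m": 2, "o2_m": 1}, "ros",
            irreversible=True, max_rate=2e-7),
        rxn("R_gpx", "glutathione peroxidase (EC 1.11.1.9)",
            {"gsh_m": -2, "h2o2_m": -1, "gssg_m": 1, "h2o_m": 2}, "ros",
            irreversible=True, max_rate=1e-3),
        # --- glutathione node --------------------------------------------
        rxn("T_gsh_ec", "GSH uptake", {"gsh_e": -1, "gsh_c": 1}, "glutathione",
            transport=True, max_rate=6e-5),
        rxn("T_gsh_cm", "GSH mitochondrial import", {"gsh_c": -1, "gsh_m": 1},
            "glutathione", transport=True, max_rate=1e-4),
        rxn("R_gr", "glutathione reductase (lumped NADH donor)",
            {"gssg_m": -1, "nadh_m": -1, "h_m": -1, "gsh_m": 2, "nad_m": 1},
            "glutathione", max_rate=5e-8),
        # --- Krebs node ---------------------------------------------------
        rxn("R_pdh", "lactate -> acetyl unit (lumped PDH)",
            {"lac_c": -1, "h2o_c": -1, "nad_m": -2, "ac_c": 1, "co2_m": 1,
             "nadh_m": 2, "h_c": 2}, "krebs", irreversible=True, max_rate=2e-3),
        rxn("R_krebs", "Krebs cycle (lumped)",
            {"lac_c": -1, "h2o_m": -2, "nad_m": -6, "adp_c": -1, "pi_c": -1,
             "co2_m": 3, "nadh_m": 6, "h_m": 4, "atp_c": 1}, "krebs", irreversible=True, max_rate=0.04),
        rxn("R_buf", "carbonic anhydrase buffer (applied analytically)",
            {"co2_m": -1, "h2o_m": -1, "hco3_c": 1, "h_c": 1}, "krebs", max_rate=0.0),
        rxn("T_co2", "CO2 outgassing to perfusate", {"co2_m": -1, "co2_e": 1},
            "krebs", transport=True, max_rate=5.0),
        rxn("T_hco3", "bicarbonate exchange", {"hco3_e": -1, "hco3_c": 1}, "krebs",
            transport=True, max_rate=1.0),
        # --- oxidative phosphorylation node ------------------------------
        rxn("T_o2_ec", "O2 diffusion", {"o2_e": -1, "o2_c": 1}, "oxphos",
            transport=True, max_rate=1.0),
        rxn("T_o2_cm", "O2 diffusion", {"o2_c": -1, "o2_m": 1}, "oxphos",
            transport=True, max_rate=1.0),
        rxn("R_oxphos", "electron transport chain + ATP synthase (lumped)",
            {"nadh_m": -1, "o2_m": -0.5, "h_m": -1, "adp_c": -2.5, "pi_c": -2.5,
             "h_c": -2.5, "nad_m": 1, "h2o_m": 1, "atp_c": 2.5, "h2o_c": 2.5},
            "oxphos", irreversible=True, max_rate=6e-4),
        # ETC electron leak to superoxide; extent is forced bookkeeping
        # (leak_fraction x O2 consumed), never free
        rxn("R_leak", "ETC electron leak",
            {"nadh_m": -1, "o2_m": -2, "nad_m": 1, "sox_m": 2, "h_m": 1},
            "oxphos", irreversible=True, max_rate=0.0),
        # --- lipid node ---------------------------------------------------
        rxn("R_acc", "acetyl-CoA carboxylase proxy (committed step)",
            {"ac_c": -1, "hco3_c": -1, "atp_c": -1, "mal_c": 1, "adp_c": 1,
             "pi_c": 1, "h_c": 1}, "lipid", irreversible=True, max_rate=5e-4),
        rxn("R_fas", "fatty-acid synthase proxy (lumped, ATP-consuming)",
            {"mal_c": -4, "nadh_m": -6, "atp_c": -4, "h_c": -9, "octa_c": 1,
             "co2_m": 4, "nad_m": 6, "h2o_c": 2, "adp_c": 4, "pi_c": 4},
            "lipid", irreversible=True, max_rate=5e-4),
        # --- mevalonate (bile proxy) node --------------------------------
        rxn("R_mev", "mevalonate synthesis (bile proxy, lumped)",
            {"ac_c": -3, "nadh_m": -2, "h_c": -4, "mev_c": 1, "nad_m": 2, "h2o_c": 2},
            "mevalonate", irreversible=True, max_rate=1e-3),
        # --- adenylate node ----------------------------------------------
        rxn("R_adk", "adenylate kinase (EC 2.7.4.3)",
            {"adp_c": -2, "atp_c": 1, "amp_c": 1}, "adenylate", max_rate=1.0),
        rxn("R_atpase", "ATP maintenance load (lumped ATPases)",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
            "adenylate", irreversible=True, max_rate=0.1),
    ]
    rxn_map = {r.id: r for r in reactions}

    # sweep order: the krebs node (which carries the CO2/bicarbonate
    # buffer) goes last so every sweep ends with pH re-equilibrated after
    # the proton-producing/consuming nodes have moved
    node_ids = ["glycolysis", "purine", "ros", "glutathione",
                "oxphos", "lipid", "mevalonate", "adenylate", "krebs"]
    nodes = []
    for nid in node_ids:
        rids = [r.id for r in reactions if r.node == nid]
        comps = sorted({s for rid in rids for s in rxn_map[rid].stoich})
        nodes.append(NetworkNode(id=nid, reactions=rids, components=comps))

    net = MetabolicNetwork(
        compartments=["extracellular", "cytosol", "mitochondrion"],
        species=species,
        reactions=rxn_map,
        nodes=nodes,
    )
    net.validate()
    return net


def build_initial_amounts(volume: float = 1.0 / 9.0) -> Dict[str, float]:
    """Intracellular state of a fresh liver before the cold flush
    (nmol/cell).  ``volume`` is the intracellular conversion factor in
    nmol per (cell mM); solvent water is sized so mole fractions track
    molarities."""
    water = 55.5e3 * volume
    return {
        "h2o_e": water, "h2o_c": water, "h2o_m": water * 0.1,
        "o2_e": 0.0, "o2_c": 1e-3, "o2_m": 1e-4,
        "h_c": 4e-5 * volume, "h_m": 4e-5 * volume,
        "glc_e": 0.0, "glc_c": 0.01, "lac_c": 0.1,
        "pi_c": 5.0, "atp_c": 2.0, "adp_c": 1.0, "amp_c": 0.5,
        "nad_m": 3.0, "nadh_m": 0.1,
        "co2_m": 0.1, "co2_e": 0.0, "hco3_e": 0.0, "hco3_c": 5.0,
        "gsh_e": 0.0, "gsh_c": 1e-5, "gsh_m": 5e-6, "gssg_m": 1e-6,
        "sox_c": 0.0, "sox_m": 1e-9, "h2o2_m": 3e-7,
        "ado_e": 0.0, "ado_c": 0.01, "hx_c": 1e-3, "xan_c": 1e-4,
        "ura_c": 1e-4, "rib_c": 0.01, "nh3_c": 1e-3,
        "ac_c": 0.05, "mal_c": 1e-3, "octa_c": 1e-3, "mev_c": 1e-3,
    }


def physiological_delta(net: MetabolicNetwork, rid: str, prop: str = "G") -> float:
    """Standard reaction energy (kJ/mol) in the pH-buffered (transformed)
    convention: buffered species (protons) are excluded, since their
    chemical potential is clamped by the acid-base buffer.  This is the
    driving force the equilibrium solver actually sees at the pH 7.4
    operating point, and the quantity the fixture targets prescribe."""
    rxn = net.reactions[rid]
    stoich = {s: c for s, c in rxn.stoich.items() if not net.species[s].buffered}
    return reaction_delta(stoich, net.species, prop)


def assert_fixture_anchors(net: MetabolicNetwork) -> None:
    """Build-time sanity gate: the fixture's hallmark energies hold."""
    dH_gpx = reaction_delta(net.reactions["R_gpx"], net.species, "H")
    if abs(dH_gpx - ReactionTargets().gpx[1]) > 1e-9:
        raise AssertionError(f"GPx reaction enthalpy {dH_gpx} != target")
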