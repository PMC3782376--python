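"""Construction of the Abeta–tau immunotherapy reaction network.

The model couples four mechanistic layers in a single well-mixed cell-scale
system, simulated over a 12-day horizon:

* a DNA-damage / p53 / Mdm2 stress-response core: ROS damages DNA, damage
  activates ATM, active ATM phosphorylates Mdm2 which is then degraded, so p53
  escapes Mdm2-mediated turnover and accumulates;
* GSK3beta activity: elevated p53 binds GSK3beta and the complex (the "active
  GSK3beta pool") both phosphorylates tau and boosts Abeta production,
  closing a self-amplifying loop because soluble Abeta and plaques generate
  ROS;
* Abeta aggregation: monomers reversibly dimerise, dimers nucleate plaques and
  deposit onto them under a saturating (Hill) growth law, plaques shed
  monomers by first-order disaggregation;
* tau dynamics: tau cycles between free and microtubule-bound pools, free tau
  is phosphorylated in two steps by the active GSK3beta pool, and
  phosphorylated tau aggregates into tangles an order of magnitude faster
  than unphosphorylated tau.

The immunotherapy extension adds four microglial activation states (total
glial pool conserved at 100), an anti-Abeta antibody species with three modes
of action (enhanced degradation of soluble Abeta, plaque disaggregation, and
full activation of microglia which then phagocytose plaques), and ROS
production by plaques and by plaque-bound glia.

Rate-constant provenance: values printed in the published model description
(the extension table and the measured Abeta turnover rates) carry provenance
``published``; the remaining base-network constants carry ``calibrated`` —
they were fixed once so that the deterministic/stochastic time courses
reproduce the documented behaviour (plaque onset around day 2, a mean maximum
plaque of ~75 molecules, no plaques at the highest Abeta clearance rate,
near-zero dimer levels, antibody half-life ~3 days, glial activation within
1–2 days of dosing) and were not tuned further. See docs/methods.md.
"""

from __future__ import annotations

import warnings

from .network import (
    Parameter,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Saturation,
    Species,
    validate_network,
)

__all__ = [
    "PARAM_ALIASES",
    "SPECIES_RENAMES",
    "AD_DEG_RATE",
    "CONTROL_DEG_RATE",
    "DEG_RATE_VARIANTS",
    "build_immunotherapy_extension",
    "build_base_model",
    "assemble_full_model",
    "build_model",
    "apply_scan_defaults",
    "canonical_param",
    "rename_species",
]

# ---------------------------------------------------------------------------
# naming conventions
# ---------------------------------------------------------------------------

#: alternate spellings of extension rate constants (reaction-table spelling ->
#: canonical parameter-table spelling), kept for SBML round-trip fidelity
PARAM_ALIASES: dict[str, str] = {
    "k_binAbetaGlia": "k_binAbPGlia",
    "k_relAbetaGlia": "k_relAbPGlia",
    "k_degAbetaGlia": "k_degAbPGlia",
    "k_disaggAbeta1": "k_disaggAbP1",
    "k_disaggAbeta2": "k_disaggAbP2",
    "k_dedimer": "k_dedimerAbeta",
    "k_genROSplaque": "k_genROSPlaque",
    "k_Mdm2PUb": "k_Mdm2Pub",
}

#: legacy species names used by the predecessor model -> current names
SPECIES_RENAMES: dict[str, str] = {
    "AggAbeta": "AbDim",
    "AbetaPlaque": "AbP",
}

#: measured Abeta monomer clearance rates (s^-1)
AD_DEG_RATE = 1.5e-5
CONTROL_DEG_RATE = 2.1e-5
#: the four clearance-rate variants examined for plaque formation
DEG_RATE_VARIANTS = (1.5e-5, 2.1e-5, 1.0e-4, 2.0e-4)


def canonical_param(pid: str) -> str:
    """Resolve an aliased/odd-case spelling to the canonical parameter id."""
    if pid in PARAM_ALIASES:
        return PARAM_ALIASES[pid]
    lowered = {k.lower(): v for k, v in PARAM_ALIASES.items()}
    return lowered.get(pid.lower(), pid)


def rename_species(net: ReactionNetwork, mapping: dict[str, str]) -> ReactionNetwork:
    """Copy of ``net`` with species ids renamed everywhere they appear."""
    out = net.copy()

    def r(sid: str) -> str:
        return mapping.get(sid, sid)

    for s in out.species:
        s.id = r(s.id)
    for rxn in out.reactions:
        rxn.reactants = {r(k): v for k, v in rxn.reactants.items()}
        rxn.products = {r(k): v for k, v in rxn.products.items()}
        rxn.modifiers = tuple(r(m) for m in rxn.modifiers)
        if rxn.rate_law is not None:
            law = rxn.rate_law
            sat = law.saturation
            rxn.rate_law = RateLaw(
                kind=law.kind,
                rate_constant=law.rate_constant,
                reactant_factors=tuple(r(f) for f in law.reactant_factors),
                saturation=None if sat is None else Saturation(r(sat.substrate), sat.half_param),
            )
    for ev in out.events:
        ev.assignments = {r(k): v for k, v in ev.assignments.items()}
    return out


def _ma(rid: str, reactants: dict[str, int], products: dict[str, int],
        k: str, factors: tuple[str, ...], modifiers: tuple[str, ...] = ()) -> Reaction:
    return Reaction(id=rid, reactants=dict(reactants), products=dict(products),
                    modifiers=modifiers,
                    rate_law=RateLaw("mass_action", k, factors))


# ---------------------------------------------------------------------------
# immunotherapy extension
# ---------------------------------------------------------------------------

def build_immunotherapy_extension() -> ReactionNetwork:
    """The immunisation fragment: new species, 19 reactions, rate constants.

    Microglia occupy four states: inactive (GliaI), two plaque-associated
    partially active states (GliaP1, GliaP2 — two stages give a realistic lag
    between plaque appearance and full activation), and fully active (GliaA),
    which requires antibody. Fully active glia bind plaques (AbP_GliaA) and
    degrade them by phagocytosis, generating ROS while plaque-bound.
    Antibodies bind soluble monomers and dimers (targeting them for enhanced
    degradation, the antibody being recycled), disaggregate plaques directly,
    and are themselves cleared with a half-life of about 3 days.
    """
    species = [
        Species("GliaI", 100, "Inactive glia"),
        Species("GliaP1", 0, "Glia associated with plaques but not able to phagocytose"),
        Species("GliaP2", 0, "Glia associated with plaques but not able to phagocytose"),
        Species("GliaA", 0, "Active glia which can phagocytose"),
        Species("antiAb", 0, "Antibody against amyloid-beta"),
        Species("AbP_GliaA", 0, "Abeta plaque bound to active glia"),
        Species("Abeta_antiAb", 0, "Abeta monomer bound to antibody"),
        Species("AbDim_antiAb", 0, "Abeta dimer bound to antibody"),
        Species("AbDim", 0, "Abeta dimer (replaces species AggAbeta)"),
        Species("AbP", 0, "Abeta plaques, counted in constituent molecules "
                          "(replaces species AbetaPlaque)"),
    ]
    p = "published"
    parameters = [
        Parameter("k_actglia1", 6.0e-7, p),      # molecule^-1 s^-1
        Parameter("k_actglia2", 6.0e-7, p),      # molecule^-1 s^-1
        Parameter("k_binAbantiAb", 1.0e-6, p),   # molecule^-1 s^-1
        Parameter("k_binAbPGlia", 1.0e-5, p),    # molecule^-1 s^-1
        Parameter("k_dedimerAbeta", 1.0e-6, p),  # s^-1
        Parameter("k_degAbetaAntiAb", 1.5e-4, p),  # s^-1
        Parameter("k_degAbPGlia", 5.0e-3, p),    # s^-1
        Parameter("k_degAntiAb", 2.75e-6, p),    # s^-1; antibody half-life ~3 d
        Parameter("k_disaggAbP1", 2.0e-4, p),    # s^-1
        Parameter("k_disaggAbP2", 1.0e-6, p),    # molecule^-1 s^-1
        Parameter("k_genROSGlia", 2.0e-5, p),    # s^-1
        Parameter("k_genROSPlaque", 2.0e-5, p),  # s^-1
        Parameter("k_inactglia1", 5.0e-6, p),    # s^-1; inactivation t1/2 ~4 d
        Parameter("k_inactglia2", 5.0e-6, p),    # s^-1
        Parameter("k_relAbPGlia", 5.0e-5, p),    # s^-1
    ]
    reactions = [
        _ma("GliaActivationStep1", {"GliaI": 1, "AbP": 1}, {"GliaP1": 1, "AbP": 1},
            "k_actglia1", ("GliaI", "AbP")),
        _ma("GliaActivationStep2", {"GliaP1": 1, "AbP": 1}, {"GliaP2": 1, "AbP": 1},
            "k_actglia1", ("GliaP1", "AbP")),
        _ma("GliaActivationStep3", {"GliaP2": 1, "antiAb": 1}, {"GliaA": 1, "antiAb": 1},
            "k_actglia2", ("GliaP2", "antiAb")),
        _ma("GliaInactivationStep1", {"GliaA": 1}, {"GliaP2": 1},
            "k_inactglia1", ("GliaA",)),
        _ma("GliaInactivationStep2", {"GliaP2": 1}, {"GliaP1": 1},
            "k_inactglia2", ("GliaP2",)),
        _ma("GliaInactivationStep3", {"GliaP1": 1}, {"GliaI": 1},
            "k_inactglia2", ("GliaP1",)),
        _ma("AbetaPlaqueBindingToGlia", {"GliaA": 1, "AbP": 1}, {"AbP_GliaA": 1},
            "k_binAbPGlia", ("GliaA", "AbP")),
        _ma("AbetaPlaqueReleaseFromGlia", {"AbP_GliaA": 1}, {"GliaA": 1, "AbP": 1},
            "k_relAbPGlia", ("AbP_GliaA",)),
        _ma("PlaqueClearanceByGlia", {"AbP_GliaA": 1}, {"GliaA": 1},
            "k_degAbPGlia", ("AbP_GliaA",)),
        _ma("ROSgenerationByGlia", {"AbP_GliaA": 1}, {"AbP_GliaA": 1, "ROS": 1},
            "k_genROSGlia", ("AbP_GliaA",)),
        _ma("ROSgenerationByPlaques", {"AbP": 1}, {"AbP": 1, "ROS": 1},
            "k_genROSPlaque", ("AbP",)),
        _ma("AntiAbRemoval", {"antiAb": 1}, {}, "k_degAntiAb", ("antiAb",)),
        _ma("AntiAbBindingToAbeta", {"Abeta": 1, "antiAb": 1}, {"Abeta_antiAb": 1},
            "k_binAbantiAb", ("Abeta", "antiAb")),
        _ma("AntiAbBindingToAbetaDimers", {"AbDim": 1, "antiAb": 1}, {"AbDim_antiAb": 1},
            "k_binAbantiAb", ("AbDim", "antiAb")),
        _ma("AbetaDegradationViaAntiAb", {"Abeta_antiAb": 1}, {"antiAb": 1},
            "k_degAbetaAntiAb", ("Abeta_antiAb",)),
        _ma("AbetaDimerDegradViaAntiAb", {"AbDim_antiAb": 1}, {"antiAb": 1},
            "k_degAbetaAntiAb", ("AbDim_antiAb",)),
        _ma("PlaqueDisaggregation", {"AbP": 1}, {"Abeta": 1},
            "k_disaggAbP1", ("AbP",)),
        _ma("PlaqueDisaggregationViaAntiAb", {"AbP": 1, "antiAb": 1},
            {"Abeta": 1, "antiAb": 1}, "k_disaggAbP2", ("AbP", "antiAb")),
        # a dimer dissociates back into its two monomers
        Reaction(id="AbetaDedimerisation", reactants={"AbDim": 1},
                 products={"Abeta": 2},
                 rate_law=RateLaw("mass_action", "k_dedimerAbeta", ("AbDim",))),
    ]
    return ReactionNetwork(species=species, parameters=parameters,
                           reactions=reactions, events=[],
                           name="immunotherapy-extension")


# ---------------------------------------------------------------------------
# reconstructed base network (GSK3beta/p53/Abeta/tau core)
# ---------------------------------------------------------------------------

def build_base_model() -> ReactionNetwork:
    """The GSK3beta–p53 stress-response core with Abeta turnover, aggregation
    and tau dynamics, using the predecessor naming (AggAbeta, AbetaPlaque).

    Initial amounts put the p53/Mdm2 module near its unstressed steady state;
    soluble Abeta starts at zero and is produced at the measured rate, so the
    aggregation cascade winds up from nothing over the first days.
    """
    c = "calibrated"
    p = "published"
    species = [
        # p53 / Mdm2 module
        Species("p53_mRNA", 10, "p53 messenger RNA"),
        Species("p53", 2, "free p53"),
        Species("Mdm2_mRNA", 2, "Mdm2 messenger RNA"),
        Species("Mdm2", 2, "free Mdm2"),
        Species("Mdm2_P", 0, "ATM-phosphorylated Mdm2 (rapidly degraded)"),
        Species("Mdm2_p53", 7, "p53-Mdm2 complex (p53 targeted for degradation)"),
        # DNA damage / ROS module
        Species("ROS", 0, "reactive oxygen species"),
        Species("damDNA", 0, "damaged DNA sites"),
        Species("ATMI", 200, "inactive ATM kinase"),
        Species("ATMA", 0, "active ATM kinase"),
        # GSK3beta
        Species("Gsk3b", 100, "free GSK3beta"),
        Species("Gsk3b_p53", 0, "GSK3beta-p53 complex: the active GSK3beta pool"),
        # Abeta
        Species("Abeta", 0, "soluble Abeta monomer"),
        Species("AggAbeta", 0, "Abeta dimer (predecessor naming)"),
        Species("AbetaPlaque", 0, "Abeta plaque, counted in molecules (predecessor naming)"),
        # tau
        Species("Tau", 30, "free unphosphorylated tau"),
        Species("MTTau", 270, "microtubule-bound tau"),
        Species("Tau_P1", 0, "singly phosphorylated tau"),
        Species("Tau_P2", 0, "doubly phosphorylated tau (aggregation-prone)"),
        Species("NFT", 0, "neurofibrillary tangles, counted in tau molecules"),
    ]
    parameters = [
        # p53/Mdm2
        Parameter("k_synp53mRNA", 1.0e-3, c),          # molecule s^-1
        Parameter("k_synp53mRNAAbeta", 2.0e-5, c),     # s^-1 (per Abeta)
        Parameter("k_degp53mRNA", 1.0e-4, c),          # s^-1
        Parameter("k_synp53", 2.0e-3, c),              # s^-1 (per mRNA)
        Parameter("k_binMdm2p53", 1.155e-3, c),        # molecule^-1 s^-1
        Parameter("k_relMdm2p53", 1.155e-5, c),        # s^-1
        Parameter("k_degp53", 8.25e-4, c),             # s^-1 (Mdm2-mediated)
        Parameter("k_synMdm2mRNA", 1.456e-4, c),         # s^-1 (per p53)
        Parameter("k_synMdm2mRNAGsk3bp53", 2.0e-5, c), # s^-1 (per complex)
        Parameter("k_degMdm2mRNA", 1.0e-4, c),         # s^-1
        Parameter("k_synMdm2", 4.95e-4, c),            # s^-1 (per mRNA)
        Parameter("k_degMdm2", 4.33e-4, c),            # s^-1
        Parameter("k_phosMdm2", 1.041e-3, c),            # molecule^-1 s^-1 (by ATMA)
        Parameter("k_dephosMdm2", 5.0e-4, c),          # s^-1
        Parameter("k_Mdm2Pub", 1.0e-3, c),             # s^-1 (ubiquitin-mediated)
        # DNA damage / ROS
        Parameter("k_genROSAbeta", 3.992e-5, c),         # s^-1 (per Abeta)
        Parameter("k_remROS", 8.126e-4, c),              # s^-1
        Parameter("k_damROS", 7.75e-4, c),              # s^-1 (per ROS)
        Parameter("k_repair", 2.0e-5, c),              # s^-1
        Parameter("k_actATM", 1.999e-6, c),              # molecule^-1 s^-1
        Parameter("k_inactATM", 1.0e-4, c),            # s^-1
        # GSK3beta
        Parameter("k_binGsk3bp53", 9.92e-6, c),         # molecule^-1 s^-1
        Parameter("k_relGsk3bp53", 4.95e-4, c),         # s^-1
        # Abeta turnover and aggregation
        Parameter("k_prodAbeta", 1.86e-5, p),          # molecule s^-1 (measured)
        Parameter("k_prodAbeta2", 7.115e-6, c),          # s^-1 (per active GSK3beta)
        Parameter("k_degAbeta", AD_DEG_RATE, p),       # s^-1 (measured, AD)
        Parameter("k_dimerAbeta", 1.337e-5, c),          # molecule^-1 s^-1
        Parameter("k_pf", 5.881e-6, c),                  # s^-1 plaque nucleation
        Parameter("k_pg", 2.119e-2, c),                  # s^-1 plaque growth (saturated)
        Parameter("k_pghalf", 78.12, c),                # molecules, half-saturation
        # tau
        Parameter("k_synTau", 1.0e-5, c),              # molecule s^-1
        Parameter("k_binMTTau", 1.0e-4, c),            # s^-1
        Parameter("k_relMTTau", 1.11e-5, c),           # s^-1
        Parameter("k_phosTauGsk3bp53", 1.854e-6, c),     # molecule^-1 s^-1
        Parameter("k_dephosTau", 9.437e-5, c),           # s^-1
        Parameter("k_aggTauP2", 1.109e-7, c),            # molecule^-1 s^-1
        Parameter("k_aggTau", 4.0e-9, c),              # 10x lower than k_aggTauP2
    ]
    reactions = [
        # --- p53 regulation ---
        _ma("P53mRNASynthesis", {}, {"p53_mRNA": 1}, "k_synp53mRNA", ()),
        _ma("P53mRNASynthesisViaAbeta", {"Abeta": 1}, {"Abeta": 1, "p53_mRNA": 1},
            "k_synp53mRNAAbeta", ("Abeta",)),
        _ma("P53mRNADegradation", {"p53_mRNA": 1}, {}, "k_degp53mRNA", ("p53_mRNA",)),
        _ma("P53Synthesis", {"p53_mRNA": 1}, {"p53_mRNA": 1, "p53": 1},
            "k_synp53", ("p53_mRNA",)),
        _ma("Mdm2P53Binding", {"p53": 1, "Mdm2": 1}, {"Mdm2_p53": 1},
            "k_binMdm2p53", ("p53", "Mdm2")),
        _ma("Mdm2P53Release", {"Mdm2_p53": 1}, {"p53": 1, "Mdm2": 1},
            "k_relMdm2p53", ("Mdm2_p53",)),
        _ma("P53DegradationViaMdm2", {"Mdm2_p53": 1}, {"Mdm2": 1},
            "k_degp53", ("Mdm2_p53",)),
        _ma("Mdm2mRNASynthesisViaP53", {"p53": 1}, {"p53": 1, "Mdm2_mRNA": 1},
            "k_synMdm2mRNA", ("p53",)),
        _ma("Mdm2mRNASynthesisViaGsk3bP53", {"Gsk3b_p53": 1},
            {"Gsk3b_p53": 1, "Mdm2_mRNA": 1}, "k_synMdm2mRNAGsk3bp53", ("Gsk3b_p53",)),
        _ma("Mdm2mRNADegradation", {"Mdm2_mRNA": 1}, {}, "k_degMdm2mRNA", ("Mdm2_mRNA",)),
        _ma("Mdm2Synthesis", {"Mdm2_mRNA": 1}, {"Mdm2_mRNA": 1, "Mdm2": 1},
            "k_synMdm2", ("Mdm2_mRNA",)),
        _ma("Mdm2Degradation", {"Mdm2": 1}, {}, "k_degMdm2", ("Mdm2",)),
        _ma("Mdm2Phosphorylation", {"Mdm2": 1, "ATMA": 1}, {"Mdm2_P": 1, "ATMA": 1},
            "k_phosMdm2", ("Mdm2", "ATMA")),
        _ma("Mdm2Dephosphorylation", {"Mdm2_P": 1}, {"Mdm2": 1},
            "k_dephosMdm2", ("Mdm2_P",)),
        _ma("Mdm2PUbiquitinDegradation", {"Mdm2_P": 1}, {}, "k_Mdm2Pub", ("Mdm2_P",)),
        # --- DNA damage response ---
        _ma("ROSgenerationByAbeta", {"Abeta": 1}, {"Abeta": 1, "ROS": 1},
            "k_genROSAbeta", ("Abeta",)),
        _ma("ROSremoval", {"ROS": 1}, {}, "k_remROS", ("ROS",)),
        _ma("DNAdamageByROS", {"ROS": 1}, {"ROS": 1, "damDNA": 1},
            "k_damROS", ("ROS",)),
        _ma("DNArepair", {"damDNA": 1}, {}, "k_repair", ("damDNA",)),
        _ma("ATMactivation", {"ATMI": 1, "damDNA": 1}, {"ATMA": 1, "damDNA": 1},
            "k_actATM", ("ATMI", "damDNA")),
        _ma("ATMinactivation", {"ATMA": 1}, {"ATMI": 1}, "k_inactATM", ("ATMA",)),
        # --- GSK3beta activity ---
        _ma("Gsk3bP53Binding", {"Gsk3b": 1, "p53": 1}, {"Gsk3b_p53": 1},
            "k_binGsk3bp53", ("Gsk3b", "p53")),
        _ma("Gsk3bP53Release", {"Gsk3b_p53": 1}, {"Gsk3b": 1, "p53": 1},
            "k_relGsk3bp53", ("Gsk3b_p53",)),
        # --- Abeta turnover and aggregation ---
        _ma("AbetaProduction", {}, {"Abeta": 1}, "k_prodAbeta", ()),
        _ma("AbetaProductionViaGsk3bP53", {"Gsk3b_p53": 1},
            {"Gsk3b_p53": 1, "Abeta": 1}, "k_prodAbeta2", ("Gsk3b_p53",)),
        _ma("AbetaDegradation", {"Abeta": 1}, {}, "k_degAbeta", ("Abeta",)),
        # two monomers form a dimer; the law is k*Abeta^2 on raw counts
        Reaction(id="AbetaDimerisation", reactants={"Abeta": 2},
                 products={"AggAbeta": 1},
                 rate_law=RateLaw("mass_action", "k_dimerAbeta", ("Abeta", "Abeta"))),
        # a dimer seeds a new plaque (two molecules enter the plaque pool)
        Reaction(id="PlaqueFormation", reactants={"AggAbeta": 1},
                 products={"AbetaPlaque": 2},
                 rate_law=RateLaw("mass_action", "k_pf", ("AggAbeta",))),
        # dimer deposition onto existing plaques: linear in plaque size when
        # small, saturating at k_pg per dimer for large plaques
        Reaction(id="PlaqueGrowth", reactants={"AggAbeta": 1},
                 products={"AbetaPlaque": 2}, modifiers=("AbetaPlaque",),
                 rate_law=RateLaw("saturating", "k_pg", ("AggAbeta",),
                                  Saturation("AbetaPlaque", "k_pghalf"))),
        # --- tau dynamics and aggregation ---
        _ma("TauSynthesis", {}, {"Tau": 1}, "k_synTau", ()),
        _ma("TauMTBinding", {"Tau": 1}, {"MTTau": 1}, "k_binMTTau", ("Tau",)),
        _ma("TauMTRelease", {"MTTau": 1}, {"Tau": 1}, "k_relMTTau", ("MTTau",)),
        _ma("TauPhosphorylationStep1", {"Tau": 1, "Gsk3b_p53": 1},
            {"Tau_P1": 1, "Gsk3b_p53": 1}, "k_phosTauGsk3bp53", ("Tau", "Gsk3b_p53")),
        _ma("TauPhosphorylationStep2", {"Tau_P1": 1, "Gsk3b_p53": 1},
            {"Tau_P2": 1, "Gsk3b_p53": 1}, "k_phosTauGsk3bp53", ("Tau_P1", "Gsk3b_p53")),
        _ma("TauDephosphorylationStep1", {"Tau_P1": 1}, {"Tau": 1},
            "k_dephosTau", ("Tau_P1",)),
        _ma("TauDephosphorylationStep2", {"Tau_P2": 1}, {"Tau_P1": 1},
            "k_dephosTau", ("Tau_P2",)),
        # aggregation is second order in the aggregating pool; phosphorylated
        # tau aggregates an order of magnitude faster than free tau
        Reaction(id="TauP2Aggregation", reactants={"Tau_P2": 2},
                 products={"NFT": 2},
                 rate_law=RateLaw("mass_action", "k_aggTauP2", ("Tau_P2", "Tau_P2"))),
        Reaction(id="TauAggregation", reactants={"Tau": 2},
                 products={"NFT": 2},
                 rate_law=RateLaw("mass_action", "k_aggTau", ("Tau", "Tau"))),
    ]
    return ReactionNetwork(species=species, parameters=parameters,
                           reactions=reactions, events=[], name="gsk3-p53-base")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_full_model(base: ReactionNetwork,
                        extension: ReactionNetwork | None = None) -> ReactionNetwork:
    """Merge the base network with the immunotherapy extension.

    Predecessor species names are modernised (AggAbeta -> AbDim,
    AbetaPlaque -> AbP), duplicate definitions are resolved in favour of the
    extension, and the merged network must validate (any unresolved species
    reference or glia-conservation failure raises).
    """
    if extension is None:
        extension = build_immunotherapy_extension()
    if not base.species and not base.reactions:
        # identity merge: the fragment alone (it references base species such
        # as ROS and Abeta, so it is returned unvalidated)
        warnings.warn("base network is empty; assembled model equals the extension",
                      stacklevel=2)
        return extension.copy()
    base = rename_species(base, SPECIES_RENAMES)

    ext_sids = {s.id for s in extension.species}
    ext_pids = {p.id for p in extension.parameters}
    ext_rids = {r.id for r in extension.reactions}

    merged = ReactionNetwork(name="abeta-tau-immunotherapy")
    merged.species = [s for s in base.species if s.id not in ext_sids] \
        + [s for s in extension.species]
    merged.parameters = [p for p in base.parameters if p.id not in ext_pids] \
        + [p for p in extension.parameters]
    merged.reactions = [r for r in base.reactions if r.id not in ext_rids] \
        + [r for r in extension.reactions]
    merged.events = list(base.events) + list(extension.events)
    merged.species = [_copy_species(s) for s in merged.species]

    violations = validate_network(merged)
    unresolved = [v for v in violations if v.kind == "undeclared-species"]
    if unresolved:
        raise ValueError(f"assembly error: {unresolved[0]}")
    conserv = [v for v in violations if v.kind == "glia-conservation"]
    if conserv:
        raise ValueError(f"structural error: {conserv[0]}")
    if violations:
        raise ValueError(f"assembly produced invalid network: {violations[0]}")
    return merged


def _copy_species(s: Species) -> Species:
    return Species(s.id, s.initial_amount, s.description)


def build_model(k_degAbeta: float = AD_DEG_RATE) -> ReactionNetwork:
    """The assembled disease model with a chosen Abeta clearance rate and no
    immunisation (no antibody source; antiAb stays at zero)."""
    net = assemble_full_model(build_base_model())
    if k_degAbeta != AD_DEG_RATE:
        net = net.with_parameter("k_degAbeta", k_degAbeta, "override")
    return net


#: alternative defaults used for all sensitivity scans (they give slightly
#: lower levels of every output; rankings are relative to the same defaults)
SCAN_DEFAULTS = {
    "k_genROSAbeta": 2.0e-5,
    "k_genROSGlia": 1.0e-5,
    "k_genROSPlaque": 1.0e-5,
}


def apply_scan_defaults(net: ReactionNetwork) -> ReactionNetwork:
    out = net.copy()
    for pid, val in SCAN_DEFAULTS.items():
        par = out.get_parameter(pid)
        par.value = val
        par.provenance = "scan-default"
    return out
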