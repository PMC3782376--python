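"""Construction of the immunotherapy extension and full-model assembly."""

import pytest

from abtau.model import (PARAM_ALIASES, assemble_full_model,
                         build_immunotherapy_extension, canonical_param,
                         apply_scan_defaults, SCAN_DEFAULTS)
from abtau.network import GLIA_POOL, ReactionNetwork, validate_network

# the published values of the extension rate constants
EXTENSION_VALUES = {
    "k_actglia1": 6.0e-7,
    "k_actglia2": 6.0e-7,
    "k_binAbantiAb": 1.0e-6,
    "k_binAbPGlia": 1.0e-5,
    "k_dedimerAbeta": 1.0e-6,
    "k_degAbetaAntiAb": 1.5e-4,
    "k_degAbPGlia": 5.0e-3,
    "k_degAntiAb": 2.75e-6,
    "k_disaggAbP1": 2.0e-4,
    "k_disaggAbP2": 1.0e-6,
    "k_genROSGlia": 2.0e-5,
    "k_genROSPlaque": 2.0e-5,
    "k_inactglia1": 5.0e-6,
    "k_inactglia2": 5.0e-6,
    "k_relAbPGlia": 5.0e-5,
}


def test_extension_initial_amounts(extension):
    assert extension.get_species("GliaI").initial_amount == 100
    for s in extension.species:
        if s.id != "GliaI":
            assert s.initial_amount == 0


def test_extension_has_19_reactions(extension):
    assert len(extension.reactions) == 19


def test_extension_construction_deterministic():
    a = build_immunotherapy_extension()
    b = build_immunotherapy_extension()
    assert a.content_hash() == b.content_hash()


def test_extension_parameter_values_verbatim(extension):
    values = extension.parameter_values()
    assert len(EXTENSION_VALUES) == 15
    for pid, val in EXTENSION_VALUES.items():
        assert values[pid] == val


def test_extension_values_present_in_assembled_model(full_model):
    values = full_model.parameter_values()
    for pid, val in EXTENSION_VALUES.items():
        assert values[pid] == val


def test_extension_glia_conservation(extension):
    """Every glial reaction interconverts states without net creation."""
    for rxn in extension.reactions:
        d = rxn.delta()
        if any(s in d for s in GLIA_POOL):
            assert sum(d.get(s, 0) for s in GLIA_POOL) == 0, rxn.id


def test_parameter_alias_map():
    assert canonical_param("k_binAbetaGlia") == "k_binAbPGlia"
    assert canonical_param("k_dedimer") == "k_dedimerAbeta"
    assert canonical_param("k_genROSplaque") == "k_genROSPlaque"
    assert canonical_param("k_Mdm2PUb") == "k_Mdm2Pub"
    assert canonical_param("k_pg") == "k_pg"  # unaliased ids pass through
    # every alias target is a real id of the assembled model or base
    for target in PARAM_ALIASES.values():
        assert target.startswith("k_")


def test_assembled_model_contains_both_halves(assembled):
    for sid in ("Tau_P2", "NFT", "GliaA", "antiAb", "AbDim", "AbP"):
        assert assembled.has_species(sid)
    assert validate_network(assembled) == []


def test_assembly_renames_legacy_species(base_model, extension):
    assert base_model.has_species("AggAbeta")
    merged = assemble_full_model(base_model.copy(), extension.copy())
    assert not merged.has_species("AggAbeta")
    assert not merged.has_species("AbetaPlaque")
    assert merged.has_species("AbDim")
    # the dimerisation reaction now produces the renamed species
    assert merged.get_reaction("AbetaDimerisation").products == {"AbDim": 1}


def test_assembly_with_empty_base_warns(extension):
    with pytest.warns(UserWarning, match="empty"):
        merged = assemble_full_model(ReactionNetwork(), extension.copy())
    assert len(merged.reactions) == len(extension.reactions)


def test_assembly_rejects_unresolved_reference(base_model, extension):
    bad = extension.copy()
    bad.species = [s for s in bad.species if s.id != "antiAb"]
    with pytest.raises(ValueError, match="antiAb"):
        assemble_full_model(base_model.copy(), bad)


def test_assembly_is_non_destructive(base_model, extension):
    h_base, h_ext = base_model.content_hash(), extension.content_hash()
    assemble_full_model(base_model, extension)
    assert base_model.content_hash() == h_base
    assert extension.content_hash() == h_ext


def test_scan_defaults_applied(full_model):
    net = apply_scan_defaults(full_model)
    for pid, val in SCAN_DEFAULTS.items():
        assert net.get_parameter(pid).value == val
        assert net.get_parameter(pid).provenance == "scan-default"
    # original untouched
    assert full_model.get_parameter("k_genROSGlia").value == 2.0e-5
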