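"""SBML round-trips, alias normalisation, diffing, unsupported constructs."""

import numpy as np
import pytest
from lxml import etree

from abtau.fixtures import FIXTURE_NAMES, make_fixture
from abtau.network import DAY, ReactionNetwork, TimedEvent
from abtau.ode import simulate_ode
from abtau.sbml import (diff_networks, export_sbml, import_sbml,
                        load_reference_model, SbmlError,
                        UnsupportedConstructError)


@pytest.mark.parametrize("name", FIXTURE_NAMES)
def test_fixture_round_trip(name, tmp_path):
    net = make_fixture(name)
    path = tmp_path / f"{name}.xml"
    export_sbml(net, path)
    assert diff_networks(net, import_sbml(path)) == []


def test_full_model_round_trip_with_event(full_model, tmp_path):
    net = full_model.copy()
    net.events.append(TimedEvent(4 * DAY, {"antiAb": 50}))
    path = tmp_path / "full.xml"
    export_sbml(net, path)
    reimported = import_sbml(path)
    assert diff_networks(net, reimported) == []
    # import(export(import(export(net)))) is stable
    path2 = tmp_path / "full2.xml"
    export_sbml(reimported, path2)
    assert diff_networks(reimported, import_sbml(path2)) == []


def test_reference_model_event_is_day4_dose_of_50():
    net = load_reference_model()
    assert len(net.events) == 1
    ev = net.events[0]
    assert ev.assignments == {"antiAb": 50.0}
    assert ev.trigger_time == pytest.approx(4 * DAY)


def test_empty_network_exports_minimal_document(tmp_path):
    path = tmp_path / "empty.xml"
    export_sbml(ReactionNetwork(name="empty"), path)
    net = import_sbml(path)
    assert net.species == [] and net.reactions == []


def test_import_insensitive_to_element_order(full_model, tmp_path):
    net = full_model.copy()
    path = tmp_path / "a.xml"
    export_sbml(net, path)
    shuffled = net.copy()
    shuffled.species = list(reversed(shuffled.species))
    shuffled.reactions = list(reversed(shuffled.reactions))
    shuffled.parameters = list(reversed(shuffled.parameters))
    path2 = tmp_path / "b.xml"
    export_sbml(shuffled, path2)
    assert diff_networks(import_sbml(path), import_sbml(path2)) == []


def test_legacy_names_normalised_on_import(base_model, tmp_path):
    """A file written with predecessor species names imports with the
    modern names (AggAbeta -> AbDim etc.)."""
    path = tmp_path / "base.xml"
    export_sbml(base_model, path)
    net = import_sbml(path)
    assert net.has_species("AbDim") and not net.has_species("AggAbeta")


def test_diff_reports_single_parameter_change(full_model):
    other = full_model.with_parameter(
        "k_degAbeta", 2 * full_model.get_parameter("k_degAbeta").value)
    report = diff_networks(full_model, other)
    assert len(report) == 1 and "k_degAbeta" in report[0]


def test_diff_reports_missing_reaction(full_model):
    other = full_model.copy()
    other.reactions = [r for r in other.reactions if r.id != "PlaqueGrowth"]
    report = diff_networks(full_model, other)
    assert len(report) == 1 and "PlaqueGrowth" in report[0]


def test_export_refuses_invalid_network(tmp_path):
    net = make_fixture("decay")
    net.reactions[0].reactants = {"Ghost": 1}
    with pytest.raises(ValueError, match="Ghost"):
        export_sbml(net, tmp_path / "bad.xml")


def test_parse_failure_is_io_error(tmp_path):
    p = tmp_path / "broken.xml"
    p.write_text("<sbml><model>")
    with pytest.raises(SbmlError):
        import_sbml(p)


def test_unsupported_construct_named(tmp_path, full_model):
    path = tmp_path / "rules.xml"
    export_sbml(make_fixture("decay"), path)
    tree = etree.parse(str(path))
    model = tree.getroot()[0]
    ns = "{http://www.sbml.org/sbml/level2/version4}"
    model.append(etree.SubElement(model, ns + "listOfRules"))
    tree.write(str(path))
    with pytest.raises(UnsupportedConstructError, match="listOfRules"):
        import_sbml(path)


def test_unclassified_kinetic_law_still_simulates(tmp_path):
    """A law outside the recognised patterns is kept as an interpreted
    expression and both engines still run (classification never blocks)."""
    path = tmp_path / "weird.xml"
    export_sbml(make_fixture("decay"), path)
    text = path.read_text()
    # replace the law k*A with k*A*A/(A) — same value, unrecognisable shape
    law = ("<apply><times/><ci> k </ci><ci> A </ci>"
           "<apply><divide/><ci> A </ci><ci> A </ci></apply></apply>")
    import re
    text = re.sub(r"<apply>.*</apply>", law, text, count=1, flags=re.S)
    path.write_text(text)
    net = import_sbml(path)
    assert net.reactions[0].rate_law.kind == "expression"
    tr = simulate_ode(net, 12 * DAY, output_step=DAY)
    expected = 50 * np.exp(-2.75e-6 * tr.grid)
    assert np.allclose(tr.series("A"), expected, rtol=1e-5)
    from abtau.ssa import simulate_ssa
    tr2 = simulate_ssa(net, 2 * DAY, grid_step=DAY, seed=0)
    assert tr2.values.min() >= 0
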