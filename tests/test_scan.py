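"""Parameter-scan mechanics, ranking and rank correlation."""

import numpy as np
import pandas as pd
import pytest

from abtau.reference import (DIRECTION_TABLE, OUTPUTS, PLAQUE_RANKING,
                             TANGLE_RANKING, reference_rank_pairs)
from abtau.scan import (ScanSettings, count_directions, rank_by_effect,
                        rank_correlation, scan_all, scan_model)

FAST = ScanSettings(rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="module")
def two_param_scan():
    return scan_all(scan_model(), FAST, parameters=["k_degAbeta", "k_prodAbeta2"])


def test_identity_factor_gives_zero_changes():
    settings = ScanSettings(factors=(1.0,), rtol=1e-6, atol=1e-8)
    res = scan_all(scan_model(), settings, parameters=["k_degAbeta", "k_prodAbeta2"])
    assert (res.pct_decrease == 0).all()
    assert (res.effect == 0).all()


def test_doubling_clearance_decreases_all_outputs(two_param_scan):
    """Faster monomer clearance starves every downstream output."""
    sub = two_param_scan[(two_param_scan.parameter == "k_degAbeta")
                         & (two_param_scan.factor == 2.0)]
    assert (sub.effect == -1).all()


def test_doubling_gsk3_driven_production_increases_all_outputs(two_param_scan):
    """More Abeta production through the active GSK3beta pool raises every
    reported output."""
    sub = two_param_scan[(two_param_scan.parameter == "k_prodAbeta2")
                         & (two_param_scan.factor == 2.0)]
    assert (sub.effect == 1).all()


def test_pct_decrease_sign_convention(two_param_scan):
    sub = two_param_scan[(two_param_scan.parameter == "k_degAbeta")
                         & (two_param_scan.factor == 2.0)
                         & (two_param_scan.output == "AbP")]
    assert float(sub.pct_decrease.iloc[0]) > 0     # a decrease is positive


def test_single_parameter_rank_is_one(two_param_scan):
    table = rank_by_effect(
        two_param_scan[two_param_scan.parameter == "k_degAbeta"],
        "AbP", "soluble_Abeta")
    assert list(table["rank"]) == [1]
    assert table.direction.iloc[0] == "up"         # doubling clearance reduces plaque


def test_rank_table_properties(two_param_scan):
    table = rank_by_effect(two_param_scan, "AbP", "soluble_Abeta")
    assert list(table["rank"]) == sorted(table["rank"])
    pct = table["pct_decrease_AbP"].to_numpy()
    assert (np.diff(pct) <= 1e-12).all()           # sorted descending


def test_count_directions_forced_cases():
    assert count_directions(pd.DataFrame()) == (0, 0)
    table = pd.DataFrame({"direction": ["up", "up", "down"]})
    assert count_directions(table) == (2, 1)


def test_rank_correlation_identical_columns():
    r, p = rank_correlation([1, 2, 3, 4], [1, 2, 3, 4])
    assert r == pytest.approx(1.0)


def test_rank_correlation_constant_column_undefined():
    with pytest.raises(ValueError, match="constant"):
        rank_correlation([1, 1, 1], [1, 2, 3])


def test_rank_correlation_matches_closed_form():
    """Cross-check against the plain product-moment formula."""
    a = [1, 2, 3, 4, 5, 6]
    b = [2, 1, 4, 3, 6, 5]
    r, _ = rank_correlation(a, b)
    xa, xb = np.array(a, float), np.array(b, float)
    manual = (np.sum((xa - xa.mean()) * (xb - xb.mean()))
              / np.sqrt(np.sum((xa - xa.mean())**2) * np.sum((xb - xb.mean())**2)))
    assert r == pytest.approx(manual, rel=1e-12)


def test_published_plaque_rank_correlation():
    """The published plaque/soluble rank columns correlate at r = 0.493,
    p = 0.0077."""
    a, b = reference_rank_pairs("plaques")
    r, p = rank_correlation(a, b)
    assert round(r, 3) == 0.493
    assert p == pytest.approx(0.0077, abs=5e-4)


def test_published_tangle_rank_correlation():
    """Tangle/phospho-tau ranks (unranked entry at lowest rank) give
    r = 0.957, p < 2.2e-16."""
    a, b = reference_rank_pairs("tangles")
    r, p = rank_correlation(a, b)
    assert round(r, 3) == 0.957
    assert p < 2.2e-16


def test_published_plaque_direction_split_is_14_14():
    ups = sum(1 for row in PLAQUE_RANKING if row[2] == "up")
    downs = sum(1 for row in PLAQUE_RANKING if row[2] == "down")
    assert (ups, downs) == (14, 14)


def test_reference_tables_consistent():
    assert len(PLAQUE_RANKING) == 28
    assert len(TANGLE_RANKING) == 36
    # every plaque-affecting parameter also affects tangles
    plaque_params = {row[1] for row in PLAQUE_RANKING}
    tangle_params = {row[1] for row in TANGLE_RANKING}
    assert plaque_params <= tangle_params
    # eight parameters are tau-specific
    assert len(tangle_params - plaque_params) == 8
    # all direction-table parameters are known outputs-wide tuples
    for pid, (cls, dirs) in DIRECTION_TABLE.items():
        assert len(dirs) == len(OUTPUTS)
        assert cls in ("aggregation", "dna-damage")


def test_failed_integration_recorded_not_raised(two_param_scan, monkeypatch):
    import abtau.scan as scan_mod

    def boom(net, settings):
        raise RuntimeError("integrator failure")

    baseline = scan_mod._maxima(scan_model(), FAST)
    monkeypatch.setattr(scan_mod, "_maxima",
                        lambda net, settings: baseline if net.get_parameter(
                            "k_pg").value == scan_model().get_parameter("k_pg").value
                        else (_ for _ in ()).throw(RuntimeError("fail")))
    res = scan_mod.scan_all(scan_model(), FAST, parameters=["k_pg"])
    assert res.failed.all()
    assert res.max_level.isna().all()
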