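"""Leave-one-out membership sensitivity: rows, identities and summaries."""

import pytest

from dispaq import (
    Panel,
    PanelRecord,
    RegionDefinition,
    leave_one_out,
    summarize_sensitivity,
    weighted_regional_le,
)
from dispaq.synthetic import OUTLIER_ID

PERIODS = ("1965-1970", "2005-2010")


def test_three_country_toy_removal_arithmetic(toy_panel, toy_region):
    result = leave_one_out(toy_panel, toy_region, PERIODS, "both")
    by_removed = {r.removed_country: r for r in result.rows}
    # equal pops: full mean 70 in 1965-70; removing the 60 country -> 75
    assert result.baseline.le["1965-1970"] == pytest.approx(70.0)
    assert by_removed["A"].le_without["1965-1970"] == pytest.approx(75.0)
    assert by_removed["A"].delta_le["1965-1970"] == pytest.approx(5.0)
    # removing the country at the mean leaves the aggregate unchanged
    assert by_removed["B"].delta_le["1965-1970"] == pytest.approx(0.0)
    assert by_removed["C"].delta_le["1965-1970"] == pytest.approx(-5.0)


def test_removal_direction_tracks_le_vs_weighted_mean(outlier_panel, outlier_region):
    result = leave_one_out(outlier_panel, outlier_region, PERIODS, "both")
    for row in result.rows:
        for lbl in PERIODS:
            rec = outlier_panel.get(row.removed_country, lbl, "both")
            full = result.baseline.le[lbl]
            if rec.le < full:
                assert row.delta_le[lbl] > 0
            elif rec.le > full:
                assert row.delta_le[lbl] < 0


def test_population_identity_reconstructs_full_aggregate(outlier_panel, outlier_region):
    """le_full·P = le_without·(P − pop_r) + le_r·pop_r for every removal."""
    result = leave_one_out(outlier_panel, outlier_region, PERIODS, "both")
    for lbl in PERIODS:
        records = {c: outlier_panel.get(c, lbl, "both") for c in outlier_region.members}
        total_pop = sum(r.population for r in records.values())
        full = result.baseline.le[lbl]
        for row in result.rows:
            rec = records[row.removed_country]
            reconstructed = (
                row.le_without[lbl] * (total_pop - rec.population)
                + rec.le * rec.population
            )
            assert reconstructed == pytest.approx(full * total_pop, rel=1e-9)


def test_outlier_removal_gives_largest_positive_delta(outlier_panel, outlier_region):
    result = leave_one_out(outlier_panel, outlier_region, PERIODS, "both")
    deltas = {r.removed_country: r.delta_le["2005-2010"] for r in result.rows}
    assert max(deltas, key=deltas.get) == OUTLIER_ID


def test_summary_extrema_match_exhaustive_enumeration(outlier_panel, outlier_region):
    result = leave_one_out(outlier_panel, outlier_region, PERIODS, "both")
    summary = summarize_sensitivity(result)
    for lbl in PERIODS:
        # brute force: recompute every reduced aggregate independently
        values = {}
        for removed in sorted(outlier_region.members):
            values[removed] = weighted_regional_le(
                outlier_panel, outlier_region.without(removed), lbl, "both"
            )
        lo = min(values, key=lambda c: (values[c], c))
        hi = max(values, key=lambda c: (values[c], c))
        assert summary.le_without_min[lbl].removed_country == lo
        assert summary.le_without_min[lbl].value == pytest.approx(values[lo])
        assert summary.le_without_max[lbl].removed_country == hi
        assert summary.le_without_max[lbl].value == pytest.approx(values[hi])
    # metric-change extrema agree with the rows themselves
    id_changes = {r.removed_country: r.id_change_pct for r in result.rows}
    assert summary.metric_change_max["id_pct"].value == pytest.approx(max(id_changes.values()))
    assert summary.metric_change_min["id_pct"].value == pytest.approx(min(id_changes.values()))


def test_missing_member_is_flagged_not_dropped():
    records = [
        PanelRecord("A", "1965-1970", "both", 60, 1),
        PanelRecord("B", "1965-1970", "both", 70, 1),
        PanelRecord("C", "1965-1970", "both", 80, 1),
        PanelRecord("A", "2005-2010", "both", 65, 1),
        PanelRecord("B", "2005-2010", "both", 75, 1),
        # C has no 2005-2010 record
    ]
    panel = Panel(records=tuple(records))
    region = RegionDefinition(name="R", members=frozenset({"A", "B", "C"}))
    result = leave_one_out(panel, region, PERIODS, "both")
    by_removed = {r.removed_country: r for r in result.rows}
    assert by_removed["C"].flags
    assert "2005-2010" in by_removed["C"].flags[0]
    assert not by_removed["A"].flags


def test_region_below_two_members_rejected(toy_panel):
    solo = RegionDefinition(name="Solo", members=frozenset({"A"}))
    with pytest.raises(ValueError):
        leave_one_out(toy_panel, solo, PERIODS, "both")


def test_influence_grows_with_population_share():
    """|delta_le| increases with the removed country's population share at a
    fixed LE deviation from the rest of the region."""
    deltas = []
    for share_pop in (1.0, 3.0, 9.0):
        records = [
            PanelRecord("low", "1965-1970", "both", 55.0, share_pop),
            PanelRecord("a", "1965-1970", "both", 70.0, 5.0),
            PanelRecord("b", "1965-1970", "both", 70.0, 5.0),
            PanelRecord("low", "2005-2010", "both", 60.0, share_pop),
            PanelRecord("a", "2005-2010", "both", 75.0, 5.0),
            PanelRecord("b", "2005-2010", "both", 75.0, 5.0),
        ]
        panel = Panel(records=tuple(records))
        region = RegionDefinition(name="R", members=frozenset({"low", "a", "b"}))
        result = leave_one_out(panel, region, PERIODS, "both")
        row = {r.removed_country: r for r in result.rows}["low"]
        deltas.append(abs(row.delta_le["1965-1970"]))
    assert deltas[0] < deltas[1] < deltas[2]
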