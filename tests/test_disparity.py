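"""The six disparity metrics, suite assembly, percent change and reductions."""

import numpy as np
import pytest

from dispaq import (
    UndefinedChangeError,
    average_reduction,
    between_group_variance,
    disparity_suite,
    disparity_suite_from_values,
    index_of_disparity,
    mean_difference_from_best,
    percent_change,
    range_difference,
    range_ratio,
    suite_change,
    symmetric_theil,
)
from oracles import oracle_sti

HAITI_MARTINIQUE = [60.7, 80.1]  # worst/best Caribbean LE, 2005-10


def test_range_difference_examples():
    assert range_difference(HAITI_MARTINIQUE) == pytest.approx(19.4)
    assert range_difference([70, 70, 70]) == 0.0
    assert range_difference([50, 60, 70]) == pytest.approx(20.0)  # interior ignored
    with pytest.raises(ValueError):
        range_difference([])


def test_range_ratio_examples_and_scale_invariance():
    assert range_ratio([70, 70]) == 1.0
    assert range_ratio(HAITI_MARTINIQUE) == pytest.approx(1.3196046128500822, rel=1e-12)
    les = [55.0, 61.2, 79.9]
    assert range_ratio([3.7 * v for v in les]) == pytest.approx(range_ratio(les), rel=1e-12)
    with pytest.raises(ValueError):
        range_ratio([0.0, 70.0])


def test_mean_difference_from_best_denominator_conventions():
    les = [70.0, 68.0, 64.0]
    assert mean_difference_from_best(les) == pytest.approx(8 / 3)
    assert mean_difference_from_best(les, include_reference=False) == pytest.approx(4.0)
    assert mean_difference_from_best([70, 70]) == 0.0
    assert mean_difference_from_best([62.1]) == 0.0  # degenerate single country
    assert mean_difference_from_best([62.1], include_reference=False) == 0.0


def test_index_of_disparity_examples():
    les = [70.0, 68.0, 64.0]
    assert index_of_disparity(les) == pytest.approx(100 * (8 / 3) / 70)
    assert index_of_disparity([70, 70, 70]) == 0.0
    assert index_of_disparity([2 * v for v in les]) == pytest.approx(
        index_of_disparity(les), rel=1e-12
    )


def test_between_group_variance_hand_examples():
    assert between_group_variance([60, 70], [1, 1]) == pytest.approx(25.0)
    assert between_group_variance([70, 70, 70], [5, 2, 9]) == 0.0
    # mu = 62.5; 0.75·6.25 + 0.25·56.25 = 18.75 (checked against an
    # unweighted expansion replicating each country pop_i times)
    assert between_group_variance([60, 70], [3, 1]) == pytest.approx(18.75)
    with pytest.raises(ValueError):
        between_group_variance([60, 70], [1, 1, 1])
    with pytest.raises(ValueError):
        between_group_variance([60, 70], [0, 0])


def test_symmetric_theil_frozen_oracle_values():
    # independent direct-summation oracle values for le {60, 70}, equal pops
    dec = symmetric_theil([60.0, 70.0], [1.0, 1.0], scale=1.0)
    assert dec.theil == pytest.approx(0.002961504541, abs=1e-11)
    assert dec.mld == pytest.approx(0.002967367760, abs=1e-11)
    assert dec.sti == pytest.approx(0.002964436151, abs=1e-11)
    assert dec.sti == pytest.approx(
        oracle_sti([60.0, 70.0], [1.0, 1.0]), rel=1e-12
    )
    zero = symmetric_theil([70, 70, 70], [1, 2, 3], scale=1000.0)
    assert zero.theil == 0.0 and zero.mld == 0.0 and zero.sti == 0.0
    with pytest.raises(ValueError):
        symmetric_theil([60.0, -1.0], [1, 1])


def test_sti_scale_multiplies_only_the_reported_value():
    a = symmetric_theil([58, 72, 66], [2, 1, 4], scale=1.0)
    b = symmetric_theil([58, 72, 66], [2, 1, 4], scale=10000.0)
    assert b.theil == a.theil and b.mld == a.mld
    assert b.sti == pytest.approx(1e4 * a.sti, rel=1e-12)


def test_bgv_matches_sti_small_dispersion_limit():
    # BGV ≈ 2 μ² · STI_unscaled as relative dispersion shrinks
    mu = 70.0
    rel_err = []
    for eps in (1.0, 0.1, 0.01):
        les = [mu - eps, mu + eps]
        pops = [1.0, 1.0]
        bgv = between_group_variance(les, pops)
        sti = symmetric_theil(les, pops, scale=1.0).sti
        rel_err.append(abs(2 * mu**2 * sti - bgv) / bgv)
    assert rel_err[0] > rel_err[1] > rel_err[2]
    assert rel_err[2] < 1e-6


def test_disparity_suite_degenerate_and_equal_slices(equality_panel):
    from dispaq import RegionDefinition

    region = RegionDefinition(name="Eq", members=frozenset(equality_panel.countries))
    suite = disparity_suite(equality_panel, region, "1965-1970", "both")
    assert suite.ler == 1.0
    for metric in ("led", "md", "id_pct", "bgv", "sti"):
        assert suite.metric(metric) == pytest.approx(0.0, abs=1e-12)

    solo = RegionDefinition(name="Solo", members=frozenset({"C01"}))
    suite = disparity_suite(equality_panel, solo, "1965-1970", "both")
    assert suite.n_countries == 1
    assert suite.ler == 1.0
    assert suite.led == suite.md == suite.id_pct == suite.bgv == suite.sti == 0.0


def test_disparity_suite_reference_tiebreak_is_lexicographic():
    suite = disparity_suite_from_values(
        "R", "1965-1970", "both",
        countries=["B", "A", "C"], les=[80.0, 80.0, 60.0], populations=[1, 1, 1],
    )
    assert suite.reference_country == "A"
    assert suite.n_countries == 3


@pytest.mark.parametrize(
    "v_from,v_to,expected",
    [
        (1.55, 1.33, -14.19),   # published LE-ratio change, Caribbean women
        (52.41, 5.43, -89.64),  # published STI change, Central America women
        (4.0, 4.0, 0.0),
    ],
)
def test_percent_change_examples(v_from, v_to, expected):
    assert round(percent_change(v_from, v_to), 2) == expected


def test_percent_change_zero_baseline_is_undefined():
    with pytest.raises(UndefinedChangeError):
        percent_change(0.0, 5.0)


def test_average_reduction_published_caribbean_headline():
    changes = {"led": -20.6, "md": -6.02, "bgv": -15.09,
               "ler": -13.73, "id_pct": -16.94, "sti": -39.66}
    avg_abs, avg_rel = average_reduction(changes)
    assert avg_abs == pytest.approx(-13.903333, abs=1e-6)
    assert avg_rel == pytest.approx(-23.443333, abs=1e-6)
    assert round(abs(avg_abs)) == 14 and round(abs(avg_rel)) == 23
    zeros = {m: 0.0 for m in changes}
    assert average_reduction(zeros) == (0.0, 0.0)
    with pytest.raises(ValueError):
        average_reduction({"led": -1.0})


def test_suite_change_wraps_percent_change_per_metric(toy_panel, toy_region):
    s0 = disparity_suite(toy_panel, toy_region, "1965-1970", "both")
    s1 = disparity_suite(toy_panel, toy_region, "2005-2010", "both")
    change = suite_change(s0, s1)
    for m in ("ler", "led", "md", "id_pct", "sti", "bgv"):
        assert change.per_metric_pct_change[m] == pytest.approx(
            percent_change(s0.metric(m), s1.metric(m))
        )
    assert change.avg_absolute_pct_change == pytest.approx(
        np.mean([change.per_metric_pct_change[m] for m in ("led", "md", "bgv")])
    )
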