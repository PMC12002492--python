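"""Unit and property tests for the contamination/risk index engine."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilrisk import indices as idx
from soilrisk.indices import (
    PLI_SCALE,
    ZC_SCALE,
    classify,
    contamination_factor,
    hazard_quotient,
    integral_score,
    pollution_load_index,
    round_half_up,
    total_pollution_index,
)
from soilrisk.reference import SURVEY_STATS

from conftest import make_table

cf_vectors = st.lists(
    st.floats(min_value=0.0, max_value=50.0, allow_nan=False), min_size=1, max_size=12
)


# --- elementary ratios -----------------------------------------------------


@pytest.mark.parametrize(
    "conc, background, expected",
    [(121.28, 60, 2.02), (910, 60, 15.17), (7.5, 7.5, 1.0), (0.0, 60, 0.0)],
)
def test_contamination_factor(conc, background, expected):
    assert round_half_up(contamination_factor(conc, background)) == expected


@pytest.mark.parametrize(
    "conc, mpc, expected", [(121.28, 55, 2.21), (203.85, 200, 1.02), (0.0, 55, 0.0)]
)
def test_hazard_quotient(conc, mpc, expected):
    assert round_half_up(hazard_quotient(conc, mpc)) == expected


def test_nonpositive_references_rejected():
    with pytest.raises(ValueError):
        contamination_factor(1.0, 0.0)
    with pytest.raises(ValueError):
        hazard_quotient(1.0, -5.0)


@given(
    conc=st.floats(min_value=0, max_value=1e5),
    mpc=st.floats(min_value=1e-3, max_value=1e5),
    k=st.floats(min_value=1e-3, max_value=1e3),
)
@settings(max_examples=50, derandomize=True)
def test_hazard_quotient_scale_invariant(conc, mpc, k):
    assert hazard_quotient(k * conc, k * mpc) == pytest.approx(hazard_quotient(conc, mpc))


# --- pollution load index --------------------------------------------------


def test_pli_survey_mean_cfs():
    """The published mean-CF vector gives PLI 1.31 over the 8 surviving CFs."""
    cfs = {"Fe": 0.99, "Mn": 0.92, "Cr": 0.46, "Sr": 1.93, "Zn": 2.02, "Cu": 0.81,
           "Pb": 1.47, "Ni": 1.71, "Mo": 0.23, "V": 0.05, "Hg": 1.22, "Co": 0.04}
    pli, n_used = pollution_load_index(cfs)
    assert n_used == 8
    assert round_half_up(pli) == 1.31


@pytest.mark.parametrize(
    "cfs, expected",
    [({"a": 1.0, "b": 4.0}, (2.0, 2)), ({"a": 0.9, "b": 0.9, "c": 0.9}, (0.9, 3)),
     ({"a": 0.5, "b": 0.1}, (0.0, 0))],
)
def test_pli_examples(cfs, expected):
    pli, n_used = pollution_load_index(cfs)
    assert (pytest.approx(pli), n_used) == expected


def test_pli_ignores_non_detected_elements():
    pli, n_used = pollution_load_index({"a": 2.0, "b": 3.0}, detected={"a": True, "b": False})
    assert pli == pytest.approx(2.0) and n_used == 1


def test_pli_empty_rejected():
    with pytest.raises(ValueError):
        pollution_load_index({})


@given(cf_vectors)
@settings(max_examples=100, derandomize=True)
def test_pli_permutation_invariant_and_bounded(cfs):
    values = {f"e{i}": v for i, v in enumerate(cfs)}
    pli, n = pollution_load_index(values)
    shuffled = dict(reversed(list(values.items())))
    pli2, n2 = pollution_load_index(shuffled)
    assert pli == pytest.approx(pli2) and n == n2
    surviving = [v for v in cfs if v > 0.7]
    if surviving:
        assert min(surviving) - 1e-12 <= pli <= max(surviving) + 1e-12


@given(cf_vectors, st.floats(min_value=1.0, max_value=100.0))
@settings(max_examples=100, derandomize=True)
def test_pli_scales_with_surviving_cfs(cfs, k):
    values = {f"e{i}": v for i, v in enumerate(cfs)}
    pli, n = pollution_load_index(values)
    if n == 0:
        return
    scaled = {e: (v * k if v > idx.PLI_EXCLUSION_CF else v) for e, v in values.items()}
    pli_k, n_k = pollution_load_index(scaled)
    assert n_k == n and pli_k == pytest.approx(k * pli, rel=1e-9)


# --- total pollution indicator --------------------------------------------


@pytest.mark.parametrize(
    "cfs, variant, expected",
    [
        ({"Sr": 1.93, "Zn": 2.02, "Ni": 1.71}, "literal", (1.66, 3)),
        ({"a": 0.3, "b": 1.2}, "literal", (0.0, 0)),
        ({"a": 2.67}, "literal", (0.67, 1)),
        ({"a": 2.67}, "classical", (2.67, 1)),
    ],
)
def test_total_pollution_index(cfs, variant, expected):
    zc, n = total_pollution_index(cfs, variant=variant)
    assert (pytest.approx(zc, abs=1e-9), n) == expected


@given(cf_vectors)
@settings(max_examples=100, derandomize=True)
def test_literal_zc_fixed_offset_below_classical(cfs):
    """ΣCF − n − 1 sits exactly 2 below the Saet form ΣCF − (n − 1)."""
    values = {f"e{i}": v for i, v in enumerate(cfs)}
    literal, n1 = total_pollution_index(values, variant="literal")
    classical, n2 = total_pollution_index(values, variant="classical")
    assert n1 == n2
    if n1 >= 1:
        assert literal == pytest.approx(classical - 2)
    else:
        assert literal == classical == 0.0


# --- integral score --------------------------------------------------------


def test_integral_score_hand_example():
    d, df, b = integral_score({"X": 3.0}, {"X": 2.0})
    assert (d, df) == (1.5, 0.5)
    assert b == pytest.approx(100 / 3)


def test_integral_score_neutral_soil():
    d, df, b = integral_score({"a": 0.5, "b": 1.0}, {"a": 10, "b": 20})
    assert d == pytest.approx(df) and b == 100.0


@given(cf_vectors)
@settings(max_examples=100, derandomize=True)
def test_b_is_100_iff_no_exceedance(cfs):
    values = {f"e{i}": v for i, v in enumerate(cfs)}
    mpcs = {e: 10.0 + 5 * i for i, e in enumerate(values)}
    _, _, b = integral_score(values, mpcs)
    assert 0 < b <= 100
    if max(cfs) <= 1:
        assert b == 100.0
    else:
        assert b < 100.0


def test_b_strictly_decreases_as_exceedance_grows():
    mpcs = {"a": 10.0, "b": 5.0}
    scores = [integral_score({"a": cf, "b": 0.4}, mpcs)[2] for cf in (1.5, 2.0, 4.0)]
    assert scores[0] > scores[1] > scores[2]


# --- brute-force subset oracle ---------------------------------------------


def _oracle(cfs, mpcs):
    """Exhaustive-enumeration oracle for PLI/Zc/D inclusion rules (<=4 elements)."""
    names = list(cfs)
    best_pli = (0.0, 0)
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(names, r):
            if all(cfs[e] > 0.7 for e in subset) and all(
                cfs[e] <= 0.7 for e in names if e not in subset
            ):
                prod = 1.0
                for e in subset:
                    prod *= cfs[e]
                best_pli = (prod ** (1.0 / r), r)
    anomalous = [e for e in names if cfs[e] >= 1.5]
    zc = sum(cfs[e] for e in anomalous) - len(anomalous) - 1 if anomalous else 0.0
    d = sum(max(cfs[e], 1.0) / mpcs[e] for e in names)
    return best_pli, (zc, len(anomalous)), d


@given(
    st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=1, max_size=4),
    st.lists(st.floats(min_value=0.5, max_value=100.0), min_size=4, max_size=4),
)
@settings(max_examples=100, derandomize=True)
def test_brute_force_oracle_agreement(cfs, mpcs):
    values = {f"e{i}": v for i, v in enumerate(cfs)}
    mpc_map = {e: mpcs[i] for i, e in enumerate(values)}
    oracle_pli, oracle_zc, oracle_d = _oracle(values, mpc_map)
    pli = pollution_load_index(values)
    zc = total_pollution_index(values)
    d, _, _ = integral_score(values, mpc_map)
    assert pli[1] == oracle_pli[1] and pli[0] == pytest.approx(oracle_pli[0])
    assert zc[1] == oracle_zc[1] and zc[0] == pytest.approx(oracle_zc[0])
    assert d == pytest.approx(oracle_d)


# --- descriptive statistics ------------------------------------------------


def test_constant_series_is_uniform(registry):
    table = make_table({"Zn": [50.0] * 5})
    stats = idx.descriptive_stats(table, registry)
    assert stats.loc["Zn", "sd"] == 0
    assert stats.loc["Zn", "cv_percent"] == 0
    assert stats.loc["Zn", "cv_regime"] == "uniform"


@pytest.mark.parametrize(
    "cv, regime",
    [(10, "uniform"), (32.9, "uniform"), (33.0, "random"), (50, "random"),
     (64.0, "random"), (66, "clustered"), (618, "clustered")],
)
def test_cv_regime_thresholds(cv, regime):
    assert idx.cv_regime(cv) == regime


def test_descriptive_stats_match_hand_computation(registry):
    values = [30.0, 60.0, 90.0, 120.0]
    table = make_table({"Zn": values})
    stats = idx.descriptive_stats(table, registry)
    x = np.asarray(values)
    assert stats.loc["Zn", "mean"] == pytest.approx(x.mean())
    assert stats.loc["Zn", "sd"] == pytest.approx(x.std(ddof=1))
    assert stats.loc["Zn", "cv_percent"] == pytest.approx(100 * x.std(ddof=1) / x.mean())
    # strict inequality against MPC 55: 3 of 4 sites over -> 75%
    assert stats.loc["Zn", "pct_over_mpc"] == 75


def test_descriptive_stats_needs_two_sites(registry):
    with pytest.raises(ValueError):
        idx.descriptive_stats(make_table({"Zn": [1.0]}, coords=np.array([[0.0, 0.0]])), registry)


# --- per-site and area-mean tables -----------------------------------------


def test_site_indices_background_soil(registry, elements):
    conc = {el: [registry[el].background] * 3 for el in elements}
    table = make_table(conc)
    si = idx.site_indices(table, registry)
    row = si.iloc[0]
    assert row["pli"] == pytest.approx(1.0)
    assert row["zc"] == 0.0 and row["b_score"] == 100.0
    assert row["pli_class"] == "low contamination" and row["zc_class"] == "permissible"


def test_site_indices_single_element_pli_is_cf(registry):
    table = make_table({"Zn": [90.0, 120.0]})
    si = idx.site_indices(table, registry)
    np.testing.assert_allclose(si["pli"], si["cf_Zn"])
    assert (si["n_pli"] == 1).all()


def test_area_mean_single_site_equals_site_row(registry, elements):
    rng = np.random.default_rng(5)
    conc = {el: [float(rng.uniform(0.5, 3) * registry[el].background)] for el in elements}
    table = make_table(conc, coords=np.array([[4000.0, 7000.0]]))
    summary = idx.area_mean_indices(table, registry)
    site_row = idx.site_indices(table, registry).iloc[0]
    full = summary["full_precision"]
    assert full["pli"] == pytest.approx(site_row["pli"])
    assert full["zc"] == pytest.approx(site_row["zc"])
    assert full["b_score"] == pytest.approx(site_row["b_score"])


def test_area_mean_reproduces_published_summary(registry):
    """Every cell of the published area-mean indicator table, at 2 d.p."""
    summary = idx.summarize_from_stats(SURVEY_STATS, registry)
    per_el = summary["per_element"]
    printed_cf = {"Fe": 0.99, "Mn": 0.92, "Cr": 0.46, "Sr": 1.93, "Zn": 2.02, "Cu": 0.81,
                  "Pb": 1.47, "Ni": 1.71, "Mo": 0.23, "V": 0.05, "Hg": 1.22, "Co": 0.04}
    printed_hq = {"Fe": 0.51, "Mn": 0.37, "Cr": 1.02, "Sr": 0.29, "Zn": 2.21, "Cu": 1.97,
                  "Pb": 1.47, "Ni": 1.71, "Mo": 0.23, "V": 0.05, "Hg": 1.22, "Co": 0.04}
    for el in printed_cf:
        assert round_half_up(per_el.loc[el, "mean_cf"]) == printed_cf[el], el
        assert round_half_up(per_el.loc[el, "mean_hq"]) == printed_hq[el], el
    assert round_half_up(summary["pli"]) == 1.31 and summary["n_pli"] == 8
    assert round_half_up(summary["zc"]) == 1.66 and summary["n_zc"] == 3
    assert round_half_up(summary["d"]) == 0.83
    assert round_half_up(summary["df"]) == 0.66
    assert summary["b_score"] == 79.52


# --- classification scales --------------------------------------------------


@pytest.mark.parametrize(
    "value, scale, label",
    [
        (1.66, ZC_SCALE, "permissible"),
        (16.0, ZC_SCALE, "permissible"),  # breakpoint -> lower class
        (16.001, ZC_SCALE, "moderately hazardous"),
        (-0.4, ZC_SCALE, "permissible"),
        (1.31, PLI_SCALE, "moderate contamination"),
        (3.38, PLI_SCALE, "considerable contamination"),
        (7.0, PLI_SCALE, "very high contamination"),
    ],
)
def test_classify(value, scale, label):
    assert classify(value, scale) == label


def test_classify_rejects_non_finite():
    with pytest.raises(ValueError):
        classify(math.nan, ZC_SCALE)


def test_scale_validation():
    with pytest.raises(ValueError):
        idx.ClassificationScale("bad", (2.0, 1.0), ("a", "b", "c"))
    with pytest.raises(ValueError):
        idx.ClassificationScale("bad", (1.0,), ("a",))
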