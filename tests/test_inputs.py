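"""N-input terms: formulas, additivity, linearity, oracle equivalence."""

import numpy as np
import pytest

from nbudget import (CROPS, Dataset, GeneratorConfig, compute_inputs,
                     ConfigurationError, atmospheric_deposition_n,
                     biological_fixation_n, chem_fertilizer_n, generate,
                     human_excrement_n, livestock_excrement_n,
                     merge_overrides, straw_return_n)

from conftest import make_record

ZERO_CROPS = {c: 0.0 for c in CROPS}


def test_chem_fertilizer_combines_pure_and_compound(params):
    rec = make_record(fertilizer_pure_n=1000.0, fertilizer_compound=1000.0)
    assert chem_fertilizer_n(rec, params) == 1350.0
    rec0 = make_record(fertilizer_pure_n=1234.5, fertilizer_compound=0.0)
    assert chem_fertilizer_n(rec0, params) == 1234.5


def test_deposition_rate_by_region_and_year(params):
    lower = make_record(reach="lower", province="jiangsu",
                        cropland_area=1000.0)
    assert atmospheric_deposition_n(lower, params) == pytest.approx(20950.0)
    plateau = make_record(year=2010, reach="upper", province="qinghai",
                          cropland_area=100.0)
    assert atmospheric_deposition_n(plateau, params) == pytest.approx(531.0)
    empty = make_record(cropland_area=0.0, paddy_area=0.0, upland_area=0.0)
    assert atmospheric_deposition_n(empty, params) == 0.0


def test_deposition_missing_year_is_configuration_error(params):
    rec = make_record(year=2005)
    with pytest.raises(ConfigurationError, match="2005"):
        atmospheric_deposition_n(rec, params)


def test_deposition_area_basis_switch(params):
    rec = make_record(cropland_area=1000.0, paddy_area=300.0,
                      upland_area=400.0, reach="lower")
    p2 = merge_overrides(params,
                         {"deposition_area_basis": "paddy_plus_upland"})
    assert atmospheric_deposition_n(rec, p2) == pytest.approx(700 * 20.95)


def test_fixation_rates_per_crop(params):
    peanut = make_record(sown_area={**ZERO_CROPS, "peanut": 10.0})
    assert biological_fixation_n(peanut, params) == 800.0
    cereal = make_record(sown_area={**ZERO_CROPS, "rice": 10.0,
                                    "wheat": 10.0})
    assert biological_fixation_n(cereal, params) == 450.0
    assert biological_fixation_n(make_record(sown_area=ZERO_CROPS),
                                 params) == 0.0


def test_crops_without_fixation_rate_contribute_zero(params):
    rec = make_record(sown_area={**ZERO_CROPS, "vegetables": 100.0,
                                 "maize": 100.0})
    assert biological_fixation_n(rec, params) == 0.0


def test_human_excrement_formula(params):
    rec = make_record(rural_adult_population=1000.0)
    assert human_excrement_n(rec, params) == pytest.approx(1700.0)
    assert human_excrement_n(
        make_record(rural_adult_population=0.0), params) == 0.0
    # full application of excrement is exactly 1/0.4 times the default
    p_full = merge_overrides(params, {"manure_applied_fraction": 1.0})
    assert human_excrement_n(rec, p_full) == pytest.approx(1700.0 * 2.5)


def test_livestock_excrement_formula_and_linearity(params):
    rec = make_record(livestock={"pigs": 100.0, "cattle": 10.0,
                                 "sheep": 0.0})
    assert livestock_excrement_n(rec, params) == pytest.approx(480.0)
    doubled = make_record(livestock={"pigs": 200.0, "cattle": 20.0,
                                     "sheep": 0.0})
    assert livestock_excrement_n(doubled, params) == pytest.approx(960.0)
    assert livestock_excrement_n(
        make_record(livestock={s: 0.0 for s in ("pigs", "cattle",
                                                "sheep")}), params) == 0.0


def test_straw_return_single_crop(params):
    p = merge_overrides(params, {"straw_params": {
        "rice": {"straw_seed_ratio": 1.0, "returned_fraction": 0.3,
                 "n_concentration": 0.005, "burned_fraction": 0.0}}})
    rec = make_record(crop_yield={**ZERO_CROPS, "rice": 10000.0})
    assert straw_return_n(rec, p) == pytest.approx(15.0)


def test_straw_return_zero_when_nothing_returned(params):
    overrides = {"straw_params": {c: {"returned_fraction": 0.0}
                                  for c in CROPS}}
    p = merge_overrides(params, overrides)
    assert straw_return_n(make_record(), p) == 0.0


def test_breakdown_component_sums_hold_exactly(params, synth_small):
    ds, _ = synth_small
    for ib in compute_inputs(ds, params):
        assert ib.n_recycn == ib.n_human + ib.n_livestin + ib.n_strawin
        assert ib.n_input_total == (ib.n_chemin + ib.n_atmin + ib.n_fin
                                    + ib.n_recycn)
        assert ib.n_fin == pytest.approx(
            ib.n_fin_symbiotic + ib.n_fin_nonsymbiotic, rel=1e-12)
        for term in (ib.n_chemin, ib.n_atmin, ib.n_fin, ib.n_human,
                     ib.n_livestin, ib.n_strawin):
            assert term >= 0.0


def naive_input_total(rec, p):
    """Spreadsheet-style recomputation, independent of the pipeline code."""
    total = rec.fertilizer_pure_n + 0.35 * rec.fertilizer_compound
    dep = {"qinghai_xizang": {2000: 3.65, 2010: 5.31},
           "upper_middle": {2000: 17.97, 2010: 23.28},
           "lower": {2000: 20.95, 2010: 26.55}}
    rc = ("qinghai_xizang" if rec.province in ("qinghai", "xizang")
          else "upper_middle" if rec.reach in ("upper", "middle")
          else "lower")
    total += rec.cropland_area * dep[rc][rec.year]
    for crop, rate in (("peanut", 80), ("soybean", 80), ("rice", 30),
                       ("wheat", 15)):
        total += rec.sown_area[crop] * rate
    total += 0.85 * rec.rural_adult_population * 5 * 0.4
    for sp, e in (("pigs", 8), ("cattle", 40), ("sheep", 5)):
        total += 0.4 * rec.livestock[sp] * e
    for crop, s in p.straw_params.items():
        total += (rec.crop_yield[crop] * s.straw_seed_ratio
                  * s.returned_fraction * s.n_concentration)
    return total


def test_totals_match_independent_oracle(params, synth_small):
    ds, _ = synth_small
    subset = Dataset(ds.records[:10])
    for ib, rec in zip(compute_inputs(subset, params), subset.records):
        assert ib.n_input_total == pytest.approx(
            naive_input_total(rec, params), rel=1e-12)


def test_terms_are_additive_over_counties(params, synth_small):
    ds, _ = synth_small
    ibs = compute_inputs(ds, params)
    total = sum(ib.n_input_total for ib in ibs)
    by_reach = sum(
        sum(ib.n_input_total
            for ib in compute_inputs(ds.subset_reach(reach), params))
        for reach in ("upper", "middle", "lower"))
    assert by_reach == pytest.approx(total, rel=1e-12)


def test_scaling_one_coefficient_scales_only_its_term(params):
    rec = make_record()
    ds = Dataset((rec,))
    base = compute_inputs(ds, params)[0]
    k = 3.0
    p2 = merge_overrides(params, {"fixation_rate": {
        "rice": params.fixation_rate["rice"] * k}})
    scaled = compute_inputs(ds, p2)[0]
    rice_term = rec.sown_area["rice"] * params.fixation_rate["rice"]
    assert scaled.n_fin == pytest.approx(
        base.n_fin + (k - 1) * rice_term, rel=1e-12)
    assert scaled.n_chemin == base.n_chemin
    assert scaled.n_recycn == base.n_recycn


def test_input_of_zeros_dataset_is_deposition_only(params):
    rec = make_record(
        sown_area=ZERO_CROPS, crop_yield=ZERO_CROPS,
        fertilizer_pure_n=0.0, fertilizer_compound=0.0,
        livestock={s: 0.0 for s in ("pigs", "cattle", "sheep")},
        rural_adult_population=0.0)
    ib = compute_inputs(Dataset((rec,)), params)[0]
    assert ib.n_input_total == ib.n_atmin > 0.0
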