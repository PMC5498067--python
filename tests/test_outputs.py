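"""N-output terms, fertilizer apportioning and mass closure."""

import pytest

from nbudget import (CROPS, AllocationError, Dataset, compute_inputs,
                     compute_outputs, fertilizer_split, gaseous_losses,
                     harvest_n, merge_overrides, residue_burn_n,
                     water_losses)
from nbudget.inputs import InputBreakdown

from conftest import make_record

ZERO_CROPS = {c: 0.0 for c in CROPS}


def _inputs_for(rec, params):
    return compute_inputs(Dataset((rec,)), params)[0]


def test_harvest_n_single_crop(params):
    p = merge_overrides(params, {"crop_n_content": {"rice": 0.012}})
    rec = make_record(crop_yield={**ZERO_CROPS, "rice": 100000.0})
    assert harvest_n(rec, p) == pytest.approx(1200.0)
    assert harvest_n(make_record(crop_yield=ZERO_CROPS), p) == 0.0


def test_harvest_matches_naive_loop(params, synth_small):
    ds, _ = synth_small
    for rec in ds.records[:10]:
        expected = sum(rec.crop_yield[c] * params.crop_n_content[c]
                       for c in CROPS)
        assert harvest_n(rec, params) == pytest.approx(expected, rel=1e-12)


def test_fertilizer_split_proportional_to_area(params):
    rec = make_record(fertilizer_pure_n=1000.0, fertilizer_compound=0.0,
                      paddy_area=60.0, upland_area=40.0,
                      cropland_area=100.0)
    split = fertilizer_split(rec, params)
    assert split == {"paddy": pytest.approx(600.0),
                     "upland": pytest.approx(400.0)}


def test_fertilizer_split_degenerate_and_conserving(params):
    all_paddy = make_record(fertilizer_pure_n=1000.0,
                            fertilizer_compound=0.0, paddy_area=50.0,
                            upland_area=0.0, cropland_area=50.0)
    assert fertilizer_split(all_paddy, params)["paddy"] == 1000.0
    rec = make_record(fertilizer_pure_n=777.7, fertilizer_compound=333.3)
    split = fertilizer_split(rec, params)
    assert split["paddy"] + split["upland"] == pytest.approx(
        777.7 + 0.35 * 333.3, rel=1e-12)


def test_fertilizer_with_no_area_is_allocation_error(params):
    rec = make_record(fertilizer_pure_n=10.0, paddy_area=0.0,
                      upland_area=0.0)
    with pytest.raises(AllocationError, match="C001"):
        fertilizer_split(rec, params)


def test_fixed_share_split_mode(params):
    p = merge_overrides(params, {"fert_split_mode": "fixed",
                                 "fert_split_paddy_share": 0.25})
    rec = make_record(fertilizer_pure_n=1000.0, fertilizer_compound=0.0)
    split = fertilizer_split(rec, p)
    assert split == {"paddy": 250.0, "upland": 750.0}


def test_gaseous_loss_fractions(params):
    rec = make_record(fertilizer_pure_n=1000.0, fertilizer_compound=0.0,
                      paddy_area=100.0, upland_area=0.0,
                      cropland_area=100.0,
                      livestock={s: 0.0 for s in ("pigs", "cattle",
                                                  "sheep")},
                      rural_adult_population=0.0)
    ib = _inputs_for(rec, params)
    denit, nh3 = gaseous_losses(rec, ib, params)
    assert denit["paddy"] == pytest.approx(360.0)
    assert nh3["paddy"] == pytest.approx(160.0)
    assert denit["upland"] == nh3["upland"] == 0.0
    assert denit["manure"] == nh3["manure"] == 0.0


def test_water_loss_fractions(params):
    rec = make_record(fertilizer_pure_n=1000.0, fertilizer_compound=0.0,
                      paddy_area=100.0, upland_area=0.0,
                      cropland_area=100.0,
                      livestock={s: 0.0 for s in ("pigs", "cattle",
                                                  "sheep")},
                      rural_adult_population=0.0)
    ib = _inputs_for(rec, params)
    water = water_losses(rec, ib, params)
    assert water["chem_runoff"] == pytest.approx(52.0)
    assert water["chem_leach"] == pytest.approx(12.0)
    assert water["organic_runoff"] == water["organic_leach"] == 0.0


def test_losses_match_naive_oracle(params, synth_small):
    ds, _ = synth_small
    ibs = compute_inputs(ds, params)
    obs = compute_outputs(ds, ibs, params)
    for rec, ib, ob in list(zip(ds.records, ibs, obs))[:8]:
        chem = rec.fertilizer_pure_n + 0.35 * rec.fertilizer_compound
        paddy = chem * rec.paddy_area / (rec.paddy_area + rec.upland_area)
        upland = chem - paddy
        manure = ib.n_human + ib.n_livestin
        assert ob.denit_total == pytest.approx(
            0.36 * paddy + 0.25 * upland + 0.15 * manure, rel=1e-12)
        assert ob.nh3_total == pytest.approx(
            0.16 * paddy + 0.11 * upland + 0.23 * manure, rel=1e-12)
        assert ob.water_total == pytest.approx(
            0.052 * paddy + 0.012 * paddy + 0.11 * upland
            + 0.032 * upland + 0.09 * manure, rel=1e-12)


def test_residue_burn_formula(params):
    p = merge_overrides(params, {"straw_params": {
        "rice": {"straw_seed_ratio": 1.0, "returned_fraction": 0.3,
                 "n_concentration": 0.005, "burned_fraction": 0.2}}})
    rec = make_record(crop_yield={**ZERO_CROPS, "rice": 10000.0})
    assert residue_burn_n(rec, p) == pytest.approx(10000 * 1.0 * 0.2
                                                   * 0.00383)
    p0 = merge_overrides(params, {"straw_params": {
        c: {"burned_fraction": 0.0} for c in CROPS}})
    assert residue_burn_n(make_record(), p0) == 0.0


def test_mass_closure_per_county(params, synth_small):
    ds, _ = synth_small
    ibs = compute_inputs(ds, params)
    obs = compute_outputs(ds, ibs, params)
    for ib, ob in zip(ibs, obs):
        assert ob.budget == ib.n_input_total - ob.n_harvout
        recombined = (ob.n_harvout + ob.n_burn + ob.nh3_total
                      + ob.denit_total + ob.water_total + ob.n_stored)
        assert recombined == pytest.approx(ib.n_input_total, rel=1e-12)


def test_zero_loss_fractions_leave_residual_as_budget_minus_burn(params):
    zero_losses = {
        "denitrification_frac": {k: 0.0 for k in ("paddy", "upland",
                                                  "manure")},
        "nh3_frac": {k: 0.0 for k in ("paddy", "upland", "manure")},
        "runoff_frac": {k: 0.0 for k in ("paddy", "upland", "organic")},
        "leaching_frac": {k: 0.0 for k in ("paddy", "upland", "organic")},
    }
    p = merge_overrides(params, zero_losses)
    rec = make_record()
    ds = Dataset((rec,))
    ib = compute_inputs(ds, p)[0]
    ob = compute_outputs(ds, compute_inputs(ds, p), p)[0]
    assert ob.n_stored == pytest.approx(ob.budget - ob.n_burn, rel=1e-12)


def test_raising_a_loss_fraction_weakly_decreases_storage(params):
    rec = make_record()
    ds = Dataset((rec,))
    base = compute_outputs(ds, compute_inputs(ds, params), params)[0]
    p2 = merge_overrides(params,
                         {"denitrification_frac": {"upland": 0.30}})
    higher = compute_outputs(ds, compute_inputs(ds, p2), p2)[0]
    assert higher.n_stored <= base.n_stored


def test_organic_pool_can_include_straw(params):
    p = merge_overrides(params, {"organic_pool_includes_straw": True})
    rec = make_record()
    ds = Dataset((rec,))
    ib = compute_inputs(ds, p)[0]
    _, nh3 = gaseous_losses(rec, ib, p)
    _, nh3_base = gaseous_losses(rec, ib, params)
    assert nh3["manure"] == pytest.approx(
        nh3_base["manure"] + 0.23 * ib.n_strawin, rel=1e-12)


def test_subterm_additivity_over_counties(params, synth_small):
    ds, _ = synth_small
    ibs = compute_inputs(ds, params)
    obs = compute_outputs(ds, ibs, params)
    total_denit = sum(ob.denit_total for ob in obs)
    per_reach = 0.0
    for reach in ("upper", "middle", "lower"):
        sub = ds.subset_reach(reach)
        sub_obs = compute_outputs(sub, compute_inputs(sub, params), params)
        per_reach += sum(ob.denit_total for ob in sub_obs)
    assert per_reach == pytest.approx(total_denit, rel=1e-12)
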