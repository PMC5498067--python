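"""Basin accounting fixture built from the study's printed component values.

The published accounting table reports each flow in Tg at one decimal.
Those component values are injected here directly as county-level flows
(in kg) so the aggregation and change operations can be checked against
the printed totals. Two sub-rows are adjusted within the printed
rounding so the component sums match the bold aggregate rows exactly:
excrement 2000 is taken as 2.0 (so straw 0.9 + excrement = recycled 2.9
as printed) and the fixation split 2010 is left as printed (0.2 + 0.6)
under the bold 0.9.
"""

from nbudget import CountyRecord, Dataset
from nbudget.inputs import InputBreakdown
from nbudget.outputs import OutputBreakdown

TG = 1e9

# printed component values, Tg
TABLE1 = {
    2000: dict(fertilizer=8.4, fixation=1.0, sym=0.4, nonsym=0.6,
               deposition=0.5, straw=0.9, excrement=2.0,
               harvest=4.6, burn=0.5,
               nh3=(0.7, 0.4, 0.7), denit=(1.7, 1.0, 0.4), water=1.1),
    2010: dict(fertilizer=9.5, fixation=0.9, sym=0.2, nonsym=0.6,
               deposition=0.6, straw=0.9, excrement=2.2,
               harvest=5.2, burn=0.6,
               nh3=(0.8, 0.5, 0.7), denit=(1.7, 1.2, 0.5), water=1.3),
}

#: cropland area assumed for the single proxy county (ha); only NSI
#: depends on it and NSI is not checked against the printed table.
PROXY_AREA = 2.0e7


def build_fixture():
    """(dataset, inputs, outputs) carrying the printed component values."""
    records, inputs, outputs = [], [], []
    for year, v in TABLE1.items():
        records.append(CountyRecord(
            county_id="BASIN", year=year, reach="middle",
            cropland_area=PROXY_AREA, paddy_area=PROXY_AREA * 0.5,
            upland_area=PROXY_AREA * 0.5))
        recycled = (v["straw"] + v["excrement"]) * TG
        total = (v["fertilizer"] + v["fixation"] + v["deposition"]) * TG \
            + recycled
        ib = InputBreakdown(
            county_id="BASIN", year=year,
            n_chemin=v["fertilizer"] * TG,
            n_atmin=v["deposition"] * TG,
            n_fin=v["fixation"] * TG,
            n_human=0.0,
            n_livestin=v["excrement"] * TG,
            n_strawin=v["straw"] * TG,
            n_recycn=recycled,
            n_input_total=total,
            n_fin_symbiotic=v["sym"] * TG,
            n_fin_nonsymbiotic=v["nonsym"] * TG)
        inputs.append(ib)
        denit = dict(zip(("paddy", "upland", "manure"),
                         (x * TG for x in v["denit"])))
        nh3 = dict(zip(("paddy", "upland", "manure"),
                       (x * TG for x in v["nh3"])))
        water = {"chem_runoff": v["water"] * TG, "chem_leach": 0.0,
                 "organic_runoff": 0.0, "organic_leach": 0.0}
        budget = total - v["harvest"] * TG
        stored = (budget - v["burn"] * TG - sum(nh3.values())
                  - sum(denit.values()) - sum(water.values()))
        outputs.append(OutputBreakdown(
            county_id="BASIN", year=year, n_harvout=v["harvest"] * TG,
            denit=denit, nh3=nh3, n_water=water, n_burn=v["burn"] * TG,
            budget=budget, n_stored=stored))
    return Dataset(tuple(records)), tuple(inputs), tuple(outputs)
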