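"""N-output and loss terms of the soil-surface balance, per county-year.

Outputs are N removed in harvested crops plus losses to the environment:
denitrification, NH3 volatilization, riverine transfer by runoff and
leaching, and residue combustion. The remainder is N stored in cropland,
defined as the closing residual so that the county budget closes exactly:

    budget   = N_input_total - N_harvest
    N_stored = budget - N_burn - sum(NH3) - sum(denit) - sum(N_water)

Loss fractions are class-specific (paddy vs upland for chemical
fertilizer, an organic-manure pool for applied excrement), so county
fertilizer N is first apportioned between paddy and upland. N2O and NO
emissions are omitted (a very small share of inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .data_model import CROPS, CountyRecord, Dataset
from .errors import AllocationError
from .inputs import InputBreakdown, chem_fertilizer_n
from .parameters import ParameterSet


@dataclass(frozen=True)
class OutputBreakdown:
    """Per-county N outputs, losses and the storage residual, kg N/y."""

    county_id: str
    year: int
    n_harvout: float
    denit: Mapping[str, float]     # paddy / upland / manure
    nh3: Mapping[str, float]       # paddy / upland / manure
    n_water: Mapping[str, float]   # chem_runoff / chem_leach / organic_runoff / organic_leach
    n_burn: float
    budget: float
    n_stored: float                # residual; may be negative

    @property
    def denit_total(self) -> float:
        return sum(self.denit.values())

    @property
    def nh3_total(self) -> float:
        return sum(self.nh3.values())

    @property
    def water_total(self) -> float:
        return sum(self.n_water.values())


def harvest_n(rec: CountyRecord, p: ParameterSet) -> float:
    """N removed in harvested crops: yield times product N content."""
    return sum(rec.crop_yield[crop] * p.crop_n_content.get(crop, 0.0)
               for crop in CROPS)


def harvest_n_by_crop(rec: CountyRecord, p: ParameterSet) -> dict[str, float]:
    return {crop: rec.crop_yield[crop] * p.crop_n_content.get(crop, 0.0)
            for crop in CROPS}


def fertilizer_split(rec: CountyRecord, p: ParameterSet) -> dict[str, float]:
    """Apportion county fertilizer N between paddy and upland.

    Default rule is proportional to the paddy:upland area split; a fixed
    paddy share can be configured instead. The shares always sum to the
    county's chemical fertilizer N.
    """
    n_chem = chem_fertilizer_n(rec, p)
    if n_chem == 0.0:
        return {"paddy": 0.0, "upland": 0.0}
    if p.fert_split_mode == "fixed":
        paddy = n_chem * p.fert_split_paddy_share
        return {"paddy": paddy, "upland": n_chem - paddy}
    total_area = rec.paddy_area + rec.upland_area
    if total_area <= 0.0:
        raise AllocationError(
            f"county {rec.county_id!r}, year {rec.year}: fertilizer N "
            f"{n_chem} > 0 but paddy and upland areas are both zero")
    paddy = n_chem * rec.paddy_area / total_area
    return {"paddy": paddy, "upland": n_chem - paddy}


def _organic_pool(inputs: InputBreakdown, p: ParameterSet) -> float:
    pool = inputs.n_human + inputs.n_livestin
    if p.organic_pool_includes_straw:
        pool += inputs.n_strawin
    return pool


def gaseous_losses(rec: CountyRecord, inputs: InputBreakdown,
                   p: ParameterSet) -> tuple[dict[str, float], dict[str, float]]:
    """Denitrification and NH3 volatilization by pool.

    Fixed fractions of each pool: chemical fertilizer on paddy and upland
    (after apportioning) and the applied organic manure (human plus
    livestock excrement N).
    """
    split = fertilizer_split(rec, p)
    manure = _organic_pool(inputs, p)
    denit = {
        "paddy": p.denitrification_frac["paddy"] * split["paddy"],
        "upland": p.denitrification_frac["upland"] * split["upland"],
        "manure": p.denitrification_frac["manure"] * manure,
    }
    nh3 = {
        "paddy": p.nh3_frac["paddy"] * split["paddy"],
        "upland": p.nh3_frac["upland"] * split["upland"],
        "manure": p.nh3_frac["manure"] * manure,
    }
    return denit, nh3


def water_losses(rec: CountyRecord, inputs: InputBreakdown,
                 p: ParameterSet) -> dict[str, float]:
    """Riverine N transfer: runoff and leaching of chemical and organic N."""
    split = fertilizer_split(rec, p)
    organic = _organic_pool(inputs, p)
    return {
        "chem_runoff": (p.runoff_frac["paddy"] * split["paddy"]
                        + p.runoff_frac["upland"] * split["upland"]),
        "chem_leach": (p.leaching_frac["paddy"] * split["paddy"]
                       + p.leaching_frac["upland"] * split["upland"]),
        "organic_runoff": p.runoff_frac["organic"] * organic,
        "organic_leach": p.leaching_frac["organic"] * organic,
    }


def residue_burn_n(rec: CountyRecord, p: ParameterSet) -> float:
    """N emitted by burning crop residues as fuel.

    Per crop: yield x straw/seed ratio x burned fraction x the
    N-emission conversion coefficient (kg N per kg residue burned).
    """
    total = 0.0
    for crop in CROPS:
        sp = p.straw_params.get(crop)
        if sp is None:
            continue
        total += (rec.crop_yield[crop] * sp.straw_seed_ratio
                  * sp.burned_fraction * p.burn_conversion)
    return total


def compute_outputs(ds: Dataset, inputs: tuple[InputBreakdown, ...],
                    p: ParameterSet) -> tuple[OutputBreakdown, ...]:
    """One OutputBreakdown per county-year, closing the budget exactly.

    ``inputs`` must come from :func:`nbudget.inputs.compute_inputs` on the
    same dataset and parameter set.
    """
    by_key = {(ib.county_id, ib.year): ib for ib in inputs}
    out = []
    for rec in ds.records:
        ib = by_key.get((rec.county_id, rec.year))
        if ib is None:
            raise KeyError(
                f"no InputBreakdown for county {rec.county_id!r}, "
                f"year {rec.year}")
        n_harv = harvest_n(rec, p)
        denit, nh3 = gaseous_losses(rec, ib, p)
        water = water_losses(rec, ib, p)
        n_burn = residue_burn_n(rec, p)
        budget = ib.n_input_total - n_harv
        n_stored = (budget - n_burn - sum(nh3.values())
                    - sum(denit.values()) - sum(water.values()))
        out.append(OutputBreakdown(
            county_id=rec.county_id, year=rec.year, n_harvout=n_harv,
            denit=denit, nh3=nh3, n_water=water, n_burn=n_burn,
            budget=budget, n_stored=n_stored))
    return tuple(out)
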