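"""Reach/basin aggregation, surplus intensity (NSI), use efficiency (NUE).

County flows (kg N/y) are summed to reach accounts; the basin account is
the sum of the three reaches, which guarantees additivity. Aggregates are
reported in Tg N/y (1 Tg = 1e9 kg), NSI in kg N/ha/y and NUE as a
dimensionless ratio. Rounding is applied only at presentation time and
never feeds back into computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .data_model import Dataset, REACHES
from .inputs import InputBreakdown
from .outputs import OutputBreakdown

logger = logging.getLogger("nbudget")

KG_PER_TG = 1e9

#: Canonical term keys of a region account, in Table-style order.
TERM_KEYS = (
    "fertilizer_n",
    "biological_fixation",
    "symbiotic_fixation",
    "non_symbiotic_fixation",
    "atmospheric_deposition",
    "recycled_n",
    "straw_returned",
    "excrement",
    "total_inputs",
    "harvest_n",
    "budget",
    "residue_combustion",
    "nh3_total", "nh3_paddy", "nh3_upland", "nh3_manure",
    "denit_total", "denit_paddy", "denit_upland", "denit_manure",
    "water_total",
    "n_stored",
)


@dataclass(frozen=True)
class RegionAccount:
    """Aggregated N flows for one region-year.

    ``terms`` are in kg N/y; :meth:`tg` converts on demand. ``nsi`` is
    budget per cropland area (kg N/ha/y); ``nue`` is harvest N over total
    input N. Either is None (with a logged warning) when its denominator
    is zero.
    """

    region: str  # upper / middle / lower / basin
    year: int
    terms: Mapping[str, float]
    cropland_area: float  # ha

    def tg(self, key: str) -> float:
        return self.terms[key] / KG_PER_TG

    @property
    def nsi(self) -> Optional[float]:
        if self.cropland_area <= 0.0:
            logger.warning("NSI undefined for %s %s: zero cropland area",
                           self.region, self.year)
            return None
        return self.terms["budget"] / self.cropland_area

    @property
    def nue(self) -> Optional[float]:
        if self.terms["total_inputs"] <= 0.0:
            logger.warning("NUE undefined for %s %s: zero total inputs",
                           self.region, self.year)
            return None
        return self.terms["harvest_n"] / self.terms["total_inputs"]


def _zero_terms() -> dict[str, float]:
    return {k: 0.0 for k in TERM_KEYS}


def _accumulate(terms: dict[str, float], ib: InputBreakdown,
                ob: OutputBreakdown) -> None:
    terms["fertilizer_n"] += ib.n_chemin
    terms["biological_fixation"] += ib.n_fin
    terms["symbiotic_fixation"] += ib.n_fin_symbiotic
    terms["non_symbiotic_fixation"] += ib.n_fin_nonsymbiotic
    terms["atmospheric_deposition"] += ib.n_atmin
    terms["recycled_n"] += ib.n_recycn
    terms["straw_returned"] += ib.n_strawin
    terms["excrement"] += ib.n_human + ib.n_livestin
    terms["total_inputs"] += ib.n_input_total
    terms["harvest_n"] += ob.n_harvout
    terms["budget"] += ob.budget
    terms["residue_combustion"] += ob.n_burn
    terms["nh3_paddy"] += ob.nh3["paddy"]
    terms["nh3_upland"] += ob.nh3["upland"]
    terms["nh3_manure"] += ob.nh3["manure"]
    terms["nh3_total"] += ob.nh3_total
    terms["denit_paddy"] += ob.denit["paddy"]
    terms["denit_upland"] += ob.denit["upland"]
    terms["denit_manure"] += ob.denit["manure"]
    terms["denit_total"] += ob.denit_total
    terms["water_total"] += ob.water_total
    terms["n_stored"] += ob.n_stored


def aggregate(inputs: Sequence[InputBreakdown],
              outputs: Sequence[OutputBreakdown],
              ds: Dataset) -> dict[tuple[str, int], RegionAccount]:
    """Aggregate county breakdowns to reach and basin accounts.

    Returns a mapping keyed by (region, year), where region is a reach or
    ``"basin"``. The basin account is formed by summing the three reach
    accounts, so basin = sum of reaches holds exactly.
    """
    reach_by_key = {(r.county_id, r.year): r.reach for r in ds.records}
    area_by_key = {(r.county_id, r.year): r.cropland_area
                   for r in ds.records}
    out_by_key = {(ob.county_id, ob.year): ob for ob in outputs}

    acc_terms: dict[tuple[str, int], dict[str, float]] = {}
    acc_area: dict[tuple[str, int], float] = {}
    for ib in inputs:
        key = (ib.county_id, ib.year)
        reach = reach_by_key[key]
        ob = out_by_key[key]
        rkey = (reach, ib.year)
        terms = acc_terms.setdefault(rkey, _zero_terms())
        _accumulate(terms, ib, ob)
        acc_area[rkey] = acc_area.get(rkey, 0.0) + area_by_key[key]

    accounts: dict[tuple[str, int], RegionAccount] = {}
    years = sorted({year for _, year in acc_terms})
    for year in years:
        basin_terms = _zero_terms()
        basin_area = 0.0
        for reach in REACHES:
            rkey = (reach, year)
            if rkey not in acc_terms:
                continue
            accounts[rkey] = RegionAccount(
                region=reach, year=year, terms=dict(acc_terms[rkey]),
                cropland_area=acc_area[rkey])
            for k in TERM_KEYS:
                basin_terms[k] += acc_terms[rkey][k]
            basin_area += acc_area[rkey]
        accounts[("basin", year)] = RegionAccount(
            region="basin", year=year, terms=basin_terms,
            cropland_area=basin_area)
    return accounts


def nsi(account: RegionAccount) -> Optional[float]:
    """N surplus intensity: budget divided by cropland area, kg N/ha/y."""
    return account.nsi


def nue(account: RegionAccount) -> Optional[float]:
    """N use efficiency: harvested-crop N divided by total N input."""
    return account.nue


@dataclass(frozen=True)
class ChangeReport:
    """Per-term absolute and percent changes between two years."""

    region: str
    year0: int
    year1: int
    absolute: Mapping[str, float]          # kg N/y
    percent: Mapping[str, Optional[float]]  # None when the base term is 0
    nsi_change: Optional[float]
    nue_change: Optional[float]


def change_report(acc_t0: RegionAccount,
                  acc_t1: RegionAccount) -> ChangeReport:
    """Absolute and percent change per term between two accounts.

    Both accounts must describe the same region; percent change is
    missing (None) for terms whose base-year value is zero.
    """
    if acc_t0.region != acc_t1.region:
        raise ValueError(
            f"cannot compare regions {acc_t0.region!r} and "
            f"{acc_t1.region!r}")
    absolute: dict[str, float] = {}
    percent: dict[str, Optional[float]] = {}
    for k in TERM_KEYS:
        delta = acc_t1.terms[k] - acc_t0.terms[k]
        absolute[k] = delta
        base = acc_t0.terms[k]
        percent[k] = None if base == 0.0 else delta / base * 100.0
    nsi0, nsi1 = acc_t0.nsi, acc_t1.nsi
    nue0, nue1 = acc_t0.nue, acc_t1.nue
    return ChangeReport(
        region=acc_t0.region, year0=acc_t0.year, year1=acc_t1.year,
        absolute=absolute, percent=percent,
        nsi_change=None if nsi0 is None or nsi1 is None else nsi1 - nsi0,
        nue_change=None if nue0 is None or nue1 is None else nue1 - nue0,
    )


# ---------------------------------------------------------------------------
# Presentation
# ---------------------------------------------------------------------------

def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding used only for presentation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


_TABLE_ROWS = (
    ("Fertilizer N", "fertilizer_n"),
    ("Biological N fixation", "biological_fixation"),
    ("  Symbiotic N-fixation", "symbiotic_fixation"),
    ("  Non-symbiotic N-fixation", "non_symbiotic_fixation"),
    ("Atmospheric deposition", "atmospheric_deposition"),
    ("Recycled N", "recycled_n"),
    ("  Crop residue used as fertilizer", "straw_returned"),
    ("  Animal and human excrement", "excrement"),
    ("Total inputs", "total_inputs"),
    ("N in the harvested crops", "harvest_n"),
    ("Budget (inputs - crop harvest)", "budget"),
    ("Crop residue combustion", "residue_combustion"),
    ("NH3 volatilization", "nh3_total"),
    ("  Paddy rice", "nh3_paddy"),
    ("  Uplands", "nh3_upland"),
    ("  Organic manure", "nh3_manure"),
    ("Denitrification", "denit_total"),
    ("  Paddy rice", "denit_paddy"),
    ("  Uplands", "denit_upland"),
    ("  Organic manure", "denit_manure"),
    ("N transported to water bodies", "water_total"),
    ("N stored in cropland", "n_stored"),
)


def render_account_table(accounts: Mapping[tuple[str, int], RegionAccount],
                         region: str = "basin",
                         tg_decimals: int = 1) -> str:
    """Aligned-text accounting table (Tg N/y) for one region, all years."""
    years = sorted(year for r, year in accounts if r == region)
    header = f"{'':38s}" + "".join(f"{y:>10d}" for y in years)
    lines = [f"Estimated agricultural N inputs and outputs (Tg), "
             f"region: {region}", header]
    for label, key in _TABLE_ROWS:
        cells = "".join(
            f"{round_half_up(accounts[(region, y)].tg(key), tg_decimals):>10.{tg_decimals}f}"
            for y in years)
        lines.append(f"{label:38s}{cells}")
    for metric in ("nsi", "nue"):
        cells = ""
        for y in years:
            val = getattr(accounts[(region, y)], metric)
            if val is None:
                cells += f"{'--':>10s}"
            elif metric == "nsi":
                cells += f"{round_half_up(val, 0):>10.0f}"
            else:
                cells += f"{round_half_up(val, 2):>10.2f}"
        label = "NSI (kg N/ha/y)" if metric == "nsi" else "NUE (-)"
        lines.append(f"{label:38s}{cells}")
    return "\n".join(lines)
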