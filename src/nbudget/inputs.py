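"""N-input terms of the soil-surface balance, per county-year.

Inputs to cropland are synthetic fertilizer N, atmospheric bulk
deposition, biological fixation by crops, and recycled N (rural human
excrement, livestock excrement and returned crop residues):

    N_input = N_chem + N_atm + N_fix + N_recyc
    N_recyc = N_human + N_livestock + N_straw

All terms are kg N per year for one county.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .data_model import CROPS, CountyRecord, Dataset
from .errors import ConfigurationError
from .parameters import ParameterSet, region_class

#: Crops whose fixation is symbiotic (legumes) vs crop-associated.
SYMBIOTIC_CROPS = ("peanut", "soybean")
NON_SYMBIOTIC_CROPS = ("rice", "wheat")


@dataclass(frozen=True)
class InputBreakdown:
    """Per-county N inputs by term, kg N/y.

    ``n_recycn`` and ``n_input_total`` are exact sums of their
    components; ``n_fin_symbiotic``/``n_fin_nonsymbiotic`` split the
    fixation term for Table-style reporting.
    """

    county_id: str
    year: int
    n_chemin: float
    n_atmin: float
    n_fin: float
    n_human: float
    n_livestin: float
    n_strawin: float
    n_recycn: float
    n_input_total: float
    n_fin_symbiotic: float = 0.0
    n_fin_nonsymbiotic: float = 0.0

    def assert_consistent(self, rel_tol: float = 0.0) -> None:
        assert self.n_recycn == self.n_human + self.n_livestin + self.n_strawin
        assert self.n_input_total == (self.n_chemin + self.n_atmin
                                      + self.n_fin + self.n_recycn)


def chem_fertilizer_n(rec: CountyRecord, p: ParameterSet) -> float:
    """Synthetic fertilizer N: pure N plus the N share of compound product."""
    return rec.fertilizer_pure_n + p.compound_n_fraction * rec.fertilizer_compound


def atmospheric_deposition_n(rec: CountyRecord, p: ParameterSet) -> float:
    """Bulk NH4+/NO3- deposition: area times the regional rate for the year."""
    rc = region_class(rec.reach, rec.province)
    table = p.deposition_rate.get(rc, {})
    if rec.year not in table:
        raise ConfigurationError(
            f"no atmospheric deposition rate for region class {rc!r} in "
            f"year {rec.year}; supply one via deposition_rate overrides")
    if p.deposition_area_basis == "paddy_plus_upland":
        area = rec.paddy_area + rec.upland_area
    else:
        area = rec.cropland_area
    return area * table[rec.year]


def biological_fixation_n(rec: CountyRecord, p: ParameterSet) -> float:
    """Sum over crops of sown area times the fixation rate (kg N/ha/y).

    Crops without a fixation rate contribute zero.
    """
    return sum(rec.sown_area[crop] * rate
               for crop, rate in p.fixation_rate.items())


def _fixation_split(rec: CountyRecord, p: ParameterSet) -> tuple[float, float]:
    sym = sum(rec.sown_area[c] * p.fixation_rate.get(c, 0.0)
              for c in SYMBIOTIC_CROPS)
    nonsym = sum(rec.sown_area[c] * p.fixation_rate.get(c, 0.0)
                 for c in NON_SYMBIOTIC_CROPS)
    return sym, nonsym


def human_excrement_n(rec: CountyRecord, p: ParameterSet) -> float:
    """Rural human excrement N applied to cropland as manure.

    Adult population is converted to total rural population, multiplied
    by the per-person excretion coefficient, then by the fraction of
    excrement actually applied to fields.
    """
    return (p.adult_to_total_pop * rec.rural_adult_population
            * p.human_excretion_coeff * p.manure_applied_fraction)


def livestock_excrement_n(rec: CountyRecord, p: ParameterSet) -> float:
    """Livestock excrement N applied as manure: applied fraction times
    the sum of headcount x per-head excretion over species."""
    return p.manure_applied_fraction * sum(
        rec.livestock[sp] * coeff for sp, coeff in p.excretion_coeff.items())


def straw_return_n(rec: CountyRecord, p: ParameterSet) -> float:
    """N in crop residues returned to the soil.

    Per crop: yield x straw/seed ratio x returned fraction x residue N
    concentration. Crops without residue parameters contribute zero.
    """
    total = 0.0
    for crop in CROPS:
        sp = p.straw_params.get(crop)
        if sp is None:
            continue
        total += (rec.crop_yield[crop] * sp.straw_seed_ratio
                  * sp.returned_fraction * sp.n_concentration)
    return total


def compute_inputs(ds: Dataset, p: ParameterSet) -> tuple[InputBreakdown, ...]:
    """One InputBreakdown per county-year; component sums hold exactly."""
    out = []
    for rec in ds.records:
        n_chem = chem_fertilizer_n(rec, p)
        n_atm = atmospheric_deposition_n(rec, p)
        n_fix = biological_fixation_n(rec, p)
        sym, nonsym = _fixation_split(rec, p)
        n_hum = human_excrement_n(rec, p)
        n_liv = livestock_excrement_n(rec, p)
        n_straw = straw_return_n(rec, p)
        n_recyc = n_hum + n_liv + n_straw
        out.append(InputBreakdown(
            county_id=rec.county_id,
            year=rec.year,
            n_chemin=n_chem,
            n_atmin=n_atm,
            n_fin=n_fix,
            n_human=n_hum,
            n_livestin=n_liv,
            n_strawin=n_straw,
            n_recycn=n_recyc,
            n_input_total=n_chem + n_atm + n_fix + n_recyc,
            n_fin_symbiotic=sym,
            n_fin_nonsymbiotic=nonsym,
        ))
    return tuple(out)
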