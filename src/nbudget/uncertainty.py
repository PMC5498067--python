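"""Monte Carlo propagation of coefficient uncertainty through the budget.

Literature coefficients are the dominant uncertainty source in a
statistics-driven nutrient budget, so each uncertain coefficient is
drawn independently around its default with a prescribed coefficient of
variation (CV), the basin budget (total inputs minus harvest N) is
recomputed per draw, and the output distribution is summarised by its
mean, 90% interval and a per-parameter contribution to variance.

Default CVs: 5% for the compound-fertilizer N content, 35% for all
biological fixation rates, 30% for human and livestock excretion
coefficients, 20% for the manure-applied fraction.

Sampling uses a zero-truncated normal (mean = default, sd = CV x
default, negatives redrawn) by default; a moment-matched lognormal is
available. Each coefficient has its own random stream derived from
(seed, crc32(key)), so adding a CV for one coefficient never changes the
draws of the others — variance comparisons across CV maps use coupled
draws. Contribution to variance is the squared Spearman rank correlation
between each coefficient's draws and the budget, normalised to sum to 1
over the varied coefficients (the standard spreadsheet-risk-tool metric;
an approximation to first-order Sobol indices).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .data_model import CROPS, SPECIES, Dataset
from .errors import ConfigurationError, ParameterError
from .parameters import (ParameterSet, get_coefficient, region_class,
                         with_coefficient)

KG_PER_TG = 1e9


def default_cv_map() -> dict[str, float]:
    """Default coefficient-of-variation map for the budget coefficients."""
    cv: dict[str, float] = {"compound_n_fraction": 0.05}
    for crop in ("peanut", "soybean", "rice", "wheat"):
        cv[f"fixation_rate.{crop}"] = 0.35
    for sp in SPECIES:
        cv[f"excretion_coeff.{sp}"] = 0.30
    cv["human_excretion_coeff"] = 0.30
    cv["manure_applied_fraction"] = 0.20
    return cv


@dataclass(frozen=True)
class UncertaintySpec:
    """Configuration of a Monte Carlo run."""

    cv_map: Mapping[str, float] = field(default_factory=default_cv_map)
    n_draws: int = 20000
    seed: int = 0
    distribution: str = "normal_truncated_at_zero"  # or "lognormal"
    target_year: Optional[int] = None

    def validate(self) -> None:
        if self.n_draws < 1:
            raise ParameterError("n_draws must be >= 1")
        for key, cv in self.cv_map.items():
            if cv < 0:
                raise ParameterError(f"CV for {key!r} must be >= 0")
        if self.distribution not in ("normal_truncated_at_zero",
                                     "lognormal"):
            raise ParameterError(
                f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class UncertaintySummary:
    """Monte Carlo summary of the basin budget (Tg N/y)."""

    mean_budget: float
    p5: float
    p95: float
    contribution_to_variance: Mapping[str, float]
    n_draws: int
    seed: int
    deterministic_budget: float
    budgets: np.ndarray = field(compare=False, repr=False, default=None)


def _key_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(key.encode())])


def _draw(rng: np.random.Generator, base_value: float, cv: float,
          distribution: str, size: int) -> np.ndarray:
    if cv == 0.0 or base_value == 0.0:
        return np.full(size, base_value)
    sd = cv * base_value
    if distribution == "lognormal":
        sigma2 = np.log1p(cv * cv)
        mu = np.log(base_value) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size)
    values = rng.normal(base_value, sd, size)
    bad = values < 0.0
    while bad.any():  # redraw negatives: truncation at zero
        values[bad] = rng.normal(base_value, sd, int(bad.sum()))
        bad = values < 0.0
    return values


def sample_matrix(base: ParameterSet,
                  spec: UncertaintySpec) -> dict[str, np.ndarray]:
    """All draws for all uncertain coefficients, one array per key.

    Deterministic given the spec's seed; each key has an independent
    stream so the matrix is column-wise stable under changes to the CV
    map.
    """
    spec.validate()
    matrix: dict[str, np.ndarray] = {}
    for key in sorted(spec.cv_map):
        base_value = get_coefficient(base, key)  # raises on unknown key
        matrix[key] = _draw(_key_rng(spec.seed, key), base_value,
                            spec.cv_map[key], spec.distribution,
                            spec.n_draws)
    return matrix


class _DrawState:
    """Per-key streams for one-draw-at-a-time sampling."""

    def __init__(self, spec: UncertaintySpec):
        self.spec = spec
        self.rngs = {key: _key_rng(spec.seed, key)
                     for key in sorted(spec.cv_map)}


def make_rng_state(spec: UncertaintySpec) -> _DrawState:
    return _DrawState(spec)


def sample_parameters(base: ParameterSet, spec: UncertaintySpec,
                      rng_state: _DrawState) -> ParameterSet:
    """Draw one sampled ParameterSet (advances the per-key streams)."""
    p = base
    for key in sorted(spec.cv_map):
        base_value = get_coefficient(base, key)
        value = float(_draw(rng_state.rngs[key], base_value,
                            spec.cv_map[key], spec.distribution, 1)[0])
        p = with_coefficient(p, key, value)
    return p


# ---------------------------------------------------------------------------
# Basin budget per draw
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _BasinTotals:
    """Dataset-level sufficient statistics for the basin budget of a year.

    Every budget term is a global coefficient times a county quantity, so
    the basin budget is exactly these totals contracted with the
    coefficients — identical to summing the per-county pipeline.
    """

    year: int
    fertilizer_pure_n: float
    fertilizer_compound: float
    cropland_by_region_class: Mapping[str, float]
    paddy_plus_upland_by_region_class: Mapping[str, float]
    sown_by_crop: Mapping[str, float]
    yield_by_crop: Mapping[str, float]
    head_by_species: Mapping[str, float]
    rural_adult_population: float


def basin_totals(ds: Dataset, year: int) -> _BasinTotals:
    crop_sown = {c: 0.0 for c in CROPS}
    crop_yield = {c: 0.0 for c in CROPS}
    heads = {s: 0.0 for s in SPECIES}
    area_crop: dict[str, float] = {}
    area_pu: dict[str, float] = {}
    pure = compound = pop = 0.0
    n = 0
    for rec in ds.records:
        if rec.year != year:
            continue
        n += 1
        rc = region_class(rec.reach, rec.province)
        area_crop[rc] = area_crop.get(rc, 0.0) + rec.cropland_area
        area_pu[rc] = (area_pu.get(rc, 0.0)
                       + rec.paddy_area + rec.upland_area)
        pure += rec.fertilizer_pure_n
        compound += rec.fertilizer_compound
        pop += rec.rural_adult_population
        for c in CROPS:
            crop_sown[c] += rec.sown_area[c]
            crop_yield[c] += rec.crop_yield[c]
        for s in SPECIES:
            heads[s] += rec.livestock[s]
    if n == 0:
        raise ConfigurationError(f"dataset has no records for year {year}")
    return _BasinTotals(
        year=year, fertilizer_pure_n=pure, fertilizer_compound=compound,
        cropland_by_region_class=area_crop,
        paddy_plus_upland_by_region_class=area_pu,
        sown_by_crop=crop_sown, yield_by_crop=crop_yield,
        head_by_species=heads, rural_adult_population=pop)


def budget_from_totals(totals: _BasinTotals, p: ParameterSet) -> float:
    """Basin budget (kg N/y) = total inputs - harvest N, from totals."""
    chem = (totals.fertilizer_pure_n
            + p.compound_n_fraction * totals.fertilizer_compound)
    areas = (totals.paddy_plus_upland_by_region_class
             if p.deposition_area_basis == "paddy_plus_upland"
             else totals.cropland_by_region_class)
    atm = 0.0
    for rc, area in areas.items():
        table = p.deposition_rate.get(rc, {})
        if totals.year not in table:
            raise ConfigurationError(
                f"no deposition rate for region class {rc!r} in year "
                f"{totals.year}")
        atm += area * table[totals.year]
    fin = sum(totals.sown_by_crop[c] * rate
              for c, rate in p.fixation_rate.items())
    human = (p.adult_to_total_pop * totals.rural_adult_population
             * p.human_excretion_coeff * p.manure_applied_fraction)
    livest = p.manure_applied_fraction * sum(
        totals.head_by_species[s] * coeff
        for s, coeff in p.excretion_coeff.items())
    straw = sum(totals.yield_by_crop[c] * sp.straw_seed_ratio
                * sp.returned_fraction * sp.n_concentration
                for c, sp in p.straw_params.items())
    harvest = sum(totals.yield_by_crop[c] * content
                  for c, content in p.crop_n_content.items())
    return chem + atm + fin + human + livest + straw - harvest


def deterministic_basin_budget(ds: Dataset, p: ParameterSet,
                               year: int) -> float:
    """Basin budget at the base coefficients (kg N/y)."""
    return budget_from_totals(basin_totals(ds, year), p)


def run_monte_carlo(ds: Dataset, base: ParameterSet,
                    spec: UncertaintySpec) -> UncertaintySummary:
    """Propagate coefficient uncertainty through the basin budget.

    Per draw, every coefficient listed in the CV map is replaced by its
    sampled value and the basin budget is recomputed from the dataset;
    the summary holds the empirical mean, the 5th/95th percentiles and
    the normalised contribution to variance per coefficient. Fully
    deterministic given (ds, base, spec).
    """
    spec.validate()
    base.validate()
    if spec.target_year is not None:
        year = spec.target_year
    else:
        years = sorted({r.year for r in ds.records})
        if len(years) != 1:
            raise ConfigurationError(
                f"dataset covers years {years}; set target_year")
        year = years[0]
    totals = basin_totals(ds, year)
    matrix = sample_matrix(base, spec)
    keys = sorted(matrix)

    budgets = np.empty(spec.n_draws)
    for i in range(spec.n_draws):
        p = base
        for key in keys:
            p = with_coefficient(p, key, float(matrix[key][i]))
        try:
            budgets[i] = budget_from_totals(totals, p)
        except Exception as exc:
            sampled = {key: float(matrix[key][i]) for key in keys}
            raise RuntimeError(
                f"budget evaluation failed at draw {i} with sampled "
                f"coefficients {sampled}") from exc

    contributions: dict[str, float] = {}
    if np.ptp(budgets) > 0.0:
        raw = {}
        for key in keys:
            col = matrix[key]
            if np.ptp(col) == 0.0:
                raw[key] = 0.0
                continue
            rho = stats.spearmanr(col, budgets).statistic
            raw[key] = 0.0 if np.isnan(rho) else float(rho) ** 2
        total = sum(raw.values())
        contributions = ({k: v / total for k, v in raw.items()}
                         if total > 0 else raw)
    else:
        contributions = {key: 0.0 for key in keys}

    return UncertaintySummary(
        mean_budget=float(budgets.mean()) / KG_PER_TG,
        p5=float(np.percentile(budgets, 5)) / KG_PER_TG,
        p95=float(np.percentile(budgets, 95)) / KG_PER_TG,
        contribution_to_variance=contributions,
        n_draws=spec.n_draws,
        seed=spec.seed,
        deterministic_budget=budget_from_totals(totals, base) / KG_PER_TG,
        budgets=budgets,
    )
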