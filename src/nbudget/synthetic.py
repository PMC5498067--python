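"""Synthetic county-statistics generator with known ground truth.

The real basin study rests on county agricultural yearbook statistics
that are not redistributable, so this module generates datasets with the
same schema and realistic magnitudes: per-reach log-normal marginals for
cropland area and fertilizer application rate (right-skewed, positive),
reach-specific paddy fractions, crop mixes, yields, livestock densities
and rural population densities. Two years are produced; the second year
is the first scaled by per-reach area and application-rate change
factors, so the regional area/rate log-rates (a, d) of the identity
decomposition are known exactly by construction.

Ground truth (regional fertilizer N, cropland area, application rate,
log-rates, decomposition shares, total N inputs and budgets) is computed
by an independent accumulation inside this module — plain loops spelling
out each balance formula — so tests of the pipeline against the
generator are non-circular.

Default sizes are 177/139/39 counties for the upper/middle/lower reaches
(the per-reach sample sizes typical of county regressions in this
basin); everything is configurable and a target basin scale (Tg of total
N inputs in the first year) can be requested, which rescales all
extensive county quantities linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .data_model import CROPS, SPECIES, REACHES, CountyRecord, Dataset
from .errors import ValidationError
from .parameters import ParameterSet, default_parameters, region_class

KG_PER_TG = 1e9

#: Reference per-hectare yields (kg/ha) used by all reach profiles.
YIELD_KG_PER_HA: dict[str, float] = {
    "rice": 6000.0, "wheat": 3800.0, "maize": 5200.0, "soybean": 1700.0,
    "peanut": 2800.0, "vegetables": 24000.0, "fruits": 9000.0,
    "oil_crops": 1800.0, "other": 3000.0,
}


@dataclass(frozen=True)
class ReachProfile:
    """Distributional profile of one reach's counties."""

    cropland_median_ha: float
    cropland_sigma: float
    paddy_fraction: float
    fert_rate_median: float  # kg N/ha/y applied per cropland ha
    fert_rate_sigma: float
    crop_shares: Mapping[str, float]  # shares of sown area; rest -> "other"
    pigs_per_ha: float
    cattle_per_ha: float
    sheep_per_ha: float
    rural_adults_per_ha: float
    provinces: tuple[str, ...]
    plateau_prob: float = 0.0  # probability of a Qinghai/Xizang county


def _default_profiles() -> dict[str, ReachProfile]:
    return {
        "upper": ReachProfile(
            cropland_median_ha=50000.0, cropland_sigma=0.7,
            paddy_fraction=0.30, fert_rate_median=180.0,
            fert_rate_sigma=0.30,
            crop_shares={"rice": 0.22, "wheat": 0.10, "maize": 0.20,
                         "soybean": 0.05, "peanut": 0.02,
                         "vegetables": 0.08, "fruits": 0.03,
                         "oil_crops": 0.08},
            pigs_per_ha=5.0, cattle_per_ha=1.0, sheep_per_ha=1.5,
            rural_adults_per_ha=8.0,
            provinces=("sichuan", "yunnan", "guizhou", "chongqing",
                       "gansu"),
            plateau_prob=0.06),
        "middle": ReachProfile(
            cropland_median_ha=70000.0, cropland_sigma=0.6,
            paddy_fraction=0.55, fert_rate_median=250.0,
            fert_rate_sigma=0.30,
            crop_shares={"rice": 0.35, "wheat": 0.10, "maize": 0.10,
                         "soybean": 0.04, "peanut": 0.03,
                         "vegetables": 0.10, "fruits": 0.03,
                         "oil_crops": 0.12},
            pigs_per_ha=4.5, cattle_per_ha=0.5, sheep_per_ha=0.4,
            rural_adults_per_ha=8.0,
            provinces=("hubei", "hunan", "jiangxi", "henan")),
        "lower": ReachProfile(
            cropland_median_ha=60000.0, cropland_sigma=0.5,
            paddy_fraction=0.65, fert_rate_median=280.0,
            fert_rate_sigma=0.30,
            crop_shares={"rice": 0.40, "wheat": 0.15, "maize": 0.05,
                         "soybean": 0.04, "peanut": 0.02,
                         "vegetables": 0.12, "fruits": 0.03,
                         "oil_crops": 0.10},
            pigs_per_ha=4.0, cattle_per_ha=0.2, sheep_per_ha=0.1,
            rural_adults_per_ha=7.0,
            provinces=("anhui", "jiangsu", "zhejiang", "shanghai")),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of a synthetic dataset."""

    n_counties: Mapping[str, int] = field(
        default_factory=lambda: {"upper": 177, "middle": 139, "lower": 39})
    seed: int = 0
    years: tuple[int, int] = (2000, 2010)
    profiles: Mapping[str, ReachProfile] = field(
        default_factory=_default_profiles)
    area_change: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REACHES})
    rate_change: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REACHES})
    target_basin_scale: Optional[float] = None  # Tg total inputs, year 0

    def validate(self) -> None:
        for reach in REACHES:
            if self.n_counties.get(reach, 0) < 1:
                raise ValidationError(
                    f"n_counties[{reach}] must be >= 1")
            prof = self.profiles[reach]
            if not 0.0 < prof.paddy_fraction < 1.0:
                raise ValidationError(
                    f"paddy_fraction for {reach} must be in (0, 1)")
            if prof.cropland_sigma <= 0 or prof.fert_rate_sigma <= 0:
                raise ValidationError(
                    f"distribution scales for {reach} must be > 0")
            if self.area_change.get(reach, 0.0) <= -1.0:
                raise ValidationError(
                    f"area_change[{reach}] must be > -1")
            if self.rate_change.get(reach, 0.0) <= -1.0:
                raise ValidationError(
                    f"rate_change[{reach}] must be > -1")


@dataclass(frozen=True)
class GroundTruth:
    """Exact regional quantities recorded at generation time.

    All masses in kg N/y, areas in ha. Regions are the three reaches
    plus "basin". Budgets are total N inputs minus harvest N computed by
    the generator's own accumulation (independent of the pipeline).
    """

    years: tuple[int, int]
    fertilizer_M: Mapping[str, Mapping[int, float]]
    cropland_A: Mapping[str, Mapping[int, float]]
    rate_D: Mapping[str, Mapping[int, float]]
    log_rates: Mapping[str, Mapping[str, float]]   # m, a, d per region
    shares: Mapping[str, Mapping[str, object]]     # share_area/share_rate/direction
    total_inputs: Mapping[str, Mapping[int, float]]
    budgets: Mapping[str, Mapping[int, float]]


def _scale_record(rec: CountyRecord, s: float,
                  fert_factor: float | None = None) -> CountyRecord:
    """Scale all extensive quantities of a record by s (fertilizer by
    fert_factor when given, else by s)."""
    f = s if fert_factor is None else fert_factor
    return replace(
        rec,
        cropland_area=rec.cropland_area * s,
        paddy_area=rec.paddy_area * s,
        upland_area=rec.upland_area * s,
        sown_area={c: v * s for c, v in rec.sown_area.items()},
        crop_yield={c: v * s for c, v in rec.crop_yield.items()},
        fertilizer_pure_n=rec.fertilizer_pure_n * f,
        fertilizer_compound=rec.fertilizer_compound * f,
        livestock={k: v * s for k, v in rec.livestock.items()},
        rural_adult_population=rec.rural_adult_population * s,
    )


def _naive_region_accounts(records: list[CountyRecord], params: ParameterSet
                           ) -> tuple[dict, dict, dict, dict]:
    """Independent accumulation of M, A, total inputs and budget.

    Plain loops spelling out every balance formula; deliberately not
    routed through the pipeline modules so generator-vs-pipeline tests
    are non-circular.
    """
    M: dict[str, dict[int, float]] = {}
    A: dict[str, dict[int, float]] = {}
    inputs: dict[str, dict[int, float]] = {}
    budgets: dict[str, dict[int, float]] = {}
    for rec in records:
        chem = (rec.fertilizer_pure_n
                + params.compound_n_fraction * rec.fertilizer_compound)
        rc = region_class(rec.reach, rec.province)
        if params.deposition_area_basis == "paddy_plus_upland":
            dep_area = rec.paddy_area + rec.upland_area
        else:
            dep_area = rec.cropland_area
        atm = dep_area * params.deposition_rate[rc][rec.year]
        fix = 0.0
        for crop, rate in params.fixation_rate.items():
            fix += rec.sown_area[crop] * rate
        human = (params.adult_to_total_pop * rec.rural_adult_population
                 * params.human_excretion_coeff
                 * params.manure_applied_fraction)
        livest = 0.0
        for sp, coeff in params.excretion_coeff.items():
            livest += params.manure_applied_fraction * rec.livestock[sp] * coeff
        straw = 0.0
        harvest = 0.0
        for crop in CROPS:
            sp_ = params.straw_params.get(crop)
            if sp_ is not None:
                straw += (rec.crop_yield[crop] * sp_.straw_seed_ratio
                          * sp_.returned_fraction * sp_.n_concentration)
            harvest += (rec.crop_yield[crop]
                        * params.crop_n_content.get(crop, 0.0))
        total_in = chem + atm + fix + human + livest + straw
        for region in (rec.reach, "basin"):
            M.setdefault(region, {}).setdefault(rec.year, 0.0)
            A.setdefault(region, {}).setdefault(rec.year, 0.0)
            inputs.setdefault(region, {}).setdefault(rec.year, 0.0)
            budgets.setdefault(region, {}).setdefault(rec.year, 0.0)
            M[region][rec.year] += chem
            A[region][rec.year] += rec.cropland_area
            inputs[region][rec.year] += total_in
            budgets[region][rec.year] += total_in - harvest
    return M, A, inputs, budgets


def _share_rule(a: float, d: float) -> dict[str, object]:
    if a == 0.0 and d == 0.0:
        return {"share_area": None, "share_rate": None,
                "direction": "mixed"}
    if a * d >= 0.0:
        total = a + d
        return {"share_area": a / total, "share_rate": d / total,
                "direction": "increase" if total > 0 else "decrease"}
    denom = abs(a) + abs(d)
    return {"share_area": abs(a) / denom, "share_rate": abs(d) / denom,
            "direction": "mixed"}


def generate(config: GeneratorConfig,
             params: ParameterSet | None = None
             ) -> tuple[Dataset, GroundTruth]:
    """Generate a two-year county dataset and its exact ground truth.

    Deterministic given ``config.seed``. ``params`` (default: the
    published coefficient set) is only used for the ground-truth
    accumulation and calibration, never stored in the data.
    """
    config.validate()
    params = params or default_parameters()
    rng = np.random.default_rng(config.seed)
    year0, year1 = config.years

    records: list[CountyRecord] = []
    for reach in REACHES:
        prof = config.profiles[reach]
        n = config.n_counties[reach]
        g_a = 1.0 + config.area_change.get(reach, 0.0)
        g_d = 1.0 + config.rate_change.get(reach, 0.0)
        other_share = 1.0 - sum(prof.crop_shares.values())
        if other_share < -1e-9:
            raise ValidationError(
                f"crop shares for {reach} sum to more than 1")
        shares = dict(prof.crop_shares)
        shares["other"] = max(other_share, 0.0)
        for i in range(n):
            cropland = rng.lognormal(math.log(prof.cropland_median_ha),
                                     prof.cropland_sigma)
            paddy_frac = float(np.clip(
                prof.paddy_fraction + rng.uniform(-0.15, 0.15),
                0.02, 0.95))
            paddy = cropland * paddy_frac
            upland = cropland - paddy
            mci = rng.uniform(1.2, 1.9)  # multiple-cropping index
            sown_total = mci * cropland
            sown = {c: sown_total * shares.get(c, 0.0) for c in CROPS}
            yield_noise = {c: rng.lognormal(-0.15 ** 2 / 2, 0.15)
                           for c in CROPS}
            crop_yield = {c: sown[c] * YIELD_KG_PER_HA[c] * yield_noise[c]
                          for c in CROPS}
            rate = rng.lognormal(math.log(prof.fert_rate_median),
                                 prof.fert_rate_sigma)
            fert_n = rate * cropland
            pure = 0.7 * fert_n
            # compound product mass carrying the remaining 30% of N
            compound = 0.3 * fert_n / params.compound_n_fraction
            livestock = {
                "pigs": prof.pigs_per_ha * cropland
                * rng.lognormal(-0.3 ** 2 / 2, 0.3),
                "cattle": prof.cattle_per_ha * cropland
                * rng.lognormal(-0.3 ** 2 / 2, 0.3),
                "sheep": prof.sheep_per_ha * cropland
                * rng.lognormal(-0.3 ** 2 / 2, 0.3),
            }
            adults = (prof.rural_adults_per_ha * cropland
                      * rng.lognormal(-0.2 ** 2 / 2, 0.2))
            if prof.plateau_prob and rng.random() < prof.plateau_prob:
                province = str(rng.choice(["qinghai", "xizang"]))
            else:
                province = str(rng.choice(list(prof.provinces)))
            base = CountyRecord(
                county_id=f"{reach[0].upper()}{i:04d}",
                year=year0, reach=reach, province=province,
                cropland_area=cropland, paddy_area=paddy,
                upland_area=upland, sown_area=sown,
                crop_yield=crop_yield, fertilizer_pure_n=pure,
                fertilizer_compound=compound, livestock=livestock,
                rural_adult_population=adults)
            records.append(base)
            # second year: areas scale by g_a, application rate by g_d
            year1_rec = _scale_record(base, g_a, fert_factor=g_a * g_d)
            records.append(replace(year1_rec, year=year1))

    if config.target_basin_scale is not None:
        _, _, inputs0, _ = _naive_region_accounts(records, params)
        actual = inputs0["basin"][year0]
        s = config.target_basin_scale * KG_PER_TG / actual
        records = [_scale_record(rec, s) for rec in records]

    ds = Dataset(tuple(records),
                 provenance=f"synthetic(seed={config.seed})")
    ds.validate()

    M, A, inputs, budgets = _naive_region_accounts(records, params)
    rate_D = {region: {year: M[region][year] / A[region][year]
                       for year in M[region]}
              for region in M}
    log_rates = {}
    shares_gt = {}
    for region in M:
        m = math.log(M[region][year1] / M[region][year0])
        a = math.log(A[region][year1] / A[region][year0])
        d = math.log(rate_D[region][year1] / rate_D[region][year0])
        log_rates[region] = {"m": m, "a": a, "d": d}
        shares_gt[region] = _share_rule(a, d)

    truth = GroundTruth(
        years=config.years, fertilizer_M=M, cropland_A=A, rate_D=rate_D,
        log_rates=log_rates, shares=shares_gt, total_inputs=inputs,
        budgets=budgets)
    return ds, truth


def scenario_paper_like(seed: int = 0,
                        n_counties: Mapping[str, int] | None = None
                        ) -> tuple[Dataset, GroundTruth]:
    """Three-reach scenario with the study's qualitative change pattern.

    Constructed per-reach (a, d) log-rates give decomposition shares of
    16/84 area/rate in the upper reach, 24/76 in the middle, and a joint
    decrease split 48/52 in the lower reach. These shares are built in by
    construction — they mirror the qualitative regional pattern, they are
    not a reproduction of the real data.
    """
    targets = {
        # (share_area, total log change)
        "upper": (0.16, 0.25),
        "middle": (0.24, 0.20),
        "lower": (0.48, -0.15),
    }
    area_change = {}
    rate_change = {}
    for reach, (share_area, total) in targets.items():
        a = share_area * total
        d = (1.0 - share_area) * total
        area_change[reach] = math.expm1(a)
        rate_change[reach] = math.expm1(d)
    config = GeneratorConfig(
        n_counties=dict(n_counties or {"upper": 60, "middle": 50,
                                       "lower": 30}),
        seed=seed, area_change=area_change, rate_change=rate_change)
    return generate(config)
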