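"""All model coefficients as declarative, overridable data.

The soil-surface N balance is driven entirely by literature coefficients:
atmospheric bulk-deposition rates per region class and year, the N content
of compound fertilizer, crop-specific biological fixation rates, per-head
excretion coefficients, the fraction of excrement applied to cropland as
manure, straw/residue parameters, crop N contents, and the fixed loss
fractions for denitrification, NH3 volatilization, runoff and leaching.
:func:`default_parameters` returns the published values; every coefficient
can be overridden from a YAML file or a partial mapping.

Unit conventions: rates are kg N/ha/y, excretion coefficients kg N per
head (or person) per year, crop N contents kg N per kg harvested product,
fractions dimensionless in [0, 1].

Two coefficient tables are *stand-ins*: the per-crop straw parameters
(straw/seed ratio, returned fraction, residue N concentration, burned
fraction) and the crop N contents were taken from the regional
nutrient-budget literature rather than printed alongside the loss
fractions, so the defaults here are representative values documented in
docs/methods.md and meant to be overridden when better local data exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .data_model import CROPS, SPECIES
from .errors import ConfigurationError, ParameterError

logger = logging.getLogger("nbudget")

#: Region classes for atmospheric deposition rates.
REGION_CLASSES = ("qinghai_xizang", "upper_middle", "lower")

#: Provinces that take the plateau (low) deposition rate regardless of reach.
LOW_DEPOSITION_PROVINCES = frozenset({"qinghai", "xizang"})


@dataclass(frozen=True)
class StrawParams:
    """Per-crop residue parameters.

    straw_seed_ratio : kg residue per kg harvested product (R_i)
    returned_fraction : fraction of residue returned to the soil (S_i)
    n_concentration : kg N per kg residue (P_i)
    burned_fraction : fraction of residue burned as fuel (B_i)
    """

    straw_seed_ratio: float
    returned_fraction: float
    n_concentration: float
    burned_fraction: float


@dataclass(frozen=True)
class ParameterSet:
    """Every coefficient of the nitrogen mass-balance model."""

    deposition_rate: Mapping[str, Mapping[int, float]]
    compound_n_fraction: float
    fixation_rate: Mapping[str, float]
    excretion_coeff: Mapping[str, float]
    human_excretion_coeff: float
    adult_to_total_pop: float
    manure_applied_fraction: float
    straw_params: Mapping[str, StrawParams]
    crop_n_content: Mapping[str, float]
    denitrification_frac: Mapping[str, float]
    nh3_frac: Mapping[str, float]
    runoff_frac: Mapping[str, float]
    leaching_frac: Mapping[str, float]
    burn_conversion: float
    deposition_area_basis: str = "cropland_area"
    # fertilizer apportioning between paddy and upland (see n_output stage)
    fert_split_mode: str = "area_proportional"  # or "fixed"
    fert_split_paddy_share: float = 0.5
    # whether returned straw N joins the organic pool subject to losses
    organic_pool_includes_straw: bool = False

    def validate(self) -> None:
        """Raise :class:`ParameterError` on any invariant violation."""
        def check_frac(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"{name} = {value} violates 0 <= fraction <= 1")

        def check_rate(name: str, value: float) -> None:
            if value < 0:
                raise ParameterError(f"{name} = {value} must be >= 0")

        for rc, table in self.deposition_rate.items():
            if rc not in REGION_CLASSES:
                raise ParameterError(
                    f"unknown deposition region class {rc!r}; valid: "
                    f"{list(REGION_CLASSES)}")
            for year, rate in table.items():
                check_rate(f"deposition_rate[{rc}][{year}]", rate)
        check_frac("compound_n_fraction", self.compound_n_fraction)
        for crop, rate in self.fixation_rate.items():
            check_rate(f"fixation_rate[{crop}]", rate)
        for sp, coeff in self.excretion_coeff.items():
            check_rate(f"excretion_coeff[{sp}]", coeff)
        check_rate("human_excretion_coeff", self.human_excretion_coeff)
        check_frac("adult_to_total_pop", self.adult_to_total_pop)
        check_frac("manure_applied_fraction", self.manure_applied_fraction)
        for crop, sp in self.straw_params.items():
            check_rate(f"straw_params[{crop}].straw_seed_ratio",
                       sp.straw_seed_ratio)
            check_frac(f"straw_params[{crop}].returned_fraction",
                       sp.returned_fraction)
            check_frac(f"straw_params[{crop}].n_concentration",
                       sp.n_concentration)
            check_frac(f"straw_params[{crop}].burned_fraction",
                       sp.burned_fraction)
            if sp.returned_fraction + sp.burned_fraction > 1.0 + 1e-12:
                raise ParameterError(
                    f"straw_params[{crop}]: returned_fraction + "
                    f"burned_fraction > 1")
        for crop, c in self.crop_n_content.items():
            check_frac(f"crop_n_content[{crop}]", c)
        for table_name in ("denitrification_frac", "nh3_frac",
                           "runoff_frac", "leaching_frac"):
            for key, f in getattr(self, table_name).items():
                check_frac(f"{table_name}[{key}]", f)
        # losses from one pool cannot exceed the pool
        pools = {
            "paddy": (self.denitrification_frac["paddy"],
                      self.nh3_frac["paddy"], self.runoff_frac["paddy"],
                      self.leaching_frac["paddy"]),
            "upland": (self.denitrification_frac["upland"],
                       self.nh3_frac["upland"], self.runoff_frac["upland"],
                       self.leaching_frac["upland"]),
            "manure": (self.denitrification_frac["manure"],
                       self.nh3_frac["manure"], self.runoff_frac["organic"],
                       self.leaching_frac["organic"]),
        }
        for pool, fracs in pools.items():
            if sum(fracs) > 1.0 + 1e-12:
                raise ParameterError(
                    f"loss fractions of the {pool} pool sum to "
                    f"{sum(fracs):.3f} > 1")
        check_rate("burn_conversion", self.burn_conversion)
        if self.deposition_area_basis not in ("cropland_area",
                                              "paddy_plus_upland"):
            raise ParameterError(
                f"deposition_area_basis {self.deposition_area_basis!r} "
                "must be 'cropland_area' or 'paddy_plus_upland'")
        if self.fert_split_mode not in ("area_proportional", "fixed"):
            raise ParameterError(
                f"fert_split_mode {self.fert_split_mode!r} must be "
                "'area_proportional' or 'fixed'")
        check_frac("fert_split_paddy_share", self.fert_split_paddy_share)


def default_parameters() -> ParameterSet:
    """The published coefficient set of the basin nitrogen budget.

    Deposition rates (kg N/ha/y) by region class and year; 35% N content of
    compound fertilizer; fixation 80 kg N/ha/y for peanut and soybean,
    30 for rice, 15 for wheat; excretion 8/40/5 kg N per pig/cattle/sheep
    per year and 5 per person, with 0.85 adult-to-total conversion and 40%
    of excrement applied as manure; denitrification 36/25/15% and NH3
    volatilization 16/11/23% for paddy/upland/manure; runoff 5.2/11% and
    leaching 1.2/3.2% of chemical N for paddy/upland, 5/4% runoff/leaching
    for organic N; 3.83 g N emitted per kg residue burned.
    """
    straw_defaults = {
        # stand-in residue table, see module docstring
        "rice": StrawParams(0.62, 0.30, 0.0091, 0.20),
        "wheat": StrawParams(1.10, 0.30, 0.0065, 0.20),
        "maize": StrawParams(1.20, 0.30, 0.0092, 0.20),
        "soybean": StrawParams(1.50, 0.30, 0.0181, 0.20),
        "peanut": StrawParams(0.80, 0.30, 0.0182, 0.20),
        "vegetables": StrawParams(0.10, 0.30, 0.0030, 0.00),
        "fruits": StrawParams(0.00, 0.00, 0.0000, 0.00),
        "oil_crops": StrawParams(2.00, 0.30, 0.0055, 0.20),
        "other": StrawParams(1.00, 0.30, 0.0050, 0.20),
    }
    crop_n_content = {
        # stand-in product N contents (kg N / kg), see module docstring
        "rice": 0.012,
        "wheat": 0.019,
        "maize": 0.014,
        "soybean": 0.053,
        "peanut": 0.028,
        "vegetables": 0.002,
        "fruits": 0.001,
        "oil_crops": 0.033,
        "other": 0.015,
    }
    p = ParameterSet(
        deposition_rate={
            "qinghai_xizang": {2000: 3.65, 2010: 5.31},
            "upper_middle": {2000: 17.97, 2010: 23.28},
            "lower": {2000: 20.95, 2010: 26.55},
        },
        compound_n_fraction=0.35,
        fixation_rate={"peanut": 80.0, "soybean": 80.0,
                       "rice": 30.0, "wheat": 15.0},
        excretion_coeff={"pigs": 8.0, "cattle": 40.0, "sheep": 5.0},
        human_excretion_coeff=5.0,
        adult_to_total_pop=0.85,
        manure_applied_fraction=0.40,
        straw_params=straw_defaults,
        crop_n_content=crop_n_content,
        denitrification_frac={"paddy": 0.36, "upland": 0.25, "manure": 0.15},
        nh3_frac={"paddy": 0.16, "upland": 0.11, "manure": 0.23},
        runoff_frac={"paddy": 0.052, "upland": 0.11, "organic": 0.05},
        leaching_frac={"paddy": 0.012, "upland": 0.032, "organic": 0.04},
        burn_conversion=0.00383,
    )
    p.validate()
    return p


def region_class(reach: str, province: str = "") -> str:
    """Deposition region class for a county.

    Qinghai/Xizang counties take the plateau rate regardless of reach;
    otherwise upper and middle reaches share one rate and the lower reach
    its own.
    """
    if province.strip().lower() in LOW_DEPOSITION_PROVINCES:
        return "qinghai_xizang"
    if reach in ("upper", "middle"):
        return "upper_middle"
    if reach == "lower":
        return "lower"
    raise ConfigurationError(f"unknown reach {reach!r}")


# ---------------------------------------------------------------------------
# Overrides, files, dotted-path access
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = {
    "compound_n_fraction", "human_excretion_coeff", "adult_to_total_pop",
    "manure_applied_fraction", "burn_conversion", "deposition_area_basis",
    "fert_split_mode", "fert_split_paddy_share",
    "organic_pool_includes_straw",
}
_MAP_FIELDS = {
    "deposition_rate", "fixation_rate", "excretion_coeff", "straw_params",
    "crop_n_content", "denitrification_frac", "nh3_frac", "runoff_frac",
    "leaching_frac",
}


def merge_overrides(base: ParameterSet,
                    overrides: Mapping[str, Any]) -> ParameterSet:
    """Return a new ParameterSet with a partial nested mapping applied.

    Unspecified keys keep their base values; each overridden key is
    logged. Unknown keys raise :class:`ParameterError` listing the valid
    keys at that level; the merged set is re-validated.
    """
    updates: dict[str, Any] = {}
    for key, value in overrides.items():
        if key in _SCALAR_FIELDS:
            updates[key] = value
            logger.info("parameter override: %s = %r", key, value)
        elif key in _MAP_FIELDS:
            if not isinstance(value, Mapping):
                raise ParameterError(
                    f"override for {key!r} must be a mapping")
            merged = dict(getattr(base, key))
            for sub, subval in value.items():
                if key == "deposition_rate":
                    if sub not in REGION_CLASSES:
                        raise ParameterError(
                            f"unknown deposition region class {sub!r}; "
                            f"valid: {list(REGION_CLASSES)}")
                    table = dict(merged.get(sub, {}))
                    table.update({int(y): float(v)
                                  for y, v in subval.items()})
                    merged[sub] = table
                elif key == "straw_params":
                    if sub not in CROPS:
                        raise ParameterError(
                            f"unknown crop {sub!r}; valid: {list(CROPS)}")
                    current = merged.get(
                        sub, StrawParams(0.0, 0.0, 0.0, 0.0))
                    if isinstance(subval, StrawParams):
                        merged[sub] = subval
                    else:
                        bad = set(subval) - {
                            f.name for f in fields(StrawParams)}
                        if bad:
                            raise ParameterError(
                                f"unknown straw_params fields {sorted(bad)}; "
                                f"valid: "
                                f"{[f.name for f in fields(StrawParams)]}")
                        merged[sub] = replace(current, **dict(subval))
                else:
                    vocab = (SPECIES if key == "excretion_coeff" else
                             CROPS if key in ("fixation_rate",
                                              "crop_n_content") else
                             ("paddy", "upland", "manure", "organic"))
                    if sub not in vocab:
                        raise ParameterError(
                            f"unknown key {sub!r} in {key}; valid: "
                            f"{list(vocab)}")
                    merged[sub] = float(subval)
                logger.info("parameter override: %s.%s = %r",
                            key, sub, subval)
            updates[key] = merged
        else:
            valid = sorted(_SCALAR_FIELDS | _MAP_FIELDS)
            raise ParameterError(
                f"unknown parameter {key!r}; valid keys: {valid}")
    merged_set = replace(base, **updates)
    merged_set.validate()
    return merged_set


def load_parameters(path: str | Path,
                    base: ParameterSet | None = None) -> ParameterSet:
    """Load a YAML parameter file as overrides onto the defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, Mapping):
        raise ParameterError(f"parameter file {path} must be a mapping")
    return merge_overrides(base or default_parameters(), overrides)


def get_coefficient(p: ParameterSet, key: str) -> float:
    """Fetch a scalar coefficient by dotted path, e.g. ``fixation_rate.rice``
    or ``deposition_rate.upper_middle.2000``."""
    parts = key.split(".")
    obj: Any = getattr(p, parts[0], None)
    if obj is None:
        raise ParameterError(f"unknown parameter path {key!r}")
    for part in parts[1:]:
        if isinstance(obj, Mapping):
            k: Any = int(part) if part.isdigit() else part
            if k not in obj:
                raise ParameterError(
                    f"unknown parameter path {key!r} (no key {part!r})")
            obj = obj[k]
        else:
            if not hasattr(obj, part):
                raise ParameterError(
                    f"unknown parameter path {key!r} (no field {part!r})")
            obj = getattr(obj, part)
    if not isinstance(obj, (int, float)):
        raise ParameterError(f"parameter path {key!r} is not a scalar")
    return float(obj)


def with_coefficient(p: ParameterSet, key: str, value: float) -> ParameterSet:
    """Return a copy of ``p`` with the scalar at a dotted path replaced."""
    get_coefficient(p, key)  # path check
    parts = key.split(".")
    if len(parts) == 1:
        return replace(p, **{parts[0]: value})
    table = dict(getattr(p, parts[0]))
    if len(parts) == 2:
        k: Any = int(parts[1]) if parts[1].isdigit() else parts[1]
        if isinstance(table[k], StrawParams):
            raise ParameterError(f"parameter path {key!r} is not a scalar")
        table[k] = value
    elif len(parts) == 3:
        k = parts[1]
        inner = table[k]
        if isinstance(inner, StrawParams):
            table[k] = replace(inner, **{parts[2]: value})
        else:
            inner = dict(inner)
            yk: Any = int(parts[2]) if parts[2].isdigit() else parts[2]
            inner[yk] = value
            table[k] = inner
    else:
        raise ParameterError(f"parameter path {key!r} too deep")
    return replace(p, **{parts[0]: table})
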