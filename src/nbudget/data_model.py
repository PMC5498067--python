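"""County-statistics schema, delimited-table IO and dataset validation.

One :class:`CountyRecord` holds a single county-year of raw agricultural
statistics: cultivated land split into paddy and upland, sown area and
harvested yield per crop, synthetic fertilizer amounts, livestock headcounts
and the rural adult population. A :class:`Dataset` is a validated collection
of such records with unique (county_id, year) keys.

All quantities are stored in the canonical units of the pipeline:
hectares for areas, kg per year for masses, plain headcounts for animals
and persons. Basin aggregates are converted to Tg only at reporting time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger("nbudget")

#: Crop vocabulary shared by sown areas, yields, fixation and residue tables.
CROPS: tuple[str, ...] = (
    "rice",
    "wheat",
    "maize",
    "soybean",
    "peanut",
    "vegetables",
    "fruits",
    "oil_crops",
    "other",
)

#: Livestock species with excretion coefficients.
SPECIES: tuple[str, ...] = ("pigs", "cattle", "sheep")

#: Hydrological reaches of the basin (assigned upstream of this package).
REACHES: tuple[str, ...] = ("upper", "middle", "lower")

#: Default tolerance for the paddy+upland vs cropland consistency check.
DEFAULT_AREA_TOLERANCE = 0.05

REQUIRED_COLUMNS = ("county_id", "year", "reach", "cropland_area")
OPTIONAL_SCALAR_COLUMNS = (
    "province",
    "paddy_area",
    "upland_area",
    "fertilizer_pure_n",
    "fertilizer_compound",
    "rural_adult_population",
)


def canonical_columns() -> tuple[str, ...]:
    """Full canonical column set of a county table, in writing order."""
    cols = list(REQUIRED_COLUMNS[:3]) + ["province", "cropland_area",
                                         "paddy_area", "upland_area"]
    cols += [f"sown_area_{c}" for c in CROPS]
    cols += [f"yield_{c}" for c in CROPS]
    cols += ["fertilizer_pure_n", "fertilizer_compound"]
    cols += [f"livestock_{s}" for s in SPECIES]
    cols += ["rural_adult_population"]
    return tuple(cols)


@dataclass(frozen=True)
class CountyRecord:
    """One county-year of raw agricultural statistics.

    Parameters
    ----------
    county_id:
        Opaque identifier, unique per county.
    year:
        Calendar year of the statistics.
    reach:
        Basin reach membership: ``upper``, ``middle`` or ``lower``.
    province:
        Province tag; only used to select the low atmospheric-deposition
        rate for the Qinghai/Xizang plateau counties.
    cropland_area, paddy_area, upland_area:
        Cultivated land in hectares; paddy + upland may not exceed
        cropland by more than the configured tolerance.
    sown_area, crop_yield:
        Per-crop sown area (ha) and harvested mass (kg/y), keyed over
        :data:`CROPS`; missing crops are normalised to 0.
    fertilizer_pure_n:
        Pure nitrogen fertilizer, kg N/y.
    fertilizer_compound:
        Compound fertilizer product mass, kg/y (N content applied later).
    livestock:
        Headcounts keyed over :data:`SPECIES`.
    rural_adult_population:
        Rural adult persons (converted to total rural population by a
        coefficient in the parameter set).
    """

    county_id: str
    year: int
    reach: str
    province: str = ""
    cropland_area: float = 0.0
    paddy_area: float = 0.0
    upland_area: float = 0.0
    sown_area: Mapping[str, float] = field(default_factory=dict)
    crop_yield: Mapping[str, float] = field(default_factory=dict)
    fertilizer_pure_n: float = 0.0
    fertilizer_compound: float = 0.0
    livestock: Mapping[str, float] = field(default_factory=dict)
    rural_adult_population: float = 0.0

    def __post_init__(self) -> None:
        for name, vocab in (("sown_area", CROPS), ("crop_yield", CROPS),
                            ("livestock", SPECIES)):
            raw = getattr(self, name)
            unknown = set(raw) - set(vocab)
            if unknown:
                raise ValidationError(
                    f"county {self.county_id!r}: unknown {name} keys "
                    f"{sorted(unknown)}; valid keys are {list(vocab)}")
            object.__setattr__(
                self, name,
                {k: float(raw.get(k, 0.0)) for k in vocab})

    def validate(self, area_tolerance: float = DEFAULT_AREA_TOLERANCE) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        if self.reach not in REACHES:
            raise ValidationError(
                f"county {self.county_id!r}: reach {self.reach!r} not in "
                f"{list(REACHES)}")
        scalars = {
            "cropland_area": self.cropland_area,
            "paddy_area": self.paddy_area,
            "upland_area": self.upland_area,
            "fertilizer_pure_n": self.fertilizer_pure_n,
            "fertilizer_compound": self.fertilizer_compound,
            "rural_adult_population": self.rural_adult_population,
        }
        for fname, value in scalars.items():
            if value < 0:
                raise ValidationError(
                    f"county {self.county_id!r}, year {self.year}: "
                    f"{fname} is negative ({value})")
        for name in ("sown_area", "crop_yield", "livestock"):
            for key, value in getattr(self, name).items():
                if value < 0:
                    raise ValidationError(
                        f"county {self.county_id!r}, year {self.year}: "
                        f"{name}[{key}] is negative ({value})")
        if not self.area_consistent(area_tolerance):
            raise ValidationError(
                f"county {self.county_id!r}, year {self.year}: paddy_area + "
                f"upland_area = {self.paddy_area + self.upland_area} exceeds "
                f"cropland_area {self.cropland_area} by more than "
                f"{area_tolerance:.0%}")

    def area_consistent(self,
                        area_tolerance: float = DEFAULT_AREA_TOLERANCE) -> bool:
        return (self.paddy_area + self.upland_area
                <= self.cropland_area * (1.0 + area_tolerance) + 1e-9)


@dataclass(frozen=True)
class Dataset:
    """Validated collection of :class:`CountyRecord`.

    Records are stored sorted by (county_id, year), so two datasets built
    from the same rows in any order compare equal. ``warnings`` and
    ``fill_counts`` document schema adaptations made while reading and do
    not participate in equality.
    """

    records: tuple[CountyRecord, ...]
    provenance: str = field(default="", compare=False)
    warnings: tuple[str, ...] = field(default=(), compare=False)
    fill_counts: Mapping[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.records,
                               key=lambda r: (r.county_id, r.year)))
        object.__setattr__(self, "records", ordered)

    @property
    def years_present(self) -> frozenset[int]:
        return frozenset(r.year for r in self.records)

    def validate(self, area_tolerance: float = DEFAULT_AREA_TOLERANCE) -> None:
        if not self.records:
            raise ValidationError("dataset is empty")
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.county_id, rec.year)
            if key in seen:
                raise ValidationError(
                    f"duplicate (county_id, year) = {key}")
            seen.add(key)
            rec.validate(area_tolerance)

    def subset_year(self, year: int) -> "Dataset":
        return Dataset(tuple(r for r in self.records if r.year == year),
                       provenance=self.provenance)

    def subset_reach(self, reach: str) -> "Dataset":
        return Dataset(tuple(r for r in self.records if r.reach == reach),
                       provenance=self.provenance)


# ---------------------------------------------------------------------------
# Reading and writing delimited tables
# ---------------------------------------------------------------------------

def load_schema_config(path: str | Path) -> dict:
    """Load a YAML column-name mapping: {delimiter: ..., columns: {canonical: actual}}."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"schema config {path} must be a mapping")
    return cfg


def read_county_table(
    path: str | Path,
    schema_config: Mapping | None = None,
    *,
    area_tolerance: float = DEFAULT_AREA_TOLERANCE,
    on_area_violation: str = "error",
) -> Dataset:
    """Read a delimited county-statistics table into a validated Dataset.

    The file must be UTF-8 delimited text (comma or tab, auto-detected
    unless ``schema_config['delimiter']`` is given) with a header row.
    ``schema_config['columns']`` maps canonical column names to the names
    used in the file, so arbitrary statistical-yearbook exports can be
    adapted without code changes.

    Missing optional columns are filled with zero and logged; unknown
    columns are ignored with a warning. Missing *required* columns raise
    :class:`SchemaError`; negative values and duplicate (county, year)
    keys raise :class:`ValidationError`. With
    ``on_area_violation="report"`` paddy+upland overshoot is recorded for
    :func:`validation_report` instead of raising.
    """
    schema_config = dict(schema_config or {})
    delimiter = schema_config.get("delimiter")
    rename = {v: k for k, v in dict(schema_config.get("columns", {})).items()}

    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header_line = fh.readline()
        delimiter = "\t" if header_line.count("\t") > header_line.count(",") else ","
    # round_trip parsing keeps write/read lossless for float64
    frame = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if rename:
        frame = frame.rename(columns=rename)

    known = set(canonical_columns())
    warnings: list[str] = []
    fill_counts: dict[str, int] = {}

    for col in frame.columns:
        if col not in known:
            msg = f"ignoring unknown column {col!r}"
            warnings.append(msg)
            logger.warning(msg)
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} is missing")
    for col in canonical_columns():
        if col not in frame.columns:
            if col == "province":
                frame[col] = ""
            else:
                frame[col] = 0.0
                fill_counts[col] = len(frame)
            msg = f"column {col!r} absent; filled with {'empty' if col == 'province' else 'zero'}"
            warnings.append(msg)
            logger.warning(msg)

    records = []
    for row in frame.itertuples(index=False):
        d = dict(zip(frame.columns, row))
        records.append(CountyRecord(
            county_id=str(d["county_id"]),
            year=int(d["year"]),
            reach=str(d["reach"]),
            province=str(d.get("province", "") or ""),
            cropland_area=float(d["cropland_area"]),
            paddy_area=float(d["paddy_area"]),
            upland_area=float(d["upland_area"]),
            sown_area={c: float(d[f"sown_area_{c}"]) for c in CROPS},
            crop_yield={c: float(d[f"yield_{c}"]) for c in CROPS},
            fertilizer_pure_n=float(d["fertilizer_pure_n"]),
            fertilizer_compound=float(d["fertilizer_compound"]),
            livestock={s: float(d[f"livestock_{s}"]) for s in SPECIES},
            rural_adult_population=float(d["rural_adult_population"]),
        ))

    ds = Dataset(tuple(records), provenance=str(path),
                 warnings=tuple(warnings), fill_counts=fill_counts)
    if on_area_violation == "error":
        ds.validate(area_tolerance)
    else:
        # still enforce everything except the area-consistency rule
        relaxed = Dataset(ds.records, provenance=ds.provenance)
        relaxed_tol = float("inf")
        relaxed.validate(relaxed_tol)
    return ds


def write_county_table(ds: Dataset, path: str | Path,
                       delimiter: str = ",") -> None:
    """Write a Dataset back to delimited text in canonical column order.

    Floats are written at full repr precision so a read/write round trip
    reproduces every numeric field exactly.
    """
    rows = []
    for r in ds.records:
        row: dict[str, object] = {
            "county_id": r.county_id, "year": r.year, "reach": r.reach,
            "province": r.province, "cropland_area": r.cropland_area,
            "paddy_area": r.paddy_area, "upland_area": r.upland_area,
            "fertilizer_pure_n": r.fertilizer_pure_n,
            "fertilizer_compound": r.fertilizer_compound,
            "rural_adult_population": r.rural_adult_population,
        }
        for c in CROPS:
            row[f"sown_area_{c}"] = r.sown_area[c]
            row[f"yield_{c}"] = r.crop_yield[c]
        for s in SPECIES:
            row[f"livestock_{s}"] = r.livestock[s]
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(canonical_columns()))
    # 17 significant digits: lossless float64 round trip
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    n_records: int
    per_reach_counts: Mapping[str, int]
    filled_zero_counts: Mapping[str, int]
    area_violations: int
    area_violation_counties: tuple[str, ...]
    negative_value_count: int


def validation_report(ds: Dataset,
                      area_tolerance: float = DEFAULT_AREA_TOLERANCE
                      ) -> ValidationReport:
    """Deterministic summary of a parsed dataset; does not mutate it."""
    per_reach = {reach: 0 for reach in REACHES}
    violations: list[str] = []
    negatives = 0
    for rec in ds.records:
        per_reach[rec.reach] = per_reach.get(rec.reach, 0) + 1
        if not rec.area_consistent(area_tolerance):
            violations.append(rec.county_id)
        values = [rec.cropland_area, rec.paddy_area, rec.upland_area,
                  rec.fertilizer_pure_n, rec.fertilizer_compound,
                  rec.rural_adult_population]
        values += list(rec.sown_area.values())
        values += list(rec.crop_yield.values())
        values += list(rec.livestock.values())
        negatives += sum(1 for v in values if v < 0)
    return ValidationReport(
        n_records=len(ds.records),
        per_reach_counts=per_reach,
        filled_zero_counts=dict(ds.fill_counts),
        area_violations=len(violations),
        area_violation_counties=tuple(violations),
        negative_value_count=negatives,
    )
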