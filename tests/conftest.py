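import pytest

from nbudget import (CountyRecord, Dataset, GeneratorConfig,
                     default_parameters, generate)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


def make_record(county_id="C001", year=2000, reach="middle", **kwargs):
    """A small, fully-populated county record with overridable fields."""
    defaults = dict(
        province="hubei",
        cropland_area=1000.0,
        paddy_area=600.0,
        upland_area=400.0,
        sown_area={"rice": 700.0, "wheat": 300.0, "maize": 200.0,
                   "soybean": 50.0, "peanut": 20.0, "vegetables": 100.0,
                   "fruits": 30.0, "oil_crops": 80.0, "other": 120.0},
        crop_yield={"rice": 4.2e6, "wheat": 1.1e6, "maize": 1.0e6,
                    "soybean": 9.0e4, "peanut": 5.6e4,
                    "vegetables": 2.4e6, "fruits": 2.7e5,
                    "oil_crops": 1.4e5, "other": 3.6e5},
        fertilizer_pure_n=2.0e5,
        fertilizer_compound=1.5e5,
        livestock={"pigs": 5000.0, "cattle": 800.0, "sheep": 1200.0},
        rural_adult_population=8000.0,
    )
    defaults.update(kwargs)
    return CountyRecord(county_id=county_id, year=year, reach=reach,
                        **defaults)


@pytest.fixture
def small_dataset():
    """Three counties, one per reach, single year."""
    return Dataset((
        make_record("U001", reach="upper", province="sichuan"),
        make_record("M001", reach="middle", province="hunan"),
        make_record("L001", reach="lower", province="jiangsu",
                    paddy_area=700.0, upland_area=300.0),
    ))


@pytest.fixture(scope="session")
def synth_small():
    """Small two-year synthetic dataset with ground truth."""
    config = GeneratorConfig(
        seed=11,
        n_counties={"upper": 12, "middle": 10, "lower": 8},
        area_change={"upper": 0.02, "middle": 0.01, "lower": -0.05},
        rate_change={"upper": 0.15, "middle": 0.10, "lower": -0.04},
    )
    return generate(config)
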