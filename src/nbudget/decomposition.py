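"""Identity decomposition of fertilizer-N input change: M = A x D.

Total fertilizer N input M (kg N/y) is the product of cropland area A
(ha) and the mean application rate D = M/A (kg N/ha/y). Taking logs,
ln(M) = ln(A) + ln(D), so between two years the log-rates

    m = ln(M1/M0),  a = ln(A1/A0),  d = ln(D1/D0)

satisfy m = a + d exactly. The change in fertilizer N input is then
attributed to cropland-area vs application-rate contributions:

* same-sign (or one zero) a and d: share_x = x / (a + d);
* opposite signs: share_x = |x| / (|a| + |d|), direction "mixed".

This is the Kaya-style two-factor attribution used for regional drivers
of emission change, applied to fertilizer N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .data_model import Dataset, REACHES
from .inputs import InputBreakdown

_IDENTITY_TOL = 1e-12


@dataclass(frozen=True)
class DecompositionResult:
    """Two-factor attribution of a fertilizer-N change for one region."""

    region: str
    period: tuple[int, int]
    M0: float  # kg N/y
    M1: float
    A0: float  # ha
    A1: float
    D0: float  # kg N/ha/y
    D1: float
    m: float   # ln(M1/M0)
    a: float   # ln(A1/A0)
    d: float   # ln(D1/D0)
    share_area: Optional[float]
    share_rate: Optional[float]
    direction: str  # increase / decrease / mixed


def decompose(M0: float, A0: float, M1: float, A1: float,
              region: str = "", period: tuple[int, int] = (0, 1)
              ) -> DecompositionResult:
    """Attribute the change M0 -> M1 to area vs rate factors.

    All four arguments must be strictly positive (logs are undefined
    otherwise). The additive identity m = a + d is asserted to 1e-12.
    """
    for name, v in (("M0", M0), ("A0", A0), ("M1", M1), ("A1", A1)):
        if v <= 0.0:
            raise ValueError(
                f"{name} = {v} must be > 0 for the log identity")
    D0, D1 = M0 / A0, M1 / A1
    m = math.log(M1 / M0)
    a = math.log(A1 / A0)
    d = math.log(D1 / D0)
    assert abs(m - (a + d)) <= _IDENTITY_TOL * max(1.0, abs(m)), \
        "log identity m = a + d violated beyond tolerance"

    share_area: Optional[float]
    share_rate: Optional[float]
    if a == 0.0 and d == 0.0:
        share_area = share_rate = None
        direction = "mixed"
    elif a * d >= 0.0:  # same sign, or one factor zero
        total = a + d
        share_area = a / total
        share_rate = d / total
        direction = "increase" if total > 0 else "decrease"
    else:
        denom = abs(a) + abs(d)
        share_area = abs(a) / denom
        share_rate = abs(d) / denom
        direction = "mixed"
    return DecompositionResult(
        region=region, period=period, M0=M0, M1=M1, A0=A0, A1=A1,
        D0=D0, D1=D1, m=m, a=a, d=d,
        share_area=share_area, share_rate=share_rate, direction=direction)


def decompose_regions(ds: Dataset,
                      inputs_t0: Sequence[InputBreakdown],
                      inputs_t1: Sequence[InputBreakdown]
                      ) -> dict[str, DecompositionResult]:
    """Per-reach and basin decomposition between two years.

    Region M is the sum of county fertilizer N; region A the sum of
    county cropland areas; the application rate D is the intensive ratio
    of the aggregates (sum M / sum A), not the mean of county rates.
    """
    y0 = {ib.year for ib in inputs_t0}
    y1 = {ib.year for ib in inputs_t1}
    if len(y0) != 1 or len(y1) != 1:
        raise ValueError("each input collection must cover exactly one year")
    year0, year1 = y0.pop(), y1.pop()

    reach_by_key = {(r.county_id, r.year): r.reach for r in ds.records}
    area_by_key = {(r.county_id, r.year): r.cropland_area
                   for r in ds.records}

    def totals(inputs: Sequence[InputBreakdown], year: int
               ) -> tuple[dict[str, float], dict[str, float]]:
        M = {reach: 0.0 for reach in REACHES}
        A = {reach: 0.0 for reach in REACHES}
        for ib in inputs:
            key = (ib.county_id, ib.year)
            reach = reach_by_key[key]
            M[reach] += ib.n_chemin
            A[reach] += area_by_key[key]
        return M, A

    M0, A0 = totals(inputs_t0, year0)
    M1, A1 = totals(inputs_t1, year1)

    results: dict[str, DecompositionResult] = {}
    for reach in REACHES:
        if M0[reach] == 0.0 and M1[reach] == 0.0 and A0[reach] == 0.0:
            continue  # reach absent from the dataset
        for year, M, A in ((year0, M0, A0), (year1, M1, A1)):
            if M[reach] <= 0.0 or A[reach] <= 0.0:
                raise ValueError(
                    f"region {reach!r} has non-positive fertilizer N or "
                    f"cropland area in year {year}")
        results[reach] = decompose(M0[reach], A0[reach],
                                   M1[reach], A1[reach],
                                   region=reach, period=(year0, year1))
    results["basin"] = decompose(
        sum(M0.values()), sum(A0.values()),
        sum(M1.values()), sum(A1.values()),
        region="basin", period=(year0, year1))
    return results
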