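"""Published Hokkaido cerebral-infarction registry aggregates (e-stat).

Annual municipality-aggregate deaths from cerebral infarction (ICD-10 I63)
in Hokkaido, 2010-2020, with the prefectural population, as released in the
public vital-statistics tables. These aggregates calibrate the synthetic
generator (the actual municipality-level extracts are not redistributed) and
provide small closed-form checks of the standardization arithmetic.
"""

from __future__ import annotations

#: deaths due to cerebral infarction per year, whole prefecture
ANNUAL_DEATHS = {
    2010: 3118, 2011: 3139, 2012: 3003, 2013: 2983, 2014: 2914,
    2015: 2812, 2016: 2766, 2017: 2759, 2018: 2726, 2019: 2668, 2020: 2622,
}

#: median municipal death count per year
ANNUAL_MEDIAN_DEATHS = {
    2010: 5, 2011: 6, 2012: 6, 2013: 6, 2014: 5, 2015: 5,
    2016: 5, 2017: 5, 2018: 5, 2019: 5, 2020: 4,
}

#: prefectural population per year (basic resident registration)
ANNUAL_POPULATION = {
    2010: 5_520_894, 2011: 5_498_916, 2012: 5_474_216, 2013: 5_462_664,
    2014: 5_460_246, 2015: 5_429_222, 2016: 5_388_911, 2017: 5_368_540,
    2018: 5_337_149, 2019: 5_302_163, 2020: 5_265_727,
}

N_MUNICIPALITIES = 188
STUDY_YEARS = tuple(range(2010, 2021))
#: 2020 municipal population summary: median and range
MEDIAN_MUNICIPAL_POPULATION = 5_795
MUNICIPAL_POPULATION_RANGE = (706, 329_306)


def total_deaths() -> int:
    """Eleven-year death total (sum of the annual aggregates)."""
    return sum(ANNUAL_DEATHS.values())


def annual_death_range() -> tuple[int, int]:
    """(min, max) annual deaths over the study period."""
    vals = ANNUAL_DEATHS.values()
    return min(vals), max(vals)
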