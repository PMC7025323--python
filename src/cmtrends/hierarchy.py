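"""Country/region hierarchy with synthetic populations and urbanisation.

The model pools information at three levels (global -> region -> country).
A :class:`RegionHierarchy` carries the membership map plus the per
(country, year, age-band) population counts used for age-standardised and
population-weighted regional aggregation, and the country urban fraction by
year used for the urbanisation adjustment.

Synthetic populations are log-linear in calendar year with a fixed
country-specific age pyramid; they stand in for UN population tables, which
this package deliberately does not ship.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import AgeBand, validate_bands, default_bands


@dataclass
class RegionHierarchy:
    """Membership of countries in regions plus demographic context.

    Attributes
    ----------
    countries : ordered unique country identifiers.
    region_of : mapping country -> region identifier.
    years : ordered calendar years covered by the study period.
    age_bands : ordered, disjoint adult age bands.
    population : DataFrame (country, year, age_lo, age_hi, population).
    urban_fraction : DataFrame (country, year, urban_fraction in [0, 1]).
    """

    countries: tuple[str, ...]
    region_of: dict[str, str]
    years: np.ndarray
    age_bands: tuple[AgeBand, ...]
    population: pd.DataFrame
    urban_fraction: pd.DataFrame
    _pop_lookup: dict = field(default=None, repr=False, compare=False)
    _urb_lookup: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.countries)) != len(self.countries):
            raise ValueError("country identifiers must be unique")
        missing = [c for c in self.countries if c not in self.region_of]
        if missing:
            raise ValueError(f"countries without region membership: {missing}")
        self.years = np.asarray(self.years, dtype=int)
        if not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive")
        self.age_bands = validate_bands(self.age_bands)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.countries:
            seen.setdefault(self.region_of[c], None)
        return tuple(seen)

    def countries_in(self, region: str) -> tuple[str, ...]:
        return tuple(c for c in self.countries if self.region_of[c] == region)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int | np.ndarray) -> np.ndarray:
        idx = np.asarray(year, dtype=int) - int(self.years[0])
        if np.any(idx < 0) or np.any(idx >= self.n_years):
            raise ValueError(f"year {year} outside study period "
                             f"{self.years[0]}-{self.years[-1]}")
        return idx

    def band_populations(self, country: str, year: int) -> np.ndarray:
        """Population per age band for one country-year, in band order."""
        if self._pop_lookup is None:
            lut: dict = {}
            for row in self.population.itertuples(index=False):
                hi = None if pd.isna(row.age_hi) else int(row.age_hi)
                lut[(row.country, int(row.year), int(row.age_lo), hi)] = float(row.population)
            object.__setattr__(self, "_pop_lookup", lut)
        try:
            return np.array([self._pop_lookup[(country, int(year), b.lo, b.hi)]
                             for b in self.age_bands])
        except KeyError as exc:
            raise KeyError(f"missing population for {country}, {year}: {exc}") from exc

    def adult_population(self, country: str, year: int) -> float:
        return float(self.band_populations(country, year).sum())

    def country_urban_fraction(self, country: str, year: int) -> float:
        if self._urb_lookup is None:
            lut = {(r.country, int(r.year)): float(r.urban_fraction)
                   for r in self.urban_fraction.itertuples(index=False)}
            object.__setattr__(self, "_urb_lookup", lut)
        return self._urb_lookup[(country, int(year))]


def make_hierarchy(
    n_regions: int,
    countries_per_region: Sequence[int],
    years: tuple[int, int] = (1980, 2014),
    age_bands: Sequence[AgeBand] | None = None,
    seed: int = 0,
) -> RegionHierarchy:
    """Build a synthetic hierarchy with smooth positive populations.

    Parameters mirror the study layout (default: 37 countries in six
    subregions observed 1980-2014 when called with ``countries_per_region=
    [7, 6, 6, 6, 6, 6]``).  Populations are log-linear in year with a fixed
    per-country age pyramid; urban fractions follow smooth logistic-style
    paths.  The same seed always reproduces the same hierarchy.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    countries_per_region = list(countries_per_region)
    if len(countries_per_region) != n_regions:
        raise ValueError(
            f"countries_per_region has {len(countries_per_region)} entries "
            f"for {n_regions} regions")
    if any(k < 1 for k in countries_per_region):
        raise ValueError("every region needs at least one country")
    y0, y1 = years
    if y1 < y0:
        raise ValueError("year range is inverted")
    year_arr = np.arange(y0, y1 + 1)
    bands = validate_bands(age_bands) if age_bands is not None else default_bands(18)

    rng = np.random.default_rng(seed)
    countries: list[str] = []
    region_of: dict[str, str] = {}
    k = 0
    for r, n_c in enumerate(countries_per_region):
        region = f"R{r + 1}"
        for _ in range(n_c):
            k += 1
            cid = f"C{k:02d}"
            countries.append(cid)
            region_of[cid] = region

    pop_rows = []
    urb_rows = []
    yc = year_arr - year_arr.mean()
    for cid in countries:
        base = float(np.exp(rng.normal(13.0, 1.0)))          # adults mid-period
        growth = float(rng.normal(0.012, 0.004))             # annual log growth
        # fixed age pyramid: geometric decay across bands
        decay = float(rng.uniform(0.55, 0.85))
        pyramid = decay ** np.arange(len(bands))
        pyramid /= pyramid.sum()
        totals = base * np.exp(growth * yc)
        for j, year in enumerate(year_arr):
            for b, w in zip(bands, pyramid):
                pop_rows.append((cid, int(year), b.lo, b.hi, totals[j] * w))
        # smooth urbanisation path rising over the period
        u0 = float(rng.uniform(0.25, 0.75))
        rate = float(rng.uniform(0.0, 0.03))
        logit_u = np.log(u0 / (1 - u0)) + rate * yc
        urb = 1.0 / (1.0 + np.exp(-logit_u))
        for j, year in enumerate(year_arr):
            urb_rows.append((cid, int(year), float(urb[j])))

    population = pd.DataFrame(
        pop_rows, columns=["country", "year", "age_lo", "age_hi", "population"])
    urban = pd.DataFrame(urb_rows, columns=["country", "year", "urban_fraction"])
    return RegionHierarchy(tuple(countries), region_of, year_arr, bands,
                           population, urban)
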