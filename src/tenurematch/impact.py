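"""Descriptive statistics and avoided-deforestation / carbon extrapolation.

Converts matched ATT estimates (changes in the probability that a 30 m
forest pixel was cleared over the 2000-2014 study window) into hectares of
avoided (or induced) forest loss and tonnes of avoided carbon emissions,
scaled from a 1% pixel sample to the full study area. Also reproduces the
per-stratum descriptive arithmetic (% forest cleared, annualised loss rate).

Sign conventions follow the ATT convention used throughout the package:
a *negative* ATT means the treatment reduced the probability of forest
loss, so its avoided-deforestation area is *positive*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .schema import PIXEL_AREA_HA

#: 1% random sample of the study area -> multiply sampled pixels by 100.
SAMPLE_SCALE = 100.0

STUDY_YEARS = 14


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_cleared(deforestation_ha: float, forest_ha: float,
                    ndigits: Optional[int] = 2) -> float:
    """Percent of year-2000 forest cleared over the study window.

    Rounded half-away-from-zero to *ndigits* decimals (2 by default, the
    precision of the descriptive tables); pass ``ndigits=None`` for the raw
    ratio.
    """
    if forest_ha <= 0:
        raise ValueError("forest area must be positive")
    if deforestation_ha < 0:
        raise ValueError("deforestation area must be non-negative")
    pct = 100.0 * deforestation_ha / forest_ha
    return pct if ndigits is None else round_half_away(pct, ndigits)


def annual_rate(percent_cleared_value: float, years: int = STUDY_YEARS,
                ndigits: Optional[int] = None) -> float:
    """Annualised forest-loss rate (fraction per year; negative = loss)."""
    if years <= 0:
        raise ValueError("years must be positive")
    rate = -(percent_cleared_value / 100.0) / years
    return rate if ndigits is None else round_half_away(rate, ndigits)


def avoided_area(att: float, n_mc: int, pixel_area_ha: float = PIXEL_AREA_HA,
                 scale: float = SAMPLE_SCALE,
                 control_loss_rate: Optional[float] = None) -> float:
    """Avoided-deforestation area in hectares, extrapolated to the study area.

    The operative formula is ``|ATT| x n_mc x pixel_area_ha x scale``,
    signed so that a negative ATT (protection reduced loss) yields a
    positive avoided area and a positive ATT yields a negative value
    (induced loss). ``n_mc`` is the number of distinct matched control
    pixels and ``scale`` undoes the 1% sampling fraction.

    ``control_loss_rate`` switches to the literal mode in which the product
    is additionally multiplied by the matched-control deforestation rate;
    the default (operative) mode omits that factor.
    """
    if n_mc < 0:
        raise ValueError("n_mc must be non-negative")
    area = -att * n_mc * pixel_area_ha * scale
    if control_loss_rate is not None:
        area *= control_loss_rate
    return area


def avoided_carbon(area_ha: float, mean_biomass_tc_per_ha: float) -> float:
    """Avoided carbon emissions (tC) for an avoided-deforestation area."""
    if mean_biomass_tc_per_ha < 0:
        raise ValueError("biomass must be non-negative")
    return area_ha * mean_biomass_tc_per_ha


@dataclass
class ExtrapolationResult:
    """Avoided deforestation and carbon for one matched comparison."""

    label: str
    att: float
    n_mc: int
    mean_biomass: float
    significant: bool = True
    pixel_area_ha: float = PIXEL_AREA_HA
    scale_factor: float = SAMPLE_SCALE
    avoided_area_ha: float = field(init=False)
    avoided_carbon_tc: float = field(init=False)

    def __post_init__(self) -> None:
        self.avoided_area_ha = avoided_area(
            self.att, self.n_mc, self.pixel_area_ha, self.scale_factor)
        self.avoided_carbon_tc = avoided_carbon(
            self.avoided_area_ha, self.mean_biomass)


def net_effect(results: Iterable[ExtrapolationResult]) -> float:
    """Net signed avoided area (ha) over the statistically significant entries.

    Direct and spillover contributions are summed together; insignificant
    entries (at the 10% level, as flagged by the caller) contribute zero.
    A negative total means protection caused net deforestation via leakage.
    """
    return sum(r.avoided_area_ha for r in results if r.significant)


def descriptive_table(pixels: pd.DataFrame,
                      pixel_area_ha: float = PIXEL_AREA_HA,
                      years: int = STUDY_YEARS) -> pd.DataFrame:
    """Per biome x tenure x protection-stratum descriptive statistics.

    Every row of *pixels* is a forested-in-2000 pixel, so forest area is
    the pixel count times the pixel area; deforestation area is the count
    of loss pixels times the pixel area.
    """
    rows = []
    grouped = pixels.groupby(["biome", "tenure", "protection_class"],
                             observed=True)
    for (biome, tenure, prot), g in grouped:
        forest_ha = len(g) * pixel_area_ha
        defo_ha = float(g["y_loss"].sum()) * pixel_area_ha
        pct = percent_cleared(defo_ha, forest_ha)
        rows.append({
            "biome": biome,
            "tenure": tenure,
            "protection_class": prot,
            "n_pixels": len(g),
            "forest_ha": forest_ha,
            "deforestation_ha": defo_ha,
            "percent_cleared": pct,
            "annual_rate": annual_rate(pct, years),
        })
    return pd.DataFrame(rows)
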