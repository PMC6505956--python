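"""Column schema shared across the pipeline.

One row of a pixel table describes a single 30 m forest pixel: its grid
position, forest biome, land-tenure regime, cadastral property, protection
status, biophysical/socio-economic covariates, and the binary 2000-2014
forest-loss outcome.
"""

from __future__ import annotations

PIXEL_AREA_HA: float = 0.09  # 30 m x 30 m

BIOMES = ("dry", "moist")
TENURES = ("ejido", "private", "parceled")
PROTECTION_CLASSES = (
    "protected",
    "unprotected_part_of_protected_property",
    "fully_unprotected",
)

#: Matching / propensity covariates (distances in km, temperature deg C,
#: precipitation mm, elevation m, slope deg, forest cover %, population
#: density per km^2, woody biomass tC/ha).
COVARIATES = [
    "dist_water_km",
    "dist_urban_km",
    "dist_large_urban_km",
    "dist_federal_road_km",
    "dist_paved_road_km",
    "dist_unpaved_road_km",
    "dist_port_km",
    "temperature_c",
    "precipitation_mm",
    "elevation_m",
    "slope_deg",
    "forest_cover_2000_pct",
    "pop_density",
    "biomass_tc_ha",
]

#: Biomass column: the single non-linear covariate of the heterogeneity model.
BIOMASS = "biomass_tc_ha"

#: Linear controls of the partial linear model: every covariate except the
#: smoothed one (biomass).
PLM_CONTROLS = [c for c in COVARIATES if c != BIOMASS]

#: Identifier / design columns required of any pixel table.
CORE_COLUMNS = [
    "pixel_id",
    "row",
    "col",
    "biome",
    "tenure",
    "property_id",
    "protection_class",
    "y_loss",
]

REQUIRED_COLUMNS = CORE_COLUMNS + COVARIATES


class SchemaError(ValueError):
    """A pixel table is missing required columns or has malformed values."""


def validate_pixel_table(df, require_outcome: bool = True) -> None:
    """Raise :class:`SchemaError` if *df* does not carry the pixel schema."""
    required = list(REQUIRED_COLUMNS)
    if not require_outcome:
        required = [c for c in required if c != "y_loss"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"pixel table missing required columns: {missing}")
    if require_outcome and not set(df["y_loss"].unique()) <= {0, 1}:
        raise SchemaError("y_loss must be binary 0/1")
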