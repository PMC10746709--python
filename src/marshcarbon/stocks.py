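"""Organic-carbon stocks from cores and vegetation, with burrow correction.

Sediment OC stocks integrate the OC density profile of each core over the
depth actually cored (no extrapolation to 1 m, so shallow-refusal cores are
never inflated) and are reduced by the areal fraction of the sediment
surface occupied by crab burrows.  Burrows are modelled as vertical
cylinders of the measured entrance diameter spanning the cored depth, so
the volumetric void fraction equals the areal fraction; an optional taper
factor scales the void downward for burrows that narrow with depth.

Units: OC density g·cm⁻³, depths cm, stocks Mg OC·ha⁻¹
(1 g·cm⁻² = 100 Mg·ha⁻¹), site totals metric tons (1 Mg = 1 t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean

from marshcarbon.datamodel import (
    BurrowSurvey,
    CoreProfile,
    CoreSlice,
    ValidationError,
    logger,
)

__all__ = [
    "SliceOC",
    "StockRecord",
    "oc_fraction_from_loi",
    "dry_bulk_density",
    "slice_oc",
    "burrow_void_fraction",
    "integrate_sediment_stock",
    "mean_oc_density",
    "biomass_oc_stock",
    "assemble_stock_record",
    "scale_to_site_tons",
    "compute_stocks",
]


@dataclass(frozen=True)
class SliceOC:
    """Derived carbon quantities for one core slice."""

    oc_fraction: float  # proportion of dry mass
    dry_bulk_density: float  # g/cm^3
    oc_density: float  # g OC/cm^3
    thickness: float  # cm

    def __post_init__(self) -> None:
        if not 0 <= self.oc_fraction <= 1:
            raise ValidationError(f"oc_fraction must be in [0,1], got {self.oc_fraction}")
        if self.thickness <= 0:
            raise ValidationError("thickness must be > 0")


@dataclass(frozen=True)
class StockRecord:
    """Per site x species OC stocks by compartment, Mg OC/ha."""

    site_id: str
    species: str
    stock_green: float
    stock_senescent: float
    stock_roots: float
    stock_sediment: float
    stock_belowground: float  # sediment + roots
    stock_total: float  # belowground + green + senescent
    burrow_void_fraction: float

    def __post_init__(self) -> None:
        for f in (
            "stock_green",
            "stock_senescent",
            "stock_roots",
            "stock_sediment",
            "stock_belowground",
            "stock_total",
        ):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")
        expect = self.stock_green + self.stock_senescent + self.stock_belowground
        if abs(self.stock_total - expect) > 1e-9:
            raise ValidationError(
                f"stock_total {self.stock_total} != green+senescent+belowground {expect}"
            )


def oc_fraction_from_loi(c_pct_raw: float, c_pct_ashed: float) -> float:
    """OC mass fraction from the LOI pair of total-C measurements.

    The incinerated (450 degC) subsample retains only inorganic C, so the
    organic fraction is the raw-minus-ashed difference.  A negative
    difference (measurement noise) is floored at 0 with a warning.
    """
    for name, v in (("c_pct_raw", c_pct_raw), ("c_pct_ashed", c_pct_ashed)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    frac = (c_pct_raw - c_pct_ashed) / 100.0
    if frac < 0:
        logger.warning(
            "negative LOI carbon difference (%.3f%% - %.3f%%); flooring OC fraction at 0",
            c_pct_raw,
            c_pct_ashed,
        )
        return 0.0
    return frac


def dry_bulk_density(sl: CoreSlice, corer_area: float) -> float:
    """Dry bulk density (g/cm^3): dry mass over slice volume."""
    if corer_area <= 0:
        raise ValueError("corer_area must be > 0")
    if sl.thickness <= 0:
        raise ValueError("slice thickness must be > 0")
    return sl.total_dry_mass / (corer_area * sl.thickness)


def slice_oc(sl: CoreSlice, corer_area: float) -> SliceOC:
    """Derive OC fraction, bulk density and OC density for one slice."""
    frac = oc_fraction_from_loi(sl.c_pct_raw, sl.c_pct_ashed)
    dbd = dry_bulk_density(sl, corer_area)
    return SliceOC(
        oc_fraction=frac,
        dry_bulk_density=dbd,
        oc_density=frac * dbd,
        thickness=sl.thickness,
    )


def burrow_void_fraction(
    burrow_count: float,
    diameters: tuple[float, ...] | list[float],
    quadrat_area: float = 625.0,
) -> float:
    """Areal fraction of the quadrat occupied by burrow openings.

    ``burrow_count`` may be a site mean (fractional).  With zero burrows
    the fraction is 0 regardless of diameters.  Raises if the openings
    would cover the whole quadrat.
    """
    if quadrat_area <= 0:
        raise ValueError("quadrat_area must be > 0")
    if burrow_count < 0:
        raise ValueError("burrow_count must be >= 0")
    if burrow_count == 0:
        return 0.0
    if not diameters:
        raise ValueError("diameters required when burrow_count > 0")
    d = mean(diameters)
    f = burrow_count * math.pi * (d / 2.0) ** 2 / quadrat_area
    if f >= 1:
        raise ValueError(f"burrow void fraction {f:.3f} >= 1: voids exceed quadrat")
    return f


def site_void_fraction(surveys: list[BurrowSurvey]) -> float:
    """Void fraction from site-mean burrow count and site-mean diameter.

    Mirrors the per-site averaging of counts and diameters: the mean count
    and the mean of all measured diameters are combined, rather than
    averaging per-quadrat void fractions.
    """
    if not surveys:
        return 0.0
    areas = {s.quadrat_area for s in surveys}
    if len(areas) != 1:
        raise ValueError("mixed quadrat areas in one site survey")
    count = mean(s.burrow_count for s in surveys)
    all_d = [d for s in surveys for d in s.diameters]
    return burrow_void_fraction(count, tuple(all_d), areas.pop())


def integrate_sediment_stock(
    profile: CoreProfile,
    void_fraction: float = 0.0,
    taper: float = 1.0,
) -> float:
    """Depth-integrated, burrow-corrected sediment OC stock (Mg OC/ha).

    Sums OC density x thickness over the slices actually cored and scales
    the areal result by (1 - taper x void_fraction).  ``taper`` < 1 models
    burrows that narrow with depth (default 1: full-depth cylinders).
    """
    if not 0 <= void_fraction < 1:
        raise ValueError("void_fraction must be in [0, 1)")
    if not 0 <= taper <= 1:
        raise ValueError("taper must be in [0, 1]")
    if not profile.slices:
        raise ValueError("empty profile")
    areal = sum(
        slice_oc(s, profile.corer_area).oc_density * s.thickness for s in profile.slices
    )  # g OC/cm^2
    return areal * (1.0 - taper * void_fraction) * 100.0


def mean_oc_density(
    profile: CoreProfile,
    void_fraction: float = 0.0,
    max_depth: float | None = None,
) -> float:
    """Thickness-weighted mean OC density (g/cm^3), burrow-corrected.

    ``max_depth`` restricts the mean to the slices whose tops lie above it
    (e.g. the dated interval of a paired geochronology core).
    """
    slices = [
        s for s in profile.slices if max_depth is None or s.top_depth < max_depth
    ]
    if not slices:
        raise ValueError("no slices above max_depth")
    total_thick = sum(s.thickness for s in slices)
    dens = sum(slice_oc(s, profile.corer_area).oc_density * s.thickness for s in slices)
    return dens / total_thick * (1.0 - void_fraction)


def biomass_oc_stock(biomass: float, c_fraction: float) -> float:
    """Vegetation OC stock (Mg OC/ha) from biomass (g/m^2) and C fraction."""
    if biomass < 0:
        raise ValueError("biomass must be >= 0")
    if biomass > 0 and not 0 < c_fraction < 1:
        raise ValueError("c_fraction must be in (0, 1)")
    return biomass * c_fraction / 100.0


def assemble_stock_record(
    site_id: str,
    species: str,
    sediment_stock: float,
    green_stock: float,
    senescent_stock: float,
    root_stock: float,
    void_fraction: float,
    root_stock_in_core: bool = False,
) -> StockRecord:
    """Combine compartment stocks into one record.

    Belowground = sediment + roots, except when the root OC is already part
    of the core measurement (``root_stock_in_core``), in which case adding
    it again would double count.
    """
    if root_stock_in_core and root_stock > 0:
        raise ValueError(
            "root_stock_in_core=True but a separate root stock was supplied"
        )
    belowground = sediment_stock if root_stock_in_core else sediment_stock + root_stock
    total = belowground + green_stock + senescent_stock
    return StockRecord(
        site_id=site_id,
        species=species,
        stock_green=green_stock,
        stock_senescent=senescent_stock,
        stock_roots=root_stock,
        stock_sediment=sediment_stock,
        stock_belowground=belowground,
        stock_total=total,
        burrow_void_fraction=void_fraction,
    )


def scale_to_site_tons(stock_mg_ha: float, area_ha: float) -> float:
    """Site total in tons OC (1 Mg = 1 t)."""
    if area_ha < 0:
        raise ValueError("area must be >= 0")
    return stock_mg_ha * area_ha


def compute_stocks(
    profiles: list[CoreProfile],
    vegetation: list,
    burrows: list[BurrowSurvey],
    taper: float = 1.0,
) -> list[StockRecord]:
    """Full stocks stage: one record per site x species.

    Sediment stocks average over the cores of each site x species group;
    the burrow void fraction uses the site x species mean count and mean
    diameter.  Vegetation compartments convert biomass x C fraction.
    """
    keys: list[tuple[str, str]] = []
    for p in profiles:
        k = (p.site_id, p.species)
        if k not in keys:
            keys.append(k)
    veg_by_key = {(v.site_id, v.species): v for v in vegetation}
    records = []
    for site_id, species in keys:
        survs = [b for b in burrows if (b.site_id, b.species) == (site_id, species)]
        void = site_void_fraction(survs)
        cores = [p for p in profiles if (p.site_id, p.species) == (site_id, species)]
        sed = mean(integrate_sediment_stock(p, void, taper) for p in cores)
        v = veg_by_key.get((site_id, species))
        green = senescent = roots = 0.0
        if v is not None:
            green = biomass_oc_stock(v.biomass_green, v.c_fraction_green)
            senescent = biomass_oc_stock(v.biomass_senescent, v.c_fraction_senescent)
            roots = biomass_oc_stock(v.biomass_roots, v.c_fraction_roots)
        records.append(
            assemble_stock_record(
                site_id, species, sed, green, senescent, roots, void
            )
        )
    return records
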