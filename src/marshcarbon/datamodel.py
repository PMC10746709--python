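"""Shared data model and CSV I/O for every pipeline stage.

All tabular inputs are plain comma-separated UTF-8 files with "." decimals
and one published, case-sensitive header per schema.  Records are frozen
dataclasses whose invariants are checked on construction, so no record with
a violated invariant ever reaches a downstream stage.  Missing numeric
values are empty cells and surface as ``None`` (never 0): a site whose
cores could not be dated simply carries an absent accretion rate.

Depth convention: centimetres below the sediment surface, positive
downward, half-open slice intervals ``[top, bottom)``.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import math
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

logger = logging.getLogger("marshcarbon")

SPECIES_CODES = ("Sa", "Sd", "Ssp")  # S. alterniflora, S. densiflora, Salicornia sp.
ZONES = ("lower", "upper", "none")
SOURCE_NAMES = ("plants", "POM", "macroalgae")


class SchemaError(ValueError):
    """Header does not match the named schema (missing/unknown column)."""


class ValidationError(ValueError):
    """A record violates a declared invariant; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


@contextmanager
def stage_timer(stage: str) -> Iterator[None]:
    """Log wall-time of a pipeline stage to stderr at INFO level."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", stage)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.3f s", stage, time.perf_counter() - t0)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteRecord:
    """Site-level metadata and climate covariates."""

    site_id: str
    latitude: float  # degrees, negative south
    area_ha: float  # hectares occupied by the dominant species
    tidal_amplitude: float  # m
    mean_annual_temperature: float  # deg C (bioclim 1)
    mean_annual_precipitation: float  # mm (bioclim 12)
    freshwater_input: int  # 1 = riverine freshwater input, 0 = none
    collection_year: int

    def __post_init__(self) -> None:
        _check(self.area_ha >= 0, f"area_ha must be >= 0, got {self.area_ha}")
        _check(self.tidal_amplitude > 0, "tidal_amplitude must be > 0")
        _check(self.freshwater_input in (0, 1), "freshwater_input must be 0 or 1")


@dataclass(frozen=True)
class CoreSlice:
    """One depth slice of a sediment core.

    ``c_pct_raw``/``c_pct_ashed`` are total-C percentages of the
    non-incinerated and incinerated (450 degC LOI) subsamples; their
    difference is the organic-C fraction.  Radionuclide activities are
    optional (only the geochronology cores carry them); ``pb214`` proxies
    supported (background) ²¹⁰Pb.
    """

    top_depth: float  # cm
    bottom_depth: float  # cm
    total_dry_mass: float  # g
    subsample_mass: float  # g
    c_pct_raw: float  # %
    c_pct_ashed: float  # %
    n_pct: float  # %
    pb210_total: float | None = None  # Bq/kg
    pb214: float | None = None  # Bq/kg
    cs137: float | None = None  # Bq/kg

    def __post_init__(self) -> None:
        _check(0 <= self.top_depth < self.bottom_depth, "need 0 <= top < bottom depth")
        _check(self.total_dry_mass > 0 and self.subsample_mass > 0, "masses must be > 0")
        for name in ("c_pct_raw", "c_pct_ashed", "n_pct"):
            v = getattr(self, name)
            _check(0 <= v <= 100, f"{name} must be in [0, 100], got {v}")
        for name in ("pb210_total", "pb214", "cs137"):
            v = getattr(self, name)
            _check(v is None or v >= 0, f"{name} must be >= 0 where present")

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth

    @property
    def mid_depth(self) -> float:
        return 0.5 * (self.top_depth + self.bottom_depth)


@dataclass(frozen=True)
class CoreProfile:
    """An ordered, contiguous stack of slices from one core."""

    core_id: str
    site_id: str
    species: str  # one of SPECIES_CODES
    zone: str  # lower / upper / none
    corer_area: float  # cm^2 cross-section
    slices: tuple[CoreSlice, ...]

    def __post_init__(self) -> None:
        _check(self.species in SPECIES_CODES, f"unknown species code {self.species!r}")
        _check(self.zone in ZONES, f"unknown zone {self.zone!r}")
        _check(self.corer_area > 0, "corer_area must be > 0")
        _check(len(self.slices) > 0, "profile must have at least one slice")
        object.__setattr__(self, "slices", tuple(self.slices))
        prev = 0.0
        for s in self.slices:
            _check(
                math.isclose(s.top_depth, prev, abs_tol=1e-9),
                f"slices must be contiguous: expected top {prev}, got {s.top_depth}",
            )
            prev = s.bottom_depth
        _check(prev <= 100 + 1e-9, f"max_depth {prev} exceeds 100 cm")

    @property
    def max_depth(self) -> float:
        return self.slices[-1].bottom_depth


@dataclass(frozen=True)
class VegetationSample:
    """Green/senescent/root biomass with carbon fractions and C:N ratios."""

    site_id: str
    species: str
    biomass_green: float  # g/m^2
    biomass_senescent: float
    biomass_roots: float
    c_fraction_green: float  # proportion of dry mass
    c_fraction_senescent: float
    c_fraction_roots: float
    cn_green: float
    cn_senescent: float
    cn_roots: float

    def __post_init__(self) -> None:
        _check(self.species in SPECIES_CODES, f"unknown species code {self.species!r}")
        for comp in ("green", "senescent", "roots"):
            b = getattr(self, f"biomass_{comp}")
            c = getattr(self, f"c_fraction_{comp}")
            cn = getattr(self, f"cn_{comp}")
            _check(b >= 0, f"biomass_{comp} must be >= 0")
            _check(0 < c < 1, f"c_fraction_{comp} must be in (0, 1)")
            if b > 0:
                _check(cn > 0, f"cn_{comp} must be > 0 where biomass > 0")


@dataclass(frozen=True)
class BurrowSurvey:
    """Burrow count and entrance diameters for one 25x25 cm quadrat."""

    site_id: str
    species: str
    burrow_count: int
    diameters: tuple[float, ...] = ()  # cm, up to 5 measured
    quadrat_area: float = 625.0  # cm^2

    def __post_init__(self) -> None:
        _check(self.species in SPECIES_CODES, f"unknown species code {self.species!r}")
        _check(self.burrow_count >= 0, "burrow_count must be >= 0")
        _check(self.quadrat_area > 0, "quadrat_area must be > 0")
        object.__setattr__(self, "diameters", tuple(self.diameters))
        _check(all(d > 0 for d in self.diameters), "diameters must be > 0")
        if self.burrow_count == 0:
            _check(not self.diameters, "no diameters allowed when burrow_count = 0")


@dataclass(frozen=True)
class IsotopeMixture:
    """delta13C / delta15N of surficial sediment (the mixture)."""

    site_id: str
    species: str
    d13c: float  # permil
    d15n: float  # permil

    def __post_init__(self) -> None:
        _check(self.species in SPECIES_CODES, f"unknown species code {self.species!r}")


@dataclass(frozen=True)
class IsotopeSource:
    """Literature signature (mean, SD per tracer) of one OM source."""

    source_name: str
    mean_d13c: float
    sd_d13c: float
    mean_d15n: float
    sd_d15n: float

    def __post_init__(self) -> None:
        _check(self.sd_d13c > 0 and self.sd_d15n > 0, "source SDs must be > 0")


@dataclass(frozen=True)
class IsotopeTable:
    """Mixtures plus candidate sources for one mixing-model run."""

    mixtures: tuple[IsotopeMixture, ...]
    sources: tuple[IsotopeSource, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mixtures", tuple(self.mixtures))
        object.__setattr__(self, "sources", tuple(self.sources))
        _check(len(self.sources) >= 2, "need at least 2 sources")


@dataclass(frozen=True)
class PlotCovariates:
    """Plot-level covariates consumed by the path analysis."""

    plot_id: str
    site_id: str
    species: str
    grain_size: float  # inverse sorting coefficient, unitless
    sar: float | None  # mm/yr, absent where dating failed
    layer_depth: float  # cm
    burrow_surface: float  # proportion of sediment surface, [0, 1)
    litter: float  # g/m^2
    ag_biomass: float
    bg_biomass: float
    cn_senescent: float
    cn_green: float
    cn_roots: float
    belowground_oc_stock: float  # g OC/m^2

    def __post_init__(self) -> None:
        _check(self.species in SPECIES_CODES, f"unknown species code {self.species!r}")
        _check(0 <= self.burrow_surface < 1, "burrow_surface must be in [0, 1)")
        _check(self.belowground_oc_stock > 0, "belowground_oc_stock must be > 0")


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------


def _fmt(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(float(v))  # exact round-trip; normalises numpy scalars
    return str(v)


def _parse_float(s: str, col: str, row: int) -> float:
    try:
        return float(s)
    except ValueError:
        raise ValidationError(f"column {col!r}: not a number: {s!r}", row=row) from None


def _parse_opt_float(s: str, col: str, row: int) -> float | None:
    return None if s == "" else _parse_float(s, col, row)


def _parse_int(s: str, col: str, row: int) -> int:
    try:
        return int(float(s)) if float(s) == int(float(s)) else int(s)
    except ValueError:
        raise ValidationError(f"column {col!r}: not an integer: {s!r}", row=row) from None


DEFAULT_CONFIG = {
    "constants": {
        "pb210_half_life_yr": 22.3,
        "reference_fallout_year": 1963,
        "quadrat_area_cm2": 625.0,
        "corer_area_cm2": 9.05,
    },
    "stocks": {"burrow_taper": 1.0},
    "sem": {"alpha": 0.05},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a nested YAML config, overlaying the package defaults."""
    import copy

    import yaml

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


@dataclass(frozen=True)
class _Schema:
    name: str
    columns: tuple[str, ...]
    record_type: type
    # grouped schemas (cores) assemble several rows into one record


SCHEMAS: dict[str, _Schema] = {}


def _register(name: str, columns: Sequence[str], record_type: type) -> None:
    SCHEMAS[name] = _Schema(name, tuple(columns), record_type)


_register(
    "sites",
    [
        "site_id",
        "latitude",
        "area_ha",
        "tidal_amplitude",
        "mean_annual_temperature",
        "mean_annual_precipitation",
        "freshwater_input",
        "collection_year",
    ],
    SiteRecord,
)
_register(
    "cores",
    [
        "core_id",
        "site_id",
        "species",
        "zone",
        "corer_area",
        "top_depth",
        "bottom_depth",
        "total_dry_mass",
        "subsample_mass",
        "c_pct_raw",
        "c_pct_ashed",
        "n_pct",
        "pb210_total",
        "pb214",
        "cs137",
    ],
    CoreProfile,
)
_register(
    "vegetation",
    [
        "site_id",
        "species",
        "biomass_green",
        "biomass_senescent",
        "biomass_roots",
        "c_fraction_green",
        "c_fraction_senescent",
        "c_fraction_roots",
        "cn_green",
        "cn_senescent",
        "cn_roots",
    ],
    VegetationSample,
)
_register(
    "burrows",
    ["site_id", "species", "quadrat_area", "burrow_count", "diameters"],
    BurrowSurvey,
)
_register("isotopes_mixtures", ["site_id", "species", "d13c", "d15n"], IsotopeMixture)
_register(
    "isotopes_sources",
    ["source_name", "mean_d13c", "sd_d13c", "mean_d15n", "sd_d15n"],
    IsotopeSource,
)
_register(
    "plots",
    [
        "plot_id",
        "site_id",
        "species",
        "grain_size",
        "sar",
        "layer_depth",
        "burrow_surface",
        "litter",
        "ag_biomass",
        "bg_biomass",
        "cn_senescent",
        "cn_green",
        "cn_roots",
        "belowground_oc_stock",
    ],
    PlotCovariates,
)

# fields parsed as optional floats / ints rather than required floats
_OPTIONAL_FLOAT = {
    "cores": {"pb210_total", "pb214", "cs137"},
    "plots": {"sar"},
}
_INT_FIELDS = {
    "sites": {"freshwater_input", "collection_year"},
    "burrows": {"burrow_count"},
}
_TEXT_FIELDS = {
    "sites": {"site_id"},
    "cores": {"core_id", "site_id", "species", "zone"},
    "vegetation": {"site_id", "species"},
    "burrows": {"site_id", "species"},
    "isotopes_mixtures": {"site_id", "species"},
    "isotopes_sources": {"source_name"},
    "plots": {"plot_id", "site_id", "species"},
}


def _parse_cell(schema: str, col: str, raw: str, row: int) -> object:
    if col in _TEXT_FIELDS.get(schema, ()):
        return raw
    if col == "diameters":
        return tuple(_parse_float(p, col, row) for p in raw.split(";") if p != "")
    if col in _INT_FIELDS.get(schema, ()):
        return _parse_int(raw, col, row)
    if col in _OPTIONAL_FLOAT.get(schema, ()):
        return _parse_opt_float(raw, col, row)
    return _parse_float(raw, col, row)


def read_table(path: str | Path, schema: str) -> list:
    """Read and validate one CSV table.

    Returns a list of records of the schema's type; for ``cores`` the
    per-slice rows are grouped (in file order) into :class:`CoreProfile`
    objects.  Any invariant violation is raised as
    :class:`ValidationError` with the 1-based data-row number.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        for col in sch.columns:
            if col not in header:
                raise SchemaError(f"{path}: missing column {col!r} for schema {schema!r}")
        idx = {c: header.index(c) for c in sch.columns}
        rows: list[tuple[int, dict[str, object]]] = []
        for i, raw_row in enumerate(reader, start=1):
            if not raw_row or all(c == "" for c in raw_row):
                continue
            cells = {c: _parse_cell(schema, c, raw_row[idx[c]].strip(), i) for c in sch.columns}
            rows.append((i, cells))
    if not rows and schema != "cores":
        return []

    if schema == "cores":
        return _assemble_cores(rows)

    records = []
    for i, cells in rows:
        try:
            records.append(sch.record_type(**cells))
        except ValidationError as e:
            raise ValidationError(str(e), row=i) from None
    return records


def _assemble_cores(rows: list[tuple[int, dict[str, object]]]) -> list[CoreProfile]:
    profiles: list[CoreProfile] = []
    groups: dict[str, list[tuple[int, dict[str, object]]]] = {}
    order: list[str] = []
    for i, cells in rows:
        cid = cells["core_id"]
        if cid not in groups:
            groups[cid] = []
            order.append(cid)
        groups[cid].append((i, cells))
    slice_fields = [f.name for f in dataclasses.fields(CoreSlice)]
    for cid in order:
        grp = groups[cid]
        first_row, head = grp[0]
        slices = []
        for i, cells in grp:
            try:
                slices.append(CoreSlice(**{f: cells[f] for f in slice_fields}))
            except ValidationError as e:
                raise ValidationError(str(e), row=i) from None
        try:
            profiles.append(
                CoreProfile(
                    core_id=cid,
                    site_id=head["site_id"],
                    species=head["species"],
                    zone=head["zone"],
                    corer_area=head["corer_area"],
                    slices=tuple(slices),
                )
            )
        except ValidationError as e:
            raise ValidationError(str(e), row=first_row) from None
    return profiles


def write_table(records: Sequence, path: str | Path, schema: str) -> Path:
    """Write records as CSV in the schema's canonical column order.

    ``read_table(write_table(x)) == x``: floats are serialised with
    ``repr`` so the round trip is exact.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(sch.columns)
        if schema == "cores":
            for prof in records:
                for s in prof.slices:
                    writer.writerow(
                        [
                            prof.core_id,
                            prof.site_id,
                            prof.species,
                            prof.zone,
                            _fmt(prof.corer_area),
                        ]
                        + [_fmt(getattr(s, f.name)) for f in dataclasses.fields(CoreSlice)]
                    )
        else:
            for rec in records:
                row = []
                for col in sch.columns:
                    v = getattr(rec, col)
                    if col == "diameters":
                        row.append(";".join(repr(float(d)) for d in v))
                    else:
                        row.append(_fmt(v))
                writer.writerow(row)
    return path
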