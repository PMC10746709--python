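"""Seeded synthetic datasets with stored ground truth for every stage.

Each generator is a pure function of its parameters and seed and emulates
the statistical structure the corresponding analysis assumes:

* cores with exponentially depth-declining OC fraction and constant bulk
  density (plus multiplicative lognormal noise);
* excess-²¹⁰Pb profiles decaying exponentially under constant accretion,
  with a Gaussian ¹³⁷Cs pulse at the fallout-peak depth;
* Poisson burrow counts per 25 x 25 cm quadrat with lognormal entrance
  diameters;
* two-tracer Gaussian mixtures drawn from the same process + residual
  model the mixing stage fits;
* multi-site plot tables generated from a linear DAG with site-level
  random intercepts.

Default parameter magnitudes follow the study region's observed ranges
(accretion 0.5-3.5 mm/yr, stocks ~5-110 Mg OC/ha, burrow densities up to
>120 per m²) so demo outputs are magnitude-realistic.  One master seed
fans out to per-stage child seeds by fixed integer offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from marshcarbon.datamodel import (
    BurrowSurvey,
    CoreProfile,
    CoreSlice,
    IsotopeMixture,
    IsotopeSource,
    IsotopeTable,
)
from marshcarbon.geochron import PB210_LAMBDA, RadionuclideProfile
from marshcarbon.pathsem import PathDAG

__all__ = [
    "GroundTruth",
    "child_seed",
    "default_slice_plan",
    "gen_core",
    "gen_radionuclide_profile",
    "gen_burrow_field",
    "gen_isotope_data",
    "gen_sem_dataset",
    "SEED_OFFSETS",
    "RUSSIAN_CORER_AREA_CM2",
]

RUSSIAN_CORER_AREA_CM2 = 9.05

SEED_OFFSETS = {
    "core": 11,
    "radionuclide": 23,
    "burrows": 37,
    "isotopes": 53,
    "sem": 71,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Per-stage child seed: fixed offset from the master, below 2^31."""
    return (int(master_seed) + SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters stored alongside each synthetic dataset."""

    stage: str
    seed: int
    params: dict = field(default_factory=dict)


def default_slice_plan(depth: float) -> tuple[tuple[float, float], ...]:
    """Slice boundaries at 5, 10, then every 10 cm down to ``depth``."""
    bounds = [0.0, 5.0, 10.0]
    while bounds[-1] < depth:
        bounds.append(min(bounds[-1] + 10.0, depth))
    bounds = [b for b in bounds if b <= depth]
    if bounds[-1] < depth:
        bounds.append(depth)
    return tuple(zip(bounds[:-1], bounds[1:]))


def gen_core(
    seed: int,
    oc_surface_fraction: float = 0.03,
    oc_decay_per_cm: float = 0.02,
    bulk_density: float = 0.9,
    depth: float = 50.0,
    slice_plan: Sequence[tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    corer_area: float = RUSSIAN_CORER_AREA_CM2,
    inorganic_c_fraction: float = 0.005,
    core_id: str = "SYN-1",
    site_id: str = "SYN",
    species: str = "Sa",
    zone: str = "none",
) -> tuple[CoreProfile, GroundTruth]:
    """Synthetic stock core: OC fraction c0*exp(-k z) with lognormal noise.

    At ``noise_sd = 0`` the OC fraction at each slice midpoint is exactly
    the exponential profile, so the integrated stock has the closed form
    ``100 * rho * sum_i c0 exp(-k mid_i) * thickness_i`` Mg OC/ha.
    """
    if depth > 100:
        raise ValueError("depth must be <= 100 cm")
    if min(oc_surface_fraction, oc_decay_per_cm, bulk_density, depth) <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    plan = tuple(slice_plan) if slice_plan is not None else default_slice_plan(depth)
    slices = []
    for top, bottom in plan:
        mid = 0.5 * (top + bottom)
        c = oc_surface_fraction * math.exp(-oc_decay_per_cm * mid)
        if noise_sd > 0:
            c *= math.exp(noise_sd * rng.standard_normal())
        c = min(c, 1.0 - inorganic_c_fraction)
        mass = bulk_density * corer_area * (bottom - top)
        slices.append(
            CoreSlice(
                top_depth=top,
                bottom_depth=bottom,
                total_dry_mass=mass,
                subsample_mass=2.0,
                c_pct_raw=(c + inorganic_c_fraction) * 100.0,
                c_pct_ashed=inorganic_c_fraction * 100.0,
                n_pct=c * 100.0 / 12.0,  # C:N ~ 12
            )
        )
    profile = CoreProfile(
        core_id=core_id,
        site_id=site_id,
        species=species,
        zone=zone,
        corer_area=corer_area,
        slices=tuple(slices),
    )
    truth = GroundTruth(
        "core",
        seed,
        {
            "oc_surface_fraction": oc_surface_fraction,
            "oc_decay_per_cm": oc_decay_per_cm,
            "bulk_density": bulk_density,
            "depth": depth,
            "noise_sd": noise_sd,
            "inorganic_c_fraction": inorganic_c_fraction,
        },
    )
    return profile, truth


def gen_radionuclide_profile(
    seed: int,
    sar: float = 2.0,
    surface_excess: float = 80.0,
    supported_level: float = 12.0,
    cs_peak_year: int = 1963,
    collection_year: int = 2016,
    noise_sd: float = 0.0,
    depth: float = 30.0,
    slice_thickness: float = 1.0,
    cs_amplitude: float = 25.0,
    cs_width_cm: float = 2.0,
    core_id: str = "SYN-G1",
) -> tuple[RadionuclideProfile, GroundTruth]:
    """Synthetic dating core under constant flux / constant sedimentation.

    Excess ²¹⁰Pb decays as ``A0 exp(-lambda x / s)`` (s = sar/10 cm/yr)
    with multiplicative lognormal noise; total ²¹⁰Pb adds the constant
    supported level (²¹⁴Pb proxy).  ¹³⁷Cs is a Gaussian pulse centred at
    the depth deposited in ``cs_peak_year``.
    """
    if sar <= 0:
        raise ValueError("sar must be > 0")
    rng = np.random.default_rng(seed)
    s_cm = sar / 10.0
    mids = np.arange(slice_thickness / 2.0, depth, slice_thickness)
    excess = surface_excess * np.exp(-PB210_LAMBDA * mids / s_cm)
    if noise_sd > 0:
        excess = excess * np.exp(noise_sd * rng.standard_normal(mids.size))
    peak_cm = s_cm * (collection_year - cs_peak_year)
    cs = cs_amplitude * np.exp(-0.5 * ((mids - peak_cm) / cs_width_cm) ** 2)
    profile = RadionuclideProfile(
        core_id=core_id,
        depths=tuple(mids),
        collection_year=collection_year,
        pb210_total=tuple(excess + supported_level),
        pb214=tuple([supported_level] * mids.size),
        cs137=tuple(cs),
    )
    truth = GroundTruth(
        "radionuclide",
        seed,
        {
            "sar": sar,
            "surface_excess": surface_excess,
            "supported_level": supported_level,
            "cs_peak_depth_cm": peak_cm,
            "noise_sd": noise_sd,
        },
    )
    return profile, truth


def gen_burrow_field(
    seed: int,
    mean_density_per_m2: float = 80.0,
    diameter_mu: float = math.log(2.0),
    diameter_sigma: float = 0.25,
    n_quadrats: int = 5,
    quadrat_area: float = 625.0,
    site_id: str = "SYN",
    species: str = "Sa",
    max_measured: int = 5,
) -> tuple[list[BurrowSurvey], GroundTruth]:
    """Poisson burrow counts per quadrat with lognormal entrance diameters."""
    if mean_density_per_m2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    lam = mean_density_per_m2 * quadrat_area / 1e4  # quadrat in m^2
    surveys = []
    for _ in range(n_quadrats):
        count = int(rng.poisson(lam))
        n_meas = min(count, max_measured)
        diam = tuple(np.exp(diameter_mu + diameter_sigma * rng.standard_normal(n_meas)))
        surveys.append(
            BurrowSurvey(
                site_id=site_id,
                species=species,
                burrow_count=count,
                diameters=diam,
                quadrat_area=quadrat_area,
            )
        )
    truth = GroundTruth(
        "burrows",
        seed,
        {
            "mean_density_per_m2": mean_density_per_m2,
            "diameter_mu": diameter_mu,
            "diameter_sigma": diameter_sigma,
            # E[d^2] for a lognormal gives the expected void fraction
            "expected_void_fraction": lam
            * math.pi
            / 4.0
            * math.exp(2 * diameter_mu + 2 * diameter_sigma**2)
            / quadrat_area,
        },
    )
    return surveys, truth


def gen_isotope_data(
    seed: int,
    true_proportions: Sequence[float],
    sources: Sequence[IsotopeSource],
    n_mixtures: int = 10,
    residual_sd: float = 0.0,
    site_id: str = "SYN",
    species: str = "Sa",
) -> tuple[IsotopeTable, GroundTruth]:
    """Tracer mixtures drawn from the process + residual model isomix fits."""
    p = np.asarray(true_proportions, float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("true_proportions must lie on the simplex")
    if p.size != len(sources):
        raise ValueError("one proportion per source required")
    rng = np.random.default_rng(seed)
    mu = np.array([[s.mean_d13c, s.mean_d15n] for s in sources])
    sig2 = np.array([[s.sd_d13c**2, s.sd_d15n**2] for s in sources])
    mean = p @ mu
    sd = np.sqrt((p**2) @ sig2 + residual_sd**2)
    draws = mean + sd * rng.standard_normal((n_mixtures, 2))
    mixtures = tuple(
        IsotopeMixture(site_id=site_id, species=species, d13c=float(d[0]), d15n=float(d[1]))
        for d in draws
    )
    table = IsotopeTable(mixtures=mixtures, sources=tuple(sources))
    truth = GroundTruth(
        "isotopes",
        seed,
        {"true_proportions": tuple(p), "residual_sd": residual_sd},
    )
    return table, truth


def gen_sem_dataset(
    seed: int,
    dag: PathDAG,
    path_coefficients: dict[tuple[str, str], float],
    site_intercept_sd: float = 0.5,
    residual_sd: float = 1.0,
    n_sites: int = 10,
    plots_per_site: int = 30,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Multi-site plot table from a linear Gaussian DAG with site intercepts.

    Exogenous nodes are standard normal; each endogenous node is the
    linear combination of its parents plus a node-specific site-level
    random intercept and iid residual noise.
    """
    for edge in path_coefficients:
        if tuple(edge) not in dag.edges:
            raise ValueError(f"coefficient given for non-edge {edge}")
    for edge in dag.edges:
        if tuple(edge) not in path_coefficients:
            raise ValueError(f"missing coefficient for edge {edge}")
    rng = np.random.default_rng(seed)
    n = n_sites * plots_per_site
    site = np.repeat([f"site{i:02d}" for i in range(n_sites)], plots_per_site)
    data = pd.DataFrame({"site_id": site})
    order = dag.topological_order()
    for node in order:
        parents = dag.parents(node)
        if not parents:
            data[node] = rng.standard_normal(n)
        else:
            val = np.zeros(n)
            for parent in parents:
                val += path_coefficients[(parent, node)] * data[parent].to_numpy()
            b_site = site_intercept_sd * rng.standard_normal(n_sites)
            val += np.repeat(b_site, plots_per_site)
            val += residual_sd * rng.standard_normal(n)
            data[node] = val
    truth = GroundTruth(
        "sem",
        seed,
        {
            "path_coefficients": dict(path_coefficients),
            "site_intercept_sd": site_intercept_sd,
            "residual_sd": residual_sd,
            "n_sites": n_sites,
            "plots_per_site": plots_per_site,
        },
    )
    return data, truth


# ---------------------------------------------------------------------------
# whole-study simulation (all CSV schemas at once)
# ---------------------------------------------------------------------------

DEFAULT_METAMODEL = PathDAG(
    nodes=(
        "grain_size",
        "sar",
        "burrow_surface",
        "ag_biomass",
        "belowground_oc_stock",
    ),
    edges=(
        ("grain_size", "belowground_oc_stock"),
        ("sar", "belowground_oc_stock"),
        ("burrow_surface", "belowground_oc_stock"),
        ("burrow_surface", "ag_biomass"),
        ("ag_biomass", "belowground_oc_stock"),
    ),
)

DEFAULT_PATH_COEFFICIENTS = {
    ("grain_size", "belowground_oc_stock"): 0.6,
    ("sar", "belowground_oc_stock"): 0.5,
    ("burrow_surface", "belowground_oc_stock"): 0.45,
    ("burrow_surface", "ag_biomass"): -0.4,
    ("ag_biomass", "belowground_oc_stock"): 0.3,
}

DEFAULT_SOURCES = (
    IsotopeSource("plants", -14.0, 1.2, 8.0, 1.0),
    IsotopeSource("POM", -24.0, 1.0, 6.0, 1.0),
)


def simulate_study(
    seed: int,
    n_sites: int = 3,
    plots_per_site: int = 5,
) -> dict:
    """Generate one coherent synthetic study across all CSV schemas.

    Returns a dict of record collections keyed by schema name plus a
    ``ground_truth`` entry; every collection passes data-model validation
    and round-trips through :func:`marshcarbon.datamodel.write_table`.
    Plot covariates are generated from the default latent metamodel and
    mapped to observable scales by the inverses of the analysis-scale
    transforms (log10 for stocks/biomass/C:N, square root for burrow
    surface, litter and aboveground biomass), so the path structure is
    linear after transforming back.
    """
    from marshcarbon.datamodel import PlotCovariates, SiteRecord, VegetationSample

    rng = np.random.default_rng(child_seed(seed, "core"))
    sites, cores, veg, burrows, mixtures = [], [], [], [], []
    truths = {}
    species_cycle = ("Sa", "Sd", "Ssp")
    for i in range(n_sites):
        sid = f"site{i:02d}"
        species = species_cycle[i % 3]
        sar_true = float(rng.uniform(0.5, 3.5))
        sites.append(
            SiteRecord(
                site_id=sid,
                latitude=-35.0 - 1.5 * i,
                area_ha=float(rng.uniform(30, 60000)),
                tidal_amplitude=float(rng.uniform(0.8, 8.0)),
                mean_annual_temperature=15.0 - 0.7 * i,
                mean_annual_precipitation=float(rng.uniform(200, 1000)),
                freshwater_input=int(rng.random() < 0.5),
                collection_year=2016,
            )
        )
        core, core_truth = gen_core(
            child_seed(seed, "core") + i,
            oc_surface_fraction=float(rng.uniform(0.01, 0.05)),
            oc_decay_per_cm=0.015,
            bulk_density=float(rng.uniform(0.6, 1.2)),
            depth=float(rng.choice([50.0, 70.0, 100.0])),
            noise_sd=0.1,
            core_id=f"{sid}-C1",
            site_id=sid,
            species=species,
        )
        cores.append(core)
        truths[f"{sid}_core"] = core_truth
        radio, radio_truth = gen_radionuclide_profile(
            child_seed(seed, "radionuclide") + i,
            sar=sar_true,
            noise_sd=0.15,
            core_id=f"{sid}-G1",
        )
        truths[f"{sid}_dating"] = radio_truth
        cores.append(_radionuclide_core(radio, sid, species))
        qs, b_truth = gen_burrow_field(
            child_seed(seed, "burrows") + i,
            mean_density_per_m2=float(rng.uniform(0, 120)),
            site_id=sid,
            species=species,
        )
        burrows.extend(qs)
        truths[f"{sid}_burrows"] = b_truth
        veg.append(
            VegetationSample(
                site_id=sid,
                species=species,
                biomass_green=float(rng.uniform(50, 1400)),
                biomass_senescent=float(rng.uniform(0, 1500)),
                biomass_roots=float(rng.uniform(60, 12000)),
                c_fraction_green=0.38,
                c_fraction_senescent=0.36,
                c_fraction_roots=0.33,
                cn_green=float(rng.uniform(15, 40)),
                cn_senescent=float(rng.uniform(30, 80)),
                cn_roots=float(rng.uniform(30, 90)),
            )
        )
        p_pom = float(rng.uniform(0.4, 0.95))
        iso, iso_truth = gen_isotope_data(
            child_seed(seed, "isotopes") + i,
            true_proportions=(1.0 - p_pom, p_pom),
            sources=DEFAULT_SOURCES,
            n_mixtures=5,
            residual_sd=0.3,
            site_id=sid,
            species=species,
        )
        mixtures.extend(iso.mixtures)
        truths[f"{sid}_isotopes"] = iso_truth

    latent, sem_truth = gen_sem_dataset(
        child_seed(seed, "sem"),
        DEFAULT_METAMODEL,
        DEFAULT_PATH_COEFFICIENTS,
        n_sites=n_sites,
        plots_per_site=plots_per_site,
    )
    truths["sem"] = sem_truth
    plots = []
    rng_p = np.random.default_rng(child_seed(seed, "sem") + 1)
    for j, row in latent.iterrows():
        plots.append(
            PlotCovariates(
                plot_id=f"plot{j:03d}",
                site_id=row["site_id"],
                species=species_cycle[j % 3],
                grain_size=float(row["grain_size"]),
                sar=float(1.5 + 0.4 * row["sar"]),
                layer_depth=float(np.clip(60 + 12 * rng_p.standard_normal(), 10, 100)),
                burrow_surface=float(
                    np.clip(0.2 + 0.04 * row["burrow_surface"], 0.0, 0.99) ** 2
                ),
                litter=float(max(8 + 2 * rng_p.standard_normal(), 0.0) ** 2),
                ag_biomass=float(max(20 + 3 * row["ag_biomass"], 0.5) ** 2),
                bg_biomass=float(10 ** (3.0 + 0.3 * rng_p.standard_normal())),
                cn_senescent=float(10 ** (1.7 + 0.1 * rng_p.standard_normal())),
                cn_green=float(10 ** (1.4 + 0.1 * rng_p.standard_normal())),
                cn_roots=float(10 ** (1.7 + 0.1 * rng_p.standard_normal())),
                belowground_oc_stock=float(
                    10 ** (3.3 + 0.25 * row["belowground_oc_stock"])
                ),
            )
        )
    return {
        "sites": sites,
        "cores": cores,
        "vegetation": veg,
        "burrows": burrows,
        "isotopes_mixtures": mixtures,
        "isotopes_sources": list(DEFAULT_SOURCES),
        "plots": plots,
        "ground_truth": truths,
    }


def _radionuclide_core(radio: RadionuclideProfile, site_id: str, species: str) -> CoreProfile:
    """Wrap a radionuclide profile as a cores.csv-compatible CoreProfile."""
    slices = []
    prev = 0.0
    for d, tot, sup, cs in zip(radio.depths, radio.pb210_total, radio.pb214, radio.cs137):
        bottom = 2 * d - prev
        slices.append(
            CoreSlice(
                top_depth=prev,
                bottom_depth=bottom,
                total_dry_mass=0.9 * RUSSIAN_CORER_AREA_CM2 * (bottom - prev),
                subsample_mass=2.0,
                c_pct_raw=2.0,
                c_pct_ashed=0.5,
                n_pct=0.2,
                pb210_total=tot,
                pb214=sup,
                cs137=cs,
            )
        )
        prev = bottom
    return CoreProfile(
        core_id=radio.core_id,
        site_id=site_id,
        species=species,
        zone="lower",
        corer_area=RUSSIAN_CORER_AREA_CM2,
        slices=tuple(slices),
    )
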