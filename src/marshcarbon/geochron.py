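"""Sediment geochronology: CF:CS ²¹⁰Pb and ¹³⁷Cs-impulse dating.

Under constant flux and constant sedimentation, excess (unsupported)
²¹⁰Pb decays exponentially with depth::

    A(x) = A0 * exp(-lambda * x / s)

so ln A is linear in depth with slope b = -lambda/s, and the sediment
accretion rate is s = -lambda/b (cm/yr).  The decay constant uses the
22.3 yr half-life of ²¹⁰Pb; supported ²¹⁰Pb is proxied by ²¹⁴Pb.  Where
excess ²¹⁰Pb cannot be separated from background, the ¹³⁷Cs impulse
method dates the activity peak to the southern-hemisphere fallout
maximum (default 1963).

Burial rates combine the accretion rate with the burrow-corrected mean
OC density of the paired stock core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from marshcarbon.datamodel import CoreProfile, ValidationError

PB210_HALF_LIFE_YR = 22.3
PB210_LAMBDA = math.log(2.0) / PB210_HALF_LIFE_YR  # 1/yr
DEFAULT_REFERENCE_YEAR = 1963

__all__ = [
    "RadionuclideProfile",
    "DatingResult",
    "GeochronError",
    "excess_pb210",
    "cfcs_fit",
    "cs137_sar",
    "burial_rate",
    "compaction_check",
    "date_core",
    "profile_from_core",
    "PB210_HALF_LIFE_YR",
    "PB210_LAMBDA",
]


class GeochronError(ValueError):
    """Dating not possible on this profile (the analysis records why)."""


@dataclass(frozen=True)
class RadionuclideProfile:
    """Radionuclide activities at slice midpoints for one core."""

    core_id: str
    depths: tuple[float, ...]  # cm, slice midpoints, strictly increasing
    collection_year: int
    pb210_total: tuple[float | None, ...] = ()
    pb214: tuple[float | None, ...] = ()
    cs137: tuple[float | None, ...] = ()
    cumulative_mass_depth: tuple[float, ...] = ()  # g/cm^2, optional

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", tuple(self.depths))
        for f in ("pb210_total", "pb214", "cs137", "cumulative_mass_depth"):
            object.__setattr__(self, f, tuple(getattr(self, f)))
        d = np.asarray(self.depths, dtype=float)
        if d.size == 0 or np.any(np.diff(d) <= 0):
            raise ValidationError("depths must be non-empty and strictly increasing")
        for f in ("pb210_total", "pb214", "cs137"):
            vals = getattr(self, f)
            if vals and len(vals) != len(self.depths):
                raise ValidationError(f"{f} length must match depths")
            if any(v is not None and v < 0 for v in vals):
                raise ValidationError(f"{f} activities must be >= 0")


@dataclass(frozen=True)
class DatingResult:
    """Accretion rate with method provenance and fit diagnostics."""

    core_id: str
    method: str  # "CFCS" or "Cs137"
    sar: float  # mm/yr
    slope: float | None = None  # 1/cm, CF:CS only
    r_squared: float | None = None
    n_points: int | None = None
    peak_depth: float | None = None  # mm, Cs137 only
    burial_rate: float | None = None  # g OC/m^2/yr

    def __post_init__(self) -> None:
        if self.method not in ("CFCS", "Cs137"):
            raise ValidationError(f"unknown dating method {self.method!r}")
        if self.sar <= 0:
            raise ValidationError("sar must be > 0")
        if self.r_squared is not None and not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError("r_squared must be in [0, 1]")


def excess_pb210(profile: RadionuclideProfile) -> tuple[np.ndarray, np.ndarray]:
    """Excess ²¹⁰Pb (total minus ²¹⁴Pb-supported) per slice.

    Returns ``(depths, excess)`` restricted to slices where both activities
    are present and the excess is positive; slices at or below background
    are excluded from fitting.  Raises :class:`GeochronError` when fewer
    than 3 positive-excess slices remain (excess not separable).
    """
    depths, excess = [], []
    n_pairs = 0
    for d, tot, sup in zip(profile.depths, profile.pb210_total, profile.pb214):
        if tot is None or sup is None:
            continue
        n_pairs += 1
        e = tot - sup
        if e > 0:
            depths.append(d)
            excess.append(e)
    if n_pairs < 3:
        raise GeochronError("pb210_total and pb214 required on at least 3 slices")
    if len(excess) < 3:
        raise GeochronError(
            "excess not separable: fewer than 3 slices above supported background"
        )
    return np.asarray(depths, float), np.asarray(excess, float)


def cfcs_fit(
    excess: np.ndarray,
    depths: np.ndarray,
    core_id: str = "",
    decay_constant: float = PB210_LAMBDA,
) -> DatingResult:
    """CF:CS accretion rate from ln(excess) vs depth by unweighted OLS.

    SAR = -lambda/slope, reported in mm/yr.  The slope must be negative
    (activities must decay with depth).
    """
    x = np.asarray(depths, float)
    y = np.asarray(excess, float)
    if x.size != y.size or x.size < 3:
        raise GeochronError("need at least 3 (depth, excess) pairs")
    if np.any(y <= 0):
        raise GeochronError("excess activities must be positive for log fit")
    if np.any(np.diff(x) <= 0):
        raise GeochronError("depths must be strictly increasing")
    ln_y = np.log(y)
    # hand-rolled OLS keeps the module free of fitting-library conventions
    xm, ym = x.mean(), ln_y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (ln_y - ym)))
    if sxx == 0:
        raise GeochronError("degenerate depth design")
    slope = sxy / sxx
    if slope >= 0:
        raise GeochronError("no monotone decay: fitted slope is non-negative")
    resid = ln_y - (ym + slope * (x - xm))
    sst = float(np.sum((ln_y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    sar_cm = -decay_constant / slope
    return DatingResult(
        core_id=core_id,
        method="CFCS",
        sar=sar_cm * 10.0,
        slope=slope,
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(x.size),
    )


def cs137_sar(
    profile: RadionuclideProfile,
    reference_year: int = DEFAULT_REFERENCE_YEAR,
) -> DatingResult:
    """Accretion rate from the depth of the ¹³⁷Cs fallout peak.

    The maximum-activity slice (shallowest on ties) is dated to
    ``reference_year``; a strict local maximum must exist (flat or
    monotonically increasing profiles carry no impulse).
    """
    pairs = [
        (d, a) for d, a in zip(profile.depths, profile.cs137) if a is not None
    ]
    if len(pairs) < 3:
        raise GeochronError("cs137 required on at least 3 slices")
    acts = np.array([a for _, a in pairs])
    depths = np.array([d for d, _ in pairs])
    i = int(np.argmax(acts))  # first max on ties
    peak = acts[i]
    if peak <= 0 or np.all(acts == peak):
        raise GeochronError("no 137Cs peak: flat or all-zero profile")
    left_ok = i == 0 or acts[i - 1] < peak
    right_ok = i == len(acts) - 1 or acts[i + 1] < peak
    if not (left_ok and right_ok) or i == len(acts) - 1:
        raise GeochronError("no 137Cs peak: activity does not decline past maximum")
    elapsed = profile.collection_year - reference_year
    if elapsed <= 0:
        raise GeochronError("collection year must postdate the reference fallout year")
    peak_mm = depths[i] * 10.0
    return DatingResult(
        core_id=profile.core_id,
        method="Cs137",
        sar=peak_mm / elapsed,
        peak_depth=peak_mm,
        n_points=len(pairs),
    )


def burial_rate(sar: float, mean_oc_density: float) -> float:
    """OC burial rate (g OC/m^2/yr) from SAR (mm/yr) and OC density (g/cm^3).

    sar/10 (cm/yr) x density (g/cm^3) = g/cm^2/yr; x 1e4 converts to m^2.
    """
    if sar <= 0 or mean_oc_density <= 0:
        raise ValueError("sar and mean_oc_density must be > 0")
    return sar * mean_oc_density * 1000.0


def compaction_check(
    field_length: float, recovered_length: float, limit: float = 0.10
) -> tuple[float, bool]:
    """Fractional core shortening and whether it is within the limit.

    The boundary is inclusive: exactly ``limit`` passes.
    """
    if field_length <= 0 or recovered_length <= 0:
        raise ValueError("lengths must be > 0")
    if recovered_length > field_length:
        raise ValueError("recovered length exceeds field length")
    c = 1.0 - recovered_length / field_length
    return c, c <= limit


def profile_from_core(core: CoreProfile, collection_year: int) -> RadionuclideProfile:
    """Extract the radionuclide profile of a core read from ``cores.csv``."""
    return RadionuclideProfile(
        core_id=core.core_id,
        depths=tuple(s.mid_depth for s in core.slices),
        collection_year=collection_year,
        pb210_total=tuple(s.pb210_total for s in core.slices),
        pb214=tuple(s.pb214 for s in core.slices),
        cs137=tuple(s.cs137 for s in core.slices),
    )


def date_core(
    profile: RadionuclideProfile,
    method: str = "auto",
    reference_year: int = DEFAULT_REFERENCE_YEAR,
    mean_oc_density: float | None = None,
) -> DatingResult:
    """Date one core, optionally attaching a burial rate.

    ``method='auto'`` tries CF:CS first and falls back to the ¹³⁷Cs
    impulse when excess ²¹⁰Pb is not separable from background.
    """
    if method not in ("auto", "cfcs", "cs137"):
        raise ValueError(f"unknown method {method!r}")
    res: DatingResult
    if method in ("auto", "cfcs"):
        try:
            d, e = excess_pb210(profile)
            res = cfcs_fit(e, d, core_id=profile.core_id)
        except GeochronError:
            if method == "cfcs":
                raise
            res = cs137_sar(profile, reference_year)
    else:
        res = cs137_sar(profile, reference_year)
    if mean_oc_density is not None:
        res = DatingResult(
            **{
                **{f: getattr(res, f) for f in res.__dataclass_fields__},
                "burial_rate": burial_rate(res.sar, mean_oc_density),
            }
        )
    return res
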