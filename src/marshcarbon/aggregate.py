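"""Study-level summaries: per-site tables, regional totals, pooled updates.

Also ships small transcriptions of the study's printed per-site summary
tables (``table1.csv``: compartment stocks per site x species;
``table2.csv``: site areas, tonnages, accretion and burial rates) used by
tests and demos; missing values (the site whose cores were too bioturbated
to date) stay missing and are excluded from summaries, never zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "summarize",
    "regional_totals",
    "pooled_update",
    "table_report",
    "load_table1",
    "load_table2",
]


@dataclass(frozen=True)
class SummaryStats:
    """Unweighted summary of one numeric column (sd with n-1 denominator)."""

    n: int
    mean: float
    sd: float
    se: float
    min: float
    max: float
    sum: float
    n_missing: int = 0
    sd_defined: bool = True  # False when n = 1 (sd reported as 0)


def summarize(values) -> SummaryStats:
    """Summary statistics with missing values excluded (count reported)."""
    arr = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    n_missing = len(list(values)) - len(arr)
    if not arr:
        raise ValueError("no values left after excluding missing")
    a = np.asarray(arr, float)
    n = a.size
    sd_defined = n > 1
    sd = float(a.std(ddof=1)) if sd_defined else 0.0
    return SummaryStats(
        n=n,
        mean=float(a.mean()),
        sd=sd,
        se=sd / math.sqrt(n),
        min=float(a.min()),
        max=float(a.max()),
        sum=float(a.sum()),
        n_missing=n_missing,
        sd_defined=sd_defined,
    )


def regional_totals(stock_records, site_areas: dict[str, float]) -> dict[str, float]:
    """Regional tonnage by compartment: sum over sites of per-ha stock x area.

    ``stock_records`` are :class:`marshcarbon.stocks.StockRecord`-like
    objects (one per site x species); the area of a site with several
    dominant species is assumed to be split evenly among them unless
    separate per-species areas are keyed as ``(site_id, species)``.
    """
    total = below = 0.0
    for rec in stock_records:
        key = (rec.site_id, rec.species)
        if key in site_areas:
            area = site_areas[key]
        elif rec.site_id in site_areas:
            n_sp = sum(1 for r in stock_records if r.site_id == rec.site_id)
            area = site_areas[rec.site_id] / n_sp
        else:
            raise ValueError(f"missing area for site {rec.site_id!r}")
        total += rec.stock_total * area
        below += rec.stock_belowground * area
    return {
        "total_tons": total,
        "belowground_tons": below,
        "belowground_pct": 100.0 * below / total if total else float("nan"),
    }


def pooled_update(existing_values, new_values) -> SummaryStats:
    """Pool a literature compilation with new values and re-summarize.

    Both lists must be in common units (e.g. Mg OC/ha for stocks,
    g OC/m^2/yr for burial); the pooling is a plain concatenation, not a
    meta-analytic weighting.
    """
    return summarize(list(existing_values) + list(new_values))


def _fixture(name: str) -> Path:
    return resources.files("marshcarbon.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Per site x species compartment stocks (Mg OC/ha) and field summaries."""
    return pd.read_csv(_fixture("table1.csv"))


def load_table2() -> pd.DataFrame:
    """Per-site areas (ha), OC tonnages, accretion (mm/yr) and burial rates."""
    return pd.read_csv(_fixture("table2.csv"))


def study_summaries(t1: pd.DataFrame | None = None, t2: pd.DataFrame | None = None) -> dict:
    """Headline aggregates recomputed from the per-site tables.

    Burial and accretion statistics pool the lower- and upper-marsh values
    of every dated site (two per site); tonnages sum the per-site columns.
    """
    t1 = load_table1() if t1 is None else t1
    t2 = load_table2() if t2 is None else t2
    sar = pd.concat([t2["sar_lower_mm_yr"], t2["sar_upper_mm_yr"]])
    burial = pd.concat([t2["burial_lower_g_m2_yr"], t2["burial_upper_g_m2_yr"]])
    return {
        "stock_total_mean": summarize(t1["stock_total"]),
        "stock_belowground_mean": summarize(t1["stock_belowground"]),
        "sar": summarize(sar.tolist()),
        "burial": summarize(burial.tolist()),
        "total_tons": float(t2["total_oc_stock_tons"].sum()),
        "belowground_tons": float(t2["belowground_oc_stock_tons"].sum()),
        "annual_burial_tons": float(t2["total_burial_t_yr"].sum()),
    }


def table_report(
    stocks=None,
    dating=None,
    mixing=None,
    sem=None,
    out_dir: str | Path | None = None,
) -> str:
    """Assemble a text report (and CSVs) from any subset of stage outputs.

    Ordering is deterministic (site then species) so reports are diffable.
    """
    lines: list[str] = ["marshcarbon report", "=" * 40]
    frames: dict[str, pd.DataFrame] = {}
    if stocks:
        df = pd.DataFrame(
            [
                {
                    "site_id": r.site_id,
                    "species": r.species,
                    "stock_green": r.stock_green,
                    "stock_senescent": r.stock_senescent,
                    "stock_roots": r.stock_roots,
                    "stock_sediment": r.stock_sediment,
                    "stock_belowground": r.stock_belowground,
                    "stock_total": r.stock_total,
                    "burrow_void_fraction": r.burrow_void_fraction,
                }
                for r in stocks
            ]
        ).sort_values(["site_id", "species"], kind="stable")
        frames["stocks"] = df
        s = summarize(df["stock_total"].tolist())
        lines += [
            "",
            f"OC stocks: {len(df)} site x species records",
            f"  total stock mean {s.mean:.2f} (SE {s.se:.2f}) Mg OC/ha, "
            f"range {s.min:.2f}-{s.max:.2f}",
        ]
    if dating:
        df = pd.DataFrame(
            [
                {
                    "core_id": r.core_id,
                    "method": r.method,
                    "sar_mm_yr": r.sar,
                    "r_squared": r.r_squared,
                    "burial_g_m2_yr": r.burial_rate,
                }
                for r in dating
            ]
        ).sort_values("core_id", kind="stable")
        frames["dating"] = df
        s = summarize(df["sar_mm_yr"].tolist())
        lines += [
            "",
            f"Geochronology: {len(df)} dated cores",
            f"  SAR mean {s.mean:.2f} mm/yr, range {s.min:.2f}-{s.max:.2f}",
        ]
        rates = [r.burial_rate for r in dating if r.burial_rate is not None]
        if rates:
            sb = summarize(rates)
            lines.append(
                f"  burial mean {sb.mean:.2f} g OC/m2/yr, range {sb.min:.2f}-{sb.max:.2f}"
            )
    if mixing:
        lines += ["", "Source partitioning (posterior mean %):"]
        for label, post in mixing.items():
            parts = ", ".join(
                f"{n} {100 * m:.0f}%" for n, m in zip(post.source_names, post.mean)
            )
            lines.append(f"  {label}: {parts}")
    if sem is not None:
        lines += [
            "",
            "Path analysis:",
            f"  Fisher's C = {sem.fisher_c:.3f}, df = {sem.df}, P = {sem.p_value:.3f}"
            + ("" if sem.dsep_ok else "  [FAILS d-separation]"),
        ]
        for (cause, effect), b in sorted(sem.std_coefficients.items()):
            lines.append(f"  {cause} -> {effect}: beta_std = {b:+.3f}")
        for node, (r2m, r2c) in sorted(sem.r2.items()):
            lines.append(f"  R2 {node}: marginal {r2m:.2f}, conditional {r2c:.2f}")
    text = "\n".join(lines) + "\n"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.txt").write_text(text, encoding="utf-8")
    return text
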