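"""OC stock arithmetic: LOI difference, bulk density, burrow correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marshcarbon import stocks, synthdata
from marshcarbon.datamodel import CoreProfile, CoreSlice


def _profile(slices, area=9.05):
    return CoreProfile("C", "S", "Sa", "none", area, tuple(slices))


def _slice(top, bottom, mass, c_raw, c_ash=0.0):
    return CoreSlice(top, bottom, mass, 2.0, c_raw, c_ash, 0.1)


@pytest.mark.parametrize(
    "raw,ashed,expected",
    [(5.0, 1.2, 0.038), (2.0, 2.0, 0.0), (0.0, 0.0, 0.0)],
)
def test_loi_difference(raw, ashed, expected):
    assert stocks.oc_fraction_from_loi(raw, ashed) == pytest.approx(expected)


def test_negative_loi_difference_floors_at_zero_with_warning(caplog):
    with caplog.at_level("WARNING", logger="marshcarbon"):
        assert stocks.oc_fraction_from_loi(1.0, 1.5) == 0.0
    assert "flooring" in caplog.text


@pytest.mark.parametrize("raw,ashed", [(-1, 0), (101, 0), (50, -2), (10, 101)])
def test_loi_domain_errors(raw, ashed):
    with pytest.raises(ValueError):
        stocks.oc_fraction_from_loi(raw, ashed)


@pytest.mark.parametrize(
    "mass,area,thick,expected",
    [(45.25, 9.05, 5.0, 1.0), (0.905, 9.05, 10.0, 0.01)],
)
def test_dry_bulk_density(mass, area, thick, expected):
    sl = _slice(0, thick, mass, 3.0)
    assert stocks.dry_bulk_density(sl, area) == pytest.approx(expected)


def test_bulk_density_profile_recovered_from_generator():
    core, truth = synthdata.gen_core(3, bulk_density=0.85, noise_sd=0.0)
    for sl in core.slices:
        assert stocks.dry_bulk_density(sl, core.corer_area) == pytest.approx(0.85)


class TestBurrowVoidFraction:
    def test_zero_count_gives_zero(self):
        assert stocks.burrow_void_fraction(0, ()) == 0.0
        assert stocks.burrow_void_fraction(0, (3.0,)) == 0.0

    def test_site_mean_inputs(self):
        # 13.8 burrows of 2.1 cm mean diameter in a 625 cm^2 quadrat
        f = stocks.burrow_void_fraction(13.8, (2.1,), 625)
        assert f == pytest.approx(0.0765, abs=5e-4)

    def test_voids_exceeding_quadrat_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            stocks.burrow_void_fraction(100, (30.0,), 625)

    def test_site_mean_of_counts_and_diameters(self):
        from marshcarbon.datamodel import BurrowSurvey

        surveys = [
            BurrowSurvey("S", "Sa", 4, (2.0, 2.2)),
            BurrowSurvey("S", "Sa", 6, (1.8,)),
        ]
        # mean count 5, mean diameter 2.0
        expected = 5 * math.pi * 1.0**2 / 625
        assert stocks.site_void_fraction(surveys) == pytest.approx(expected)


class TestIntegrateSedimentStock:
    def test_unit_conversion_single_slice(self):
        # oc_density 0.02 g/cm^3 over 10 cm with no voids -> 20 Mg/ha
        sl = _slice(0, 10, 0.02 / 0.04 * 9.05 * 10, 4.0)  # dbd=0.5, frac=0.04
        prof = _profile([sl])
        assert stocks.integrate_sediment_stock(prof, 0.0) == pytest.approx(20.0)
        assert stocks.integrate_sediment_stock(prof, 0.1) == pytest.approx(18.0)

    def test_matches_hand_summed_oracle(self, rng):
        slices, acc, prev = [], 0.0, 0.0
        area = 9.05
        for _ in range(8):
            thick = float(rng.uniform(3, 12))
            mass = float(rng.uniform(10, 80))
            c_raw = float(rng.uniform(0.5, 6.0))
            sl = _slice(prev, prev + thick, mass, c_raw)
            # independent arithmetic: fraction x density x thickness
            acc += (c_raw / 100.0) * (mass / (area * thick)) * thick
            slices.append(sl)
            prev += thick
        prof = _profile(slices, area)
        assert stocks.integrate_sediment_stock(prof) == pytest.approx(
            acc * 100.0, abs=1e-10
        )

    def test_no_extrapolation_beyond_cored_depth(self):
        half = _profile([_slice(0, 50, 200.0, 4.0)])
        full = _profile([_slice(0, 50, 200.0, 4.0), _slice(50, 100, 200.0, 4.0)])
        assert stocks.integrate_sediment_stock(half) == pytest.approx(
            stocks.integrate_sediment_stock(full) / 2
        )

    @given(
        f1=st.floats(0, 0.8),
        f2=st.floats(0, 0.8),
        c=st.floats(0.1, 5.0),
        d=st.floats(0.2, 1.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_void_fraction_and_closed_form(self, f1, f2, c, d):
        depth = 40.0
        prof = _profile([_slice(0, depth, d * 9.05 * depth, c)])
        lo, hi = sorted((f1, f2))
        s_lo = stocks.integrate_sediment_stock(prof, lo)
        s_hi = stocks.integrate_sediment_stock(prof, hi)
        assert s_hi <= s_lo  # stock shrinks as voids grow
        # constant-density closed form: 100 * c * d * D * (1 - f)
        assert s_lo == pytest.approx(100 * (c / 100) * d * depth * (1 - lo), rel=1e-12)

    def test_additive_over_slices(self):
        s1, s2 = _slice(0, 10, 50.0, 3.0), _slice(10, 30, 80.0, 2.0)
        whole = stocks.integrate_sediment_stock(_profile([s1, s2]))
        top = stocks.integrate_sediment_stock(_profile([s1]))
        bottom = stocks.integrate_sediment_stock(
            _profile([_slice(0, 20, 80.0, 2.0)])  # same thickness/mass as s2
        )
        assert whole == pytest.approx(top + bottom)


@pytest.mark.parametrize(
    "biomass,c_fraction,expected",
    [
        (0.0, 0.5, 0.0),
        (207.3, 0.39, 0.808),  # green tissue -> printed 0.81 Mg/ha
        (10276.2, 0.3297, 33.88),  # roots, back-solved carbon fraction
    ],
)
def test_biomass_oc_stock(biomass, c_fraction, expected):
    assert stocks.biomass_oc_stock(biomass, c_fraction) == pytest.approx(expected, abs=5e-3)


class TestAssembleStockRecord:
    def test_component_sum_matches_printed_total(self):
        rec = stocks.assemble_stock_record(
            "Bahia Samborombon", "Sd", 34.15, 3.85, 3.45, 3.64, 0.05
        )
        assert rec.stock_belowground == pytest.approx(37.79)
        # printed total is 45.10; component-rounded sum gives 45.09
        assert rec.stock_total == pytest.approx(45.09, abs=1e-9)

    def test_all_zero_components(self):
        rec = stocks.assemble_stock_record("S", "Sa", 0.0, 0.0, 0.0, 0.0, 0.0)
        assert rec.stock_total == 0.0

    def test_root_in_core_with_separate_roots_is_an_error(self):
        with pytest.raises(ValueError):
            stocks.assemble_stock_record(
                "S", "Sa", 10.0, 1.0, 1.0, 2.0, 0.0, root_stock_in_core=True
            )

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_total_is_exact_sum(self, parts):
        sed, green, sen, roots = parts
        rec = stocks.assemble_stock_record("S", "Sa", sed, green, sen, roots, 0.0)
        assert rec.stock_total == pytest.approx(sed + roots + green + sen, abs=1e-9)


@pytest.mark.parametrize("stock,area,expected", [(0.0, 0.0, 0.0), (10.0, 100.0, 1000.0)])
def test_scale_to_site_tons(stock, area, expected):
    assert stocks.scale_to_site_tons(stock, area) == expected


def test_compute_stocks_end_to_end(synthetic_study):
    recs = stocks.compute_stocks(
        [c for c in synthetic_study["cores"] if c.zone == "none"],
        synthetic_study["vegetation"],
        synthetic_study["burrows"],
    )
    assert len(recs) == 3
    for r in recs:
        assert 0 <= r.burrow_void_fraction < 1
        assert r.stock_total >= r.stock_belowground
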