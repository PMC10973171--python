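"""Beer-Lambert quantification: single measurements, serial-dilution fits,
calibration fits, and unit bookkeeping."""

import io

import numpy as np
import pytest

from mrnaquant import (
    Composition,
    DegenerateDesignError,
    DilutionSeries,
    MacResult,
    Measurement,
    SeriesSpec,
    ValidationError,
    composition,
    compute_mac,
    concentration_from_a260,
    fit_beer_lambert,
    fit_dilution_series,
    simulate_series,
    totals,
)


@pytest.fixture()
def mac_unit():
    """A construct with MAC260 = 1e6 and MW = 5e5 for clean arithmetic."""
    return MacResult(mac_260=1.0e6, mol_weight=5.0e5, composition=Composition({}))


@pytest.fixture()
def mac_acgu(registry):
    return compute_mac(composition("ACGU" * 250), registry)


class TestSingleMeasurement:
    def test_zero_absorbance_gives_zero(self, mac_unit):
        rep = concentration_from_a260(Measurement(0.0), mac_unit)
        assert rep.molar_concentration == 0.0
        assert rep.mass_concentration == 0.0

    def test_direct_beer_lambert_arithmetic(self, mac_unit):
        rep = concentration_from_a260(Measurement(0.25, dilution=20), mac_unit)
        assert rep.molar_concentration == pytest.approx(5000.0)  # nM

    def test_linearity_in_absorbance(self, mac_unit):
        r1 = concentration_from_a260(Measurement(0.3), mac_unit)
        r2 = concentration_from_a260(Measurement(0.6), mac_unit)
        assert r2.molar_concentration == pytest.approx(2 * r1.molar_concentration)
        assert r2.mass_concentration == pytest.approx(2 * r1.mass_concentration)

    def test_path_length_scaling(self, mac_unit):
        r1 = concentration_from_a260(Measurement(0.5, path_length=1.0), mac_unit)
        r2 = concentration_from_a260(Measurement(0.5, path_length=0.5), mac_unit)
        assert r2.molar_concentration == pytest.approx(2 * r1.molar_concentration)

    def test_unit_roundtrip_via_mol_weight(self, mac_acgu):
        rep = concentration_from_a260(Measurement(0.8, dilution=10), mac_acgu)
        back_nM = rep.mass_concentration / mac_acgu.mol_weight * 1e6
        assert back_nM == pytest.approx(rep.molar_concentration, rel=1e-9)

    @pytest.mark.parametrize(
        "kwargs", [{"a260": -0.1}, {"a260": 1.0, "dilution": 0.5},
                   {"a260": 1.0, "path_length": 0.0}]
    )
    def test_invalid_measurements(self, kwargs):
        with pytest.raises(ValidationError):
            Measurement(**kwargs)

    def test_zero_mac_guidance(self, mac_unit):
        empty = MacResult(mac_260=0.0, mol_weight=0.0, composition=Composition({}))
        with pytest.raises(ValidationError, match="empty sequence"):
            concentration_from_a260(Measurement(0.5), empty)


class TestDilutionSeries:
    def test_noise_free_series_recovers_stock_exactly(self, mac_acgu):
        truth = 2.0e-7  # M
        series = simulate_series(SeriesSpec(concentration=truth, cv=0.0), mac_acgu)
        rep = fit_dilution_series(series, mac_acgu)
        assert rep.molar_concentration == pytest.approx(truth * 1e9, rel=1e-9)
        assert rep.fit.r == pytest.approx(1.0, abs=1e-12)
        assert not rep.fit.intercept_warning

    def test_single_point_falls_back_to_direct_calculation(self, mac_unit):
        series = DilutionSeries(((4.0, (0.2, 0.3)),))
        rep = fit_dilution_series(series, mac_unit)
        direct = concentration_from_a260(Measurement(0.25, dilution=4.0), mac_unit)
        assert rep.molar_concentration == pytest.approx(direct.molar_concentration)
        assert rep.fit is None

    def test_duplicate_dilutions_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            DilutionSeries(((2.0, (0.1,)), (2.0, (0.2,))))

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValidationError):
            DilutionSeries(((2.0, (-0.1,)),))

    def test_intercept_beyond_tolerance_warns(self, mac_unit):
        pts = tuple((d, (0.5 / d + 0.02,)) for d in (1.0, 2.0, 4.0, 8.0))
        with pytest.warns(UserWarning, match="intercept"):
            rep = fit_dilution_series(DilutionSeries(pts), mac_unit)
        assert rep.fit.intercept_warning

    def test_pooled_equals_averaged_for_balanced_replicates(self, mac_unit):
        rng = np.random.default_rng(7)
        pts = tuple(
            (d, tuple(0.6 / d * (1 + rng.normal(0, 0.01, 3))))
            for d in (1.0, 2.0, 5.0, 10.0)
        )
        series = DilutionSeries(pts)
        avg = fit_dilution_series(series, mac_unit)
        pooled = fit_dilution_series(series, mac_unit, pooled=True)
        # balanced design: identical slope, hence identical concentration
        assert pooled.molar_concentration == pytest.approx(
            avg.molar_concentration, rel=1e-9
        )

    def test_csv_roundtrip(self, mac_unit):
        csv = "dilution,a260\n1,0.80\n1,0.82\n2,0.41\n4,0.20\n"
        series = DilutionSeries.from_csv(io.StringIO(csv))
        assert series.points[0] == (1.0, (0.80, 0.82))
        assert len(series.points) == 3

    def test_csv_missing_column(self):
        with pytest.raises(ValidationError, match="a260"):
            DilutionSeries.from_csv(io.StringIO("dilution,abs\n1,0.5\n"))

    def test_modified_construct_consistency_with_scaled_absorbance(self, registry):
        # Quantifying a modified construct with its modified MAC must agree
        # with quantifying the unmodified isosequence with the unmodified MAC
        # when the synthetic A260 is scaled by the hypochromicity ratio.
        from mrnaquant import apply_scheme, hypochromicity_ratio, parse_scheme

        seq = "ACGU" * 100
        scheme = parse_scheme("U:m1Y")
        mac_u = compute_mac(composition(seq), registry)
        mac_m = compute_mac(apply_scheme(composition(seq), scheme), registry)
        ratio = hypochromicity_ratio(seq, scheme, "none", registry)
        a_u = 0.5
        rep_u = concentration_from_a260(Measurement(a_u), mac_u)
        rep_m = concentration_from_a260(Measurement(a_u * ratio), mac_m)
        assert rep_m.molar_concentration == pytest.approx(
            rep_u.molar_concentration, rel=1e-9
        )


class TestBeerLambertCalibration:
    def test_exact_recovery_and_perfect_correlation(self):
        eps = 9000.0
        c = np.linspace(1e-5, 1e-4, 8)
        eps_hat, r = fit_beer_lambert(c, eps * c)
        assert eps_hat == pytest.approx(eps, rel=1e-12)
        assert r >= 0.9999

    def test_path_length_division(self):
        c = np.linspace(1e-5, 1e-4, 5)
        eps_hat, _ = fit_beer_lambert(c, 9000.0 * 0.2 * c, path_length=0.2)
        assert eps_hat == pytest.approx(9000.0, rel=1e-12)

    def test_noise_bias_small(self):
        # 0.5% multiplicative noise, n=8: the mean estimate over many seeds
        # stays within 0.5% of the true coefficient
        eps, c = 9000.0, np.linspace(1e-5, 1e-4, 8)
        estimates = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            a = eps * c * (1 + rng.normal(0, 0.005, c.size))
            estimates.append(fit_beer_lambert(c, a)[0])
        assert abs(np.mean(estimates) / eps - 1) < 0.005

    def test_degenerate_designs(self):
        with pytest.raises(DegenerateDesignError):
            fit_beer_lambert([1e-5], [0.09])
        with pytest.raises(DegenerateDesignError):
            fit_beer_lambert([1e-5, 1e-5], [0.09, 0.09])

    def test_mismatched_lengths(self):
        with pytest.raises(ValidationError):
            fit_beer_lambert([1e-5, 2e-5], [0.1])

    def test_linear_range_warning(self):
        c = np.linspace(1e-5, 2e-4, 5)
        with pytest.warns(UserWarning, match="linear range"):
            fit_beer_lambert(c, 9000.0 * c)


class TestTotals:
    def test_micromole_arithmetic(self, mac_unit):
        rep = concentration_from_a260(Measurement(1.0), mac_unit)  # 1000 nM
        assert rep.molar_concentration == pytest.approx(1000.0)
        rep = totals(rep, 100.0)
        assert rep.total_amount_mol == pytest.approx(1e-4)

    def test_microgram_arithmetic(self, mac_unit):
        rep = concentration_from_a260(Measurement(0.1), mac_unit)  # 50 ng/uL
        assert rep.mass_concentration == pytest.approx(50.0)
        rep = totals(rep, 100.0)
        assert rep.total_amount_mass == pytest.approx(5.0)

    def test_zero_concentration_zero_totals(self, mac_unit):
        rep = totals(concentration_from_a260(Measurement(0.0), mac_unit), 50.0)
        assert rep.total_amount_mol == 0.0
        assert rep.total_amount_mass == 0.0

    def test_nonpositive_volume(self, mac_unit):
        rep = concentration_from_a260(Measurement(0.5), mac_unit)
        with pytest.raises(ValidationError):
            totals(rep, 0.0)
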