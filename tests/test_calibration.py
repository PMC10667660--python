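"""Unit conversions, the fixed-slope NB dose-response fit, and quantification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from isgquant.calibration import (
    CalibrationError,
    CalibrationPoint,
    ConversionFactors,
    SampleFactors,
    build_spikein_series,
    detection_efficiency,
    dna_to_sample_conc,
    expected_reaction_conc,
    fit_internal_standard_curve,
    isg_reaction_conc,
    loq_threshold,
    mass_to_copies,
    nb_loglik,
    poisson_intercept,
    quantify_asvs,
    reaction_to_dna_conc,
    reads_to_reaction_conc,
)
from isgquant.simulate import SimulationConfig, simulate_library


class TestMassToCopies:
    def test_zero_mass_gives_zero(self):
        assert mass_to_copies(0.0, 615) == 0.0

    def test_standard_length_molecule(self):
        # 6.02e23 / (660e9 * 615)
        assert mass_to_copies(1.0, 615) == pytest.approx(1.483e9, rel=1e-3)

    def test_inverse_proportional_to_length(self):
        assert mass_to_copies(1.0, 1230) == pytest.approx(mass_to_copies(1.0, 615) / 2)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            mass_to_copies(1.0, 0)


class TestSpikeInSeries:
    def test_printed_gradient_total(self):
        spike = build_spikein_series([4.0e6, 4.0e5, 4.0e4, 4.0e3])
        assert spike.total_conc == pytest.approx(1.111e6, rel=1e-12)
        assert spike.per_variant_conc["ISG01"] == pytest.approx(1.0e6)

    def test_single_solution_is_unmixed(self):
        spike = build_spikein_series([5.0e4])
        assert spike.total_conc == pytest.approx(5.0e4)

    def test_equal_levels_conserve_total(self):
        spike = build_spikein_series([1000.0, 1000.0])
        assert all(v == pytest.approx(500.0) for v in spike.per_variant_conc.values())
        assert spike.total_conc == pytest.approx(1000.0)

    def test_from_stock_and_dilution_factors(self):
        spike = build_spikein_series(stock_conc=4.0e8,
                                     dilution_factors=[100, 1000, 10000, 100000])
        assert spike.total_conc == pytest.approx(1.111e6)

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            build_spikein_series([])


class TestConversionChain:
    def test_unit_ratios_are_identity(self):
        f = ConversionFactors(D=1, E=1, F=1, G=1, H=1, I=1)
        assert expected_reaction_conc(123.0, f) == pytest.approx(123.0)

    def test_worked_example(self):
        f = ConversionFactors(D=1, E=10, F=3, G=4, H=2.5, I=50)
        assert expected_reaction_conc(1e6, f) == pytest.approx(3750.0)
        assert reaction_to_dna_conc(3750.0, f) == pytest.approx(1e6)

    def test_round_trip_identity(self):
        f = ConversionFactors(D=2, E=7, F=1.5, G=6, H=3, I=25)
        y = 8.4e5
        z = expected_reaction_conc(y, f)
        assert reaction_to_dna_conc(z, f) == pytest.approx(y, rel=1e-12)
        z2 = expected_reaction_conc(y, f, include_sample_mix=False)
        assert reaction_to_dna_conc(z2, f, include_sample_mix=False) == pytest.approx(
            y, rel=1e-12
        )

    def test_sample_and_isg_fractions_are_complementary(self):
        f = ConversionFactors()
        assert f.sample_fraction + f.isg_fraction == pytest.approx(1.0)
        assert isg_reaction_conc(1.111e6, f) == pytest.approx(
            1.111e6 * 0.25 * 2.5 / 50
        )

    def test_sample_conversion(self):
        s = SampleFactors(c_extraction_vol=100.0, a_sample_amount=0.2, unit="g")
        assert dna_to_sample_conc(1e6, s) == pytest.approx(5e8)
        half = SampleFactors(c_extraction_vol=100.0, a_sample_amount=0.1, unit="g")
        assert dna_to_sample_conc(1e6, half) == pytest.approx(1e9)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            ConversionFactors(F=5, G=4)
        with pytest.raises(ValueError):
            SampleFactors(c_extraction_vol=0, a_sample_amount=1)


class TestDetectionEfficiency:
    def test_reads_per_copy(self):
        assert detection_efficiency(90, 10) == pytest.approx(9.0)
        assert detection_efficiency(0, 10) == 0.0
        with pytest.raises(ValueError):
            detection_efficiency(10, 0)

    def test_curve_de_equals_exp_intercept(self):
        x = np.log([40.0, 400.0, 4000.0])
        pts = [CalibrationPoint(xi, int(round(math.exp(xi + 1.7)))) for xi in x]
        curve = fit_internal_standard_curve(pts, compute_wald=False)
        for xi, p in zip(x, pts):
            de = detection_efficiency(p.reads, math.exp(xi))
            assert de == pytest.approx(curve.detection_efficiency, rel=0.01)


class TestFixedSlopeFit:
    def test_noiseless_exact_model_input(self):
        x = np.log([40, 400, 4000, 40000])
        pts = [CalibrationPoint(xi, int(round(math.exp(xi + 2.0)))) for xi in x]
        curve = fit_internal_standard_curve(pts)
        assert abs(curve.intercept_b - 2.0) < 0.02
        assert curve.converged
        assert curve.wald_p_free_slope < 0.05

    def test_poisson_limit_recovers_closed_form(self):
        rng = np.random.default_rng(42)
        x = np.log([40, 400, 4000, 40000]).repeat(2)
        y = rng.poisson(np.exp(x + 1.2))
        pts = [CalibrationPoint(xi, int(yi)) for xi, yi in zip(x, y)]
        curve = fit_internal_standard_curve(pts, compute_wald=False)
        assert curve.intercept_b == pytest.approx(
            poisson_intercept(x, y.astype(float)), abs=1e-6
        )

    def test_attains_grid_search_maximum(self):
        """The profile-ML fit reaches the dense-grid likelihood maximum."""
        for trial in range(8):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(3, 9))
            x = rng.uniform(0, 9, size=n)
            th = float(rng.uniform(0.5, 20))
            mu = np.exp(x + rng.uniform(-1, 3))
            y = rng.poisson(rng.gamma(th, mu / th))
            if not (y > 0).any() or np.unique(x).size < 2:
                continue
            pts = [CalibrationPoint(xi, int(yi)) for xi, yi in zip(x, y)]
            curve = fit_internal_standard_curve(pts, compute_wald=False)
            bs = np.linspace(curve.intercept_b - 1, curve.intercept_b + 1, 161)
            ts = np.exp(np.linspace(-3, 12, 241))
            grid_max = _grid_loglik_max(bs, ts, x, y)
            assert curve.loglik >= grid_max - 1e-6

    def test_all_zero_reads_rejected(self):
        pts = [CalibrationPoint(1.0, 0), CalibrationPoint(2.0, 0)]
        with pytest.raises(CalibrationError):
            fit_internal_standard_curve(pts)

    def test_single_dose_rejected(self):
        pts = [CalibrationPoint(1.0, 10), CalibrationPoint(1.0, 12)]
        with pytest.raises(CalibrationError):
            fit_internal_standard_curve(pts)


def _grid_loglik_max(bs, thetas, x, y):
    """Independent dense-grid evaluation of the written NB log-likelihood."""
    B, T = np.meshgrid(bs, thetas, indexing="ij")
    ll = np.zeros_like(B)
    for xi, yi in zip(x, y):
        mu = np.exp(xi + B)
        ll += (
            gammaln(yi + T) - gammaln(T) - gammaln(yi + 1)
            + T * np.log(T / (T + mu)) + yi * np.log(mu / (T + mu))
        )
    return float(ll.max())


class TestReadsToConc:
    def test_definition_and_zero(self):
        curve = _fake_curve(b=math.log(10.0))
        assert reads_to_reaction_conc(math.exp(curve.intercept_b), curve) == pytest.approx(1.0)
        assert reads_to_reaction_conc(0, curve) == 0.0
        assert reads_to_reaction_conc(250, curve) == pytest.approx(25.0)

    def test_strictly_increasing(self):
        curve = _fake_curve(b=1.3)
        zs = [reads_to_reaction_conc(r, curve) for r in range(0, 100, 7)]
        assert all(b > a for a, b in zip(zs, zs[1:]))


def _fake_curve(b):
    from isgquant.calibration import CalibrationCurve

    return CalibrationCurve(
        intercept_b=b, dispersion=5.0, intercept_se=0.1,
        wald_p_free_slope=0.01, n_points=4, converged=True,
    )


class TestLoq:
    def test_lowest_detected_level_sets_threshold(self):
        assert loq_threshold({1e3: 0, 1e4: 35, 1e5: 300, 1e6: 2900}) == 35

    def test_all_levels_detected(self):
        assert loq_threshold({1e3: 4, 1e4: 35, 1e5: 300}) == 4

    def test_variant_reads_averaged_per_level(self):
        assert loq_threshold({1e3: [0, 0], 1e4: [30, 40]}) == 35

    def test_nothing_detected_is_an_error(self):
        with pytest.raises(CalibrationError):
            loq_threshold({1e3: 0, 1e4: 0})


class TestQuantifyAsvs:
    def test_recovers_simulated_concentrations(self):
        cfg = SimulationConfig(seed=11)
        lib = simulate_library(cfg)
        quant, curve = quantify_asvs(lib.asv_table, cfg.spike, cfg.factors,
                                     compute_wald=False)
        bio = quant[quant.label == "biological"]
        total = bio["conc_dna"].sum()
        truth = lib.truth["conc_dna"].sum()
        assert total == pytest.approx(truth, rel=0.5)
        assert curve.detection_efficiency == pytest.approx(8.0, rel=0.5)
        assert bio["above_loq"].all()

    def test_isg_only_table_gives_valid_curve(self):
        cfg = SimulationConfig(seed=12, taxa=())
        lib = simulate_library(cfg)
        quant, curve = quantify_asvs(lib.asv_table, cfg.spike, cfg.factors,
                                     compute_wald=False)
        assert (quant.label == "ISG").all()
        assert curve.converged

    def test_invariant_under_row_reordering(self):
        cfg = SimulationConfig(seed=13)
        lib = simulate_library(cfg)
        quant1, _ = quantify_asvs(lib.asv_table, cfg.spike, cfg.factors,
                                  compute_wald=False)
        shuffled = lib.asv_table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        quant2, _ = quantify_asvs(shuffled, cfg.spike, cfg.factors, compute_wald=False)
        a = quant1.set_index("asv_id")["conc_dna"].sort_index()
        b = quant2.set_index("asv_id")["conc_dna"].sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_below_loq_rows_flagged_not_censored(self):
        cfg = SimulationConfig(seed=14)
        lib = simulate_library(cfg)
        table = lib.asv_table.copy()
        table.loc[len(table)] = {
            "asv_id": "rare", "sequence": "", "reads": 1, "label": "biological",
            "variant_id": "", "spike_conc": np.nan, "expected_reads": 1.0,
        }
        quant, _ = quantify_asvs(table, cfg.spike, cfg.factors, compute_wald=False)
        rare = quant[quant.asv_id == "rare"].iloc[0]
        assert not rare["above_loq"]
        assert rare["conc_dna"] > 0

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="label"):
            quantify_asvs(
                pd.DataFrame({"asv_id": ["a"], "reads": [1]}),
                build_spikein_series([1e4]),
                ConversionFactors(),
            )
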