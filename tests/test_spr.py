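import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pntkit import datasets
from pntkit.spr import (
    STANDARD_CONCENTRATIONS_M,
    WEAK_BINDER_CONCENTRATIONS_M,
    Kinetic1to1,
    classify_scan,
    ddg,
    fit_global,
    kd_from_rates,
    simulate_sensorgram,
)

T_GRID = np.arange(0.0, 600.5, 1.0)
T_ASSOC = 240.0


class TestSimulate:
    def test_association_plateau_is_langmuir_equilibrium(self):
        m = Kinetic1to1(kon=1e6, koff=1e-3, Rmax=80.0)
        C = 5e-9
        g = simulate_sensorgram(m, C, np.arange(0.0, 20000.0, 10.0), 19990.0)
        expected = m.Rmax * C / (C + m.KD)
        assert g.response_RU[-2] == pytest.approx(expected, rel=1e-3)

    def test_saturation_approaches_rmax(self):
        m = Kinetic1to1(kon=1e6, koff=1e-3, Rmax=80.0)
        g = simulate_sensorgram(m, 1e-4, np.arange(0.0, 2000.0, 1.0), 1999.0)
        assert g.response_RU.max() == pytest.approx(80.0, rel=1e-3)

    def test_observed_association_rate(self):
        # kon*C + koff = 2e5*20e-9 + 1.5e-3 = 5.5e-3 /s
        m = Kinetic1to1(kon=2.0e5, koff=1.5e-3, Rmax=100.0)
        C = 20e-9
        k_obs = m.kon * C + m.koff
        assert k_obs == pytest.approx(5.5e-3)
        g = simulate_sensorgram(m, C, T_GRID, 500.0)
        R_eq = m.Rmax * C / (C + m.KD)
        t_e = 1.0 / k_obs
        idx = np.argmin(np.abs(T_GRID - t_e))
        assert g.response_RU[idx] == pytest.approx(R_eq * (1 - math.exp(-1.0)), rel=1e-3)

    def test_dissociation_is_single_exponential_in_koff(self):
        m = Kinetic1to1(kon=2.0e5, koff=1.5e-3, Rmax=100.0)
        g = simulate_sensorgram(m, 60e-9, T_GRID, T_ASSOC)
        i0 = int(T_ASSOC) + 1
        ratio = g.response_RU[i0 + 100] / g.response_RU[i0]
        assert ratio == pytest.approx(math.exp(-m.koff * 100.0), rel=1e-6)

    def test_seeded_noise_reproducible(self):
        m = Kinetic1to1(kon=2.0e5, koff=1.5e-3, Rmax=100.0)
        a = simulate_sensorgram(m, 20e-9, T_GRID, T_ASSOC, 1.0, seed=4)
        b = simulate_sensorgram(m, 20e-9, T_GRID, T_ASSOC, 1.0, seed=4)
        np.testing.assert_array_equal(a.response_RU, b.response_RU)


class TestGlobalFit:
    def test_noiseless_recovery_to_machine_precision(self):
        true = Kinetic1to1(kon=2.0e5, koff=1.5e-3, Rmax=100.0)
        grams = [simulate_sensorgram(true, C, T_GRID, T_ASSOC) for C in STANDARD_CONCENTRATIONS_M]
        fit = fit_global(grams)
        assert fit.kon == pytest.approx(true.kon, rel=1e-4)
        assert fit.koff == pytest.approx(true.koff, rel=1e-4)
        assert fit.KD == fit.koff / fit.kon  # identity, not an independent fit

    def test_noisy_recovery_within_5_percent(self):
        true = Kinetic1to1(kon=2.0e5, koff=1.5e-3, Rmax=100.0)
        rng = np.random.default_rng(11)
        grams = [simulate_sensorgram(true, C, T_GRID, T_ASSOC, 1.0, rng)
                 for C in STANDARD_CONCENTRATIONS_M]
        fit = fit_global(grams)
        assert fit.KD == pytest.approx(true.KD, rel=0.05)
        assert fit.kon == pytest.approx(true.kon, rel=0.05)

    def test_weak_binder_at_micromolar_series(self):
        true = Kinetic1to1(kon=2.0e3, koff=2.0e-3, Rmax=100.0)  # KD = 1 uM
        rng = np.random.default_rng(8)
        grams = [simulate_sensorgram(true, C, T_GRID, T_ASSOC, 1.0, rng)
                 for C in WEAK_BINDER_CONCENTRATIONS_M]
        fit = fit_global(grams)
        assert fit.KD == pytest.approx(1e-6, rel=0.10)

    def test_kd_outside_concentration_range_warns(self):
        true = Kinetic1to1(kon=1e3, koff=1e-2, Rmax=100.0)  # KD = 10 uM
        grams = [simulate_sensorgram(true, C, T_GRID, T_ASSOC)
                 for C in STANDARD_CONCENTRATIONS_M]
        with pytest.warns(UserWarning, match="outside"):
            fit = fit_global(grams)
        assert fit.warnings

    def test_too_few_concentrations_rejected(self):
        true = Kinetic1to1(kon=2e5, koff=1.5e-3, Rmax=100.0)
        grams = [simulate_sensorgram(true, C, T_GRID, T_ASSOC) for C in (20e-9, 40e-9)]
        with pytest.raises(ValueError, match="at least 3"):
            fit_global(grams)


class TestDerivedQuantities:
    def test_wildtype_kd_is_7p5_nM(self):
        kd, _ = kd_from_rates(2.0e5, 1.5e-3)
        assert kd * 1e9 == pytest.approx(7.5, rel=1e-12)

    def test_second_reference_kd_documents_rounding(self):
        # printed value is 5.1 nM (from unrounded fit constants); division of
        # the rounded printed rates gives 5.23 nM
        kd, _ = kd_from_rates(4.4e5, 2.3e-3)
        assert kd * 1e9 == pytest.approx(5.227, abs=0.005)

    def test_zero_sigma_propagates_to_zero(self):
        _, se = kd_from_rates(2.0e5, 1.5e-3, 0.0, 0.0)
        assert se == 0.0

    def test_error_propagation_quadrature(self):
        kd, se = kd_from_rates(2.0e5, 1.5e-3, 0.03e5, 0.01e-3)
        expected = kd * math.hypot(0.03 / 2.0, 0.01 / 1.5)
        assert se == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "kd_mut, kd_ref, expected",
        [
            (930.0, 7.5, 12.0),   # strong hot spot
            (5.0, 7.5, -1.0),     # slightly tighter binder
            (2340.0, 5.1, 15.2),  # the most detrimental substitution
        ],
    )
    def test_ddg_reproduces_printed_values(self, kd_mut, kd_ref, expected):
        value, _ = ddg(kd_mut, kd_ref)
        assert value == pytest.approx(expected, abs=0.15)

    def test_identical_kd_gives_zero(self):
        assert ddg(7.5, 7.5)[0] == 0.0

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(1e-2, 1e4), b=st.floats(1e-2, 1e4))
    def test_ddg_antisymmetry(self, a, b):
        assert ddg(a, b)[0] == pytest.approx(-ddg(b, a)[0], abs=1e-9)


class TestScanClassification:
    def test_published_eh_surface_yields_6_hotspots(self):
        annotated = classify_scan(datasets.EH_SCAN)
        assert int(annotated["hotspot"].sum()) == 6
        hot = set(annotated.loc[annotated["hotspot"], "mutation"])
        assert hot == {"F77A", "L79A", "K99A", "D111A", "V112A", "Y114A"}

    def test_published_ml_surface_yields_7_hotspots(self):
        annotated = classify_scan(datasets.ML_SCAN)
        assert int(annotated["hotspot"].sum()) == 7
        hot = set(annotated.loc[annotated["hotspot"], "mutation"])
        assert hot == {"M89A", "N90A", "K92A", "L96A", "L97A", "D101A", "R105A"}

    def test_reference_only_table_has_no_hotspots(self):
        table = datasets.EH_SCAN.head(1).reset_index(drop=True)
        annotated = classify_scan(table)
        assert int(annotated["hotspot"].sum()) == 0

    def test_missing_reference_raises(self):
        table = datasets.EH_SCAN[datasets.EH_SCAN["mutation"] != "None"]
        with pytest.raises(ValueError, match="reference"):
            classify_scan(table)

    @pytest.mark.parametrize(
        "mutation, expected",
        [("E100A", "~1x"), ("I48A", "~1x"), ("R80A", "~10x"), ("Y114A", "~10x"),
         ("K99A", "~100x"), ("V112A", "~100x")],
    )
    def test_fold_categories_by_nearest_decade(self, mutation, expected):
        annotated = classify_scan(datasets.EH_SCAN).set_index("mutation")
        assert annotated.loc[mutation, "fold_category"] == expected

    def test_most_detrimental_is_thousandfold(self):
        annotated = classify_scan(datasets.ML_SCAN).set_index("mutation")
        assert annotated.loc["R105A", "fold_category"] == "~1000x"

    def test_recomputed_ddg_matches_every_printed_value(self):
        for table in (datasets.EH_SCAN, datasets.ML_SCAN):
            annotated = classify_scan(table)
            printed = annotated.dropna(subset=["ddG_kJmol"])
            diff = (printed["ddG_calc_kJmol"] - printed["ddG_kJmol"]).abs()
            assert diff.max() < 0.15
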