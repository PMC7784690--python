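import numpy as np
import pandas as pd
import pytest

from gpptkin import (
    FirstOrder,
    GpptKinetics,
    KineticPoint,
    MichaelisMenten,
    MoundRecord,
    SegmentRate,
    SimConfig,
    build_points,
    cell_specific_rate,
    estimate_activity,
    fit_kinetics,
    mixing_ratio_to_umol_per_l,
    pooled_fit,
    segment_rates,
    simulate_gppt,
)
from conftest import KM_TRUE, VMAX_TRUE, exact_mm_segments


class TestBuildPoints:
    def test_unit_conversion_of_injectate(self):
        # 900 µl/l at 298.15 K, 1 atm -> ~36.8 µmol/l (rounded to ~40 µM)
        c = mixing_ratio_to_umol_per_l(900.0, 298.15)
        assert c == pytest.approx(36.79, abs=0.05)

    def test_normalisation_endpoints(self, noiseless_inert_dataset):
        ds = noiseless_inert_dataset
        cfg = ds.config_echo
        pts = build_points(ds)
        # first extraction sample is nearly undiluted injectate, last is
        # nearly background: the relative concentrations span (0, 1)
        assert 0.85 < pts[0].c_rel_ar <= 1.0
        assert pts[-1].c_rel_ar < 0.05
        for p in pts:
            assert p.c_rel_ch4 == pytest.approx(p.c_rel_ar, rel=1e-10)

    def test_matched_ch4_equals_simulated_value(self, noiseless_fo_dataset):
        """The window aggregate must return the simulator's exact reading."""
        ds = noiseless_fo_dataset
        ch4 = ds.ch4_series.set_index("time_s")["ch4_ppmv"]
        pts = build_points(ds, match_window=5.0)
        for p in pts:
            t_s = p.t_e + ds.config_echo.t_inj
            expected = mixing_ratio_to_umol_per_l(ch4.loc[t_s], ds.config_echo.temperature)
            assert p.c_ch4 == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_relative_concentration_flagged(self, noiseless_fo_dataset):
        ds = noiseless_fo_dataset
        ar = ds.ar_samples.copy()
        # depress one extraction sample below background
        i = ar.index[ar["phase"] == "extraction"][5]
        ar.loc[i, "ar_fraction"] = ds.config_echo.ar_bg * 0.5
        ds2 = type(ds)(
            ch4_series=ds.ch4_series, ar_samples=ar, background=ds.background,
            config_echo=ds.config_echo, mound_id="flagged",
        )
        pts = build_points(ds2)
        assert sum(not p.usable for p in pts) == 1
        with pytest.raises(ValueError):
            [p for p in pts if not p.usable][0].log_ratio()

    def test_missing_window_rejected(self, noiseless_fo_dataset):
        ds = noiseless_fo_dataset
        t0 = float(ds.extraction_ar()["time_s"].iloc[0])
        gap = ds.ch4_series[(ds.ch4_series["time_s"] - t0).abs() > 5.0]
        ds2 = type(ds)(ch4_series=gap.reset_index(drop=True), ar_samples=ds.ar_samples,
                       background=ds.background, config_echo=ds.config_echo, mound_id="gap")
        with pytest.raises(ValueError, match="no CH4 readings"):
            build_points(ds2, match_window=5.0)


class TestEstimateActivity:
    def test_inert_dataset_gives_zero(self, noiseless_inert_dataset):
        fit = estimate_activity(build_points(noiseless_inert_dataset))
        assert abs(fit.k) < 1e-10

    def test_negative_k_flagged_not_truncated(self):
        # a rising tracer-normalised CH4 trend implies apparent production
        pts = [
            KineticPoint(t_e=float(te), t_star=te / 1800.0, c_rel_ar=0.5,
                         c_rel_ch4=0.5 * np.exp(0.3 * te / 1800.0), c_ch4=10.0)
            for te in (100, 400, 800, 1200)
        ]
        fit = estimate_activity(pts)
        assert fit.k == pytest.approx(-0.3, rel=1e-9)
        assert fit.no_detectable_oxidation

    def test_noiseless_first_order_recovery(self, noiseless_fo_dataset):
        fit = estimate_activity(build_points(noiseless_fo_dataset))
        assert fit.k == pytest.approx(2.0, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_within_ten_percent(self):
        cfg = SimConfig(kinetics=FirstOrder(k=1.0), noise_ch4=0.02, noise_ar=0.02,
                        n_ar_ext=12, seed=7)
        fit = estimate_activity(build_points(simulate_gppt(cfg)))
        assert fit.k == pytest.approx(1.0, rel=0.10)

    def test_too_few_points_rejected(self):
        pts = [KineticPoint(t_e=1, t_star=1, c_rel_ar=0.5, c_rel_ch4=0.5, c_ch4=1.0)] * 2
        with pytest.raises(ValueError):
            estimate_activity(pts)


class TestSegmentRates:
    def test_three_points_one_segment(self, noiseless_fo_dataset):
        pts = build_points(noiseless_fo_dataset)[:3]
        segs = segment_rates(pts)
        assert len(segs) == 1

    def test_sliding_windows_count(self, noiseless_fo_dataset):
        pts = build_points(noiseless_fo_dataset)
        segs = segment_rates(pts)
        assert len(segs) == len(pts) - 2

    def test_rate_identity_exact(self, noiseless_mm_dataset):
        for s in segment_rates(build_points(noiseless_mm_dataset)):
            assert s.r_ox == s.k_local * s.c_bar  # exact product, not approx

    def test_first_order_segments_collinear_through_origin(self, noiseless_fo_dataset):
        segs = segment_rates(build_points(noiseless_fo_dataset))
        for s in segs:
            assert s.k_local == pytest.approx(2.0, rel=1e-6)
            assert s.r_ox == pytest.approx(2.0 * s.c_bar, rel=1e-6)

    def test_mm_segments_lie_on_curve(self, noiseless_mm_dataset):
        """Noise-free MM segments fall on the true curve within the
        window-discretisation tolerance (<=5% relative)."""
        segs = segment_rates(build_points(noiseless_mm_dataset))
        for s in segs:
            expected = VMAX_TRUE * s.c_bar / (KM_TRUE + s.c_bar)
            assert s.r_ox == pytest.approx(expected, rel=0.05)

    def test_window_skips_flagged_points(self, noiseless_fo_dataset):
        pts = build_points(noiseless_fo_dataset)
        pts[4].usable = False
        segs = segment_rates(pts)
        assert len(segs) == len(pts) - 2 - 3  # three windows touch point 4


class TestFitKinetics:
    def test_exact_mm_points_recovered(self):
        fit = fit_kinetics(exact_mm_segments())
        assert fit.selected_model == "michaelis_menten"
        assert fit.km == pytest.approx(KM_TRUE, rel=1e-6)
        assert fit.vmax == pytest.approx(VMAX_TRUE, rel=1e-6)

    def test_half_saturation_identity(self):
        fit = fit_kinetics(exact_mm_segments())
        assert fit.predict(fit.km) == pytest.approx(fit.vmax / 2.0, rel=1e-9)

    def test_grid_search_oracle_agreement(self):
        """NLS must agree with an exhaustive grid search to <0.5%."""
        segs = exact_mm_segments()
        c = np.array([s.c_bar for s in segs])
        r = np.array([s.r_ox for s in segs])
        km_grid = np.linspace(1.0, 60.0, 1200)
        vmax_grid = np.linspace(10.0, 150.0, 1400)
        rss = (
            (vmax_grid[None, :, None] * c[None, None, :]
             / (km_grid[:, None, None] + c[None, None, :]) - r) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        fit = fit_kinetics(segs)
        assert fit.km == pytest.approx(km_grid[i], rel=0.005)
        assert fit.vmax == pytest.approx(vmax_grid[j], rel=0.005)

    def test_linear_selected_for_proportional_data(self):
        segs = [SegmentRate(c_bar=c, k_local=2.0, r_ox=2.0 * c) for c in (2, 8, 15, 25, 36)]
        fit = fit_kinetics(segs)
        assert fit.selected_model == "linear"
        assert fit.km is None and fit.vmax is None
        assert fit.lin_slope == pytest.approx(2.0, rel=1e-9)

    def test_mm_withheld_when_linear_wins(self):
        rng = np.random.default_rng(3)
        segs = [
            SegmentRate(c_bar=c, k_local=1.0, r_ox=1.0 * c * float(np.exp(rng.normal(0, 0.05))))
            for c in np.linspace(1, 35, 10)
        ]
        fit = fit_kinetics(segs)
        if fit.selected_model == "linear":
            assert fit.km is None
        else:
            assert fit.aic_mm < fit.aic_lin

    def test_selection_invariant(self):
        fit = fit_kinetics(exact_mm_segments())
        assert fit.aic_mm < fit.aic_lin

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_kinetics(exact_mm_segments()[:2])
        same_c = [SegmentRate(c_bar=5.0, k_local=1.0, r_ox=5.0)] * 4
        with pytest.raises(ValueError):
            fit_kinetics(same_c)


class TestPooledFit:
    def test_single_mound_identity(self, mm_results):
        pooled = pooled_fit([mm_results.kinetics])
        assert pooled.km == pytest.approx(mm_results.kinetics.km, rel=1e-9)
        assert pooled.vmax == pytest.approx(mm_results.kinetics.vmax, rel=1e-9)

    def test_duplicated_replicates_identity(self, mm_results):
        pooled = pooled_fit([mm_results.kinetics] * 3)
        assert pooled.km == pytest.approx(mm_results.kinetics.km, rel=1e-6)

    def test_pooled_km_within_per_mound_range(self):
        from gpptkin import simulate_mound_population

        datasets = simulate_mound_population(5, seed=21, km_range=(5.0, 30.0))
        fits = [GpptKinetics(ds).fit().kinetics for ds in datasets]
        mm_fits = [f for f in fits if f.selected_model == "michaelis_menten"]
        assert len(mm_fits) >= 2
        pooled = pooled_fit(fits)
        kms = [f.km for f in mm_fits]
        assert min(kms) <= pooled.km <= max(kms)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pooled_fit([])


class TestCellSpecificRate:
    def test_unit_arithmetic(self):
        # 1 µmol/h over 1e6 cells = 1e-12 mol/cell/h
        v = cell_specific_rate(1.0, dry_mass=1.0, copies_per_g=2e6, copies_per_cell=2.0)
        assert v == pytest.approx(1e-12, rel=1e-12)

    def test_hand_example(self):
        v = cell_specific_rate(10.0, dry_mass=1e4, copies_per_g=2e6, copies_per_cell=2.0)
        assert v == pytest.approx(1e-15, rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            cell_specific_rate(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            cell_specific_rate(1.0, 1.0, -5.0)


class TestModelLayer:
    def test_results_structure(self, mm_results):
        d = mm_results.to_dict()
        assert d["kinetics"]["selected_model"] == "michaelis_menten"
        assert d["activity"]["n"] == 12
        assert len(d["segments"]) == 10

    def test_summary_text(self, mm_results):
        s = mm_results.summary()
        assert "michaelis_menten" in s
        assert "Km" in s and "Vmax" in s

    def test_plot_returns_axes(self, mm_results):
        import matplotlib

        matplotlib.use("Agg")
        ax = mm_results.plot()
        assert ax.get_xlabel().startswith("CH4")


class TestMoundRecord:
    def test_validation(self):
        rec = MoundRecord("m1", "Mn", "core", dry_mass=2e4, micro_porosity=0.3,
                          macro_porosity=0.1, water_content=0.08, volume=50.0)
        assert rec.species == "Mn"
        with pytest.raises(ValueError):
            MoundRecord("m2", "Xx", "core", 1.0, 0.1, 0.1, 0.1, 1.0)
        with pytest.raises(ValueError):
            MoundRecord("m3", "Mn", "core", 1.0, 1.4, 0.1, 0.1, 1.0)
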