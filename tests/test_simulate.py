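"""Synthetic-data generator: design schedule, attribute distributions,
spectra rendering and the nonlinear-link structure."""

import numpy as np
import pandas as pd
import pytest

from nirpowder.core import default_wavenumber_grid
from nirpowder.errors import ParameterError
from nirpowder.pls import fit_pls, predict_pls
from nirpowder.simulate import (
    BandModel,
    SimConfig,
    default_band_model,
    generate_ccd_design,
    generate_dataset,
    render_spectra,
    sample_attributes,
)

#: Printed three-factor extraction schedule (run order ignored): ethanol
#: concentration %, ethanol volume L, decoction time h.
EXTRACTION_SCHEDULE = [
    (90, 5, 1.75), (90, 5, 3.00), (80, 4, 0.50), (80, 4, 3.00), (90, 4, 1.75),
    (90, 6, 1.75), (100, 6, 0.50), (80, 6, 3.00), (100, 5, 1.75), (90, 5, 1.75),
    (100, 4, 0.50), (90, 5, 1.75), (80, 5, 1.75), (100, 4, 3.00), (100, 6, 3.00),
    (80, 6, 0.50), (90, 5, 1.75), (90, 5, 0.50), (90, 5, 1.75), (90, 5, 1.75),
]


def zero_spread_config(**overrides):
    cfg = SimConfig(**overrides)
    for g in cfg.group_params.values():
        for key in ("cryptotanshinone", "tanshinone_iia", "moisture", "d50"):
            g[key] = (g[key][0], 0.0)
        g["dt_noise_sd"] = 0.0
        g["ssa_noise_sd"] = 0.0
    cfg.sigma_jitter_lo = 0.0
    cfg.sigma_jitter_hi = 0.0
    return cfg


class TestCcdDesign:
    def test_reproduces_printed_schedule(self):
        df = generate_ccd_design(alpha=1.0, n_center_rows=6)
        assert len(df) == 20
        got = sorted((round(a, 2), round(b, 2), round(c, 2)) for a, b, c in
                     zip(df["ethanol_concentration"], df["ethanol_volume"],
                         df["decoction_time"]))
        assert got == sorted(EXTRACTION_SCHEDULE)

    def test_no_center_rows_gives_14_distinct(self):
        df = generate_ccd_design(n_center_rows=0)
        assert len(df) == 14
        assert len(df.drop_duplicates(["ethanol_concentration", "ethanol_volume",
                                       "decoction_time"])) == 14

    def test_face_centered_axial_points(self):
        df = generate_ccd_design(alpha=1.0, n_center_rows=0)
        axial = df.iloc[8:]
        rows = set(zip(axial["ethanol_concentration"], axial["ethanol_volume"],
                       axial["decoction_time"]))
        assert (90.0, 4.0, 1.75) in rows and (90.0, 6.0, 1.75) in rows
        assert (80.0, 5.0, 1.75) in rows and (100.0, 5.0, 1.75) in rows

    def test_alpha_must_be_positive(self):
        with pytest.raises(ParameterError):
            generate_ccd_design(alpha=0.0)

    def test_deterministic_ordering(self):
        a = generate_ccd_design()
        b = generate_ccd_design()
        pd.testing.assert_frame_equal(a, b)


class TestSampleAttributes:
    def test_group_means_match_study_statistics_at_large_n(self):
        targets = {
            "homemade": dict(cryptotanshinone=21, tanshinone_iia=25,
                             specific_surface_area=0.240, d10=12.05, d50=52.52,
                             d90=126.1, tapped_density=0.72, moisture=3.01),
            "commercial": dict(cryptotanshinone=18, tanshinone_iia=12,
                               specific_surface_area=0.317, d10=6.917, d50=27.49,
                               d90=101.0, tapped_density=0.73, moisture=3.21),
        }
        cfg = SimConfig(n_homemade=3000, n_commercial=3000)
        tab = sample_attributes(cfg, seed=7).table
        for group, tg in targets.items():
            sub = tab[tab.group == group]
            for attr, mean in tg.items():
                assert abs(sub[attr].mean() - mean) <= 0.3 * mean, (group, attr)

    def test_commercial_moisture_mean_window(self):
        cfg = SimConfig(n_homemade=0, n_commercial=3000)
        tab = sample_attributes(cfg, seed=5).table
        assert 2.7 <= tab["moisture"].mean() <= 3.7

    def test_zero_spread_collapses_groups_to_points(self):
        tab = sample_attributes(zero_spread_config(), seed=1).table
        for _, sub in tab.groupby("group"):
            vals = sub.drop(columns=["sample_id", "group"])
            assert (vals.nunique() == 1).all()

    def test_quantile_ordering_holds_in_bulk(self):
        cfg = SimConfig(n_homemade=5000, n_commercial=5000)
        tab = sample_attributes(cfg, seed=3).table
        assert (tab["d10"] < tab["d50"]).all()
        assert (tab["d50"] < tab["d90"]).all()


class TestRenderSpectra:
    def single_component_config(self):
        cfg = zero_spread_config()
        cfg.noise_sd = 0.0
        cfg.baseline_amplitude = 0.0
        cfg.baseline_d50_coeff = 0.0
        cfg.baseline_d10_coeff = 0.0
        cfg.scatter_slope = 0.0
        return cfg

    def test_beer_lambert_proportionality(self):
        # One absorbing component, no artifacts: spectrum scales with content.
        cfg = self.single_component_config()
        bands = BandModel(bands={
            "cryptotanshinone": default_band_model().bands["cryptotanshinone"],
            "tanshinone_iia": [(5000.0, 50.0, 0.0)],
            "matrix": [(5000.0, 50.0, 0.0)],
            "water": [(5000.0, 50.0, 0.0)],
        })
        attrs = sample_attributes(cfg, seed=1)
        t = attrs.table.copy()
        t.loc[0, "cryptotanshinone"] = 10.0
        t.loc[1, "cryptotanshinone"] = 30.0
        from nirpowder.core import AttributeTable
        attrs = AttributeTable(t)
        s = render_spectra(attrs, bands, cfg, seed=0)
        a0, a1 = s.absorbance[0], s.absorbance[1]
        mask = a0 > 1e-6
        np.testing.assert_allclose(a1[mask] / a0[mask], 3.0, rtol=1e-9)

    def test_d50_change_is_multiplicative_up_to_baseline(self):
        cfg = self.single_component_config()
        cfg.scatter_slope = 8.0
        attrs = sample_attributes(cfg, seed=2)
        t = attrs.table.copy()
        t.loc[1] = t.loc[0]
        t.loc[1, "sample_id"] = "twin"
        d50 = t.loc[0, "d50"]
        t.loc[1, ["d10", "d50", "d90"]] = [t.loc[0, "d10"] * 2, d50 * 2,
                                           t.loc[0, "d90"] * 2]
        from nirpowder.core import AttributeTable
        s = render_spectra(AttributeTable(t), None, cfg, seed=0)
        ratio = s.absorbance[1] / s.absorbance[0]
        m0 = 1 + cfg.scatter_slope * (1 / d50 - cfg.u_center)
        m1 = 1 + cfg.scatter_slope * (1 / (2 * d50) - cfg.u_center)
        np.testing.assert_allclose(ratio, m1 / m0, rtol=1e-9)

    def test_default_spectra_positive_with_high_snr(self):
        cfg = SimConfig()
        ds = generate_dataset(cfg, seed=11)
        a = ds.spectra.absorbance
        assert a.min() > 0.0
        assert a.max() / cfg.noise_sd > 20.0

    def test_band_outside_grid_rejected(self):
        cfg = SimConfig()
        bands = default_band_model()
        bands.bands["water"] = [(4001.0, 10.0, 1.0)]
        attrs = sample_attributes(cfg, seed=1)
        bands.bands["water"] = [(9999.0, 10.0, 1.0)]  # inside: fine
        render_spectra(attrs, bands, cfg, seed=0)
        with pytest.raises(ParameterError):
            BandModel(bands={"water": [(3000.0, 10.0, 1.0)]})


class TestGenerateDataset:
    def test_default_size_and_grid(self):
        ds = generate_dataset(seed=0)
        assert ds.n_samples == 50
        assert ds.spectra.n_points == 751
        np.testing.assert_array_equal(ds.spectra.wavenumbers,
                                      default_wavenumber_grid())

    def test_same_seed_is_bitwise_identical(self):
        a = generate_dataset(seed=123)
        b = generate_dataset(seed=123)
        np.testing.assert_array_equal(a.spectra.absorbance, b.spectra.absorbance)
        pd.testing.assert_frame_equal(a.attributes.table, b.attributes.table)

    def test_different_seeds_differ_but_share_config_echo(self):
        a = generate_dataset(seed=1)
        b = generate_dataset(seed=2)
        assert not np.array_equal(a.spectra.absorbance, b.spectra.absorbance)
        assert a.spectra.meta["sim_config"] == b.spectra.meta["sim_config"]


class TestLinkStructure:
    def test_noiseless_two_component_mixture_fits_exactly_with_two_lvs(self):
        cfg = SimConfig()
        cfg.noise_sd = 0.0
        cfg.baseline_amplitude = 0.0
        cfg.baseline_d50_coeff = 0.0
        cfg.baseline_d10_coeff = 0.0
        cfg.scatter_slope = 0.0
        bands = BandModel(bands={
            "cryptotanshinone": default_band_model().bands["cryptotanshinone"],
            "tanshinone_iia": default_band_model().bands["tanshinone_iia"],
            "matrix": [(5000.0, 50.0, 0.0)],
            "water": [(5000.0, 50.0, 0.0)],
        })
        attrs = sample_attributes(cfg, seed=4)
        s = render_spectra(attrs, bands, cfg, seed=0)
        y = attrs.values("cryptotanshinone")
        m = fit_pls(s.absorbance, y, 2)
        resid = predict_pls(m, s.absorbance) - y
        assert np.sqrt(np.mean(resid ** 2)) < 1e-8 * np.std(y)

    def test_best_linear_map_hits_residual_floor_on_tapped_density(self):
        # Train a plain linear model on many samples and test out of sample:
        # the nonlinear part of the link is invisible to it by construction.
        cfg = SimConfig(n_homemade=480, n_commercial=720)
        ds = generate_dataset(cfg, seed=9)
        X = ds.spectra.absorbance
        y = ds.attributes.values("tapped_density")
        n_train = 1000
        Xc = X[:n_train] - X[:n_train].mean(axis=0)
        yc = y[:n_train] - y[:n_train].mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        pred = (X[n_train:] - X[:n_train].mean(axis=0)) @ beta + y[:n_train].mean()
        resid_frac = np.var(pred - y[n_train:]) / np.var(y[n_train:])
        assert resid_frac >= cfg.nonlinear_residual_floor
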