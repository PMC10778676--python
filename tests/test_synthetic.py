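"""Tests for the synthetic-panel generator."""

import numpy as np
import pandas as pd
import pytest

from ricegi import (
    GeneratorConfig,
    generate_hydrolysis_curves,
    generate_raw_measurements,
    generate_variety_table,
    nearest_psd_correlation,
)
from ricegi.config import ConfigError, VARIABLES, default_correlation
from ricegi.synthetic import cinf_for_target_egi
from ricegi.kinetics import EGI_INTERCEPT, EGI_SLOPE


class TestConfig:
    def test_counts_must_sum(self):
        with pytest.raises(ConfigError, match="type_counts"):
            GeneratorConfig(n_varieties=5, type_counts={"Long A": 3})

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError, match="noise_sd"):
            GeneratorConfig(noise_sd=-1.0)

    def test_timepoints_must_start_at_zero_and_increase(self):
        with pytest.raises(ConfigError, match="timepoints"):
            GeneratorConfig(timepoints=(0.0, 20.0, 20.0, 120.0))
        with pytest.raises(ConfigError, match="timepoints"):
            GeneratorConfig(timepoints=(10.0, 20.0, 120.0))

    def test_correlation_matrix_validation(self):
        bad = np.eye(16)
        bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(ConfigError, match="symmetric"):
            GeneratorConfig(target_correlation=bad)
        with pytest.raises(ConfigError, match="square|16"):
            GeneratorConfig(target_correlation=np.eye(4))

    def test_default_correlation_is_psd_with_published_entries(self):
        r = default_correlation()
        assert np.linalg.eigvalsh(r).min() >= -1e-12
        idx = {v: i for i, v in enumerate(VARIABLES)}
        assert r[idx["RS"], idx["eGI"]] == pytest.approx(-0.90, abs=0.01)
        assert r[idx["Tg"], idx["eGI"]] == pytest.approx(-0.90, abs=0.01)
        assert r[idx["SB"], idx["eGI"]] == pytest.approx(-0.70, abs=0.01)
        assert r[idx["FIBER"], idx["PRTD"]] == pytest.approx(0.70, abs=0.01)


class TestCurves:
    def test_noiseless_curves_are_exact_model(self):
        cfg = GeneratorConfig(noise_sd=0.0, seed=1)
        curves, ref = generate_hydrolysis_curves(cfg)
        kin = cfg.per_type_kinetics
        for name, typ in zip(cfg.variety_names(), cfg.variety_types()):
            cinf, k = kin[typ]
            expected = cinf * -np.expm1(-k * np.asarray(cfg.timepoints))
            assert np.max(np.abs(curves[name].C - expected)) == 0.0

    def test_single_point_value(self):
        # C_inf=85, k=0.03 at t=20 -> 85*(1-exp(-0.6))
        cfg = GeneratorConfig(
            n_varieties=1, type_counts={"Long A": 1},
            per_type_kinetics={"Long A": (85.0, 0.03)}, noise_sd=0.0, seed=0)
        curves, _ = generate_hydrolysis_curves(cfg)
        c = curves["LA01"]
        assert c.C[list(c.t).index(20.0)] == pytest.approx(
            85.0 * (1 - np.exp(-0.6)), abs=1e-9)

    def test_time_zero_is_zero_for_every_variety(self):
        cfg = GeneratorConfig(noise_sd=3.0, seed=2)
        curves, ref = generate_hydrolysis_curves(cfg)
        for c in list(curves.values()) + [ref]:
            assert c.C[0] == 0.0

    def test_reference_exceeds_all_varieties(self):
        cfg = GeneratorConfig(seed=3)
        _, ref = generate_hydrolysis_curves(cfg)
        ref_cinf, ref_k = 100.0, 0.35
        for cinf, k in cfg.per_type_kinetics.values():
            assert ref_cinf > cinf and ref_k > k

    def test_seeding_determinism(self):
        cfg = GeneratorConfig(seed=7)
        a, ra = generate_hydrolysis_curves(cfg)
        b, rb = generate_hydrolysis_curves(GeneratorConfig(seed=7))
        assert np.array_equal(ra.C, rb.C)
        for k in a:
            assert np.array_equal(a[k].C, b[k].C)

    def test_replicates_keying(self):
        cfg = GeneratorConfig(
            n_varieties=2, type_counts={"Long A": 2}, replicates=3, seed=4)
        curves, _ = generate_hydrolysis_curves(cfg)
        assert sorted(curves) == [
            "LA01#r1", "LA01#r2", "LA01#r3", "LA02#r1", "LA02#r2", "LA02#r3"]

    def test_table_coupling_inverts_egi(self):
        """Coupled curves carry the table's eGI through the AUC chain."""
        egi = 72.0
        k = 0.023
        cinf = cinf_for_target_egi(egi, k)
        auc_ref = 100.0 * 240 + (100.0 / 0.35) * (np.exp(-0.35 * 240) - 1)
        auc = cinf * 240 + (cinf / k) * (np.exp(-k * 240) - 1)
        assert EGI_INTERCEPT + EGI_SLOPE * 100 * auc / auc_ref == pytest.approx(
            egi, abs=1e-9)


class TestVarietyTable:
    def test_shape_types_and_determinism(self, default_cfg):
        t1 = generate_variety_table(default_cfg)
        t2 = generate_variety_table(GeneratorConfig(seed=default_cfg.seed))
        assert list(t1.columns) == ["variety", "type", *VARIABLES]
        assert len(t1) == 22
        assert t1["type"].value_counts()["Long A"] == 11
        pd.testing.assert_frame_equal(t1, t2)

    def test_sample_correlation_approaches_target(self):
        cfg = GeneratorConfig(n_varieties=2000, type_counts={"Long A": 2000}, seed=21)
        table = generate_variety_table(cfg)
        sample = np.corrcoef(table[list(VARIABLES)].to_numpy().T)
        target = nearest_psd_correlation(cfg.target_correlation)
        assert np.max(np.abs(sample - target)) <= 0.08

    def test_identity_target_gives_independence(self):
        cfg = GeneratorConfig(
            n_varieties=2000, type_counts={"Long A": 2000},
            target_correlation=np.eye(16), seed=22)
        table = generate_variety_table(cfg)
        sample = np.corrcoef(table[list(VARIABLES)].to_numpy().T)
        off = sample - np.eye(16)
        assert np.max(np.abs(off)) <= 0.08


class TestNearestPSD:
    def test_indefinite_matrix_repaired_with_warning(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        m[1, 2] = m[2, 1] = 0.9
        m[0, 2] = m[2, 0] = -0.5  # indefinite triangle
        assert np.linalg.eigvalsh(m).min() < 0
        with pytest.warns(RuntimeWarning, match="indefinite"):
            fixed = nearest_psd_correlation(m)
        w = np.linalg.eigvalsh(fixed)
        assert w.min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)
        # eigenvalue-clipping oracle: same construction, done directly
        ev, q = np.linalg.eigh(m)
        ref = (q * np.clip(ev, 1e-8, None)) @ q.T
        d = np.sqrt(np.diag(ref))
        ref = ref / np.outer(d, d)
        np.fill_diagonal(ref, 1.0)
        assert np.allclose(fixed, ref)

    def test_psd_matrix_untouched(self):
        r = default_correlation()
        assert np.array_equal(nearest_psd_correlation(r), r)


class TestRawMeasurements:
    def test_cooking_inverts_wup(self):
        cfg = GeneratorConfig(seed=30)
        table = generate_variety_table(cfg)
        raw = generate_raw_measurements(cfg, table)
        merged = raw.cooking.merge(table[["variety", "WUp"]], on="variety")
        expected = 12.0 * (1 + merged["WUp"] / 100.0)
        assert np.allclose(merged["cooked_mass_g"], expected)
        assert (raw.cooking["uncooked_mass_g"] == 12.0).all()

    def test_noiseless_digestogram_is_exact_first_order(self):
        from ricegi import ViscosityTrace, fit_digestogram

        cfg = GeneratorConfig(seed=31, rva_noise_sd=0.0)
        raw = generate_raw_measurements(cfg)
        sub = raw.digestograms[raw.digestograms["variety"] == "LA01"]
        trace = ViscosityTrace(
            "LA01", sub["time_min"].to_numpy(), sub["viscosity_cP"].to_numpy())
        fit = fit_digestogram(trace)
        assert fit.rss <= 1e-9  # exact model evaluation, zero residual

    def test_pasting_trace_single_interior_peak(self):
        cfg = GeneratorConfig(seed=32)
        table = generate_variety_table(cfg)
        raw = generate_raw_measurements(cfg, table)
        for name, sub in raw.pasting.groupby("variety"):
            v = sub.sort_values("time_min")["viscosity_cP"].to_numpy()
            interior = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
            # strict local maxima among interior points, ignoring flat baseline
            peaks = np.flatnonzero(interior & (v[1:-1] > v.min() + 1.0))
            assert len(peaks) == 1, name

    def test_determinism_across_all_outputs(self):
        a = generate_raw_measurements(GeneratorConfig(seed=33))
        b = generate_raw_measurements(GeneratorConfig(seed=33))
        for x, y in [(a.cooking, b.cooking), (a.biometry, b.biometry),
                     (a.pasting, b.pasting), (a.digestograms, b.digestograms)]:
            pd.testing.assert_frame_equal(x, y)
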