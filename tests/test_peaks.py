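import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoscreen import peaks, synthdata as sd
from glycoscreen.exceptions import ConfigurationError


def _table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "rt_min", "mz", "area"])


class TestAlignPeaks:
    def test_identical_samples_one_feature_per_peak(self, peak_frame):
        m = peaks.align_peaks(peak_frame)
        assert m.n_features == 3
        assert (m.values > 0).all().all()

    def test_within_tolerance_merges(self):
        t = _table([("a", 5.0, 1000.00, 100.0), ("b", 5.2, 1000.05, 90.0)])
        assert peaks.align_peaks(t).n_features == 1

    def test_beyond_mz_tolerance_splits(self):
        t = _table([("a", 5.0, 1000.00, 100.0), ("b", 5.2, 1000.07, 90.0)])
        assert peaks.align_peaks(t).n_features == 2

    def test_beyond_rt_tolerance_splits(self):
        t = _table([("a", 5.0, 1000.00, 100.0), ("b", 5.35, 1000.00, 90.0)])
        assert peaks.align_peaks(t).n_features == 2

    def test_one_peak_per_sample_per_feature(self):
        # two in-tolerance peaks in the same sample: only nearest joins
        t = _table([
            ("a", 5.0, 1000.00, 100.0),
            ("b", 5.0, 1000.01, 50.0),
            ("b", 5.0, 1000.04, 40.0),
        ])
        m = peaks.align_peaks(t)
        counts = m.provenance.groupby(["feature_id", "sample_id"]).size()
        assert (counts == 1).all()
        assert m.n_features == 2

    def test_sample_order_invariance(self, small_config):
        sim = sd.simulate(small_config)
        t = sim.tables.samples
        shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = peaks.align_peaks(t)
        b = peaks.align_peaks(shuffled)
        assert a.n_features == b.n_features
        pa = set(map(tuple, a.provenance[["sample_id", "peak_id"]].to_numpy()))
        pb = set(map(tuple, b.provenance[["sample_id", "peak_id"]].to_numpy()))
        assert pa == pb

    def test_self_alignment_no_new_features(self, peak_frame):
        dup = peak_frame.copy()
        dup["sample_id"] = dup.sample_id + "_copy"
        m = peaks.align_peaks(pd.concat([peak_frame, dup], ignore_index=True))
        assert m.n_features == peaks.align_peaks(peak_frame).n_features

    def test_empty_table_empty_matrix(self):
        m = peaks.align_peaks(_table([]))
        assert m.n_features == 0

    def test_negative_tolerance_rejected(self, peak_frame):
        with pytest.raises(ConfigurationError):
            peaks.align_peaks(peak_frame, tol_mz=-0.1)

    def test_consensus_is_weighted_mean(self):
        t = _table([("a", 5.0, 1000.00, 300.0), ("b", 5.2, 1000.03, 100.0)])
        m = peaks.align_peaks(t)
        assert m.features.mz.iloc[0] == pytest.approx((300 * 1000.0 + 100 * 1000.03) / 400)
        assert m.features.rt.iloc[0] == pytest.approx((300 * 5.0 + 100 * 5.2) / 400)

    def test_simulator_recovery_rate(self, small_config):
        sim = sd.simulate(small_config)
        m = peaks.align_peaks(sim.tables.samples)
        reg = sim.truth.registry
        found = sum(
            bool((((m.features.mz - r.mz).abs() <= 0.06)
                  & ((m.features.rt - r.rt).abs() <= 0.3)).any())
            for r in reg.itertuples()
        )
        assert found >= 0.99 * len(reg)


class TestComputeCV:
    def test_constant_replicates(self):
        assert peaks.compute_cv([10, 10, 10]) == 0.0

    def test_hand_computed_two_replicates(self):
        # sd([8,12]) = 2.828427..., mean 10 -> 28.284271 %
        assert peaks.compute_cv([8, 12]) == pytest.approx(28.2842712474619, abs=1e-9)

    def test_undefined_cases(self):
        assert np.isnan(peaks.compute_cv([5.0]))
        assert np.isnan(peaks.compute_cv([0.0, 0.0]))

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=2, max_size=8),
        st.floats(min_value=0.01, max_value=1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, reps, c):
        base = peaks.compute_cv(reps)
        scaled = peaks.compute_cv([c * r for r in reps])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestSNR:
    def _matrix_with_area(self, area):
        t = _table([(s, 5.0, 1000.0, area) for s in ("a", "b", "c")])
        return peaks.align_peaks(t)

    def test_snr_five_retained(self):
        m = self._matrix_with_area(500.0)
        snr = peaks.estimate_snr(m, peaks.NoiseFloorModel.constant(100.0))
        assert snr.iloc[0] == pytest.approx(5.0)
        flags = peaks.build_flags(
            m, pd.Series(0.0, index=m.features.feature_id), snr,
            peaks.flag_artifacts(m),
        )
        assert flags.pass_egp.iloc[0]  # removal requires snr < 5 strictly

    def test_snr_one_at_noise_floor(self):
        m = self._matrix_with_area(100.0)
        snr = peaks.estimate_snr(m, peaks.NoiseFloorModel.constant(100.0))
        assert snr.iloc[0] == pytest.approx(1.0)

    def test_local_noise_floor_window(self):
        noise = _table([("n", 5.0, 800.0, 100.0), ("n", 12.0, 800.0, 1000.0)])
        model = peaks.NoiseFloorModel.from_peaks(noise)
        assert model.floor_at(5.1) == 100.0
        assert model.floor_at(12.1) == 1000.0
        assert model.floor_at(8.0) == 550.0  # no local peaks: global median

    def test_programmed_ratio_recovered(self):
        cfg = sd.CohortConfig(
            n_per_group={"healthy": 20, "CRC": 0, "GC": 0, "EC": 0},
            n_true_egps=50, base_area=2000.0, noise_floor=100.0,
            noise_sd=0.2, seed=21,
        )
        sim = sd.simulate(cfg)
        m = peaks.align_peaks(sim.tables.samples)
        snr = peaks.estimate_snr(m, peaks.NoiseFloorModel.constant(cfg.noise_floor))
        # base areas are lognormal around 2000 -> ratios spread around 20
        assert (snr > 5).mean() > 0.9


class TestArtifactFlags:
    def test_satellite_free_no_flags(self, small_config):
        # noisy run so co-eluting features do not correlate by construction
        import dataclasses
        cfg = dataclasses.replace(
            small_config,
            satellite_rates={"isotope": 0.0, "adduct": 0.0, "fragment": 0.0},
            n_noise_peaks=0,
        )
        sim = sd.simulate(cfg)
        m = peaks.align_peaks(sim.tables.samples)
        f = peaks.flag_artifacts(m)
        assert not f.any().any()

    def test_constructed_adduct_flagged(self):
        rows = []
        for s in ("a", "b", "c"):
            rows.append((s, 5.0, 1000.0, 1000.0))
            rows.append((s, 5.0, 1021.982, 300.0))
        m = peaks.align_peaks(_table(rows))
        f = peaks.flag_artifacts(m)
        adduct_fid = m.features.feature_id[m.features.mz > 1010].iloc[0]
        assert f.loc[adduct_fid, "is_adduct"]
        parent_fid = m.features.feature_id[m.features.mz < 1010].iloc[0]
        assert not f.loc[parent_fid].any()

    def test_constructed_isotope_flagged(self):
        rows = []
        for s in ("a", "b"):
            rows.append((s, 5.0, 1000.0, 1000.0))
            rows.append((s, 5.05, 1001.00335, 400.0))
        f = peaks.flag_artifacts(peaks.align_peaks(_table(rows)))
        assert f.is_isotope.sum() == 1

    def test_correlated_lower_mz_fragment_flagged(self):
        rng = np.random.default_rng(0)
        rows = []
        for i, s in enumerate(f"s{k}" for k in range(8)):
            a = 1000.0 * float(rng.lognormal(0, 0.3))
            rows.append((s, 5.0, 1500.0, a))
            rows.append((s, 5.02, 1100.0, 0.5 * a))
        f = peaks.flag_artifacts(peaks.align_peaks(_table(rows)))
        m = peaks.align_peaks(_table(rows))
        frag_fid = m.features.feature_id[m.features.mz < 1200].iloc[0]
        assert f.loc[frag_fid, "is_fragment"]

    def test_simulator_isotopes_flagged(self):
        cfg = sd.CohortConfig(
            n_per_group={"healthy": 20, "CRC": 10, "GC": 0, "EC": 0},
            n_true_egps=100,
            satellite_rates={"isotope": 0.5, "adduct": 0.0, "fragment": 0.0},
            seed=17,
        )
        sim = sd.simulate(cfg)
        m = peaks.align_peaks(sim.tables.samples)
        f = peaks.flag_artifacts(m)
        roles = pd.Series(sim.truth.peak_roles)
        prov = m.provenance.merge(
            roles.rename("role"), left_on="peak_id", right_index=True
        )
        feat_role = prov.groupby("feature_id").role.agg(lambda s: s.mode().iat[0])
        iso = feat_role[feat_role == "isotope"].index
        parents = feat_role[feat_role == "parent"].index
        assert f.loc[iso, "is_isotope"].mean() >= 0.95
        assert f.loc[parents, "is_isotope"].mean() <= 0.02


class TestSelectAndNormalize:
    def _fixture_matrix(self, n):
        rows = [(s, 1.0 + 0.4 * i, 900.0 + 10 * i, 1000.0)
                for i in range(n) for s in ("a", "b")]
        return peaks.align_peaks(_table(rows))

    def test_cv_boundary_semantics(self):
        m = self._fixture_matrix(2)
        fids = m.features.feature_id
        cv = pd.Series([50.0, 60.0], index=fids)
        snr = pd.Series([10.0, 10.0], index=fids)
        flags = peaks.build_flags(m, cv, snr, peaks.flag_artifacts(m))
        sel, report = peaks.select_egps(m, flags)
        assert report["removed_cv"] == 1  # 50.0 % exactly is retained
        assert fids.iloc[0] in set(sel.features.feature_id)

    def test_step_counts_sum(self):
        m = self._fixture_matrix(16)
        fids = m.features.feature_id
        cv = pd.Series(10.0, index=fids)
        snr = pd.Series(10.0, index=fids)
        art = peaks.flag_artifacts(m)
        cv.iloc[0] = 80.0
        snr.iloc[1] = 2.0
        snr.iloc[2] = 2.0
        art.iloc[3, 0] = True
        art.iloc[4, 1] = True
        art.iloc[5, 2] = True
        flags = peaks.build_flags(m, cv, snr, art)
        sel, report = peaks.select_egps(m, flags)
        assert report == {
            "input": 16, "removed_cv": 1, "removed_snr": 2,
            "removed_artifact": 3, "output": 10,
        }
        assert set(sel.features.feature_id) <= set(fids)

    def test_qc_normalization_arithmetic(self):
        m = self._fixture_matrix(1)
        qc = pd.DataFrame({"q1": [100.0], "q2": [100.0]},
                          index=m.features.feature_id)
        norm, excluded = peaks.normalize_to_qc(m, qc)
        assert excluded == []
        assert norm.values.iloc[0, 0] == pytest.approx(10.0)  # 1000 / 100

    def test_qc_zero_mean_excluded(self):
        m = self._fixture_matrix(2)
        qc = pd.DataFrame({"q1": [100.0, 0.0]}, index=m.features.feature_id)
        norm, excluded = peaks.normalize_to_qc(m, qc)
        assert len(excluded) == 1
        assert norm.n_features == 1

    def test_sample_scaling_linearity(self):
        m = self._fixture_matrix(3)
        qc = pd.DataFrame({"q1": [100.0] * 3}, index=m.features.feature_id)
        norm, _ = peaks.normalize_to_qc(m, qc)
        doubled = peaks.FeatureMatrix(
            features=m.features, values=m.values.assign(a=m.values["a"] * 2),
            provenance=m.provenance,
        )
        norm2, _ = peaks.normalize_to_qc(doubled, qc)
        assert np.allclose(norm2.values["a"], 2 * norm.values["a"])


class TestFullPipeline:
    def test_information_preserving_on_clean_simulation(self, clean_config):
        """Noise-free, satellite-free run: pipeline output equals planted
        abundance over QC level to within 1e-9 relative error."""
        sim = sd.simulate(clean_config)
        res = peaks.run_pipeline(
            sim.tables.samples, sim.tables.qc_intra, sim.tables.qc_inter,
            noise_model=peaks.NoiseFloorModel.constant(1.0),
        )
        assert res.report["output"] == clean_config.n_true_egps
        truth = sim.truth
        groups = {s.id: s for s in sim.subjects}
        feats = res.egp_matrix.features
        for r in truth.registry.itertuples():
            sel = (feats.mz - r.mz).abs() < 1e-9
            assert sel.sum() == 1
            fid = feats.feature_id[sel].iloc[0]
            eff = truth.effect_lookup("CRC")[r.species_id]
            for sample_id, value in res.egp_matrix.values.loc[fid].items():
                subj = groups[sample_id]
                factor = sd._stage_factor(subj.stage, clean_config)
                expected = 2.0 ** (eff * factor) if subj.group == "CRC" else 1.0
                assert value == pytest.approx(expected, rel=1e-9)

    def test_pipeline_reports_consistent(self, small_config):
        sim = sd.simulate(small_config)
        res = peaks.run_pipeline(
            sim.tables.samples, sim.tables.qc_intra, sim.tables.qc_inter,
            noise_model=peaks.NoiseFloorModel.constant(small_config.noise_floor),
        )
        r = res.report
        assert r["input"] - r["removed_cv"] - r["removed_snr"] - r["removed_artifact"] \
            == r["output"]
        assert set(res.egp_matrix.values.columns) == {s.id for s in sim.subjects}
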