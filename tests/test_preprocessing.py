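"""Kernel-level behavior: detection, QC, background, dye, normalization, beta, rcp."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methrel as mr
from methrel.preprocessing import _qn_matrix
from methrel.synthetic_data import GREEN, RED


@pytest.fixture(scope="module")
def qc_manifest():
    return mr.generate_manifest(400, 0.84, 40, 30, 80, seed=31)


@pytest.fixture(scope="module")
def qc_dataset(qc_manifest):
    truth = mr.simulate_truth(qc_manifest, 10, 0, seed=32)
    return mr.simulate_intensities(truth, qc_manifest, seed=33)


class TestDetection:
    def test_extreme_and_central_probes(self, qc_dataset, qc_manifest):
        ds = qc_dataset.copy()
        probe = qc_manifest.cpg_ids[0]
        ds.meth.loc[probe] = 1e8          # 50+ SDs above background
        pvals = mr.detection_pvalues(ds, qc_manifest)
        assert (pvals.loc[probe] < 1e-10).all()

    def test_probe_at_background_mean_has_p_half(self, qc_manifest, qc_dataset):
        ds = qc_dataset.copy()
        pvals = mr.detection_pvalues(ds, qc_manifest)
        # plant a type-II probe exactly at its null mean on one array
        probe = qc_manifest.cpg_ids_of_type("II")[0]
        array = ds.meth.columns[0]
        neg = qc_manifest.negative_ids
        chans = qc_manifest.probes.loc[neg, "channel"]
        mu = {}
        for ch in (RED, GREEN):
            ids = neg[chans == ch]
            mu[ch] = np.concatenate(
                [ds.meth.loc[ids, array].to_numpy(), ds.unmeth.loc[ids, array].to_numpy()]
            ).mean()
        ds.meth.loc[probe, array] = mu[GREEN]
        ds.unmeth.loc[probe, array] = mu[RED]
        pvals = mr.detection_pvalues(ds, qc_manifest)
        assert pvals.loc[probe, array] == pytest.approx(0.5, abs=1e-12)

    def test_background_only_probes_have_uniform_pvalues(self):
        """Under the null (pure background) detection p-values are Uniform(0,1)."""
        manifest = mr.generate_manifest(300, 0.84, 20, 10, 200, seed=40)
        truth = mr.simulate_truth(manifest, 30, 0, seed=41)
        rejections = 0
        for seed in range(5):
            ds = mr.simulate_intensities(truth, manifest, seed=seed)
            # overwrite a probe set with pure background draws (its own channels)
            rng = np.random.default_rng(seed + 100)
            null_probes = manifest.cpg_ids_of_type("II")[:80]
            shape = ds.meth.loc[null_probes].shape
            neg = manifest.negative_ids
            chans = manifest.probes.loc[neg, "channel"]
            for mat, ch in ((ds.meth, GREEN), (ds.unmeth, RED)):
                ids = neg[chans == ch]
                draws = np.vstack([ds.meth.loc[ids], ds.unmeth.loc[ids]])
                mat.loc[null_probes] = rng.normal(
                    draws.mean(axis=0), draws.std(axis=0, ddof=1), shape
                ).clip(min=0)
            pvals = mr.detection_pvalues(ds, manifest).loc[null_probes].to_numpy().ravel()
            if stats.kstest(pvals, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_requires_negative_controls(self, qc_dataset):
        bare = mr.generate_manifest(400, 0.84, 40, 30, 0, seed=31)
        with pytest.raises(mr.CapabilityError):
            mr.detection_pvalues(qc_dataset, bare)


class TestSampleQC:
    def test_planted_failures_are_exactly_identified(self, qc_manifest, qc_dataset):
        ds = qc_dataset.copy()
        arrays = ds.meth.columns
        bad_det, bad_med, good = arrays[1], arrays[4], arrays[0]
        cpg = qc_manifest.cpg_ids
        n_fail = int(round(0.06 * len(cpg)))
        # 6% of probes at background level -> detection failures on bad_det
        ds.meth.loc[cpg[:n_fail], bad_det] = 1.0
        ds.unmeth.loc[cpg[:n_fail], bad_det] = 1.0
        # global intensity collapse on bad_med
        ds.meth[bad_med] *= 0.01
        ds.unmeth[bad_med] *= 0.01
        pvals = mr.detection_pvalues(ds, qc_manifest)
        report = mr.sample_qc(ds, pvals, qc_manifest)
        assert set(report.excluded_ids) == {bad_det, bad_med}
        assert "detection" in report.reasons[bad_det]
        assert "median" in report.reasons[bad_med]
        assert report.reasons[good] == ""

    def test_borderline_array_retained(self, qc_manifest, qc_dataset):
        ds = qc_dataset.copy()
        arrays = ds.meth.columns
        cpg = qc_manifest.cpg_ids
        n_fail = int(0.049 * len(cpg))  # below the 5% rule
        ds.meth.loc[cpg[:n_fail], arrays[2]] = 1.0
        ds.unmeth.loc[cpg[:n_fail], arrays[2]] = 1.0
        pvals = mr.detection_pvalues(ds, qc_manifest)
        report = mr.sample_qc(ds, pvals, qc_manifest)
        assert arrays[2] not in report.excluded_ids


class TestBackground:
    def test_oob_removes_injected_background(self, qc_manifest):
        truth = mr.simulate_truth(qc_manifest, 40, 0, seed=50)
        cfg = mr.TechConfig().noise_free()
        cfg.bg_mean_red = cfg.bg_mean_green = 500.0
        cfg.bg_sd = 30.0
        ds = mr.simulate_intensities(truth, qc_manifest, cfg, seed=51)
        corrected = mr.background_correct(ds, "oob", qc_manifest)
        neg = qc_manifest.negative_ids
        resid = corrected.meth.loc[neg].to_numpy().mean()
        # background-only probes land near the floor after correction
        assert resid < 0.05 * 500.0

    def test_zero_background_is_identity_up_to_floor(self, qc_manifest, noise_free_dataset,
                                                     small_manifest):
        corrected = mr.background_correct(noise_free_dataset, "oob", small_manifest)
        raw = noise_free_dataset.meth.to_numpy()
        cor = corrected.meth.to_numpy()
        mask = raw > 1.0
        assert np.abs(cor[mask] - raw[mask]).max() <= 1.0 + 1e-9

    def test_neg_and_oob_agree_when_sources_share_law(self, qc_manifest):
        truth = mr.simulate_truth(qc_manifest, 60, 0, seed=52)
        cfg = mr.TechConfig()
        cfg.bg_array_sd = 0.0  # both estimators target the same constant level
        ds = mr.simulate_intensities(truth, qc_manifest, cfg, seed=53)
        a = mr.background_correct(ds, "oob", qc_manifest)
        b = mr.background_correct(ds, "neg", qc_manifest)
        diff = np.abs(a.meth.to_numpy() - b.meth.to_numpy()).mean()
        # estimation error of two independent means of the same law
        assert diff < 3 * cfg.bg_sd / np.sqrt(60)


class TestDye:
    @pytest.mark.parametrize("d", [0.5, 2.0])
    def test_relic_neutralizes_multiplicative_bias(self, qc_manifest, d):
        truth = mr.simulate_truth(qc_manifest, 30, 0, seed=60)
        cfg = mr.TechConfig().noise_free()
        ds = mr.simulate_intensities(truth, qc_manifest, cfg, seed=61)
        # inject a known dye factor on all red-channel measurements
        from methrel.preprocessing import _channel_masks
        mmask, umask = _channel_masks(ds, qc_manifest, RED)
        ds.meth.iloc[mmask, :] *= d
        ds.unmeth.iloc[umask, :] *= d
        corrected = mr.dye_correct(ds, "relic", qc_manifest)
        pairs = qc_manifest.control_pairs()
        red = corrected.meth.loc[pairs[RED]].to_numpy() + corrected.unmeth.loc[pairs[RED]].to_numpy()
        green = corrected.meth.loc[pairs[GREEN]].to_numpy() + corrected.unmeth.loc[pairs[GREEN]].to_numpy()
        assert abs(np.log(red / green).mean()) < 0.01

    def test_no_bias_is_near_identity(self, qc_manifest):
        truth = mr.simulate_truth(qc_manifest, 30, 0, seed=62)
        cfg = mr.TechConfig().noise_free()
        ds = mr.simulate_intensities(truth, qc_manifest, cfg, seed=63)
        corrected = mr.dye_correct(ds, "relic", qc_manifest)
        ratio = corrected.meth.to_numpy() / np.maximum(ds.meth.to_numpy(), 1.0)
        assert np.abs(np.log(ratio[ds.meth.to_numpy() > 10])).max() < 1e-6

    def test_mean_and_relic_agree_for_pure_scale_bias(self, qc_manifest):
        truth = mr.simulate_truth(qc_manifest, 20, 0, seed=64)
        cfg = mr.TechConfig().noise_free()
        cfg.dye_bias_sd = 0.3
        ds = mr.simulate_intensities(truth, qc_manifest, cfg, seed=65)
        a = mr.dye_correct(ds, "mean", qc_manifest)
        b = mr.dye_correct(ds, "relic", qc_manifest)
        big = ds.meth.to_numpy() > 10
        rel = np.abs(a.meth.to_numpy()[big] - b.meth.to_numpy()[big]) / a.meth.to_numpy()[big]
        assert rel.max() < 1e-6


class TestQuantileNormalize:
    def test_identical_arrays_unchanged(self, qc_manifest, qc_dataset):
        ds = qc_dataset.copy()
        first = ds.meth.columns[0]
        for col in ds.meth.columns:
            ds.meth[col] = ds.meth[first]
            ds.unmeth[col] = ds.unmeth[first]
        out = mr.quantile_normalize(ds, "q2", qc_manifest)
        np.testing.assert_allclose(out.meth.to_numpy(), ds.meth.to_numpy(), rtol=1e-12)

    def test_monotone_distortion_equalizes_distributions(self, qc_manifest, qc_dataset):
        ds = qc_dataset.copy()
        a0 = ds.meth.columns[0]
        ds.meth[a0] = ds.meth[a0] ** 1.3 + 5.0
        ds.unmeth[a0] = ds.unmeth[a0] ** 1.3 + 5.0
        out = mr.quantile_normalize(ds, "q1", qc_manifest)
        cpg = qc_manifest.cpg_ids
        for dt in ("I", "II"):
            rows = cpg[qc_manifest.probes.loc[cpg, "design_type"] == dt]
            sub = out.meth.loc[rows].to_numpy()
            sorted_cols = np.sort(sub, axis=0)
            assert np.abs(sorted_cols - sorted_cols[:, [0]]).max() < 1e-9

    def test_q1_and_q3_differ_under_type2_compression(self, qc_manifest):
        truth = mr.simulate_truth(qc_manifest, 25, 0, seed=70)
        cfg = mr.TechConfig()
        cfg.type2_compression = 0.5
        ds = mr.simulate_intensities(truth, qc_manifest, cfg, seed=71)
        out1 = mr.quantile_normalize(ds, "q1", qc_manifest)
        out3 = mr.quantile_normalize(ds, "q3", qc_manifest)
        assert np.abs(out1.meth.to_numpy() - out3.meth.to_numpy()).max() > 1.0

    def test_single_array_warns_and_noops(self, qc_manifest, qc_dataset):
        ds = mr.drop_arrays(qc_dataset, qc_dataset.meth.columns[1:])
        with pytest.warns(UserWarning):
            out = mr.quantile_normalize(ds, "q1", qc_manifest)
        np.testing.assert_array_equal(out.meth.to_numpy(), ds.meth.to_numpy())

    def test_ties_get_average_reference_values(self):
        x = np.array([[1.0, 2.0], [1.0, 1.0], [3.0, 4.0]])
        out = _qn_matrix(x)
        # tied entries within a column share one interpolated value
        assert out[0, 0] == out[1, 0]
        ref = np.sort(x, axis=0).mean(axis=1)
        np.testing.assert_allclose(np.sort(out[:, 1]), ref, rtol=1e-12)


class TestBeta:
    @pytest.mark.parametrize(
        "m,u,offset,expected",
        [(100.0, 100.0, 100.0, 1.0 / 3.0), (0.0, 0.0, 100.0, 0.0), (7.0, 7.0, 0.0, 0.5)],
    )
    def test_beta_arithmetic(self, qc_manifest, qc_dataset, m, u, offset, expected):
        ds = qc_dataset.copy()
        probe = qc_manifest.cpg_ids[5]
        ds.meth.loc[probe] = m
        ds.unmeth.loc[probe] = u
        beta = mr.compute_beta(ds, qc_manifest, offset=offset)
        assert beta.values.loc[probe].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_beta_range_enforced(self, qc_dataset, qc_manifest):
        beta = mr.compute_beta(qc_dataset, qc_manifest)
        v = beta.values.to_numpy()
        assert v.min() >= 0 and v.max() < 1


class TestRCP:
    def test_exactly_inverts_linear_compression(self, small_truth, small_manifest):
        cfg = mr.TechConfig().noise_free()
        cfg.type2_compression = 0.8
        ds = mr.simulate_intensities(small_truth, small_manifest, cfg, seed=80)
        beta = mr.compute_beta(ds, small_manifest, offset=0.0)
        fixed = mr.rcp_correct(beta, small_manifest)
        truth_beta = small_truth.true_beta.loc[ds.sample_sheet["subject_id"]].to_numpy().T
        assert np.abs(fixed.values.to_numpy() - truth_beta).max() < 1e-6

    def test_identity_when_uncompressed(self, small_truth, small_manifest,
                                        noise_free_dataset):
        beta = mr.compute_beta(noise_free_dataset, small_manifest, offset=0.0)
        fixed = mr.rcp_correct(beta, small_manifest)
        assert np.abs(fixed.values.to_numpy() - beta.values.to_numpy()).max() < 1e-8

    def test_reduces_pair_discrepancy_under_noisy_compression(self, small_manifest):
        """Corrected type-II betas sit closer to their matched type-I partners."""
        wins = 0
        pairs = small_manifest.neighbor_pairs()
        for seed in range(20):
            truth = mr.simulate_truth(small_manifest, 20, 0, seed=seed + 200)
            cfg = mr.TechConfig()
            cfg.type2_compression = 0.7
            ds = mr.simulate_intensities(truth, small_manifest, cfg, seed=seed + 300)
            beta = mr.compute_beta(ds, small_manifest)
            fixed = mr.rcp_correct(beta, small_manifest)
            gap_raw = np.abs(
                beta.values.loc[pairs["type_ii"]].to_numpy()
                - beta.values.loc[pairs["type_i"]].to_numpy()
            ).mean()
            gap_fix = np.abs(
                fixed.values.loc[pairs["type_ii"]].to_numpy()
                - fixed.values.loc[pairs["type_i"]].to_numpy()
            ).mean()
            wins += gap_fix < gap_raw
        assert wins >= 18

    def test_requires_enough_pairs(self, qc_dataset):
        sparse = mr.generate_manifest(400, 0.84, 5, 30, 80, seed=31)
        beta = mr.compute_beta(qc_dataset, sparse)
        with pytest.raises(mr.CapabilityError):
            mr.rcp_correct(beta, sparse)


class TestPipelineRunner:
    def test_raw_passthrough_on_noise_free_data(self, small_truth, small_manifest,
                                                noise_free_dataset):
        beta = mr.run_pipeline(noise_free_dataset, mr.RAW_SPEC, small_manifest, offset=0.0)
        want = small_truth.true_beta.loc[
            noise_free_dataset.sample_sheet["subject_id"]
        ].to_numpy().T
        assert np.abs(beta.values.to_numpy() - want).max() < 1e-12
        assert beta.provenance == "raw"

    def test_recommended_pipeline_runs_end_to_end(self, small_dataset, small_manifest):
        spec = mr.PipelineSpec(bg="oob", dye="relic", norm="q1", probe="rcp")
        beta = mr.run_pipeline(small_dataset, spec, small_manifest)
        v = beta.values.to_numpy()
        assert v.shape == (len(small_manifest.cpg_ids), small_dataset.meth.shape[1])
        assert v.min() >= 0 and v.max() <= 1
        assert beta.provenance == spec.label

    def test_array_order_equivariance(self, small_dataset, small_manifest):
        spec = mr.PipelineSpec(bg="oob", dye="mean", norm="q2")
        beta = mr.run_pipeline(small_dataset, spec, small_manifest)
        perm = list(small_dataset.meth.columns[::-1])
        shuffled = mr.IntensityDataset(
            small_dataset.meth[perm], small_dataset.unmeth[perm],
            small_dataset.oob[perm], small_dataset.sample_sheet.loc[perm],
        )
        beta2 = mr.run_pipeline(shuffled, spec, small_manifest)
        np.testing.assert_allclose(
            beta2.values[beta.values.columns].to_numpy(), beta.values.to_numpy(), rtol=1e-10
        )


class TestKernelIdentifiability:
    QUIET = dict(
        bg_mean_red=200.0, bg_mean_green=200.0, bg_sd=30.0, bg_array_sd=0.0,
        dye_bias_sd=0.0, type2_compression=1.0, type2_compression_sd=0.0,
        batch_sds={"chip": 0.0, "position": 0.0, "plate": 0.0, "well": 0.0},
        occasion_shift_sd=0.0,
    )

    @classmethod
    def _pair_msd(cls, seed, overrides, spec, selection):
        """Mean squared replicate beta difference over the affected probes."""
        manifest = mr.generate_manifest(400, 0.84, 50, 30, 50, seed=seed)
        truth = mr.simulate_truth(manifest, 20, 20, seed=seed + 1)
        ds = mr.simulate_intensities(
            truth, manifest, mr.TechConfig(**{**cls.QUIET, **overrides}), seed=seed + 2
        )
        beta = mr.run_pipeline(ds, spec, manifest)
        sel = manifest.cpg_ids_of_type("II") if selection == "type2" else manifest.cpg_ids
        sheet = ds.sample_sheet
        out = []
        for _, grp in sheet[sheet["replicate_pair_id"].notna()].groupby("replicate_pair_id"):
            a, b = grp.sort_values("occasion").index
            d = beta.values.loc[sel, a].to_numpy() - beta.values.loc[sel, b].to_numpy()
            out.append((d ** 2).mean())
        return np.mean(out)

    @pytest.mark.parametrize(
        "overrides,spec,selection",
        [
            ({"dye_bias_sd": 0.3}, mr.PipelineSpec(dye="relic"), "type2"),
            ({"bg_mean_red": 2000.0, "bg_mean_green": 2000.0, "bg_array_sd": 0.4},
             mr.PipelineSpec(bg="oob"), "all"),
            ({"type2_compression": 0.8, "type2_compression_sd": 0.1},
             mr.PipelineSpec(probe="rcp"), "type2"),
        ],
        ids=["dye", "background", "probe_type"],
    )
    def test_matching_kernel_removes_injected_replicate_variance(self, overrides, spec,
                                                                 selection):
        """With one artifact class injected, the matching kernel removes >= 90%
        of the between-replicate variance the artifact added (median over seeds)."""
        reductions = []
        for seed in range(0, 200, 10):
            with_art = self._pair_msd(seed, overrides, mr.RAW_SPEC, selection)
            with_kernel = self._pair_msd(seed, overrides, spec, selection)
            baseline = self._pair_msd(seed, {}, mr.RAW_SPEC, selection)
            reductions.append((with_art - with_kernel) / (with_art - baseline))
        assert np.median(reductions) >= 0.9


class TestGrid:
    def test_full_product_size(self):
        specs = mr.enumerate_grid(bg=("none", "oob", "neg"), dye=("none", "mean", "relic"),
                                  norm=("none", "q1", "q2", "q3"), probe=("none", "rcp"))
        assert len(specs) == 72
        labels = [s.label for s in specs]
        assert len(set(labels)) == 72
        assert "raw" in labels

    def test_single_level_axes(self):
        specs = mr.enumerate_grid(bg=["none"], dye=["none"], norm=["none"], probe=["none"])
        assert len(specs) == 1 and specs[0].is_raw

    def test_duplicate_levels_rejected(self):
        with pytest.raises(mr.ParameterError):
            mr.enumerate_grid(bg=["oob", "oob"], dye=["none"], norm=["none"], probe=["none"])
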