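"""Denoising-quality metrics: quality criteria, %dSTD, SNR, epochs."""

import numpy as np
import pytest

from aslica.asl_io import AslAcquisition
from aslica.evaluate import (
    delta_std_map,
    delta_std_probability,
    poor_fit_count,
    quality_criteria,
    repeatability_cov,
    repetition_curve,
    snr_summary,
    split_epochs,
)
from aslica.kinetics import KineticConstants, PerfusionFit
from aslica.preprocess import AslSub


def _sub_with_masks(data, acq, gm, nonbrain, brain=None):
    T = data.shape[3]
    return AslSub(
        data=data,
        acq=acq,
        plds=acq.pld_of_volume(np.arange(T)) if T == acq.n_diff_volumes else np.resize(np.asarray(acq.plds), T),
        gm_mask=gm,
        brain_mask=brain if brain is not None else gm,
        nonbrain_mask=nonbrain,
    )


class TestQualityCriteria:
    GRID = (12, 12, 4)

    def _masks(self):
        gm = np.zeros(self.GRID, bool)
        gm[3:9, 3:9, 1:3] = True
        nonbrain = np.zeros(self.GRID, bool)
        nonbrain[0:2, :, :] = True
        return gm, nonbrain

    def test_constant_signal_against_analytic_values(self, acq):
        gm, nonbrain = self._masks()
        rng = np.random.default_rng(0)
        c, sigma = 5.0, 1.0
        T = acq.n_diff_volumes
        data = np.zeros(self.GRID + (T,))
        data[gm] = c + 0.01 * rng.standard_normal((gm.sum(), T))
        data[nonbrain] = sigma * rng.standard_normal((nonbrain.sum(), T))
        q = quality_criteria(_sub_with_masks(data, acq, gm, nonbrain), gm, nonbrain)
        assert q.tcnr == pytest.approx(c / sigma, rel=0.1)
        assert q.prop_gt_zero == 1.0
        assert q.cov == pytest.approx(0.0, abs=0.01)
        assert q.tsnr > 100

    def test_null_series_rejects_at_alpha_rate(self, acq):
        """Zero-mean noise: the proportion significantly above zero
        calibrates to the nominal alpha = 0.05."""
        gm, nonbrain = self._masks()
        T = acq.n_diff_volumes
        props = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = rng.standard_normal(self.GRID + (T,))
            q = quality_criteria(_sub_with_masks(data, acq, gm, nonbrain), gm, nonbrain)
            props.append(q.prop_gt_zero)
        assert np.mean(props) == pytest.approx(0.05, abs=0.02)

    def test_scale_invariance(self, acq):
        gm, nonbrain = self._masks()
        rng = np.random.default_rng(1)
        data = rng.standard_normal(self.GRID + (acq.n_diff_volumes,)) + 0.3
        sub1 = _sub_with_masks(data, acq, gm, nonbrain)
        sub2 = _sub_with_masks(2.0 * data, acq, gm, nonbrain)
        q1 = quality_criteria(sub1, gm, nonbrain)
        q2 = quality_criteria(sub2, gm, nonbrain)
        np.testing.assert_allclose(q1.as_array(), q2.as_array(), rtol=1e-10)

    def test_empty_masks_rejected(self, acq):
        gm, nonbrain = self._masks()
        data = np.zeros(self.GRID + (acq.n_diff_volumes,))
        sub = _sub_with_masks(data, acq, gm, nonbrain)
        with pytest.raises(ValueError, match="empty"):
            quality_criteria(sub, np.zeros(self.GRID, bool), nonbrain)


class TestDeltaStd:
    def test_identity_denoiser_gives_zero(self, acq, full_noise_dataset):
        sub, _, _ = full_noise_dataset
        np.testing.assert_allclose(delta_std_map(sub, sub), 0.0, atol=1e-5)

    def test_halved_std_reads_fifty_percent(self, acq):
        rng = np.random.default_rng(0)
        grid = (5, 5, 2)
        T = acq.n_diff_volumes
        base = rng.standard_normal(grid + (T,))
        orig = AslSub(data=base, acq=acq, plds=acq.pld_of_volume(np.arange(T)))
        mean = base.mean(axis=3, keepdims=True)
        halved = AslSub(
            data=mean + 0.5 * (base - mean), acq=acq,
            plds=acq.pld_of_volume(np.arange(T)),
        )
        np.testing.assert_allclose(delta_std_map(orig, halved), 50.0, rtol=1e-6)

    def test_matches_voxel_loop_oracle(self, acq):
        rng = np.random.default_rng(1)
        grid = (4, 4, 2)
        T = acq.n_diff_volumes
        a = rng.standard_normal(grid + (T,))
        b = rng.standard_normal(grid + (T,))
        orig = AslSub(data=a, acq=acq, plds=acq.pld_of_volume(np.arange(T)))
        corr = AslSub(data=b, acq=acq, plds=acq.pld_of_volume(np.arange(T)))
        got = delta_std_map(orig, corr)
        for idx in np.ndindex(grid):
            s0 = np.std(a[idx], ddof=1)
            s1 = np.std(b[idx], ddof=1)
            np.testing.assert_allclose(
                got[idx], 100.0 * (s0 - s1) / s0, rtol=1e-10
            )

    def test_probability_map_counts_threshold_exceedances(self):
        maps = [np.full((3, 3, 1), v) for v in (30.0, 30.0, 30.0, 10.0)]
        prob = delta_std_probability(maps, threshold=25.0)
        np.testing.assert_allclose(prob, 0.75)

    def test_probability_default_threshold_is_25(self):
        maps = [np.full((2, 2, 1), 25.0)]
        np.testing.assert_allclose(delta_std_probability(maps), 1.0)

    def test_empty_map_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            delta_std_probability([])


def _fit_from(cbf, sd_cbf, att=None, sd_att=None, converged=None):
    shape = cbf.shape
    att = att if att is not None else np.full(shape, 1.0)
    sd_att = sd_att if sd_att is not None else np.full(shape, 0.1)
    converged = converged if converged is not None else np.ones(shape, bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = cbf / sd_cbf
    return PerfusionFit(
        cbf=cbf, att=att, sd_cbf=sd_cbf, sd_att=sd_att, z=z,
        residual=np.zeros(shape), converged=converged,
    )


class TestSnrSummary:
    def test_constant_maps_closed_form(self):
        shape = (6, 6, 2)
        gm = np.ones(shape, bool)
        fit = _fit_from(np.full(shape, 60.0), np.full(shape, 12.0))
        s = snr_summary(fit, gm)
        assert s["cbf_snr"] == pytest.approx(5.0)
        assert s["cbf_mean"] == pytest.approx(60.0)
        assert s["cbf_variance"] == pytest.approx(144.0)

    def test_doubling_sd_halves_snr_only(self):
        shape = (4, 4, 2)
        gm = np.ones(shape, bool)
        rng = np.random.default_rng(0)
        cbf = rng.uniform(20, 80, shape)
        sd = rng.uniform(5, 15, shape)
        s1 = snr_summary(_fit_from(cbf, sd), gm)
        s2 = snr_summary(_fit_from(cbf, 2 * sd), gm)
        assert s2["cbf_snr"] == pytest.approx(s1["cbf_snr"] / 2)
        assert s2["cbf_mean"] == pytest.approx(s1["cbf_mean"])

    def test_matches_voxel_loop_oracle(self):
        shape = (4, 4, 2)
        rng = np.random.default_rng(1)
        gm = rng.random(shape) > 0.3
        cbf = rng.uniform(20, 80, shape)
        sd = rng.uniform(5, 15, shape)
        att = rng.uniform(0.5, 2.0, shape)
        sd_att = rng.uniform(0.05, 0.3, shape)
        s = snr_summary(_fit_from(cbf, sd, att, sd_att), gm)
        vals = [cbf[i] / sd[i] for i in np.ndindex(shape) if gm[i]]
        np.testing.assert_allclose(s["cbf_snr"], np.mean(vals), rtol=1e-10)
        np.testing.assert_allclose(
            s["att_variance"],
            np.mean([sd_att[i] ** 2 for i in np.ndindex(shape) if gm[i]]),
            rtol=1e-10,
        )

    def test_nonconverged_voxels_excluded(self):
        shape = (3, 3, 1)
        gm = np.ones(shape, bool)
        cbf = np.full(shape, 60.0)
        conv = np.ones(shape, bool)
        conv[0, 0, 0] = False
        cbf[0, 0, 0] = 1e6
        s = snr_summary(_fit_from(cbf, np.full(shape, 10.0), converged=conv), gm)
        assert s["cbf_mean"] == pytest.approx(60.0)
        assert s["n_voxels"] == 8


class TestEpochs:
    def test_six_epochs_of_five_plds(self, acq, full_noise_dataset):
        sub, _, _ = full_noise_dataset
        epochs = split_epochs(sub)
        assert len(epochs) == 6
        for ep in epochs:
            assert ep.n_volumes == 5
            np.testing.assert_array_equal(np.sort(ep.plds), acq.plds)

    def test_concatenated_epochs_permute_the_input(self, full_noise_dataset):
        sub, _, _ = full_noise_dataset
        epochs = split_epochs(sub)
        ids = np.concatenate([ep.volume_ids for ep in epochs])
        assert sorted(ids) == list(range(sub.n_volumes))

    def test_single_repeat_gives_one_epoch(self, phantom):
        acq1 = AslAcquisition(plds=(0.4, 0.8, 1.2, 1.6, 2.0), n_repeats=1)
        data = np.random.default_rng(0).standard_normal(phantom.grid + (5,))
        sub = AslSub(data=data, acq=acq1, plds=np.asarray(acq1.plds))
        epochs = split_epochs(sub)
        assert len(epochs) == 1
        np.testing.assert_array_equal(epochs[0].data, sub.data)

    def test_scrubbed_series_fails_strict_split(self, full_noise_dataset):
        sub, _, _ = full_noise_dataset
        scrubbed = sub.take_volumes(np.arange(1, sub.n_volumes))
        with pytest.raises(ValueError, match="one volume per PLD"):
            split_epochs(scrubbed, strict=True)
        assert len(split_epochs(scrubbed, strict=False)) == 6


class TestRepeatability:
    def test_identical_epochs_give_zero_cov(self, clean_dataset, phantom):
        sub, m0, _ = clean_dataset
        gm = phantom.pve_gm >= 0.7
        cov = repeatability_cov(sub, m0, KineticConstants(), gm)
        assert cov == pytest.approx(0.0, abs=1e-6)

    def test_scaled_epochs_match_hand_calculation(self, phantom):
        """Epoch estimates {50, 60, 70}: CoV = sample std / mean."""
        from tests.conftest import build_subtracted

        acq3 = AslAcquisition(plds=(0.4, 0.8, 1.2, 1.6, 2.0), n_repeats=3)
        sub, m0, _ = build_subtracted(phantom, acq3, noise=[], seed=0)
        scales = np.array([50.0, 60.0, 70.0]) / 60.0
        data = sub.data.copy()
        for r in range(3):
            data[..., r * 5 : (r + 1) * 5] *= scales[r]
        scaled = sub.with_data(data)
        gm = phantom.pve_gm >= 0.999
        cov = repeatability_cov(scaled, m0, KineticConstants(), gm)
        expected = np.std([50.0, 60.0, 70.0], ddof=1) / 60.0
        assert cov == pytest.approx(expected, rel=0.02)


class TestRepetitionCurve:
    def test_rows_cover_six_down_to_two(self, thermal_dataset, phantom):
        sub, m0, _ = thermal_dataset
        gm = phantom.pve_gm >= 0.7
        rows = repetition_curve(sub, m0, KineticConstants(), gm)
        assert [r["n_reps"] for r in rows] == [6, 5, 4, 3, 2]

    def test_retained_volumes_are_first_repetitions(self, thermal_dataset, phantom):
        sub, _, _ = thermal_dataset
        keep = np.where(sub.volume_ids < 3 * 5)[0]
        sub3 = sub.take_volumes(keep)
        assert sub3.n_volumes == 15
        assert set(sub3.volume_ids) == set(range(15))


class TestPoorFitCount:
    def test_no_poor_fits_when_all_z_high(self):
        shape = (4, 4, 1)
        gm = np.ones(shape, bool)
        fit = _fit_from(np.full(shape, 60.0), np.full(shape, 20.0))  # z = 3
        assert poor_fit_count(fit, gm) == 0

    def test_counts_constructed_low_z_voxels(self):
        shape = (5, 5, 1)
        gm = np.ones(shape, bool)
        sd = np.full(shape, 10.0)
        cbf = np.full(shape, 50.0)  # z = 5
        flat = cbf.reshape(-1)
        flat[:7] = 10.0  # z = 1 at exactly 7 voxels
        assert poor_fit_count(_fit_from(cbf, sd), gm) == 7

    def test_boundary_z_of_exactly_two_not_counted(self):
        shape = (3, 3, 1)
        gm = np.ones(shape, bool)
        fit = _fit_from(np.full(shape, 20.0), np.full(shape, 10.0))  # z = 2.0
        assert poor_fit_count(fit, gm) == 0

    def test_nonconverged_count_as_poor(self):
        shape = (3, 3, 1)
        gm = np.ones(shape, bool)
        conv = np.ones(shape, bool)
        conv[0, 0, 0] = False
        fit = _fit_from(
            np.full(shape, 60.0), np.full(shape, 10.0), converged=conv
        )
        assert poor_fit_count(fit, gm) == 1
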