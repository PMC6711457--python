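"""Feature extraction, rating rule, threshold selection, trained classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aslica.asl_io import AslAcquisition, ComponentLabels
from aslica.classify import (
    FEATURE_COLUMNS,
    ComponentClassifier,
    RuleCutoffs,
    extract_features,
    pld_power_baseline,
    predict_labels,
    rule_classify,
    select_threshold,
    train_classifier,
)
from aslica.decompose import IcaDecomposition
from aslica.preprocess import AslSub


def _manual_decomposition(maps, mixing, mask):
    """Build an IcaDecomposition directly from given factors."""
    maps = np.asarray(maps, dtype=float)
    mixing = np.asarray(mixing, dtype=float)
    K = maps.shape[0]
    return IcaDecomposition(
        maps=maps,
        mixing=mixing,
        amplitudes=np.ones(K),
        explained_variance_ratio=np.full(K, 1.0 / K),
        eigenvalues=np.ones(mixing.shape[0]),
        voxel_mean=np.zeros((1, maps.shape[1])),
        volume_mean=np.zeros((mixing.shape[0], 1)),
        mask=mask,
    )


def _dummy_sub(acq, grid=(8, 8, 4), motion=None):
    T = acq.n_diff_volumes
    return AslSub(
        data=np.zeros(grid + (T,)),
        acq=acq,
        plds=acq.pld_of_volume(np.arange(T)),
        motion=motion,
        brain_mask=np.ones(grid, bool),
    )


class TestFeatures:
    def test_pld_locked_waveform_concentrates_power(self, acq):
        """A repeated PLD-block waveform has all its power at the cycle
        fundamental (6 cycles per scan) and its harmonics, and fits the
        block basis perfectly."""
        T = acq.n_diff_volumes
        block = np.array([2.0, 1.0, 0.5, -0.5, -1.5])
        tc = np.tile(block, acq.n_repeats)
        mask = np.ones((8, 8, 4), bool)
        V = mask.sum()
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((1, V))
        dec = _manual_decomposition(maps, tc[:, None], mask)
        sub = _dummy_sub(acq)
        feats = extract_features(dec, sub, acq)
        assert feats.loc[0, "pld_power_ratio"] == pytest.approx(1.0, abs=1e-10)
        assert feats.loc[0, "pld_fit_r2"] == pytest.approx(1.0, abs=1e-10)
        # power sits exactly at bins {6, 12} of the T=30 periodogram
        p = np.abs(np.fft.rfft(tc - tc.mean())) ** 2
        hot = np.where(p[1:] > 1e-10 * p[1:].max())[0] + 1
        assert set(hot) <= {6, 12}

    def test_white_noise_power_ratio_near_exchangeability_baseline(self, acq):
        T = acq.n_diff_volumes
        mask = np.ones((6, 6, 2), bool)
        rng = np.random.default_rng(1)
        sub = _dummy_sub(acq, grid=(6, 6, 2))
        ratios = []
        for _ in range(100):
            tc = rng.standard_normal(T)
            dec = _manual_decomposition(
                rng.standard_normal((1, mask.sum())), tc[:, None], mask
            )
            ratios.append(
                extract_features(dec, sub, acq).loc[0, "pld_power_ratio"]
            )
        baseline = pld_power_baseline(T, acq.n_repeats)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - baseline) < max(3 * se, 0.02)

    def test_map_on_gm_mask_has_full_overlap(self, acq):
        grid = (8, 8, 4)
        mask = np.ones(grid, bool)
        gm = np.zeros(grid, bool)
        gm[2:6, 2:6, 1:3] = True
        edge = np.zeros(grid, bool)
        edge[0, :, :] = True
        m = np.where(gm, 5.0, 0.01)[mask]
        dec = _manual_decomposition(
            m[None, :], np.random.default_rng(2).standard_normal((30, 1)), mask
        )
        sub = _dummy_sub(acq)
        feats = extract_features(dec, sub, acq, gm_mask=gm, edge_mask=edge)
        assert feats.loc[0, "gm_overlap"] == pytest.approx(1.0)
        assert feats.loc[0, "edge_frac"] == 0.0

    def test_motion_correlation_detects_matching_trace(self, acq):
        T = acq.n_diff_volumes
        rng = np.random.default_rng(3)
        tc = rng.standard_normal(T)
        motion = rng.standard_normal((T, 6)) * 0.01
        motion[:, 2] = tc * 0.5
        mask = np.ones((6, 6, 2), bool)
        dec = _manual_decomposition(
            rng.standard_normal((1, mask.sum())), tc[:, None], mask
        )
        sub = _dummy_sub(acq, grid=(6, 6, 2), motion=motion)
        feats = extract_features(dec, sub, acq)
        assert feats.loc[0, "motion_corr"] > 0.99

    def test_indivisible_volume_count_rejected(self, acq):
        bad_acq = AslAcquisition(plds=(0.4, 0.8, 1.2, 1.6), n_repeats=6)
        mask = np.ones((6, 6, 2), bool)
        dec = _manual_decomposition(
            np.zeros((1, mask.sum())), np.zeros((30, 1)), mask
        )
        sub = _dummy_sub(acq, grid=(6, 6, 2))
        with pytest.raises(ValueError, match="divisible"):
            extract_features(dec, sub, bad_acq)


class TestRuleClassify:
    @staticmethod
    def _frame(gm=0.0, edge=1.0, r2=0.0, power=0.0):
        df = pd.DataFrame(
            [
                {
                    "gm_overlap": gm,
                    "edge_frac": edge,
                    "csf_frac": 0.0,
                    "pld_power_ratio": power,
                    "pld_fit_r2": r2,
                    "motion_corr": 0.0,
                    "spike_score": 1.0,
                    "spectral_entropy": 0.5,
                }
            ]
        )
        df.attrs["pld_power_baseline"] = 2 / 15
        return df

    def test_all_three_criteria_give_signal(self):
        f = self._frame(gm=0.9, edge=0.0, r2=0.9, power=0.9)
        assert rule_classify(f).labels == ["signal"]

    def test_single_criterion_gives_noise(self):
        f = self._frame(power=0.9)  # only C
        assert rule_classify(f).labels == ["noise"]

    def test_two_criteria_suffice(self):
        f = self._frame(gm=0.9, edge=0.0, power=0.9)  # A and C
        assert rule_classify(f).labels == ["signal"]

    @settings(max_examples=50, deadline=None)
    @given(
        gm=st.floats(0, 1),
        edge=st.floats(0, 1),
        r2=st.floats(0, 1),
        power=st.floats(0, 1),
        bump=st.floats(0, 0.5),
        which=st.sampled_from(["gm_overlap", "pld_fit_r2", "pld_power_ratio"]),
    )
    def test_monotone_in_signal_evidence(self, gm, edge, r2, power, bump, which):
        """Raising GM overlap, block-fit R2 or PLD power never flips
        signal to noise."""
        f = self._frame(gm=gm, edge=edge, r2=r2, power=power)
        before = rule_classify(f).labels[0]
        f2 = f.copy()
        f2.attrs["pld_power_baseline"] = f.attrs["pld_power_baseline"]
        f2.loc[0, which] = min(f2.loc[0, which] + bump, 1.0)
        after = rule_classify(f2).labels[0]
        assert not (before == "signal" and after == "noise")

    def test_explicit_power_cutoff_overrides_factor(self):
        f = self._frame(gm=0.9, edge=0.0, power=0.35)
        strict = RuleCutoffs(power=0.9)
        lax = RuleCutoffs(power=0.1)
        assert rule_classify(f, strict).labels == ["noise"]
        assert rule_classify(f, lax).labels == ["signal"]


class TestSelectThreshold:
    def test_separable_case(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        truth = ComponentLabels(labels=["signal", "signal", "noise", "noise"])
        thr, tpr, tnr, flagged = select_threshold(probs, truth, 0.90)
        assert 0.2 < thr <= 0.8
        assert tpr == 1.0 and tnr == 1.0 and not flagged

    def test_matches_brute_force_over_random_sets(self):
        """Exhaustive scan over every threshold in [0,1] is the oracle."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 30)
            probs = rng.random(n)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            thr, tpr, tnr, flagged = select_threshold(probs, y, 0.90)
            # oracle: evaluate every distinct decision rule
            grid = np.concatenate([[0.0], np.sort(np.unique(probs)), [1.0]])
            cand = np.concatenate([grid, (grid[:-1] + grid[1:]) / 2])
            best_tnr, best_found = -1.0, False
            for c in cand:
                pred = probs >= c
                t = (pred & (y == 1)).sum() / (y == 1).sum()
                u = (~pred & (y == 0)).sum() / (y == 0).sum()
                if t > 0.90:
                    best_found = True
                    best_tnr = max(best_tnr, u)
            if best_found:
                assert not flagged
                assert tnr == pytest.approx(best_tnr)
                assert tpr > 0.90
            else:
                assert flagged

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        probs = rng.random(20)
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 0, 1
        _, tpr1, tnr1, _ = select_threshold(probs, y, 0.90)
        squashed = probs**3  # strictly monotone
        _, tpr2, tnr2, _ = select_threshold(squashed, y, 0.90)
        assert (tpr1, tnr1) == (tpr2, tnr2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_threshold(np.array([]), np.array([]), 0.9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            select_threshold(np.array([0.5, 0.6]), np.array([1, 1]), 0.9)


def _toy_training(rng, n_subjects=4, n_per=10, flip=0.0):
    """Linearly separable toy corpus over two informative features."""
    sets = []
    for s in range(n_subjects):
        y = rng.integers(0, 2, n_per)
        y[:2] = [0, 1]
        X = pd.DataFrame(0.0, index=range(n_per), columns=FEATURE_COLUMNS)
        X["pld_power_ratio"] = y * 0.8 + 0.1 + rng.normal(0, 0.02, n_per)
        X["gm_overlap"] = y * 0.6 + 0.2 + rng.normal(0, 0.02, n_per)
        X["spectral_entropy"] = rng.random(n_per)
        yy = y.copy()
        if flip:
            swap = rng.random(n_per) < flip
            yy[swap] = 1 - yy[swap]
        labels = ComponentLabels(
            labels=["signal" if v else "noise" for v in yy]
        )
        sets.append((X, labels, f"subj{s}"))
    return sets


class TestTrainedClassifier:
    def test_separable_corpus_reaches_perfect_loso_rates(self):
        rng = np.random.default_rng(0)
        model = train_classifier(_toy_training(rng))
        assert model.loso_tpr_ == 1.0 and model.loso_tnr_ == 1.0
        assert not model.threshold_flagged_
        assert 0 < model.threshold_ < 1

    def test_shuffled_labels_give_chance_accuracy(self):
        """Permutation null: destroying the feature-label link drops
        held-out accuracy to ~0.5."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sets = _toy_training(rng, n_subjects=4, n_per=16)
            # shuffle labels within each subject
            shuffled = []
            for X, labels, sid in sets:
                lab = list(labels.labels)
                rng.shuffle(lab)
                shuffled.append((X, ComponentLabels(labels=lab), sid))
            model = train_classifier(shuffled[:3])
            Xh, labh, _ = shuffled[3]
            pred = model.predict(Xh)
            accs.append(np.mean(pred == labh.as_binary()))
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_duplicating_rows_leaves_decision_function_unchanged(self):
        rng = np.random.default_rng(1)
        sets = _toy_training(rng)
        X = pd.concat([s[0] for s in sets], ignore_index=True)
        y = np.concatenate([s[1].as_binary() for s in sets])
        g = np.concatenate([[s[2]] * len(s[1]) for s in sets])
        a = ComponentClassifier(C=1e6).fit(X, y, groups=g)
        X2 = pd.concat([X, X], ignore_index=True)
        b = ComponentClassifier(C=1e6).fit(
            X2, np.tile(y, 2), groups=np.tile(g, 2)
        )
        pa = a.predict_proba(X)
        pb = b.predict_proba(X)
        np.testing.assert_allclose(pa, pb, atol=1e-6)

    def test_single_class_training_rejected(self):
        X = pd.DataFrame(0.0, index=range(6), columns=FEATURE_COLUMNS)
        with pytest.raises(ValueError, match="both classes"):
            ComponentClassifier().fit(X, np.ones(6, dtype=int))

    def test_fewer_than_two_subjects_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="2 subjects"):
            train_classifier(_toy_training(rng, n_subjects=1))

    def test_probability_at_threshold_is_signal(self):
        rng = np.random.default_rng(3)
        model = train_classifier(_toy_training(rng))
        X = _toy_training(np.random.default_rng(4))[0][0]
        probs = model.predict_proba(X)
        model.threshold_ = float(probs[0])  # force the boundary case
        assert model.predict(X)[0] == 1

    def test_empty_component_list_predicts_empty(self):
        rng = np.random.default_rng(5)
        model = train_classifier(_toy_training(rng))
        empty = pd.DataFrame(columns=FEATURE_COLUMNS, dtype=float)
        assert len(predict_labels(model, empty)) == 0

    def test_json_round_trip_preserves_decisions(self, tmp_path):
        rng = np.random.default_rng(6)
        model = train_classifier(_toy_training(rng))
        model.to_json(tmp_path / "model.json")
        back = ComponentClassifier.from_json(tmp_path / "model.json")
        X = _toy_training(np.random.default_rng(7))[0][0]
        np.testing.assert_allclose(
            model.predict_proba(X), back.predict_proba(X), atol=1e-10
        )
        assert back.threshold_ == model.threshold_
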