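"""Cross-validation guard, metrics, spectral statistics, cohort stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frustmi import (
    CANONICAL_BANDS,
    ModelConfig,
    SignalRecord,
    aggregate_cohort,
    band_psd_ttest,
    confusion_metrics,
    crossval,
    evoked_spectrum,
    paired_tests,
    rm_anova,
    score_resilience,
    separability_metrics,
    stratified_trial_folds,
)
from frustmi.evaluate import band_power
from frustmi.fbcsp import FilterBankSpec

from helpers import make_windowset

FAST_CFG = ModelConfig(seed=0, backend="lda", n_pairs=1,
                       bank=FilterBankSpec(((8.0, 12.0), (16.0, 24.0))))


class TestLeakageGuard:
    def test_same_trial_windows_share_fold(self):
        ws = make_windowset(n_trials=15, windows_per_trial=4)
        report = crossval(ws, FAST_CFG, task="mi", k=5, seed=1)
        trial_ids = np.asarray([str(t) for t in ws.trial_id])
        for t in set(trial_ids):
            assert t in report.fold_of_trial

    def test_fold_partition_stratified(self):
        labels = {f"t{i:03d}": ("left" if i % 2 == 0 else "right") for i in range(20)}
        folds = stratified_trial_folds(np.array(list(labels)), labels, 5, seed=0)
        assert set(folds.values()) == set(range(5))
        for fold in range(5):
            members = [t for t, f in folds.items() if f == fold]
            n_left = sum(labels[t] == "left" for t in members)
            assert abs(n_left - (len(members) - n_left)) <= 1

    def test_too_few_trials_rejected(self):
        ws = make_windowset(n_trials=4)
        with pytest.raises(ValueError, match="folds|trials"):
            crossval(ws, FAST_CFG, task="mi", k=5, seed=0)

    def test_random_labels_score_at_chance(self):
        """Null calibration: unguessable labels give accuracy inside the
        binomial 95% band around 50%."""
        gen = np.random.default_rng(8)
        ws = make_windowset(n_trials=30, windows_per_trial=3, seed=8,
                            labeler=lambda i: str(gen.choice(["left", "right"])))
        report = crossval(ws, FAST_CFG, task="mi", k=5, seed=8)
        n_trials = 30  # windows within a trial are correlated; n = trials
        half_width = 1.96 * np.sqrt(0.25 / n_trials)
        assert abs(report.mean_accuracy - 0.5) <= half_width + 0.05

    def test_memorizer_exposes_guard_effect(self):
        """A nearest-neighbour memorizer looks perfect when sibling windows
        leak across the split, but drops to chance under the trial guard."""
        from sklearn.neighbors import KNeighborsClassifier

        class Memorizer:
            def __init__(self, cfg):
                self.knn = KNeighborsClassifier(n_neighbors=1)

            def fit(self, windows, labels, covs=None):
                self.knn.fit(windows.reshape(len(windows), -1), labels)
                return self

            def predict(self, windows, covs=None):
                return self.knn.predict(windows.reshape(len(windows), -1))

        # overlapping sibling windows: same trial -> nearly identical content
        gen = np.random.default_rng(3)
        n_trials, wpt = 20, 4
        windows, trial_ids, mi = [], [], []
        for i in range(n_trials):
            base = gen.normal(size=(2, 400))
            label = str(gen.choice(["left", "right"]))
            for w in range(wpt):
                jittered = base + gen.normal(0, 0.01, size=base.shape)
                windows.append(jittered)
                trial_ids.append(f"t{i:03d}")
                mi.append(label)
        from frustmi import WindowSet

        ws = WindowSet(
            windows=np.stack(windows), mi_label=np.array(mi, dtype=object),
            state_label=np.full(len(mi), "none", dtype=object),
            subject_id=np.full(len(mi), "S01", dtype=object),
            trial_id=np.array(trial_ids, dtype=object),
            window_len=400, step=100, rate=250.0,
        )
        guarded = crossval(ws, FAST_CFG, task="mi", k=5, seed=3,
                           pipeline_factory=Memorizer)
        unguarded = crossval(ws, FAST_CFG, task="mi", k=5, seed=3,
                             pipeline_factory=Memorizer, guard=False)
        assert unguarded.mean_accuracy > 0.95
        assert guarded.mean_accuracy < 0.75


class TestConfusionMetrics:
    def test_identity_matrix_perfect(self):
        out = confusion_metrics(np.eye(3) * 10)
        assert np.allclose(out["precision"], 100.0)
        assert np.allclose(out["recall"], 100.0)

    def test_uniform_matrix_one_third(self):
        out = confusion_metrics(np.full((3, 3), 5.0))
        assert np.allclose(out["precision"], 100 / 3)
        assert np.allclose(out["recall"], 100 / 3)

    def test_cohort_confusion_equal_prior_precision(self):
        """Row-normalized cohort matrix: low-class precision is its diagonal
        share of the predicted-low column (equal priors)."""
        from frustmi.datasets import reference_state_confusion

        cm = reference_state_confusion()
        out = confusion_metrics(cm, classes=["low", "mid", "high"])
        assert out.loc["low", "precision"] == pytest.approx(100 * 88.1 / 101.6, abs=1e-9)
        assert round(out.loc["low", "precision"], 1) == 86.7
        assert out.loc["low", "recall"] == pytest.approx(88.1)

    def test_empty_column_flagged_not_nan_propagated(self):
        cm = np.array([[10.0, 0.0], [5.0, 0.0]])
        out = confusion_metrics(cm, classes=["a", "b"])
        assert bool(out.loc["b", "precision_defined"]) is False
        assert bool(out.loc["a", "precision_defined"]) is True
        assert np.isfinite(out.loc["a", "precision"])


class TestBandStats:
    def test_toy_vectors_match_pooled_variance_formula(self):
        """The two-sample statistic follows the textbook pooled-variance
        formula: A=[1,2,3] vs B=[2,3,4] gives t = -1.225."""
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        t, _ = stats.ttest_ind(a, b, equal_var=True)  # same path band stats use
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_manual)
        assert t == pytest.approx(-1.2247, abs=1e-4)

    def test_gamma_boost_gives_negative_t_growing_with_n(self, rng):
        results = {}
        for n in (10, 40):
            a = rng.normal(size=(n, 2, 500))
            boost = rng.normal(size=(n, 2, 500))
            from scipy.signal import butter, sosfiltfilt

            sos = butter(4, (30, 45), btype="band", fs=250.0, output="sos")
            b = a + 0.8 * sosfiltfilt(sos, boost, axis=-1)
            bs = band_psd_ttest(a, b, rate=250.0)
            results[n] = bs.t("Gamma")
            # arithmetic oracle on the extracted band powers
            pa = band_power(a, 250.0, CANONICAL_BANDS["Gamma"])
            pb = band_power(b, 250.0, CANONICAL_BANDS["Gamma"])
            t_manual, _ = stats.ttest_ind(pa, pb, equal_var=True)
            assert bs.t("Gamma") == pytest.approx(t_manual)
        assert results[10] < 0 and results[40] < 0
        assert abs(results[40]) > abs(results[10])

    def test_null_groups_small_t(self, rng):
        a = rng.normal(size=(20, 2, 500))
        b = rng.normal(size=(20, 2, 500))
        bs = band_psd_ttest(a, b, rate=250.0)
        assert np.all(np.abs(bs.table["t"]) < 4)

    def test_single_window_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 windows"):
            band_psd_ttest(rng.normal(size=(1, 2, 500)),
                           rng.normal(size=(5, 2, 500)), rate=250.0)


class TestEvokedSpectrum:
    def _record(self, amp=10.0, seconds=4.0, rate=250.0):
        t = np.arange(int(rate * seconds)) / rate
        return SignalRecord(amp * np.sin(2 * np.pi * 10 * t)[None], rate, ["Oz"])

    def test_single_record_zero_std(self):
        freqs, mean_db, std_db = evoked_spectrum([self._record()], "Oz")
        assert np.allclose(std_db, 0)

    def test_peak_at_10hz(self):
        freqs, mean_db, _ = evoked_spectrum([self._record()], "Oz")
        assert freqs[np.argmax(mean_db)] == pytest.approx(10.0, abs=1.0)

    def test_doubling_amplitude_adds_6db(self):
        f1, m1, _ = evoked_spectrum([self._record(amp=10)], "Oz")
        f2, m2, _ = evoked_spectrum([self._record(amp=20)], "Oz")
        peak = np.argmax(m1)
        assert m2[peak] - m1[peak] == pytest.approx(20 * np.log10(2), abs=0.1)

    def test_unknown_channel(self):
        with pytest.raises(KeyError):
            evoked_spectrum([self._record()], "Fz")


class TestCohortStats:
    def test_singleton(self):
        mean, std = aggregate_cohort([42.0])
        assert mean == 42.0 and std == 0.0

    def test_permutation_invariant(self, rng):
        vals = rng.normal(70, 5, 12)
        a, b = aggregate_cohort(vals), aggregate_cohort(vals[::-1])
        assert a == pytest.approx(b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cohort([])

    def test_paired_equal_vectors(self):
        res = paired_tests([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.t_stat == 0.0 and res.t_p == 1.0 and res.degenerate

    def test_paired_constant_shift(self):
        a = np.array([60.0, 65.0, 70.0, 75.0, 80.0])
        res = paired_tests(a + 5, a)
        assert res.t_p < 1e-6
        assert res.degenerate and res.t_stat == np.inf

    def test_paired_sign_flip_symmetry(self, rng):
        a = rng.normal(70, 5, 8)
        b = a + rng.normal(2, 1, 8)
        r1 = paired_tests(a, b)
        r2 = paired_tests(b, a)
        assert r1.t_stat == pytest.approx(-r2.t_stat)
        assert r1.t_p == pytest.approx(r2.t_p)


class TestRMAnova:
    def test_identical_columns_f_zero(self):
        mat = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        f, p = rm_anova(mat)
        assert f == 0.0 and p == 1.0

    def test_large_offsets_significant(self, rng):
        base = rng.normal(0, 0.1, (10, 3))
        mat = base + np.array([0.0, 5.0, 10.0])
        _, p = rm_anova(mat)
        assert p < 0.01

    def test_matches_manual_sum_of_squares(self):
        """3 x 3 integer table against hand-computed one-way RM ANOVA."""
        mat = np.array([[1.0, 2.0, 5.0], [2.0, 4.0, 6.0], [3.0, 3.0, 7.0]])
        n, k = mat.shape
        grand = mat.mean()
        ss_cond = n * np.sum((mat.mean(axis=0) - grand) ** 2)
        ss_subj = k * np.sum((mat.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((mat - grand) ** 2)
        ss_err = ss_tot - ss_cond - ss_subj
        f_manual = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        f, p = rm_anova(mat)
        assert f == pytest.approx(f_manual)
        p_manual = 1 - stats.f.cdf(f_manual, k - 1, (k - 1) * (n - 1))
        assert p == pytest.approx(p_manual)

    def test_missing_cells_rejected(self):
        mat = np.array([[1.0, np.nan, 3.0], [2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="missing"):
            rm_anova(mat)


class TestSeparability:
    def test_point_clusters_distance_and_flag(self):
        x = np.array([[0.0, 0.0]] * 3 + [[3.0, 4.0]] * 3)
        y = np.array(["a"] * 3 + ["b"] * 3)
        out = separability_metrics(x, y, seed=0, cv=2)
        assert out["centroid_distances"]["a-b"] == pytest.approx(5.0)
        assert out["separated"] and np.isinf(out["fisher_ratio"])

    def test_overlapping_clusters_probe_at_chance(self, rng):
        x = rng.normal(size=(200, 2))
        y = np.array(["a", "b"] * 100)
        out = separability_metrics(x, y, seed=0)
        assert abs(out["probe_accuracy"] - 0.5) < 0.12

    def test_gaussian_centroids_match_analytic(self, rng):
        means = {"a": np.array([0.0, 0.0]), "b": np.array([4.0, 0.0]),
                 "c": np.array([0.0, 3.0])}
        pts, labs = [], []
        for lab, m in means.items():
            pts.append(rng.normal(m, 0.2, size=(100, 2)))
            labs += [lab] * 100
        out = separability_metrics(np.concatenate(pts), np.array(labs), seed=0)
        assert out["centroid_distances"]["a-b"] == pytest.approx(4.0, abs=0.1)
        assert out["centroid_distances"]["a-c"] == pytest.approx(3.0, abs=0.1)
        assert out["centroid_distances"]["b-c"] == pytest.approx(5.0, abs=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            separability_metrics(np.zeros((4, 2)), np.array(["a"] * 4))


class TestResilienceScore:
    @pytest.mark.parametrize(
        "fill,expected_score,expected_cat",
        [(7, 175, "high"), (1, 25, "general")],
    )
    def test_extremes(self, fill, expected_score, expected_cat):
        score, cat = score_resilience([fill] * 25)
        assert (score, cat) == (expected_score, expected_cat)

    def test_boundary_146_high_145_general(self):
        items_146 = [6] * 21 + [5] * 4  # 126 + 20 = 146
        assert sum(items_146) == 146
        assert score_resilience(items_146) == (146, "high")
        items_145 = [6] * 20 + [5] * 5
        assert sum(items_145) == 145
        assert score_resilience(items_145) == (145, "general")

    @pytest.mark.parametrize("items", [[5] * 24, [5] * 26, [5] * 24 + [8], [5] * 24 + [0]])
    def test_validation(self, items):
        with pytest.raises(ValueError):
            score_resilience(items)
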