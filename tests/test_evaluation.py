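"""ROC/AUC, bootstrap, rank correlation, survival curves, and heatmaps."""

import numpy as np
import pandas as pd
import pytest

from piter.evaluation import (
    SurvivalRecord,
    bootstrap_ci,
    evaluate_cohort,
    heatmap_from_csv,
    heatmap_to_csv,
    km_estimate,
    logrank_test,
    render_heatmap,
    roc_auc,
    spearman_rho,
)


def pair_count_auc(scores, labels):
    """Mann-Whitney oracle: correctly ordered (pos, neg) pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_four_pair_example(self):
        assert roc_auc([0.8, 0.6, 0.7, 0.2], [1, 1, 0, 0]).auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-9)

    def test_shuffled_labels_average_half(self, rng):
        scores = rng.random(100)
        labels = np.array([0] * 50 + [1] * 50)
        aucs = []
        for _ in range(1000):
            rng.shuffle(labels)
            aucs.append(roc_auc(scores, labels).auc)
        assert 0.48 <= np.mean(aucs) <= 0.52


class TestBootstrap:
    def test_constant_data_zero_width(self):
        data = np.full(10, 3.5)
        ci = bootstrap_ci(data, np.mean, n_replicates=200, seed=0)
        assert ci.lower == ci.upper == ci.point_estimate == 3.5

    def test_seed_reproducibility(self, rng):
        data = rng.normal(size=25)
        a = bootstrap_ci(data, np.mean, n_replicates=500, seed=7)
        b = bootstrap_ci(data, np.mean, n_replicates=500, seed=7)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_endpoints_are_order_statistics(self, rng):
        data = rng.normal(size=30)
        ci = bootstrap_ci(data, np.mean, n_replicates=999, seed=3)
        # nearest-rank convention: endpoints are actual replicate values
        assert ci.lower <= ci.point_estimate <= ci.upper

    def test_degenerate_resamples_redrawn(self, rng):
        """An AUC statistic is undefined on one-class resamples; those are
        redrawn rather than propagated."""
        data = np.column_stack([rng.random(6), [1, 0, 0, 0, 0, 0]])

        def stat(a):
            if len(np.unique(a[:, 1])) < 2:
                raise ValueError("one class")
            return roc_auc(a[:, 0], a[:, 1]).auc

        ci = bootstrap_ci(data, stat, n_replicates=100, seed=0)
        assert ci.n_redrawn > 0
        assert np.isfinite([ci.lower, ci.upper]).all()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]), np.mean)


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([1.0, 2.5, 3.0, 7.0, 11.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tied_example_matches_midrank_pearson(self):
        x = [1, 2, 2, 4]
        y = [3, 1, 4, 4]

        def midranks(v):
            v = np.asarray(v, float)
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


def rec(pid, t, e, g="high"):
    return SurvivalRecord(patient_id=pid, time=t, event=e, group=g)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """times [2,4,6], events [1,0,1]: S(2)=2/3, censor at 4, S(6)=0."""
        curves = km_estimate([rec("a", 2, 1), rec("b", 4, 0), rec("c", 6, 1)])
        sf = curves["high"].set_index("time")["survival"]
        assert sf.loc[2.0] == pytest.approx(2 / 3)
        assert sf.loc[4.0] == pytest.approx(2 / 3)
        assert sf.loc[6.0] == pytest.approx(0.0)

    def test_no_events_stays_at_one(self):
        curves = km_estimate([rec(f"p{i}", 10 + i, 0) for i in range(5)])
        assert (curves["high"]["survival"] == 1.0).all()

    def test_all_events_steps_through_quarters(self):
        curves = km_estimate([rec(f"p{i}", t, 1) for i, t in enumerate([1, 2, 3, 4])])
        sf = curves["high"]["survival"].tolist()
        assert sf[-4:] == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 30, size=12).astype(float)
        curves = km_estimate([rec(f"p{i}", t, 1) for i, t in enumerate(times)])
        sf = curves["high"].set_index("time")["survival"]
        for t in np.unique(times):
            assert sf.loc[t] == pytest.approx((times > t).mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        recs = [rec("a", 5, 1, "high"), rec("b", 8, 0, "high"),
                rec("c", 5, 1, "low"), rec("d", 8, 0, "low")]
        chi2, p = logrank_test(recs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_observed_minus_expected(self):
        """Group A events at 1,2; group B events at 3,4.  O-E tabulation:
        t=1: n=4, nA=2, E_A=1/2; t=2: n=3, nA=1, E_A=1/3;
        t=3: n=2, nA=0, E_A=0;   t=4: n=1, nA=0, E_A=0.
        O_A - E_A = 2 - 5/6; V = sum of hypergeometric variances."""
        recs = [rec("a1", 1, 1, "A"), rec("a2", 2, 1, "A"),
                rec("b1", 3, 1, "B"), rec("b2", 4, 1, "B")]
        chi2, _ = logrank_test(recs)
        o_minus_e = 2 - (0.5 + 1 / 3)
        var = (2 * 2) / (4 * 4 * 3) * 1 * 3 + (1 * 2) / (3 * 3 * 2) * 1 * 2
        assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-9)

    def test_group_swap_symmetric(self):
        recs = [rec("a", 2, 1, "A"), rec("b", 9, 1, "A"),
                rec("c", 4, 1, "B"), rec("d", 7, 0, "B")]
        chi2a, _ = logrank_test(recs)
        swapped = [rec(r.patient_id, r.time, r.event, "B" if r.group == "A" else "A")
                   for r in recs]
        chi2b, _ = logrank_test(swapped)
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_no_events_rejected(self):
        recs = [rec("a", 2, 0, "A"), rec("b", 3, 0, "B")]
        with pytest.raises(ValueError):
            logrank_test(recs)


class TestHeatmap:
    def test_single_patch_grid(self, tmp_path):
        preds = pd.DataFrame({"x": [0], "y": [0], "p_tmb_high": [0.9]})
        grid = render_heatmap(preds, (1024, 1024), 512)
        assert grid.shape == (2, 2)
        assert grid[0, 0] == pytest.approx(0.9)
        assert np.isnan(grid).sum() == 3

    def test_grid_dimensions_ceil(self):
        preds = pd.DataFrame({"x": [0], "y": [0], "p_tmb_high": [0.5]})
        grid = render_heatmap(preds, (1100, 700), 512)
        assert grid.shape == (2, 3)  # ceil(700/512) x ceil(1100/512)

    def test_overlap_averaged_with_warning(self):
        preds = pd.DataFrame({"x": [0, 10], "y": [0, 10], "p_tmb_high": [0.2, 0.8]})
        with pytest.warns(UserWarning):
            grid = render_heatmap(preds, (512, 512), 512)
        assert grid[0, 0] == pytest.approx(0.5)

    def test_out_of_bounds_rejected(self):
        preds = pd.DataFrame({"x": [2000], "y": [0], "p_tmb_high": [0.5]})
        with pytest.raises(ValueError):
            render_heatmap(preds, (1024, 1024), 512)

    def test_csv_round_trip(self, tmp_path):
        preds = pd.DataFrame({"x": [0, 512], "y": [0, 512], "p_tmb_high": [0.25, 0.75]})
        grid = render_heatmap(preds, (1024, 1024), 512)
        heatmap_to_csv(grid, tmp_path / "g.csv")
        back = heatmap_from_csv(tmp_path / "g.csv")
        np.testing.assert_allclose(grid, back, equal_nan=True)


class TestEvaluateCohort:
    def make_inputs(self, rng, with_survival=True):
        n = 30
        labels = np.array([0, 1] * (n // 2))
        scores = np.clip(labels * 0.4 + rng.normal(0.3, 0.15, n), 0, 1)
        manifest = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "slide_id": [f"P{i}S0" for i in range(n)],
            "cohort": "t",
            "split": "val",
            "tmb_value": labels * 20 + rng.uniform(0, 9, n),
            "tmb_class": np.where(labels == 1, "high", "low"),
            "surv_time_days": rng.integers(30, 900, n) if with_survival else "",
            "surv_event": rng.integers(0, 2, n) if with_survival else "",
        })
        frame = pd.DataFrame({"patient_id": manifest["patient_id"],
                              "piter_score": scores})
        return frame, manifest

    def test_report_fields_and_survival(self, rng):
        frame, manifest = self.make_inputs(rng)
        report = evaluate_cohort(frame, manifest, cutoff=0.5, n_bootstrap=200, seed=0)
        for key in ("auc", "auc_ci_low", "auc_ci_high", "rho",
                    "sensitivity", "specificity", "logrank_chi2", "logrank_p"):
            assert key in report
        assert report["auc_ci_low"] <= report["auc"] <= report["auc_ci_high"]

    def test_rank_invariance(self, rng):
        frame, manifest = self.make_inputs(rng, with_survival=False)
        r1 = evaluate_cohort(frame, manifest, n_bootstrap=100, seed=1)
        ranked = frame.copy()
        ranked["piter_score"] = frame["piter_score"].rank()
        r2 = evaluate_cohort(ranked, manifest, n_bootstrap=100, seed=1)
        assert r1["auc"] == pytest.approx(r2["auc"], abs=1e-12)
        assert r1["rho"] == pytest.approx(r2["rho"], abs=1e-12)

    def test_minus_infinity_cutoff_calls_everyone_high(self, rng):
        frame, manifest = self.make_inputs(rng, with_survival=False)
        report = evaluate_cohort(frame, manifest, cutoff=-np.inf, n_bootstrap=100, seed=0)
        assert report["sensitivity"] == 1.0
        assert report["specificity"] == 0.0

    def test_missing_label_columns_rejected(self, rng):
        frame, manifest = self.make_inputs(rng, with_survival=False)
        with pytest.raises(ValueError, match="tmb_class"):
            evaluate_cohort(frame, manifest.drop(columns=["tmb_class"]))
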