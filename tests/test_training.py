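"""Training recipe: losses, schedule, augmentation, batch sampling, and the
end-to-end loop."""

import math

import numpy as np
import pytest

from piter.data import PatchBag, cohort_to_bags
from piter.nn import BackboneSpec, build_model
from piter.synth import SynthConfig, generate_cohort
from piter.training import (
    TrainingConfig,
    advcs_loss,
    augment_patch,
    cosine_lr,
    cross_entropy,
    sample_batch,
    train,
)


class TestLosses:
    def test_binary_coin_flip_is_ln2(self):
        assert cross_entropy([0.5, 0.5], 0) == pytest.approx(math.log(2), abs=1e-9)
        assert cross_entropy([0.5, 0.5], 1) == pytest.approx(math.log(2), abs=1e-9)

    def test_uniform_over_n_slides_is_ln_n(self):
        probs = np.full(20, 1 / 20)
        assert cross_entropy(probs, 7) == pytest.approx(math.log(20), abs=1e-9)
        assert cross_entropy(probs, 7) == pytest.approx(2.9957, abs=1e-4)

    def test_certain_prediction_is_zero(self):
        p = np.zeros(3)
        p[2] = 1.0
        assert cross_entropy(p, 2) == 0.0

    def test_out_of_range_target(self):
        with pytest.raises(ValueError):
            cross_entropy([0.5, 0.5], 2)

    def test_advcs_total_arithmetic(self):
        total = advcs_loss([0.5, 0.5], 0, np.full(20, 0.05), 3, alpha=0.5)
        assert total == pytest.approx(0.6931 + 0.5 * 2.9957, abs=1e-3)

    def test_alpha_zero_is_task_only(self):
        total = advcs_loss([0.5, 0.5], 0, None, None, alpha=0.0)
        assert total == pytest.approx(math.log(2), abs=1e-9)

    def test_alpha_positive_requires_confounder(self):
        with pytest.raises(ValueError):
            advcs_loss([0.5, 0.5], 0, None, None, alpha=1.0)


class TestReversalDirection:
    def test_backbone_gradient_equals_minus_alpha_times_unreversed(self, rng):
        """The confounder term's gradient into a backbone weight equals
        -lambda * alpha * dCE_conf/dw, checked by finite differences."""
        spec = BackboneSpec(input_px=16, representation_dim=6, channels=(4,))
        alpha, lam = 0.7, 1.0
        model = build_model(spec, 2, 4, lam=lam, seed=2)
        x = rng.integers(0, 256, size=(3, 16, 16, 3), dtype=np.uint8)
        targets = np.array([1, 0, 2])

        def conf_ce():
            _, logits, _ = model.forward(x)
            z = logits - logits.max(axis=1, keepdims=True)
            ls = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            return float(-np.mean(ls[np.arange(3), targets]))

        # analytic gradient through the reversal
        _, conf_logits, _ = model.forward(x, train=True)
        p = np.exp(conf_logits - conf_logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        dconf = p.copy()
        dconf[np.arange(3), targets] -= 1.0
        dconf *= alpha / 3
        model.backward(np.zeros((3, 2)), dconf)

        w = model.backbone[0].w
        grad = w["grad"].copy()
        eps = 1e-5
        for idx in [(0, 0), (2, 13), (3, 20)]:
            orig = w["value"][idx]
            w["value"][idx] = orig + eps
            up = conf_ce()
            w["value"][idx] = orig - eps
            down = conf_ce()
            w["value"][idx] = orig
            fd = (up - down) / (2 * eps)
            assert grad[idx] == pytest.approx(-lam * alpha * fd, abs=1e-5)


class TestSchedule:
    def test_endpoints_exact(self):
        assert cosine_lr(0.0) == 6e-4
        assert cosine_lr(1.0) == 6e-6

    def test_midpoint(self):
        assert cosine_lr(0.5) == pytest.approx(3.03e-4, rel=1e-3)

    def test_monotone_non_increasing(self):
        ts = np.linspace(0, 1, 101)
        lrs = [cosine_lr(t) for t in ts]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cosine_lr(1.2)


class TestAugmentation:
    def test_pixel_multiset_preserved(self, rng):
        patch = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        out = augment_patch(patch, rng)
        np.testing.assert_array_equal(np.sort(patch.ravel()), np.sort(out.ravel()))

    def test_deterministic_given_state(self):
        patch = np.arange(8 * 8 * 3, dtype=np.uint8).reshape(8, 8, 3)
        a = augment_patch(patch, np.random.default_rng(5))
        b = augment_patch(patch, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_patch(np.zeros((4, 6, 3), dtype=np.uint8), rng)

    def test_rotation_and_flip_frequencies(self):
        """Over 10,000 draws each rotation lands in [0.24, 0.26] and the flip
        rate in [0.49, 0.51] (multinomial bands; seeded)."""
        patch = np.arange(16, dtype=np.uint8).reshape(4, 4, 1)
        variants = {}
        for k in range(4):
            r = np.rot90(patch, k=k, axes=(0, 1))
            variants[r.tobytes()] = (k, False)
            variants[np.ascontiguousarray(r[:, ::-1]).tobytes()] = (k, True)
        rng = np.random.default_rng(1)
        rot_counts = np.zeros(4)
        flips = 0
        n = 10_000
        for _ in range(n):
            out = augment_patch(patch, rng)
            k, flipped = variants[out.tobytes()]
            rot_counts[k] += 1
            flips += flipped
        assert all(0.24 <= c / n <= 0.26 for c in rot_counts)
        assert 0.49 <= flips / n <= 0.51


class TestSampleBatch:
    def make_bags(self):
        rng = np.random.default_rng(0)
        return [
            PatchBag("P0", 0, {"S0": rng.integers(0, 255, (10, 8, 8, 3), dtype=np.uint8)}),
            PatchBag("P1", 1, {"S1": rng.integers(0, 255, (4, 8, 8, 3), dtype=np.uint8)}),
        ]

    def test_all_draws_come_from_one_slide_with_replacement(self):
        bags = self.make_bags()
        patches, labels, sid = sample_batch(bags, 32, np.random.default_rng(1))
        assert patches.shape[0] == 32
        source = bags[0].slides["S0"] if sid == "S0" else bags[1].slides["S1"]
        flat = {p.tobytes() for p in source}
        assert all(p.tobytes() in flat for p in patches)

    def test_labels_inherit_from_patient(self):
        bags = self.make_bags()
        for trial in range(5):
            _, labels, sid = sample_batch(bags, 8, np.random.default_rng(trial))
            expected = 0 if sid == "S0" else 1
            assert (labels == expected).all()

    def test_draw_frequencies_uniform_over_slide_patches(self):
        bag = PatchBag("P", 1, {"S": np.arange(5, dtype=np.uint8).reshape(5, 1, 1, 1)})
        rng = np.random.default_rng(7)
        counts = np.zeros(5)
        n = 10_000
        patches, _, _ = sample_batch([bag], n, rng)
        for p in patches:
            counts[int(p.ravel()[0])] += 1
        freq = counts / n
        # multinomial band: p=0.2, sd ~ 0.004
        assert np.all(np.abs(freq - 0.2) < 0.016)

    def test_empty_slide_skipped_with_warning(self):
        bag = PatchBag("P", 1, {
            "empty": np.zeros((0, 4, 4, 3), dtype=np.uint8),
            "full": np.ones((3, 4, 4, 3), dtype=np.uint8),
        })
        with pytest.warns(UserWarning):
            _, _, sid = sample_batch([bag], 4, np.random.default_rng(0))
        assert sid == "full"


def tiny_cohort(seed=0, signal=1.0, confound=0.0, n=12, patches=16):
    cfg = SynthConfig(
        n_patients=n, slides_per_patient=1, patches_per_slide=patches,
        patch_px=32, signal_strength=signal, confound_strength=confound,
        split_fractions={"train": 0.5, "val": 0.5}, balanced_labels=True,
        seed=seed,
    )
    return generate_cohort(cfg)


class TestTrainLoop:
    def test_zero_epochs_returns_initial_model(self):
        cohort = tiny_cohort()
        bags = cohort_to_bags(cohort, "train")
        model = build_model(BackboneSpec(input_px=32, representation_dim=8,
                                         channels=(4, 8)), 2, 0, seed=0)
        before = [p["value"].copy() for p in model.parameters()]
        model, history = train(model, bags, [], TrainingConfig(epochs=0, alpha=0))
        assert history.empty
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p["value"])

    def test_single_class_training_rejected(self):
        bag = PatchBag("P", 1, {"S": np.zeros((4, 32, 32, 3), dtype=np.uint8)})
        model = build_model(BackboneSpec(input_px=32, representation_dim=8,
                                         channels=(4,)), 2, 0, seed=0)
        with pytest.raises(ValueError):
            train(model, [bag], [], TrainingConfig(epochs=1, alpha=0))

    def test_learns_separable_cohort(self):
        """Full-strength texture, no confound: training loss falls and
        held-out patient AUC is high."""
        cohort = tiny_cohort(seed=3, n=20, patches=24)
        tr = cohort_to_bags(cohort, "train")
        va = cohort_to_bags(cohort, "val")
        model = build_model(BackboneSpec(input_px=32), 2, 0, seed=3)
        model, history = train(model, tr, va, TrainingConfig(epochs=10, alpha=0, seed=3))
        first = history[history["epoch"] == 0]["task_loss"].mean()
        last = history[history["epoch"] == history["epoch"].max()]["task_loss"].mean()
        assert last < first
        assert history["val_auc"].dropna().max() > 0.9

    def test_loss_decomposition_and_lr_bounds(self):
        cohort = tiny_cohort(seed=5, n=8, patches=12, confound=0.5)
        tr = cohort_to_bags(cohort, "train")
        n_slides = sum(len(b.slides) for b in tr)
        model = build_model(BackboneSpec(input_px=32, representation_dim=8,
                                         channels=(4, 8)), 2, n_slides, seed=5)
        cfg = TrainingConfig(epochs=2, alpha=0.5, seed=5)
        model, history = train(model, tr, [], cfg)
        np.testing.assert_allclose(
            history["total_loss"],
            history["task_loss"] + cfg.alpha * history["conf_loss"],
            atol=1e-6,
        )
        assert (history["lr"] >= cfg.lr_min).all()
        assert (history["lr"] <= cfg.lr_max).all()
        assert (np.diff(history["lr"]) <= 1e-15).all()
        assert np.isfinite(history[["task_loss", "conf_loss"]]).all().all()

    def test_advcs_harmless_without_confounding(self):
        """On an unconfounded cohort the AdvCS run's validation AUC stays
        within 0.1 of the plain run (3 seeds)."""
        diffs = []
        for seed in range(3):
            cohort = tiny_cohort(seed=20 + seed, n=24, patches=20)
            tr = cohort_to_bags(cohort, "train")
            va = cohort_to_bags(cohort, "val")
            n_slides = sum(len(b.slides) for b in tr)
            aucs = {}
            for alpha in (0.0, 1.0):
                model = build_model(
                    BackboneSpec(input_px=32), 2,
                    0 if alpha == 0 else n_slides, seed=20 + seed,
                )
                model, hist = train(
                    model, tr, va,
                    TrainingConfig(epochs=6, alpha=alpha, seed=20 + seed),
                )
                aucs[alpha] = hist["val_auc"].dropna().max()
            diffs.append(abs(aucs[0.0] - aucs[1.0]))
        assert np.mean(diffs) <= 0.1
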