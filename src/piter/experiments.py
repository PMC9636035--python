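"""Reference desk-scale experiments on synthetic cohorts.

These functions define the package's benchmark conditions in one place so
the test suite and the reproduction script run exactly the same protocol:

* :func:`confounded_benchmark` — the adversarial-confounder-suppression
  mechanism experiment: a cohort whose slide-level colour shift correlates
  with the TMB label in training (rho = 0.9) but not in validation, trained
  once with the confounder head (AdvCS) and once without (alpha = 0).
  AdvCS should both (i) reduce slide-ID decodability of the representation
  towards chance and (ii) generalise at least as well on held-out patients.
* :func:`signal_benchmark` — signal recovery without confounding: with a
  full-strength texture signal the held-out patient AUC should be high;
  with no signal it should sit in the chance band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import cohort_to_bags
from .nn import BackboneSpec, build_model, probe_confounder, representations
from .synth import SynthConfig, generate_cohort
from .training import TrainingConfig, _patient_auc, train


@dataclass
class BenchmarkResult:
    val_auc: float
    probe_accuracy: float
    probe_chance: float

    @property
    def probe_excess(self) -> float:
        return self.probe_accuracy - self.probe_chance


def _mechanism_cohort(seed: int, train_corr: float = 0.9) -> SynthConfig:
    """Study conditions for the mechanism experiment: 10 training patients
    (20 slides at 2 slides/patient, 50 patches each), a large balanced
    validation arm for a stable AUC readout, full-strength texture signal
    and colour confound."""
    return SynthConfig(
        n_patients=50,
        slides_per_patient=2,
        patches_per_slide=50,
        patch_px=64,
        signal_strength=1.0,
        confound_strength=1.0,
        confound_label_corr={"train": train_corr, "val": 0.0},
        split_fractions={"train": 0.2, "val": 0.8},
        balanced_labels=True,
        seed=seed,
    )


def _train_and_probe(cfg: SynthConfig, alpha: float, epochs: int, seed: int) -> BenchmarkResult:
    cohort = generate_cohort(cfg)
    train_bags = cohort_to_bags(cohort, "train")
    val_bags = cohort_to_bags(cohort, "val")
    n_slides = sum(len(b.slides) for b in train_bags)
    model = build_model(
        BackboneSpec(input_px=cfg.patch_px),
        n_task_classes=2,
        n_confounder_classes=0 if alpha == 0 else n_slides,
        lam=1.0,
        seed=seed + 100,
    )
    tcfg = TrainingConfig(epochs=epochs, alpha=alpha, seed=seed + 200)
    model, _ = train(model, train_bags, val_bags, tcfg)
    auc = _patient_auc(model, val_bags)

    reps, sids = [], []
    for bag in train_bags:
        for sid, arr in bag.slides.items():
            reps.append(representations(model, arr))
            sids.extend([sid] * arr.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe = probe_confounder(np.concatenate(reps), sids, seed=0)
    return BenchmarkResult(
        val_auc=float(auc),
        probe_accuracy=probe["accuracy"],
        probe_chance=probe["chance"],
    )


def confounded_benchmark(
    seed: int, alpha: float = 3.0, epochs: int = 10
) -> dict[str, BenchmarkResult]:
    """AdvCS vs plain training on the confounded cohort for one seed.

    Returns {"baseline": ..., "advcs": ...}.  The AdvCS run succeeds for
    this seed when its validation AUC beats the baseline and its probe
    excess over chance is at most half of the baseline's.
    """
    cfg = _mechanism_cohort(seed)
    return {
        "baseline": _train_and_probe(cfg, alpha=0.0, epochs=epochs, seed=seed),
        "advcs": _train_and_probe(cfg, alpha=alpha, epochs=epochs, seed=seed),
    }


def signal_benchmark(
    seed: int, signal_strength: float, n_patients: int = 80, epochs: int = 10
) -> float:
    """Held-out patient AUC on an unconfounded cohort (40 validation
    patients at the default size)."""
    cfg = SynthConfig(
        n_patients=n_patients,
        slides_per_patient=1,
        patches_per_slide=30,
        patch_px=64,
        signal_strength=signal_strength,
        confound_strength=0.0,
        confound_label_corr=0.0,
        split_fractions={"train": 0.5, "val": 0.5},
        balanced_labels=True,
        seed=seed,
    )
    return _train_and_probe(cfg, alpha=0.0, epochs=epochs, seed=seed).val_auc
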