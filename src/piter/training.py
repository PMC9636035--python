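"""Training with adversarial confounder suppression (AdvCS).

The optimization recipe: Adam with decoupled weight decay 0.01, cosine
learning-rate schedule from 6e-4 down to 6e-6 over the training run
(20 epochs at production scale), batches of 32 patches drawn with
replacement from the tissue region of a single slide, and augmentation by
random 90-degree rotations plus horizontal flips at probability 0.5.

The AdvCS objective is ``CE_task + alpha * CE_confounder`` where the
confounder head classifies the slide ID behind a gradient-reversal layer:
the head descends its cross-entropy while the shared backbone ascends it,
suppressing slide-identity information in the representation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PatchBag
from .nn import AdvCSModel, log_softmax, softmax


@dataclass
class TrainingConfig:
    batch_size: int = 32
    epochs: int = 20
    lr_max: float = 6e-4
    lr_min: float = 6e-6
    weight_decay: float = 0.01
    aug_rot90: bool = True
    aug_flip_p: float = 0.5
    lam: float = 1.0  # gradient-reversal weight
    alpha: float = 3.0  # confounder-loss weight
    lambda_warmup_frac: float = 0.0  # optional linear warm-up of lam; off by
    # default so suppression acts before the shortcut entrenches
    mixed_task_batches: bool = False  # ablation: draw task batches across slides
    # adversary schedule: the confounder head is refit to near-optimality on
    # a replay buffer of recent representations at every backbone step (a
    # weak adversary suppresses nothing; only the gradient through a
    # well-trained slide classifier measures true decodability)
    conf_refit_iters: int = 60  # lbfgs iterations per refit of the head
    conf_buffer_size: int = 960
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_min >= self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("alpha and lambda must be >= 0")


# ---------------------------------------------------------------------------
# losses and schedule
# ---------------------------------------------------------------------------


def cross_entropy(probs: np.ndarray, target: int | np.ndarray) -> float:
    """Mean -log p(target) over a batch of probability rows."""
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    t = np.atleast_1d(np.asarray(target))
    if np.any(t < 0) or np.any(t >= p.shape[1]):
        raise ValueError("target class out of range")
    picked = p[np.arange(p.shape[0]), t]
    return float(-np.mean(np.log(np.clip(picked, 1e-300, None))))


def cross_entropy_from_logits(logits: np.ndarray, target: np.ndarray) -> float:
    """Numerically stable cross-entropy via log-softmax."""
    t = np.atleast_1d(np.asarray(target))
    ls = log_softmax(np.atleast_2d(logits))
    if np.any(t < 0) or np.any(t >= ls.shape[1]):
        raise ValueError("target class out of range")
    return float(-np.mean(ls[np.arange(ls.shape[0]), t]))


def _masked_log_softmax(logits: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Log-softmax restricted to the ``allowed`` (boolean mask) classes per
    row; disallowed entries come back as -inf."""
    z = np.where(allowed, logits, -np.inf)
    zmax = z.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        e = np.where(allowed, np.exp(z - zmax), 0.0)
    return z - zmax - np.log(e.sum(axis=1, keepdims=True))


def advcs_loss(
    task_probs: np.ndarray,
    task_target: int | np.ndarray,
    conf_probs: np.ndarray | None,
    conf_target: int | np.ndarray | None,
    alpha: float,
) -> float:
    """Total loss = CE_task + alpha * CE_confounder."""
    ce_task = cross_entropy(task_probs, task_target)
    if alpha == 0:
        return ce_task
    if conf_probs is None or conf_target is None:
        raise ValueError("alpha > 0 requires confounder outputs and targets")
    return ce_task + alpha * cross_entropy(conf_probs, conf_target)


def cosine_lr(t: float, lr_max: float = 6e-4, lr_min: float = 6e-6) -> float:
    """lr(t) = lr_min + (lr_max - lr_min)(1 + cos(pi t))/2 for t in [0, 1]."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("step fraction t must be in [0, 1]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t))


def augment_patch(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate by k*90 degrees (k uniform on {0,1,2,3}) then flip horizontally
    with probability 0.5.  Pixel multiset is preserved."""
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augmentation requires a square patch")
    k = int(rng.integers(0, 4))
    out = np.rot90(patch, k=k, axes=(0, 1))
    if rng.random() < 0.5:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def sample_batch(
    bags: list[PatchBag],
    batch_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Draw one training batch: pick a slide uniformly at random, then
    ``batch_size`` patches uniformly *with replacement* from that slide.
    Labels are the slide's patient-level label."""
    slides = []
    for bag in bags:
        for sid, arr in bag.slides.items():
            if arr.shape[0] == 0:
                warnings.warn(f"slide {sid} has no tissue patches; skipped")
                continue
            slides.append((sid, arr, bag.label))
    if not slides:
        raise ValueError("no non-empty slides to sample from")
    sid, arr, label = slides[int(rng.integers(len(slides)))]
    idx = rng.integers(0, arr.shape[0], size=batch_size)
    return arr[idx], np.full(batch_size, label, dtype=int), sid


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class AdamW:
    """Adam with decoupled weight decay (applied to weight matrices only)."""

    def __init__(self, params: list[dict], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p["grad"]
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p["value"] -= lr * p.get("lr_mult", 1.0) * mhat / (np.sqrt(vhat) + self.eps)
            if p["value"].ndim >= 2 and self.wd > 0:
                p["value"] -= lr * self.wd * p["value"]
            p["grad"] = None


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def score_bags(model: AdvCSModel, bags: list[PatchBag], positive_class: int = 1) -> pd.DataFrame:
    """Per-patient median of patch probabilities for the positive class."""
    from .nn import predict_patches

    rows = []
    for bag in bags:
        probs = predict_patches(model, bag.all_patches())
        rows.append(
            {
                "patient_id": bag.patient_id,
                "label": bag.label,
                "score": float(np.median(probs[:, positive_class])),
                "n_patches_used": int(probs.shape[0]),
            }
        )
    return pd.DataFrame(rows)


def _patient_auc(model: AdvCSModel, bags: list[PatchBag]) -> float:
    from sklearn.metrics import roc_auc_score

    if not bags:
        return float("nan")
    df = score_bags(model, bags)
    if df["label"].nunique() < 2:
        return float("nan")
    return float(roc_auc_score(df["label"], df["score"]))


def train(
    model: AdvCSModel,
    train_bags: list[PatchBag],
    val_bags: list[PatchBag] | None,
    config: TrainingConfig,
) -> tuple[AdvCSModel, pd.DataFrame]:
    """Train with the AdvCS objective; returns the model restored to the
    best-validation-AUC checkpoint and a per-step history frame.

    An epoch is defined as one pass over the training slides in shuffled
    order, with ceil(n_patches / batch_size) batches per slide (patches are
    drawn with replacement, so an epoch is a schedule unit, not an exact
    data pass).
    """
    labels = sorted({bag.label for bag in train_bags})
    if len(labels) < 2:
        raise ValueError("need >= 2 task classes in the training labels")

    ss = np.random.SeedSequence(config.seed)
    rng_sample, rng_aug = [np.random.default_rng(s) for s in ss.spawn(2)]

    slides = []
    for bag in train_bags:
        for sid, arr in bag.slides.items():
            if arr.shape[0] == 0:
                warnings.warn(f"slide {sid} has no tissue patches; skipped")
                continue
            slides.append((sid, arr, bag.label))
    if not slides:
        raise ValueError("no non-empty training slides")
    slide_index = {sid: i for i, sid in enumerate(sorted(s[0] for s in slides))}

    use_conf = config.alpha > 0 and model.conf_head is not None
    if config.alpha > 0 and model.conf_head is None:
        raise ValueError("alpha > 0 but the model has no confounder branch")
    if use_conf and model.n_confounder_classes != len(slide_index):
        raise ValueError(
            f"model confounder classes ({model.n_confounder_classes}) != "
            f"number of training slides ({len(slide_index)})"
        )

    batches_per_epoch = sum(
        math.ceil(arr.shape[0] / config.batch_size) for _, arr, _ in slides
    )
    total_steps = max(1, config.epochs * batches_per_epoch)

    history_rows: list[dict] = []
    if config.epochs == 0:
        return model, pd.DataFrame(history_rows)

    head_param_ids = (
        {id(p) for p in model.conf_head.params()} if model.conf_head is not None else set()
    )
    main_params = [p for p in model.parameters() if id(p) not in head_param_ids]
    opt = AdamW(main_params, weight_decay=config.weight_decay)
    buf_reps: list[np.ndarray] = []
    buf_targets: list[np.ndarray] = []
    head_clf = None
    head_classes: tuple | None = None
    best_auc = -np.inf
    best_state = model.state_dict()
    step = 0
    base_lam = model.lam

    # flat pool for the confounder branch's mixed-slide batches
    pool_patches = np.concatenate([arr for _, arr, _ in slides], axis=0)
    pool_conf = np.concatenate(
        [np.full(arr.shape[0], slide_index[sid]) for sid, arr, _ in slides]
    )
    pool_labels = np.concatenate(
        [np.full(arr.shape[0], label) for _, arr, label in slides]
    )
    # label of each confounder class (slide); the adversary is conditional:
    # it only suppresses slide decodability *within* a label group, so the
    # task's own information is structurally out of its reach
    slide_label_of = np.zeros(len(slide_index), dtype=int)
    for sid, _, label in slides:
        slide_label_of[slide_index[sid]] = label

    for epoch in range(config.epochs):
        order = rng_sample.permutation(len(slides))
        for si in order:
            sid, arr, label = slides[si]
            n_batches = math.ceil(arr.shape[0] / config.batch_size)
            for _ in range(n_batches):
                t = step / total_steps
                lr = cosine_lr(t, config.lr_max, config.lr_min)
                if config.lambda_warmup_frac > 0:
                    model.grl.lam = base_lam * min(1.0, t / config.lambda_warmup_frac)

                if config.mixed_task_batches:
                    idx = rng_sample.integers(0, pool_patches.shape[0],
                                              size=config.batch_size)
                    raw, targets = pool_patches[idx], pool_labels[idx]
                else:
                    idx = rng_sample.integers(0, arr.shape[0], size=config.batch_size)
                    raw = arr[idx]
                    targets = np.full(config.batch_size, label, dtype=int)
                batch = np.stack(
                    [augment_patch(x, rng_aug) if config.aug_rot90 else x for x in raw]
                )

                n = batch.shape[0]
                task_logits, _, _ = model.forward(batch, train=True)
                task_p = softmax(task_logits)
                ce_task = cross_entropy_from_logits(task_logits, targets)
                dtask = task_p.copy()
                dtask[np.arange(n), targets] -= 1.0
                dtask /= n
                model.backward(dtask)

                # The confounder branch works on its own mixed-slide batch:
                # the adversary needs slide-diverse batches to estimate (and
                # suppress) slide decodability, which a single-slide task
                # batch cannot provide.
                ce_conf = 0.0
                if use_conf:
                    cidx = rng_sample.integers(0, pool_patches.shape[0],
                                               size=config.batch_size)
                    # unaugmented: the adversary measures decodability of the
                    # representation as deployed, the same quantity a post-hoc
                    # linear probe sees
                    cbatch = pool_patches[cidx]
                    conf_targets = pool_conf[cidx]
                    _, _, rep_c = model.forward(cbatch, train=True)
                    buf_reps.append(rep_c.copy())
                    buf_targets.append(conf_targets)
                    n_buf = sum(r.shape[0] for r in buf_reps)
                    while n_buf - buf_reps[0].shape[0] >= config.conf_buffer_size:
                        n_buf -= buf_reps.pop(0).shape[0]
                        buf_targets.pop(0)
                    labels_c = pool_labels[cidx]

                    # refit the adversary to near-optimality on the buffer
                    # (warm-started lbfgs; the head is a multinomial logistic
                    # regression on the frozen representation)
                    from sklearn.linear_model import LogisticRegression

                    all_reps = np.concatenate(buf_reps)
                    all_tg = np.concatenate(buf_targets)
                    classes = tuple(np.unique(all_tg))
                    if head_clf is None or classes != head_classes:
                        # lightly regularized (C=10): the adversary must find
                        # at least as much slide information as any post-hoc
                        # probe, or the gate releases pressure too early
                        head_clf = LogisticRegression(
                            warm_start=True, max_iter=config.conf_refit_iters,
                            tol=1e-3, C=10.0,
                        )
                        head_classes = classes
                    if len(classes) >= 2:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            head_clf.fit(all_reps, all_tg)
                        w_full = np.zeros_like(model.conf_head.w["value"])
                        b_full = np.zeros_like(model.conf_head.b["value"])
                        cls = np.array(classes)
                        if len(classes) == 2 and head_clf.coef_.shape[0] == 1:
                            w_full[cls[1]] = head_clf.coef_[0]
                            b_full[cls[1]] = head_clf.intercept_[0]
                        else:
                            w_full[cls] = head_clf.coef_
                            b_full[cls] = head_clf.intercept_
                        model.conf_head.w["value"] = w_full
                        model.conf_head.b["value"] = b_full

                    # Conditional suppression: cross-entropies and gradients
                    # are computed under a softmax restricted to slides with
                    # the same task label as the sample.  Within-group
                    # decodability (staining idiosyncrasies, scanner hue) is
                    # exactly the confound; the label partition itself is
                    # never attacked.
                    all_lab = slide_label_of[all_tg]
                    allowed_buf = slide_label_of[None, :] == all_lab[:, None]
                    mls_buf = _masked_log_softmax(
                        model.conf_head.forward(all_reps), allowed_buf
                    )
                    ce_cond_buf = float(
                        -np.mean(mls_buf[np.arange(all_tg.size), all_tg])
                    )
                    group_sizes = np.array(
                        [(slide_label_of == y).sum() for y in all_lab]
                    )
                    cond_chance = float(np.mean(np.log(group_sizes)))

                    # reversal through the refreshed head on the fresh batch
                    conf_logits = model.conf_head.forward(
                        model.grl.forward(rep_c, train=True), train=True
                    )
                    ce_conf = cross_entropy_from_logits(conf_logits, conf_targets)
                    # Pressure while the head beats within-group chance;
                    # smooth ramp (full reversal 0.1 nats below chance)
                    # avoids bang-bang oscillation.
                    conf_gate = min(1.0, max(0.0, (cond_chance - ce_cond_buf) / 0.1))
                    if conf_gate > 0.0:
                        allowed_c = slide_label_of[None, :] == labels_c[:, None]
                        p_masked = np.exp(
                            _masked_log_softmax(conf_logits, allowed_c)
                        )
                        dconf = p_masked
                        dconf[np.arange(n), conf_targets] -= 1.0
                        dconf *= config.alpha / n
                        model.backward(np.zeros((n, model.n_task_classes)),
                                       dconf, conf_gate=conf_gate)
                        for p in model.conf_head.params():
                            p["grad"] = None  # head trains only from the buffer

                total = ce_task + config.alpha * ce_conf
                if not np.isfinite(total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: "
                        f"task={ce_task} conf={ce_conf}"
                    )
                opt.step(lr)
                history_rows.append(
                    {
                        "epoch": epoch,
                        "step": step,
                        "lr": lr,
                        "task_loss": ce_task,
                        "conf_loss": ce_conf,
                        "total_loss": total,
                        "val_auc": np.nan,
                    }
                )
                step += 1

        val_auc = _patient_auc(model, val_bags) if val_bags else float("nan")
        history_rows[-1]["val_auc"] = val_auc
        if not math.isnan(val_auc) and val_auc >= best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
        elif math.isnan(val_auc):
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.grl.lam = base_lam
    return model, pd.DataFrame(history_rows)
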