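"""A compact convolutional classifier stack with a gradient-reversal
confounder head, implemented directly on numpy arrays.

The same stack serves two deployments: *TumorNet* (3-class: normal / LUAD /
LUSC tissue) and *TMBNet* (binary high/low tumor mutational burden).  For
adversarial confounder suppression the penultimate representation feeds two
linear heads: the task head, and a confounder head that classifies the
slide ID through a gradient-reversal operator.  On the forward pass the
operator is the identity; on the backward pass it multiplies the gradient
by -lambda, so the confounder head *descends* its cross-entropy while the
shared backbone *ascends* it — driving the representation towards
slide-invariance.

All layers expose ``forward``/``backward`` with cached activations, and
parameters as (value, grad) pairs, which is sufficient for Adam with
decoupled weight decay on CPU at the patch sizes used here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _accumulate(param: dict, grad: np.ndarray) -> None:
    """Gradients accumulate across backward passes until the optimizer step
    clears them (several head-specific passes may share one update)."""
    param["grad"] = grad if param["grad"] is None else param["grad"] + grad


class Layer:
    def params(self) -> list[dict]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (configurable) convolution via im2col; NCHW layout.

    The backward pass scatters column gradients back to the padded input
    with a single ``bincount`` over precomputed flat indices, which keeps
    pure-numpy training fast enough for the small test backbone.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.w = {"value": rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, fan_in)), "grad": None}
        self.b = {"value": np.zeros(c_out), "grad": None}
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def params(self):
        return [self.w, self.b]

    def _flat_indices(self, n: int, h: int, w: int) -> tuple[np.ndarray, tuple]:
        key = (n, h, w)
        if key not in self._idx_cache:
            k, s, p = self.k, self.stride, self.pad
            hp, wp = h + 2 * p, w + 2 * p
            ho = (hp - k) // s + 1
            wo = (wp - k) // s + 1
            c_idx = np.repeat(np.arange(self.c_in), k * k)
            kh = np.tile(np.repeat(np.arange(k), k), self.c_in)
            kw = np.tile(np.arange(k), self.c_in * k)
            oy = s * np.repeat(np.arange(ho), wo)
            ox = s * np.tile(np.arange(wo), ho)
            # (positions, c*k*k) flat index into one padded sample
            rows = (oy[:, None] + kh[None, :]) * wp + (ox[:, None] + kw[None, :])
            flat = c_idx[None, :] * (hp * wp) + rows
            per_sample = self.c_in * hp * wp
            batch_flat = (flat[None, :, :] + (np.arange(n) * per_sample)[:, None, None])
            self._idx_cache[key] = (batch_flat.ravel(), (ho, wo, hp, wp))
        return self._idx_cache[key]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        flat_idx, (ho, wo, hp, wp) = self._flat_indices(n, h, w)
        xp = np.zeros((n, c, hp, wp), dtype=x.dtype)
        xp[:, :, self.pad : self.pad + h, self.pad : self.pad + w] = x
        cols = xp.ravel()[flat_idx].reshape(n * ho * wo, c * self.k * self.k)
        out = cols @ self.w["value"].T + self.b["value"]
        if train:
            self._cache = (cols, flat_idx, (n, c, h, w, hp, wp, ho, wo))
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, flat_idx, (n, c, h, w, hp, wp, ho, wo) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        _accumulate(self.w, dflat.T @ cols)
        _accumulate(self.b, dflat.sum(axis=0))
        dcols = dflat @ self.w["value"]
        dxp = np.bincount(flat_idx, weights=dcols.ravel(), minlength=n * c * hp * wp)
        dxp = dxp.reshape(n, c, hp, wp)
        return dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    """NCHW -> (N, C) average over spatial dims."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        w0 = np.zeros((d_out, d_in)) if zero_init else rng.normal(
            0, np.sqrt(1.0 / d_in), (d_out, d_in))
        self.w = {"value": w0, "grad": None}
        self.b = {"value": np.zeros(d_out), "grad": None}

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w["value"].T + self.b["value"]

    def backward(self, dout):
        _accumulate(self.w, dout.T @ self._x)
        _accumulate(self.b, dout.sum(axis=0))
        return dout @ self.w["value"]


class GradientReversal(Layer):
    """Identity on the forward pass; multiplies the gradient by -lambda on
    the backward pass."""

    def __init__(self, lam: float = 1.0):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.lam = float(lam)

    def forward(self, x, train=False):
        return x

    def backward(self, dout):
        return -self.lam * dout


def gradient_reverse(values: np.ndarray, lam: float) -> np.ndarray:
    """Forward pass of the gradient-reversal operator: the identity.  The
    backward behaviour (upstream gradient = -lambda x downstream gradient)
    lives on :class:`GradientReversal`, which this wraps."""
    return GradientReversal(lam).forward(np.asarray(values))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class BackboneSpec:
    """Architecture configuration.

    ``small_cnn`` is a three-block strided CNN sized to train on CPU; the
    field's production choice (an EfficientNet-style backbone) would slot in
    behind the same interface but is not bundled, as no deep-learning
    runtime is a dependency of this package.
    """

    architecture: str = "small_cnn"
    input_px: int = 64
    representation_dim: int = 32
    channels: tuple[int, ...] = (8, 16, 32)
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.representation_dim <= 0:
            raise ValueError("representation_dim must be > 0")
        if self.architecture != "small_cnn":
            raise ValueError(f"unknown architecture: {self.architecture}")
        if self.pretrained:
            raise ValueError("no pretrained weights are bundled")


class AdvCSModel:
    """Backbone + task head + (optional) gradient-reversed confounder head.

    Both heads consume the same penultimate representation.  With
    ``n_confounder_classes == 0`` the confounder branch is absent and the
    model is a plain classifier.
    """

    def __init__(self, spec: BackboneSpec, n_task_classes: int,
                 n_confounder_classes: int = 0, lam: float = 1.0,
                 rng: np.random.Generator | None = None):
        if n_task_classes < 2:
            raise ValueError("need >= 2 task classes")
        if n_confounder_classes == 1:
            raise ValueError("confounder classes must be 0 (disabled) or >= 2")
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.n_task_classes = n_task_classes
        self.n_confounder_classes = n_confounder_classes
        self.lam = float(lam)

        chans = spec.channels
        layers: list[Layer] = []
        c_prev = 3
        for c in chans:
            layers.append(Conv2D(c_prev, c, k=3, stride=2, pad=1, rng=rng))
            layers.append(ReLU())
            c_prev = c
        layers.append(GlobalAvgPool())
        layers.append(Dense(c_prev, spec.representation_dim, rng=rng))
        layers.append(ReLU())
        self.backbone = layers
        self.task_head = Dense(spec.representation_dim, n_task_classes, rng=rng)
        self.grl = GradientReversal(lam)
        self.conf_head = (
            Dense(spec.representation_dim, n_confounder_classes, rng=rng)
            if n_confounder_classes > 0
            else None
        )

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[dict]:
        out = []
        for layer in self.backbone:
            out.extend(layer.params())
        out.extend(self.task_head.params())
        if self.conf_head is not None:
            out.extend(self.conf_head.params())
        return out

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        """x: (N, P, P, 3) uint8 or float in [0,255].  Returns
        (task_logits, conf_logits_or_None, representation)."""
        h = self._prep(x)
        for layer in self.backbone:
            h = layer.forward(h, train=train)
        rep = h
        task_logits = self.task_head.forward(rep, train=train)
        conf_logits = None
        if self.conf_head is not None:
            conf_logits = self.conf_head.forward(
                self.grl.forward(rep, train=train), train=train
            )
        return task_logits, conf_logits, rep

    def backward(self, dtask: np.ndarray, dconf: np.ndarray | None = None,
                 conf_gate: float = 1.0) -> None:
        """Backpropagate head gradients.

        ``conf_gate`` scales only the reversed gradient flowing from the
        confounder head into the backbone (the head's own parameters always
        receive their full descent gradient).  Training gates it to zero
        once the head is at chance level, which keeps the adversarial game
        from diverging: the objective is a chance-level confounder head,
        not an arbitrarily confused one.
        """
        drep = self.task_head.backward(dtask)
        if dconf is not None:
            if self.conf_head is None:
                raise ValueError("confounder gradient given but branch absent")
            drep = drep + conf_gate * self.grl.backward(self.conf_head.backward(dconf))
        for layer in reversed(self.backbone):
            drep = layer.backward(drep)

    @staticmethod
    def _prep(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        x = x / 255.0 - 0.5
        return x.transpose(0, 3, 1, 2)  # NHWC -> NCHW

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model")
        for p, v in zip(params, state):
            if p["value"].shape != v.shape:
                raise ValueError("parameter shape mismatch")
            p["value"] = v.copy()

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Single-file weights (.npz) plus a JSON sidecar with the spec."""
        path = Path(path)
        np.savez(path, *[p["value"] for p in self.parameters()])
        meta = {
            "architecture": self.spec.architecture,
            "input_px": self.spec.input_px,
            "representation_dim": self.spec.representation_dim,
            "channels": list(self.spec.channels),
            "n_task_classes": self.n_task_classes,
            "n_confounder_classes": self.n_confounder_classes,
            "lambda": self.lam,
        }
        if extra:
            meta.update(extra)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AdvCSModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        spec = BackboneSpec(
            architecture=meta["architecture"],
            input_px=meta["input_px"],
            representation_dim=meta["representation_dim"],
            channels=tuple(meta["channels"]),
        )
        model = cls(
            spec,
            meta["n_task_classes"],
            meta["n_confounder_classes"],
            lam=meta["lambda"],
        )
        with np.load(path) as z:
            model.load_state_dict([z[k] for k in z.files])
        return model


def build_model(
    spec: BackboneSpec,
    n_task_classes: int,
    n_confounder_classes: int = 0,
    lam: float = 1.0,
    seed: int = 0,
) -> AdvCSModel:
    """Construct an AdvCS model with seeded initialization."""
    return AdvCSModel(
        spec, n_task_classes, n_confounder_classes, lam=lam,
        rng=np.random.default_rng(seed),
    )


def predict_patches(
    model: AdvCSModel, patches: np.ndarray | list, batch_size: int = 64
) -> np.ndarray:
    """Task-class probabilities for a stack of patches, order-preserving and
    deterministic (evaluation mode, no augmentation)."""
    if len(patches) == 0:
        return np.zeros((0, model.n_task_classes))
    arr = np.asarray(patches)
    if arr.shape[1] != model.spec.input_px or arr.shape[2] != model.spec.input_px:
        raise ValueError(
            f"patch size {arr.shape[1:3]} != model input {model.spec.input_px}"
        )
    probs = []
    for i in range(0, arr.shape[0], batch_size):
        logits, _, _ = model.forward(arr[i : i + batch_size], train=False)
        probs.append(softmax(logits))
    return np.concatenate(probs, axis=0)


def representations(model: AdvCSModel, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
    reps = []
    arr = np.asarray(patches)
    for i in range(0, arr.shape[0], batch_size):
        _, _, rep = model.forward(arr[i : i + batch_size], train=False)
        reps.append(rep)
    return np.concatenate(reps, axis=0)


def probe_confounder(
    reps: np.ndarray,
    slide_ids: list[str] | np.ndarray,
    probe_split: float = 0.5,
    seed: int = 0,
) -> dict:
    """Accuracy of a fresh linear classifier predicting slide ID from frozen
    representations, on held-out patches (stratified split within slides).

    Returns {"accuracy", "chance", "n_slides"}; chance = 1 / n_slides.
    Slides with fewer than 2 patches are excluded with a warning.
    """
    import warnings

    from sklearn.linear_model import LogisticRegression

    slide_ids = np.asarray(slide_ids)
    reps = np.asarray(reps)
    rng = np.random.default_rng(seed)

    keep_slides = []
    for sid in np.unique(slide_ids):
        if (slide_ids == sid).sum() >= 2:
            keep_slides.append(sid)
        else:
            warnings.warn(f"slide {sid} has < 2 patches; excluded from probe")
    if len(keep_slides) < 2:
        raise ValueError("need >= 2 slides with >= 2 patches for the probe")

    train_idx, test_idx = [], []
    for sid in keep_slides:
        idx = np.flatnonzero(slide_ids == sid)
        idx = rng.permutation(idx)
        n_train = max(1, int(round(probe_split * len(idx))))
        n_train = min(n_train, len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx, test_idx = np.array(train_idx), np.array(test_idx)

    clf = LogisticRegression(max_iter=500)
    clf.fit(reps[train_idx], slide_ids[train_idx])
    acc = float((clf.predict(reps[test_idx]) == slide_ids[test_idx]).mean())
    return {"accuracy": acc, "chance": 1.0 / len(keep_slides), "n_slides": len(keep_slides)}
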