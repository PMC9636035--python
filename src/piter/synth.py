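"""Synthetic H&E-like confounded cohorts.

Every downstream stage of the pipeline (tiling, stain handling, TMB
classification with adversarial confounder suppression, biomarker
evaluation) is testable on cohorts produced here, without any external
download.  The generator emulates the structure that matters for the
method, not histological realism:

* per-patch texture whose statistics depend on a binary TMB label —
  hematoxylin-like nucleus blobs whose density and radius increase with
  ``signal_strength`` for TMB-high patients;
* a per-slide additive RGB shift acting as a confounder (a surrogate for
  slide-level staining / scanner variation), whose *sign* is correlated
  with the patient label at a controllable level per split — this is the
  shortcut that adversarial confounder suppression must remove;
* multiple slides per patient, so patients are bags of patches;
* optional exponential survival times tied to the latent label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = [
    "patient_id",
    "slide_id",
    "cohort",
    "split",
    "tmb_value",
    "tmb_class",
    "surv_time_days",
    "surv_event",
]

# Background ("eosin") base colour and nucleus ("hematoxylin") colour, 8-bit RGB.
_BG_RGB = np.array([232.0, 190.0, 205.0])
_NUCLEUS_RGB = np.array([72.0, 48.0, 120.0])
_BG_NOISE_SD = 4.0

# Nucleus texture model: mean count per 64x64 patch and base radius as a
# fraction of the patch edge.  TMB-high patients get up to +150% density and
# +50% radius at signal_strength = 1, sized so the morphological signal is
# genuinely informative at the single-patch level.
_BASE_NUCLEI_PER_64 = 6.0
_DENSITY_GAIN = 1.5
_RADIUS_FRAC = 0.04
_RADIUS_GAIN = 0.5

# Slide-level confound: signed base shift direction (RGB intensity levels at
# confound_strength = 1) plus per-slide jitter so each slide has a unique hue.
_CONFOUND_BASE = np.array([26.0, -12.0, 20.0])
_CONFOUND_JITTER_SD = 7.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic cohort.

    ``confound_label_corr`` may be a single float applied to all splits or a
    mapping ``{"train": 0.9, "val": 0.0, ...}`` so the confound–label
    correlation can differ between training and validation — the regime in
    which a slide-colour shortcut generalises badly.
    """

    n_patients: int = 40
    slides_per_patient: int = 2
    patches_per_slide: int = 50
    patch_px: int = 64
    signal_strength: float = 1.0
    confound_strength: float = 0.0
    confound_label_corr: float | Mapping[str, float] = 0.0
    tmb_prevalence: float = 0.5
    balanced_labels: bool = False  # stratified: exactly round(n * prevalence) highs
    seed: int = 0
    split_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"train": 0.6, "val": 0.2, "test": 0.2}
    )
    cohort_name: str = "synthetic"
    survival: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.slides_per_patient < 1 or self.patches_per_slide < 1:
            raise ValueError("all counts must be >= 1")
        if self.patch_px < 16:
            raise ValueError("patch_px < 16: nucleus blobs are unrenderable")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ValueError("confound_strength must be in [0, 1]")
        for rho in self._corr_values():
            if not -1.0 <= rho <= 1.0:
                raise ValueError("confound_label_corr must be in [-1, 1]")
        if not 0.0 < self.tmb_prevalence < 1.0:
            raise ValueError("tmb_prevalence must be in (0, 1)")
        total = sum(self.split_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("split_fractions must sum to 1")

    def _corr_values(self) -> list[float]:
        if isinstance(self.confound_label_corr, Mapping):
            return list(self.confound_label_corr.values())
        return [float(self.confound_label_corr)]

    def corr_for_split(self, split: str) -> float:
        if isinstance(self.confound_label_corr, Mapping):
            return float(self.confound_label_corr.get(split, 0.0))
        return float(self.confound_label_corr)


@dataclass
class SynthCohort:
    """A generated cohort: manifest, in-memory patch images, and ground truth.

    ``images`` maps slide_id to a list of ``(x, y, uint8 RGB array)`` patches.
    ``truth`` records the latent per-patient label (1 = TMB-high) and the
    per-slide confound shift actually applied.
    """

    config: SynthConfig
    manifest: pd.DataFrame
    images: dict[str, list[tuple[int, int, np.ndarray]]]
    patient_labels: dict[str, int]
    slide_shifts: dict[str, np.ndarray]
    image_store: Path | None = None

    @property
    def n_patches(self) -> int:
        return sum(len(v) for v in self.images.values())


def generate_patch_image(
    label: int,
    confound_shift: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one H&E-like patch: pink background plus dark nucleus blobs.

    Nucleus count is Poisson with a mean that grows with
    ``signal_strength`` when ``label`` is high; nucleus radius grows
    likewise.  ``confound_shift`` is added to every channel and the result
    clipped to [0, 255].  Deterministic given the rng state.
    """
    if config.patch_px < 16:
        raise ValueError("patch_px < 16: nucleus blobs are unrenderable")
    p = config.patch_px
    shift = np.asarray(confound_shift, dtype=float).reshape(3)

    img = _BG_RGB + rng.normal(0.0, _BG_NOISE_SD, size=(p, p, 3))

    area_scale = (p / 64.0) ** 2
    boost = config.signal_strength * float(label)
    lam = _BASE_NUCLEI_PER_64 * area_scale * (1.0 + _DENSITY_GAIN * boost)
    n_nuclei = int(rng.poisson(lam))
    r0 = _RADIUS_FRAC * p * (1.0 + _RADIUS_GAIN * boost)

    yy, xx = np.mgrid[0:p, 0:p]
    for _ in range(n_nuclei):
        cx, cy = rng.uniform(2, p - 2, size=2)
        ax = r0 * rng.uniform(0.8, 1.2)
        ay = r0 * rng.uniform(0.8, 1.2)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d2 = (u / ax) ** 2 + (v / ay) ** 2
        w = 0.9 * np.exp(-0.5 * d2 * 4.0)  # compact Gaussian profile
        img += w[..., None] * (_NUCLEUS_RGB - img)

    img += shift
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _assign_splits(n: int, fractions: Mapping[str, float], rng: np.random.Generator) -> list[str]:
    order = rng.permutation(n)
    splits = [""] * n
    names = list(fractions)
    # largest-remainder allocation so counts are deterministic
    raw = np.array([fractions[s] * n for s in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(-(raw - counts))[:rem]:
        counts[i] += 1
    pos = 0
    for name, c in zip(names, counts):
        for idx in order[pos : pos + c]:
            splits[idx] = name
        pos += c
    return splits


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a full cohort in memory.

    Patients get latent TMB labels at ``tmb_prevalence``; each slide gets a
    signed hue shift whose sign agrees with the patient label with
    probability (1 + rho)/2, rho being the split's confound–label
    correlation, so corr(sign, ±1-coded label) = rho in expectation.
    """
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    rng = np.random.default_rng(config.seed)

    n = config.n_patients
    patient_ids = [f"P{i:04d}" for i in range(n)]
    if config.balanced_labels:
        # stratified: labels exactly at prevalence, splits balanced per label
        n_high = int(round(n * config.tmb_prevalence))
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[:n_high]] = 1
        splits = [""] * n
        for lab in (0, 1):
            idx = np.flatnonzero(labels == lab)
            sub = _assign_splits(len(idx), config.split_fractions, rng)
            for i, s in zip(idx, sub):
                splits[i] = s
    else:
        labels = (rng.random(n) < config.tmb_prevalence).astype(int)
        splits = _assign_splits(n, config.split_fractions, rng)

    rows = []
    images: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    patient_labels: dict[str, int] = {}
    slide_shifts: dict[str, np.ndarray] = {}
    cols = int(math.ceil(math.sqrt(config.patches_per_slide)))

    for i, pid in enumerate(patient_ids):
        label = int(labels[i])
        patient_labels[pid] = label
        split = splits[i]
        rho = config.corr_for_split(split)
        if label == 1:
            tmb_value = float(np.round(rng.uniform(10.0, 60.0), 2))
        else:
            tmb_value = float(np.round(rng.uniform(0.0, 9.9), 2))
        if config.survival:
            # TMB-high (biomarker-positive) patients survive longer on average
            mean_t = 700.0 if label == 1 else 350.0
            t_event = rng.exponential(mean_t)
            t_cens = rng.exponential(900.0)
            surv_time = float(np.round(max(min(t_event, t_cens), 1.0), 1))
            surv_event = int(t_event <= t_cens)
        else:
            surv_time, surv_event = "", ""

        for s in range(config.slides_per_patient):
            slide_id = f"{pid}S{s}"
            p_plus = (1.0 + rho) / 2.0 if label == 1 else (1.0 - rho) / 2.0
            sign = 1.0 if rng.random() < p_plus else -1.0
            shift = sign * config.confound_strength * _CONFOUND_BASE
            shift = shift + rng.normal(
                0.0, _CONFOUND_JITTER_SD * config.confound_strength, size=3
            )
            slide_shifts[slide_id] = shift
            patches = []
            for k in range(config.patches_per_slide):
                x = (k % cols) * config.patch_px
                y = (k // cols) * config.patch_px
                patches.append((x, y, generate_patch_image(label, shift, config, rng)))
            images[slide_id] = patches
            rows.append(
                {
                    "patient_id": pid,
                    "slide_id": slide_id,
                    "cohort": config.cohort_name,
                    "split": split,
                    "tmb_value": tmb_value,
                    "tmb_class": "high" if label == 1 else "low",
                    "surv_time_days": surv_time,
                    "surv_event": surv_event,
                }
            )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return SynthCohort(
        config=config,
        manifest=manifest,
        images=images,
        patient_labels=patient_labels,
        slide_shifts=slide_shifts,
    )


def write_cohort(cohort: SynthCohort, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write manifest.csv plus ``images/<slide_id>_<x>_<y>.png``; return the
    manifest path.  Refuses to write into a non-empty directory unless
    ``overwrite`` is set."""
    if cohort.manifest.empty or not cohort.images:
        raise ValueError("cannot write an empty cohort")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    for slide_id, patches in sorted(cohort.images.items()):
        for x, y, arr in patches:
            Image.fromarray(arr).save(img_dir / f"{slide_id}_{x}_{y}.png")
    cohort.image_store = out
    return manifest_path


def read_cohort(in_dir: str | Path) -> SynthCohort:
    """Reconstruct a cohort written by :func:`write_cohort` (truth fields are
    recovered from the manifest's tmb_class; slide shifts are not persisted)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv", keep_default_na=False)
    manifest["tmb_value"] = pd.to_numeric(manifest["tmb_value"], errors="coerce")
    images: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    patient_labels: dict[str, int] = {}
    for _, row in manifest.iterrows():
        patient_labels[row["patient_id"]] = 1 if row["tmb_class"] == "high" else 0
        slide_id = row["slide_id"]
        if slide_id in images:
            continue
        patches = []
        for path in sorted((in_dir / "images").glob(f"{slide_id}_*_*.png")):
            stem = path.stem
            coords = stem[len(slide_id) + 1 :].split("_")
            x, y = int(coords[0]), int(coords[1])
            patches.append((x, y, np.asarray(Image.open(path).convert("RGB"))))
        if not patches:
            raise FileNotFoundError(f"no images found for slide {slide_id}")
        patches.sort(key=lambda t: (t[1], t[0]))
        images[slide_id] = patches
    cfg = SynthConfig(
        n_patients=manifest["patient_id"].nunique(),
        slides_per_patient=max(
            1, len(manifest) // max(1, manifest["patient_id"].nunique())
        ),
        patches_per_slide=max(1, max(len(v) for v in images.values())),
    )
    return SynthCohort(
        config=cfg,
        manifest=manifest,
        images=images,
        patient_labels=patient_labels,
        slide_shifts={},
        image_store=in_dir,
    )
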