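"""PITER biomarker assembly: TMB labelling, tumor-patch filtering, median
bag aggregation, and Youden-index cutoff selection.

The PITER score of a patient is the median of the TMB-high probabilities of
that patient's tumor patches (all slides pooled into one bag).  The binary
biomarker call thresholds the score at a cutoff chosen to maximize the
Youden index J = sensitivity + specificity - 1 on the training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# TMB-high thresholds: 206 nonsynonymous mutations in exome-count mode
# (approximately 10 mut/Mb on a targeted-panel scale), or 10 mut/Mb directly.
TMB_CUTOFF_COUNT = 206.0
TMB_CUTOFF_PER_MB = 10.0


@dataclass(frozen=True)
class TMBLabel:
    raw_value: float
    mode: str  # "count" or "per_mb"
    cutoff: float
    tmb_class: str  # "high" or "low"


@dataclass
class PiterScore:
    patient_id: str
    score: float  # aggregated probability of TMB-high, in [0, 1]
    n_patches_used: int
    predicted_class: str | None = None  # at a stored cutoff

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")
        if self.n_patches_used < 1:
            raise ValueError("n_patches_used must be >= 1")


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def label_tmb(raw_value: float, mode: str = "per_mb", cutoff: float | None = None) -> TMBLabel:
    """Binary TMB class: high iff raw_value >= cutoff (206 in count mode,
    10 mut/Mb in panel mode by default)."""
    if raw_value < 0:
        raise ValueError("TMB value must be >= 0")
    if mode not in ("count", "per_mb"):
        raise ValueError("mode must be 'count' or 'per_mb'")
    if cutoff is None:
        cutoff = TMB_CUTOFF_COUNT if mode == "count" else TMB_CUTOFF_PER_MB
    cls = "high" if raw_value >= cutoff else "low"
    return TMBLabel(raw_value=float(raw_value), mode=mode, cutoff=float(cutoff), tmb_class=cls)


def filter_tumor_patches(
    patch_probs: pd.DataFrame,
    histology: str,
    tumor_threshold: float = 0.5,
) -> pd.DataFrame:
    """Keep a patch iff (1 - p_normal) >= threshold AND its argmax tissue
    class matches the slide's histology.

    ``patch_probs`` needs columns p_normal, p_luad, p_lusc (plus any
    provenance columns, which are passed through).  Returns the frame with a
    ``kept`` column; rows with kept == 1 are the tumor patches.
    """
    if histology not in ("LUAD", "LUSC"):
        raise ValueError("histology must be 'LUAD' or 'LUSC'")
    required = ["p_normal", "p_luad", "p_lusc"]
    missing = [c for c in required if c not in patch_probs.columns]
    if missing:
        raise ValueError(f"missing probability columns: {missing}")
    probs = patch_probs[required].to_numpy()
    argmax = np.argmax(probs, axis=1)  # 0 normal, 1 luad, 2 lusc
    want = 1 if histology == "LUAD" else 2
    kept = ((1.0 - probs[:, 0]) >= tumor_threshold) & (argmax == want)
    out = patch_probs.copy()
    out["kept"] = kept.astype(int)
    frac = float(kept.mean()) if len(kept) else 0.0
    logger.info("tumor filter retained %.1f%% of %d patches", 100 * frac, len(kept))
    return out


def aggregate_bag(patch_scores, level: str = "patient") -> float:
    """Median of the patch probabilities in one bag (even counts: mean of
    the two central values).  The ``level`` argument is documentation of
    what the bag is — the caller assembles slide- or patient-level bags."""
    scores = np.asarray(list(patch_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty bag")
    if level not in ("slide", "patient"):
        raise ValueError("level must be 'slide' or 'patient'")
    return float(np.median(scores))


def youden_cutoff(scores, labels) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Patients with score >= cutoff are called high.  Candidate cutoffs are
    the midpoints between adjacent distinct sorted scores plus -inf/+inf
    sentinels; ties in J are broken towards the larger cutoff (higher
    specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to pick a cutoff")

    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best = None
    for c in candidates:
        called_high = scores >= c
        sens = float((called_high & (labels == 1)).sum() / n_pos)
        spec = float((~called_high & (labels == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and c > best[1]):
            best = (j, c, sens, spec)
    _, cutoff, sens, spec = best
    return CutoffResult(cutoff=float(cutoff), sensitivity=sens, specificity=spec)


def score_patients(
    tmbnet,
    manifest: pd.DataFrame,
    images: dict[str, list],
    tumornet=None,
    histology: str = "LUAD",
    tumor_threshold: float = 0.5,
    cutoff: float | None = None,
) -> list[PiterScore]:
    """Full scoring path: (optional) TumorNet filtering, TMBNet patch
    probabilities, patient-level median aggregation.

    ``images`` maps slide_id to a list of (x, y, pixels) patches (the layout
    produced by the synthetic generator / tiler).  When ``tumornet`` is None
    every patch is treated as tumor (appropriate for cohorts without a
    normal-tissue compartment).
    """
    from .nn import predict_patches

    patients = manifest.drop_duplicates("patient_id")["patient_id"].tolist()
    missing = [
        pid
        for pid in patients
        if not any(
            sid in images for sid in manifest[manifest["patient_id"] == pid]["slide_id"]
        )
    ]
    if missing:
        raise KeyError(f"patients missing from the patch store: {missing}")

    results = []
    for pid in patients:
        slide_ids = manifest[manifest["patient_id"] == pid]["slide_id"].unique()
        patches = []
        for sid in slide_ids:
            patches.extend(arr for _, _, arr in images.get(sid, []))
        patches = np.stack(patches)
        if tumornet is not None:
            probs3 = predict_patches(tumornet, patches)
            df = pd.DataFrame(probs3, columns=["p_normal", "p_luad", "p_lusc"])
            kept = filter_tumor_patches(df, histology, tumor_threshold)["kept"].to_numpy()
            if kept.sum() == 0:
                raise ValueError(f"all patches filtered out for patient {pid}")
            patches = patches[kept.astype(bool)]
        p_high = predict_patches(tmbnet, patches)[:, 1]
        score = aggregate_bag(p_high, level="patient")
        predicted = None
        if cutoff is not None:
            predicted = "high" if score >= cutoff else "low"
        results.append(
            PiterScore(
                patient_id=pid,
                score=score,
                n_patches_used=int(len(p_high)),
                predicted_class=predicted,
            )
        )
    return results


def scores_to_frame(scores: list[PiterScore], cutoff: float | None = None) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "piter_score": s.score,
                "n_patches_used": s.n_patches_used,
                "predicted_class": s.predicted_class if s.predicted_class is not None else "",
                "cutoff_used": cutoff if cutoff is not None else "",
            }
            for s in scores
        ]
    )
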