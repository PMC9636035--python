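"""Patient bags and manifest handling.

A *bag* is the multiple-instance unit of this pipeline: all patches of one
patient across that patient's slides, each patch labelled with the
patient-level TMB class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import MANIFEST_COLUMNS, SynthCohort


@dataclass
class PatchBag:
    """All patches of one patient, grouped by slide."""

    patient_id: str
    label: int  # 1 = TMB-high
    slides: dict[str, np.ndarray] = field(default_factory=dict)  # slide -> (n, P, P, 3) uint8

    @property
    def slide_ids(self) -> list[str]:
        return list(self.slides)

    @property
    def n_patches(self) -> int:
        return sum(a.shape[0] for a in self.slides.values())

    def all_patches(self) -> np.ndarray:
        return np.concatenate(list(self.slides.values()), axis=0)


def cohort_to_bags(cohort: SynthCohort, split: str | None = None) -> list[PatchBag]:
    """Group a synthetic cohort's patches into per-patient bags, optionally
    restricted to one manifest split."""
    mf = cohort.manifest
    if split is not None:
        mf = mf[mf["split"] == split]
    bags: dict[str, PatchBag] = {}
    for _, row in mf.iterrows():
        pid, sid = row["patient_id"], row["slide_id"]
        if pid not in bags:
            bags[pid] = PatchBag(patient_id=pid, label=cohort.patient_labels[pid])
        patches = cohort.images[sid]
        bags[pid].slides[sid] = np.stack([arr for _, _, arr in patches])
    return list(bags.values())


def validate_manifest(df: pd.DataFrame, require_survival: bool = False) -> pd.DataFrame:
    """Check the cohort manifest schema; return the frame unchanged."""
    missing = [c for c in MANIFEST_COLUMNS[:6] if c not in df.columns]
    if require_survival:
        missing += [c for c in ("surv_time_days", "surv_event") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = set(df["tmb_class"].unique()) - {"high", "low"}
    if bad:
        raise ValueError(f"invalid tmb_class values: {sorted(bad)}")
    return df


def load_patch_store(images_dir, slide_ids) -> dict[str, list[tuple[int, int, np.ndarray]]]:
    """Load ``<slide_id>_<x>_<y>.png`` patch files for the given slides into
    the in-memory store layout used throughout the package."""
    from pathlib import Path

    from PIL import Image

    images_dir = Path(images_dir)
    store: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    for sid in slide_ids:
        patches = []
        for path in sorted(images_dir.glob(f"{sid}_*_*.png")):
            coords = path.stem[len(sid) + 1 :].split("_")
            if len(coords) != 2:
                continue
            x, y = int(coords[0]), int(coords[1])
            patches.append((x, y, np.asarray(Image.open(path).convert("RGB"))))
        if not patches:
            raise FileNotFoundError(f"no patch images for slide {sid} in {images_dir}")
        patches.sort(key=lambda t: (t[1], t[0]))
        store[sid] = patches
    return store


def bags_from_store(
    manifest: pd.DataFrame, store: dict[str, list], split: str | None = None
) -> list[PatchBag]:
    """Assemble patient bags from a manifest plus an on-disk patch store."""
    mf = manifest if split is None else manifest[manifest["split"] == split]
    labels = patient_labels_from_manifest(manifest)
    bags: dict[str, PatchBag] = {}
    for _, row in mf.iterrows():
        pid, sid = row["patient_id"], row["slide_id"]
        if pid not in bags:
            bags[pid] = PatchBag(patient_id=pid, label=labels[pid])
        bags[pid].slides[sid] = np.stack([arr for _, _, arr in store[sid]])
    return list(bags.values())


def patient_labels_from_manifest(df: pd.DataFrame) -> dict[str, int]:
    out: dict[str, int] = {}
    for _, row in df.drop_duplicates("patient_id").iterrows():
        out[row["patient_id"]] = 1 if row["tmb_class"] == "high" else 0
    return out
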