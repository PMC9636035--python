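"""Slide preprocessing: tissue masking, magnification resampling, tiling,
and H&E stain normalization.

Slides are converted into stain-normalized, tissue-only square patches at a
working magnification (default 10x).  Stain normalization follows the
Macenko optical-density construction: pixel optical densities are projected
onto the plane of their top two principal directions, the extreme angular
directions give the hematoxylin and eosin unit vectors, and patches are
re-composed in a reference stain basis after rescaling concentrations.
A simpler Reinhard LAB-statistics matcher is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import uniform_filter
from skimage.color import rgb2hsv, rgb2lab, lab2rgb
from skimage.transform import downscale_local_mean, resize

DEFAULT_SATURATION_THRESHOLD = 0.07
DEFAULT_MIN_TISSUE_FRACTION = 0.5


def load_slide_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF slide image as an 8-bit RGB array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


@dataclass
class SlideRecord:
    """One stained slide: pixel source plus identifiers and magnification."""

    slide_id: str
    patient_id: str
    pixels: np.ndarray | None = None
    path: str | Path | None = None
    native_magnification: float = 40.0
    microns_per_pixel: float | None = None

    def __post_init__(self) -> None:
        if self.native_magnification <= 0:
            raise ValueError("native_magnification must be > 0")
        if self.pixels is None and self.path is None:
            raise ValueError("SlideRecord needs pixels or a path")

    @property
    def image(self) -> np.ndarray:
        if self.pixels is None:
            self.pixels = load_slide_image(self.path)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("slide image must be RGB (H, W, 3)")
        return self.pixels


@dataclass
class TissueMask:
    mask: np.ndarray
    magnification: float

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class Patch:
    """A square tile with provenance at the working magnification."""

    slide_id: str
    patient_id: str
    x: int
    y: int
    size_px: int
    magnification: float
    pixels: np.ndarray
    tissue_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("patch offsets must be >= 0")
        if self.pixels.shape != (self.size_px, self.size_px, 3):
            raise ValueError("patch pixels must be size_px x size_px x 3")


def compute_tissue_mask(
    slide: SlideRecord,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    magnification: float | None = None,
) -> TissueMask:
    """Foreground = pixels whose HSV saturation (after a 3-px box blur)
    exceeds the threshold.  White background has saturation ~0; stained
    tissue is strongly saturated."""
    img = slide.image
    sat = rgb2hsv(img.astype(float) / 255.0)[..., 1]
    sat = uniform_filter(sat, size=3)
    mask = sat > saturation_threshold
    return TissueMask(mask=mask, magnification=magnification or slide.native_magnification)


def resample_to_magnification(slide: SlideRecord, target_magnification: float) -> SlideRecord:
    """Downsample to a lower objective power.  Integer ratios use area
    averaging; fractional ratios fall back to anti-aliased bilinear resizing.
    Upsampling is refused."""
    native = slide.native_magnification
    if target_magnification > native:
        raise ValueError("cannot upsample: target magnification exceeds native")
    if target_magnification == native:
        return replace(slide)
    img = slide.image
    ratio = native / target_magnification
    if abs(ratio - round(ratio)) < 1e-9:
        f = int(round(ratio))
        out = downscale_local_mean(img.astype(float), (f, f, 1))
    else:
        h = int(round(img.shape[0] / ratio))
        w = int(round(img.shape[1] / ratio))
        out = resize(
            img.astype(float), (h, w, 3), order=1, anti_aliasing=True, preserve_range=True
        )
    mpp = slide.microns_per_pixel * ratio if slide.microns_per_pixel is not None else None
    return SlideRecord(
        slide_id=slide.slide_id,
        patient_id=slide.patient_id,
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        native_magnification=target_magnification,
        microns_per_pixel=mpp,
    )


def tile_slide(
    slide: SlideRecord,
    mask: TissueMask,
    patch_px: int,
    stride: int | None = None,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> list[Patch]:
    """Cut a row-major grid of fully-contained tiles; keep a tile iff its
    mask coverage reaches ``min_tissue_fraction``.  Partial edge tiles are
    dropped.  Coordinates are 0-based (x, y) = (column, row) of the
    top-left corner."""
    if stride is None:
        stride = patch_px
    if stride < 1:
        raise ValueError("stride must be >= 1")
    img = slide.image
    h, w = img.shape[:2]
    if mask.mask.shape != (h, w):
        raise ValueError("mask does not match image dimensions")
    if patch_px > h or patch_px > w:
        warnings.warn("patch_px exceeds image dimension; no tiles produced")
        return []
    patches = []
    for y in range(0, h - patch_px + 1, stride):
        for x in range(0, w - patch_px + 1, stride):
            frac = float(mask.mask[y : y + patch_px, x : x + patch_px].mean())
            if frac >= min_tissue_fraction:
                patches.append(
                    Patch(
                        slide_id=slide.slide_id,
                        patient_id=slide.patient_id,
                        x=x,
                        y=y,
                        size_px=patch_px,
                        magnification=slide.native_magnification,
                        pixels=img[y : y + patch_px, x : x + patch_px].copy(),
                        tissue_fraction=frac,
                    )
                )
    return patches


# ---------------------------------------------------------------------------
# Stain normalization (Macenko)
# ---------------------------------------------------------------------------

_OD_EPS = 1.0  # added before the log so pure black maps to a finite OD


def rgb_to_od(img: np.ndarray) -> np.ndarray:
    """Optical density: OD = -ln((I + 1) / 256), per channel."""
    return -np.log((img.astype(float) + _OD_EPS) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    out = 256.0 * np.exp(-od) - _OD_EPS
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class StainReference:
    """Two unit optical-density vectors (hematoxylin, eosin columns of a
    3x2 matrix) plus robust maximum concentrations for rescaling."""

    stain_matrix: np.ndarray  # (3, 2), unit columns, nonnegative
    max_concentrations: np.ndarray  # (2,), positive

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must have unit norm")
        if np.any(self.stain_matrix < -1e-9):
            raise ValueError("stain matrix entries must be nonnegative")
        if np.any(self.max_concentrations <= 0):
            raise ValueError("max concentrations must be positive")


def fit_stain_reference(
    image: np.ndarray,
    od_threshold: float = 0.15,
    percentile: float = 99.0,
) -> StainReference:
    """Estimate H&E stain vectors by the Macenko construction.

    Stained pixels (OD norm above threshold) are projected onto the plane of
    the top two principal directions of their OD cloud; the extreme angular
    directions at ``100 - percentile`` and ``percentile`` give the two stain
    vectors.  The hematoxylin column is, by convention, the more blue-heavy
    one (larger blue optical density).
    """
    od = rgb_to_od(image).reshape(-1, 3)
    keep = od[np.linalg.norm(od, axis=1) > od_threshold]
    if keep.shape[0] < 100:
        raise ValueError("insufficient stained tissue above od_threshold")

    cov = np.cov(keep.T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argsort(evals)[::-1][:2]]  # (3, 2) top-2 plane
    # orient the basis so projections are mostly positive
    for j in range(2):
        if v[:, j].sum() < 0:
            v[:, j] = -v[:, j]

    proj = keep @ v
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, 100.0 - percentile)
    hi = np.percentile(phi, percentile)
    v1 = v @ np.array([np.cos(lo), np.sin(lo)])
    v2 = v @ np.array([np.cos(hi), np.sin(hi)])
    vecs = np.stack([v1, v2], axis=1)
    vecs = np.clip(vecs, 0.0, None)
    norms = np.linalg.norm(vecs, axis=0)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate stain direction")
    vecs = vecs / norms

    # ordering convention: hematoxylin is the blue-heavier stain, i.e. the
    # column with the larger blue OD component (~0.29 vs eosin's ~0.11)
    if vecs[2, 0] < vecs[2, 1]:
        vecs = vecs[:, ::-1]

    conc = np.linalg.lstsq(vecs, keep.T, rcond=None)[0]
    conc = np.clip(conc, 0.0, None)
    max_c = np.percentile(conc, percentile, axis=1)
    max_c = np.maximum(max_c, 1e-6)
    return StainReference(stain_matrix=vecs, max_concentrations=max_c)


def stain_normalize(
    patch: np.ndarray,
    source_ref: StainReference,
    target_ref: StainReference,
) -> np.ndarray:
    """Map a patch from its source stain basis to a target basis.

    The patch is deconvolved against the source stain matrix, the two
    concentration maps are rescaled by the ratio of robust maxima, and the
    image is re-composed with the target matrix via Beer-Lambert.
    """
    m_src, m_tgt = source_ref.stain_matrix, target_ref.stain_matrix
    cos_angle = abs(float(m_src[:, 0] @ m_src[:, 1]))
    if cos_angle > 1.0 - 1e-6:
        raise ValueError("singular deconvolution: collinear stain vectors")
    shape = patch.shape
    od = rgb_to_od(patch).reshape(-1, 3)
    conc = np.linalg.lstsq(m_src, od.T, rcond=None)[0]
    conc = np.clip(conc, 0.0, None)
    scale = target_ref.max_concentrations / source_ref.max_concentrations
    od_out = (m_tgt @ (conc * scale[:, None])).T
    return od_to_rgb(od_out).reshape(shape)


def compose_from_stains(
    concentrations: np.ndarray, stain_matrix: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Beer-Lambert synthesis: build an RGB image from known stain vectors
    and per-pixel concentrations (the inverse of deconvolution; useful as a
    ground-truth construction)."""
    od = (np.asarray(stain_matrix) @ concentrations).T
    return od_to_rgb(od).reshape(shape + (3,))


def reinhard_normalize(patch: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Reinhard colour transfer: match per-channel LAB mean/std to a target
    image.  Provided as a lighter-weight alternative to Macenko."""
    src = rgb2lab(patch.astype(float) / 255.0)
    tgt = rgb2lab(target.astype(float) / 255.0)
    out = np.empty_like(src)
    for c in range(3):
        s_mu, s_sd = src[..., c].mean(), src[..., c].std() + 1e-9
        t_mu, t_sd = tgt[..., c].mean(), tgt[..., c].std() + 1e-9
        out[..., c] = (src[..., c] - s_mu) / s_sd * t_sd + t_mu
    rgb = lab2rgb(out)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
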