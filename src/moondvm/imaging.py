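"""Recover detections from shadowgraph frames.

Shadowgraph optics project collimated light through a 10 cm water path onto
a camera, so organisms appear as dark, size-preserving silhouettes on a
bright field. The processing chain is: flat-field correction (divide by a
per-pixel background estimate), dark-threshold binarization and 8-connected
component labelling, ROI extraction with pixel-area thresholds, moment-based
ellipse morphometry with an equivalent spherical diameter (ESD) from a
prolate-spheroid volume model, a pluggable rule-based taxon classifier, and
a hard ESD admissibility filter (> 0.36 mm, the size below which the
instrument's practical resolution cannot be trusted).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "Frame",
    "Morphometry",
    "DETECTION_COLUMNS",
    "estimate_background",
    "flatfield",
    "binarize_segment",
    "extract_rois",
    "measure_roi",
    "classify_roi",
    "rule_based_classifier",
    "segment_frame",
    "detect_profile",
    "filter_detections",
]

#: columns of a detection table
DETECTION_COLUMNS = (
    "profile_id",
    "frame_index",
    "centroid_row",
    "centroid_col",
    "area_px",
    "major_axis_mm",
    "minor_axis_mm",
    "esd_mm",
    "taxon",
    "score",
    "depth_m",
)

ESD_MIN_MM = 0.36


@dataclass
class Frame:
    """One 8-bit grayscale shadowgraph frame with its depth metadata."""

    pixels: np.ndarray           # uint8, (rows, cols); row 0 = shallowest
    pixel_pitch_mm: float        # mm per pixel (0.021 at full resolution)
    top_depth_m: float           # depth of the frame's top edge
    time: datetime | None = None
    profile_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")

    @property
    def height_m(self) -> float:
        return self.pixels.shape[0] * self.pixel_pitch_mm / 1000.0

    @property
    def bottom_depth_m(self) -> float:
        return self.top_depth_m + self.height_m


# ---------------------------------------------------------------------------
# Flat-fielding
# ---------------------------------------------------------------------------

def estimate_background(frames: list[np.ndarray] | np.ndarray, window: int = 21) -> np.ndarray:
    """Per-pixel background from a sliding median over frames.

    For fewer frames than the window the median runs over what is available.
    """
    stack = np.asarray([np.asarray(f, dtype=float) for f in frames])
    if stack.ndim != 3:
        raise ValueError("expected a stack of 2-D frames")
    w = min(window, stack.shape[0])
    return np.median(stack[:w], axis=0)


def flatfield(pixels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Divide a frame by a background reference to remove optical gradients.

    The ratio image is rescaled to unit mean and mapped back to 8-bit at the
    original mean grey level, so corrected frames remain comparable to the
    raw ones.
    """
    ref = np.asarray(reference, dtype=float)
    img = np.asarray(pixels, dtype=float)
    if ref.shape != img.shape:
        raise ValueError(f"reference shape {ref.shape} != frame shape {img.shape}")
    if np.any(ref <= 0):
        raise ValueError("reference contains non-positive pixels")
    ratio = img / ref
    ratio /= ratio.mean()
    out = np.clip(ratio * img.mean(), 0, 255)
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def binarize_segment(pixels: np.ndarray, k_sigma: float = 3.0) -> np.ndarray:
    """Label connected dark particles in a flat-fielded frame.

    Foreground is every pixel darker than (background mean − k_sigma × SD),
    with background statistics taken over the whole frame (particles are
    sparse). If that threshold is degenerate — no spread, or a threshold
    claiming more than a quarter of the frame — an Otsu threshold is used
    instead. Components are 8-connected.
    """
    img = np.asarray(pixels, dtype=float)
    mean, sd = img.mean(), img.std()
    if sd < 1e-9:
        return np.zeros(img.shape, dtype=int)
    thr = mean - k_sigma * sd
    mask = img < thr
    frac = mask.mean()
    if thr <= img.min() or frac > 0.25:
        try:
            thr = threshold_otsu(img.astype(np.uint8))
            mask = img < thr
        except ValueError:
            return np.zeros(img.shape, dtype=int)
        if mask.mean() > 0.5:  # frame is mostly dark: nothing sensible to segment
            return np.zeros(img.shape, dtype=int)
    return measure.label(mask, connectivity=2)


@dataclass
class Vignette:
    """One extracted ROI: mask and image crop with its frame-coordinate bbox."""

    mask: np.ndarray    # bool, cropped with margin
    image: np.ndarray   # uint8 crop, same shape as mask
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1) in frame coords
    area_px: int
    label: int


def extract_rois(
    labels: np.ndarray,
    pixels: np.ndarray,
    min_px: int = 50,
    max_px: int = 500_000,
    margin_px: int = 5,
) -> list[Vignette]:
    """Crop one vignette per labelled component inside [min_px, max_px].

    The default ``min_px`` keeps the smallest admissible organism (0.36 mm
    ESD, ≈230 px silhouette area at 21 µm pitch) with comfortable margin
    while rejecting noise speckle; divide it by scale_factor² when working
    on downscaled frames.
    """
    if min_px >= max_px:
        raise ValueError("min_px must be < max_px")
    img = np.asarray(pixels)
    out = []
    for region in measure.regionprops(labels):
        if not (min_px <= region.area <= max_px):
            continue
        r0, c0, r1, c1 = region.bbox
        r0m, c0m = max(r0 - margin_px, 0), max(c0 - margin_px, 0)
        r1m = min(r1 + margin_px, labels.shape[0])
        c1m = min(c1 + margin_px, labels.shape[1])
        mask = labels[r0m:r1m, c0m:c1m] == region.label
        out.append(
            Vignette(
                mask=mask,
                image=img[r0m:r1m, c0m:c1m].copy(),
                bbox=(r0m, c0m, r1m, c1m),
                area_px=int(region.area),
                label=int(region.label),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

@dataclass
class Morphometry:
    area_px: int
    major_axis_mm: float
    minor_axis_mm: float
    esd_mm: float
    aspect_ratio: float
    solidity: float
    n_protrusions: int
    centroid_row: float   # vignette-local, body centroid
    centroid_col: float


def measure_roi(vignette: Vignette | np.ndarray, pixel_pitch_mm: float, opening_radius: int = 2) -> Morphometry:
    """Ellipse morphometry and ESD of one silhouette.

    Thin appendages (copepod antennae) inflate moment-based axes, so the
    body is isolated by a small morphological opening before the ellipse
    fit; the removed residual provides the protrusion count used by the
    classifier. The volume model is a prolate spheroid on the fitted axes,
    V = (π/6)·major·minor², giving ESD = (major · minor²)^(1/3) — which
    reduces to the diameter for a circular silhouette.
    """
    mask = vignette.mask if isinstance(vignette, Vignette) else np.asarray(vignette, bool)
    if mask.sum() == 0:
        raise ValueError("empty vignette: no foreground pixels")
    body = morphology.opening(mask, morphology.disk(opening_radius)) if opening_radius else mask
    if body.sum() < 4:
        body = mask
    props = measure.regionprops(body.astype(int))[0]
    major_px = props.axis_major_length
    minor_px = max(props.axis_minor_length, 1.0)  # 1-px-thin objects: floor at one pixel
    major_mm = major_px * pixel_pitch_mm
    minor_mm = minor_px * pixel_pitch_mm
    if minor_mm > major_mm:
        major_mm, minor_mm = minor_mm, major_mm
    esd = (major_mm * minor_mm**2) ** (1.0 / 3.0)

    full = measure.regionprops(mask.astype(int))[0]
    residual = mask & ~body
    n_prot = 0
    if residual.any():
        for r in measure.regionprops(measure.label(residual, connectivity=2)):
            if r.area >= max(3, opening_radius):
                n_prot += 1
    return Morphometry(
        area_px=int(mask.sum()),
        major_axis_mm=float(major_mm),
        minor_axis_mm=float(minor_mm),
        esd_mm=float(esd),
        aspect_ratio=float(major_mm / minor_mm),
        solidity=float(full.solidity),
        n_protrusions=n_prot,
        centroid_row=float(props.centroid[0]),
        centroid_col=float(props.centroid[1]),
    )


# ---------------------------------------------------------------------------
# Classification (rule-based stand-in behind a pluggable interface)
# ---------------------------------------------------------------------------

def rule_based_classifier(morph: Morphometry) -> tuple[str, float]:
    """Default taxon rule: shape separates the two crustacean groups.

    Copepods are elongated (aspect ≥ 2) and carry thin antennae
    (≥ 2 protrusions); cladocerans are compact ovoids of high solidity.
    The score is a bounded margin from the decision surface. Any callable
    with this signature can replace it (e.g. a learned model).
    """
    if morph.aspect_ratio >= 2.0 or morph.n_protrusions >= 2:
        margin = max(morph.aspect_ratio - 2.0, 0.5 * (morph.n_protrusions - 1))
        return "copepod", float(np.clip(0.6 + 0.4 * margin, 0.0, 1.0))
    if morph.aspect_ratio < 2.0 and morph.solidity >= 0.9:
        margin = min(2.0 - morph.aspect_ratio, 10.0 * (morph.solidity - 0.9))
        return "cladoceran", float(np.clip(0.6 + 0.4 * margin, 0.0, 1.0))
    return "other", 0.5


def classify_roi(morph: Morphometry, classifier=None) -> tuple[str, float]:
    """Apply a taxon classifier (default: the rule-based one) to one ROI."""
    taxon, score = (classifier or rule_based_classifier)(morph)
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"classifier score {score} outside [0, 1]")
    return taxon, score


# ---------------------------------------------------------------------------
# Frame- and profile-level drivers
# ---------------------------------------------------------------------------

def segment_frame(
    frame: Frame,
    reference: np.ndarray | None = None,
    *,
    k_sigma: float = 3.0,
    min_px: int | None = None,
    max_px: int = 500_000,
    margin_px: int = 5,
    opening_radius: int | None = None,
    classifier=None,
    scale_factor: int = 1,
) -> pd.DataFrame:
    """Full per-frame chain: flat-field → segment → measure → classify.

    ``scale_factor`` only rescales the pixel-area threshold and opening
    radius defaults for downscaled frames; the pitch is read from the frame.
    Depth is assigned as top_depth + centroid_row × pitch.
    """
    if min_px is None:
        min_px = max(int(round(50 / scale_factor**2)), 3)
    if opening_radius is None:
        opening_radius = 2 if scale_factor <= 2 else 1
    pixels = flatfield(frame.pixels, reference) if reference is not None else frame.pixels
    labels = binarize_segment(pixels, k_sigma=k_sigma)
    rows = []
    for vig in extract_rois(labels, pixels, min_px=min_px, max_px=max_px, margin_px=margin_px):
        morph = measure_roi(vig, frame.pixel_pitch_mm, opening_radius=opening_radius)
        taxon, score = classify_roi(morph, classifier)
        row0, col0 = vig.bbox[0], vig.bbox[1]
        centroid_row = row0 + morph.centroid_row
        centroid_col = col0 + morph.centroid_col
        rows.append(
            {
                "profile_id": frame.profile_id,
                "frame_index": frame.frame_index,
                "centroid_row": centroid_row,
                "centroid_col": centroid_col,
                "area_px": morph.area_px,
                "major_axis_mm": morph.major_axis_mm,
                "minor_axis_mm": morph.minor_axis_mm,
                "esd_mm": morph.esd_mm,
                "taxon": taxon,
                "score": score,
                "depth_m": frame.top_depth_m + centroid_row * frame.pixel_pitch_mm / 1000.0,
            }
        )
    return pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))


def detect_profile(
    frames: list[Frame],
    *,
    background_window: int = 21,
    scale_factor: int = 1,
    classifier=None,
    k_sigma: float = 3.0,
) -> pd.DataFrame:
    """Detections for a whole profile, flat-fielding against a blocked median.

    The per-pixel median background is estimated once per window of
    ``background_window`` consecutive frames and shared by the frames of
    that window; organisms are sparse enough that the median is unaffected
    by which frames contribute.
    """
    if not frames:
        return pd.DataFrame(columns=list(DETECTION_COLUMNS))
    stack = [f.pixels for f in frames]
    tables = []
    for lo in range(0, len(frames), background_window):
        hi = min(lo + background_window, len(frames))
        reference = np.maximum(estimate_background(stack[lo:hi], window=background_window), 1.0)
        for frame in frames[lo:hi]:
            tables.append(
                segment_frame(
                    frame, reference, classifier=classifier,
                    scale_factor=scale_factor, k_sigma=k_sigma,
                )
            )
    non_empty = [t for t in tables if len(t)]
    if not non_empty:
        return pd.DataFrame(columns=list(DETECTION_COLUMNS))
    return pd.concat(non_empty, ignore_index=True)


def filter_detections(detections: pd.DataFrame, esd_min: float = ESD_MIN_MM) -> pd.DataFrame:
    """Keep detections strictly above the ESD admissibility bound; order kept."""
    if detections.empty:
        return detections.copy()
    return detections.loc[detections["esd_mm"] > esd_min].reset_index(drop=True)
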