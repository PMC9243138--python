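"""Intrinsic-signal imaging: fractional reflectance change (dR/R), z-scored
activation maps, activated-region extraction, and Sobel-based c-Fos counting.

The z-map normalizes each pixel's dR/R by the mean and population standard
deviation taken over all pixels of the same map, so a valid z-map always has
pixel mean 0 and SD 1 and is invariant under positive affine transforms of
the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage import filters, measure, morphology
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError, ValidationError

#: number of pre-stimulus frames averaged into the dR/R base image
BASELINE_FRAMES = 20


@dataclass
class ImageStack:
    """Time-ordered reflectance frames with the stimulus-onset frame index."""

    frames: np.ndarray          # (T, H, W)
    frame_rate: float = 20.0
    stimulus_onset_index: int = BASELINE_FRAMES
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (T, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frames contain non-finite values")
        if self.stimulus_onset_index < BASELINE_FRAMES:
            raise ValidationError(
                f"need >= {BASELINE_FRAMES} frames before the stimulus onset")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ZMap:
    """Z-scored dR/R map (pixel mean 0, population SD 1 over all pixels)."""

    values: np.ndarray
    source_window: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        v = self.values
        if abs(float(v.mean())) > 1e-9 or abs(float(v.std()) - 1.0) > 1e-9:
            raise ValidationError("z-map must have pixel mean 0 and population SD 1")


@dataclass(frozen=True)
class ActiveRegion:
    """Largest suprathreshold connected component of a z-map."""

    mask: np.ndarray
    centroid: tuple | None      # (row, col), |z|-weighted; None if empty
    area: int

    @property
    def empty(self) -> bool:
        return self.centroid is None


@dataclass(frozen=True)
class CellCountResult:
    count: int
    centroids: np.ndarray       # (n, 2) row/col
    parameters: dict

    def __post_init__(self):
        if self.count != len(self.centroids):
            raise ValidationError("count must equal the number of centroids")


# ---------------------------------------------------------------------------
# stack I/O: multi-page TIFF + sidecar JSON
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = {"frame_rate": stack.frame_rate,
               "stimulus_onset_index": int(stack.stimulus_onset_index)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ImageStack(frames=frames, frame_rate=float(sidecar["frame_rate"]),
                      stimulus_onset_index=int(sidecar["stimulus_onset_index"]))


# ---------------------------------------------------------------------------
# dR/R and z-map
# ---------------------------------------------------------------------------

def compute_drr(stack: ImageStack,
                response_window: tuple[int, int] | None = None) -> np.ndarray:
    """Fractional reflectance change (response - base) / base.

    The base image is the average of the 20 frames immediately preceding the
    stimulus onset; the response image averages ``response_window`` (frame
    indices, half-open), defaulting to the 2 s after onset.
    """
    onset = stack.stimulus_onset_index
    if response_window is None:
        response_window = (onset, min(stack.n_frames,
                                      onset + int(round(2.0 * stack.frame_rate))))
    lo, hi = response_window
    if lo < onset or hi <= lo or hi > stack.n_frames:
        raise ParameterError("response_window must lie after the stimulus onset "
                             "and inside the stack")
    base = stack.frames[onset - BASELINE_FRAMES:onset].mean(axis=0)
    n_zero = int(np.sum(base == 0.0))
    if n_zero:
        raise DegenerateInputError(
            f"{n_zero} pixels have zero baseline reflectance; dR/R is undefined")
    resp = stack.frames[lo:hi].mean(axis=0)
    return (resp - base) / base


def zscore_map(drr: np.ndarray,
               source_window: tuple | None = None) -> ZMap:
    """Z-score a dR/R map over all of its own pixels (population SD)."""
    drr = np.asarray(drr, dtype=float)
    if drr.size < 2:
        raise ParameterError("z-scoring needs at least 2 pixels")
    sd = float(drr.std())      # population SD (divide by N)
    # treat float-rounding residue on a constant map as zero spread
    if sd <= 1e-13 * max(1.0, abs(float(drr.mean()))):
        raise DegenerateInputError("constant dR/R map has zero SD; z-map undefined")
    return ZMap(values=(drr - drr.mean()) / sd, source_window=source_window)


def active_region(zmap: ZMap, z_threshold: float = 2.0,
                  min_area_px: int = 10) -> ActiveRegion:
    """Largest connected component with |z| >= threshold and sufficient area.

    The centroid is the |z|-intensity-weighted mean pixel position of the
    component; an empty result (no component) is returned, not an error.
    """
    if not np.isfinite(z_threshold):
        raise ParameterError("z_threshold must be finite")
    z = zmap.values
    mask = np.abs(z) >= z_threshold
    labels = measure.label(mask, connectivity=2)
    best_label, best_area = 0, 0
    for region in measure.regionprops(labels):
        if region.area >= min_area_px and region.area > best_area:
            best_label, best_area = region.label, region.area
    if best_label == 0:
        return ActiveRegion(mask=np.zeros_like(mask), centroid=None, area=0)
    comp = labels == best_label
    w = np.abs(z) * comp
    rr, cc = np.nonzero(comp)
    wt = w[rr, cc]
    centroid = (float(np.sum(rr * wt) / wt.sum()),
                float(np.sum(cc * wt) / wt.sum()))
    return ActiveRegion(mask=comp, centroid=centroid, area=int(best_area))


# ---------------------------------------------------------------------------
# c-Fos counting (DAB histology)
# ---------------------------------------------------------------------------

def count_cfos(image: np.ndarray, min_area_px: int = 20,
               max_area_px: int = 400) -> CellCountResult:
    """Count labelled somata: Sobel edge magnitude, Otsu binarization,
    morphological closing + hole filling, then connected components filtered
    to the plausible soma-area range.

    Overlapping somata merge into one component — a documented limitation of
    the connected-components stage.  A blank image counts zero cells.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ParameterError("image must be finite")
    params = {"min_area_px": min_area_px, "max_area_px": max_area_px,
              "threshold": "otsu", "edge": "sobel"}
    if image.max() == image.min():
        return CellCountResult(0, np.empty((0, 2)), params)
    grad = filters.sobel(image)
    thr = filters.threshold_otsu(grad)
    binary = grad > thr
    binary = ndimage.binary_closing(binary, structure=morphology.disk(2))
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    centroids = [r.centroid for r in measure.regionprops(labels)
                 if min_area_px <= r.area <= max_area_px]
    return CellCountResult(len(centroids),
                           np.asarray(centroids).reshape(-1, 2), params)
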