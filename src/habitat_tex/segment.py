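"""Semi-automatic lesion segmentation on subtraction images.

The segmentation protocol: subtract the pre-contrast frame from each
post-contrast frame, normalize the operator-supplied region of interest
(ROI) of the 4th-phase subtraction image to the window mean +/- 3 SD,
requantize to 8 bits, delineate the lesion with a spatial fuzzy C-means
(FCM) clustering of gray levels (memberships smoothed by a local window
each iteration), and refine the candidate mask morphologically
(largest 4-connected component, hole filling, 3x3-cross opening).

All coordinates are 0-based row-major ``(row, col)``; masks are aligned to
the full image frame.  Segmentation is a pure function of the pixel data —
scanner/cohort tags play no role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synth import DCEStudy

__all__ = [
    "QuantizedROI",
    "FCMParams",
    "DegenerateROIError",
    "SegmentationFailure",
    "subtract",
    "roi_from_mask",
    "normalize_quantize",
    "spatial_fcm",
    "refine",
    "select_slice",
    "segment_study",
]

#: 4-connectivity structuring element, also used as the opening footprint.
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class DegenerateROIError(ValueError):
    """ROI has zero gray-level spread (sigma = 0); normalization undefined."""


class SegmentationFailure(RuntimeError):
    """No usable lesion component could be produced."""


@dataclass
class QuantizedROI:
    """A clipped, 8-bit requantized ROI patch with its normalization window.

    ``mu`` and ``sigma`` are the mean and SD of the raw gray levels inside
    the ROI; values were clipped to ``[mu - 3 sigma, mu + 3 sigma]`` and
    mapped linearly onto ``[0, 255]`` with half-up rounding, so the window
    reproduces the mapping exactly.
    """

    patch: np.ndarray  # uint8 (r, c)
    mu: float
    sigma: float
    box: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open, image frame

    def __post_init__(self) -> None:
        if self.patch.min() < 0 or self.patch.max() > 255:
            raise ValueError("quantized patch must lie in [0, 255]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class FCMParams:
    """Spatial fuzzy C-means settings (deterministic by construction)."""

    clusters: int = 2
    fuzziness: float = 2.0
    window: int = 3  # side of the mean filter applied to memberships
    tol: float = 1e-5
    max_iter: int = 100
    init_centroids: tuple[float, ...] = (64.0, 192.0)
    seed: int = 0  # reserved; the default init is deterministic


def subtract(study: DCEStudy) -> np.ndarray:
    """Subtraction series: ``post_k - pre`` for the 8 phases, stored signed."""
    if study.post.shape[1:] != study.pre.shape:
        raise ValueError("pre/post shape mismatch")
    return study.post.astype(np.float64) - study.pre.astype(np.float64)[None]


def roi_from_mask(mask: np.ndarray, dilate: int = 10) -> tuple[int, int, int, int]:
    """Bounding box of ``mask`` dilated by ``dilate`` pixels, clipped to frame.

    Stands in for the radiologist's hand-drawn ROI in the synthetic
    pipeline.  Returns a half-open box ``(r0, c0, r1, c1)``.
    """
    if not mask.any():
        raise SegmentationFailure("empty truth mask, cannot derive ROI")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(int(rows[0]) - dilate, 0)
    r1 = min(int(rows[-1]) + 1 + dilate, mask.shape[0])
    c0 = max(int(cols[0]) - dilate, 0)
    c1 = min(int(cols[-1]) + 1 + dilate, mask.shape[1])
    return r0, c0, r1, c1


def normalize_quantize(
    image: np.ndarray, roi: tuple[int, int, int, int]
) -> QuantizedROI:
    """Clip an ROI to mean +/- 3 SD and requantize to 8 bits.

    The window statistics are computed over the ROI pixels; values are
    clipped to ``[mu - 3 sigma, mu + 3 sigma]``, mapped linearly to
    ``[0, 255]`` and rounded half-up.
    """
    r0, c0, r1, c1 = roi
    patch = np.asarray(image, dtype=np.float64)[r0:r1, c0:c1]
    if patch.size < 16:
        raise ValueError("ROI must contain at least 16 pixels")
    mu = float(patch.mean())
    sigma = float(patch.std())
    if sigma == 0:
        raise DegenerateROIError("constant ROI: sigma = 0")
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    clipped = np.clip(patch, lo, hi)
    scaled = (clipped - lo) / (hi - lo) * 255.0
    quant = np.floor(scaled + 0.5).astype(np.uint8)  # round half-up
    return QuantizedROI(patch=quant, mu=mu, sigma=sigma, box=(r0, c0, r1, c1))


def spatial_fcm(qroi: QuantizedROI, params: FCMParams | None = None) -> np.ndarray:
    """Delineate the lesion by spatial fuzzy C-means on gray levels.

    Standard FCM membership/centroid updates on pixel intensities, with the
    spatial twist that after every membership update the membership maps are
    smoothed by a ``window x window`` mean filter, which regularizes the
    contour against isolated noisy pixels.  A pixel joins the cluster with
    the highest final membership; the lesion is the cluster with the
    brightest centroid (lesions enhance, background does not).

    Returns the candidate lesion mask on the patch grid.
    """
    params = params or FCMParams()
    x = qroi.patch.astype(np.float64).ravel()
    shape = qroi.patch.shape
    c = params.clusters
    m = params.fuzziness
    centroids = np.array(params.init_centroids[:c], dtype=np.float64)
    if centroids.size != c:
        raise ValueError("need one initial centroid per cluster")

    u = np.full((c, x.size), 1.0 / c)
    exponent = 2.0 / (m - 1.0)
    converged = False
    for _ in range(params.max_iter):
        d = np.abs(x[None, :] - centroids[:, None])
        d = np.maximum(d, 1e-12)
        inv = d ** (-exponent)
        u_new = inv / inv.sum(axis=0, keepdims=True)
        # spatial regularization: local mean of each membership map
        u_new = np.stack([
            ndimage.uniform_filter(ui.reshape(shape), size=params.window, mode="nearest").ravel()
            for ui in u_new
        ])
        u_new /= u_new.sum(axis=0, keepdims=True)
        um = u_new ** m
        centroids = (um @ x) / np.maximum(um.sum(axis=1), 1e-12)
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn("spatial FCM did not converge; returning current assignment",
                      RuntimeWarning, stacklevel=2)
    labels = np.argmax(u, axis=0).reshape(shape)
    return labels == int(np.argmax(centroids))


def refine(mask: np.ndarray) -> np.ndarray:
    """Morphological refinement of a candidate mask.

    Keeps the largest 4-connected component, fills holes, then applies a
    binary opening with a 3x3 cross.  Raises if nothing survives.
    """
    if not mask.any():
        raise SegmentationFailure("empty candidate mask")
    lab, n = ndimage.label(mask, structure=CROSS)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    largest = lab == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(largest)
    opened = ndimage.binary_opening(filled, structure=CROSS)
    if not opened.any():
        raise SegmentationFailure("mask vanished after morphological opening")
    # opening can split the component; keep the largest piece again
    lab2, n2 = ndimage.label(opened, structure=CROSS)
    if n2 > 1:
        sizes2 = ndimage.sum_labels(np.ones_like(lab2), lab2, index=np.arange(1, n2 + 1))
        opened = lab2 == (1 + int(np.argmax(sizes2)))
    return ndimage.binary_fill_holes(opened)


def select_slice(volumes: np.ndarray, roi_per_slice=None) -> int:
    """Pick the slice with the largest enhancing area on phase-4 subtraction.

    Automated surrogate for the reading-room rule of choosing the slice
    with the maximum tumor diameter.  2D input (no slice axis) returns 0.
    ``volumes`` is either a (8, R, C) subtraction series (treated as one
    slice) or a (S, 8, R, C) stack of per-slice subtraction series.
    """
    volumes = np.asarray(volumes)
    if volumes.ndim == 3:
        return 0
    if volumes.ndim != 4:
        raise ValueError("expected (8,R,C) or (S,8,R,C)")
    areas = []
    for s in range(volumes.shape[0]):
        phase4 = volumes[s, 3]
        thr = phase4.mean() + 2.0 * phase4.std()
        areas.append(int((phase4 > thr).sum()))
    if max(areas) == 0:
        raise SegmentationFailure("no enhancing region on any slice")
    return int(np.argmax(areas))  # argmax takes the smallest index on ties


@dataclass
class SegmentationResult:
    mask: np.ndarray  # full-frame boolean lesion mask
    qroi: QuantizedROI  # quantized phase-4 subtraction ROI (texture input)
    params: FCMParams = field(default_factory=FCMParams)


def segment_study(
    study: DCEStudy,
    roi: tuple[int, int, int, int] | None = None,
    truth_mask: np.ndarray | None = None,
    params: FCMParams | None = None,
    phase: int = 4,
) -> SegmentationResult:
    """Run the full segmentation chain on one study.

    ``roi`` is the operator box; if absent it is derived from
    ``truth_mask`` (synthetic stand-in for the hand-drawn ROI).
    ``phase`` is 1-based; the protocol reads the 4th subtraction phase.
    """
    sub = subtract(study)
    if roi is None:
        if truth_mask is None:
            raise ValueError("need either an ROI box or a truth mask")
        roi = roi_from_mask(truth_mask)
    qroi = normalize_quantize(sub[phase - 1], roi)
    cand = spatial_fcm(qroi, params)
    if not cand.any():
        raise SegmentationFailure("FCM produced an empty lesion cluster")
    refined = refine(cand)
    full = np.zeros(study.pre.shape, dtype=bool)
    r0, c0, r1, c1 = qroi.box
    full[r0:r1, c0:c1] = refined
    return SegmentationResult(mask=full, qroi=qroi, params=params or FCMParams())
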