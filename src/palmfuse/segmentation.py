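"""Palm-region segmentation by mode-method thresholding and binary morphology.

Palm images (flatbed scanner) and infrared palm-dorsum images share one
property that makes segmentation easy: a bright hand on a dark background,
so the gray-level histogram is bimodal.  The mode method places the
threshold at the valley — the gray value with the minimum count strictly
between the two dominant histogram peaks P1 and P2.  The binarized mask is
then repaired by dilating twice and eroding twice (a closing that fills
dark principal-line pixels and boundary nicks) and reduced to its largest
8-connected component.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import NoBimodalStructureError, PalmFuseError

#: Default structuring element: 3x3 square, origin at center.
SQUARE_3x3 = np.ones((3, 3), dtype=bool)

#: Moving-average window (bins) applied to the histogram before extremum
#: detection; raw IR histograms are spiky.
HIST_SMOOTH_WINDOW = 5


def gray_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit image (counts indexed by gray value)."""
    img = np.asarray(img)
    return np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]


def _smooth_counts(counts: np.ndarray, window: int = HIST_SMOOTH_WINDOW) -> np.ndarray:
    kernel = np.ones(window) / window
    # reflect padding keeps the end bins comparable to interior bins
    padded = np.pad(counts.astype(float), window // 2, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local maxima (plateau -> median index)."""
    maxima: list[int] = []
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def select_mode_threshold(counts: np.ndarray) -> int:
    """Mode-method threshold: histogram valley between the two dominant peaks.

    The (smoothed) histogram must be bimodal.  The two local maxima with the
    largest counts are taken as the peaks P1 < P2; the returned threshold B
    is the gray value with the minimum smoothed count strictly between them.
    A plateau of minimal bins is broken at its median index, which is
    deterministic and symmetric.

    Raises
    ------
    NoBimodalStructureError
        If fewer than two local maxima remain after smoothing.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) != 256 or counts.sum() == 0:
        raise PalmFuseError("histogram must be 256 non-negative counts")
    smooth = _smooth_counts(counts)
    maxima = _local_maxima(smooth)
    if len(maxima) < 2:
        raise NoBimodalStructureError("no bimodal structure in histogram")
    # two dominant peaks by smoothed count; ties broken toward lower gray
    top2 = sorted(sorted(maxima, key=lambda i: (-smooth[i], i))[:2])
    lo, hi = top2
    if hi - lo < 2:
        raise NoBimodalStructureError("peaks adjacent: no interior valley")
    valley = smooth[lo + 1 : hi]
    run = np.flatnonzero(valley == valley.min())
    # plateau tie-break: median index of the minimal run
    return int(lo + 1 + run[(len(run) - 1) // 2])


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground = pixels >= threshold (hand brighter than background)."""
    return (np.asarray(img) >= threshold).astype(np.uint8)


def morph(mask: np.ndarray, se: np.ndarray = SQUARE_3x3, kind: str = "dilate") -> np.ndarray:
    """Binary dilation (union of translates) or erosion (intersection).

    Cells translated outside the grid are dropped; the output has the same
    shape as the input.
    """
    se = np.asarray(se).astype(bool)
    if se.size == 0 or not se.any():
        raise PalmFuseError("invalid structuring element: no set cell")
    mask = np.asarray(mask).astype(bool)
    if kind == "dilate":
        out = ndimage.binary_dilation(mask, structure=se)
    elif kind == "erode":
        # outside-the-grid counts as foreground: the exact dual of dilation
        # (which treats outside as background), and keeps the wrist's
        # bottom-edge contact through the dilate/dilate/erode/erode repair
        out = ndimage.binary_erosion(mask, structure=se, border_value=1)
    else:
        raise PalmFuseError(f"unknown morphology kind: {kind!r}")
    return out.astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    labels, n = ndimage.label(np.asarray(mask) > 0, structure=np.ones((3, 3)))
    if n == 0:
        return np.zeros_like(mask, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)


def segment_palm_region(img: np.ndarray, se: np.ndarray = SQUARE_3x3) -> np.ndarray:
    """Full segmentation: mode threshold, dilate x2, erode x2, largest component."""
    th = select_mode_threshold(gray_histogram(img))
    mask = binarize(img, th)
    for _ in range(2):
        mask = morph(mask, se, "dilate")
    for _ in range(2):
        mask = morph(mask, se, "erode")
    return largest_component(mask)
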