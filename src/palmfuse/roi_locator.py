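"""Peg-free ROI localization from the hand contour distance profile.

The hand is presented fingers-up with the wrist on the bottom image edge.
The palm mask's inner border is traced counterclockwise from the
bottom-left foreground pixel; the Euclidean distance from the wrist
midpoint ``W_M`` to each contour pixel forms a distance-distribution
profile whose five local maxima are the fingertips and whose four local
minima between consecutive tips are the finger webs FW1..FW4 (ordered from
the thumb side).  The segment FS between FW2 and FW4 fixes both the
rotation normalization (rotate by -theta so FS is horizontal) and the ROI:
a square of side 1.5*|FS|, top side parallel to FS at offset |FS|/4 toward
the palm, horizontally centered on the FW2/FW4 midpoint.  Palm ROIs are
normalized to 256x256 pixels, palm-dorsum (vein) ROIs to 64x64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.transform import SimilarityTransform, resize, warp

from .errors import HandNotOutstretchedError, PalmFuseError, RoiOutOfFrameError
from .segmentation import segment_palm_region

ROI_SIZE = {"palm": 256, "dorsum": 64}

#: Profile smoothing window as a fraction of contour length, and the
#: prominence floor (fraction of profile range) a fingertip peak must have.
PROFILE_SMOOTH_FRAC = 0.02
PEAK_PROMINENCE_FRAC = 0.05


@dataclass
class ContourPath:
    """Closed, counterclockwise 8-connected inner-border path."""

    points: np.ndarray  # (N, 2) int array of (row, col)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def euclidean_length(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]).astype(float), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class DistanceProfile:
    values: np.ndarray  # D_E(i), pixels
    wrist_mid: tuple[float, float]  # (row, col) of W_M


@dataclass
class FingerWebs:
    webs: np.ndarray  # (4, 2) (row, col), FW1..FW4 from the thumb side
    tips: np.ndarray  # (5, 2)
    web_indices: np.ndarray = field(default=None)  # contour indices of webs
    tip_indices: np.ndarray = field(default=None)

    @property
    def FW2(self) -> np.ndarray:
        return self.webs[1]

    @property
    def FW4(self) -> np.ndarray:
        return self.webs[3]

    @property
    def midpoint(self) -> np.ndarray:
        """FWm: midpoint of FW2 and FW4."""
        return (self.webs[1].astype(float) + self.webs[3].astype(float)) / 2.0


@dataclass
class ROIQuad:
    """Axis-aligned square ROI in the rotation-normalized frame.

    Corners in order R1 (top-left, the ROI origin), R2 (top-right),
    R3 (bottom-right), R4 (bottom-left); (row, col) subpixel coordinates.
    """

    corners: np.ndarray  # (4, 2) float
    theta_deg: float

    @property
    def side(self) -> float:
        return float(np.linalg.norm(self.corners[1] - self.corners[0]))


# 8-neighbour offsets in clockwise order (array coordinates, row down):
# W, NW, N, NE, E, SE, S, SW.  Scanning clockwise from the backtrack makes
# the trace run up the left side of the hand first, i.e. counterclockwise
# as displayed.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_contour(mask: np.ndarray) -> ContourPath:
    """Moore-neighbour inner-border trace of the palm component.

    Starts at the leftmost foreground pixel of the bottom-most foreground
    row and follows the border counterclockwise (as displayed) until the
    start is re-entered the same way (Jacob's stopping criterion).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise PalmFuseError("no region")
    rows = np.flatnonzero(mask.any(axis=1))
    r0 = rows[-1]
    c0 = int(np.flatnonzero(mask[r0])[0])
    start = (int(r0), c0)

    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    if not any(fg((start[0] + dr, start[1] + dc)) for dr, dc in _MOORE):
        return ContourPath(points=np.array([start]))

    path = [start]
    cur = start
    backtrack = (start[0], start[1] - 1)  # background by construction
    first_exit: tuple | None = None
    limit = 8 * int(mask.sum()) + 16
    for _ in range(limit):
        base = _MOORE.index((backtrack[0] - cur[0], backtrack[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(base + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if fg(cand):
                nxt = cand
                prev_dr, prev_dc = _MOORE[(base + k - 1) % 8]
                # last-tested background cell; adjacent to nxt since
                # consecutive Moore-ring cells are 8-adjacent
                new_backtrack = (cur[0] + prev_dr, cur[1] + prev_dc)
                break
        if cur == start:
            if first_exit is None:
                first_exit = nxt
            elif nxt == first_exit:  # Jacob's criterion: exit repeats
                break
        if nxt != start:
            path.append(nxt)
        cur, backtrack = nxt, new_backtrack
    else:
        raise PalmFuseError("contour tracing did not terminate")
    return ContourPath(points=np.array(path, dtype=int))


def distance_profile(contour: ContourPath, mask: np.ndarray) -> DistanceProfile:
    """Distances D_E(i) from the wrist midpoint to every contour pixel.

    W_M is the midpoint of the (largest) foreground run on the bottom row.
    """
    mask = np.asarray(mask) > 0
    bottom = mask[-1]
    if not bottom.any():
        raise PalmFuseError("wrist not found")
    cols = np.flatnonzero(bottom)
    # largest contiguous run on the bottom row
    breaks = np.flatnonzero(np.diff(cols) > 1)
    runs = np.split(cols, breaks + 1)
    run = max(runs, key=len)
    wm = (float(mask.shape[0] - 1), float(run[0] + run[-1]) / 2.0)
    pts = contour.points.astype(float)
    values = np.hypot(pts[:, 0] - wm[0], pts[:, 1] - wm[1])
    return DistanceProfile(values=values, wrist_mid=wm)


def _smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    if window < 3:
        return values.astype(float)
    kernel = np.ones(window) / window
    padded = np.pad(values.astype(float), window // 2, mode="wrap")
    return np.convolve(padded, kernel, mode="valid")[: len(values)]


def locate_finger_webs(profile: DistanceProfile, contour: ContourPath) -> FingerWebs:
    """Fingertips (5 profile maxima) and finger webs (4 interleaved minima).

    The profile is smoothed over ~2% of the contour length; fingertip peaks
    must have prominence >= 5% of the profile range.  Each web is the
    profile minimum between two consecutive tips.  Webs come back ordered
    along the contour from the thumb side (the trace runs up the thumb side
    first).
    """
    vals = profile.values
    n = len(vals)
    window = max(3, int(round(PROFILE_SMOOTH_FRAC * n)) | 1)
    smooth = _smooth_profile(vals, window)
    rng = float(smooth.max() - smooth.min())
    if rng <= 0:
        raise HandNotOutstretchedError("hand not outstretched: flat profile")
    peaks, _ = find_peaks(smooth, prominence=PEAK_PROMINENCE_FRAC * rng)
    if len(peaks) != 5:
        raise HandNotOutstretchedError(
            f"hand not outstretched: {len(peaks)} fingertip maxima (need 5)"
        )
    web_idx = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = smooth[a : b + 1]
        web_idx.append(int(a + np.argmin(seg)))
    web_idx = np.array(web_idx)
    return FingerWebs(
        webs=contour.points[web_idx].copy(),
        tips=contour.points[peaks].copy(),
        web_indices=web_idx,
        tip_indices=np.asarray(peaks),
    )


def rotation_angle(fw2, fw4) -> float:
    """Angle theta (degrees, in (-90, 90]) between segment FS and horizontal.

    Points are (row, col); theta = arctan(delta_row / delta_col).
    """
    (r2, c2), (r4, c4) = (np.asarray(fw2, float), np.asarray(fw4, float))
    dr, dc = r2 - r4, c2 - c4
    if dr == 0 and dc == 0:
        raise PalmFuseError("degenerate web pair")
    if dc == 0:
        return 90.0
    return math.degrees(math.atan(dr / dc))


def build_roi_quad(fw2, fw4, theta_deg: float = 0.0) -> ROIQuad:
    """Square ROI from the rotation-normalized FW2/FW4 pair.

    Side = 1.5 * |FW2 FW4|; top side parallel to FS at offset |FS|/4 toward
    the palm (increasing row; wrist-at-bottom convention), horizontally
    centered at FWm.
    """
    fw2 = np.asarray(fw2, dtype=float)
    fw4 = np.asarray(fw4, dtype=float)
    d = float(np.linalg.norm(fw2 - fw4))
    if d == 0:
        raise PalmFuseError("degenerate web pair")
    row = (fw2[0] + fw4[0]) / 2.0
    cmid = (fw2[1] + fw4[1]) / 2.0
    side = 1.5 * d
    top = row + d / 4.0
    left = cmid - side / 2.0
    corners = np.array(
        [
            [top, left],
            [top, left + side],
            [top + side, left + side],
            [top + side, left],
        ]
    )
    return ROIQuad(corners=corners, theta_deg=theta_deg)


def _rotation_transform(theta_deg: float, center_rc: np.ndarray) -> SimilarityTransform:
    """Forward transform rotating points by -theta about center (x,y coords)."""
    phi = -math.radians(theta_deg)
    cx, cy = float(center_rc[1]), float(center_rc[0])
    t1 = SimilarityTransform(translation=(-cx, -cy))
    rot = SimilarityTransform(rotation=phi)
    t2 = SimilarityTransform(translation=(cx, cy))
    return SimilarityTransform(matrix=t2.params @ rot.params @ t1.params)


def rotate_about(img: np.ndarray, theta_deg: float, center_rc) -> np.ndarray:
    """Rotate the image by -theta about center (bilinear), same frame size."""
    tform = _rotation_transform(theta_deg, np.asarray(center_rc, float))
    out = warp(
        np.asarray(img, float),
        inverse_map=tform.inverse,
        order=1,
        preserve_range=True,
        mode="constant",
        cval=0.0,
    )
    return out


def transform_points(points: np.ndarray, theta_deg: float, center_rc) -> np.ndarray:
    """Apply the same rotation to (row, col) points analytically."""
    tform = _rotation_transform(theta_deg, np.asarray(center_rc, float))
    pts = np.atleast_2d(np.asarray(points, float))
    xy = pts[:, ::-1]  # (col, row) -> (x, y)
    out = tform(xy)
    return out[:, ::-1]


def crop_quad(img: np.ndarray, quad: ROIQuad, out_size: int) -> np.ndarray:
    """Subpixel bilinear crop of the axis-aligned quad, then resize.

    Raises RoiOutOfFrameError if the quad exceeds the image bounds.
    """
    h, w = np.asarray(img).shape[:2]
    top, left = quad.corners[0]
    side = quad.side
    if top < -0.5 or left < -0.5 or top + side > h - 0.5 or left + side > w - 0.5:
        raise RoiOutOfFrameError("ROI out of frame")
    n = max(2, int(round(side)))
    rr = top + np.arange(n) * (side / n)
    cc = left + np.arange(n) * (side / n)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    from scipy.ndimage import map_coordinates

    crop = map_coordinates(np.asarray(img, float), [grid_r, grid_c], order=1, mode="nearest")
    out = resize(crop, (out_size, out_size), order=1, preserve_range=True, anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_roi(img: np.ndarray, kind: str = "palm", return_details: bool = False):
    """Full peg-free ROI pipeline for one image.

    segment -> trace -> distance profile -> webs -> rotate by -theta about
    FWm (web coordinates transformed analytically) -> crop the ROI quad ->
    resize to 256x256 (palm) or 64x64 (dorsum).
    """
    if kind not in ROI_SIZE:
        raise PalmFuseError(f"kind must be one of {sorted(ROI_SIZE)}")
    mask = segment_palm_region(img)
    contour = trace_contour(mask)
    profile = distance_profile(contour, mask)
    webs = locate_finger_webs(profile, contour)
    theta = rotation_angle(webs.FW2, webs.FW4)
    center = webs.midpoint
    rotated = rotate_about(img, theta, center)
    fw2r, fw4r = transform_points(np.vstack([webs.FW2, webs.FW4]), theta, center)
    quad = build_roi_quad(fw2r, fw4r, theta_deg=theta)
    roi = crop_quad(rotated, quad, ROI_SIZE[kind])
    if return_details:
        return roi, {
            "mask": mask,
            "contour": contour,
            "profile": profile,
            "webs": webs,
            "theta_deg": theta,
            "quad": quad,
            "center": center,
        }
    return roi
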