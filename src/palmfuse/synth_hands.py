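"""Seeded synthetic palm and palm-dorsum image generator with ground truth.

No public dataset exists for scanner palm images paired with infrared
palm-dorsum images, so every pipeline stage is exercised on synthetic
captures that reproduce the properties the method depends on:

* bimodal gray histograms (dark background ~20, bright skin ~180);
* a five-fingered outstretched silhouette whose contour distance profile
  has five fingertip maxima and four finger-web minima;
* palmprints as thin dark polylines with hard edges (high local gradient);
* dorsum veins as bright ridges with smooth bell-shaped cross profiles
  (IR veins are warmer than skin);
* per-capture jitter: rotation, translation, brightness offset and noise,
  emulating peg-free acquisition.

The silhouette is a parametric palm (trapezoid with an elliptic bottom
cap) plus five capsule fingers fanned slightly apart so each finger web is
a narrow, well-localized notch.  All geometry is transformed analytically
by the capture jitter before rasterization, so ground-truth web/tip/line
coordinates are exact.  Palm canvases are 845x829 (portrait, fingers up),
dorsum canvases 240x320 — the original sensor sizes of the modality pair
being emulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon
from skimage.measure import perimeter_crofton

PALM_SHAPE = (845, 829)  # rows, cols
DORSUM_SHAPE = (240, 320)

BACKGROUND_GRAY = 20.0
SKIN_GRAY = 180.0
LINE_GRAY = 60.0
VEIN_AMPLITUDE = 45.0


@dataclass
class CaptureJitter:
    """Per-capture acquisition jitter; ranges are enforced at construction."""

    rotation_deg: float = 0.0  # in [-15, 15]
    translation: tuple[float, float] = (0.0, 0.0)  # (drow, dcol), each in [-20, 20]
    brightness: float = 0.0  # gray-level offset in [-10, 10]
    noise_sigma: float = 3.0

    def __post_init__(self):
        if abs(self.rotation_deg) > 15 + 1e-9:
            raise ValueError("rotation out of range [-15, 15] deg")
        if max(abs(self.translation[0]), abs(self.translation[1])) > 20 + 1e-9:
            raise ValueError("translation out of range [-20, 20] px")
        if abs(self.brightness) > 10 + 1e-9:
            raise ValueError("brightness offset out of range [-10, 10]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class IdentityParams:
    """Anatomical parameters of one synthetic identity.

    Geometry is expressed in the hand frame: origin at the palm-top
    center, y down (rows), x right (cols).  `scale` maps the palm-canvas
    design to the smaller dorsum canvas.
    """

    finger_lengths: np.ndarray  # (5,) px, thumb..little
    finger_widths: np.ndarray  # (5,) px
    finger_angles: np.ndarray  # (5,) deg from vertical (fan)
    finger_pitch: float  # base-to-base spacing, px
    palm_breadth: float  # palm half-width at the top, px
    palm_height: float  # palm-top to bottom-cap center, px
    wrist_halfwidth: float
    line_ctrl: list = field(default_factory=list)  # palm principal lines
    vein_ctrl: list = field(default_factory=list)  # dorsum vein polylines
    vein_sigma: float = 3.0  # ridge half-width (Gaussian sigma), px
    background_gray: float = BACKGROUND_GRAY
    skin_gray: float = SKIN_GRAY
    seed: int = 0

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.finger_lengths,
                self.finger_widths,
                self.finger_angles,
                [self.finger_pitch, self.palm_breadth, self.palm_height],
            ]
        )


@dataclass
class GroundTruth:
    """Exact geometry of one rendered capture (canvas coordinates)."""

    silhouette: np.ndarray  # bool mask
    webs: np.ndarray  # (4, 2) (row, col), FW1..FW4 from thumb side
    tips: np.ndarray  # (5, 2)
    palm_center: np.ndarray  # (2,)
    line_traces: list  # list of (k, 2) arrays (palm only)
    vein_traces: list  # list of (k, 2) arrays (dorsum only)
    jitter: CaptureJitter = None

    @property
    def perimeter(self) -> float:
        """Crofton perimeter estimate of the silhouette."""
        return float(perimeter_crofton(self.silhouette, directions=4))


# ---------------------------------------------------------------------------
# identity sampling


def _sample_identity(rng: np.random.Generator, seed: int) -> IdentityParams:
    lengths = np.array([150, 185, 205, 190, 150]) * rng.uniform(0.92, 1.08, 5)
    widths = np.array([50, 52, 54, 52, 46]) * rng.uniform(0.94, 1.06, 5)
    angles = np.array([-10.0, -5.0, 0.0, 5.0, 10.0]) + rng.uniform(-1.5, 1.5, 5)
    pitch = 66.0 * rng.uniform(0.96, 1.05)
    # keep every base gap a narrow notch (>= 6 px) so webs stay localized
    for i in range(4):
        gap = pitch - (widths[i] + widths[i + 1]) / 2.0
        if gap < 6.0:
            shrink = (6.0 - gap) / 2.0 + 0.5
            widths[i] -= shrink
            widths[i + 1] -= shrink
    breadth = 2.0 * pitch + widths[0] / 2.0 + rng.uniform(0, 8)
    height = 250.0 * rng.uniform(0.95, 1.05)
    wrist = 78.0 * rng.uniform(0.92, 1.08)

    def bezier(p0, p1, p2, k=40):
        t = np.linspace(0, 1, k)[:, None]
        p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
        return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2

    j = lambda s: rng.uniform(-s, s, 2)  # noqa: E731 control-point jitter
    line_ctrl = [
        bezier([62, -120] + j(10), [40, 10] + j(14), [85, 138] + j(10)),
        bezier([112, -128] + j(10), [130, 0] + j(14), [155, 118] + j(10)),
        bezier([75, -60] + j(8), [150, -105] + j(12), [235, -80] + j(10)),
    ]
    # dorsum canvas scale; vein topology carries most of the between-identity
    # signal for the vein modality, so its control points get a wide spread
    s = 0.27
    # veins live inside the dorsum ROI catchment (palm-frame box roughly
    # x in [-50, 120], y in [40, 220] below the web line, before scaling)
    vein_ctrl = [
        bezier(np.array([50, -40]) * s + j(7), np.array([120, 20]) * s + j(10),
               np.array([215, 95]) * s + j(7)),
        bezier(np.array([45, 100]) * s + j(7), np.array([130, 110]) * s + j(10),
               np.array([220, 10]) * s + j(7)),
        bezier(np.array([100, -20]) * s + j(6), np.array([150, 60]) * s + j(8),
               np.array([195, 115]) * s + j(6)),
    ]
    return IdentityParams(
        finger_lengths=lengths,
        finger_widths=widths,
        finger_angles=angles,
        finger_pitch=pitch,
        palm_breadth=breadth,
        palm_height=height,
        wrist_halfwidth=wrist,
        line_ctrl=line_ctrl,
        vein_ctrl=vein_ctrl,
        vein_sigma=3.0 * rng.uniform(0.9, 1.15),
        seed=seed,
    )


def make_identity(master_seed: int, index: int, min_distance: float = 0.02) -> IdentityParams:
    """Sample one identity; rejection-sample away from earlier identities.

    Identities must differ by at least ``min_distance`` RMS relative
    difference over the anatomical parameter vector from every lower-index
    identity of the same master seed (re-derived deterministically), so no
    two cohort members collide.
    """
    earlier: list[np.ndarray] = []
    cand = None
    for i in range(index + 1):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i]))
        for _ in range(64):
            cand = _sample_identity(rng, seed=i)
            v = cand.as_vector()
            if all(
                np.linalg.norm((v - e) / np.maximum(np.abs(e), 1e-9)) / math.sqrt(len(v))
                >= min_distance
                for e in earlier
            ):
                break
        earlier.append(cand.as_vector())
    return cand


# ---------------------------------------------------------------------------
# geometry + rasterization


def _hand_layout(params: IdentityParams, kind: str):
    """Scaled geometry and canvas anchors for one modality."""
    if kind == "palm":
        shape, s = PALM_SHAPE, 1.0
        y_top = 420.0
    else:
        shape, s = DORSUM_SHAPE, 0.27
        y_top = 108.0
    cx = shape[1] / 2.0
    return shape, s, y_top, cx


def _jitter_transform(jitter: CaptureJitter, pivot_rc: np.ndarray):
    """(row, col) point transform: rotate about pivot, then translate."""
    th = math.radians(jitter.rotation_deg)
    cos, sin = math.cos(th), math.sin(th)
    pr, pc = pivot_rc
    tr, tc = jitter.translation

    def apply(pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        y = pts[:, 0] - pr
        x = pts[:, 1] - pc
        # rotation by `th` as displayed (y axis down)
        xn = cos * x - sin * y
        yn = sin * x + cos * y
        return np.column_stack([yn + pr + tr, xn + pc + tc])

    return apply


def _dist_to_polyline(rr, cc, pts):
    d2 = np.full(rr.shape, np.inf)
    pts = np.asarray(pts, float)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        vr, vc = r1 - r0, c1 - c0
        seg2 = vr * vr + vc * vc
        if seg2 == 0:
            dr, dc = rr - r0, cc - c0
        else:
            t = np.clip(((rr - r0) * vr + (cc - c0) * vc) / seg2, 0.0, 1.0)
            dr, dc = rr - (r0 + t * vr), cc - (c0 + t * vc)
        d2 = np.minimum(d2, dr * dr + dc * dc)
    return np.sqrt(d2)


def _capsule_mask(shape, a, b, radius):
    """Pixels within `radius` of segment a-b, evaluated only in a bbox."""
    h, w = shape
    r0 = max(0, int(min(a[0], b[0]) - radius - 2))
    r1 = min(h, int(max(a[0], b[0]) + radius + 3))
    c0 = max(0, int(min(a[1], b[1]) - radius - 2))
    c1 = min(w, int(max(a[1], b[1]) + radius + 3))
    out = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return out
    rr, cc = np.mgrid[r0:r1, c0:c1]
    out[r0:r1, c0:c1] = _dist_to_polyline(rr.astype(float), cc.astype(float), [a, b]) <= radius
    return out


def _palm_outline(params: IdentityParams, s: float, y_top: float, cx: float) -> np.ndarray:
    """Dense polygon outline of palm body + wrist, hand frame -> canvas."""
    bw = params.palm_breadth * s
    bh = params.palm_height * s
    ww = params.wrist_halfwidth * s
    bot_hw = bw * 0.92
    # top edge (left->right), right side down, elliptic bottom cap with a
    # wrist tongue that extends far past the canvas bottom (so the wrist
    # still crosses the bottom row after rotation jitter)
    t = np.linspace(0, 1, 24)
    top = np.column_stack([np.zeros_like(t), -bw + 2 * bw * t])
    right = np.column_stack([bh * t[1:], bw + (bot_hw - bw) * t[1:]])
    phi = np.linspace(0, math.pi / 2 * 0.96, 16)[1:]
    cap_r = np.column_stack([bh + 0.35 * bh * np.sin(phi), bot_hw * np.cos(phi)])
    wrist_depth = bh + 2000.0  # clipped by the canvas
    wrist = np.array(
        [[bh + 0.30 * bh, ww], [wrist_depth, ww], [wrist_depth, -ww], [bh + 0.30 * bh, -ww]]
    )
    cap_l = np.column_stack([bh + 0.35 * bh * np.sin(phi[::-1]), -bot_hw * np.cos(phi[::-1])])
    left = np.column_stack([bh * t[::-1], -bw + (bw - bot_hw) * (1 - t[::-1])])
    pts = np.vstack([top, right, cap_r, wrist, cap_l, left[1:]])
    return pts + np.array([y_top, cx])


def _finger_geometry(params: IdentityParams, s: float, y_top: float, cx: float,
                     width_factor: float = 1.0):
    """Base/tip segments, tip points and web points in canvas coordinates.

    ``width_factor`` thins the fingers on the small dorsum canvas so the
    web notches stay wider than what two dilations can seal.
    """
    bases, tips_seg, tips_gt, radii = [], [], [], []
    xs = (np.arange(5) - 2.0) * params.finger_pitch * s
    for i in range(5):
        w = params.finger_widths[i] * width_factor * s / 2.0
        length = params.finger_lengths[i] * s
        ang = math.radians(params.finger_angles[i])
        base = np.array([y_top + 2.0 * s, cx + xs[i]])
        d = np.array([-math.cos(ang), math.sin(ang)])  # up, fanned
        tip = base + (length - w) * d
        bases.append(base)
        tips_seg.append(tip)
        tips_gt.append(base + length * d)  # cap apex
        radii.append(w)
    webs = []
    for i in range(4):
        left = xs[i] + params.finger_widths[i] * width_factor * s / 2.0
        right = xs[i + 1] - params.finger_widths[i + 1] * width_factor * s / 2.0
        webs.append([y_top, cx + (left + right) / 2.0])
    return bases, tips_seg, tips_gt, radii, np.array(webs)


def _render(params: IdentityParams, jitter: CaptureJitter, seed: int, kind: str):
    shape, s, y_top, cx = _hand_layout(params, kind)
    h, w = shape
    pivot = np.array([y_top + params.palm_height * s / 2.0, cx])
    T = _jitter_transform(jitter, pivot)

    # --- silhouette ------------------------------------------------------
    outline = T(_palm_outline(params, s, y_top, cx))
    sil = np.zeros(shape, dtype=bool)
    rr, cc = polygon(outline[:, 0], outline[:, 1], shape=shape)
    sil[rr, cc] = True
    wf = 0.72 if kind == "dorsum" else 1.0
    bases, tips_seg, tips_gt, radii, webs = _finger_geometry(params, s, y_top, cx, wf)
    for base, tip, rad in zip(bases, tips_seg, radii):
        a, b = T(np.vstack([base, tip]))
        sil |= _capsule_mask(shape, a, b, rad)

    webs = T(webs)
    tips = T(np.vstack(tips_gt))

    # --- gray levels -----------------------------------------------------
    img = np.full(shape, params.background_gray, dtype=float)
    img[sil] = params.skin_gray

    line_traces, vein_traces = [], []
    if kind == "palm":
        for ctrl in params.line_ctrl:
            trace = T(np.asarray(ctrl) + np.array([y_top, cx]))
            line_traces.append(trace)
            lw = 4.0  # principal-line width: hard-edged, closable by 3x3 morphology
            r0 = max(0, int(trace[:, 0].min() - 6))
            r1 = min(h, int(trace[:, 0].max() + 7))
            c0 = max(0, int(trace[:, 1].min() - 6))
            c1 = min(w, int(trace[:, 1].max() + 7))
            gr, gc = np.mgrid[r0:r1, c0:c1]
            near = _dist_to_polyline(gr.astype(float), gc.astype(float), trace) <= lw / 2.0
            sub = img[r0:r1, c0:c1]
            sub[near & sil[r0:r1, c0:c1]] = LINE_GRAY
    else:
        dorsum_anchor = np.array([y_top, cx])
        for ctrl in params.vein_ctrl:
            trace = T(np.asarray(ctrl) + dorsum_anchor)
            vein_traces.append(trace)
            r0 = max(0, int(trace[:, 0].min() - 12))
            r1 = min(h, int(trace[:, 0].max() + 13))
            c0 = max(0, int(trace[:, 1].min() - 12))
            c1 = min(w, int(trace[:, 1].max() + 13))
            gr, gc = np.mgrid[r0:r1, c0:c1]
            d = _dist_to_polyline(gr.astype(float), gc.astype(float), trace)
            bump = VEIN_AMPLITUDE * np.exp(-(d**2) / (2.0 * params.vein_sigma**2))
            sub = img[r0:r1, c0:c1]
            inside = sil[r0:r1, c0:c1]
            sub[inside] = np.maximum(sub[inside], params.skin_gray + bump[inside])

    img += jitter.brightness
    if jitter.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter.noise_sigma, shape)
        # mild spatial smoothing: keeps adjacent-pixel noise jumps small so
        # vein cross-profiles stay smooth, as IR optics would
        img += gaussian_filter(noise, 0.8) * 2.0
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(
        silhouette=sil,
        webs=webs,
        tips=tips,
        palm_center=T(pivot)[0],
        line_traces=line_traces,
        vein_traces=vein_traces,
        jitter=jitter,
    )
    return img, gt


def generate_palm_image(params: IdentityParams, jitter: CaptureJitter | None = None,
                        seed: int = 0):
    """Render one 845x829 scanner-style palm capture with ground truth."""
    jitter = jitter or CaptureJitter()
    img, gt = _render(params, jitter, seed, "palm")
    _check_in_canvas(gt, PALM_SHAPE)
    return img, gt


def generate_dorsum_image(params: IdentityParams, jitter: CaptureJitter | None = None,
                          seed: int = 0):
    """Render one 240x320 IR-style palm-dorsum capture with ground truth."""
    jitter = jitter or CaptureJitter(noise_sigma=1.5)
    img, gt = _render(params, jitter, seed, "dorsum")
    _check_in_canvas(gt, DORSUM_SHAPE)
    return img, gt


def _check_in_canvas(gt: GroundTruth, shape) -> None:
    pts = np.vstack([gt.webs, gt.tips])
    if (pts < 0).any() or (pts[:, 0] >= shape[0]).any() or (pts[:, 1] >= shape[1]).any():
        raise ValueError("params out of range: silhouette outside canvas")
    if not gt.silhouette[-1].any():
        raise ValueError("params out of range: wrist does not reach image bottom")


# ---------------------------------------------------------------------------
# cohorts


def draw_jitter(rng: np.random.Generator, kind: str) -> CaptureJitter:
    """Default capture-jitter distribution of the study conditions.

    Rotation +-10 deg and brightness +-10 for both modalities; translation
    +-20 px on the large palm canvas but +-8 px on the small dorsum canvas
    so the ROI stays in frame; noise sigma 3 (scanner) / 1.5 (IR).
    """
    if kind == "palm":
        t_max, sigma = 20.0, 3.0
    else:
        t_max, sigma = 8.0, 1.5
    return CaptureJitter(
        rotation_deg=float(rng.uniform(-10, 10)),
        translation=(float(rng.uniform(-t_max, t_max)), float(rng.uniform(-t_max, t_max))),
        brightness=float(rng.uniform(-10, 10)),
        noise_sigma=sigma,
    )


def iter_cohort(n_ids: int, n_per_id: int, master_seed: int):
    """Yield (identity_index, capture_index, kind, image, ground_truth)."""
    if n_ids < 2:
        raise ValueError("need at least two identities")
    for i in range(n_ids):
        params = make_identity(master_seed, i)
        for j in range(n_per_id):
            for kind in ("palm", "dorsum"):
                ss = np.random.SeedSequence([master_seed, i, j, 0 if kind == "palm" else 1])
                rng = np.random.default_rng(ss)
                jit = draw_jitter(rng, kind)
                pix_seed = int(rng.integers(0, 2**31 - 1))
                gen = generate_palm_image if kind == "palm" else generate_dorsum_image
                img, gt = gen(params, jit, seed=pix_seed)
                yield i, j, kind, img, gt


def generate_cohort(n_ids: int, n_per_id: int, master_seed: int, out_dir: str | Path):
    """Write a cohort to disk: id_XXX/{palm,dorsum}_YYY.png + ground truth.

    Returns the list of written image paths.
    """
    from .io import write_gray

    out_dir = Path(out_dir)
    written = []
    truth: dict[str, dict] = {}
    for i, j, kind, img, gt in iter_cohort(n_ids, n_per_id, master_seed):
        d = out_dir / f"id_{i:03d}"
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{kind}_{j:03d}.png"
        write_gray(path, img)
        written.append(path)
        truth[f"id_{i:03d}/{kind}_{j:03d}"] = {
            "webs": gt.webs.tolist(),
            "tips": gt.tips.tolist(),
            "rotation_deg": gt.jitter.rotation_deg,
            "translation": list(gt.jitter.translation),
        }
    (out_dir / "ground_truth.json").write_text(json.dumps(
        {"n_ids": n_ids, "n_per_id": n_per_id, "master_seed": master_seed, "captures": truth},
        indent=1,
    ))
    return written
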