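"""Different-resolution image fusion in the Haar wavelet domain.

The 256x256 palmprint ROI (gray-inverted so its dark principal lines
become bright, matching the bright IR veins) is decomposed three DWT
levels; the 64x64 vein ROI one level.  Both end at 32x32 subbands, which
are fused coefficient-wise and reconstructed back up through the palm
pyramid:

    stage 1: IDWT(fused 32x32 set)               -> 64x64 approximation
    stage 2: IDWT(that + palm level-2 details)   -> 128x128
    stage 3: IDWT(that + palm level-1 details)   -> 256x256 fused image

The hybrid Avg-Max rule averages the approximation (LL) subbands and takes
the elementwise maximum of the detail (LH/HL/HH) subbands: approximations
carry the smooth vein luminance, details the sharp palm lines.  Haar with
orthonormal taps (1/sqrt 2) keeps DWT/IDWT exact inverses.  Coefficients
are fused raw, exactly as the rule is written: because the palm LL band
sits three decomposition levels deep (gain 2^3) and the vein LL only one
(gain 2^1), the averaged approximation effectively weights palm luminance
4x the vein's — a property of the different-resolution scheme itself, not
a normalization choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import PalmFuseError

_WAVELET = "haar"
_MODE = "periodization"

FUSION_RULES = ("avg_max", "avg", "max", "min", "weighted")


@dataclass
class CoefficientSet:
    """One DWT stage: approximation LL and details LH, HL, HH (equal shape)."""

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray

    def __post_init__(self):
        shapes = {np.shape(b) for b in (self.LL, self.LH, self.HL, self.HH)}
        if len(shapes) != 1:
            raise PalmFuseError("inconsistent subbands")

    @property
    def shape(self):
        return np.shape(self.LL)

    def bands(self):
        return {"LL": self.LL, "LH": self.LH, "HL": self.HL, "HH": self.HH}


@dataclass
class CoefficientPyramid:
    """DWT pyramid; levels[0] is the finest stage."""

    levels: list

    @property
    def deepest_LL(self) -> np.ndarray:
        return self.levels[-1].LL


def invert_gray(img: np.ndarray) -> np.ndarray:
    """Reverse gray levels: g -> 255 - g."""
    return (255 - np.asarray(img, dtype=np.uint8)).astype(np.uint8)


def haar_dwt2(img: np.ndarray) -> CoefficientSet:
    """One 2-D orthonormal Haar DWT stage (subbands half the side length)."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] % 2 or img.shape[1] % 2:
        raise PalmFuseError("haar_dwt2 requires even 2-D dimensions")
    cA, (cH, cV, cD) = pywt.dwt2(img, _WAVELET, mode=_MODE)
    # pywt: cH = horizontal detail (LH band), cV = vertical (HL), cD = HH
    return CoefficientSet(LL=cA, LH=cH, HL=cV, HH=cD)


def haar_idwt2(coeffs: CoefficientSet) -> np.ndarray:
    """Inverse of :func:`haar_dwt2` (exact to machine precision)."""
    return pywt.idwt2((coeffs.LL, (coeffs.LH, coeffs.HL, coeffs.HH)), _WAVELET, mode=_MODE)


def decompose(img: np.ndarray, levels: int) -> CoefficientPyramid:
    """Repeated DWT of the approximation band, `levels` times."""
    sets = []
    cur = np.asarray(img, dtype=float)
    for _ in range(levels):
        cset = haar_dwt2(cur)
        sets.append(cset)
        cur = cset.LL
    return CoefficientPyramid(levels=sets)


def fuse_coefficients(palm: CoefficientSet, vein: CoefficientSet, rule: str = "avg_max",
                      weight: float = 0.5) -> CoefficientSet:
    """Fuse two equal-shape coefficient sets by the given rule.

    avg_max (the hybrid rule): average LL, signed elementwise max of
    details.  avg / max / min / weighted apply one rule to all subbands;
    `weight` is the palm share for the weighted rule.
    """
    if palm.shape != vein.shape:
        raise PalmFuseError("inconsistent subbands")
    if rule not in FUSION_RULES:
        raise PalmFuseError(f"unknown fusion rule {rule!r}")

    def combine(a, b, how):
        if how == "avg":
            return (a + b) / 2.0
        if how == "max":
            return np.maximum(a, b)
        if how == "min":
            return np.minimum(a, b)
        if how == "weighted":
            return weight * a + (1.0 - weight) * b
        raise PalmFuseError(how)

    if rule == "avg_max":
        return CoefficientSet(
            LL=combine(palm.LL, vein.LL, "avg"),
            LH=combine(palm.LH, vein.LH, "max"),
            HL=combine(palm.HL, vein.HL, "max"),
            HH=combine(palm.HH, vein.HH, "max"),
        )
    return CoefficientSet(
        **{k: combine(pa, vb, rule) for (k, pa), vb in zip(palm.bands().items(), vein.bands().values())}
    )


def fuse_avg_max(palm: CoefficientSet, vein: CoefficientSet) -> CoefficientSet:
    """The hybrid Avg-Max rule: LL averaged, details elementwise max."""
    return fuse_coefficients(palm, vein, rule="avg_max")


def fuse_images(palm_roi: np.ndarray, vein_roi: np.ndarray, rule: str = "avg_max",
                weight: float = 0.5, prefuse_normalize: bool = False) -> np.ndarray:
    """Fuse a 256x256 palm ROI and a 64x64 vein ROI into a 256x256 image.

    The palm ROI is gray-inverted first.  Set ``prefuse_normalize`` to
    min-max stretch both ROIs to [0, 255] before decomposition.
    """
    palm_roi = np.asarray(palm_roi)
    vein_roi = np.asarray(vein_roi)
    if palm_roi.shape != (256, 256) or vein_roi.shape != (64, 64):
        raise PalmFuseError("resize ROIs first: need palm 256x256 and vein 64x64")
    palm = invert_gray(palm_roi).astype(float)
    vein = vein_roi.astype(float)
    if prefuse_normalize:
        palm = _stretch(palm)
        vein = _stretch(vein)
    pyr = decompose(palm, 3)  # deepest subbands 32x32
    vset = haar_dwt2(vein)  # 32x32 subbands
    fused = fuse_coefficients(pyr.levels[2], vset, rule=rule, weight=weight)
    # three IDWT stages back up the palm pyramid
    approx = haar_idwt2(fused)  # 64x64
    for lvl in (pyr.levels[1], pyr.levels[0]):
        approx = haar_idwt2(CoefficientSet(LL=approx, LH=lvl.LH, HL=lvl.HL, HH=lvl.HH))
    return np.clip(np.floor(approx + 0.5), 0, 255).astype(np.uint8)


def _stretch(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img, dtype=float)
    return (img - lo) * (255.0 / (hi - lo))
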