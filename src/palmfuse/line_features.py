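"""Line-like-feature extraction and multiresolution block-count features.

Palm lines and vein ridges are locally linear, so four 3x3 Sobel kernels
(0, 45, 90, 135 degrees) are convolved at every pixel and the strongest
response magnitude becomes the enhanced gray level.  Because capture
conditions vary, the binarization threshold is not fixed: the classic
iterative (isodata-style) scheme starts from a random threshold and
repeats Th <- (mean(background) + mean(object)) / 2 until it stops moving.
Pixels above the threshold form the line-like image (LLI), summarized as
counts of LLI pixels in n x n non-overlapping blocks — the feature-pass
filter (FPF).  Block counts are insensitive to small residual translation
of the ROI, which is what makes them usable as verification features.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .errors import NoSeparationError, PalmFuseError

#: 3x3 Sobel kernels; the name is the orientation of the line they enhance.
SOBEL_BANK = {
    0: np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float),
    45: np.array([[-2, -1, 0], [-1, 0, 1], [0, 1, 2]], dtype=float),
    90: np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float),
    135: np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=float),
}


def sobel_enhance(img: np.ndarray) -> np.ndarray:
    """Max-of-four directional Sobel response, min-max rescaled to 0-255.

    Response magnitudes are compared (a gray level is non-negative, and
    magnitude keeps the operator equivariant under 90-degree rotation of
    the input).  Borders use replicate padding.
    """
    img = np.asarray(img, dtype=float)
    responses = [np.abs(convolve(img, k, mode="nearest")) for k in SOBEL_BANK.values()]
    best = np.maximum.reduce(responses)
    lo, hi = float(best.min()), float(best.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    out = (best - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def iterative_threshold(img: np.ndarray, seed: int = 0) -> int:
    """Iterative threshold selection on an 8-bit image.

    Starts from a random integer threshold strictly between the image min
    and max (seeded) and iterates ``Th <- round((mu_B + mu_O) / 2)`` with
    background = pixels <= Th and object = pixels > Th, until the
    threshold repeats.

    Raises
    ------
    NoSeparationError
        If the image is constant (fewer than two gray values).
    """
    img = np.asarray(img)
    gmin, gmax = int(img.min()), int(img.max())
    if gmax - gmin < 1:
        raise NoSeparationError("no separation: constant image")
    rng = np.random.default_rng(seed)
    # initial threshold strictly between the extreme gray values
    th = int(rng.integers(gmin + 1, gmax)) if gmax - gmin > 1 else gmin
    counts = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]
    gray = np.arange(256)
    csum = np.cumsum(counts)
    cval = np.cumsum(counts * gray)
    total_n, total_v = csum[-1], cval[-1]
    for _ in range(512):
        nb, vb = csum[th], cval[th]
        no, vo = total_n - nb, total_v - vb
        mu_b = vb / nb if nb else float(th)
        mu_o = vo / no if no else float(th)
        new = int(np.floor((mu_b + mu_o) / 2.0 + 0.5))
        if new == th:
            return th
        th = new
    return th


def extract_lli(img: np.ndarray, seed: int = 0) -> np.ndarray:
    """Binary line-like image: enhanced pixels strictly above the threshold."""
    th = iterative_threshold(img, seed=seed)
    return (np.asarray(img) > th).astype(np.uint8)


def fpf_features(lli: np.ndarray, block_px: int) -> np.ndarray:
    """Feature-pass filter: LLI pixel counts per (block_px x block_px) block.

    For an m x m LLI, returns the n x n = (m/block_px)^2 counts flattened
    row-major.  m must be divisible by block_px.
    """
    lli = np.asarray(lli)
    if lli.ndim != 2 or lli.shape[0] != lli.shape[1]:
        raise PalmFuseError("LLI must be square")
    m = lli.shape[0]
    if block_px < 1 or m % block_px:
        raise PalmFuseError("invalid block size")
    n = m // block_px
    blocks = (lli > 0).astype(np.int64).reshape(n, block_px, n, block_px)
    return blocks.sum(axis=(1, 3)).reshape(-1)


def image_features(img: np.ndarray, block_px: int, seed: int = 0,
                   scale: bool = False) -> np.ndarray:
    """Enhance -> LLI -> FPF counts for one image.

    With ``scale`` the counts are divided by block_px**2 into [0, 1]
    (the scaling used before SVM verification).
    """
    lli = extract_lli(sobel_enhance(img), seed=seed)
    feats = fpf_features(lli, block_px).astype(float)
    if scale:
        feats /= float(block_px) ** 2
    return feats


class LineFeatureTransformer:
    """Stateless sklearn-style transformer: images -> FPF feature matrix.

    Parameters
    ----------
    block_px : int
        Block side in pixels (32 for 256x256 palm/fused ROIs, 16 for
        64x64 vein ROIs by default elsewhere).
    seed : int
        Seed for the random initial threshold of the iterative scheme.
    scale : bool
        Divide counts by block_px**2 so features land in [0, 1].
    """

    def __init__(self, block_px: int = 32, seed: int = 0, scale: bool = True):
        self.block_px = block_px
        self.seed = seed
        self.scale = scale

    def get_params(self, deep: bool = True):
        return {"block_px": self.block_px, "seed": self.seed, "scale": self.scale}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.array(
            [image_features(img, self.block_px, seed=self.seed, scale=self.scale) for img in X]
        )

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
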