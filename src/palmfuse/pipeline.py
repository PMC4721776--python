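"""End-to-end pipeline: images -> ROI -> fusion -> features -> verification.

The stages compose as sklearn-style transformers (`RoiExtractor`,
`ImageFuser`, `LineFeatureTransformer`) feeding the `IdentityVerifier`
classifiers, orchestrated here for the three operating modes:

* ``palm``  — 256x256 palm ROI features (block 32 by default);
* ``vein``  — 64x64 dorsum ROI features (block 16);
* ``fused`` — Avg-Max wavelet fusion of both ROIs, then features.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import PalmFuseError
from .line_features import LineFeatureTransformer, image_features
from .roi_locator import extract_roi
from .verification import VerificationReport, evaluate_kfold
from .wavelet_fusion import FUSION_RULES, fuse_images

DEFAULT_BLOCK = {"palm": 32, "fused": 32, "vein": 16}


@dataclass
class PipelineConfig:
    """Every knob of a pipeline run; embedded verbatim in reports."""

    mode: str = "fused"  # palm | vein | fused
    block_px: int | None = None  # None -> mode default (32, 32, 16)
    k: int = 5
    seed: int = 42
    fusion_rule: str = "avg_max"
    fusion_weight: float = 0.5
    prefuse_normalize: bool = False
    threshold_seed: int = 0
    scale_features: bool = True
    svm_C: float | None = None
    svm_sigma: float | None = None

    def __post_init__(self):
        if self.mode not in DEFAULT_BLOCK:
            raise PalmFuseError(f"mode must be one of {sorted(DEFAULT_BLOCK)}")
        if self.fusion_rule not in FUSION_RULES:
            raise PalmFuseError(f"unknown fusion rule {self.fusion_rule!r}")
        if self.block_px is None:
            self.block_px = DEFAULT_BLOCK[self.mode]

    def as_dict(self) -> dict:
        return asdict(self)


class RoiExtractor:
    """Stateless transformer: raw hand images -> normalized square ROIs."""

    def __init__(self, kind: str = "palm"):
        self.kind = kind

    def get_params(self, deep=True):
        return {"kind": self.kind}

    def set_params(self, **p):
        for k, v in p.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.array([extract_roi(img, kind=self.kind) for img in X])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class ImageFuser:
    """Stateless transformer: (palm_roi, vein_roi) pairs -> fused images."""

    def __init__(self, rule: str = "avg_max", weight: float = 0.5,
                 prefuse_normalize: bool = False):
        self.rule = rule
        self.weight = weight
        self.prefuse_normalize = prefuse_normalize

    def get_params(self, deep=True):
        return {"rule": self.rule, "weight": self.weight,
                "prefuse_normalize": self.prefuse_normalize}

    def set_params(self, **p):
        for k, v in p.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.array([
            fuse_images(p, v, rule=self.rule, weight=self.weight,
                        prefuse_normalize=self.prefuse_normalize)
            for p, v in X
        ])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def run_single(palm_img=None, dorsum_img=None, cfg: PipelineConfig | None = None) -> np.ndarray:
    """ROI -> (fusion) -> enhancement -> LLI -> FPF features for one capture."""
    cfg = cfg or PipelineConfig()
    try:
        if cfg.mode == "fused":
            if palm_img is None:
                raise PalmFuseError("fused mode requires the palm image")
            if dorsum_img is None:
                raise PalmFuseError("fused mode requires the dorsum image")
            roi_p = extract_roi(palm_img, "palm")
            roi_v = extract_roi(dorsum_img, "dorsum")
            work = fuse_images(roi_p, roi_v, rule=cfg.fusion_rule, weight=cfg.fusion_weight,
                               prefuse_normalize=cfg.prefuse_normalize)
        elif cfg.mode == "palm":
            if palm_img is None:
                raise PalmFuseError("palm mode requires the palm image")
            work = extract_roi(palm_img, "palm")
        else:
            if dorsum_img is None:
                raise PalmFuseError("vein mode requires the dorsum image")
            work = extract_roi(dorsum_img, "dorsum")
    except PalmFuseError as exc:
        raise PalmFuseError(f"[{cfg.mode} preprocessing] {exc}") from exc
    return image_features(work, cfg.block_px, seed=cfg.threshold_seed, scale=cfg.scale_features)


@dataclass
class CohortImages:
    """In-memory cohort: per-identity lists of (palm_img, dorsum_img) pairs."""

    captures: dict = field(default_factory=dict)  # id -> list of (palm, dorsum)


def cohort_features(captures: dict, cfg: PipelineConfig) -> dict:
    """Feature vectors per identity for the configured mode."""
    out = {}
    for ident, pairs in captures.items():
        out[ident] = np.array([run_single(p, d, cfg) for p, d in pairs])
    return out


def run_evaluation(captures: dict, cfg: PipelineConfig | None = None) -> VerificationReport:
    """Full k-fold FRR/FAR evaluation of a cohort in the configured mode."""
    cfg = cfg or PipelineConfig()
    feats = cohort_features(captures, cfg)
    report = evaluate_kfold(feats, k=cfg.k, seed=cfg.seed, C=cfg.svm_C, sigma=cfg.svm_sigma)
    report.config.update(cfg.as_dict())
    return report


def load_cohort_dir(cohort_dir: str | Path) -> dict:
    """Read the documented id_XXX/{palm,dorsum}_YYY.png cohort layout."""
    from .io import read_gray

    cohort_dir = Path(cohort_dir)
    captures: dict[str, list] = {}
    id_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir() and re.match(r"id_\d+$", d.name))
    if not id_dirs:
        raise PalmFuseError(f"malformed cohort layout: no id_XXX directories in {cohort_dir}")
    for d in id_dirs:
        palms = sorted(d.glob("palm_*.png"))
        pairs = []
        for p in palms:
            v = d / p.name.replace("palm_", "dorsum_")
            pairs.append((read_gray(p), read_gray(v) if v.exists() else None))
        if not pairs:
            raise PalmFuseError(f"malformed cohort layout: no palm images in {d}")
        captures[d.name] = pairs
    return captures


def write_report(report: VerificationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=1))
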