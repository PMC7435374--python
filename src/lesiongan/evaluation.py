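"""Output quality metrics: Dice overlap per tumor region, and FID.

Dice follows the BraTS grouping of the internal 5-class encoding:
whole tumor = {edema, core, enhancing}, tumor core = {core, enhancing},
enhancing = {enhancing}.  FID is the Wasserstein-2 distance between
Gaussian fits to deep features of the two image sets,

    d^2 = ||mu_r - mu_f||^2 + tr(S_r + S_f - 2 (S_r S_f)^{1/2}),

with the matrix square root symmetrized for numerical stability.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from .networks import FeatureExtractor
from .preprocessing import SemanticLabel

REGION_CODES = {"whole": (2, 3, 4), "core": (3, 4), "en": (4,)}
DEFAULT_EPS = 1e-6


@dataclasses.dataclass
class DiceReport:
    whole: float
    core: float
    en: float

    @property
    def mean(self) -> float:
        return (self.whole + self.core + self.en) / 3.0

    def to_dict(self) -> dict:
        return {"whole": self.whole, "core": self.core, "en": self.en, "mean": self.mean}


def dice_score(p_true: np.ndarray, p_pred: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """2 * |true ∩ pred| / (|true| + |pred| + eps) over binary masks."""
    t = np.asarray(p_true).astype(bool)
    p = np.asarray(p_pred).astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"mask shapes differ: {t.shape} vs {p.shape}")
    inter = float(np.sum(t & p))
    return 2.0 * inter / (float(t.sum()) + float(p.sum()) + eps)


def region_dice(true_label: SemanticLabel | np.ndarray, pred_label: SemanticLabel | np.ndarray,
                eps: float = DEFAULT_EPS) -> DiceReport:
    """Per-region Dice over the whole / core / enhancing grouping."""
    t = true_label.classes if isinstance(true_label, SemanticLabel) else np.asarray(true_label)
    p = pred_label.classes if isinstance(pred_label, SemanticLabel) else np.asarray(pred_label)
    if t.shape != p.shape:
        raise ValueError(f"label shapes differ: {t.shape} vs {p.shape}")
    scores = {name: dice_score(np.isin(t, codes), np.isin(p, codes), eps)
              for name, codes in REGION_CODES.items()}
    return DiceReport(**scores)


def frechet_distance(features_real: np.ndarray, features_fake: np.ndarray) -> float:
    """Frechet distance between Gaussian fits to two feature-vector sets."""
    fr = np.asarray(features_real, dtype=np.float64)
    ff = np.asarray(features_fake, dtype=np.float64)
    if fr.ndim == 1:
        fr = fr[:, None]
    if ff.ndim == 1:
        ff = ff[:, None]
    if fr.shape[1] != ff.shape[1]:
        raise ValueError(f"feature dims differ: {fr.shape[1]} vs {ff.shape[1]}")
    if fr.shape[0] < 2 or ff.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    mu_r, mu_f = fr.mean(axis=0), ff.mean(axis=0)
    cov_r = np.atleast_2d(np.cov(fr, rowvar=False))
    cov_f = np.atleast_2d(np.cov(ff, rowvar=False))
    diff = mu_r - mu_f
    prod = linalg.sqrtm(cov_r @ cov_f)
    if np.iscomplexobj(prod):
        prod = prod.real
    prod = (prod + prod.T) / 2.0  # symmetrize against numerical asymmetry
    d2 = float(diff @ diff + np.trace(cov_r) + np.trace(cov_f) - 2.0 * np.trace(prod))
    return max(d2, 0.0)


def fid_images(real_images, fake_images, extractor: FeatureExtractor) -> float:
    """FID between two image sets under the extractor's pooled deep features."""
    real = np.asarray(real_images, dtype=np.float64)
    fake = np.asarray(fake_images, dtype=np.float64)
    if real.size == 0 or fake.size == 0:
        raise ValueError("image sets must be non-empty")
    return frechet_distance(extractor.pooled(real), extractor.pooled(fake))
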