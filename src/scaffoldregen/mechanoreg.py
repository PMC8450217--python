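"""Mechanoregulation: mapping local mechanics to a favoured tissue class.

The stimulus is the pair (hydrostatic stress sigma_h, minimal principal
strain eps_min), following the tissue-differentiation theory of Claes and
Heigele, extended with a bone-resorption zone for near-zero stimuli.
Each (sigma_h, eps_min) pair maps to exactly one of four classes by an
ordered rule list (first match wins), which makes boundary behaviour
explicit:

1. RESORPTION  if |eps_min| < eps_res and |sigma_h| < sigma_res
2. BONE        if |eps_min| <= eps_bone and |sigma_h| <= sigma_bone
3. CARTILAGE   if |eps_min| <= eps_cart and sigma_h <= -sigma_bone
4. FIBROUS     otherwise

Strains are in percent, stresses in MPa, compression negative; the
threshold magnitudes for bone and cartilage come from the cited theory
(5% strain / 0.15 MPa / 15% strain); the resorption bounds sit below the
model's operating strain range and, like everything else here, are
configuration parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd


class TissueClass(IntEnum):
    """Favoured differentiation outcome of the local mechanical stimulus."""

    RESORPTION = 0
    BONE = 1
    CARTILAGE = 2
    FIBROUS = 3


class Tissue(IntEnum):
    """Deposited tissue types carried by the agent lattice."""

    GRANULATION = 0
    FIBROUS_TISSUE = 1
    CARTILAGE = 2
    BONE = 3


#: deposited tissue produced under each stimulus class (resorption deposits none)
TISSUE_FOR_CLASS = {
    TissueClass.BONE: Tissue.BONE,
    TissueClass.CARTILAGE: Tissue.CARTILAGE,
    TissueClass.FIBROUS: Tissue.FIBROUS_TISSUE,
}


@dataclass(frozen=True)
class StimulusThresholds:
    """Zone bounds of the stimulus classifier.

    ``eps_*`` are strain magnitudes in percent, ``sigma_*`` stress
    magnitudes in MPa.
    """

    eps_bone: float = 5.0
    sigma_bone: float = 0.15
    eps_cart: float = 15.0
    eps_res: float = 0.01
    sigma_res: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.eps_res < self.eps_bone < self.eps_cart):
            raise ValueError("need 0 < eps_res < eps_bone < eps_cart")
        if not (0 < self.sigma_res < self.sigma_bone):
            raise ValueError("need 0 < sigma_res < sigma_bone")


def classify_field(
    sigma_h: np.ndarray,
    eps_min_pct: np.ndarray,
    thresholds: StimulusThresholds = StimulusThresholds(),
) -> np.ndarray:
    """Vectorized classifier; returns uint8 TissueClass values.

    ``eps_min_pct`` is the minimal principal strain in percent.
    """
    s = np.asarray(sigma_h, dtype=float)
    e = np.asarray(eps_min_pct, dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(e).all()):
        raise ValueError("non-finite stimulus input")
    t = thresholds
    out = np.full(s.shape, TissueClass.FIBROUS, dtype=np.uint8)
    res = (np.abs(e) < t.eps_res) & (np.abs(s) < t.sigma_res)
    bone = ~res & (np.abs(e) <= t.eps_bone) & (np.abs(s) <= t.sigma_bone)
    cart = ~res & ~bone & (np.abs(e) <= t.eps_cart) & (s <= -t.sigma_bone)
    out[cart] = TissueClass.CARTILAGE
    out[bone] = TissueClass.BONE
    out[res] = TissueClass.RESORPTION
    return out


def classify_stimulus(
    sigma_h: float,
    eps_min_pct: float,
    thresholds: StimulusThresholds = StimulusThresholds(),
) -> TissueClass:
    """Scalar form of :func:`classify_field`."""
    return TissueClass(
        int(classify_field(np.array([sigma_h]), np.array([eps_min_pct]), thresholds)[0])
    )


def favoured_fractions(
    classes: np.ndarray, tissue_mask: np.ndarray
) -> pd.Series:
    """Volume fraction of TISSUE elements per stimulus class.

    ``classes`` holds one TissueClass value per element (flat C order);
    voxel elements share one volume, so fractions are plain counts over
    the tissue region and sum to one.
    """
    sel = classes[tissue_mask]
    if sel.size == 0:
        raise ValueError("zero tissue volume: no TISSUE elements in the grid")
    counts = np.bincount(sel, minlength=4).astype(float)
    frac = counts / sel.size
    return pd.Series(frac, index=[c.name for c in TissueClass])
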