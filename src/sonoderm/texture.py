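"""Per-layer echogenicity, intensity-dispersion and GLCM texture features.

Echogenicity follows the three-band convention used in dermatologic
ultrasound: a pixel is low-echogenic below 30, medium-echogenic in
[50, 150] and high-echogenic above 200.  The gaps (30-49 and 151-200) are
deliberately unclassified, so the three ratios need not sum to 1; each is
the count divided by *all* pixels of the layer region.

GLCM features are computed on a masked, symmetric gray-level co-occurrence
matrix at full 256-level quantization, distance 1, four directions
(0, 45, 90, 135 degrees).  Only pixel pairs with *both* members inside the
region mask are counted, which keeps layer-boundary pixels from
contaminating the layer's texture.  Correlation of a constant region
(zero variance) is reported as 0 with a degeneracy flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOW_ECHO_MAX",
    "MID_ECHO_RANGE",
    "HIGH_ECHO_MIN",
    "GLCM_OFFSETS",
    "IntensityFeatures",
    "echogenicity_ratios",
    "intensity_stats",
    "glcm_features",
]

LOW_ECHO_MAX = 30        # low echogenicity: value < 30
MID_ECHO_RANGE = (50, 150)  # medium: 50 <= value <= 150
HIGH_ECHO_MIN = 200      # high: value > 200

#: (row offset, column offset) per direction, distance 1.
GLCM_OFFSETS = {
    "d0": (0, 1),     # 0 deg
    "d45": (-1, 1),   # 45 deg
    "d90": (-1, 0),   # 90 deg
    "d135": (-1, -1), # 135 deg
}


@dataclass
class GLCMDirection:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    degenerate_correlation: bool = False


@dataclass
class IntensityFeatures:
    lep_ratio: float
    mep_ratio: float
    hep_ratio: float
    mpi: float
    piv: float
    epi: float
    #: per-direction GLCM features; a direction with no valid pixel pair is
    #: absent from the map rather than reported as zero.
    glcm: dict[str, GLCMDirection] = field(default_factory=dict)

    def glcm_mean(self, feature: str) -> float:
        vals = [getattr(d, feature) for d in self.glcm.values()]
        return float(np.mean(vals)) if vals else float("nan")


def _masked_values(frame_pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return np.asarray(frame_pixels)[m].astype(np.int64)


def echogenicity_ratios(frame_pixels: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """(LEP, MEP, HEP): fractions of low/medium/high-echogenic pixels.

    Each ratio divides by the total region pixel count; the unclassified
    fraction is ``1 - lep - mep - hep``.
    """
    v = _masked_values(frame_pixels, mask)
    n = v.size
    lep = int((v < LOW_ECHO_MAX).sum()) / n
    mep = int(((v >= MID_ECHO_RANGE[0]) & (v <= MID_ECHO_RANGE[1])).sum()) / n
    hep = int((v > HIGH_ECHO_MIN).sum()) / n
    return lep, mep, hep


def intensity_stats(frame_pixels: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """(MPI, PIV, EPI) for the region.

    MPI is the arithmetic mean intensity; PIV the sample SD (n-1; zero for
    a single pixel); EPI the Shannon entropy (bits) of the 256-bin
    intensity histogram divided by 8, so it lies in [0, 1] with 1 for a
    uniform histogram.
    """
    v = _masked_values(frame_pixels, mask)
    mpi = float(v.mean())
    piv = float(v.std(ddof=1)) if v.size > 1 else 0.0
    counts = np.bincount(v, minlength=256)
    p = counts[counts > 0] / v.size
    epi = float(-(p * np.log2(p)).sum() / 8.0)
    return mpi, piv, epi


def _glcm_direction(values_i: np.ndarray, values_j: np.ndarray) -> GLCMDirection:
    """Features of one symmetric co-occurrence distribution.

    ``values_i``/``values_j`` are the gray levels of each in-mask pixel
    pair (one entry per ordered occurrence after symmetrization).
    """
    i = np.concatenate([values_i, values_j]).astype(np.float64)
    j = np.concatenate([values_j, values_i]).astype(np.float64)
    n = i.size
    diff2 = (i - j) ** 2
    contrast = float(diff2.mean())
    homogeneity = float((1.0 / (1.0 + diff2)).mean())
    # energy needs the actual joint probabilities
    codes = (i * 256 + j).astype(np.int64)
    counts = np.bincount(codes)
    p = counts[counts > 0] / n
    energy = float((p ** 2).sum())
    mu_i, mu_j = i.mean(), j.mean()
    sd_i, sd_j = i.std(), j.std()  # population moments of the marginals
    if sd_i * sd_j == 0:
        return GLCMDirection(contrast, 0.0, energy, homogeneity, degenerate_correlation=True)
    corr = float(((i - mu_i) * (j - mu_j)).mean() / (sd_i * sd_j))
    return GLCMDirection(contrast, corr, energy, homogeneity)


def glcm_features(frame_pixels: np.ndarray, mask: np.ndarray) -> dict[str, GLCMDirection]:
    """Masked GLCM features per direction at distance 1, 256 gray levels.

    Co-occurrences are counted symmetrically between pixel pairs that are
    both inside the mask.  Directions with no valid pair are omitted from
    the result.
    """
    img = np.asarray(frame_pixels).astype(np.int64)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    out: dict[str, GLCMDirection] = {}
    for name, (dr, dc) in GLCM_OFFSETS.items():
        # slice pairs (r, c) and (r + dr, c + dc)
        r0a, r0b = max(0, -dr), max(0, dr)
        c0a, c0b = max(0, -dc), max(0, dc)
        h, w = img.shape
        hh, ww = h - abs(dr), w - abs(dc)
        a = img[r0a:r0a + hh, c0a:c0a + ww]
        b = img[r0b:r0b + hh, c0b:c0b + ww]
        ma = m[r0a:r0a + hh, c0a:c0a + ww]
        mb = m[r0b:r0b + hh, c0b:c0b + ww]
        valid = ma & mb
        if not valid.any():
            continue
        out[name] = _glcm_direction(a[valid], b[valid])
    return out


def extract_intensity_features(frame_pixels: np.ndarray, mask: np.ndarray) -> IntensityFeatures:
    lep, mep, hep = echogenicity_ratios(frame_pixels, mask)
    mpi, piv, epi = intensity_stats(frame_pixels, mask)
    return IntensityFeatures(lep, mep, hep, mpi, piv, epi, glcm_features(frame_pixels, mask))
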