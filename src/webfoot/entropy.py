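"""Disorderliness entropy of proliferating-cell distributions in sections.

Each transverse toe section is imaged in two channels: a nuclear counterstain
(Hoechst; all nuclei, used as a tissue-extent proxy) and a mitosis marker
(PHH3; proliferating cells). Both channels are binarised with Otsu's method.
The statistic is

    S = sum over ordered pairs of distinct foreground pixels of
        ln( d(pair) / W_max )

where d is the Euclidean pixel distance on the proliferating-cell mask and
W_max is the maximum row-wise width of the nuclei mask, which normalises for
the very different section widths of joints vs phalanx centres. Self-pairs
(zero distance) are excluded; each unordered pair therefore counts twice.
Because S grows like N^2 in the number of foreground pixels, the per-pair
mean S / (N(N-1)) is reported alongside.

Sections are aggregated hierarchically: mean over the three section
replicates of an individual, then mean over the three individuals of a
species, separately for the second-joint and mid-phalanx positions; the
headline comparison is the joint/phalanx ratio per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.spatial.distance import cdist, pdist

from .errors import (
    DegenerateImageError,
    InputError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "otsu_threshold",
    "binarise",
    "max_width",
    "pairwise_log_entropy",
    "entropy_S",
    "measure_section",
    "summarize",
    "SectionMeasurement",
    "EntropySummary",
    "load_channel",
]

JOINT = "joint"
PHALANX = "phalanx"
POSITIONS = (JOINT, PHALANX)

# channel index used when an RGB image must be reduced to one channel
_RGB_CHANNEL = {"nuclei": 2, "proliferating": 1}  # blue / green


def _as_grayscale(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale raster, got shape {img.shape}")
    if img.size == 0:
        raise ValidationError("empty image")
    return img


def load_channel(path, channel: str) -> np.ndarray:
    """Read a PNG/TIFF section image as an 8-bit grayscale array.

    RGB inputs are reduced to the channel named by ``channel`` ("nuclei" ->
    blue, "proliferating" -> green); 16-bit inputs are rescaled to 8 bits by
    max-normalisation.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        if channel not in _RGB_CHANNEL:
            raise InputError(f"unknown channel tag {channel!r}")
        arr = arr[:, :, _RGB_CHANNEL[channel]]
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float64)
        top = arr.max()
        if top > 0:
            arr = arr / top * 255.0
        arr = np.round(arr).astype(np.uint8)
    return arr


def otsu_threshold(image) -> int:
    """Otsu threshold of an 8-bit image on the full 256-bin histogram.

    Returns the integer t in [0, 255] maximising the between-class variance
    of the split (<= t) vs (> t); the first maximum wins on ties. Foreground
    is strictly above the threshold.
    """
    img = _as_grayscale(image)
    flat = np.asarray(img, dtype=np.int64).ravel()
    if flat.min() < 0 or flat.max() > 255:
        raise ValidationError("intensities must lie in [0, 255]")
    hist = np.bincount(flat, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(256)
    sigma_b[valid] = (mu_total * w0[valid] - mu[valid]) ** 2 / (w0[valid] * w1[valid])
    return int(np.argmax(sigma_b))


def binarise(image, threshold: int) -> np.ndarray:
    """Boolean mask: pixel strictly above the threshold -> foreground."""
    if not 0 <= threshold <= 255:
        raise ValidationError(f"threshold must be in [0, 255], got {threshold}")
    return _as_grayscale(image) > threshold


def max_width(mask) -> int:
    """Maximum row-wise foreground extent W_max, in pixels.

    Per row with any foreground: last foreground column - first + 1; W_max is
    the maximum over rows. The medio-lateral axis is assumed horizontal.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValidationError(f"expected a 2-D mask, got shape {m.shape}")
    rows = m.any(axis=1)
    if not rows.any():
        raise UndefinedStatisticError("empty mask: W_max undefined")
    first = m.argmax(axis=1)
    last = m.shape[1] - 1 - m[:, ::-1].argmax(axis=1)
    widths = (last - first + 1)[rows]
    return int(widths.max())


_CHUNK = 8000


def pairwise_log_entropy(coords, w_max: float) -> tuple[float, float]:
    """Sum over ordered pairs of distinct points of ln(distance / w_max).

    ``coords`` is an (n, 2) array of point coordinates in pixel units (any
    orientation; the statistic only sees distances). Returns ``(S, S per
    ordered pair)``. Coincident points make the statistic undefined
    (ln 0 = -inf) and raise.
    """
    pts = np.asarray(coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"coords must be (n, 2), got {pts.shape}")
    n = pts.shape[0]
    if n < 2:
        raise UndefinedStatisticError(f"need >= 2 points for S, got {n}")
    if w_max <= 0:
        raise ValidationError(f"w_max must be > 0, got {w_max}")
    if n <= _CHUNK:
        d = pdist(pts)
        if np.any(d == 0.0):
            raise UndefinedStatisticError("coincident points: ln(0) undefined")
        total = 2.0 * float(np.sum(np.log(d / w_max)))
    else:  # block the n^2 distance matrix to bound memory
        total = 0.0
        for i in range(0, n, _CHUNK):
            block = pts[i : i + _CHUNK]
            for j in range(i, n, _CHUNK):
                d = cdist(block, pts[j : j + _CHUNK])
                if j == i:
                    iu = np.triu_indices(d.shape[0], k=1, m=d.shape[1])
                    d = d[iu]
                d = d.ravel()
                if np.any(d == 0.0):
                    raise UndefinedStatisticError("coincident points: ln(0) undefined")
                total += 2.0 * float(np.sum(np.log(d / w_max)))
    return total, total / (n * (n - 1))


def entropy_S(mask, w_max: float) -> tuple[float, float, int]:
    """Entropy S of a binary mask's foreground pixels.

    Pixel coordinates are 0-based pixel centres; distances Euclidean in pixel
    units. Returns ``(S, S_per_pair, N)`` with N the foreground pixel count.
    """
    m = np.asarray(mask, dtype=bool)
    coords = np.argwhere(m)
    if coords.shape[0] < 2:
        raise UndefinedStatisticError(
            f"need >= 2 foreground pixels for S, got {coords.shape[0]}"
        )
    S, per_pair = pairwise_log_entropy(coords, w_max)
    return S, per_pair, int(coords.shape[0])


def _centroids(mask) -> np.ndarray:
    """Connected-component centroids (8-connectivity), as (n, 2) float coords."""
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=np.ones((3, 3)))
    if n == 0:
        return np.empty((0, 2))
    return np.asarray(ndimage.center_of_mass(mask, labels, range(1, n + 1)), dtype=np.float64)


@dataclass
class SectionMeasurement:
    """Per-section record: the statistic plus everything needed to audit it."""

    species: str
    individual: str
    position: str
    section: int
    S: float
    S_per_pair: float
    w_max: int
    n_foreground: int
    nuclei_threshold: int
    prolif_threshold: int
    centroid_mode: bool = False

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ValidationError(f"position must be one of {POSITIONS}, got {self.position!r}")


def measure_section(
    nuclei,
    prolif,
    species: str,
    individual: str,
    position: str,
    section: int = 1,
    centroid_mode: bool = False,
    threshold_override: int | None = None,
) -> SectionMeasurement:
    """Run the full per-section pipeline on a paired-channel image.

    Otsu-binarise both channels (``threshold_override`` replaces both Otsu
    thresholds when given); W_max from the nuclei mask; S from the
    proliferating-cell mask normalised by that W_max. With ``centroid_mode``
    each connected blob on the proliferating mask is reduced to its centroid
    before the pair sum (off by default: the statistic is defined over raw
    pixels).
    """
    nuc = _as_grayscale(nuclei)
    pro = _as_grayscale(prolif)
    if nuc.shape != pro.shape:
        raise ValidationError(f"channel shapes differ: {nuc.shape} vs {pro.shape}")
    if threshold_override is None:
        t_nuc = otsu_threshold(nuc)
        t_pro = otsu_threshold(pro)
    else:
        t_nuc = t_pro = int(threshold_override)
    nuc_mask = binarise(nuc, t_nuc)
    pro_mask = binarise(pro, t_pro)
    w = max_width(nuc_mask)
    if centroid_mode:
        pts = _centroids(pro_mask)
        if pts.shape[0] < 2:
            raise UndefinedStatisticError("fewer than 2 blobs in centroid mode")
        S, per_pair = pairwise_log_entropy(pts, w)
        n_fg = int(pts.shape[0])
    else:
        S, per_pair, n_fg = entropy_S(pro_mask, w)
    return SectionMeasurement(
        species=species,
        individual=str(individual),
        position=position,
        section=int(section),
        S=S,
        S_per_pair=per_pair,
        w_max=w,
        n_foreground=n_fg,
        nuclei_threshold=t_nuc,
        prolif_threshold=t_pro,
        centroid_mode=centroid_mode,
    )


@dataclass
class EntropySummary:
    """Nested means: section -> individual -> species, per position."""

    per_individual: pd.DataFrame
    per_species: pd.DataFrame
    ratios: dict = field(default_factory=dict)

    def ratio(self, species: str) -> float:
        return self.ratios[species]

    def plot(self, path=None):
        """Bar chart of mean S per species and position (joint vs phalanx)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        piv = self.per_species.pivot(index="species", columns="position", values="mean_S")
        piv = piv.reindex(columns=[JOINT, PHALANX])
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(piv.index))
        ax.bar(x - 0.2, piv[JOINT], width=0.4, color="white", edgecolor="black", label="joint")
        ax.bar(x + 0.2, piv[PHALANX], width=0.4, color="black", label="phalanx centre")
        ax.set_xticks(x)
        ax.set_xticklabels(piv.index)
        ax.set_ylabel("entropy S")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig


def summarize(measurements) -> EntropySummary:
    """Aggregate per-section measurements into the species-level comparison.

    Per individual: arithmetic mean of its section replicates. Per species and
    position: mean over individuals. The joint/phalanx ratio is reported per
    species where the phalanx mean is nonzero.
    """
    ms = list(measurements)
    if not ms:
        raise ValidationError("no measurements to summarise")
    df = pd.DataFrame(
        {
            "species": [m.species for m in ms],
            "individual": [m.individual for m in ms],
            "position": [m.position for m in ms],
            "section": [m.section for m in ms],
            "S": [m.S for m in ms],
        }
    )
    per_ind = (
        df.groupby(["species", "position", "individual"], sort=True)["S"]
        .agg(mean_S="mean", n_sections="count")
        .reset_index()
    )
    per_sp = (
        per_ind.groupby(["species", "position"], sort=True)["mean_S"]
        .agg(mean_S="mean", n_individuals="count")
        .reset_index()
    )
    ratios = {}
    for sp, grp in per_sp.groupby("species"):
        vals = dict(zip(grp["position"], grp["mean_S"]))
        if JOINT in vals and PHALANX in vals and vals[PHALANX] != 0:
            ratios[sp] = vals[JOINT] / vals[PHALANX]
    return EntropySummary(per_individual=per_ind, per_species=per_sp, ratios=ratios)
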