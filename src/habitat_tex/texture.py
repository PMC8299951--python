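"""Masked 2D texture features: histogram, GLCM, run-length, wavelet subbands.

Extracts the canonical 467-feature vector from an arbitrary masked region
of an 8-bit quantized image:

========== =====================================================  =====
family     layout                                                 count
========== =====================================================  =====
histogram  mean, variance, skewness, kurtosis                         4
GLCM       19 statistics x (4 angles x 4 distances directional
           + 4 angle-averaged matrices, one per distance)            380
GRLM       11 run-length statistics x 4 angles (distance 1)           44
DWT        3 wavelets (haar, db2, sym4) x (4 scales x 3 detail
           orientations + scale-4 approximation)                      39
========== =====================================================  =====

Co-occurrence pairs and gray-level runs are counted strictly inside the
mask (both pixels of a pair; runs truncate at mask boundaries), so the
features are independent of anything outside the region.  Gray levels use
1-based values in moment-type statistics (the standard co-occurrence /
run-length indexing, which also keeps low-gray-level emphasis finite at
quantized level 0).  Entropies use the natural logarithm with 0*log 0 = 0.

A region for which a feature family is undefined (no valid pairs at an
offset, an empty zone) yields NaN sentinels for the affected entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

__all__ = [
    "GLCM_STATS",
    "GRLM_STATS",
    "WAVELETS",
    "ANGLES",
    "DISTANCES",
    "CoocMatrix",
    "RunLengthMatrix",
    "FeatureVector",
    "feature_names",
    "histogram_features",
    "glcm",
    "glcm_stats",
    "glcm_block",
    "grlm",
    "grlm_stats",
    "grlm_block",
    "dwt_decompose",
    "dwt_block",
    "extract_all",
]

ANGLES = (0, 45, 90, 135)
DISTANCES = (1, 2, 3, 4)
WAVELETS = ("haar", "db2", "sym4")

#: (row, col) step of a unit offset at each angle.
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_STATS = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "max_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "idn",
    "idmn",
)

GRLM_STATS = (
    "sre",  # short run emphasis
    "lre",  # long run emphasis
    "gln",  # gray-level non-uniformity
    "rln",  # run-length non-uniformity
    "rp",  # run percentage (fraction of image in runs)
    "lgre",  # low gray-level run emphasis
    "hgre",  # high gray-level run emphasis
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
)


@dataclass
class CoocMatrix:
    """Normalized symmetric gray-level co-occurrence matrix."""

    P: np.ndarray  # (levels, levels), sums to 1
    levels: int
    angle: int | None  # None for an angle-averaged matrix
    distance: int


@dataclass
class RunLengthMatrix:
    """Gray-level run-length counts R[level, length-1] along one angle."""

    R: np.ndarray  # (levels, max_len) integer counts
    levels: int
    angle: int
    n_pixels: int  # region pixel count (for run percentage)


@dataclass
class FeatureVector:
    """Ordered 467-entry feature vector for one region."""

    names: list[str]
    values: np.ndarray
    region: str = "whole"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    @property
    def is_missing(self) -> bool:
        """True when the whole region was empty (all-NaN vector)."""
        return bool(np.isnan(self.values).all())

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# ---------------------------------------------------------------------------
# canonical naming
# ---------------------------------------------------------------------------

def feature_names(wavelets: tuple[str, ...] = WAVELETS) -> list[str]:
    """The canonical 467-name schema, in extraction order."""
    names = [f"hist_{s}" for s in ("mean", "variance", "skewness", "kurtosis")]
    for stat in GLCM_STATS:
        for a in ANGLES:
            for d in DISTANCES:
                names.append(f"glcm_{stat}_a{a}_d{d}")
        for d in DISTANCES:
            names.append(f"glcm_{stat}_amean_d{d}")
    for stat in GRLM_STATS:
        for a in ANGLES:
            names.append(f"grlm_{stat}_a{a}")
    for w in wavelets:
        for s in (1, 2, 3, 4):
            for o in ("H", "V", "D"):
                names.append(f"dwt_{w}_{s}{o}H")
        names.append(f"dwt_{w}_4LL")
    return names


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(values: np.ndarray) -> dict[str, float]:
    """Population moments of the region gray levels.

    Kurtosis is the non-excess fourth standardized moment (3 for a normal
    distribution); a zero-variance region reports skewness = kurtosis = 0.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        return {k: np.nan for k in ("mean", "variance", "skewness", "kurtosis")}
    mean = v.mean()
    var = v.var()
    if var == 0:
        return {"mean": float(mean), "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    z = v - mean
    skew = (z**3).mean() / var**1.5
    kurt = (z**4).mean() / var**2
    return {"mean": float(mean), "variance": float(var),
            "skewness": float(skew), "kurtosis": float(kurt)}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _requantize(patch: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit gray values onto ``levels`` equal-width bins."""
    if levels == 256:
        return patch.astype(np.int64)
    return (patch.astype(np.int64) * levels) // 256


def glcm(
    patch: np.ndarray,
    mask: np.ndarray,
    angle: int,
    distance: int,
    levels: int = 256,
) -> CoocMatrix | None:
    """Masked symmetric co-occurrence matrix at one (angle, distance) offset.

    Both pixels of a counted pair must lie inside the mask; pairs are
    counted in both directions and the matrix normalized to sum to 1.
    Returns ``None`` when the offset admits no valid pair.
    """
    if angle not in _ANGLE_STEPS:
        raise ValueError(f"angle must be one of {ANGLES}")
    q = _requantize(patch, levels)
    dr, dc = (distance * s for s in _ANGLE_STEPS[angle])
    rows, cols = mask.shape
    r0s, r0e = max(0, -dr), min(rows, rows - dr)
    c0s, c0e = max(0, -dc), min(cols, cols - dc)
    m1 = mask[r0s:r0e, c0s:c0e]
    m2 = mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    both = m1 & m2
    if not both.any():
        return None
    v1 = q[r0s:r0e, c0s:c0e][both]
    v2 = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc][both]
    idx = np.concatenate([v1 * levels + v2, v2 * levels + v1])
    counts = np.bincount(idx, minlength=levels * levels).astype(np.float64)
    P = counts.reshape(levels, levels)
    P /= P.sum()
    return CoocMatrix(P=P, levels=levels, angle=angle, distance=distance)


@lru_cache(maxsize=8)
def _glcm_grids(levels: int):
    i = np.arange(1, levels + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    k_diff = np.arange(levels, dtype=np.float64)  # |i-j| values
    k_sum = np.arange(2, 2 * levels + 1, dtype=np.float64)  # i+j values
    sum_idx = (I + J - 2).astype(np.int64).ravel()  # bins 0..2L-2
    diff_idx = np.abs(I - J).astype(np.int64).ravel()  # bins 0..L-1
    return i, I, J, k_diff, k_sum, sum_idx, diff_idx


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_stats(cm: CoocMatrix) -> dict[str, float]:
    """The 19 co-occurrence statistics of one matrix.

    Standard Haralick / Soh / Clausi formulas with 1-based gray values;
    the degenerate zero-variance matrix reports correlation = 1 (a single
    repeated gray pair is perfectly correlated with itself).
    """
    P = cm.P
    L = cm.levels
    i, I, J, k_diff, k_sum, sum_idx, diff_idx = _glcm_grids(L)

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    p_sum = np.bincount(sum_idx, weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(diff_idx, weights=P.ravel(), minlength=L)

    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    autocorr = float(np.sum(I * J * P))
    contrast = float(k_diff**2 @ p_diff)
    if var_x > 0 and var_y > 0:
        correlation = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 1.0
    spq = k_sum - (mu_x + mu_y)
    cluster_prom = float((spq**4) @ p_sum)
    cluster_shade = float((spq**3) @ p_sum)
    dissimilarity = float(k_diff @ p_diff)
    pnz = P[P > 0]
    energy = float((pnz**2).sum())
    entropy = float(-(pnz * np.log(pnz)).sum())
    homogeneity = float((p_diff / (1.0 + k_diff**2)).sum())
    max_prob = float(pnz.max())
    sum_of_squares = float(((i - mu_x) ** 2) @ px)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = float(-_xlogx(p_sum).sum())
    diff_average = dissimilarity
    difference_variance = float(((k_diff - diff_average) ** 2) @ p_diff)
    difference_entropy = float(-_xlogx(p_diff).sum())

    hx = float(-_xlogx(px).sum())
    hy = float(-_xlogx(py).sum())
    # HXY1 = -sum_ij p log(px py) collapses to HX + HY exactly
    hxy1 = hx + hy
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0

    idn = float((p_diff / (1.0 + k_diff / L)).sum())
    idmn = float((p_diff / (1.0 + k_diff**2 / L**2)).sum())

    return {
        "autocorrelation": autocorr,
        "contrast": contrast,
        "correlation": float(correlation),
        "cluster_prominence": cluster_prom,
        "cluster_shade": cluster_shade,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "max_probability": max_prob,
        "sum_of_squares": sum_of_squares,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "idn": idn,
        "idmn": idmn,
    }


def glcm_block(
    patch: np.ndarray, mask: np.ndarray, levels: int = 256
) -> dict[str, float]:
    """All 380 GLCM features of one region.

    For every distance: the four directional matrices plus their
    angle-averaged matrix (element-wise mean of the available directional
    matrices); 19 statistics each -> 19 x (16 + 4) = 380 values.  A
    missing offset propagates NaN to its statistics.
    """
    out: dict[str, float] = {}
    nan_stats = {s: np.nan for s in GLCM_STATS}
    for d in DISTANCES:
        mats: dict[int, CoocMatrix | None] = {
            a: glcm(patch, mask, a, d, levels=levels) for a in ANGLES
        }
        for a, cm in mats.items():
            stats = glcm_stats(cm) if cm is not None else nan_stats
            for s, v in stats.items():
                out[f"glcm_{s}_a{a}_d{d}"] = v
        avail = [cm.P for cm in mats.values() if cm is not None]
        if avail:
            mean_cm = CoocMatrix(
                P=np.mean(avail, axis=0), levels=levels, angle=None, distance=d
            )
            stats = glcm_stats(mean_cm)
        else:
            stats = nan_stats
        for s, v in stats.items():
            out[f"glcm_{s}_amean_d{d}"] = v
    return out


# ---------------------------------------------------------------------------
# GRLM
# ---------------------------------------------------------------------------

def _lines_along(patch: np.ndarray, mask: np.ndarray, angle: int):
    """Yield (values, in_mask) 1D lines tracing the image along ``angle``."""
    if angle == 0:
        for r in range(patch.shape[0]):
            yield patch[r], mask[r]
    elif angle == 90:
        for c in range(patch.shape[1]):
            yield patch[:, c], mask[:, c]
    elif angle == 45:
        fp, fm = np.fliplr(patch), np.fliplr(mask)
        for k in range(-patch.shape[0] + 1, patch.shape[1]):
            yield np.diagonal(fp, offset=k), np.diagonal(fm, offset=k)
    elif angle == 135:
        for k in range(-patch.shape[0] + 1, patch.shape[1]):
            yield np.diagonal(patch, offset=k), np.diagonal(mask, offset=k)
    else:
        raise ValueError(f"angle must be one of {ANGLES}")


def grlm(
    patch: np.ndarray, mask: np.ndarray, angle: int, levels: int = 256
) -> RunLengthMatrix | None:
    """Masked gray-level run-length matrix along one angle (distance 1).

    Runs are maximal constant-gray segments along the angle's lines,
    truncated wherever the line leaves the mask.  Returns ``None`` for an
    empty region.
    """
    if not mask.any():
        return None
    q = _requantize(patch, levels)
    gray_runs: list[np.ndarray] = []
    len_runs: list[np.ndarray] = []
    for vals, inm in _lines_along(q, mask, angle):
        if not inm.any():
            continue
        coded = np.where(inm, vals, -1)
        # boundaries where the coded value changes
        change = np.flatnonzero(np.diff(coded)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [coded.size]))
        keep = coded[starts] >= 0
        gray_runs.append(coded[starts[keep]])
        len_runs.append(ends[keep] - starts[keep])
    grays = np.concatenate(gray_runs)
    lengths = np.concatenate(len_runs)
    R = np.zeros((levels, int(lengths.max())), dtype=np.int64)
    np.add.at(R, (grays, lengths - 1), 1)
    return RunLengthMatrix(R=R, levels=levels, angle=angle, n_pixels=int(mask.sum()))


def grlm_stats(rlm: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length statistics (Galloway / Chu catalog).

    Gray levels enter low/high emphasis as 1-based values; run percentage
    is the number of runs divided by the region pixel count.
    """
    R = rlm.R.astype(np.float64)
    n_runs = R.sum()
    if n_runs == 0:
        return {s: np.nan for s in GRLM_STATS}
    g = np.arange(1, rlm.levels + 1, dtype=np.float64)[:, None]  # 1-based
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    r_g = R.sum(axis=1)  # runs per gray level
    r_l = R.sum(axis=0)  # runs per length
    return {
        "sre": float((R / l**2).sum() / n_runs),
        "lre": float((R * l**2).sum() / n_runs),
        "gln": float((r_g**2).sum() / n_runs),
        "rln": float((r_l**2).sum() / n_runs),
        "rp": float(n_runs / rlm.n_pixels),
        "lgre": float((R / g**2).sum() / n_runs),
        "hgre": float((R * g**2).sum() / n_runs),
        "srlge": float((R / (g**2 * l**2)).sum() / n_runs),
        "srhge": float((R * g**2 / l**2).sum() / n_runs),
        "lrlge": float((R * l**2 / g**2).sum() / n_runs),
        "lrhge": float((R * g**2 * l**2).sum() / n_runs),
    }


def grlm_block(
    patch: np.ndarray, mask: np.ndarray, levels: int = 256
) -> dict[str, float]:
    """All 44 run-length features (11 statistics x 4 angles)."""
    out: dict[str, float] = {}
    for a in ANGLES:
        rlm = grlm(patch, mask, a, levels=levels)
        stats = grlm_stats(rlm) if rlm is not None else {s: np.nan for s in GRLM_STATS}
        for s, v in stats.items():
            out[f"grlm_{s}_a{a}"] = v
    return out


# ---------------------------------------------------------------------------
# DWT
# ---------------------------------------------------------------------------

def dwt_decompose(
    patch: np.ndarray, wavelet: str, levels: int = 4, mode: str = "symmetric"
):
    """4-level 2D wavelet decomposition (thin wrapper, mode exposed for tests).

    Small regions legitimately reach scales where every coefficient feels
    the boundary; the library's warning about that is expected and muted.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Level value .* too high")
        return pywt.wavedec2(patch.astype(np.float64), wavelet, mode=mode, level=levels)


def _masked_patch_for_dwt(patch: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
    """Bounding-box crop, mean-fill outside the mask, zero-pad to 16k x 16k."""
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub = patch[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].astype(np.float64)
    subm = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    filled = np.where(subm, sub, sub[subm].mean())
    r, c = filled.shape
    pr = (-r) % 16 if r % 16 else 0
    pc = (-c) % 16 if c % 16 else 0
    if r < 16:
        pr = 16 - r
    if c < 16:
        pc = 16 - c
    return np.pad(filled, ((0, pr), (0, pc)))


def dwt_block(
    patch: np.ndarray, mask: np.ndarray, wavelet: str
) -> dict[str, float]:
    """The 13 wavelet-subband features of one region for one wavelet family.

    Mean absolute coefficient of each detail subband over 4 scales and 3
    orientations (H = horizontal, V = vertical, D = diagonal detail), plus
    the scale-4 approximation subband.
    """
    names = [f"dwt_{wavelet}_{s}{o}H" for s in (1, 2, 3, 4) for o in ("H", "V", "D")]
    names.append(f"dwt_{wavelet}_4LL")
    prepared = _masked_patch_for_dwt(patch, mask)
    if prepared is None:
        return {n: np.nan for n in names}
    coeffs = dwt_decompose(prepared, wavelet, levels=4)
    cA4 = coeffs[0]
    out: dict[str, float] = {}
    # coeffs[1] is scale 4, coeffs[4] is scale 1
    for idx, scale in zip(range(1, 5), (4, 3, 2, 1)):
        cH, cV, cD = coeffs[idx]
        out[f"dwt_{wavelet}_{scale}HH"] = float(np.abs(cH).mean())
        out[f"dwt_{wavelet}_{scale}VH"] = float(np.abs(cV).mean())
        out[f"dwt_{wavelet}_{scale}DH"] = float(np.abs(cD).mean())
    out[f"dwt_{wavelet}_4LL"] = float(np.abs(cA4).mean())
    return {n: out[n] for n in names}


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------

def extract_all(
    patch: np.ndarray,
    mask: np.ndarray,
    region: str = "whole",
    levels: int = 256,
    wavelets: tuple[str, ...] = WAVELETS,
) -> FeatureVector:
    """Extract the full 467-entry feature vector for one masked region.

    An empty region (an absent kinetic zone) yields an all-NaN vector with
    ``is_missing`` set, which downstream modeling uses to exclude the
    patient from that zone's model.
    """
    names = feature_names(wavelets)
    if not mask.any():
        return FeatureVector(names=names, values=np.full(len(names), np.nan), region=region)
    vals: dict[str, float] = {}
    hist = histogram_features(patch[mask])
    vals.update({f"hist_{k}": v for k, v in hist.items()})
    vals.update(glcm_block(patch, mask, levels=levels))
    vals.update(grlm_block(patch, mask, levels=levels))
    for w in wavelets:
        vals.update(dwt_block(patch, mask, w))
    return FeatureVector(
        names=names, values=np.array([vals[n] for n in names]), region=region
    )
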