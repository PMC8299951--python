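"""Pixelwise enhancement kinetics and intratumoral subregion partition.

For each pixel the relative enhancement at post-contrast phase t is

    H(m, n, t) = (I(m, n, t) - I(m, n, t0)) / I(m, n, t0)

with the pre-contrast intensity I(., t0) clamped below by one gray level
to keep the ratio finite.  The time to peak, TTP(m, n) = argmax_t H, is
the phase at which a pixel's enhancement peaks (earliest phase on ties).
Lesion pixels are then partitioned by TTP into three kinetic habitats:
early (phases 1-4), moderate (5-6) and late (7-8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import DCEStudy, N_PHASES, ZONE_PHASES

__all__ = [
    "DENOM_FLOOR",
    "SubregionMap",
    "relative_enhancement",
    "time_to_peak",
    "partition",
    "partition_study",
]

#: Denominator clamp for near-zero pre-contrast intensities (gray levels).
DENOM_FLOOR = 1.0

ZONES = ("early", "moderate", "late")


@dataclass
class SubregionMap:
    """Per-pixel kinetic habitat labels within a lesion mask.

    ``ttp`` holds the peak phase (1..8) for lesion pixels and 0 elsewhere;
    ``zone`` holds 0 = background, 1 = early, 2 = moderate, 3 = late.
    The three zones partition the mask exactly; empty zones are legal.
    """

    ttp: np.ndarray
    zone: np.ndarray
    counts: dict[str, int]

    def zone_mask(self, name: str) -> np.ndarray:
        code = {"early": 1, "moderate": 2, "late": 3}[name]
        return self.zone == code


def relative_enhancement(study: DCEStudy) -> np.ndarray:
    """Relative enhancement tensor H with phase axis first, shape (8, R, C)."""
    pre = study.pre.astype(np.float64)
    post = study.post.astype(np.float64)
    if post.shape[0] != N_PHASES:
        raise ValueError(f"expected {N_PHASES} post-contrast phases")
    denom = np.maximum(pre, DENOM_FLOOR)
    return (post - pre[None]) / denom[None]


def time_to_peak(H: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel peak phase (1-based) inside ``mask``; 0 outside.

    Ties resolve to the earliest phase (``argmax`` convention), keeping
    "time to peak" minimal for flat curves.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    ttp = np.zeros(mask.shape, dtype=np.int64)
    ttp[mask] = 1 + np.argmax(H[:, mask], axis=0)
    return ttp


def partition(ttp: np.ndarray, mask: np.ndarray) -> SubregionMap:
    """Partition lesion pixels into early/moderate/late kinetic habitats."""
    zone = np.zeros(mask.shape, dtype=np.int64)
    for code, name in enumerate(ZONES, start=1):
        lo, hi = ZONE_PHASES[name]
        zone[mask & (ttp >= lo) & (ttp <= hi)] = code
    counts = {name: int((zone == code).sum()) for code, name in enumerate(ZONES, start=1)}
    return SubregionMap(ttp=np.where(mask, ttp, 0), zone=zone, counts=counts)


def partition_study(study: DCEStudy, mask: np.ndarray) -> SubregionMap:
    """Convenience: enhancement -> TTP -> habitat partition for one study."""
    H = relative_enhancement(study)
    ttp = time_to_peak(H, mask)
    return partition(ttp, mask)
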