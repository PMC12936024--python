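"""Bone-erosion lesion extraction and weighted severity scoring from 3D masks.

Erosion lesions are connected components of a binary label volume (axis
order z, y, x with voxel spacing in mm).  The pathological-erosion filter
keeps only lesions spanning at least two consecutive axial slices — a proxy
that excludes physiological cortical defects and vascular channels, which
appear on single slices.  Retained lesions feed a linear weighted composite:

    score = 100 * (0.3 * I_count + 0.4 * I_diam + 0.3 * I_vol)

where I_count = min(n_lesions / count_cap, 1), I_diam = min(mean max
diameter / diam_cap, 1), and I_vol = erosion volume / bone volume clamped to
[0, 1].  The 0.3/0.4/0.3 weights come from expert analytic-hierarchy
weighting and are taken as given constants; the normalisation caps and the
severity grade cut-offs are configuration, not published constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

SITES = ("wrist", "MPJ", "PIPJ")
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class LabelVolume:
    """Binary erosion labels with a same-shape bone-tissue mask and spacing (dz, dy, dx) mm."""

    array: np.ndarray
    spacing: tuple[float, float, float]
    bone_mask: np.ndarray
    joint_site: str = "wrist"

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        self.bone_mask = np.asarray(self.bone_mask)
        if self.array.ndim != 3 or self.array.shape != self.bone_mask.shape:
            raise ValueError("label array and bone mask must be 3D with identical shapes")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.joint_site not in SITES:
            raise ValueError(f"joint_site must be one of {SITES}")


@dataclass
class Lesion:
    """One connected erosion component with its volumetric metrics.

    Diameters are Euclidean distances between voxel centres in mm: axial is
    the maximum within any single z-plane, vertical the maximum within any
    plane containing the z axis (voxels sharing an x or a y index).
    """

    voxels: np.ndarray  # (n, 3) int indices, rows (z, y, x)
    n_slices: int
    volume_mm3: float
    max_diam_axial_mm: float
    max_diam_vertical_mm: float
    max_diam_mm: float


def _max_pairwise(points: np.ndarray) -> float:
    """Exact maximum pairwise Euclidean distance (points already in mm)."""
    if len(points) < 2:
        return 0.0
    if len(points) > 5000:
        # hull acceleration: the diameter is attained on the convex hull
        from scipy.spatial import ConvexHull

        try:
            points = points[ConvexHull(points).vertices]
        except Exception:
            pass  # degenerate (coplanar/collinear) sets fall back to all pairs
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def lesion_diameters(
    voxels: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[float, float, float]:
    """(axial, vertical, max) diameters in mm for a non-empty voxel set."""
    vox = np.asarray(voxels)
    if vox.size == 0:
        raise ValueError("empty lesion")
    dz, dy, dx = spacing
    mm = vox * np.array([dz, dy, dx])
    axial = 0.0
    for z in np.unique(vox[:, 0]):
        axial = max(axial, _max_pairwise(mm[vox[:, 0] == z][:, 1:]))
    vertical = 0.0
    for x in np.unique(vox[:, 2]):
        vertical = max(vertical, _max_pairwise(mm[vox[:, 2] == x][:, :2]))
    for y in np.unique(vox[:, 1]):
        vertical = max(vertical, _max_pairwise(mm[vox[:, 1] == y][:, [0, 2]]))
    return axial, vertical, max(axial, vertical)


def _make_lesion(voxels: np.ndarray, spacing: tuple[float, float, float]) -> Lesion:
    dz, dy, dx = spacing
    axial, vertical, diam = lesion_diameters(voxels, spacing)
    return Lesion(
        voxels=voxels,
        n_slices=len(np.unique(voxels[:, 0])),
        volume_mm3=float(len(voxels)) * dz * dy * dx,
        max_diam_axial_mm=axial,
        max_diam_vertical_mm=vertical,
        max_diam_mm=diam,
    )


def extract_lesions(volume: LabelVolume, connectivity: int = 26) -> list[Lesion]:
    """Connected components of the erosion labels with per-lesion metrics.

    ``connectivity`` is 6, 18 or 26 (voxel face / edge / corner adjacency).
    Lesions are ordered by (min z, min y, min x) of their voxel sets.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labelled, n = ndimage.label(volume.array > 0, structure=structure)
    lesions = []
    for lab in range(1, n + 1):
        voxels = np.argwhere(labelled == lab)
        lesions.append(_make_lesion(voxels, volume.spacing))
    lesions.sort(key=lambda L: tuple(L.voxels.min(axis=0)))
    return lesions


def filter_pathological(lesions: Sequence[Lesion], min_slices: int = 2) -> list[Lesion]:
    """Keep lesions whose voxels occupy >= ``min_slices`` *consecutive* z slices."""
    kept = []
    for lesion in lesions:
        zs = np.unique(lesion.voxels[:, 0])
        longest = run = 1
        for prev, cur in zip(zs, zs[1:]):
            run = run + 1 if cur == prev + 1 else 1
            longest = max(longest, run)
        if longest >= min_slices:
            kept.append(lesion)
    return kept


@dataclass(frozen=True)
class SeverityWeights:
    """Linear-composite weights and min-max normalisation caps."""

    w_count: float = 0.3
    w_diam: float = 0.4
    w_volratio: float = 0.3
    count_cap: int = 10
    diam_cap_mm: float = 10.0

    def __post_init__(self) -> None:
        if abs(self.w_count + self.w_diam + self.w_volratio - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.count_cap <= 0 or self.diam_cap_mm <= 0:
            raise ValueError("normalisation caps must be positive")


def composite_from_indicators(i_count: float, i_diam: float, i_vol: float,
                              weights: SeverityWeights = SeverityWeights()) -> float:
    """Score 0-100 from already-normalised indicators in [0, 1]."""
    return 100.0 * (weights.w_count * i_count + weights.w_diam * i_diam + weights.w_volratio * i_vol)


def composite_score(
    lesions: Sequence[Lesion],
    bone_mask: np.ndarray,
    spacing: tuple[float, float, float],
    weights: SeverityWeights = SeverityWeights(),
) -> float:
    """Weighted 0-100 severity score from retained lesions and the bone mask.

    Monotone non-decreasing in lesion count, mean max diameter and erosion
    volume ratio.  No lesions scores 0; zero bone volume is rejected.
    """
    dz, dy, dx = spacing
    bone_volume = float(np.count_nonzero(bone_mask)) * dz * dy * dx
    if bone_volume <= 0:
        raise ValueError("bone mask has zero volume")
    if not lesions:
        return 0.0
    i_count = min(len(lesions) / weights.count_cap, 1.0)
    i_diam = min(np.mean([L.max_diam_mm for L in lesions]) / weights.diam_cap_mm, 1.0)
    i_vol = min(max(sum(L.volume_mm3 for L in lesions) / bone_volume, 0.0), 1.0)
    return composite_from_indicators(i_count, i_diam, i_vol, weights)


def grade_severity(
    score: float, cutoffs: tuple[float, float] = (33.3, 66.7), n_lesions: int = 0
) -> str:
    """Map a 0-100 score to none / mild / moderate / severe.

    'none' requires score 0 with no lesions; a boundary score goes to the
    higher grade.
    """
    lo, hi = cutoffs
    if not 0 < lo < hi < 100:
        raise ValueError("cutoffs must be strictly increasing within (0, 100)")
    if score == 0 and n_lesions == 0:
        return "none"
    if score >= hi:
        return "severe"
    if score >= lo:
        return "moderate"
    return "mild"


@dataclass
class SeverityScore:
    """Composite severity output for one patient."""

    overall: float
    grade: str
    per_site: dict[str, float] = field(default_factory=dict)
    rapid_progression: bool = False
    special_site: bool = False
    cutoffs: tuple[float, float] = (33.3, 66.7)


@dataclass
class ProgressionResult:
    annual_rate: float | None  # % per year; None when undefined (baseline 0)
    rapid: bool
    eligible: bool  # follow-up count and interval conditions met


def progression_flags(
    scores: Sequence[float],
    times_months: Sequence[float],
    rapid_rate: float = 30.0,
    min_followups: int = 3,
    min_interval_months: float = 6.0,
) -> ProgressionResult:
    """Annual score growth rate and the rapid-progression flag.

    ``times_months`` are months since baseline, strictly increasing.  The
    annual rate is 100 * (last - first) / first per year elapsed.  Rapid
    progression requires rate >= ``rapid_rate`` AND >= ``min_followups``
    scans with every consecutive interval >= ``min_interval_months``.  A
    zero baseline score leaves the rate undefined and the flag false.
    """
    scores = list(scores)
    times = list(times_months)
    if len(scores) != len(times) or len(scores) < 2:
        raise ValueError("need >= 2 (score, time) pairs of equal length")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("timestamps must be strictly increasing")
    eligible = len(scores) >= min_followups and all(
        b - a >= min_interval_months for a, b in zip(times, times[1:])
    )
    if scores[0] == 0:
        return ProgressionResult(annual_rate=None, rapid=False, eligible=eligible)
    years = (times[-1] - times[0]) / 12.0
    rate = 100.0 * (scores[-1] - scores[0]) / scores[0] / years
    return ProgressionResult(annual_rate=rate, rapid=eligible and rate >= rapid_rate, eligible=eligible)


def special_site_flag(
    site_erosion_volume: float, site_bone_volume: float, threshold: float = 0.40
) -> bool:
    """True when site erosion volume reaches ``threshold`` of site bone volume (>=)."""
    if site_erosion_volume < 0 or site_bone_volume <= 0:
        raise ValueError("volumes must be non-negative and bone volume positive")
    return site_erosion_volume / site_bone_volume >= threshold


def score_volume(
    volume: LabelVolume,
    weights: SeverityWeights = SeverityWeights(),
    cutoffs: tuple[float, float] = (33.3, 66.7),
    connectivity: int = 26,
    min_slices: int = 2,
) -> tuple[SeverityScore, list[Lesion]]:
    """End-to-end scoring of one label volume: extract, filter, score, grade."""
    lesions = filter_pathological(extract_lesions(volume, connectivity), min_slices)
    score = composite_score(lesions, volume.bone_mask, volume.spacing, weights)
    dz, dy, dx = volume.spacing
    bone_volume = float(np.count_nonzero(volume.bone_mask)) * dz * dy * dx
    special = special_site_flag(sum(L.volume_mm3 for L in lesions), bone_volume) if (
        volume.joint_site == "wrist"
    ) else False
    result = SeverityScore(
        overall=score,
        grade=grade_severity(score, cutoffs, n_lesions=len(lesions)),
        per_site={volume.joint_site: score},
        special_site=special,
        cutoffs=cutoffs,
    )
    return result, lesions
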