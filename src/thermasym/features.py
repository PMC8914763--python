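"""Left-right thermal-asymmetry features.

Eight statistics summarize the asymmetry between the two sides of the face
and of the mouth cavity.  For each view the split yields two pixel-temperature
collections, and the features are (absolute) differences of side statistics:

========  ==========================================================
dTf, dTm  |mean(side A) - mean(side B)| of the face / mouth, °C
dTfmax,   |max(side A) - max(side B)|, °C
dTmmax
nf, nm    number of pixels on the warmer side whose temperature
          exceeds the cooler side's maximum by more than the
          asymmetry threshold (default 0.4 °C)
dDEVf,    |MAD(side A) - MAD(side B)|, °C, where MAD is the mean
dDEVm     absolute deviation about the side mean
========  ==========================================================

Absolute differences make every feature invariant to the arbitrary geometric
side labeling.  Because contour estimation is itself uncertain, each feature
vector is the average of several repeated estimates in which the hull
vertices are jittered before ellipse fitting — emulating the manual
adjustment of a few contour points between repeat tracings.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import PipelineConfig
from .edges import body_roi_mask, detect_edges, mouth_roi_mask
from .exceptions import ThermasymError
from .io import Thermogram
from .symmetry import (
    AxisLine,
    Hull,
    RegionPair,
    convex_hull,
    fit_ellipse,
    split_regions,
    symmetry_axis,
)

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "region_summary",
    "count_exceeding",
    "extract_features",
    "estimate_axis",
    "averaged_features",
    "is_asymmetric",
]

FEATURE_NAMES = ("dTf", "dTfmax", "nf", "dDEVf", "dTm", "dTmmax", "nm", "dDEVm")


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """The eight asymmetry statistics for one patient.

    All entries are nonnegative; the counts ``nf``/``nm`` are integers for a
    single estimate but may be fractional after averaging across estimates.
    """

    dTf: float
    dTfmax: float
    nf: float
    dDEVf: float
    dTm: float
    dTmmax: float
    nm: float
    dDEVm: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ThermasymError("feature vector contains non-finite entries")
        if np.any(arr < 0):
            raise ThermasymError("features are absolute differences and must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def region_summary(temps: np.ndarray) -> tuple[float, float, float]:
    """Mean, maximum, and mean absolute deviation about the mean of a
    pixel-temperature collection."""
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ThermasymError("region_summary of an empty collection")
    mean = float(temps.mean())
    return mean, float(temps.max()), float(np.abs(temps - mean).mean())


def count_exceeding(pair: RegionPair, delta_t: float) -> int:
    """Pixels on the warmer side hotter than (cooler side's max + delta_t).

    The warmer side is the one with the larger mean; the comparison is strict
    (strictly higher temperature than the cooler maximum plus the margin).
    """
    if delta_t <= 0:
        raise ThermasymError("delta_t must be > 0")
    mean_a = pair.side_a_temps.mean()
    mean_b = pair.side_b_temps.mean()
    warm, cool = (
        (pair.side_a_temps, pair.side_b_temps)
        if mean_a >= mean_b
        else (pair.side_b_temps, pair.side_a_temps)
    )
    return int(np.count_nonzero(warm > cool.max() + delta_t))


def _pair_features(pair: RegionPair, delta_t: float) -> tuple[float, float, int, float]:
    mean_a, max_a, mad_a = region_summary(pair.side_a_temps)
    mean_b, max_b, mad_b = region_summary(pair.side_b_temps)
    return (
        abs(mean_a - mean_b),
        abs(max_a - max_b),
        count_exceeding(pair, delta_t),
        abs(mad_a - mad_b),
    )


def extract_features(
    face_pair: RegionPair,
    mouth_pair: RegionPair,
    config: PipelineConfig | None = None,
    patient_id: str = "",
) -> FeatureVector:
    """Compute the eight-feature asymmetry vector from one split per view."""
    config = config or PipelineConfig()
    dTf, dTfmax, nf, dDEVf = _pair_features(face_pair, config.delta_t_threshold_c)
    dTm, dTmmax, nm, dDEVm = _pair_features(mouth_pair, config.delta_t_threshold_c)
    return FeatureVector(
        dTf=dTf, dTfmax=dTfmax, nf=nf, dDEVf=dDEVf,
        dTm=dTm, dTmmax=dTmmax, nm=nm, dDEVm=dDEVm,
        patient_id=patient_id,
    )


def estimate_axis(
    tg: Thermogram,
    config: PipelineConfig | None = None,
    jitter: np.ndarray | None = None,
) -> tuple[Hull, AxisLine]:
    """Edge -> hull -> ellipse -> axis for one view.

    The region of interest is the warm body mask for the face view and the
    warm cavity mask for the mouth view.  ``jitter`` (same shape as the hull
    vertex array) perturbs the vertices before ellipse fitting only; the
    unperturbed hull still bounds the analysis field.
    """
    config = config or PipelineConfig()
    roi = mouth_roi_mask(tg, config) if tg.view == "mouth" else body_roi_mask(tg, config)
    edge_map = detect_edges(tg, config, roi_mask=roi)
    hull = convex_hull(edge_map.points)
    verts = hull.vertices
    if jitter is not None:
        verts = verts + jitter
    ellipse = fit_ellipse(verts)
    return hull, symmetry_axis(ellipse)


def _single_estimate(
    face_tg: Thermogram,
    mouth_tg: Thermogram,
    config: PipelineConfig,
    patient_id: str,
    rng: np.random.Generator | None,
) -> FeatureVector:
    pairs = []
    for tg in (face_tg, mouth_tg):
        roi = mouth_roi_mask(tg, config) if tg.view == "mouth" else body_roi_mask(tg, config)
        edge_map = detect_edges(tg, config, roi_mask=roi)
        hull = convex_hull(edge_map.points)
        verts = hull.vertices
        if rng is not None and config.jitter_px > 0:
            verts = verts + rng.uniform(-config.jitter_px, config.jitter_px, size=verts.shape)
        axis = symmetry_axis(fit_ellipse(verts))
        pairs.append(split_regions(tg, hull, axis))
    return extract_features(pairs[0], pairs[1], config, patient_id)


def averaged_features(
    face_tg: Thermogram,
    mouth_tg: Thermogram,
    config: PipelineConfig | None = None,
    seed: int = 0,
    patient_id: str | None = None,
) -> FeatureVector:
    """Feature vector averaged over repeated contour estimates.

    The first estimate uses the detected hull as-is; estimates 2..n perturb
    each hull vertex by an independent uniform offset in ±``jitter_px`` per
    coordinate before the ellipse fit, then the component-wise mean of all
    successful estimates is returned.  Deterministic given ``seed``.  An
    estimate that fails (e.g. a degenerate split) is discarded; an error is
    raised only if every estimate fails.
    """
    config = config or PipelineConfig()
    pid = patient_id if patient_id is not None else face_tg.id
    rng = np.random.default_rng(seed)
    vectors = []
    failures: list[Exception] = []
    for k in range(config.n_estimates):
        jitter_rng = rng if k > 0 else None
        try:
            vectors.append(_single_estimate(face_tg, mouth_tg, config, pid, jitter_rng))
        except ThermasymError as exc:
            failures.append(exc)
    if not vectors:
        raise ThermasymError(
            f"all {config.n_estimates} feature estimates failed; first error: {failures[0]}"
        )
    mean = np.mean([v.as_array() for v in vectors], axis=0)
    return FeatureVector(**dict(zip(FEATURE_NAMES, mean)), patient_id=pid)


def is_asymmetric(fv: FeatureVector, config: PipelineConfig | None = None) -> bool:
    """Baseline threshold rule: abnormal iff the larger of the face and mouth
    mean asymmetries is strictly above the threshold (asymmetry not higher
    than 0.4 °C is the normal criterion, so exactly 0.4 °C is normal)."""
    config = config or PipelineConfig()
    return max(fv.dTf, fv.dTm) > config.delta_t_threshold_c
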