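"""Quantitative evaluation: vessel suppression ratio, lesion detection, rater agreement.

The vessel suppression ratio for one vessel caliber class is

    R_s = SI_WM / (0.5 * (SI_WM + SI_vessel))

where ``SI_WM`` is the mean signal of a homogeneous white-matter ROI and
``SI_vessel`` is the mean of the three vessel-ROI means of that class.
R_s ranges over (0, 2]: 2 means the vessel signal is fully suppressed to
background (zero), 1 means vessels are isointense to WM, and values below 1
mean vessels are brighter than WM (as on post-contrast GRE images).

Lesion detection against phantom ground truth replaces the reader study: a
detection call is a connected supra-threshold component inside the brain,
away from known vessel truth and at least ``min_size_vox`` voxels large; a
call hits a true lesion when its centroid falls inside the lesion sphere.
Sensitivity is reported per lesion, overall and for the >=2 mm maximum-
axial-diameter subgroup, plus spurious-call (false positive) counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.inter_rater import cohens_kappa

from .errors import DegenerateInputError
from .phantom import PhantomSpec, PhantomTruth
from .preprocess import Volume3D

_STRUCT26 = np.ones((3, 3, 3), bool)

__all__ = [
    "RoiSet", "SuppressionReport", "DetectionReport", "RatingTable",
    "place_phantom_rois", "roi_mean", "vessel_suppression_ratio",
    "suppression_report", "detect_lesions", "weighted_kappa",
]


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class RoiSet:
    """Nine vessel ROIs (three per caliber class) and one WM ROI.

    Each ROI is an (n, 3) integer array of voxel indices.  ``slice_index``
    records the nominal axial level of the ROI scheme.
    """

    wm_roi: np.ndarray
    vessel_rois: dict[int, list[np.ndarray]]
    slice_index: int = 0

    def __post_init__(self) -> None:
        for t in (1, 2, 3):
            if len(self.vessel_rois.get(t, [])) != 3:
                raise ValueError(f"expected exactly 3 ROIs for vessel type {t}")
        seen: set[tuple[int, int, int]] = set()
        for roi in self.all_rois():
            vox = {tuple(v) for v in roi}
            if seen & vox:
                raise ValueError("ROIs must be pairwise disjoint")
            seen |= vox

    def all_rois(self) -> list[np.ndarray]:
        return [self.wm_roi] + [r for t in (1, 2, 3) for r in self.vessel_rois[t]]


def _ball_indices(center: np.ndarray, radius: float, shape) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2 + 1e-9
    off = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    vox = np.rint(center).astype(int) + off
    ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    return vox[ok]


def place_phantom_rois(truth: PhantomTruth, spec: PhantomSpec) -> RoiSet:
    """Deterministic phantom analogue of the nine-ROI manual placement.

    For each vessel class, spherical ROIs of that class's vessel radius are
    centered at the centerline midpoints of the first three segments and
    restricted to true vessel voxels of the class.  The WM ROI is a
    radius-3 ball at the WM voxel deepest inside vessel- and lesion-free
    white matter.
    """
    vessel_rois: dict[int, list[np.ndarray]] = {}
    used = np.zeros(truth.label_map.shape, bool)
    for t in (1, 2, 3):
        segs = truth.segments_of_type(t)
        if len(segs) < 3:
            raise ValueError(f"need >=3 vessel segments of type {t}, found {len(segs)}")
        rois = []
        vmask = truth.vessel_mask(t)
        for seg in segs[:3]:
            mid = seg.points_vox[len(seg.points_vox) // 2]
            radius = max(seg.radius_mm / truth.voxel_size_mm, 1.0)
            vox = _ball_indices(mid, radius, truth.label_map.shape)
            keep = vmask[vox[:, 0], vox[:, 1], vox[:, 2]] & ~used[vox[:, 0], vox[:, 1], vox[:, 2]]
            vox = vox[keep]
            if len(vox) == 0:
                raise ValueError(f"empty ROI on a type-{t} segment midpoint")
            used[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            rois.append(vox)
        vessel_rois[t] = rois

    wm = truth.wm_mask() & ~ndimage.binary_dilation(
        truth.vessel_mask() | truth.lesion_mask(), structure=_STRUCT26, iterations=2
    )
    depth = ndimage.distance_transform_edt(wm)
    center = np.unravel_index(int(np.argmax(depth)), depth.shape)
    wm_vox = _ball_indices(np.asarray(center), 3.0, truth.label_map.shape)
    keep = wm[wm_vox[:, 0], wm_vox[:, 1], wm_vox[:, 2]]
    wm_roi = wm_vox[keep]
    return RoiSet(wm_roi=wm_roi, vessel_rois=vessel_rois, slice_index=int(center[2]))


def roi_mean(vol: Volume3D, roi: np.ndarray) -> float:
    """Arithmetic mean of the voxel values inside one ROI."""
    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("empty ROI")
    if np.any(roi < 0) or np.any(roi >= np.asarray(vol.shape)):
        raise ValueError("ROI voxels out of volume bounds")
    return float(vol.data[roi[:, 0], roi[:, 1], roi[:, 2]].mean())


# ---------------------------------------------------------------------------
# Vessel suppression ratio
# ---------------------------------------------------------------------------

def vessel_suppression_ratio(si_wm: float, si_vessel: float) -> float:
    """R_s = SI_WM / (0.5 * (SI_WM + SI_vessel)); in (0, 2], 2 = full suppression."""
    if si_wm <= 0:
        raise ValueError("SI_WM must be positive")
    if si_vessel < 0:
        raise ValueError("SI_vessel must be non-negative")
    return si_wm / (0.5 * (si_wm + si_vessel))


@dataclass
class SuppressionReport:
    """R_s per modality and vessel type, with the underlying ROI means."""

    rows: list[dict] = field(default_factory=list)

    def r_s(self, modality: str, vessel_type: int) -> float:
        for row in self.rows:
            if row["modality"] == modality and row["vessel_type"] == vessel_type:
                return row["r_s"]
        raise KeyError((modality, vessel_type))

    def mean_r_s(self, modality: str) -> float:
        vals = [r["r_s"] for r in self.rows if r["modality"] == modality]
        if not vals:
            raise KeyError(modality)
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def suppression_report(vols: list[Volume3D], rois: RoiSet) -> SuppressionReport:
    """Compute R_s for each volume and vessel type over one ROI scheme.

    ``SI_vessel`` for a class is the mean of its three ROI means (not the
    pooled voxel mean).  Volume order is preserved in the report.
    """
    report = SuppressionReport()
    for vol in vols:
        si_wm = roi_mean(vol, rois.wm_roi)
        for t in (1, 2, 3):
            si_vessel = float(np.mean([roi_mean(vol, r) for r in rois.vessel_rois[t]]))
            report.rows.append(
                {
                    "modality": vol.modality,
                    "vessel_type": t,
                    "si_wm": si_wm,
                    "si_vessel": si_vessel,
                    "r_s": vessel_suppression_ratio(si_wm, si_vessel),
                }
            )
    return report


# ---------------------------------------------------------------------------
# Lesion detection
# ---------------------------------------------------------------------------

@dataclass
class DetectionReport:
    """Per-lesion tallies for one volume (or pooled over several).

    ``tp + fn`` always equals the number of true lesions.  Sensitivities are
    percentages; they are ``None`` (flagged undefined) when the relevant
    denominator is zero.
    """

    n_true: int
    tp: int
    fn: int
    fp: int
    n_true_ge2mm: int = 0
    tp_ge2mm: int = 0
    matched_lesions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_true:
            raise ValueError("TP + FN must equal the number of true lesions")

    @classmethod
    def from_counts(cls, tp: int, n_true: int, fp: int = 0,
                    tp_ge2mm: int = 0, n_true_ge2mm: int = 0) -> "DetectionReport":
        return cls(n_true=n_true, tp=tp, fn=n_true - tp, fp=fp,
                   n_true_ge2mm=n_true_ge2mm, tp_ge2mm=tp_ge2mm)

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    @property
    def sensitivity_pct(self) -> float | None:
        return self._pct(self.tp, self.n_true)

    @property
    def sensitivity_ge2mm_pct(self) -> float | None:
        return self._pct(self.tp_ge2mm, self.n_true_ge2mm)

    @property
    def undefined(self) -> bool:
        return self.n_true == 0

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true, "tp": self.tp, "fn": self.fn, "fp": self.fp,
            "sensitivity_pct": self.sensitivity_pct,
            "n_true_ge2mm": self.n_true_ge2mm, "tp_ge2mm": self.tp_ge2mm,
            "sensitivity_ge2mm_pct": self.sensitivity_ge2mm_pct,
        }


def detect_lesions(
    vol: Volume3D,
    truth: PhantomTruth,
    call_threshold: float = 0.65,
    min_size_vox: int = 2,
    vessel_exclusion_dilation_vox: int = 2,
    size_split_mm: float = 2.0,
) -> DetectionReport:
    """Score a vessel-suppressed volume against phantom lesion truth.

    Candidate calls are 26-connected components of ``vol > call_threshold``
    inside the brain, outside the (dilated) true vessel set, of at least
    ``min_size_vox`` voxels.  A call matches a true lesion when the call
    centroid lies within the lesion radius; every lesion is matched at most
    once, and unmatched calls count as false positives.
    """
    if vol.shape != truth.label_map.shape:
        raise ValueError("volume and truth grids differ")
    brain = truth.brain_mask()
    excl = truth.vessel_mask()
    if excl.any() and vessel_exclusion_dilation_vox > 0:
        excl = ndimage.binary_dilation(excl, structure=_STRUCT26,
                                       iterations=vessel_exclusion_dilation_vox)
    cand = (vol.data > call_threshold) & brain & ~excl
    labels, n_comp = ndimage.label(cand, structure=_STRUCT26)
    centroids, sizes = [], []
    if n_comp:
        idx = np.arange(1, n_comp + 1)
        comp_sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
        coms = ndimage.center_of_mass(cand, labels, index=idx)
        for size, com in zip(comp_sizes, coms):
            if size >= min_size_vox:
                centroids.append(np.asarray(com))
                sizes.append(int(size))

    vox = truth.voxel_size_mm
    matched: set[int] = set()
    fp = 0
    order = np.argsort(sizes)[::-1] if sizes else []
    for ci in order:
        c = centroids[ci]
        hit = None
        best = np.inf
        for li, les in enumerate(truth.lesions):
            if li in matched:
                continue
            d = float(np.linalg.norm(c - np.asarray(les.center_vox)))
            if d <= les.radius_mm / vox and d < best:
                hit, best = li, d
        if hit is None:
            fp += 1
        else:
            matched.add(hit)

    ge2 = [li for li, l in enumerate(truth.lesions) if l.max_axial_diameter_mm >= size_split_mm]
    report = DetectionReport(
        n_true=len(truth.lesions),
        tp=len(matched),
        fn=len(truth.lesions) - len(matched),
        fp=fp,
        n_true_ge2mm=len(ge2),
        tp_ge2mm=len(matched & set(ge2)),
        matched_lesions=sorted(matched),
    )
    if report.undefined:
        warnings.warn("no true lesions: per-lesion sensitivity undefined")
    return report


def per_patient_summary(reports: list[DetectionReport]) -> dict:
    """Per-volume ('per patient') aggregation of detection reports.

    A lesion-bearing volume counts as detected when it has at least one TP;
    a volume with at least one spurious call counts once as a false-positive
    volume, whether or not it bears lesions.
    """
    bearing = [r for r in reports if r.n_true > 0]
    detected = sum(1 for r in bearing if r.tp > 0)
    return {
        "n_volumes": len(reports),
        "n_lesion_bearing": len(bearing),
        "per_patient_sensitivity_pct": (None if not bearing else 100.0 * detected / len(bearing)),
        "fp_volumes": sum(1 for r in reports if r.fp > 0),
    }


# ---------------------------------------------------------------------------
# Rater agreement
# ---------------------------------------------------------------------------

@dataclass
class RatingTable:
    """Two raters' ordinal scores (three-point scale) over the same items."""

    rater_a: np.ndarray
    rater_b: np.ndarray
    n_categories: int = 3
    weighting: str = "linear"  # or "quadratic"

    def __post_init__(self) -> None:
        self.rater_a = np.asarray(self.rater_a, int)
        self.rater_b = np.asarray(self.rater_b, int)
        if self.rater_a.shape != self.rater_b.shape or self.rater_a.ndim != 1:
            raise ValueError("raters must score the same 1D item list")
        if len(self.rater_a) < 2:
            raise ValueError("need at least 2 rated items")
        for r in (self.rater_a, self.rater_b):
            if np.any((r < 1) | (r > self.n_categories)):
                raise ValueError(f"scores must lie in 1..{self.n_categories}")
        if self.weighting not in ("linear", "quadratic"):
            raise ValueError("weighting must be 'linear' or 'quadratic'")

    def contingency(self) -> np.ndarray:
        k = self.n_categories
        table = np.zeros((k, k))
        np.add.at(table, (self.rater_a - 1, self.rater_b - 1), 1)
        return table


def weighted_kappa(table: RatingTable | np.ndarray, weighting: str | None = None) -> float:
    """Weighted Cohen's kappa for two raters on an ordinal scale.

    Accepts a :class:`RatingTable` or a k x k contingency table directly.
    Returns ``nan`` (with a warning) when both raters used a single
    category throughout, in which case chance agreement is 1 and kappa is
    undefined.
    """
    if isinstance(table, RatingTable):
        cont = table.contingency()
        scheme = table.weighting if weighting is None else weighting
    else:
        cont = np.asarray(table, float)
        scheme = weighting or "linear"
        if cont.ndim != 2 or cont.shape[0] != cont.shape[1]:
            raise ValueError("contingency table must be square")
    marg_a = cont.sum(axis=1)
    marg_b = cont.sum(axis=0)
    if (marg_a > 0).sum() == 1 and (marg_b > 0).sum() == 1:
        warnings.warn("single rating category for both raters; kappa undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = cohens_kappa(cont, wt=scheme, return_results=True)
    kappa = float(res.kappa)
    if not np.isfinite(kappa):
        warnings.warn("degenerate rating table; kappa undefined")
    return kappa


KAPPA_BANDS = (
    (0.81, 1.00, "excellent"),
    (0.61, 0.80, "good"),
    (0.41, 0.60, "moderate"),
    (0.21, 0.40, "fair"),
    (0.00, 0.20, "slight"),
)


def kappa_interpretation(kappa: float) -> str:
    """Conventional qualitative band for a kappa value."""
    for lo, hi, name in KAPPA_BANDS:
        if lo <= kappa <= hi + 1e-12:
            return name
    return "poor"
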