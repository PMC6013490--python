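"""Digital head phantoms with paired GRE-like / BB-like contrast.

A phantom is an ellipsoidal "brain" (white-matter core wrapped in a
grey-matter shell, optionally surrounded by a detached bright skull/scalp
rim) containing three caliber classes of tubular vessels and spherical
blob metastases:

* type 1 — thick midline tubes (dural-sinus analogue, radius ~3 voxels),
* type 2 — medium lateral branches off the midline trunk (~2 voxels),
* type 3 — thin, short cortical branches near the brain surface (~1 voxel),
  deliberately *not* connected to the trunk.

Two co-registered renderings are produced from one ground-truth label map.
On the GRE-like volume both vessels and lesions are bright relative to white
matter; on the BB-like volume vessel voxels sit at the background level
(flowing blood suppressed) while lesions stay bright, the WM/GM contrast is
reduced, and a mild Gaussian blur emulates the lower image quality of the
long fast-spin-echo acquisition.  Optionally a fraction of vessel voxels is
left at GRE brightness on the BB volume, emulating imperfect flow
suppression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PlacementError, ShapeMismatchError
from .preprocess import Volume3D, write_volume

# label codes
BG, GM, WM, VESSEL1, VESSEL2, VESSEL3, LESION, SKULL = range(8)
VESSEL_LABELS = {1: VESSEL1, 2: VESSEL2, 3: VESSEL3}
TISSUE_ROLES = ("background", "gm", "wm", "vessel", "lesion", "skull")

# tissue intensity levels in [0, 1]; GRE: vessels and lesions bright, strong
# WM/GM contrast.  BB: vessels at background, lesions retained, weaker WM/GM
# contrast.
DEFAULT_LEVELS_GRE = {
    "background": 0.05, "gm": 0.35, "wm": 0.50, "vessel": 0.95, "lesion": 0.80, "skull": 0.60,
}
DEFAULT_LEVELS_BB = {
    "background": 0.05, "gm": 0.40, "wm": 0.50, "vessel": 0.05, "lesion": 0.80, "skull": 0.60,
}


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom; the defaults are the study conditions."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 1.0
    n_lesions: int = 10
    lesion_radius_range_mm: tuple[float, float] = (0.75, 5.5)
    vessel_counts: dict[int, int] = field(default_factory=lambda: {1: 3, 2: 3, 3: 4})
    vessel_radius_mm: dict[int, float] = field(default_factory=lambda: {1: 3.0, 2: 2.0, 3: 1.0})
    tissue_levels_gre: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LEVELS_GRE))
    tissue_levels_bb: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LEVELS_BB))
    noise_sd: float = 0.02
    bb_blur_sigma_vox: float = 0.5
    residual_vessel_fraction: float = 0.0
    skull_rim: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        for levels in (self.tissue_levels_gre, self.tissue_levels_bb):
            for role in TISSUE_ROLES:
                if role not in levels:
                    raise ValueError(f"missing tissue level for {role!r}")
                if not 0.0 <= levels[role] <= 1.0:
                    raise ValueError(f"tissue level {role!r} outside [0, 1]")
        if not 0.0 <= self.residual_vessel_fraction <= 1.0:
            raise ValueError("residual_vessel_fraction must lie in [0, 1]")
        extent_mm = min(self.grid_shape) * self.voxel_size_mm
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi < extent_mm / 2):
            raise ValueError("lesion radii must be positive and smaller than the grid")
        for t, r in self.vessel_radius_mm.items():
            if not (0 < r < extent_mm / 2):
                raise ValueError(f"vessel radius for type {t} out of range")
        if self.noise_sd < 0 or self.bb_blur_sigma_vox < 0:
            raise ValueError("noise_sd and bb_blur_sigma_vox must be non-negative")

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0

    @property
    def brain_radii_vox(self) -> np.ndarray:
        # slightly anisotropic ellipsoid, leaving room for the skull rim and
        # for a CSF-like gap wide enough that morphological closing cannot
        # bridge brain and skull during brain extraction
        return np.asarray(self.grid_shape) * np.array([0.40, 0.40, 0.38])


@dataclass
class Lesion:
    center_vox: tuple[float, float, float]
    radius_mm: float

    @property
    def max_axial_diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


@dataclass
class VesselSegment:
    points_vox: np.ndarray  # (n, 3) centerline polyline
    radius_mm: float
    vtype: int  # caliber class 1/2/3


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: label map, object lists, residual-vessel voxels."""

    label_map: np.ndarray
    lesions: list[Lesion]
    vessel_segments: list[VesselSegment]
    residual_vessel_voxels: np.ndarray  # (n, 3) int voxel indices
    voxel_size_mm: float = 1.0

    def brain_mask(self) -> np.ndarray:
        return (self.label_map >= GM) & (self.label_map <= LESION)

    def vessel_mask(self, vtype: int | None = None) -> np.ndarray:
        if vtype is None:
            return (self.label_map >= VESSEL1) & (self.label_map <= VESSEL3)
        return self.label_map == VESSEL_LABELS[vtype]

    def lesion_mask(self) -> np.ndarray:
        return self.label_map == LESION

    def wm_mask(self) -> np.ndarray:
        return self.label_map == WM

    def segments_of_type(self, vtype: int) -> list[VesselSegment]:
        return [s for s in self.vessel_segments if s.vtype == vtype]

    def to_json_dict(self) -> dict:
        return {
            "voxel_size_mm": self.voxel_size_mm,
            "lesions": [
                {"center_vox": list(l.center_vox), "radius_mm": l.radius_mm,
                 "max_axial_diameter_mm": l.max_axial_diameter_mm}
                for l in self.lesions
            ],
            "vessel_segments": [
                {"points_vox": s.points_vox.tolist(), "radius_mm": s.radius_mm, "vtype": s.vtype}
                for s in self.vessel_segments
            ],
            "residual_vessel_voxels": self.residual_vessel_voxels.tolist(),
        }


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_rho(shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Normalized ellipsoidal radius: rho <= 1 inside the brain surface."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return np.sqrt(rho2)


def _ball_offsets(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_vox**2 + 1e-9
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _paint_tube(mask: np.ndarray, points: np.ndarray, radius_vox: float) -> None:
    """Rasterize a tube by stamping balls densely along the polyline."""
    offsets = _ball_offsets(radius_vox)
    shape = np.asarray(mask.shape)
    step = max(0.25, 0.3 * radius_vox)
    samples = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n = max(1, int(np.ceil(length / step)))
        for i in range(1, n + 1):
            samples.append(a + seg * (i / n))
    for p in samples:
        vox = np.rint(p).astype(int) + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        v = vox[ok]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True


def _arc(p0: np.ndarray, p1: np.ndarray, bulge: np.ndarray, n: int = 24) -> np.ndarray:
    """Quadratic-Bezier-like arc from p0 to p1 bowed toward p0/2+p1/2+bulge."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    mid = (p0 + p1) / 2 + bulge
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p1


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _midline_trunk_points(spec: PhantomSpec) -> np.ndarray:
    """Dome-shaped midline trunk (sagittal-sinus analogue) in the x mid-plane."""
    c = spec.center
    ry, rz = spec.brain_radii_vox[1], spec.brain_radii_vox[2]
    y = np.linspace(c[1] - 0.70 * ry, c[1] + 0.70 * ry, 48)
    z = c[2] + 0.58 * rz * np.sin(np.pi * (y - y[0]) / (y[-1] - y[0]))
    x = np.full_like(y, c[0])
    return np.stack([x, y, z], axis=1)


def _trunk_point(trunk: np.ndarray, frac: float) -> np.ndarray:
    return trunk[int(round(frac * (len(trunk) - 1)))]


def _type1_segments(spec: PhantomSpec, trunk: np.ndarray, count: int) -> list[np.ndarray]:
    """The trunk plus midline branches hanging off it (toward the brain core)."""
    if count == 0:
        return []
    segs = [trunk]
    c, rz = spec.center, spec.brain_radii_vox[2]
    fracs = np.linspace(0.12, 0.88, max(count - 1, 0) + 2)[1:-1]
    for f in fracs:
        start = _trunk_point(trunk, float(f))
        end = np.array([c[0], start[1] + (8.0 if f < 0.5 else -8.0), c[2] - 0.30 * rz])
        segs.append(_arc(start, end, np.array([0.0, 0.0, -4.0]), n=20))
    return segs[:count]


def _type2_segments(spec: PhantomSpec, trunk: np.ndarray, count: int) -> list[np.ndarray]:
    """Medium lateral branches leaving the trunk, alternating sides."""
    segs = []
    rx = spec.brain_radii_vox[0]
    fracs = np.linspace(0.2, 0.8, count) if count else []
    for i, f in enumerate(fracs):
        start = _trunk_point(trunk, float(f))
        side = 1.0 if i % 2 == 0 else -1.0
        end = start + np.array([side * 0.55 * rx, (i - count / 2) * 3.0, -0.35 * spec.brain_radii_vox[2]])
        segs.append(_arc(start, end, np.array([side * 3.0, 0.0, 2.0]), n=20))
    return segs


def _type3_segments(spec: PhantomSpec, rng: np.random.Generator, count: int) -> list[np.ndarray]:
    """Short thin cortical branches just below the brain surface, unconnected."""
    c = spec.center
    radii = spec.brain_radii_vox
    segs = []
    for _ in range(count):
        # direction away from midline so segments stay clear of type-1/2 vessels
        theta = rng.uniform(0.25 * np.pi, 0.75 * np.pi)  # polar, avoid poles
        phi = rng.uniform(0, 2 * np.pi)
        u = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)])
        if abs(u[0]) < 0.45:  # push laterally, away from the midline plane
            u[0] = np.sign(u[0] or 1.0) * 0.45
            u /= np.linalg.norm(u)
        center = c + u * radii * 0.80
        # tangent direction on the surface
        t = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(t) < 1e-6:
            t = np.cross(u, [0.0, 1.0, 0.0])
        t /= np.linalg.norm(t)
        half = t * rng.uniform(5.0, 8.0)
        segs.append(_arc(center - half, center + half, u * 2.0, n=12))
    return segs


def generate_truth(spec: PhantomSpec) -> PhantomTruth:
    """Build the ground-truth label map and object lists for one phantom.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`PlacementError`
    when the requested lesions cannot be placed without overlap after bounded
    retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    vox = spec.voxel_size_mm
    c = spec.center
    radii = spec.brain_radii_vox

    rho = _ellipsoid_rho(shape, c, radii)
    label = np.zeros(shape, np.int16)
    label[rho <= 1.0] = GM
    label[rho <= 0.88] = WM
    if spec.skull_rim:
        label[(rho > 1.14) & (rho <= 1.22)] = SKULL

    brain = (label == GM) | (label == WM)

    # --- vessels ---------------------------------------------------------
    trunk = _midline_trunk_points(spec)
    counts = {t: int(spec.vessel_counts.get(t, 0)) for t in (1, 2, 3)}
    seg_points = {
        1: _type1_segments(spec, trunk, counts[1]),
        2: _type2_segments(spec, trunk, counts[2]) if counts[1] else
           [_arc(c, c + np.array([(1 if i % 2 == 0 else -1) * 0.55 * radii[0], i * 3.0, -8.0]),
                 np.array([0.0, 3.0, 0.0])) for i in range(counts[2])],
        3: _type3_segments(spec, rng, counts[3]),
    }

    segments: list[VesselSegment] = []
    vessel_any = np.zeros(shape, bool)
    for vtype in (1, 2, 3):
        r_vox = spec.vessel_radius_mm[vtype] / vox
        for pts in seg_points[vtype]:
            tube = np.zeros(shape, bool)
            _paint_tube(tube, pts, r_vox)
            tube &= brain | (label == LESION)  # clip to brain
            new = tube & ~vessel_any & (label != SKULL)
            label[new] = VESSEL_LABELS[vtype]
            vessel_any |= tube
            segments.append(VesselSegment(points_vox=np.asarray(pts), radius_mm=spec.vessel_radius_mm[vtype], vtype=vtype))

    # --- lesions ---------------------------------------------------------
    vessel_dist = ndimage.distance_transform_edt(~vessel_any) if vessel_any.any() else None
    lesions: list[Lesion] = []
    max_tries = 300 * max(spec.n_lesions, 1)
    tries = 0
    lo_r, hi_r = spec.lesion_radius_range_mm
    while len(lesions) < spec.n_lesions:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(lesions)} of {spec.n_lesions} lesions after {tries} tries"
            )
        tries += 1
        r_mm = rng.uniform(lo_r, hi_r)
        r_vox = r_mm / vox
        center = c + (rng.uniform(-1, 1, 3)) * radii * 0.85
        rho_c = float(np.sqrt(np.sum(((center - c) / radii) ** 2)))
        if rho_c > 1.0 - (r_vox + 1.5) / float(radii.min()):
            continue  # ball would poke out of the brain
        if vessel_dist is not None:
            iv = tuple(np.rint(center).astype(int))
            if vessel_dist[iv] < r_vox + 3.0:
                continue  # keep a clear gap from vessels
        if any(np.linalg.norm(np.asarray(l.center_vox) - center) < r_vox + l.radius_mm / vox + 3.0
               for l in lesions):
            continue
        ball = _ball_offsets(r_vox) + np.rint(center).astype(int)
        ok = np.all((ball >= 0) & (ball < np.asarray(shape)), axis=1)
        ball = ball[ok]
        inside = label[ball[:, 0], ball[:, 1], ball[:, 2]]
        if np.any((inside == BG) | (inside == SKULL) | ((inside >= VESSEL1) & (inside <= VESSEL3))):
            continue
        label[ball[:, 0], ball[:, 1], ball[:, 2]] = LESION
        lesions.append(Lesion(center_vox=tuple(float(x) for x in center), radius_mm=float(r_mm)))

    # --- residual (unsuppressed) vessel voxels on BB ---------------------
    vess_idx = np.argwhere((label >= VESSEL1) & (label <= VESSEL3))
    n_res = int(round(spec.residual_vessel_fraction * len(vess_idx)))
    if n_res > 0:
        pick = rng.choice(len(vess_idx), size=n_res, replace=False)
        residual = vess_idx[np.sort(pick)]
    else:
        residual = np.empty((0, 3), int)

    return PhantomTruth(
        label_map=label,
        lesions=lesions,
        vessel_segments=segments,
        residual_vessel_voxels=residual,
        voxel_size_mm=vox,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _levels_lut(levels: dict[str, float]) -> np.ndarray:
    lut = np.empty(8, np.float64)
    lut[BG] = levels["background"]
    lut[GM] = levels["gm"]
    lut[WM] = levels["wm"]
    lut[VESSEL1] = lut[VESSEL2] = lut[VESSEL3] = levels["vessel"]
    lut[LESION] = levels["lesion"]
    lut[SKULL] = levels["skull"]
    return lut


def render_pair(truth: PhantomTruth, spec: PhantomSpec) -> tuple[Volume3D, Volume3D]:
    """Render the co-registered GRE-like and BB-like volumes for one truth.

    The two volumes are voxelwise registered by construction.  The BB volume
    is blurred (if configured), residual vessel voxels are then restored to
    GRE brightness (flow artifacts are sharp), and independent Gaussian noise
    is finally added to both volumes and clipped to [0, 1].
    """
    if truth.label_map.shape != spec.grid_shape:
        raise ShapeMismatchError("truth label map does not match spec grid shape")

    gre = _levels_lut(spec.tissue_levels_gre)[truth.label_map]
    bb = _levels_lut(spec.tissue_levels_bb)[truth.label_map]

    if spec.bb_blur_sigma_vox > 0:
        bb = ndimage.gaussian_filter(bb, sigma=spec.bb_blur_sigma_vox)

    if len(truth.residual_vessel_voxels):
        idx = truth.residual_vessel_voxels
        bb[idx[:, 0], idx[:, 1], idx[:, 2]] = spec.tissue_levels_gre["vessel"]

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, 0xBB])
        gre = gre + noise_rng.normal(0.0, spec.noise_sd, gre.shape)
        bb = bb + noise_rng.normal(0.0, spec.noise_sd, bb.shape)
        gre = np.clip(gre, 0.0, 1.0)
        bb = np.clip(bb, 0.0, 1.0)

    spacing = (spec.voxel_size_mm,) * 3
    return (
        Volume3D(data=gre, spacing_mm=spacing, modality="GRE"),
        Volume3D(data=bb, spacing_mm=spacing, modality="BB"),
    )


def generate_pair(spec: PhantomSpec) -> tuple[PhantomTruth, Volume3D, Volume3D]:
    """Convenience: truth plus rendered pair in one call."""
    truth = generate_truth(spec)
    gre, bb = render_pair(truth, spec)
    return truth, gre, bb


def write_phantom(outdir: str | Path, truth: PhantomTruth, spec: PhantomSpec,
                  gre: Volume3D, bb: Volume3D) -> None:
    """Write the rendered pair (NIfTI), label map (NIfTI) and truth tables (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(gre, outdir / "gre.nii.gz")
    write_volume(bb, outdir / "bb.nii.gz")
    spacing = (spec.voxel_size_mm,) * 3
    write_volume(Volume3D(truth.label_map.astype(np.float64), spacing), outdir / "labels.nii.gz")
    (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict()))
    spec_dict = asdict(spec)
    spec_dict["vessel_counts"] = {str(k): v for k, v in spec.vessel_counts.items()}
    spec_dict["vessel_radius_mm"] = {str(k): v for k, v in spec.vessel_radius_mm.items()}
    (outdir / "spec.json").write_text(json.dumps(spec_dict, indent=2))
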