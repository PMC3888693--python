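"""Synthetic co-registered fundus / SLO / OCT-boundary scenes.

Real studies of nerve-fiber-layer texture pair a 45° color fundus photograph
with a 30° SLO image and an OCT volume of the same eye; none of those inputs
can ship with a software package.  This module generates scenes with the
*statistical structure* that the downstream analysis assumes, so every stage
(preprocessing, feature extraction, registration, thickness reconstruction,
modelling) runs end-to-end and its behaviour can be checked against known
ground truth:

* a smooth RNFL-like thickness field around a synthetic optic disc, thicker
  in the superior/inferior bundles and decaying peripherally;
* a fundus image whose green/blue intensity rises with local thickness
  (``effect_mean``) and whose striation contrast — an oriented sinusoid
  fanning radially around the disc, mimicking fiber bundles — scales with
  thickness (``effect_contrast``); the red channel carries only a weak
  thickness signal plus strong low-frequency "reflection" blobs;
* dark curvilinear vessels recorded in an exclusion mask;
* a 30°-field SLO view of the same scene under a known, invertible
  second-order polynomial warp (the registration ground truth);
* 61–121 evenly spaced B-scan ILM/ONFL boundary pairs sampling the
  thickness field along SLO rows.

Everything is deterministic given ``SceneConfig.seed``: one seeded generator
drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .register import QuadraticTransform, apply_transform
from .thickness import BScanBoundaries

__all__ = ["SceneConfig", "GroundTruthScene", "generate_scene", "generate_landmarks", "write_scene"]


@dataclass
class SceneConfig:
    """Parameters of one synthetic eye.

    Geometry defaults are desk-scale: a 480×480 fundus raster (45° field)
    and a 320×320 SLO raster whose footprint covers the central two thirds
    of the fundus, preserving the 30°/45° field-of-view ratio.  Thickness
    spans 20–180 µm, the physiological peripapillary range.  ``effect_mean``
    and ``effect_contrast`` are dimensionless gains (fraction of full
    intensity scale per unit normalized thickness); ``noise_sd`` is additive
    Gaussian noise as a fraction of full scale.
    """

    fundus_size: tuple[int, int] = (480, 480)
    slo_size: tuple[int, int] = (320, 320)
    n_bscans: int = 61
    bscan_spacing_um: float = 124.3
    thickness_range_um: tuple[float, float] = (20.0, 180.0)
    stripe_period_px: float = 9.0
    effect_mean: float = 0.35
    effect_contrast: float = 0.28
    noise_sd: float = 0.02
    warp_coeffs: np.ndarray | None = None  # 12 reals, SLO→fundus; None → drawn
    n_landmarks: int = 12
    seed: int = 0
    # secondary knobs
    axial_scale_um: float = 3.87  # µm per OCT depth pixel
    slo_pixel_pitch_um: float = 28.1  # µm per SLO pixel (30° ≈ 9 mm across)
    n_rois: int = 20
    roi_size_px: int = 41
    vessel_contrast: float = 0.45
    red_reflection_amp: float = 0.20
    bit_depth: int = 16

    def validate(self) -> None:
        if not (61 <= self.n_bscans <= 121):
            raise ValueError("n_bscans must lie in [61, 121]")
        if self.thickness_range_um[0] < 0 or (
            self.thickness_range_um[1] <= self.thickness_range_um[0]
        ):
            raise ValueError("thickness_range_um must be a nonnegative (min, max)")
        if self.n_landmarks < 6:
            raise ValueError("n_landmarks must be >= 6 (12 unknowns, 2 per pair)")
        if self.warp_coeffs is not None and np.size(self.warp_coeffs) != 12:
            raise ValueError("warp_coeffs must hold 12 reals")
        if min(self.fundus_size) < 4 * self.roi_size_px:
            raise ValueError(
                f"fundus raster {self.fundus_size} too small to host "
                f"{self.roi_size_px}-px ROI windows around an optic disc"
            )
        if min(self.slo_size) < 64:
            raise ValueError("SLO raster too small for the B-scan layout")


@dataclass
class GroundTruthScene:
    """One synthetic eye with full ground truth attached."""

    fundus: np.ndarray  # (H, W, 3) float, [0, 2^bit_depth − 1]
    slo: np.ndarray  # (h, w) float, same scale
    thickness_field: np.ndarray  # (h, w) µm on the SLO grid
    bscan_boundaries: list[BScanBoundaries]
    landmarks: tuple[np.ndarray, np.ndarray]  # (floating SLO xy, reference fundus xy)
    roi_centers: list[tuple[int, int]]  # fundus (row, col)
    true_warp: QuadraticTransform  # SLO (x, y) → fundus (x, y)
    vessel_mask: np.ndarray  # fundus-frame boolean exclusion mask
    od_center_fundus: tuple[float, float]  # (row, col)
    od_radius_fundus: float
    od_center_slo: tuple[float, float]
    od_radius_slo: float
    config: SceneConfig

    def thickness_at_fundus(self, points_rc) -> np.ndarray:
        """Ground-truth thickness (µm) at fundus (row, col) points."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        return _thickness_analytic(
            pts[:, 1], pts[:, 0], self.od_center_fundus, self.od_radius_fundus,
            self.config.thickness_range_um,
        )


# --------------------------------------------------------------------------
# analytic fields (fundus frame, x = col, y = row)
# --------------------------------------------------------------------------

def _thickness_analytic(x, y, od_center_rc, od_radius, t_range):
    """Smooth RNFL-like thickness: superior/inferior bundles, radial decay."""
    cy, cx = od_center_rc
    dx, dy = np.asarray(x) - cx, np.asarray(y) - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    radial = np.exp(-((r - 2.2 * od_radius) ** 2) / (2 * (2.0 * od_radius) ** 2))
    angular = 0.30 + 0.70 * np.sin(theta) ** 2
    f = np.clip(radial * angular, 0.0, 1.0)
    tmin, tmax = t_range
    return tmin + (tmax - tmin) * f


def _stripe_analytic(x, y, od_center_rc, od_radius, period_px):
    """Oriented sinusoid fanning radially around the disc (fiber striation)."""
    cy, cx = od_center_rc
    theta = np.arctan2(np.asarray(y) - cy, np.asarray(x) - cx)
    # integer harmonic count so the pattern closes smoothly over 2π; spacing
    # equals period_px at the reference radius 2.5·r_od
    m = max(4, int(round(2 * np.pi * 2.5 * od_radius / period_px)))
    return np.cos(m * theta)


def _red_reflection(shape, rng, n_blobs=6):
    """Low-frequency bright blobs mimicking reflections from deep layers."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    out = np.zeros(shape)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.15, 0.85, 2) * (H, W)
        s = rng.uniform(0.15, 0.35) * min(H, W)
        out += rng.uniform(0.5, 1.0) * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    peak = out.max()
    return out / peak if peak > 0 else out


def _draw_vessels(shape, od_center_rc, od_radius, rng):
    """Stamp dark arcade-like curves; returns (profile 0..1, boolean mask)."""
    H, W = shape
    canvas = np.zeros(shape, dtype=bool)
    cy, cx = od_center_rc
    yy, xx = np.mgrid[0:H, 0:W]
    # two arcades (superior/inferior) plus two nasal branches
    specs = []
    for sign in (+1, -1):
        specs.append((np.pi / 2 * sign, sign * 1.9, 9.0))  # arcade
        specs.append((np.pi * (0.95 + 0.1 * rng.uniform()), sign * 0.5, 7.0))
    for theta0, bend, reach in specs:
        t = np.linspace(0.0, 1.0, 900)
        r = od_radius * (0.9 + reach * t)
        ang = theta0 + bend * t**1.4 * rng.uniform(0.85, 1.15)
        px = cx + r * np.cos(ang)
        py = cy + r * np.sin(ang)
        width = 3.2 - 1.8 * t
        keep = (px >= 0) & (px < W) & (py >= 0) & (py < H)
        for xi, yi, wi in zip(px[keep], py[keep], width[keep]):
            r0, r1 = int(max(yi - wi, 0)), int(min(yi + wi, H - 1)) + 1
            c0, c1 = int(max(xi - wi, 0)), int(min(xi + wi, W - 1)) + 1
            sub = (yy[r0:r1, c0:c1] - yi) ** 2 + (xx[r0:r1, c0:c1] - xi) ** 2 <= wi**2
            canvas[r0:r1, c0:c1] |= sub
    profile = ndimage.gaussian_filter(canvas.astype(float), 1.2)
    if profile.max() > 0:
        profile /= profile.max()
    mask = profile > 0.05  # slightly dilated exclusion mask
    return profile, mask


def _default_warp(cfg: SceneConfig, rng: np.random.Generator) -> QuadraticTransform:
    """SLO→fundus ground-truth warp: similarity + small quadratic terms.

    The linear part centers the SLO footprint on the central 2/3 of the
    fundus; quadratic coefficients are drawn small enough that the warp
    stays invertible over the raster (max quadratic displacement a few px).
    """
    fh, fw = cfg.fundus_size
    sh, sw = cfg.slo_size
    scale_x = (2 / 3) * fw / sw
    scale_y = (2 / 3) * fh / sh
    tx, ty = fw / 6, fh / 6
    a = np.zeros((2, 6))
    a[0, 3], a[0, 5] = scale_x, tx
    a[1, 4], a[1, 5] = scale_y, ty
    # ~3 px of quadratic distortion at the far corner
    qscale = 3.0 / max(sw, sh) ** 2
    a[:, 0:3] += rng.uniform(-qscale, qscale, size=(2, 3))
    # small shear/rotation and jitter of the linear part
    a[0, 4] += rng.uniform(-0.02, 0.02)
    a[1, 3] += rng.uniform(-0.02, 0.02)
    a[:, 5] += rng.uniform(-3, 3, size=2)
    return QuadraticTransform(a, kind="quadratic")


# --------------------------------------------------------------------------
# scene assembly
# --------------------------------------------------------------------------

def generate_scene(cfg: SceneConfig) -> GroundTruthScene:
    """Build one deterministic synthetic eye from ``cfg``.

    Fundus green/blue intensity at each pixel follows

        I = baseline + effect_mean·T̃ + effect_contrast·T̃·stripe + noise,

    with T̃ the thickness field normalized to [0, 1]; the red channel gets a
    fivefold-weaker thickness gain plus strong smooth reflection blobs.  The
    SLO is the same underlying scene evaluated through the ground-truth
    SLO→fundus warp (each SLO pixel looks up the fundus-frame fields at its
    warped position), with its own noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fh, fw = cfg.fundus_size
    sh, sw = cfg.slo_size
    tmin, tmax = cfg.thickness_range_um

    od_center = (fh * 0.5, fw * 0.42)  # (row, col)
    od_radius = 0.055 * min(fh, fw)

    if cfg.warp_coeffs is None:
        warp = _default_warp(cfg, rng)
    else:
        warp = QuadraticTransform(np.asarray(cfg.warp_coeffs, float).reshape(2, 6))

    # fundus-frame fields
    yy, xx = np.mgrid[0:fh, 0:fw].astype(float)
    T_f = _thickness_analytic(xx, yy, od_center, od_radius, cfg.thickness_range_um)
    Tn_f = (T_f - tmin) / (tmax - tmin)
    stripe_f = _stripe_analytic(xx, yy, od_center, od_radius, cfg.stripe_period_px)
    reflect = _red_reflection((fh, fw), rng)
    vessel_profile, vessel_mask = _draw_vessels((fh, fw), od_center, od_radius, rng)

    def channel(base, gain_mean, gain_contrast, extra=0.0):
        img = base + gain_mean * Tn_f + gain_contrast * Tn_f * stripe_f + extra
        img = img * (1.0 - cfg.vessel_contrast * vessel_profile)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        return np.clip(img, 0.0, 1.0)

    G = channel(0.22, cfg.effect_mean, cfg.effect_contrast)
    B = channel(0.18, 0.90 * cfg.effect_mean, 0.90 * cfg.effect_contrast)
    R = channel(0.45, 0.05 * cfg.effect_mean, 0.03 * cfg.effect_contrast,
                extra=cfg.red_reflection_amp * reflect)
    max_val = float(2**cfg.bit_depth - 1)
    fundus = np.stack([R, G, B], axis=-1) * max_val

    # SLO frame: evaluate the same scene through the forward warp
    vv, uu = np.mgrid[0:sh, 0:sw].astype(float)
    slo_pts = np.column_stack([uu.ravel(), vv.ravel()])  # (x, y)
    fundus_pts = apply_transform(warp, slo_pts)
    fx = fundus_pts[:, 0].reshape(sh, sw)
    fy = fundus_pts[:, 1].reshape(sh, sw)
    T_s = _thickness_analytic(fx, fy, od_center, od_radius, cfg.thickness_range_um)
    Tn_s = (T_s - tmin) / (tmax - tmin)
    stripe_s = _stripe_analytic(fx, fy, od_center, od_radius, cfg.stripe_period_px)
    vessel_s = ndimage.map_coordinates(vessel_profile, [fy, fx], order=1, mode="constant")
    slo = (0.30 + 0.45 * Tn_s + 0.12 * Tn_s * stripe_s) * (1 - cfg.vessel_contrast * vessel_s)
    if cfg.noise_sd > 0:
        slo = slo + rng.normal(0.0, cfg.noise_sd, size=slo.shape)
    slo = np.clip(slo, 0.0, 1.0) * max_val

    # OD geometry in the SLO frame (for thickness-map masking): locate the
    # warped disc center numerically via the linear part of the warp
    Mi = np.linalg.inv(warp.a[:, 3:5])
    od_xy_f = np.array([od_center[1], od_center[0]])
    od_xy_s = Mi @ (od_xy_f - warp.a[:, 5])
    od_center_slo = (float(od_xy_s[1]), float(od_xy_s[0]))
    od_radius_slo = od_radius / float(np.sqrt(abs(np.linalg.det(warp.a[:, 3:5]))))

    # B-scan boundary curves sampling the SLO-grid thickness field
    margin = max(4, sh // 32)
    rows = np.unique(np.round(np.linspace(margin, sh - 1 - margin, cfg.n_bscans)).astype(int))
    if len(rows) < cfg.n_bscans:
        raise ValueError(
            f"SLO raster of {sh} rows cannot host {cfg.n_bscans} distinct B-scan rows"
        )
    cols = np.arange(sw, dtype=float)
    scans = []
    for r in rows:
        ilm = 45.0 + 4.0 * np.sin(2 * np.pi * cols / sw + 0.3)
        onfl = ilm + T_s[r, :] / cfg.axial_scale_um
        scans.append(BScanBoundaries(float(r), ilm, onfl, cfg.axial_scale_um))

    # vessel-free ROI centers in the peripapillary annulus
    from .features import propose_roi_centers

    roi_centers = propose_roi_centers(
        (fh, fw), od_center, od_radius, cfg.n_rois, rng,
        vessel_mask=vessel_mask, size_px=cfg.roi_size_px,
        r_min_factor=1.6, r_max_factor=4.6,
    )

    scene = GroundTruthScene(
        fundus=fundus, slo=slo, thickness_field=T_s, bscan_boundaries=scans,
        landmarks=(np.empty((0, 2)), np.empty((0, 2))), roi_centers=roi_centers,
        true_warp=warp, vessel_mask=vessel_mask,
        od_center_fundus=od_center, od_radius_fundus=od_radius,
        od_center_slo=od_center_slo, od_radius_slo=od_radius_slo, config=cfg,
    )
    scene.landmarks = generate_landmarks(scene, cfg.n_landmarks, jitter_px=0.0, rng=rng)
    return scene


def generate_landmarks(
    scene: GroundTruthScene,
    n: int = 12,
    jitter_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-uniform landmark pairs linked by the ground-truth warp.

    ``n`` SLO-frame points are laid out on a near-square grid spanning the
    raster interior (mimicking landmarks "selected possibly uniformly
    throughout the images") and mapped through ``true_warp``; ``jitter_px``
    of Gaussian noise on the reference coordinates emulates manual-picking
    error.  With ``jitter_px = 0`` the correspondences are exact, so a
    least-squares fit recovers the warp to machine precision.
    """
    if n < 6:
        raise ValueError(
            "need at least 6 landmark pairs (12 coordinates) to determine "
            "the 12-parameter quadratic transform"
        )
    if rng is None:
        rng = np.random.default_rng(scene.config.seed + 104729)
    sh, sw = scene.slo.shape
    gx = int(np.ceil(np.sqrt(n)))
    gy = int(np.ceil(n / gx))  # both axes span the full interior
    xs = np.linspace(0.08 * sw, 0.92 * sw, gx)
    ys = np.linspace(0.08 * sh, 0.92 * sh, gy)
    grid = np.array([(x, y) for y in ys for x in xs])
    floating = grid[:n]
    reference = apply_transform(scene.true_warp, floating)
    if jitter_px > 0:
        reference = reference + rng.normal(0.0, jitter_px, size=reference.shape)
    return floating, reference


# --------------------------------------------------------------------------
# artifact export
# --------------------------------------------------------------------------

def write_scene(scene: GroundTruthScene, outdir: str | Path) -> dict[str, str]:
    """Write a scene as plain raster/CSV artifacts plus a YAML manifest.

    Fundus and SLO go out as 16-bit TIFF, the thickness field as 32-bit
    float TIFF; landmarks, ROI centers and per-scan boundary curves as CSV
    with documented headers.  Returns a name→path map.
    """
    import tifffile
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name, fname, arr, dtype):
        p = outdir / fname
        tifffile.imwrite(p, arr.astype(dtype))
        paths[name] = str(p)

    _save("fundus", "fundus.tif", np.round(scene.fundus), np.uint16)
    _save("slo", "slo.tif", np.round(scene.slo), np.uint16)
    _save("thickness_field", "thickness_um.tif", scene.thickness_field, np.float32)
    _save("vessel_mask", "vessel_mask.tif", scene.vessel_mask * np.uint8(255), np.uint8)

    flo, ref = scene.landmarks
    lm = pd.DataFrame(
        {"x_float": flo[:, 0], "y_float": flo[:, 1], "X_ref": ref[:, 0], "Y_ref": ref[:, 1]}
    )
    lm.to_csv(outdir / "landmarks.csv", index=False)
    paths["landmarks"] = str(outdir / "landmarks.csv")

    rc = pd.DataFrame(scene.roi_centers, columns=["row", "col"])
    rc.to_csv(outdir / "roi_centers.csv", index=False)
    paths["roi_centers"] = str(outdir / "roi_centers.csv")

    rows = []
    for i, b in enumerate(scene.bscan_boundaries):
        for col, (a, o) in enumerate(zip(b.ilm, b.onfl)):
            rows.append((i, b.row_position, col, a, o))
    bounds = pd.DataFrame(
        rows, columns=["scan_id", "row_position", "column", "ilm_px", "onfl_px"]
    )
    bounds.to_csv(outdir / "bscan_boundaries.csv", index=False)
    paths["bscan_boundaries"] = str(outdir / "bscan_boundaries.csv")

    (outdir / "transform_true.json").write_text(scene.true_warp.to_json())
    paths["transform_true"] = str(outdir / "transform_true.json")

    cfg = asdict(scene.config)
    cfg["warp_coeffs"] = scene.true_warp.a.ravel().tolist()
    manifest = {
        "config": _plain(cfg),
        "od_center_fundus": list(scene.od_center_fundus),
        "od_radius_fundus": scene.od_radius_fundus,
        "od_center_slo": list(scene.od_center_slo),
        "od_radius_slo": scene.od_radius_slo,
        "axial_scale_um": scene.config.axial_scale_um,
        "files": {k: Path(v).name for k, v in paths.items()},
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    paths["manifest"] = str(outdir / "manifest.yaml")
    return paths


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
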