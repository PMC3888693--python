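"""End-to-end pipeline: scenes → channels → features → registration →
thickness → correlation/regression report.

The stage order follows the analysis flow: preprocess the fundus image into
R/G/B/GB channels, extract first-order features from vessel-free ROIs,
register the SLO frame to the fundus frame from landmark pairs, reconstruct
the dense thickness map from B-scan boundaries, pair each fundus ROI with
the mean thickness of its 7×7 tROI window, then run the Spearman and
regression analyses on the pooled table.

Thickness is sampled in the SLO frame and the fundus ROI center is mapped
into that frame through the (inverse of the) fitted transform; warping the
whole thickness map into the fundus frame is available for visualization
but would interpolate an already-interpolated raster, so it is not used for
measurement.

Everything is deterministic for a fixed config: per-eye scene seeds are
``seed + eye_index`` and the report embeds a hash of the canonical config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import extract_rois, first_order_features
from .model import fit_eq4, spearman_by_image, spearman_pooled, within_eye_error
from .preprocess import make_channels
from .register import LandmarkSet, QuadraticTransform, fit_transform, invert_points, residual_energy
from .synthetic import SceneConfig, generate_scene, write_scene
from .thickness import InvalidWindowError, interpolate_map, sample_troi

__all__ = ["PipelineConfig", "run_pipeline"]

CORE_FEATURES = ("mu", "sigma", "entropy")
ALL_FEATURES = ("mu", "sigma", "entropy", "skewness", "kurtosis")
CHANNELS = ("R", "G", "B", "GB")


@dataclass
class PipelineConfig:
    """Parameters of one batch run.

    ``scene`` holds overrides for :class:`~rnfltex.synthetic.SceneConfig`
    fields (synthetic mode).  Parameter defaults mirror the analysis
    protocol: 20-px CLAHE tiles, 41-px fundus ROIs, 7-px thickness windows.
    """

    output_dir: str = "rnfltex_run"
    n_eyes: int = 15
    seed: int = 0
    scene: dict = field(default_factory=dict)
    tile_px: int = 20
    clip_limit: float = 0.01
    roi_px: int = 41
    troi_px: int = 7
    n_bins: int = 256
    transform_kind: str = "quadratic"
    landmark_jitter_px: float = 0.0
    interp_method: str = "bilinear"
    od_mask_factor: float = 1.15  # OD mask radius as a multiple of disc radius
    normalization: str = "zscore"
    write_artifacts: bool = True

    def validate(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.roi_px % 2 == 0 or self.troi_px % 2 == 0:
            raise ValueError("ROI and tROI window sizes must be odd")
        if self.transform_kind not in ("affine", "quadratic"):
            raise ValueError("transform_kind must be 'affine' or 'quadratic'")
        if self.interp_method not in ("bilinear", "spline"):
            raise ValueError("interp_method must be 'bilinear' or 'spline'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _scene_config(cfg: PipelineConfig, eye_index: int) -> SceneConfig:
    overrides = dict(cfg.scene)
    overrides.setdefault("roi_size_px", cfg.roi_px)
    overrides["seed"] = int(cfg.seed + eye_index)
    for key in ("fundus_size", "slo_size", "thickness_range_um"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    return SceneConfig(**overrides)


def analyze_eye(scene, cfg: PipelineConfig, eye_id: str) -> tuple[pd.DataFrame, dict]:
    """Run preprocess → features → register → thickness for one scene.

    Returns the per-eye rows of the paired dataset and a per-eye diagnostic
    record (registration energy, dropped-ROI bookkeeping).
    """
    channels = make_channels(
        scene.fundus, tile_px=cfg.tile_px, clip_limit=cfg.clip_limit,
        bit_depth=scene.config.bit_depth, linear=True,
    )

    # fundus ROIs, shared admissibility across channels (same mask/centers)
    rois_by_channel: dict[str, list] = {}
    rejected = []
    for tag in CHANNELS:
        samples, rej = extract_rois(
            channels[tag], scene.roi_centers, vessel_mask=scene.vessel_mask,
            size_px=cfg.roi_px,
        )
        rois_by_channel[tag] = samples
        if tag == "GB":
            rejected = rej

    # registration: SLO floating → fundus reference
    lm = LandmarkSet(*scene.landmarks)
    transform = fit_transform(lm, kind=cfg.transform_kind)
    energy = residual_energy(transform, lm)

    # dense thickness map on the SLO grid, optic disc masked
    tmap = interpolate_map(
        scene.bscan_boundaries, scene.slo.shape, method=cfg.interp_method,
        od_center=scene.od_center_slo,
        od_radius=scene.od_radius_slo * cfg.od_mask_factor,
    )

    # pair each fundus ROI with its tROI thickness in the SLO frame
    admissible = [s.center for s in rois_by_channel["GB"]]
    fundus_xy = np.array([(c, r) for r, c in admissible], dtype=float)
    slo_xy, ok = invert_points(transform, fundus_xy)

    rows = []
    dropped_troi = 0
    for i, (center, (x, y), converged) in enumerate(zip(admissible, slo_xy, ok)):
        if not converged:
            dropped_troi += 1
            continue
        try:
            thick = sample_troi(tmap, (y, x), window_px=cfg.troi_px)
        except InvalidWindowError:
            dropped_troi += 1
            continue
        row: dict = {"eye_id": eye_id, "roi_id": i}
        for tag in CHANNELS:
            fv = first_order_features(rois_by_channel[tag][i], n_bins=cfg.n_bins)
            row.update({
                f"mu_{tag}": fv.mu, f"sigma_{tag}": fv.sigma,
                f"entropy_{tag}": fv.entropy, f"skewness_{tag}": fv.skewness,
                f"kurtosis_{tag}": fv.kurtosis,
            })
        row["thickness_um"] = thick
        rows.append(row)

    diag = {
        "eye_id": eye_id,
        "n_rois": len(rows),
        "n_rejected_froi": len(rejected),
        "n_dropped_troi": dropped_troi,
        "registration_energy": energy,
        "transform": transform.a.ravel().tolist(),
    }
    return pd.DataFrame(rows), diag


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full synthetic-cohort analysis and write its report.

    Writes ``paired_dataset.csv``, ``report.json`` and (optionally) per-eye
    scene artifacts under ``cfg.output_dir``; returns the report dict.  The
    report contains no timestamps, so identical config+seed yields
    byte-identical output.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables, diags = [], []
    for i in range(cfg.n_eyes):
        eye_id = f"eye{i:02d}"
        scene = generate_scene(_scene_config(cfg, i))
        if cfg.write_artifacts:
            write_scene(scene, outdir / eye_id)
        table, diag = analyze_eye(scene, cfg, eye_id)
        tables.append(table)
        diags.append(diag)

    data = pd.concat(tables, ignore_index=True)
    data.to_csv(outdir / "paired_dataset.csv", index=False)

    correlations: dict = {"pooled": {}, "per_eye": {}}
    for feat in ALL_FEATURES:
        for ch in CHANNELS:
            col = f"{feat}_{ch}"
            r, p = spearman_pooled(data, col)
            correlations["pooled"][col] = {"r_s": r, "p": p}
    for feat in CORE_FEATURES:
        for ch in CHANNELS:
            col = f"{feat}_{ch}"
            _, summary, skipped = spearman_by_image(data, col)
            correlations["per_eye"][col] = {**summary, "n_skipped": len(skipped)}

    model = fit_eq4(data, normalization=cfg.normalization)
    err_table, err_mean, err_sd = within_eye_error(data, model)

    report = {
        "package": "rnfltex",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_eyes": cfg.n_eyes,
        "n_samples": int(len(data)),
        "eyes": diags,
        "correlations": correlations,
        "model": model.to_dict(),
        "within_eye_error": {
            "per_eye": err_table.to_dict(orient="records"),
            "mean_median_rel_error": err_mean,
            "sd_median_rel_error": err_sd,
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report
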