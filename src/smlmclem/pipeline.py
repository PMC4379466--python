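"""End-to-end pipeline driver.

Runs simulate -> localize -> quality -> resolution -> render -> register from
a single YAML/JSON config, writing every artifact plus a manifest recording
inputs, parameters, seeds and output hashes.  All randomness flows from the
config seed, so an identical config reproduces identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as smio
from .camera import CameraModel, PSFModel
from .density import DensityParams, compute_density_resolution
from .emimage import synthesize_em_image
from .localize import LocalizeSettings, LocalizationTable, localize_movie
from .movie import render_movie
from .nena import NenaError, accuracy_trend, estimate_accuracy_nena
from .register import ControlPointSet, Transform2D, estimate_transform, make_overlay
from .render import RenderSettings, render_sr_image, render_widefield_reference
from .structures import generate_structure
from .switching import SwitchingParams, simulate_switching

__all__ = ["PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

KNOWN_KEYS = {
    "seed",
    "field_of_view_nm",
    "structure",
    "switching",
    "camera",
    "psf",
    "movie",
    "localize",
    "quality",
    "resolution",
    "render",
    "register",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _validate(config: dict) -> None:
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise PipelineError(
            f"unknown config keys: {sorted(unknown)}; expected {sorted(KNOWN_KEYS)}"
        )
    if "seed" not in config:
        raise PipelineError("config must set a seed")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the configured pipeline and return the artifact directory.

    Partial outputs are retained on failure; the raised
    :class:`PipelineError` names the failing stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    fov = tuple(config.get("field_of_view_nm", (2560.0, 2560.0)))

    camera = CameraModel(**config.get("camera", {}))
    psf = PSFModel(**config.get("psf", {}))
    movie_cfg = dict(config.get("movie", {}))
    n_frames = int(movie_cfg.get("n_frames", 300))
    shape = tuple(movie_cfg.get("shape_px", (32, 32)))
    background = float(movie_cfg.get("background", 5.0))

    # ---- simulate ----------------------------------------------------
    @_stage("simulate")
    def simulate():
        struct_cfg = dict(config.get("structure", {"kind": "membrane_pair"}))
        kind = struct_cfg.pop("kind", "membrane_pair")
        emitters = generate_structure(kind, struct_cfg, fov, seed=seed)
        params = SwitchingParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.get("switching", {}).items()
        })
        schedule = simulate_switching(emitters, params, n_frames, camera, seed=seed + 1)
        movie = render_movie(
            schedule, psf, camera, shape, background=background, seed=seed + 2
        )
        smio.write_movie(movie, out / "movie.tif")
        import pandas as pd

        gt = LocalizationTable(
            df=pd.DataFrame(
                {
                    "frame": schedule.frame,
                    "x_nm": schedule.x,
                    "y_nm": schedule.y,
                    "photons": schedule.photons,
                    "background": background,
                    "fit_sigma_nm": psf.sigma_psf,
                    "log_likelihood": 0.0,
                    "n_merged": 1,
                    "emitter_id": schedule.emitter_id,
                }
            ),
            metadata={
                "pixel_size_nm": camera.pixel_size,
                "frame_time_ms": camera.frame_period_ms,
                "source": "ground_truth",
            },
        )
        smio.write_localizations(gt, out / "ground_truth.csv")
        return emitters, movie

    emitters, movie = simulate()

    # ---- localize ----------------------------------------------------
    @_stage("localize")
    def localize():
        from dataclasses import replace

        from .localize import merge_consecutive

        settings = LocalizeSettings(**config.get("localize", {}))
        # the unmerged table keeps the adjacent-frame repeats that the
        # accuracy estimator needs; merging is applied for density/rendering
        raw = localize_movie(movie, psf, replace(settings, merge=False))
        if len(raw) == 0:
            raise ValueError("no localizations found")
        merged = (
            merge_consecutive(raw, settings.merge_radius_nm) if settings.merge else raw
        )
        smio.write_localizations(raw, out / "localizations_raw.csv")
        smio.write_localizations(merged, out / "localizations.csv")
        return raw, merged

    raw_table, table = localize()

    # ---- quality -----------------------------------------------------
    @_stage("quality")
    def quality():
        qcfg = dict(config.get("quality", {}))
        radius = float(qcfg.get("search_radius_nm", 200.0))
        est = estimate_accuracy_nena(raw_table, radius)
        report: dict[str, Any] = {
            "sigma_loc_nm": est.sigma_loc,
            "n_pairs": est.n_pairs,
            "background_fraction": est.fit_background_fraction,
            "confidence_halfwidth_nm": est.confidence_halfwidth,
        }
        n_epochs = int(qcfg.get("n_epochs", 0))
        if n_epochs >= 2:
            try:
                trend = accuracy_trend(raw_table, n_epochs, radius)
                report["trend_sigma_nm"] = [
                    e.sigma_loc if e.valid else None for e in trend
                ]
            except NenaError as exc:
                report["trend_error"] = str(exc)
        (out / "quality.json").write_text(json.dumps(report, indent=2))
        return est

    est = quality()

    # ---- resolution --------------------------------------------------
    @_stage("resolution")
    def resolution():
        rcfg = dict(config.get("resolution", {}))
        params = DensityParams(K=int(rcfg.get("K", 20)))
        result = compute_density_resolution(
            table, est.sigma_loc, params, field_of_view=fov
        )
        (out / "resolution.json").write_text(json.dumps(result.summary, indent=2))
        per_point = table.df.copy()
        per_point["mean_knn_nm"] = result.mean_knn_nm
        per_point["rho_per_um2"] = result.rho_per_um2
        per_point["nyquist_nm"] = result.nyquist_nm
        per_point["structural_nm"] = result.structural_nm
        smio.write_localizations(
            LocalizationTable(df=per_point, metadata=dict(table.metadata)),
            out / "localizations_resolution.csv",
        )
        return result

    densres = resolution()

    # ---- render ------------------------------------------------------
    @_stage("render")
    def render():
        rcfg = dict(config.get("render", {}))
        settings = RenderSettings(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in rcfg.items()
        })
        intensity, color = render_sr_image(table, densres, settings, fov)
        widefield = render_widefield_reference(
            table, settings=settings, field_of_view=fov
        )
        smio.write_image(intensity, out / "sr_intensity.tif")
        smio.write_image(color, out / "sr_color.png")
        smio.write_image(widefield, out / "widefield.tif")
        legend = {
            "colormap": settings.colormap,
            "density_range_per_um2": list(settings.density_range),
            "out_pixel_nm": settings.out_pixel,
        }
        (out / "legend.json").write_text(json.dumps(legend, indent=2))
        return intensity, color

    _, sr_color = render()

    # ---- register ----------------------------------------------------
    @_stage("register")
    def register():
        rcfg = dict(config.get("register", {}))
        tcfg = dict(rcfg.get("transform", {}))
        true_t = Transform2D.similarity(
            scale=float(tcfg.get("scale", 0.1)),
            rotation_deg=float(tcfg.get("rotation_deg", 15.0)),
            translation=tuple(tcfg.get("translation_px", (20.0, 10.0))),
        )
        em_size = tuple(rcfg.get("em_size_px", (256, 256)))
        em_img, _ = synthesize_em_image(
            emitters,
            true_t,
            size=em_size,
            noise_level=float(rcfg.get("noise_level", 0.02)),
            seed=seed + 3,
        )
        smio.write_image(em_img, out / "em.tif")
        rng = np.random.default_rng(seed + 4)
        n_cp = min(8, len(emitters))
        idx = rng.choice(len(emitters), size=n_cp, replace=False)
        cps = ControlPointSet(
            source=emitters.positions[idx],
            target=true_t.apply(emitters.positions[idx]),
        )
        smio.write_control_points(cps, out / "control_points.csv")
        fitted = estimate_transform(cps, kind=rcfg.get("kind", "similarity"))
        fitted.save(out / "transform.json")
        render_cfg = dict(config.get("render", {}))
        sr_pixel = float(render_cfg.get("out_pixel", 5.0))
        overlay = make_overlay(
            sr_color, em_img, fitted, alpha=float(rcfg.get("alpha", 0.5)),
            sr_pixel_nm=sr_pixel,
        )
        smio.write_image(overlay, out / "overlay.png")

    register()

    # ---- manifest ----------------------------------------------------
    artifacts = sorted(
        p.name
        for p in out.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config,
        "seed": seed,
        "outputs": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
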