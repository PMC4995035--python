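"""End-to-end extraction pipeline and run manifest.

The three-stage sequence: sparse decomposition into fibers/artifacts
content, filament enhancement, multi-scale line detection with adaptive
binarization, then segment fitting and fiber merging, with evaluation and
overlay rendering at the end.  Every run writes a manifest recording the
input checksum, the fully resolved configuration and per-stage summary
statistics, so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .enhance import EnhancementConfig, enhance
from .extract import Fiber, MergeConfig, extract_fibers
from .imgio import read_config, read_image, write_config, write_image
from .linedetect import (
    LineResponseConfig,
    ThresholdConfig,
    multiscale_response,
    wellner_binarize,
)
from .mca import MCAConfig, mca_decompose
from .metrics import angular_distribution, orientation_stats
from .transforms import curvelet_dictionary, udwt_dictionary

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "render_overlay",
           "fibers_to_table", "segments_to_table"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage configurations plus paths, seed and stage toggles."""

    mca: MCAConfig = field(default_factory=MCAConfig)
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    line: LineResponseConfig = field(default_factory=LineResponseConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    curvelet_scales: int = 4
    curvelet_angles: int = 8
    udwt_levels: int = 4
    udwt_wavelet: str = "db4"
    skip_decomposition: bool = False
    seed: int = 0
    input_path: str | None = None
    output_dir: str | None = None

    _FLAT = {
        "mca.n_iter": ("mca", "n_iter"),
        "mca.p": ("mca", "p"),
        "mca.delta": ("mca", "delta"),
        "mca.gamma_init_k": ("mca", "gamma_init_k"),
        "mca.gamma_final_k": ("mca", "gamma_final_k"),
        "mca.tv_target": ("mca", "tv_target"),
        "dict.curvelet.scales": (None, "curvelet_scales"),
        "dict.curvelet.angles": (None, "curvelet_angles"),
        "dict.udwt.levels": (None, "udwt_levels"),
        "dict.udwt.wavelet": (None, "udwt_wavelet"),
        "enh.sigma": ("enhancement", "gaussian_sigma"),
        "enh.beta": ("enhancement", "laplace_beta"),
        "enh.laplace_center": ("enhancement", "laplace_center"),
        "enh.laplace_magnitude": ("enhancement", "laplace_magnitude"),
        "enh.dg_sigma": ("enhancement", "dg_sigma"),
        "enh.n_orientations": ("enhancement", "n_orientations"),
        "line.W": ("line", "W"),
        "line.angle_step": ("line", "angle_step_deg"),
        "line.include_pixel_term": ("line", "include_pixel_term"),
        "thr.b": ("threshold", "b"),
        "thr.median_window": ("threshold", "median_window"),
        "thr.mode": ("threshold", "mode"),
        "thr.min_object_px": ("threshold", "min_object_px"),
        "merge.T_theta": ("merge", "T_theta"),
        "merge.overlap_tol_px": ("merge", "overlap_tol_px"),
        "merge.L": ("merge", "L"),
        "pipeline.skip_decomposition": (None, "skip_decomposition"),
        "pipeline.seed": (None, "seed"),
    }

    def to_flat(self) -> dict:
        out = {}
        for key, (sub, attr) in self._FLAT.items():
            obj = self if sub is None else getattr(self, sub)
            out[key] = getattr(obj, attr)
        return out

    @classmethod
    def from_flat(cls, values: dict) -> "PipelineConfig":
        cfg = cls()
        for key, val in values.items():
            if key not in cls._FLAT:
                raise KeyError(f"unknown config key: {key}")
            sub, attr = cls._FLAT[key]
            obj = cfg if sub is None else getattr(cfg, sub)
            setattr(obj, attr, val)
        for sub in (cfg.mca, cfg.enhancement, cfg.line, cfg.threshold, cfg.merge):
            sub.__post_init__()
        return cfg

    def save(self, path) -> None:
        write_config(path, self.to_flat())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_flat(read_config(path))


def fibers_to_table(fibers: list[Fiber]):
    """Fiber list as a DataFrame (endpoint coordinates are (row, col))."""
    import pandas as pd

    rows = []
    for i, f in enumerate(fibers):
        (r0, c0), (r1, c1) = f.endpoints
        rows.append(
            dict(
                fiber_id=i,
                theta_deg=f.theta_deg,
                length_px=f.length_px,
                y0=r0,
                x0=c0,
                y1=r1,
                x1=c1,
                n_pixels=len(f.pixels),
                polyline=";".join(f"{r},{c}" for r, c in f.pixels),
            )
        )
    cols = ["fiber_id", "theta_deg", "length_px", "y0", "x0", "y1", "x1",
            "n_pixels", "polyline"]
    return pd.DataFrame(rows, columns=cols)


def segments_to_table(segments):
    import pandas as pd

    rows = []
    for i, s in enumerate(segments):
        (r0, c0), (r1, c1) = s.endpoints
        rows.append(
            dict(
                segment_id=i,
                theta_deg=s.theta_deg,
                length_px=s.length_px,
                y0=r0,
                x0=c0,
                y1=r1,
                x1=c1,
                n_pixels=len(s.pixels),
            )
        )
    cols = ["segment_id", "theta_deg", "length_px", "y0", "x0", "y1", "x1", "n_pixels"]
    return pd.DataFrame(rows, columns=cols)


def render_overlay(image: np.ndarray, fibers: list[Fiber]) -> np.ndarray:
    """Draw fibers over the image, colored by orientation.

    Colors come from a cyclic palette over [0, 180), so 0 and 180 degrees
    map to the same color.
    """
    from matplotlib import colormaps

    cmap = colormaps["hsv"]
    rgb = np.repeat(np.clip(image, 0, 1)[..., None], 3, axis=2)
    for f in fibers:
        color = np.array(cmap((f.theta_deg % 180.0) / 180.0)[:3])
        rr = np.clip(f.pixels[:, 0], 0, image.shape[0] - 1)
        cc = np.clip(f.pixels[:, 1], 0, image.shape[1] - 1)
        rgb[rr, cc] = color
    return rgb


@dataclass
class RunResult:
    """In-memory outputs of a pipeline run plus the manifest dict."""

    fibers: list
    segments: list
    images: dict
    manifest: dict


def run_pipeline(
    cfg: PipelineConfig,
    image: np.ndarray | None = None,
    truth_mask: np.ndarray | None = None,
) -> RunResult:
    """Execute the full extraction pipeline.

    ``image`` may be passed directly; otherwise ``cfg.input_path`` is
    loaded.  When ``cfg.output_dir`` is set, all intermediate images,
    fiber/segment tables, the orientation histogram, an overlay rendering
    and the JSON manifest are written there.  A stage failure raises
    :class:`StageError` naming the stage; outputs of completed stages are
    preserved on disk.
    """
    t_start = time.time()
    if image is None:
        if cfg.input_path is None:
            raise ValueError("either an image or cfg.input_path is required")
        image = read_image(cfg.input_path)
    image = np.asarray(image, dtype=float)

    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "actintrace",
        "version": __version__,
        "input_sha256": hashlib.sha256(
            np.ascontiguousarray(image).tobytes()
        ).hexdigest(),
        "config": {k: repr(v) for k, v in cfg.to_flat().items()},
        "stages": {},
        "outputs": {},
    }
    images: dict = {"input": image}

    def record(stage: str, arr: np.ndarray, fname: str | None = None) -> None:
        images[stage] = arr
        stats = dict(
            shape=list(arr.shape),
            min=float(np.min(arr)),
            max=float(np.max(arr)),
            mean=float(np.mean(arr)),
            elapsed_s=round(time.time() - t_start, 3),
        )
        manifest["stages"][stage] = stats
        if out_dir and fname:
            write_image(out_dir / fname, arr.astype(np.float32))
            manifest["outputs"][stage] = fname

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            if out_dir:
                (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(name, exc) from exc

    if cfg.skip_decomposition:
        u_f = image
        record("fibers_image", u_f, "u_f.tif")
    else:
        def _decompose():
            d_f = curvelet_dictionary(cfg.curvelet_scales, cfg.curvelet_angles)
            d_a = udwt_dictionary(cfg.udwt_levels, cfg.udwt_wavelet)
            return mca_decompose(image, d_f, d_a, cfg.mca)

        dec = run_stage("decompose", _decompose)
        record("fibers_image", dec.fibers, "u_f.tif")
        record("artifacts_image", dec.artifacts, "v_a.tif")
        record("residual", dec.residual, "residual.tif")
        manifest["stages"]["decompose"] = {
            "estimated_noise_sigma": dec.estimated_noise_sigma
        }
        u_f = dec.fibers

    u_E = run_stage("enhance", lambda: enhance(u_f, cfg.enhancement))
    record("enhanced", u_E, "u_E.tif")

    u_G = run_stage("line_response", lambda: multiscale_response(u_E, cfg.line))
    record("line_response", u_G, "u_G.tif")

    u_B = run_stage("binarize", lambda: wellner_binarize(u_G, cfg.threshold))
    record("binary_mask", u_B.astype(float), "u_B.tif")

    fibers, segments = run_stage(
        "extract", lambda: extract_fibers(u_B, cfg.merge)
    )
    manifest["stages"]["extract"] = {
        "n_segments": len(segments),
        "n_fibers": len(fibers),
    }

    hist = angular_distribution(fibers) if fibers else None
    if fibers:
        stats = orientation_stats(fibers)
        manifest["stages"]["orientation"] = {
            "mean_deg": stats.mean_deg,
            "variance_deg2": stats.variance_deg2,
        }

    if truth_mask is not None:
        from .metrics import acc_sn_sp, confusion_counts

        c = confusion_counts(u_B, truth_mask)
        acc, sn, sp = acc_sn_sp(c)
        manifest["stages"]["evaluation"] = dict(
            TP=c.TP, FP=c.FP, TN=c.TN, FN=c.FN, acc=acc, sn=sn, sp=sp
        )

    if out_dir:
        fibers_to_table(fibers).to_csv(out_dir / "fibers.csv", index=False)
        segments_to_table(segments).to_csv(out_dir / "segments.csv", index=False)
        manifest["outputs"]["fibers"] = "fibers.csv"
        manifest["outputs"]["segments"] = "segments.csv"
        if hist is not None:
            hist.table().to_csv(out_dir / "histogram.csv", index=False)
            manifest["outputs"]["histogram"] = "histogram.csv"
        overlay = render_overlay(image, fibers)
        write_image(out_dir / "overlay.png", overlay)
        manifest["outputs"]["overlay"] = "overlay.png"
        cfg.save(out_dir / "config.txt")
        manifest["outputs"]["config"] = "config.txt"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(fibers=fibers, segments=segments, images=images, manifest=manifest)
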