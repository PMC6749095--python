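"""Readers, writers, configuration and the stage-chaining pipeline.

Image data travels as OME-TIFF with ``TZCYX`` axis order and physical
calibration in the metadata; tracks and measurement tables are CSV with
units spelled out in the column names; configuration is YAML with unknown
keys rejected.  Missing calibration is an error, never a silent default.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import ImageStack, Track

__all__ = [
    "write_stack",
    "read_stack",
    "write_tracks_csv",
    "read_tracks_csv",
    "ExperimentConfig",
    "run_pipeline",
]

TRACK_COLUMNS = ["track_id", "frame", "t_seconds", "x_um", "y_um", "intensity"]


def write_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as OME-TIFF with calibration metadata."""
    meta = {
        "axes": "TZCYX",
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    if stack.z_spacing_um:
        meta["PhysicalSizeZ"] = stack.z_spacing_um
        meta["PhysicalSizeZUnit"] = "µm"
    if stack.frame_interval_s:
        meta["TimeIncrement"] = stack.frame_interval_s
        meta["TimeIncrementUnit"] = "s"
    tifffile.imwrite(str(path), stack.data, ome=True, metadata=meta,
                     photometric="minisblack")


def read_stack(
    path,
    expected_axes: str = "TZCYX",
    pixel_size_um: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    z_spacing_um: Optional[float] = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into a ``TZCYX`` :class:`ImageStack`.

    Axes are normalised to TZCYX, promoting missing axes to singletons.
    Calibration is taken from the OME metadata unless overridden by the
    keyword arguments (an explicit override wins and is logged with a
    warning); if neither source provides a pixel size, this is an error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "T")
        meta_px = meta_dt = meta_dz = None
        if tf.ome_metadata:
            try:
                ome = tifffile.xml2dict(tf.ome_metadata)
                pixels = ome["OME"]["Image"]
                if isinstance(pixels, list):
                    pixels = pixels[0]
                pixels = pixels["Pixels"]
                meta_px = pixels.get("PhysicalSizeX")
                meta_dz = pixels.get("PhysicalSizeZ")
                meta_dt = pixels.get("TimeIncrement")
            except (KeyError, TypeError):
                pass

    # normalise axes to TZCYX
    for ax in expected_axes:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TZCYX"]
    data = np.transpose(data, order)

    px = pixel_size_um if pixel_size_um is not None else meta_px
    if pixel_size_um is not None and meta_px is not None and pixel_size_um != meta_px:
        warnings.warn(
            f"pixel size override {pixel_size_um} μm supersedes metadata {meta_px} μm",
            stacklevel=2,
        )
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata and no override given")
    dt = frame_interval_s if frame_interval_s is not None else (meta_dt or 0.0)
    dz = z_spacing_um if z_spacing_um is not None else (meta_dz or 0.0)
    return ImageStack(data=data, pixel_size_um=float(px),
                      frame_interval_s=float(dt), z_spacing_um=float(dz))


def write_tracks_csv(path, tracks: Sequence[Track]) -> None:
    """Write tracks as CSV with a calibration comment header."""
    frames = [t.to_dataframe() for t in tracks]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    cal = tracks[0] if tracks else None
    with open(path, "w") as fh:
        if cal is not None:
            fh.write(f"# pixel_size_um={cal.pixel_size_um} "
                     f"frame_interval_s={cal.frame_interval_s}\n")
        df.to_csv(fh, index=False)


def read_tracks_csv(path) -> list[Track]:
    """Read a track CSV (optionally with a calibration comment header)."""
    px, dt = 1.0, 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                key, _, val = token.partition("=")
                if key == "pixel_size_um":
                    px = float(val)
                elif key == "frame_interval_s":
                    dt = float(val)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        tracks.append(Track.from_dataframe(sub.reset_index(drop=True),
                                           pixel_size_um=px, frame_interval_s=dt))
    return tracks


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "pixel_size_um", "frame_interval_s", "z_spacing_um", "seed", "out_dir",
    "simulate", "render", "detect", "track", "msd", "morph", "frap", "pulsechase",
}


@dataclass
class ExperimentConfig:
    """Validated experiment configuration (YAML-backed).

    Physical calibrations must be positive; unknown top-level keys are
    rejected so typos fail loudly.  Stage parameter dictionaries are passed
    through to the corresponding pipeline stages.
    """

    pixel_size_um: float = 0.1
    frame_interval_s: float = 1 / 32
    z_spacing_um: float = 0.2
    seed: int = 0
    out_dir: str = "."
    simulate: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    track: dict = field(default_factory=dict)
    msd: dict = field(default_factory=dict)
    morph: dict = field(default_factory=dict)
    frap: dict = field(default_factory=dict)
    pulsechase: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_s", "z_spacing_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: ExperimentConfig, stages: Sequence[str]) -> dict:
    """Execute pipeline stages in order, chaining artifacts on disk.

    Supported stages: ``simulate`` (trajectories → tracks CSV), ``render``
    (tracks → OME-TIFF movie), ``detect`` (movie → candidate CSV),
    ``track`` (candidates → tracked CSV), ``msd`` (tracks → per-track
    estimates CSV + ensemble report).  Each output carries the config hash
    and seed; a stage whose upstream artifact is missing raises an error
    naming the missing stage.
    """
    from . import detect as detect_mod
    from . import motion, simulate as sim, tracking

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": []}

    paths = {
        "tracks": out / "tracks_truth.csv",
        "movie": out / "movie.ome.tif",
        "candidates": out / "candidates.csv",
        "tracked": out / "tracks_measured.csv",
        "estimates": out / "estimates.csv",
    }

    def require(artifact: str, producer: str) -> Path:
        p = paths[artifact]
        if not p.exists():
            raise FileNotFoundError(
                f"missing {p.name}: run the '{producer}' stage first")
        return p

    for stage in stages:
        if stage == "simulate":
            p = config.simulate
            model = sim.MotionModel(
                kind=p.get("kind", "brownian"),
                diffusion_um2_s=p.get("diffusion_um2_s", 5.9e-2),
                drift_speed_um_s=p.get("drift_speed_um_s", 0.0),
                drift_persistence_s=p.get("drift_persistence_s", 1.0),
            )
            tracks = sim.simulate_ensemble(
                model,
                n_tracks=p.get("n_tracks", 23),
                n_frames=p.get("n_frames", 64),
                frame_interval_s=config.frame_interval_s,
                seed=config.seed,
                start_um=tuple(p.get("start_um", (3.2, 3.2))),
                bounds_um=tuple(p["bounds_um"]) if "bounds_um" in p else None,
            )
            write_tracks_csv(paths["tracks"], tracks)
            with open(out / "tracks_truth.yaml", "w") as fh:
                yaml.safe_dump({"stage": "simulate", "seed": config.seed,
                                "config_hash": config.hash(),
                                "params": dict(p),
                                "frame_interval_s": config.frame_interval_s}, fh)
        elif stage == "render":
            tracks = read_tracks_csv(require("tracks", "simulate"))
            p = config.render
            acq = sim.AcquisitionConfig(
                frame_interval_s=config.frame_interval_s,
                pixel_size_um=config.pixel_size_um,
                shot_noise=p.get("shot_noise", True),
                read_noise_sd=p.get("read_noise_sd", 1.0),
                background_level=p.get("background_level", 10.0),
                field_px=tuple(p.get("field_px", (64, 64))),
            )
            stack, _ = sim.render_timelapse(tracks, acq, seed=config.seed,
                                            amplitude=p.get("amplitude", 100.0))
            write_stack(paths["movie"], stack)
        elif stage == "detect":
            stack = read_stack(require("movie", "render"),
                               pixel_size_um=config.pixel_size_um)
            p = config.detect
            movie = stack.data[:, 0, 0]
            per_frame = detect_mod.detect_movie(
                movie,
                sigma=p.get("sigma_px", 1.7),
                threshold_n_sd=p.get("threshold_n_sd", 3.0),
                min_size_px=p.get("min_size_px", 2),
            )
            detect_mod.candidates_to_dataframe(per_frame).to_csv(
                paths["candidates"], index=False)
        elif stage == "track":
            cand_df = pd.read_csv(require("candidates", "detect"))
            p = config.track
            params = tracking.TrackingParams(
                max_displacement_px=p.get("max_displacement_px", 10.0),
                w_intensity=p.get("w_intensity", 0.80),
                w_intensity_variation=p.get("w_intensity_variation", 0.20),
                w_movement=p.get("w_movement", 0.40),
                w_center=p.get("w_center", 0.0),
            )
            n_frames = int(cand_df["frame"].max()) + 1 if len(cand_df) else 0
            per_frame = [[] for _ in range(n_frames)]
            for _, row in cand_df.iterrows():
                per_frame[int(row["frame"])].append(detect_mod.SpotCandidate(
                    frame=int(row["frame"]), x_px=row["x_px"], y_px=row["y_px"],
                    score=row["score"], raw_intensity=row["raw_intensity"],
                    size_px=int(row["size_px"])))
            tr = tracking.track_particle(per_frame, params,
                                         pixel_size_um=config.pixel_size_um,
                                         frame_interval_s=config.frame_interval_s)
            write_tracks_csv(paths["tracked"], [tr])
        elif stage == "msd":
            src = paths["tracked"] if paths["tracked"].exists() else require(
                "tracks", "simulate")
            tracks = read_tracks_csv(src)
            rows = []
            for tr in tracks:
                msd = motion.compute_msd(tr, max_lag=config.msd.get("max_lag", 16))
                est = motion.fit_alpha(msd)
                rows.append({
                    "track_id": tr.track_id,
                    "alpha": est.alpha,
                    "D_um2_s": est.D_um2_s,
                    "r2": est.r_squared,
                    "class": motion.classify_motion(est).value,
                })
            est_df = pd.DataFrame(rows)
            est_df.to_csv(paths["estimates"], index=False)
            alphas = est_df["alpha"].to_numpy()
            report["msd"] = {
                "n_tracks": len(alphas),
                "mean_alpha": float(alphas.mean()),
                "sem_alpha": float(alphas.std(ddof=1) / np.sqrt(len(alphas)))
                if len(alphas) > 1 else float("nan"),
                "mean_D_um2_s": float(est_df["D_um2_s"].mean()),
            }
        elif stage == "morph":
            from . import morphometry
            from .types import CellMeasurement

            p = config.morph
            acq = sim.AcquisitionConfig(
                pixel_size_um=config.pixel_size_um,
                z_spacing_um=config.z_spacing_um,
                psf_sigma_um=p.get("psf_sigma_um", 0.05),
                shot_noise=p.get("shot_noise", False),
                read_noise_sd=p.get("read_noise_sd", 0.0),
            )
            specs = [
                sim.InclusionSpec(center_um=tuple(s["center_um"]),
                                  radii_um=tuple(s["radii_um"]),
                                  intensity_rel=s.get("intensity_rel", 1.6))
                for s in p.get("inclusions",
                               [{"center_um": (3.2, 3.2, 0.0),
                                 "radii_um": (0.5, 0.5, 0.5)}])
            ]
            cyto = p.get("cytoplasm_mean", 100.0)
            stack, _ = sim.render_cell_zstack(specs, acq, seed=config.seed,
                                              n_slices=p.get("n_slices", 17),
                                              cytoplasm_mean=cyto)
            objs = morphometry.segment_objects(
                stack, CellMeasurement(cytoplasm_mean=cyto),
                k_threshold=p.get("k_threshold", 1.2))
            pd.DataFrame([{
                "label": o.label, "class": o.object_class.value if o.object_class else "",
                "z_slice": o.z_slice, "area_um2": o.area_um2,
                "perimeter_um": o.perimeter_um, "CR": o.circularity,
                "aspect_ratio": o.aspect_ratio, "volume_um3": o.apparent_volume_um3,
                "mean_intensity": o.mean_intensity,
            } for o in objs]).to_csv(out / "objects.csv", index=False)
            report["morph"] = {"n_objects": len(objs)}
        elif stage == "frap":
            from .flux import frap_quantify, shell_core_ratio
            from .types import CellMeasurement

            p = config.frap
            acq = sim.AcquisitionConfig(
                pixel_size_um=config.pixel_size_um,
                shot_noise=p.get("shot_noise", True),
                read_noise_sd=p.get("read_noise_sd", 0.5),
                background_level=p.get("background_level", 5.0),
            )
            stack, gt = sim.simulate_frap(
                p.get("radius_um", 0.5), p.get("mode", "interior_mixing"),
                p.get("exchange_rate_per_min", 0.5), p.get("bleach_depth", 0.9),
                acq, p.get("duration_min", 10.0), seed=config.seed)
            gp = gt.true_parameters
            cell = CellMeasurement(cytoplasm_mean=acq.background_level + 0.2,
                                   background=acq.background_level)
            fs = frap_quantify(stack, cell, k_threshold=p.get("k_threshold", 1.4),
                               times_min=gp["times_min"],
                               pre_bleach_index=0)
            fs.data.to_csv(out / "frap_series.csv", index=False)
            b = gp["bleach_frame"]
            r_px = gp["radius_um"] / acq.pixel_size_um
            ratios = [shell_core_ratio(stack.data[t, 0, 0], gp["center_px"], r_px,
                                       background=acq.background_level)
                      for t in range(b + 4, min(b + 11, stack.n_frames))]
            report["frap"] = {
                "mode": gp["mode"],
                "final_diameter_ratio": float(fs.data["diameter_ratio"].iloc[-1]),
                "shell_core_ratio": float(np.mean(ratios)),
            }
        elif stage == "pulsechase":
            from .flux import correct_bleaching, normalize_pulse_chase, turnover_summary
            from .types import BleachDecayModel

            p = config.pulsechase
            ret = {"green": p.get("retention_green", 0.97),
                   "red": p.get("retention_red", 0.96)}
            acq = sim.AcquisitionConfig(shot_noise=False, read_noise_sd=0.0,
                                        channels=("green", "red"),
                                        bleach_retention_per_exposure=ret)
            model = sim.PulseChaseModel(
                k_in_per_min=p.get("k_in_per_min", 0.02),
                k_out_per_min=p.get("k_out_per_min", 0.012),
                k_deg_per_min=p.get("k_deg_per_min", 0.008),
                division_times_min=tuple(p.get("division_times_min", ())),
            )
            series = sim.simulate_pulse_chase(
                model, acq, p.get("duration_min", 270.0),
                p.get("sampling_interval_min", 10.0), seed=config.seed,
                noise_sd_frac=p.get("noise_sd_frac", 0.0))
            corr = correct_bleaching(
                series, BleachDecayModel(ret["red"], 1.0, "red"))
            norm = normalize_pulse_chase(corr)
            norm.data.to_csv(out / "pulsechase_series.csv", index=False)
            t_max, drop = turnover_summary(corr, "red")
            report["pulsechase"] = {"time_of_max_min": t_max,
                                    "percent_drop": drop}
        else:
            raise ValueError(f"unknown stage: {stage!r}")
        report["stages"].append(stage)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
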