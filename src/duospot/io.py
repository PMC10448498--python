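"""File I/O and run configuration.

Frames travel as multi-page 16-bit grayscale TIFF, ground truth and counts
as CSV with units embedded in column names, configuration as YAML, reports
as JSON.  A run report lists every output file with a checksum so a run is
reproducible from its config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .optics import CameraGeometry
from .simulate import (DetectionSlab, FilterConfig, FrameStack, NoiseSpec,
                       TRUTH_COLUMNS)
from .detect import DetectionParams, DetectionResult

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_stack",
    "read_stack",
    "write_truth",
    "read_truth",
    "write_counts",
    "read_counts",
    "write_pairs",
    "write_overlay",
    "write_report",
    "file_checksum",
    "RunReport",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


_CONFIG_SECTIONS = {
    "seed", "output_dir", "optics", "camera", "slab", "species", "noise",
    "detection", "training", "assay",
}

_SECTION_KEYS = {
    "optics": {"cauchy_A", "cauchy_B", "gain_px", "axis_angle_deg", "anchor"},
    "camera": {"pixel_pitch_um", "magnification", "frame_size_px",
               "exposure_ms", "frame_interval_ms"},
    "slab": {"disc_diameter_um", "thickness_um"},
    "noise": {"background", "read_noise_sd"},
    "detection": {"dog_sigma_small", "dog_sigma_large", "threshold_k",
                  "expected_separation_px", "separation_tol_px",
                  "axis_angle_deg", "angle_tol_deg",
                  "min_pair_intensity_ratio", "median_window_px",
                  "edge_margin_px"},
    "training": {"depth", "base_channels", "patch_size_px", "epochs",
                 "learning_rate", "batch_size", "pos_weight", "seed"},
    "assay": {"k_sd", "r2_min"},
}

_UNIT_FACTORS = {"mol/L": 1.0, "mmol/L": 1e-3, "umol/L": 1e-6, "nmol/L": 1e-9,
                 "pmol/L": 1e-12, "fmol/L": 1e-15}


def parse_concentration(value, unit: str = "mol/L") -> float:
    """Concentration with explicit units to mol/L."""
    if unit not in _UNIT_FACTORS:
        raise ConfigError(f"unknown concentration unit {unit!r}; "
                          f"use one of {sorted(_UNIT_FACTORS)}")
    v = float(value) * _UNIT_FACTORS[unit]
    if v < 0:
        raise ConfigError("concentration must be nonnegative")
    return v


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML document."""

    seed: int = 0
    output_dir: str = "duospot_out"
    camera: CameraGeometry = field(default_factory=CameraGeometry)
    slab: DetectionSlab | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    optics: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(doc) - _CONFIG_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        sub = doc.get(section) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")
    cfg = RunConfig(raw=doc)
    cfg.seed = int(doc.get("seed", 0))
    cfg.output_dir = str(doc.get("output_dir", "duospot_out"))
    if "camera" in doc:
        cfg.camera = CameraGeometry(**doc["camera"])
    if "slab" in doc:
        cfg.slab = DetectionSlab(**doc["slab"])
    if "noise" in doc:
        cfg.noise = NoiseSpec(**doc["noise"])
    if "detection" in doc:
        cfg.detection = DetectionParams(**doc["detection"])
    cfg.optics = doc.get("optics", {})
    cfg.species = doc.get("species", {})
    cfg.training = doc.get("training", {})
    cfg.assay = doc.get("assay", {})
    return cfg


# ------------------------------------------------------------------- files

def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Multi-page 16-bit grayscale TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = dict(stack.metadata)
    meta["frame_size_px"] = stack.geometry.frame_size_px
    meta["pixel_pitch_um"] = stack.geometry.pixel_pitch_um
    meta["magnification"] = stack.geometry.magnification
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    frames = frames.astype(np.uint16, copy=False)
    meta = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    geom = CameraGeometry(
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 6.5)),
        magnification=float(meta.get("magnification", 60.0)),
        frame_size_px=int(frames.shape[-1]),
    )
    filt = FilterConfig(meta.get("filter_mode", "longpass"))
    return FrameStack(frames, geom, filt, meta)


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return df


def write_counts(counts: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"frame": np.arange(len(counts)), "count": counts}
                 ).to_csv(path, index=False)
    return path


def read_counts(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["count"].to_numpy()


def write_pairs(results: list[DetectionResult], path: str | Path) -> Path:
    rows = []
    for k, res in enumerate(results):
        for p in res.pairs:
            rows.append((k, p.row1, p.col1, p.row2, p.col2,
                         p.separation_px, p.score))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["frame", "row1", "col1", "row2", "col2",
                                "sep_px", "score"]).to_csv(path, index=False)
    return path


def write_overlay(frame: np.ndarray, result: DetectionResult,
                  path: str | Path, pad_px: float = 5.0) -> Path:
    """PNG of a frame with rectangles drawn around each detected double
    spot (review image for visual inspection of the counting)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(6, 6), dpi=150)
    lo, hi = np.percentile(frame, [1, 99.9])
    ax.imshow(frame, cmap="gray", vmin=lo, vmax=max(hi, lo + 1))
    for p in result.pairs:
        r0 = min(p.row1, p.row2) - pad_px
        c0 = min(p.col1, p.col2) - pad_px
        h = abs(p.row2 - p.row1) + 2 * pad_px
        w = abs(p.col2 - p.col1) + 2 * pad_px
        ax.add_patch(Rectangle((c0, r0), w, h, fill=False, edgecolor="lime",
                               linewidth=0.8))
    ax.set_axis_off()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
    return path


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunReport:
    """Manifest of a run: config hash, seed, stage summaries, output files."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_checksum(path)

    def to_json(self) -> dict:
        return asdict(self)

    @staticmethod
    def config_hash_of(config_text: str) -> str:
        return hashlib.sha256(config_text.encode()).hexdigest()
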