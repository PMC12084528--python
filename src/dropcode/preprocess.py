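"""Raw frames to per-channel 1-D traces.

Order of operations mirrors the acquisition pipeline: geometric
correction (undistortion map and/or rotation so channels run
horizontally), division by a role-matched background frame so the
background sits at 1 everywhere and streak amplitudes become
illumination-independent, segmentation into the parallel channel strips,
and a line average across each strip's width giving the trace
``S_m,n(x)`` that all decoding operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class Calibration:
    """Geometric correction: optional undistortion map then rotation.

    ``map_rows``/``map_cols`` give, for every output pixel, the input
    coordinate to sample (as for ``scipy.ndimage.map_coordinates``); the
    map is supplied, never fitted here.  ``rotation_deg`` rotates about
    the frame centre (positive = counter-clockwise) to bring the
    channels horizontal.
    """

    rotation_deg: float = 0.0
    map_rows: np.ndarray | None = None
    map_cols: np.ndarray | None = None

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.map_rows is None


@dataclass
class FrameStack:
    """Ordered 16-bit frames with per-frame role labels and timing."""

    frames: np.ndarray                    # (n, h, w) uint16
    roles: list[str]                      # "bead" | "substrate"
    exposures: np.ndarray                 # ms
    start_times: np.ndarray               # ms
    calibration: Calibration | None = None
    truth: pd.DataFrame | None = None     # ground truth when simulated

    def __post_init__(self) -> None:
        if len(self.roles) != len(self.frames):
            raise ValueError("one role per frame required")
        bad = set(self.roles) - {"bead", "substrate"}
        if bad:
            raise ValueError(f"unknown frame roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_indices(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    # -- persistence: multi-page TIFF + sidecar CSV (roles/timing) ----------

    def save(self, directory: str | Path, stem: str = "stack") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(directory / f"{stem}.tif", self.frames,
                         photometric="minisblack")
        pd.DataFrame({
            "frame": np.arange(len(self)),
            "role": self.roles,
            "exposure_ms": self.exposures,
            "start_ms": self.start_times,
        }).to_csv(directory / f"{stem}_frames.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(directory / f"{stem}_truth.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path, stem: str = "stack") -> "FrameStack":
        directory = Path(directory)
        frames = tifffile.imread(directory / f"{stem}.tif")
        if frames.ndim == 2:
            frames = frames[None]
        meta = pd.read_csv(directory / f"{stem}_frames.csv")
        truth_path = directory / f"{stem}_truth.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else None
        return cls(frames=frames, roles=list(meta["role"]),
                   exposures=meta["exposure_ms"].to_numpy(),
                   start_times=meta["start_ms"].to_numpy(), truth=truth)


def correct_frame(frame: np.ndarray,
                  calibration: Calibration | None) -> np.ndarray:
    """Apply the supplied undistortion map and rotation to one frame."""
    out = np.asarray(frame, dtype=float)
    if calibration is None or calibration.is_identity:
        if calibration is not None and calibration.rotation_deg == 0.0:
            return out.copy()
        return out.copy()
    if calibration.map_rows is not None:
        if calibration.map_rows.shape != out.shape:
            raise ValueError("calibration map shape does not match frame")
        out = ndimage.map_coordinates(
            out, [calibration.map_rows, calibration.map_cols], order=1,
            mode="nearest")
    if calibration.rotation_deg != 0.0:
        out = ndimage.rotate(out, calibration.rotation_deg, reshape=False,
                             order=1, mode="nearest")
    return out


def smooth_background(background: np.ndarray, sigma: float = 5.0) -> np.ndarray:
    """Gaussian-smooth a measured background frame before division, so
    its own read noise is not imprinted onto every normalized frame."""
    return ndimage.gaussian_filter(np.asarray(background, dtype=float), sigma)


def normalize_background(frame: np.ndarray, background: np.ndarray,
                         eps: float = 1.0) -> np.ndarray:
    """Divide a frame by its background so background-only pixels sit at 1.

    Background pixels at or below ``eps`` counts are floored at ``eps``
    (with a logged count) to keep the ratio finite.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    n_bad = int(np.count_nonzero(background < eps))
    if n_bad:
        logger.warning("flooring %d background pixels below %g", n_bad, eps)
        background = np.maximum(background, eps)
    return frame / background


def segment_channels(frame: np.ndarray, geometry) -> list[np.ndarray]:
    """Cut a corrected frame into the ``n_channels`` horizontal strips."""
    if frame.shape != geometry.frame_shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match geometry "
            f"{geometry.frame_shape}"
        )
    return [frame[geometry.channel_rows(n)]
            for n in range(geometry.n_channels)]


def line_average(strip: np.ndarray):
    """Average a channel strip over its width: ``values[x] = mean_y strip``."""
    strip = np.asarray(strip, dtype=float)
    if strip.size == 0:
        raise ValueError("empty channel strip")
    return strip.mean(axis=0)


def frame_to_traces(frame: np.ndarray, background: np.ndarray, geometry,
                    calibration: Calibration | None = None) -> np.ndarray:
    """Full per-frame pipeline: correct, normalize, segment, line-average.

    Returns an ``(n_channels, trace_length)`` array of normalized traces.
    """
    corrected = correct_frame(frame, calibration)
    normalized = normalize_background(corrected, background)
    strips = segment_channels(normalized, geometry)
    return np.stack([line_average(s) for s in strips])
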