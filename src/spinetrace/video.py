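"""Two-channel fluorescence video container and TIFF I/O.

A recording consists of a *structure* channel (a cell-fill label such as
tdTomato, used for segmentation) and a *protein* channel (a tagged protein
such as GFP-cofilin, used for density/flux measurements), sampled at a fixed
frame interval. Intensities are stored as floating-point fractions of full
scale so that 12-bit camera data and synthetic data share one convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FluoVideo", "read_video", "write_video"]

#: Full-scale value used when writing 16-bit TIFF output.
U16_SCALE = 65535


@dataclass
class FluoVideo:
    """A two-channel time-lapse video.

    Parameters
    ----------
    structure, protein : ndarray, shape (T, H, W)
        Per-frame intensities in [0, 1] for the cell-fill channel and the
        tagged-protein channel.
    frame_interval : float
        Time between consecutive frames, in seconds.
    """

    structure: np.ndarray
    protein: np.ndarray
    frame_interval: float = 180.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.structure = np.asarray(self.structure, dtype=np.float64)
        self.protein = np.asarray(self.protein, dtype=np.float64)
        if self.structure.ndim != 3 or self.protein.shape != self.structure.shape:
            raise ValueError(
                "structure and protein must be (T, H, W) arrays of equal shape"
            )
        if self.n_frames < 2:
            raise ValueError("a video needs at least two frames")
        if not (np.isfinite(self.structure).all() and np.isfinite(self.protein).all()):
            raise ValueError("intensities must be finite")
        if self.structure.min() < 0 or self.protein.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.structure.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.structure.shape[1:]


def write_video(video: FluoVideo, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the two channels as multi-page 16-bit TIFFs.

    Returns a mapping from channel name to the written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, stack in (("structure", video.structure), ("protein", video.protein)):
        data = np.clip(stack, 0.0, 1.0)
        path = out / f"{name}.tif"
        tifffile.imwrite(
            path, (data * U16_SCALE).round().astype(np.uint16), photometric="minisblack"
        )
        paths[name] = path
    return paths


def _read_stack(path: str | os.PathLike) -> np.ndarray:
    arr = tifffile.imread(path).astype(np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    info = np.iinfo(np.uint16) if arr.max() > 1.0 else None
    if info is not None:
        arr = arr / U16_SCALE
    return arr


def read_video(
    structure_path: str | os.PathLike,
    protein_path: str | os.PathLike,
    frame_interval: float = 180.0,
) -> FluoVideo:
    """Read a two-channel video from per-channel multi-page TIFFs."""
    return FluoVideo(
        structure=_read_stack(structure_path),
        protein=_read_stack(protein_path),
        frame_interval=frame_interval,
    )
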