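"""Time-lapse photon-count image stacks and their TIFF round-trip.

The container holds a (time, row, col) array of non-negative integer photon
counts per pixel dwell, together with the acquisition metadata that gives the
counts their physical meaning (dwell time, pixel size).  Stacks are stored as
multi-page TIFF with page order = time and metadata embedded as a plain-text
JSON description tag, so a written stack reloads bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

__all__ = ["ImageStack", "write_stack", "read_stack"]

#: default pixel dwell time, microseconds
DEFAULT_DWELL_TIME_US = 40.0
#: default pixel size, nanometres
DEFAULT_PIXEL_SIZE_NM = 156.0


@dataclass
class ImageStack:
    """A time-ordered stack of 2-D photon-count frames.

    Parameters
    ----------
    frames
        Integer array of shape ``(T, H, W)``; photon counts per pixel dwell.
    dwell_time_us
        Scanner dwell time per pixel per frame, in microseconds.  Brightness
        values derived from the stack are in counts per this dwell.
    pixel_size_nm
        Lateral pixel size in nanometres.
    metadata
        Free-form provenance (simulation config digest, seed, source path).
    """

    frames: np.ndarray
    dwell_time_us: float = DEFAULT_DWELL_TIME_US
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (time, row, col); got shape {self.frames.shape}")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise TypeError(f"photon counts must be integer, got dtype {self.frames.dtype}")
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames for fluctuation analysis")
        if self.frames.min() < 0:
            raise ValueError("photon counts must be non-negative")
        if self.dwell_time_us <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("dwell_time_us and pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            np.array_equal(self.frames, other.frames)
            and self.dwell_time_us == other.dwell_time_us
            and self.pixel_size_nm == other.pixel_size_nm
        )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack to a multi-page TIFF (16-bit unsigned), page order = time.

    Acquisition metadata and provenance are embedded as a JSON description
    tag and survive a round-trip through :func:`read_stack`.
    """
    path = Path(path)
    frames = stack.frames
    if frames.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("photon counts exceed the 16-bit range of the TIFF container")
    desc = json.dumps(
        {
            "dwell_time_us": stack.dwell_time_us,
            "pixel_size_nm": stack.pixel_size_nm,
            "metadata": stack.metadata,
        }
    )
    tifffile.imwrite(
        path, frames.astype(np.uint16), description=desc, photometric="minisblack"
    )
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Load a multi-page TIFF written by :func:`write_stack`.

    Foreign TIFFs without the JSON description tag load with default
    acquisition metadata.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description or ""
    dwell = DEFAULT_DWELL_TIME_US
    pixel = DEFAULT_PIXEL_SIZE_NM
    meta: dict[str, Any] = {"source": str(path)}
    if desc:
        try:
            info = json.loads(desc)
            dwell = float(info.get("dwell_time_us", dwell))
            pixel = float(info.get("pixel_size_nm", pixel))
            meta.update(info.get("metadata", {}))
        except (json.JSONDecodeError, AttributeError, TypeError):
            pass
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames, dwell_time_us=dwell, pixel_size_nm=pixel, metadata=meta)
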