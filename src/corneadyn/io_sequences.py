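"""I/O and container types for air-puff tonometry image sequences.

Two containers are used throughout the package:

``ImageSequence``
    An (M, N, I) grayscale voxel block -- rows × columns × frames -- with
    intensities normalised to [0, 1], as recorded by the high-speed
    Scheimpflug camera of a non-contact (air-puff) tonometer during an
    intraocular-pressure measurement.

``Map2D``
    An (N, I) per-column, per-frame map in pixel units: contour row
    position, relative deformation, eyeball displacement, corneal
    deflection, fast residual, response pattern or pattern error.

Conventions fixed here and relied upon everywhere else:

* indexing is 0-based; axis order is (row m, column n, frame i);
* m grows downward (toward the eye interior), n left to right, i in time,
  so a *larger* contour value means the corneal surface sits deeper;
* intensities live in [0, 1] so that threshold parameters are scale-free;
* missing contour values are NaN, never 0 (row 0 is a valid position);
* any 1-based formula from the literature is translated to 0-based at
  this boundary and nowhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DEFAULT_FRAME_INTERVAL_S",
    "VENDOR_PRINTED_FRAME_INTERVAL_S",
    "MAP_ROLES",
    "ImageSequence",
    "Map2D",
    "read_sequence",
    "write_sequence",
    "write_map",
    "read_map",
    "DimensionError",
    "EmptyInputError",
    "DegenerateInputError",
    "TooShortError",
    "ContourError",
    "ConfigError",
]

#: Seconds per frame used by default.  140 frames at this interval span
#: ~32.3 ms, which makes the FFT bin arithmetic of the 150-500 Hz band
#: (harmonics 7-15 of a 140-sample record) physically consistent.
DEFAULT_FRAME_INTERVAL_S = 231e-6

#: Frame interval printed in the vendor documentation.  Recorded verbatim
#: in sequence metadata but not used as a default: it is inconsistent with
#: the 150-500 Hz band arithmetic over a 140-frame record.
VENDOR_PRINTED_FRAME_INTERVAL_S = 23e-6

MAP_ROLES = ("contour", "deformation", "eyeball", "cornea", "fast", "pattern", "error")

_IMAGE_EXTENSIONS = (".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg")


class DimensionError(ValueError):
    """Shapes or mask sizes are inconsistent."""


class EmptyInputError(ValueError):
    """A sequence or directory contains no frames."""


class DegenerateInputError(ValueError):
    """Input has no structure to act on (e.g. constant intensities)."""


class TooShortError(ValueError):
    """Time signal too short for spectral analysis."""


class ContourError(RuntimeError):
    """Contour extraction or validation failed in a way that cannot be repaired."""


class ConfigError(ValueError):
    """Invalid pipeline or module configuration."""


@dataclass
class ImageSequence:
    """Grayscale image sequence, shape (M, N, I), intensities in [0, 1].

    Parameters
    ----------
    data:
        Float array indexed (row m, column n, frame i).
    frame_interval_s:
        Seconds between consecutive frames; > 0.
    meta:
        Free-form provenance metadata (source path, original dtype, ...).
    """

    data: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise DimensionError(f"sequence must be 3-D (M,N,I), got shape {self.data.shape}")
        if min(self.data.shape) < 3:
            raise DimensionError(
                f"every dimension must be >= 3 for 3-D filtering, got {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("sequence intensities must be finite")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities must lie in [0,1], got range [{lo}, {hi}]")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def frame(self, i: int) -> np.ndarray:
        """Return frame i as an (M, N) view."""
        return self.data[:, :, i]

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class Map2D:
    """Per-column, per-frame map, shape (N, I), pixel units.

    ``role`` tags what the map holds (see :data:`MAP_ROLES`).  Maps with
    role ``"contour"`` store row positions in [0, M-1]; NaN marks a column
    where detection failed.
    """

    values: np.ndarray
    role: str = "contour"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError(f"Map2D must be 2-D (N,I), got shape {self.values.shape}")
        if self.role not in MAP_ROLES:
            raise ValueError(f"unknown map role {self.role!r}; expected one of {MAP_ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "Map2D":
        return Map2D(self.values.copy(), self.role)


def _normalise_frames(frames: np.ndarray, source: str) -> np.ndarray:
    """Rescale integer images to [0,1] by the dtype maximum; pass floats through."""
    if frames.dtype.kind in "ui":
        return frames.astype(np.float32) / np.iinfo(frames.dtype).max
    frames = frames.astype(np.float32)
    return frames


def _to_gray(frame: np.ndarray, source: str) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(np.float64)
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 1] == rgb[..., 2]).all():
            raise ValueError(f"{source}: colour frames are not supported")
        return frame[..., 0]
    raise DimensionError(f"{source}: expected a single-channel frame, got shape {frame.shape}")


def read_sequence(path: str | Path, fmt: str | None = None) -> ImageSequence:
    """Read an image sequence from a multi-page TIFF or a directory of frames.

    Parameters
    ----------
    path:
        A multi-page TIFF file or a directory of per-frame BMP/PNG/TIFF
        images (frames ordered by lexicographic filename).
    fmt:
        ``"tiff_stack"`` or ``"image_dir"``; inferred from ``path`` when None.

    Returns
    -------
    ImageSequence
        8/16-bit inputs are rescaled to [0,1] by the dtype maximum.  If a
        JSON sidecar (``<stem>.json`` next to a stack, ``metadata.json``
        inside a directory) exists, its ``frame_interval_s`` is honoured.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "image_dir" if path.is_dir() else "tiff_stack"
    if fmt == "tiff_stack":
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        frames = [_to_gray(p, str(path)) for p in pages]
        sidecar = path.with_suffix(".json")
    elif fmt == "image_dir":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS)
        if not files:
            raise EmptyInputError(f"no image frames found in {path}")
        frames = [_to_gray(np.asarray(iio.imread(f)), str(f)) for f in files]
        sidecar = path / "metadata.json"
    else:
        raise ConfigError(f"unknown sequence format {fmt!r}")
    if not frames:
        raise EmptyInputError(f"no frames in {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise DimensionError(f"frames in {path} have mixed resolutions: {sorted(shapes)}")
    dtypes = {f.dtype for f in frames}
    if len(dtypes) != 1:
        raise DimensionError(f"frames in {path} have mixed dtypes: {sorted(map(str, dtypes))}")
    stack = np.stack(frames, axis=-1)  # (M, N, I)
    data = np.clip(_normalise_frames(stack, str(path)), 0.0, 1.0)

    frame_interval_s = DEFAULT_FRAME_INTERVAL_S
    meta: dict = {
        "source": str(path),
        "source_dtype": str(stack.dtype),
        "vendor_printed_frame_interval_s": VENDOR_PRINTED_FRAME_INTERVAL_S,
    }
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        frame_interval_s = float(side.get("frame_interval_s", frame_interval_s))
        meta.update(side.get("meta", {}))
    return ImageSequence(data, frame_interval_s=frame_interval_s, meta=meta)


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as an 8-bit multi-page TIFF plus a JSON sidecar.

    Intensities are quantised to 8 bits, so a write/read round trip agrees
    voxelwise within 1/255.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data8 = np.rint(np.clip(seq.data, 0.0, 1.0) * 255).astype(np.uint8)
    tifffile.imwrite(path, np.moveaxis(data8, 2, 0))  # pages = frames
    sidecar = {
        "dims": list(seq.dims),
        "frame_interval_s": seq.frame_interval_s,
        "meta": {k: v for k, v in seq.meta.items() if isinstance(v, (str, int, float, bool))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _map_frame(m: Map2D) -> pd.DataFrame:
    n_cols, n_frames = m.shape
    return pd.DataFrame(m.values, index=pd.Index(range(n_cols), name="n"), columns=range(n_frames))


def write_map(m: Map2D, path: str | Path, fmt: str = "csv") -> None:
    """Serialise a map; CSV keeps a frame-index header row and a column-index
    first column, with NaN (missing) written as empty cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        _map_frame(m).to_csv(path, na_rep="")
    elif fmt == "tiff":
        tifffile.imwrite(path, m.values.astype(np.float32))
    else:
        raise ConfigError(f"unknown map format {fmt!r}")


def read_map(path: str | Path, role: str = "contour", fmt: str = "csv") -> Map2D:
    """Inverse of :func:`write_map`; empty CSV cells come back as NaN."""
    path = Path(path)
    if fmt == "csv":
        frame = pd.read_csv(path, index_col=0)
        return Map2D(frame.to_numpy(dtype=float), role)
    if fmt == "tiff":
        return Map2D(tifffile.imread(path).astype(float), role)
    raise ConfigError(f"unknown map format {fmt!r}")
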