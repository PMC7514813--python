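"""Binary pedestrian silhouette frames and sequences.

Coordinate convention (used by every module in this package): masks are
2D numpy arrays indexed ``[row, col]`` with row 0 at the *top* of the
image and 0-based indices throughout.  A mask holds only 0 (background)
and 1 (pedestrian foreground); any nonzero source pixel is foreground.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

__all__ = [
    "BinarySilhouette",
    "SilhouetteSequence",
    "read_silhouette",
    "write_silhouette",
    "load_sequence",
    "natural_sort_key",
]


@dataclass
class BinarySilhouette:
    """One frame's binary foreground mask.

    Parameters
    ----------
    mask : ndarray of shape (height, width)
        Binary {0, 1} mask, dtype uint8.
    frame_index : int
        Position of this frame in its sequence (0-based, >= 0).
    """

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {mask.shape}")
        if mask.size == 0:
            raise ValueError("mask must be non-empty")
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        # binarize: any nonzero source value counts as foreground
        self.mask = (mask != 0).astype(np.uint8)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SilhouetteSequence:
    """Temporally ordered silhouettes with a known frame rate.

    Invariants enforced at construction: frame indices increase strictly
    by 1 with no gaps, all frames share one image size, and the frame
    rate (``theta``, frames per second) is positive.  The inter-frame
    interval is ``1 / frame_rate_hz`` seconds.
    """

    frames: list[BinarySilhouette]
    frame_rate_hz: float
    view_tag: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")
        first = self.frames[0]
        for prev, curr in zip(self.frames, self.frames[1:]):
            if curr.frame_index != prev.frame_index + 1:
                raise ValueError(
                    "frame indices must increase by exactly 1: got "
                    f"{prev.frame_index} followed by {curr.frame_index}"
                )
        bad = [f.frame_index for f in self.frames if f.shape != first.shape]
        if bad:
            raise ValueError(
                f"all frames must share dimensions {first.shape}; "
                f"offending frame indices: {bad}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[BinarySilhouette]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> BinarySilhouette:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def masks(self) -> np.ndarray:
        """Stack all masks into one (n_frames, height, width) uint8 array."""
        return np.stack([f.mask for f in self.frames])


def read_silhouette(
    path: str | Path, threshold: int = 128, frame_index: int = 0
) -> BinarySilhouette:
    """Read one silhouette mask from an image file (PNG, BMP, ...).

    Source pixels with gray value >= ``threshold`` become foreground (1),
    the rest background (0); this tolerates anti-aliased mask edges.  RGB
    images are reduced to gray by the plain per-pixel channel mean before
    thresholding; an alpha channel, if present, is ignored.
    """
    path = Path(path)
    try:
        img = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"could not read silhouette image {path!s}: {exc}") from exc
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError(f"zero-sized image: {path!s}")
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    elif img.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {img.ndim} in {path!s}")
    mask = (img >= threshold).astype(np.uint8)
    return BinarySilhouette(mask=mask, frame_index=frame_index)


def write_silhouette(s: BinarySilhouette, path: str | Path) -> None:
    """Write a silhouette as an 8-bit image with values {0, 255}.

    Round-trips exactly through :func:`read_silhouette` at the default
    threshold.
    """
    path = Path(path)
    try:
        iio.imwrite(path, (s.mask * 255).astype(np.uint8))
    except OSError as exc:
        raise IOError(f"could not write silhouette image {path!s}: {exc}") from exc


_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(name: str) -> tuple:
    """Numeric-aware sort key: 'f2.png' sorts before 'f10.png'."""
    return tuple(
        int(part) if part.isdigit() else part for part in _NUM_RE.split(name)
    )


def load_sequence(
    directory: str | Path,
    pattern: str = "*.png",
    frame_rate_hz: float = 25.0,
    threshold: int = 128,
    view_tag: str | None = None,
    subject_id: str | None = None,
) -> SilhouetteSequence:
    """Load a directory of frame images as a silhouette sequence.

    Filenames matching ``pattern`` are sorted with natural (numeric-aware)
    ordering, so unpadded frame numbers sort temporally.  Frames receive
    indices 0..N-1 in that order.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory!s}")
    paths = sorted(directory.glob(pattern), key=lambda p: natural_sort_key(p.name))
    if len(paths) < 2:
        raise ValueError(
            f"sequence too short: found {len(paths)} frame(s) matching "
            f"{pattern!r} in {directory!s}, need at least 2"
        )
    frames = [
        read_silhouette(p, threshold=threshold, frame_index=i)
        for i, p in enumerate(paths)
    ]
    shape0 = frames[0].shape
    bad = [p.name for p, f in zip(paths, frames) if f.shape != shape0]
    if bad:
        raise ValueError(
            f"inconsistent image dimensions (expected {shape0}): {', '.join(bad)}"
        )
    return SilhouetteSequence(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        view_tag=view_tag,
        subject_id=subject_id,
    )
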