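"""Consecutive-silhouettes-difference maps (CSD-maps).

A CSD-map fuses the spatiotemporal information of ``n`` consecutive
binary silhouettes into one integer image: each pixel's value is the
sum of powers of two over the frames in which that pixel is foreground,
so the value (0 .. 2**n - 1) is a complete code of the pixel's
foreground-membership pattern across the window.

Bit-order convention
--------------------
The *newest* frame in the window owns bit 0, the next-newest bit 1, and
so on.  With n = 2 this reproduces the classical two-frame difference
labels literally: a pixel foreground only in the current frame gets 1,
only in the previous frame gets 2, in both gets 3, in neither 0.

For the classifier, a CSD-map is cropped to the tight bounding box of
its nonzero support, scaled to [0, 1] by dividing by 2**n - 1, and
resized to a fixed (height, width) with bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

from .silhouettes import BinarySilhouette, SilhouetteSequence

__all__ = [
    "CSDMap",
    "NormalizedCSDMap",
    "CSDEncoder",
    "encode_2csd",
    "encode_ncsd",
    "normalize_csd",
    "stream_csd",
    "export_map_png",
]

MAX_WINDOW = 8  # values must fit one byte; in practice n <= 6 is used


@dataclass
class CSDMap:
    """Integer CSD-map of ``n`` consecutive silhouettes.

    ``values[r, c]`` is in [0, 2**n - 1]; 0 exactly where all ``n``
    frames are background.  ``anchor_frame_index`` is the index of the
    newest frame in the window.
    """

    values: np.ndarray
    n: int
    anchor_frame_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("CSD-map values must be 2D")
        if not 2 <= self.n <= MAX_WINDOW:
            raise ValueError(f"window size n must be in [2, {MAX_WINDOW}], got {self.n}")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedCSDMap:
    """Fixed-size real-valued CSD-map ready for the classifier.

    ``values`` has shape exactly (height, width) with entries in [0, 1].
    """

    values: np.ndarray
    n: int
    anchor_frame_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("normalized CSD-map values must be 2D")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def _check_window(frames: Sequence[BinarySilhouette], check_consecutive: bool) -> None:
    shape0 = frames[0].shape
    for f in frames[1:]:
        if f.shape != shape0:
            raise ValueError(
                f"all frames in a window must share dimensions; got {shape0} and {f.shape}"
            )
    if check_consecutive:
        for prev, curr in zip(frames, frames[1:]):
            if curr.frame_index != prev.frame_index + 1:
                raise ValueError(
                    "window frames must have consecutive indices "
                    f"(got {prev.frame_index} then {curr.frame_index}); "
                    "pass check_consecutive=False for ad-hoc pairs"
                )


def encode_ncsd(
    window: Sequence[BinarySilhouette], check_consecutive: bool = True
) -> CSDMap:
    """Encode ``n`` consecutive silhouettes (oldest first) into a CSD-map.

    Per pixel, the value is the sum of ``2**b(k)`` over the frames ``k``
    whose mask is foreground there, where the newest frame owns bit 0
    and older frames successively higher bits.  A pixel foreground in
    every frame therefore receives ``2**n - 1``.
    """
    n = len(window)
    if not 2 <= n <= MAX_WINDOW:
        raise ValueError(f"window size n must be in [2, {MAX_WINDOW}], got {n}")
    _check_window(window, check_consecutive)
    values = np.zeros(window[0].shape, dtype=np.uint8)
    # newest frame -> bit 0: reverse the oldest-first window before the bit sum
    for bit, frame in enumerate(reversed(window)):
        values |= frame.mask << bit
    return CSDMap(values=values, n=n, anchor_frame_index=window[-1].frame_index)


def encode_2csd(
    prev: BinarySilhouette, curr: BinarySilhouette, check_consecutive: bool = True
) -> CSDMap:
    """Two-frame CSD-map: current-only -> 1, previous-only -> 2, both -> 3.

    Equivalent to :func:`encode_ncsd` on ``[prev, curr]``; kept separate
    because the two-frame case is the canonical frame-difference code.
    """
    return encode_ncsd([prev, curr], check_consecutive=check_consecutive)


def normalize_csd(m: CSDMap, target_w: int = 32, target_h: int = 48) -> NormalizedCSDMap:
    """Crop a CSD-map to its nonzero bounding box, scale to [0,1], resize.

    The tight bounding box of nonzero values is cut out, values are
    divided by ``2**n - 1``, and the crop is resized to exactly
    ``(target_h, target_w)`` with bilinear interpolation.  The result is
    translation invariant: shifting the silhouette inside the source
    frame does not change the output.

    Raises
    ------
    ValueError
        If the map is all zero ("empty CSD-map"); callers streaming over
        a sequence should skip such windows.
    """
    if target_w < 2 or target_h < 2:
        raise ValueError("target_w and target_h must each be >= 2")
    rows, cols = np.nonzero(m.values)
    if rows.size == 0:
        raise ValueError("empty CSD-map: no nonzero pixels to normalize")
    crop = m.values[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    scaled = crop.astype(np.float32) / np.float32(2**m.n - 1)
    out = _sk_resize(
        scaled,
        (target_h, target_w),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)
    # bilinear interpolation of values in [0,1] stays in [0,1]; clip guards
    # against float round-off at the boundaries only
    np.clip(out, 0.0, 1.0, out=out)
    return NormalizedCSDMap(values=out, n=m.n, anchor_frame_index=m.anchor_frame_index)


def stream_csd(
    seq: SilhouetteSequence,
    n: int = 2,
    target_w: int = 32,
    target_h: int = 48,
) -> list[NormalizedCSDMap]:
    """Slide a length-``n`` window over a sequence, one map per anchor.

    Produces one normalized CSD-map per anchor frame index from ``n-1``
    to ``len(seq)-1`` (stride 1).  Windows whose CSD-map is all zero
    (pedestrian fully out of frame) are skipped rather than raising.
    """
    if len(seq) < n:
        raise ValueError(f"sequence too short: {len(seq)} frames < window n={n}")
    out: list[NormalizedCSDMap] = []
    for end in range(n - 1, len(seq)):
        m = encode_ncsd(seq.frames[end - n + 1 : end + 1])
        if not m.values.any():
            continue
        out.append(normalize_csd(m, target_w=target_w, target_h=target_h))
    return out


def export_map_png(m: NormalizedCSDMap, path) -> None:
    """Write a normalized CSD-map as an 8-bit grayscale PNG (value*255).

    For visual inspection only — quantized to 256 levels; use the array
    in ``m.values`` (or an .npy dump) for lossless storage.
    """
    import imageio.v3 as iio

    iio.imwrite(path, np.round(m.values * 255).astype(np.uint8))


class CSDEncoder(TransformerMixin, BaseEstimator):
    """Sliding-window CSD-map encoder as a scikit-learn transformer.

    Stateless (``fit`` only validates parameters).  ``transform`` maps a
    :class:`~csdgait.silhouettes.SilhouetteSequence` — or a stacked
    (n_frames, height, width) binary array — to a float32 array of shape
    (n_maps, target_h, target_w) plus, via :meth:`transform_maps`, the
    anchored :class:`NormalizedCSDMap` objects.

    Parameters
    ----------
    n : int, default 2
        Window size (number of consecutive silhouettes), 2..8.
    target_w, target_h : int
        Output width and height of each normalized map.
    """

    def __init__(self, n: int = 2, target_w: int = 32, target_h: int = 48):
        self.n = n
        self.target_w = target_w
        self.target_h = target_h

    def fit(self, X=None, y=None) -> "CSDEncoder":
        if not 2 <= self.n <= MAX_WINDOW:
            raise ValueError(f"n must be in [2, {MAX_WINDOW}], got {self.n}")
        if self.target_w < 2 or self.target_h < 2:
            raise ValueError("target_w and target_h must each be >= 2")
        self.n_features_out_ = self.target_h * self.target_w
        return self

    def transform_maps(self, X) -> list[NormalizedCSDMap]:
        """Like :meth:`transform` but returns anchored map objects."""
        seq = self._as_sequence(X)
        return stream_csd(
            seq, n=self.n, target_w=self.target_w, target_h=self.target_h
        )

    def transform(self, X) -> np.ndarray:
        maps = self.transform_maps(X)
        if not maps:
            return np.empty((0, self.target_h, self.target_w), dtype=np.float32)
        return np.stack([m.values for m in maps])

    @staticmethod
    def _as_sequence(X) -> SilhouetteSequence:
        if isinstance(X, SilhouetteSequence):
            return X
        arr = np.asarray(X)
        if arr.ndim != 3:
            raise ValueError(
                "expected a SilhouetteSequence or (n_frames, h, w) array, "
                f"got shape {arr.shape}"
            )
        frames = [BinarySilhouette(mask=a, frame_index=i) for i, a in enumerate(arr)]
        return SilhouetteSequence(frames=frames, frame_rate_hz=25.0)
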