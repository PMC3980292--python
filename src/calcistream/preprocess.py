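"""Frame ingestion and per-frame preprocessing.

Three steps precede the streaming factorisation: (1) for dual-excitation
(Fura-type) data, the ratio of consecutive 340 nm / 380 nm frames, a
calcium-dependent and bleaching-robust signal; (2) optional spatial Gaussian
smoothing; (3) pixel-wise z-score normalisation with *running* mean and
standard deviation, updated one frame at a time (Welford one-pass moments, so
the final statistics equal the batch statistics to machine precision).

The running z-score uses the statistics *including* the current frame, so the
earliest frames are normalised against immature estimates — a deliberate
property of the online setting, not a defect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter


class MovieFormatError(RuntimeError):
    """Raised when frames in a movie disagree in shape or cannot be read."""


@dataclass(frozen=True)
class RawFrame:
    """One movie frame: flattened pixel vector plus its stream position."""

    pixels: np.ndarray          # length-n, row-major: pixel (r, c) -> r*width + c
    index: int
    image_shape: tuple[int, int]
    channel: str = "single"     # {"single", "ex340", "ex380"}

    @property
    def image(self) -> np.ndarray:
        return self.pixels.reshape(self.image_shape)


def _read_image(path) -> np.ndarray:
    try:
        import tifffile

        if str(path).lower().endswith((".tif", ".tiff")):
            return np.asarray(tifffile.imread(path), dtype=np.float64)
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise MovieFormatError(f"cannot read frame file {path!r}: {exc}") from exc


def read_movie(path, layout: str | None = None, channel: str = "single"):
    """Yield :class:`RawFrame` objects from a TIFF stack or a frame directory.

    ``layout`` is ``"tiff_stack"``, ``"frame_directory"`` or None (inferred
    from whether ``path`` is a directory).  Directory frames are read in
    lexicographic filename order, which equals numeric order for zero-padded
    names.  All frames must share one shape.
    """
    if layout is None:
        layout = "frame_directory" if os.path.isdir(path) else "tiff_stack"

    if layout == "tiff_stack":
        import tifffile

        try:
            stack = np.asarray(tifffile.imread(path), dtype=np.float64)
        except (OSError, ValueError) as exc:
            raise MovieFormatError(f"cannot read TIFF stack {path!r}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        shape = stack.shape[1:]
        for i, frame in enumerate(stack):
            yield RawFrame(pixels=frame.ravel(), index=i,
                           image_shape=shape, channel=channel)
    elif layout == "frame_directory":
        names = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".tif", ".tiff", ".png"))
        )
        if not names:
            raise MovieFormatError(f"no frame files found in {path!r}")
        shape = None
        for i, name in enumerate(names):
            img = _read_image(os.path.join(path, name))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise MovieFormatError(
                    f"frame {i} ({name}) has shape {img.shape}, expected {shape}"
                )
            yield RawFrame(pixels=img.ravel(), index=i,
                           image_shape=shape, channel=channel)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def frames_from_matrix(movie: np.ndarray, image_shape, channel: str = "single"):
    """Adapt an in-memory (m, n) movie matrix to the frame iterator protocol."""
    for i, row in enumerate(movie):
        yield RawFrame(pixels=np.asarray(row, dtype=np.float64), index=i,
                       image_shape=tuple(image_shape), channel=channel)


def pair_fura_frames(frames, epsilon: float = 1e-6):
    """Collapse an alternating ex340/ex380 stream into ratio frames.

    Consecutive (340, 380) frames become one time point at half the raw frame
    rate; a trailing unpaired frame is dropped.
    """
    it = iter(frames)
    out_index = 0
    while True:
        try:
            f340 = next(it)
        except StopIteration:
            return
        try:
            f380 = next(it)
        except StopIteration:
            return
        rf = ratio_frame(f340, f380, epsilon=epsilon)
        yield replace(rf, index=out_index)
        out_index += 1


def ratio_frame(f340: RawFrame, f380: RawFrame, epsilon: float = 1e-6) -> RawFrame:
    """Elementwise 340/380 excitation ratio of a consecutive frame pair."""
    if f340.image_shape != f380.image_shape:
        raise MovieFormatError(
            f"ratio pair shape mismatch: {f340.image_shape} vs {f380.image_shape}"
        )
    ratio = f340.pixels / (f380.pixels + epsilon)
    return RawFrame(pixels=ratio, index=f340.index,
                    image_shape=f340.image_shape, channel="single")


def spatial_filter(frame: RawFrame | np.ndarray, width: int = 9,
                   image_shape=None) -> RawFrame | np.ndarray:
    """2-D Gaussian smoothing with an odd ``width``-pixel kernel.

    sigma = width / 4, the kernel is truncated to exactly ``width`` pixels and
    normalised (total intensity preserved); reflect boundary.  width=1 is the
    identity.  Accepts a RawFrame or a 2-D array.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("filter width must be odd and >= 1")
    if isinstance(frame, RawFrame):
        if width == 1:
            return frame
        img = gaussian_filter(
            frame.image, sigma=width / 4.0, mode="reflect",
            truncate=((width - 1) // 2) / (width / 4.0),
        )
        return replace(frame, pixels=img.ravel())
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim == 1:
        if image_shape is None:
            raise ValueError("image_shape required for flat pixel vectors")
        img = img.reshape(image_shape)
        flat = True
    else:
        flat = False
    if width == 1:
        out = img.copy()
    else:
        out = gaussian_filter(
            img, sigma=width / 4.0, mode="reflect",
            truncate=((width - 1) // 2) / (width / 4.0),
        )
    return out.ravel() if flat else out


# ---------------------------------------------------------------------------
# incremental z-score normalisation
# ---------------------------------------------------------------------------

@dataclass
class NormalisationState:
    """Welford running moments per pixel: count, mean, sum of squared devs."""

    count: int
    mean: np.ndarray
    m2: np.ndarray

    @classmethod
    def empty(cls, n_pixels: int) -> "NormalisationState":
        return cls(count=0,
                   mean=np.zeros(n_pixels, dtype=np.float64),
                   m2=np.zeros(n_pixels, dtype=np.float64))

    @property
    def sigma(self) -> np.ndarray:
        """Population (1/N) standard deviation of the frames seen so far."""
        if self.count == 0:
            return np.zeros_like(self.mean)
        return np.sqrt(self.m2 / self.count)


def _welford_update(state: NormalisationState, x: np.ndarray) -> None:
    state.count += 1
    delta = x - state.mean
    state.mean += delta / state.count
    state.m2 += delta * (x - state.mean)


def update_normalise(
    state: NormalisationState,
    frame: RawFrame | np.ndarray,
    sigma_floor: float = 1e-6,
) -> tuple[np.ndarray, NormalisationState]:
    """Ingest one frame; return its z-scored pixels and the updated state.

    The frame is normalised with the statistics *after* the update, so the
    first frame maps to all zeros and a constant pixel stays at zero.  The
    sigma floor guards dead (zero-variance) pixels.
    """
    x = frame.pixels if isinstance(frame, RawFrame) else np.asarray(frame)
    x = x.astype(np.float64, copy=False)
    if x.shape != state.mean.shape:
        raise ValueError(
            f"frame has {x.shape[0]} pixels, state expects {state.mean.shape[0]}"
        )
    new = NormalisationState(count=state.count, mean=state.mean.copy(),
                             m2=state.m2.copy())
    _welford_update(new, x)
    z = (x - new.mean) / np.maximum(new.sigma, sigma_floor)
    return z, new


def normalise_movie(movie: np.ndarray, sigma_floor: float = 1e-6) -> np.ndarray:
    """Batch z-score with final (full-movie) statistics, population sigma."""
    mu = movie.mean(axis=0)
    sd = movie.std(axis=0)
    return (movie - mu) / np.maximum(sd, sigma_floor)
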