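"""Functional unit maps from the coefficient images S.

Overlaying the rows of S yields a segmentation of the image plane into
regions with correlated activity: each pixel is assigned to the row with the
largest coefficient, provided that coefficient clears a threshold; everything
else is background.  Streaming snapshots of the map show how the segmentation
completes as evidence accumulates from the movie stream.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streaming import FactorModel, StreamConfig, StreamProcessor
from .synthetic import GroundTruth


@dataclass
class UnitMap:
    """Per-pixel unit assignment (0 = background, 1..c = units)."""

    labels: np.ndarray        # length-n int
    confidence: np.ndarray    # length-n, winning coefficient where labelled
    image_shape: tuple[int, int]
    frame_index: int = -1

    @property
    def label_image(self) -> np.ndarray:
        return self.labels.reshape(self.image_shape)


def build_map(
    S: np.ndarray,
    threshold_mode: str = "relative",
    threshold: float = 0.5,
    image_shape=None,
    frame_index: int = -1,
) -> UnitMap:
    """Arg-max assignment over the rows of S with a per-row threshold.

    Rows of S carry arbitrary scale (the component matrix they are computed
    from weights directions by eigenvalue), so each row is first normalised
    to unit Euclidean norm; the arg-max then compares coefficient *profiles*
    and the whole labelling is invariant to positive rescaling of any row.

    ``threshold_mode``:
      - ``"relative"`` (default): pixel kept if the winning coefficient
        exceeds ``threshold`` times that row's maximum (the 0.5 default is
        the FWHM cut of the winning source's coefficient profile);
      - ``"quantile"``: winning coefficient above that row's ``threshold``
        quantile;
      - ``"absolute"``: fixed cutoff, applied to the unit-norm rows.
    Ties go to the lowest row index.
    """
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    c, n = S.shape
    if image_shape is None:
        image_shape = (1, n)
    norms = np.linalg.norm(S, axis=1)
    S = S / np.maximum(norms, 1e-300)[:, None]
    winner = np.argmax(S, axis=0)          # ties -> lowest index
    winval = S[winner, np.arange(n)]

    if threshold_mode == "relative":
        row_max = S.max(axis=1)
        cut = threshold * np.maximum(row_max, 0.0)
        keep = (winval > cut[winner]) & (winval > 0)
    elif threshold_mode == "quantile":
        cut = np.quantile(S, threshold, axis=1)
        keep = winval > cut[winner]
    elif threshold_mode == "absolute":
        keep = winval > threshold
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    labels = np.where(keep, winner + 1, 0)
    confidence = np.where(keep, winval, 0.0)
    return UnitMap(labels=labels.astype(np.int64), confidence=confidence,
                   image_shape=tuple(image_shape), frame_index=frame_index)


def completeness(model: FactorModel, truth: GroundTruth) -> float:
    """Fraction of ground-truth units with >= 1 selected pixel inside them."""
    from .batch import units_hit

    hits = units_hit(model, truth)
    return sum(hits.values()) / len(hits) if hits else float("nan")


@dataclass
class MapSnapshot:
    frame_index: int
    unit_map: UnitMap
    model: FactorModel
    completeness: float | None = None


def map_timeline(
    movie,
    image_shape,
    config: StreamConfig | None = None,
    snapshot_every: int = 100,
    truth: GroundTruth | None = None,
    threshold_mode: str = "relative",
    threshold: float = 0.5,
) -> tuple[StreamProcessor, list[MapSnapshot]]:
    """Stream a movie and capture unit-map snapshots at a fixed cadence.

    Snapshots are taken at frames ``snapshot_every, 2*snapshot_every, ...``
    and at the final frame; if ``snapshot_every`` exceeds the stream length a
    single final map is returned.  With ground truth each snapshot carries
    map completeness (fraction of units already hit by a selected pixel).
    """
    config = config or StreamConfig()
    movie = np.asarray(movie)
    m = movie.shape[0]
    proc = StreamProcessor(image_shape, config)
    snapshots: list[MapSnapshot] = []

    def snap(frame_index: int) -> None:
        model = proc.current_model(with_T=False)
        umap = build_map(model.S, threshold_mode=threshold_mode,
                         threshold=threshold, image_shape=image_shape,
                         frame_index=frame_index)
        comp = completeness(model, truth) if truth is not None else None
        snapshots.append(MapSnapshot(frame_index=frame_index, unit_map=umap,
                                     model=model, completeness=comp))

    for i in range(m):
        proc.process_frame(movie[i])
        at_snapshot = snapshot_every and ((i + 1) % snapshot_every == 0)
        if i > config.warmup and (at_snapshot or i == m - 1):
            if snapshots and snapshots[-1].frame_index == i:
                continue
            snap(i)
    if not snapshots:
        snap(m - 1)
    return proc, snapshots


# ---------------------------------------------------------------------------
# rendering / export
# ---------------------------------------------------------------------------

def _palette(n_units: int, palette_seed: int = 0) -> np.ndarray:
    """Deterministic, pairwise-distinct RGB colours for unit ids 1..n."""
    rng = np.random.default_rng(palette_seed)
    offset = rng.random()
    order = rng.permutation(n_units)
    colours = np.zeros((n_units, 3), dtype=np.uint8)
    used = set()
    for rank, u in enumerate(order):
        hue = (offset + rank / max(n_units, 1)) % 1.0
        val = 1.0 if rank % 2 == 0 else 0.72
        rgb = tuple(int(round(255 * x))
                    for x in colorsys.hsv_to_rgb(hue, 0.9, val))
        while rgb in used:  # nudge until distinct (uint8 rounding collisions)
            rgb = (rgb[0], rgb[1], min(rgb[2] + 1, 255) if rgb[2] < 255
                   else max(rgb[2] - 1, 0))
        used.add(rgb)
        colours[u] = rgb
    return colours


def render_map(unit_map: UnitMap, palette_seed: int = 0
               ) -> tuple[np.ndarray, pd.DataFrame]:
    """False-colour RGB image of a unit map plus its colour legend.

    Background is black; colours are deterministic per palette seed and
    pairwise distinct across units.
    """
    n_units = int(unit_map.labels.max())
    colours = _palette(n_units, palette_seed) if n_units else \
        np.zeros((0, 3), dtype=np.uint8)
    h, w = unit_map.image_shape
    rgb = np.zeros((h * w, 3), dtype=np.uint8)
    labelled = unit_map.labels > 0
    rgb[labelled] = colours[unit_map.labels[labelled] - 1]
    legend = pd.DataFrame({
        "unit": np.arange(1, n_units + 1),
        "r": colours[:, 0], "g": colours[:, 1], "b": colours[:, 2],
    })
    return rgb.reshape(h, w, 3), legend


def save_map(unit_map: UnitMap, prefix, palette_seed: int = 0) -> None:
    """Write a unit map as 16-bit label TIFF, RGB PNG and a pixel CSV."""
    import imageio.v3 as iio
    import tifffile

    tifffile.imwrite(f"{prefix}_labels.tif",
                     unit_map.label_image.astype(np.uint16))
    rgb, legend = render_map(unit_map, palette_seed)
    iio.imwrite(f"{prefix}_map.png", rgb)
    legend.to_csv(f"{prefix}_legend.csv", index=False)
    h, w = unit_map.image_shape
    labelled = np.nonzero(unit_map.labels)[0]
    pd.DataFrame({
        "pixel_row": labelled // w,
        "pixel_col": labelled % w,
        "unit": unit_map.labels[labelled],
        "confidence": unit_map.confidence[labelled],
    }).to_csv(f"{prefix}_pixels.csv", index=False)
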