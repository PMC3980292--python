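"""Real-time display transforms: temporal high-pass and incremental scaling.

A real-time viewer cannot know the movie's final value range, so the
false-colour scale is driven by cumulative minimum / maximum, and slow level
changes (photobleaching) are removed beforehand by a causal first-order
high-pass (default cutoff 0.025 Hz).  Both updates are O(1) per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _blue_red_table() -> np.ndarray:
    """Fixed 256-entry blue -> white -> red diverging colour table."""
    t = np.linspace(0.0, 1.0, 256)
    r = np.where(t < 0.5, 2 * t, 1.0)
    b = np.where(t < 0.5, 1.0, 2 * (1 - t))
    g = 1.0 - np.abs(2 * t - 1.0)
    table = np.stack([r, g, b], axis=1)
    return np.round(255 * table).astype(np.uint8)


BLUE_RED = _blue_red_table()


@dataclass
class DisplayState:
    """Per-stream display memory: cumulative extrema + high-pass EMA."""

    frame_rate: float
    cutoff: float = 0.025
    running_min: float | None = None
    running_max: float | None = None
    ema: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cutoff >= self.frame_rate / 2:
            raise ValueError("cutoff must be below the Nyquist frequency")

    @property
    def alpha(self) -> float:
        """EMA coefficient matching the analogue pole exp(-2*pi*fc/fs)."""
        return 1.0 - np.exp(-2.0 * np.pi * self.cutoff / self.frame_rate)


def highpass(state: DisplayState, frame: np.ndarray
             ) -> tuple[np.ndarray, DisplayState]:
    """Causal first-order high-pass: y = x - EMA(x).

    The first frame initialises the EMA, so constant input is rejected from
    the start; a step decays with time constant 1/(2*pi*cutoff) seconds.
    The filter is linear and time-invariant in its steady state.
    """
    x = np.asarray(frame, dtype=np.float64)
    if state.ema is None:
        ema = x.copy()
    else:
        ema = state.ema + state.alpha * (x - state.ema)
    y = x - ema
    new = DisplayState(frame_rate=state.frame_rate, cutoff=state.cutoff,
                       running_min=state.running_min,
                       running_max=state.running_max, ema=ema)
    return y, new


def update_scale_and_colour(state: DisplayState, frame: np.ndarray
                            ) -> tuple[np.ndarray, DisplayState]:
    """Map a frame to the blue-red ramp under cumulative min/max scaling.

    running_min is non-increasing and running_max non-decreasing over the
    stream; a degenerate range maps everything to the mid colour.
    Returns (uint8 RGB array with shape frame.shape + (3,), new state).
    """
    x = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("frame contains non-finite values")
    lo = float(x.min()) if state.running_min is None \
        else min(state.running_min, float(x.min()))
    hi = float(x.max()) if state.running_max is None \
        else max(state.running_max, float(x.max()))
    if hi > lo:
        idx = np.clip((x - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    else:
        idx = np.full(x.shape, 128, dtype=np.uint8)
    rgb = BLUE_RED[idx]
    new = DisplayState(frame_rate=state.frame_rate, cutoff=state.cutoff,
                       running_min=lo, running_max=hi, ema=state.ema)
    return rgb, new
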