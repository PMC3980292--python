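"""Synthetic calcium-imaging movies with known ground truth.

Movies follow the non-negative mixture model ``A = T @ S + N``: a small number
of spatial units ("glomeruli") with smooth, overlapping footprints, each driven
by a stimulus-locked response trace plus low-amplitude spontaneous activity.
Every unit keeps a *pure* pixel at its centre (a pixel whose time series is
proportional to exactly one source), which is the identifiability condition the
convex-cone selection step relies on.  Optional photobleaching (multiplicative
decay on a baseline fluorescence), structured background components
(illumination / staining artifacts) and Gaussian sensor noise emulate the
nuisance structure of real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d


class PlacementError(RuntimeError):
    """Raised when a footprint cannot be placed in the image."""


# ---------------------------------------------------------------------------
# stimulus protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered list of (stimulus label, onset frame) for one recording.

    Parameters
    ----------
    entries : tuple of (str, int)
        Stimulus label and 0-based onset frame, onsets strictly increasing.
    n_frames : int
        Total movie length in frames; all onsets are below it.
    frame_rate : float
        Acquisition rate in Hz.
    """

    entries: tuple[tuple[str, int], ...]
    n_frames: int
    frame_rate: float = 5.0

    def __post_init__(self) -> None:
        onsets = [int(o) for _, o in self.entries]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.n_frames):
            raise ValueError("stimulus onsets must lie inside [0, n_frames)")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.entries]

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray([o for _, o in self.entries], dtype=int)

    @property
    def unique_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["label", "onset_frame"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, n_frames: int | None = None,
                 frame_rate: float = 5.0) -> "StimulusProtocol":
        df = pd.read_csv(path)
        entries = tuple(
            (str(lab), int(onset))
            for lab, onset in zip(df["label"], df["onset_frame"])
        )
        if n_frames is None:
            n_frames = int(df["onset_frame"].max()) + 1 if len(df) else 1
        return cls(entries=entries, n_frames=int(n_frames), frame_rate=frame_rate)


def generate_protocol(
    labels,
    reference_labels=(),
    reference_every: int = 5,
    interstimulus_frames: int = 60,
    lead_in_frames: int = 20,
    frame_rate: float = 5.0,
    seed: int = 0,
    shuffle: bool = True,
    total_frames: int | None = None,
) -> StimulusProtocol:
    """Build a stimulation sequence with periodically repeated references.

    The base ``labels`` are (optionally) shuffled, and after every
    ``reference_every`` of them the full set of ``reference_labels`` is
    inserted; a trailing partial block is also followed by the references, so
    22 base odours with 2 references at block size 5 yield 32 stimulations with
    each reference repeated 5 times.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    if interstimulus_frames < 1:
        raise ValueError("interstimulus_frames must be >= 1")
    rng = np.random.default_rng(seed)
    base = list(labels)
    if shuffle:
        rng.shuffle(base)

    seq: list[str] = []
    since_ref = 0
    for lab in base:
        seq.append(lab)
        since_ref += 1
        if reference_labels and since_ref == reference_every:
            seq.extend(reference_labels)
            since_ref = 0
    if reference_labels and since_ref:
        seq.extend(reference_labels)

    onsets = [lead_in_frames + i * interstimulus_frames for i in range(len(seq))]
    n_frames = onsets[-1] + interstimulus_frames
    if total_frames is not None:
        n_frames = max(n_frames, int(total_frames))
    return StimulusProtocol(
        entries=tuple(zip(seq, onsets)), n_frames=n_frames, frame_rate=frame_rate
    )


# ---------------------------------------------------------------------------
# footprints and sources
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Footprint:
    """Spatial weight profile of one unit: a truncated Gaussian disc.

    ``radius`` is the support radius; the Gaussian sigma is ``radius / 2`` and
    the profile is cut at 2*sigma, so weights are 1 at the centre and decay
    monotonically to ``exp(-2) ~ 0.135`` at the rim.
    """

    center: tuple[int, int]
    radius: float
    pixel_indices: np.ndarray  # flat indices into the image, row-major
    weights: np.ndarray        # same length, in (0, 1], max 1 at the centre
    image_shape: tuple[int, int]

    @property
    def center_index(self) -> int:
        return self.center[0] * self.image_shape[1] + self.center[1]

    @property
    def core_indices(self) -> np.ndarray:
        """Pixels of the FWHM core (weight >= 0.5)."""
        return self.pixel_indices[self.weights >= 0.5]


def _make_footprint(center, radius, image_shape) -> Footprint:
    h, w = image_shape
    r0, c0 = center
    rad = int(np.ceil(radius))
    rows = np.arange(max(0, r0 - rad), min(h, r0 + rad + 1))
    cols = np.arange(max(0, c0 - rad), min(w, c0 + rad + 1))
    dd = (rows[:, None] - r0) ** 2 + (cols[None, :] - c0) ** 2
    sigma = radius / 2.0
    mask = dd <= radius**2
    weights = np.exp(-dd / (2.0 * sigma**2))[mask]
    flat = (rows[:, None] * w + cols[None, :])[mask]
    return Footprint(
        center=(int(r0), int(c0)),
        radius=float(radius),
        pixel_indices=flat.astype(np.int64),
        weights=weights.astype(np.float64),
        image_shape=(int(h), int(w)),
    )


@dataclass(frozen=True)
class SourceSignal:
    """Temporal signal of one unit: stimulus responses + spontaneous drift."""

    unit_id: int
    trace: np.ndarray                      # length-m
    stimulus_responses: dict[str, float]   # label -> peak amplitude
    spontaneous_amplitude: float


def _response_kernel(m: int, frame_rate: float,
                     rise_s: float = 0.5, decay_s: float = 3.0) -> np.ndarray:
    """Difference-of-exponentials calcium transient, peak-normalised to 1."""
    t = np.arange(m, dtype=np.float64)
    tau_r = max(rise_s * frame_rate, 1e-3)
    tau_d = max(decay_s * frame_rate, 1e-3)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = k.max()
    if peak <= 0:
        k = np.zeros(m)
        k[0] = 1.0
        return k
    return k / peak


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything needed to render a movie and validate recovery against it."""

    image_shape: tuple[int, int]
    footprints: list[Footprint]
    sources: list[SourceSignal]
    mixing: np.ndarray                 # c_true x n, non-negative
    pure_pixels: dict[int, int]        # unit_id -> flat pixel index
    protocol: StimulusProtocol
    noise_sigma: float
    bleach_tau: float | None           # seconds, or None
    baseline: float
    noise_seed: int
    background_maps: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 0)))   # b x n, in [0, 1]
    background_traces: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 0)))   # m x b

    @property
    def n_units(self) -> int:
        return len(self.footprints)

    @property
    def n_pixels(self) -> int:
        return self.image_shape[0] * self.image_shape[1]

    @property
    def n_frames(self) -> int:
        return self.protocol.n_frames

    @property
    def traces(self) -> np.ndarray:
        """Stacked source traces, m x c_true."""
        return np.stack([s.trace for s in self.sources], axis=1)

    def footprint_masks(self) -> list[np.ndarray]:
        """Boolean support mask (flat, length n) per unit."""
        masks = []
        for fp in self.footprints:
            m = np.zeros(self.n_pixels, dtype=bool)
            m[fp.pixel_indices] = True
            masks.append(m)
        return masks


def generate_ground_truth(
    image_shape=(120, 160),
    n_units: int = 20,
    radius_range=(4.0, 7.0),
    protocol: StimulusProtocol | None = None,
    noise_sigma: float = 0.2,
    bleach_tau: float | None = None,
    baseline: float = 1.0,
    spontaneous_amplitude: float = 0.2,
    response_prob: float = 0.5,
    amplitude_range=(0.5, 1.5),
    n_background: int = 8,
    background_amplitude: float = 0.5,
    background_timescale_s: float = 60.0,
    seed: int = 0,
    response_seed: int | None = None,
    ensure_pure: bool = True,
    max_tries: int = 20000,
) -> GroundTruth:
    """Place footprints, draw per-unit odour tuning, and assemble ground truth.

    ``response_seed`` lets two "individuals" share the same odour tuning table
    while having independent footprints, spontaneous activity and noise.
    Deterministic for a fixed seed pair.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if protocol is None:
        protocol = generate_protocol(
            [f"odour_{i:02d}" for i in range(8)], seed=seed
        )
    h, w = image_shape
    n = h * w
    m = protocol.n_frames

    ss = np.random.SeedSequence(seed)
    s_place, s_resp, s_spont, s_bg, s_noise = ss.spawn(5)
    rng_place = np.random.default_rng(s_place)
    rng_resp = (np.random.default_rng(response_seed)
                if response_seed is not None else np.random.default_rng(s_resp))
    rng_spont = np.random.default_rng(s_spont)
    rng_bg = np.random.default_rng(s_bg)
    noise_seed = int(s_noise.generate_state(1, np.uint32)[0] % (2**31))

    # --- placement: centres far enough apart that every centre pixel is pure
    centers: list[tuple[int, int]] = []
    radii: list[float] = []
    for u in range(n_units):
        placed = False
        for _ in range(max_tries):
            radius = float(rng_place.uniform(*radius_range))
            rad = int(np.ceil(radius))
            if h - 2 * rad - 2 <= 0 or w - 2 * rad - 2 <= 0:
                break
            r0 = int(rng_place.integers(rad + 1, h - rad - 1))
            c0 = int(rng_place.integers(rad + 1, w - rad - 1))
            ok = True
            for (r1, c1), rr in zip(centers, radii):
                d = np.hypot(r0 - r1, c0 - c1)
                if d < 0.8 * (radius + rr) or d < max(radius, rr) + 1.0:
                    ok = False
                    break
            if ok:
                centers.append((r0, c0))
                radii.append(radius)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place unit {u} of {n_units} in image {image_shape}"
            )

    footprints = [_make_footprint(c, r, image_shape)
                  for c, r in zip(centers, radii)]
    mixing = np.zeros((n_units, n), dtype=np.float64)
    for u, fp in enumerate(footprints):
        mixing[u, fp.pixel_indices] = fp.weights

    pure_pixels: dict[int, int] = {}
    for u, fp in enumerate(footprints):
        j = fp.center_index
        if ensure_pure:
            others = np.delete(mixing[:, j], u)
            if np.any(others != 0):
                raise PlacementError(
                    f"centre pixel of unit {u} is not pure; placement invalid"
                )
        pure_pixels[u] = int(j)

    # --- temporal sources
    kernel = _response_kernel(m, protocol.frame_rate)
    odours = protocol.unique_labels
    sources: list[SourceSignal] = []
    for u in range(n_units):
        responds = rng_resp.random(len(odours)) < response_prob
        if not responds.any():
            responds[rng_resp.integers(len(odours))] = True
        amps = rng_resp.uniform(*amplitude_range, size=len(odours))
        responses = {lab: float(a) for lab, a, r in zip(odours, amps, responds) if r}
        trace = np.zeros(m, dtype=np.float64)
        for lab, onset in protocol.entries:
            a = responses.get(lab)
            if a:
                trace[onset:] += a * kernel[: m - onset]
        if spontaneous_amplitude > 0:
            spont = gaussian_filter1d(
                rng_spont.standard_normal(m), sigma=2.0 * protocol.frame_rate
            )
            sd = spont.std()
            if sd > 0:
                trace += spontaneous_amplitude * spont / sd
        sources.append(SourceSignal(
            unit_id=u, trace=trace,
            stimulus_responses=responses,
            spontaneous_amplitude=float(spontaneous_amplitude),
        ))

    # --- structured background (staining / illumination artifacts)
    if n_background > 0:
        maps = np.empty((n_background, n))
        trs = np.empty((m, n_background))
        for b in range(n_background):
            fld = gaussian_filter(
                rng_bg.standard_normal((h, w)), sigma=min(h, w) / 6.0
            )
            fld -= fld.min()
            peak = fld.max()
            maps[b] = (fld / peak if peak > 0 else fld).ravel()
            # illumination / staining artifacts drift far more slowly than
            # stimulus responses (tens of seconds to minutes)
            tr = gaussian_filter1d(
                rng_bg.standard_normal(m),
                sigma=background_timescale_s * protocol.frame_rate,
            )
            sd = tr.std()
            trs[:, b] = background_amplitude * (tr / sd if sd > 0 else tr)
        background_maps, background_traces = maps, trs
    else:
        background_maps = np.zeros((0, n))
        background_traces = np.zeros((m, 0))

    return GroundTruth(
        image_shape=(int(h), int(w)),
        footprints=footprints,
        sources=sources,
        mixing=mixing,
        pure_pixels=pure_pixels,
        protocol=protocol,
        noise_sigma=float(noise_sigma),
        bleach_tau=bleach_tau,
        baseline=float(baseline),
        noise_seed=noise_seed,
        background_maps=background_maps,
        background_traces=background_traces,
    )


def render_movie(truth: GroundTruth, dtype=np.float64) -> np.ndarray:
    """Render the movie matrix ``A`` (m x n) from ground truth.

    With ``noise_sigma == 0``, ``bleach_tau is None`` and no background
    components, A equals ``traces @ mixing`` exactly.
    """
    A = truth.traces @ truth.mixing
    if truth.background_maps.size:
        A = A + truth.background_traces @ truth.background_maps
    if truth.bleach_tau is not None:
        t = np.arange(truth.n_frames, dtype=np.float64)
        tau_frames = truth.bleach_tau * truth.protocol.frame_rate
        A = A + truth.baseline * np.exp(-t / tau_frames)[:, None]
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.noise_seed)
        A = A + rng.normal(0.0, truth.noise_sigma, size=A.shape)
    return np.ascontiguousarray(A, dtype=dtype)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_movie_tiff(path, movie: np.ndarray, image_shape) -> None:
    """Write an (m, n) movie matrix as a multi-page 32-bit float TIFF."""
    import tifffile

    m = movie.shape[0]
    stack = movie.reshape(m, *image_shape).astype(np.float32)
    tifffile.imwrite(path, stack)


def save_ground_truth(path, truth: GroundTruth) -> None:
    """Persist ground truth (mixing, traces, pure pixels, protocol) as HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["image_shape"] = truth.image_shape
        f.attrs["noise_sigma"] = truth.noise_sigma
        f.attrs["baseline"] = truth.baseline
        f.attrs["noise_seed"] = truth.noise_seed
        if truth.bleach_tau is not None:
            f.attrs["bleach_tau"] = truth.bleach_tau
        f.create_dataset("mixing", data=truth.mixing)
        f.create_dataset("traces", data=truth.traces)
        f.create_dataset(
            "pure_pixels",
            data=np.array(sorted(truth.pure_pixels.items()), dtype=np.int64),
        )
        labs = np.array([lab for lab, _ in truth.protocol.entries], dtype="S")
        f.create_dataset("protocol/labels", data=labs)
        f.create_dataset("protocol/onsets", data=truth.protocol.onsets)
        f.attrs["n_frames"] = truth.protocol.n_frames
        f.attrs["frame_rate"] = truth.protocol.frame_rate
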