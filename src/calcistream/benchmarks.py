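"""Reference experiments on synthetic movies.

Each function builds its own inputs from the synthetic generator, runs the
method under study and measures a quantitative outcome: streaming-vs-batch
selection agreement, map segmentation quality, exact identifiability of pure
pixels, CCIPCA convergence angles, incremental map completion, normalisation
exactness, the chemosensing pipeline and the display filter constants.
Problem sizes are chosen so a full sweep runs in minutes on one CPU core;
streaming runs use float32 frame history and snapshot-cadence cone selection
(selection is a pure function of V, so the final model is unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .batch import MatchReport, batch_pipeline, compare_models
from .chemosense import (euclidean_distances, extract_features, is_pure_subtree,
                         mantel_test, ward_cluster)
from .display import DisplayState, highpass
from .maps import build_map, map_timeline
from .preprocess import NormalisationState, update_normalise
from .streaming import PCMatrix, StreamConfig, run_stream, update_ipca
from .synthetic import generate_ground_truth, generate_protocol, render_movie

# Standard benchmark geometry: a honeybee-scale field of view with 20 units.
BENCH_SHAPE = (120, 160)
BENCH_UNITS = 20
BENCH_FRAMES = 3000
MEAN_AMPLITUDE = 1.0   # amplitude_range (0.5, 1.5); SNR = mean amp / noise sd


def benchmark_truth(seed: int = 0, snr: float = 5.0, n_units: int = BENCH_UNITS,
                    image_shape=BENCH_SHAPE, n_frames: int = BENCH_FRAMES,
                    frame_rate: float = 5.0, **kwargs):
    """Ground truth + rendered movie for the standard benchmark conditions."""
    protocol = generate_protocol(
        [f"odour_{i:02d}" for i in range(24)],
        reference_labels=("heptyl_acetate", "nonanone"),
        reference_every=5, interstimulus_frames=84, lead_in_frames=40,
        frame_rate=frame_rate, seed=seed, total_frames=n_frames,
    )
    truth = generate_ground_truth(
        image_shape=image_shape, n_units=n_units, protocol=protocol,
        noise_sigma=MEAN_AMPLITUDE / snr, seed=seed, **kwargs,
    )
    movie = render_movie(truth, dtype=np.float32)
    return truth, movie


@dataclass
class StreamBatchResult:
    stream_model: object
    batch_model: object
    report: MatchReport
    truth: object
    movie: np.ndarray = field(repr=False)


def stream_vs_batch(seed: int = 0, snr: float = 5.0, k: int = 50, c: int = 50,
                    match_radius: float = 5.0, spatial_filter_width: int = 1,
                    n_frames: int = BENCH_FRAMES) -> StreamBatchResult:
    """Run both pipelines on one synthetic movie and match their selections.

    The batch model acts as the reference: its footprint-resident selections
    are matched against the full streaming set within ``match_radius``.
    The spatial pre-filter is off by default here: synthetic sensor noise is
    white, so top-k denoising suffices and the evaluation keeps the full
    spatial resolution of the footprints (for camera data the pipeline
    default of width 9 applies).
    """
    truth, movie = benchmark_truth(seed=seed, snr=snr, n_frames=n_frames)
    cfg = StreamConfig(k=k, c=c, spatial_filter_width=spatial_filter_width,
                       select_every=100, compute_recon=False,
                       keep_history=False)
    _, stream_model = run_stream(movie, truth.image_shape, cfg)
    batch = batch_pipeline(movie, k=k, c=c, image_shape=truth.image_shape,
                           spatial_filter_width=spatial_filter_width,
                           with_T=False)
    report = compare_models(batch.model, stream_model, truth=truth,
                            match_radius=match_radius)
    return StreamBatchResult(stream_model=stream_model,
                             batch_model=batch.model, report=report,
                             truth=truth, movie=movie)


def map_jaccard_scores(model, truth, threshold_mode: str = "relative",
                       threshold: float = 0.5) -> np.ndarray:
    """Per-unit Jaccard overlap between map regions and FWHM footprint cores.

    Standard segmentation scoring: each true unit is paired with the map
    region that overlaps its core best (max Jaccard over labels); units no
    region touches score 0.
    """
    umap = build_map(model.S, threshold_mode=threshold_mode,
                     threshold=threshold, image_shape=truth.image_shape)
    regions = [set(np.nonzero(umap.labels == r + 1)[0].tolist())
               for r in range(model.c)]
    scores = np.zeros(truth.n_units)
    for u, fp in enumerate(truth.footprints):
        core = set(fp.core_indices.tolist())
        best = 0.0
        for region in regions:
            if not region & core:
                continue
            best = max(best, len(region & core) / len(region | core))
        scores[u] = best
    return scores


def pure_pixel_recovery(seeds=range(10), n_units_range=(5, 20),
                        image_shape=(64, 64)) -> dict:
    """Exact identifiability on noiseless mixtures with pure pixels present.

    For each seed, a noiseless movie (no background, no bleaching) is built
    and the convex cone is run on the raw mixture with c = number of sources;
    reports the fraction of seeds with exact pure-pixel-set recovery and the
    worst relative Frobenius reconstruction error of T S against the movie.
    """
    from .streaming import compute_S, convex_cone

    seeds = list(seeds)
    lo, hi = n_units_range
    exact = []
    worst_err = 0.0
    for idx, seed in enumerate(seeds):
        n_units = lo + (idx * 3) % (hi - lo + 1)
        protocol = generate_protocol(
            [f"odour_{i:02d}" for i in range(10)], interstimulus_frames=30,
            lead_in_frames=10, frame_rate=5.0, seed=seed,
        )
        truth = generate_ground_truth(
            image_shape=image_shape, n_units=n_units, radius_range=(3.0, 5.0),
            protocol=protocol, noise_sigma=0.0, n_background=0,
            spontaneous_amplitude=0.05, seed=seed,
        )
        A = render_movie(truth)
        cone = convex_cone(A, n_units)
        sel = set(int(j) for j in cone.indices)
        pure = set(truth.pure_pixels.values())
        exact.append(sel == pure)
        S = compute_S(A, cone.basis, nonneg=None)
        err = np.linalg.norm(A - cone.basis @ S) / np.linalg.norm(A)
        worst_err = max(worst_err, float(err))
    return {"exact_fraction": float(np.mean(exact)),
            "worst_rel_error": worst_err, "n_seeds": len(seeds)}


def ccipca_convergence(seeds=range(5), n_pixels: int = 16, k: int = 5,
                       n_frames: int = 5000,
                       spectrum=(9.0, 4.0, 1.0)) -> dict:
    """Principal angles between incremental and batch subspaces.

    Stationary zero-mean Gaussian stream with covariance
    diag(spectrum + 0.1 ...); after the stream, the top-1 and top-3 CCIPCA
    subspaces are compared with the batch PCA of the same frames (sampling
    error cancels).  Angles are averaged over seeds, in degrees.
    """
    from scipy.linalg import subspace_angles

    sd = np.sqrt(np.concatenate([
        np.asarray(spectrum, dtype=float),
        np.full(n_pixels - len(spectrum), 0.1),
    ]))
    a1, a3 = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_frames, n_pixels)) * sd
        V = PCMatrix.empty(k, n_pixels)
        for x in X:
            update_ipca(V, x, copy=False)
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        Vn = V.normalised()
        a1.append(np.degrees(subspace_angles(Vn[:1].T, Vt[:1].T).max()))
        a3.append(np.degrees(subspace_angles(Vn[:3].T, Vt[:3].T).max()))
    return {"top1_deg": float(np.mean(a1)), "top3_deg": float(np.mean(a3)),
            "n_frames": n_frames, "n_seeds": len(list(seeds))}


def map_completion(seeds=range(20), snr: float = 10.0, k: int = 50,
                   c: int = 50, snapshot_every: int = 100,
                   n_frames: int = BENCH_FRAMES,
                   warmup_frames: int | None = None) -> dict:
    """Incremental map completeness across seeds of the benchmark movie.

    For each seed: stream the movie, record completeness (fraction of units
    hit by a selected pixel) at snapshot frames, and measure (a) whether the
    completeness curve is non-decreasing after the CCIPCA seeding phase
    (default 4*k frames) and (b) the ratio of completeness at frame 600 to
    its final value.
    """
    if warmup_frames is None:
        warmup_frames = 4 * k
    monotone = []
    ratio_600 = []
    for seed in seeds:
        truth, movie = benchmark_truth(seed=seed, snr=snr, n_frames=n_frames)
        cfg = StreamConfig(k=k, c=c, spatial_filter_width=1, select_every=0,
                           compute_recon=False, keep_history=False)
        _, snaps = map_timeline(movie, truth.image_shape, cfg,
                                snapshot_every=snapshot_every, truth=truth)
        frames = np.array([s.frame_index for s in snaps])
        comp = np.array([s.completeness for s in snaps])
        after = comp[frames >= warmup_frames]
        monotone.append(bool(np.all(np.diff(after) >= 0)))
        at600 = comp[frames <= 600][-1] if np.any(frames <= 600) else comp[0]
        ratio_600.append(float(at600 / comp[-1]) if comp[-1] > 0 else 0.0)
    return {
        "monotone_fraction": float(np.mean(monotone)),
        "ratio_600_mean": float(np.mean(ratio_600)),
        "ratio_600_min": float(np.min(ratio_600)),
        "n_seeds": len(list(seeds)),
    }


def normalisation_exactness(seed: int = 0, n_frames: int = 1000,
                            n_pixels: int = 200) -> dict:
    """Relative error of streaming mu/sigma against batch moments."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_frames, n_pixels)) * rng.uniform(
        0.5, 3.0, n_pixels) + rng.uniform(-5, 5, n_pixels)
    state = NormalisationState.empty(n_pixels)
    for x in X:
        _, state = update_normalise(state, x)
    mu_err = np.abs(state.mean - X.mean(axis=0)) / np.maximum(
        np.abs(X.mean(axis=0)), 1.0)
    sd_err = np.abs(state.sigma - X.std(axis=0)) / X.std(axis=0)
    return {"max_rel_error": float(max(mu_err.max(), sd_err.max())),
            "n_frames": n_frames}


@dataclass
class ChemosensorOutcome:
    pure_subtree_rate: float     # fraction of reference odours forming one
    mantel_r: float
    mantel_p: float
    n_stimuli: int


def _chemo_protocol(seed: int):
    refs = ("heptyl_acetate", "nonanone")
    protocol = generate_protocol(
        [f"odour_{i:02d}" for i in range(22)], reference_labels=refs,
        reference_every=5, interstimulus_frames=40, lead_in_frames=20,
        frame_rate=4.0, seed=seed,
    )
    return refs, protocol


def _chemo_outcome(refs, protocol, feature_sets, n_permutations: int,
                   seed: int) -> ChemosensorOutcome:
    distances = [euclidean_distances(F) for F in feature_sets]
    first = feature_sets[0]
    tree = ward_cluster(first)
    labels = first.stimulus_labels
    pure = [
        is_pure_subtree(tree, [i for i, lab in enumerate(labels) if lab == ref])
        for ref in refs
    ]
    mant = mantel_test(distances[0], distances[1],
                       n_permutations=n_permutations, seed=seed)
    return ChemosensorOutcome(
        pure_subtree_rate=float(np.mean(pure)),
        mantel_r=mant.r, mantel_p=mant.p, n_stimuli=len(labels),
    )


def chemosensor_experiment(seed: int = 0, snr: float = 5.0,
                           n_units: int = 12,
                           n_permutations: int = 999) -> ChemosensorOutcome:
    """Fig.-9-style analysis of response-unit time series at a given SNR.

    A 32-stimulation protocol (22 odours + heptyl acetate and nonanone
    repeated 5x each) drives two "individuals" that share the odour tuning
    table but have independent spontaneous activity; each individual's unit
    time series carry independent white measurement noise with
    sd = mean response amplitude / snr.  The first individual is
    Ward-clustered (reference repeats should form pure subtrees) and the two
    odour distance matrices are Mantel-correlated.
    """
    refs, protocol = _chemo_protocol(seed)
    feature_sets = []
    for indiv in range(2):
        truth = generate_ground_truth(
            image_shape=(64, 64), n_units=n_units, radius_range=(3.0, 5.0),
            protocol=protocol, noise_sigma=0.0, n_background=0,
            seed=seed * 2 + indiv + 1, response_seed=seed + 77,
        )
        rng = np.random.default_rng((seed * 2 + indiv + 13) % 2**31)
        T = truth.traces + rng.normal(0.0, MEAN_AMPLITUDE / snr,
                                      size=truth.traces.shape)
        feature_sets.append(extract_features(T, protocol))
    return _chemo_outcome(refs, protocol, feature_sets, n_permutations, seed)


def chemosensor_from_movies(seed: int = 0, snr: float = 5.0,
                            image_shape=(64, 64), n_units: int = 12,
                            k: int = 24, c: int = 24,
                            n_permutations: int = 999) -> ChemosensorOutcome:
    """End-to-end variant: movies -> streaming factorisation -> features.

    Harder than :func:`chemosensor_experiment`: the unit series must first be
    *found* in movies that also contain structured background drift, and the
    measured series carry per-pixel noise and z-score scale distortions.
    Pre-onset baseline subtraction removes slow drift that would otherwise
    shift whole-window maxima.
    """
    refs, protocol = _chemo_protocol(seed)
    feature_sets = []
    for indiv in range(2):
        truth = generate_ground_truth(
            image_shape=image_shape, n_units=n_units, radius_range=(3.0, 5.0),
            protocol=protocol, noise_sigma=MEAN_AMPLITUDE / snr,
            n_background=4, seed=seed * 2 + indiv + 1,
            response_seed=seed + 77,
        )
        movie = render_movie(truth, dtype=np.float32)
        cfg = StreamConfig(k=k, c=c, spatial_filter_width=5, select_every=200,
                           compute_recon=False, keep_history=True)
        _, model = run_stream(movie, truth.image_shape, cfg)
        feature_sets.append(
            extract_features(model.T, protocol, baseline_mode="subtract"))
    return _chemo_outcome(refs, protocol, feature_sets, n_permutations, seed)


def highpass_characteristics(frame_rate: float = 5.0, cutoff: float = 0.025,
                             n_frames: int = 400) -> dict:
    """DC rejection and step-response time constant of the display filter."""
    # DC: constant input after convergence
    state = DisplayState(frame_rate=frame_rate, cutoff=cutoff)
    y = None
    for _ in range(n_frames):
        y, state = highpass(state, np.array([1.0]))
    dc_rejection = float(abs(y[0]))

    # step response: settle on zeros, then unit step; fit exponential decay
    state = DisplayState(frame_rate=frame_rate, cutoff=cutoff)
    for _ in range(10):
        _, state = highpass(state, np.array([0.0]))
    ys = []
    for _ in range(60):
        y, state = highpass(state, np.array([1.0]))
        ys.append(y[0])
    ys = np.asarray(ys)
    t = np.arange(len(ys)) / frame_rate
    slope = np.polyfit(t, np.log(ys), 1)[0]
    tau_est = -1.0 / slope
    tau_true = 1.0 / (2.0 * np.pi * cutoff)
    return {"dc_rejection": dc_rejection,
            "tau_seconds": float(tau_est),
            "tau_rel_error": float(abs(tau_est - tau_true) / tau_true),
            "n_frames": n_frames}
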