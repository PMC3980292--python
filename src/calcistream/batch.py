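"""Offline reference path: exact batch PCA + convex-cone selection.

This is the oracle the streaming pipeline is compared against: z-score the
whole movie with its final statistics, take the exact top-k right singular
directions (no n x n covariance matrix is ever formed), and run the same
convex-cone implementation on them.  ``compare_models`` quantifies how well
two runs agree, in the spirit of overlaying the offline reference's
glomerular selections on the online result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import normalise_movie, spatial_filter
from .streaming import FactorModel, compute_S, convex_cone
from .synthetic import GroundTruth


def batch_pca(A: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal directions of a z-scored movie matrix.

    Returns ``(V_exact, explained_variance)`` with orthonormal rows ordered by
    decreasing variance; the sign of each row is fixed so its
    largest-magnitude entry is positive.  Uses ARPACK with a fixed start
    vector for k well below min(m, n), full SVD otherwise — deterministic
    either way.
    """
    A = np.asarray(A)
    m, n = A.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"k={k} must be in [1, min(m, n)={min(m, n)}]")
    if k < min(m, n) - 1:
        from scipy.sparse.linalg import svds

        v0 = np.full(min(m, n), 1.0 / np.sqrt(min(m, n)))
        _, s, Vt = svds(A.astype(np.float64, copy=False), k=k, v0=v0)
        order = np.argsort(s)[::-1]
        s, Vt = s[order], Vt[order]
    else:
        _, s, Vt = np.linalg.svd(A.astype(np.float64, copy=False),
                                 full_matrices=False)
        s, Vt = s[:k], Vt[:k]
    for r in range(k):
        j = int(np.argmax(np.abs(Vt[r])))
        if Vt[r, j] < 0:
            Vt[r] = -Vt[r]
    explained = (s**2) / m
    return np.ascontiguousarray(Vt), explained


@dataclass
class BatchResult:
    """Exact top-k directions, their variances, and the assembled model."""

    V_exact: np.ndarray
    explained_variance: np.ndarray
    model: FactorModel


def batch_pipeline(
    movie: np.ndarray,
    k: int,
    c: int,
    image_shape,
    spatial_filter_width: int = 1,
    sigma_floor: float = 1e-6,
    nonneg: str | None = "clip",
    pre_normalised: bool = False,
    with_T: bool = True,
) -> BatchResult:
    """Full offline run: (filter) -> z-score -> batch PCA -> convex cone.

    Mirrors the streaming pipeline but with exact full-movie statistics and
    exact PCA; shares the convex-cone implementation with the stream.  The
    cone operates on the singular-value-weighted component matrix (whose
    column geometry equals that of the rank-k movie, and which matches the
    eigenvalue-sized rows the incremental estimator maintains); the reported
    ``V_exact`` keeps orthonormal rows.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    A = np.asarray(movie, dtype=np.float64)
    if spatial_filter_width > 1:
        A = np.stack([
            spatial_filter(row, spatial_filter_width, image_shape=image_shape)
            for row in A
        ])
    if not pre_normalised:
        A = normalise_movie(A, sigma_floor=sigma_floor)
    V, explained = batch_pca(A, k)
    m = A.shape[0]
    weighted = np.sqrt(explained * m)[:, None] * V   # singular values * V
    cone = convex_cone(weighted, c)
    S = compute_S(weighted, cone.basis, nonneg=nonneg)
    model = FactorModel(selected=cone.indices, S=S,
                        image_shape=tuple(image_shape), basis=cone.basis)
    if with_T:
        model.T = A[:, cone.indices]
    return BatchResult(V_exact=V, explained_variance=explained, model=model)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class MatchReport:
    """Greedy position matching between two selected-pixel sets."""

    hit_fraction: float          # matched pairs / reference set size
    mean_position_error: float   # mean distance over matched pairs (px)
    n_matched: int
    n_reference: int
    pairs: list[tuple[int, int]]                 # (index in a, index in b)
    units_hit_a: dict[int, bool] | None = None   # per ground-truth unit
    units_hit_b: dict[int, bool] | None = None

    @property
    def units_hit_fraction_a(self) -> float:
        d = self.units_hit_a or {}
        return sum(d.values()) / len(d) if d else float("nan")

    @property
    def units_hit_fraction_b(self) -> float:
        d = self.units_hit_b or {}
        return sum(d.values()) / len(d) if d else float("nan")


def units_hit(model: FactorModel, truth: GroundTruth) -> dict[int, bool]:
    """Per-unit flag: does any selected pixel fall inside the true footprint?"""
    sel = set(int(j) for j in model.selected)
    return {
        u: bool(sel.intersection(fp.pixel_indices.tolist()))
        for u, fp in enumerate(truth.footprints)
    }


def _greedy_match(pos_a: np.ndarray, pos_b: np.ndarray, radius: float):
    from scipy.spatial.distance import cdist

    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    D = cdist(pos_a.astype(float), pos_b.astype(float))
    pairs = []
    D = D.copy()
    while True:
        ij = np.unravel_index(np.argmin(D), D.shape)
        if not np.isfinite(D[ij]) or D[ij] > radius:
            break
        pairs.append((int(ij[0]), int(ij[1]), float(D[ij])))
        D[ij[0], :] = np.inf
        D[:, ij[1]] = np.inf
        if not np.isfinite(D).any():
            break
    return pairs


def compare_models(
    a: FactorModel,
    b: FactorModel,
    truth: GroundTruth | None = None,
    match_radius: float = 5.0,
) -> MatchReport:
    """Match the selected-pixel positions of two models within a radius.

    With ground truth, model ``a`` is treated as the reference and only its
    selections that fall inside true footprints enter the matching (the
    analogue of keeping only the glomerular signals of the offline
    reference); per-unit recovery flags are reported for both models.
    Without truth, the full sets are matched symmetrically and the hit
    fraction is n_matched / max(c_a, c_b).
    """
    if a.image_shape != b.image_shape:
        raise ValueError("models have different image shapes")
    pos_a_all = a.positions()
    pos_b = b.positions()

    hit_a = hit_b = None
    if truth is not None:
        hit_a = units_hit(a, truth)
        hit_b = units_hit(b, truth)
        in_fp = np.zeros(truth.n_pixels, dtype=bool)
        for fp in truth.footprints:
            in_fp[fp.pixel_indices] = True
        keep = in_fp[a.selected]
        pos_a = pos_a_all[keep]
        denom = max(int(keep.sum()), 1)
    else:
        pos_a = pos_a_all
        denom = max(len(pos_a), len(pos_b), 1)

    pairs = _greedy_match(pos_a, pos_b, match_radius)
    mean_err = float(np.mean([d for _, _, d in pairs])) if pairs else float("nan")
    return MatchReport(
        hit_fraction=len(pairs) / denom,
        mean_position_error=mean_err,
        n_matched=len(pairs),
        n_reference=denom,
        pairs=[(i, j) for i, j, _ in pairs],
        units_hit_a=hit_a,
        units_hit_b=hit_b,
    )
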