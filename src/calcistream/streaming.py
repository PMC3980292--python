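"""Streaming factorisation core: CCIPCA, convex-cone selection, per-frame loop.

The movie matrix ``A`` (m time points x n pixels) is approximated as
``A_k = T S`` with ``k << m, n``.  Instead of batch PCA, a candid
covariance-free incremental PCA (CCIPCA) maintains the top-k principal
component matrix ``V`` (k x n) one frame at a time:

    V_r <- ((i-1)/i) V_r + (1/i) x (x . V_r / ||V_r||)        (update)
    x   <- x - (x . v_hat) v_hat                              (downdate)

applied in order r = 1..k, where x is the z-scored frame and v_hat the unit
vector of the freshly updated row.  Rows keep an eigenvalue-sized norm.

The convex-cone step then picks ``c`` extreme columns (pixels) of ``V``:
greedily take the column of largest residual norm, orthonormalise it into the
basis, project it out of every column, repeat.  Under the non-negative mixture
model, with a pure pixel present per unit, the extreme columns are exactly the
pure-pixel time series, so the selected pixels land inside the units and the
matching coefficient images ``S`` segment the movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (NormalisationState, RawFrame, spatial_filter,
                         update_normalise, _welford_update)


# ---------------------------------------------------------------------------
# CCIPCA
# ---------------------------------------------------------------------------

@dataclass
class PCMatrix:
    """Incremental principal-component estimate: k unnormalised rows."""

    components: np.ndarray   # k x n; row r is the running estimate V_(r)
    frames_seen: int = 0

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @classmethod
    def empty(cls, k: int, n_pixels: int) -> "PCMatrix":
        return cls(components=np.zeros((k, n_pixels), dtype=np.float64),
                   frames_seen=0)

    def normalised(self) -> np.ndarray:
        """Unit-norm copies of the initialised rows (zero rows stay zero)."""
        V = self.components.copy()
        norms = np.linalg.norm(V, axis=1)
        nz = norms > 0
        V[nz] /= norms[nz, None]
        return V


def update_ipca(V: PCMatrix, frame: np.ndarray, amnesic: float = 0.0,
                copy: bool = True) -> PCMatrix:
    """One CCIPCA step with the (already normalised) frame.

    Row r of V is seeded from the r-th incoming frame's residual after
    downdating against the earlier rows (deterministic, data-driven
    initialisation); from then on it follows the 1/i averaging rule, with an
    optional amnesic weight shifting mass to recent frames (default off).
    The input frame is never modified.
    """
    x = np.asarray(frame, dtype=np.float64).copy()
    if x.shape[0] != V.components.shape[1]:
        raise ValueError("frame length does not match PCMatrix")
    out = PCMatrix(components=V.components.copy(), frames_seen=V.frames_seen) \
        if copy else V
    C = out.components
    i = out.frames_seen + 1
    k = C.shape[0]
    w_old = max((i - 1.0 - amnesic) / i, 0.0)
    w_new = (1.0 + amnesic) / i
    for r in range(min(i, k)):
        if r == i - 1:
            # initialisation: residual of the i-th frame (Gram-Schmidt
            # against rows 0..r-1 has already happened via the downdates)
            nx = np.linalg.norm(x)
            if nx > 0:
                C[r] = x
            else:  # degenerate frame: canonical basis fallback
                C[r] = 0.0
                C[r, r % C.shape[1]] = 1.0
        else:
            nv = np.linalg.norm(C[r])
            if nv == 0.0:
                # dead row: re-seed from the current residual
                nx = np.linalg.norm(x)
                if nx > 0:
                    C[r] = x
                else:
                    C[r, r % C.shape[1]] = 1.0
                nv = np.linalg.norm(C[r])
            proj = np.dot(x, C[r]) / nv
            C[r] *= w_old
            C[r] += (w_new * proj) * x
        # downdate the working frame against the unit vector of row r
        v = C[r]
        nv = np.linalg.norm(v)
        if nv > 0:
            x -= (np.dot(x, v) / (nv * nv)) * v
    out.frames_seen = i
    return out


# ---------------------------------------------------------------------------
# convex cone selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeResult:
    """Greedy extreme-column selection: indices, orthonormal basis, flag."""

    indices: np.ndarray   # selected column indices, in selection order
    basis: np.ndarray     # d x s, orthonormal columns
    complete: bool        # False if fewer than c columns were selectable


def convex_cone(M: np.ndarray, c: int, tol: float = 1e-9,
                on_insufficient: str = "warn") -> ConeResult:
    """Select ``c`` extreme columns of M (d x n) by greedy norm-downdating.

    Each round picks the column of largest residual Euclidean norm (ties go to
    the lowest index), appends its residual direction (unit-normalised,
    re-orthogonalised against the basis) and removes that direction from every
    column.  Downdating with a unit direction is an exact orthogonal
    projection, so the returned basis is orthonormal and residual norms are
    non-increasing across rounds.  Columns whose residual norm falls below
    ``tol`` times the initial maximum are ineligible.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("M must be a 2-D matrix")
    d, n = M.shape
    if c < 1:
        raise ValueError("c must be >= 1")
    sqn = np.einsum("ij,ij->j", M, M)
    max0 = float(np.sqrt(sqn.max())) if n else 0.0
    thresh = (tol * max0) ** 2

    indices: list[int] = []
    Q = np.zeros((d, min(c, d, n)), dtype=np.float64)
    s = 0
    while s < c:
        p = int(np.argmax(sqn))
        if sqn[p] <= thresh or s >= Q.shape[1]:
            msg = (f"only {s} of {c} requested columns have residual norm "
                   f"above tolerance")
            if on_insufficient == "error":
                raise ValueError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            break
        b = M[:, p].copy()
        if s:
            # residual direction of the selected column (orthogonal to the
            # basis, so b . (residual column j) == b . (original column j))
            b -= Q[:, :s] @ (Q[:, :s].T @ b)
            b -= Q[:, :s] @ (Q[:, :s].T @ b)   # second pass for stability
        nb = np.linalg.norm(b)
        if nb <= tol * max(max0, 1e-300):
            sqn[p] = 0.0
            continue
        b /= nb
        proj = b @ M
        sqn -= proj * proj
        np.maximum(sqn, 0.0, out=sqn)
        sqn[p] = 0.0
        Q[:, s] = b
        indices.append(p)
        s += 1
    return ConeResult(indices=np.asarray(indices, dtype=np.int64),
                      basis=Q[:, :s].copy(), complete=(s == c))


def compute_S(M: np.ndarray, basis: np.ndarray, nonneg: str | None = "clip"):
    """Coefficient images ``S = basis.T @ M`` for an orthonormal basis.

    ``nonneg``: None keeps signed projections; ``"clip"`` zeroes negative
    entries (streaming-safe default); ``"nnls"`` refits each pixel by
    non-negative least squares (offline option).
    """
    M = np.asarray(M, dtype=np.float64)
    basis = np.asarray(basis, dtype=np.float64)
    if basis.shape[0] != M.shape[0]:
        raise ValueError("basis and matrix dimensions do not match")
    S = basis.T @ M
    if nonneg is None:
        return S
    if nonneg == "clip":
        return np.maximum(S, 0.0)
    if nonneg == "nnls":
        from scipy.optimize import nnls

        S_out = np.empty_like(S)
        for j in range(M.shape[1]):
            S_out[:, j], _ = nnls(basis, M[:, j])
        return S_out
    raise ValueError(f"unknown nonneg mode {nonneg!r}")


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reconstruction:
    """Low-rank approximation of one frame and its residual norm."""

    frame_hat: np.ndarray
    residual_norm: float


def reconstruct(frame: np.ndarray, S: np.ndarray,
                rcond: float = 1e-10) -> Reconstruction:
    """Project a frame onto the row space of S (pseudoinverse projector).

    Rank-deficient S is handled by discarding singular directions below
    ``rcond`` times the largest singular value; the operation is idempotent
    and non-expansive.
    """
    frame = np.asarray(frame, dtype=np.float64)
    S = np.atleast_2d(np.asarray(S, dtype=np.float64))
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > rcond * (sv[0] if sv.size else 0.0)
    B = Vt[keep]
    hat = B.T @ (B @ frame)
    return Reconstruction(frame_hat=hat,
                          residual_norm=float(np.linalg.norm(frame - hat)))


# ---------------------------------------------------------------------------
# factor model and the per-frame loop
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Selected pixels, their time series T and coefficient images S."""

    selected: np.ndarray            # c pixel indices, selection order
    S: np.ndarray                   # c x n coefficient images
    image_shape: tuple[int, int]
    T: np.ndarray | None = None     # m x c time series of the selected pixels
    basis: np.ndarray | None = None  # orthonormal basis in component space

    @property
    def c(self) -> int:
        return len(self.selected)

    def positions(self) -> np.ndarray:
        """(c, 2) array of (row, col) positions of the selected pixels."""
        w = self.image_shape[1]
        return np.stack([self.selected // w, self.selected % w], axis=1)


@dataclass
class StreamConfig:
    """Configuration of the per-frame pipeline.

    k/c = 50 are the standard settings for antennal-lobe movies; the spatial
    filter width of 9 pixels matches the standard preprocessing.  The cone
    selection is a pure function of V, so ``select_every`` only thins how
    often a model snapshot is produced, never what it contains.
    """

    k: int = 50
    c: int = 50
    spatial_filter_width: int = 9
    sigma_floor: float = 1e-6
    select_every: int = 1
    warmup: int = 2
    nonneg: str | None = "clip"
    amnesic: float = 0.0
    compute_recon: bool = True
    keep_history: bool = True
    history_dtype: type = np.float32
    cone_tol: float = 1e-9


@dataclass
class FrameResult:
    """Outcome of one call to :meth:`StreamProcessor.process_frame`."""

    index: int
    is_warmup: bool
    normalised: np.ndarray
    pcs: PCMatrix
    model: FactorModel | None = None
    recon: Reconstruction | None = None


class StreamProcessor:
    """Per-frame driver: normalise -> update CCIPCA -> select -> reconstruct.

    Processing each frame is a pure function of (state, frame); for a fixed
    input stream and configuration the resulting FactorModel is bit-identical
    between runs (there is no hidden randomness).
    """

    def __init__(self, image_shape, config: StreamConfig | None = None):
        self.image_shape = tuple(image_shape)
        self.config = config or StreamConfig()
        n = self.image_shape[0] * self.image_shape[1]
        self.n_pixels = n
        self.norm_state = NormalisationState.empty(n)
        self.pcs = PCMatrix.empty(self.config.k, n)
        self.frames_processed = 0
        self.history: list[np.ndarray] = []
        self._model: FactorModel | None = None
        self._model_frames = -1

    # -- internals ---------------------------------------------------------
    def _preprocess(self, frame) -> np.ndarray:
        x = frame.pixels if isinstance(frame, RawFrame) else np.asarray(frame)
        x = x.astype(np.float64, copy=False)
        if x.shape[0] != self.n_pixels:
            raise ValueError("frame size does not match processor image shape")
        if self.config.spatial_filter_width > 1:
            x = spatial_filter(x, self.config.spatial_filter_width,
                               image_shape=self.image_shape)
        self._last_filtered = x
        # in-place Welford (the functional update_normalise copies state)
        _welford_update(self.norm_state, x)
        sd = np.maximum(self.norm_state.sigma, self.config.sigma_floor)
        return (x - self.norm_state.mean) / sd

    def _select(self) -> FactorModel:
        cone = convex_cone(self.pcs.components, self.config.c,
                           tol=self.config.cone_tol)
        S = compute_S(self.pcs.components, cone.basis, nonneg=self.config.nonneg)
        model = FactorModel(selected=cone.indices, S=S,
                            image_shape=self.image_shape, basis=cone.basis)
        self._model = model
        self._model_frames = self.frames_processed
        return model

    # -- public API --------------------------------------------------------
    def process_frame(self, frame) -> FrameResult:
        """Run Cone_updating for one frame of the stream."""
        cfg = self.config
        idx = self.frames_processed
        z = self._preprocess(frame)
        self.frames_processed += 1
        if cfg.keep_history:
            # raw (filtered) pixels: post-hoc analyses re-normalise with the
            # *final* statistics, which online z-scores cannot provide
            self.history.append(self._last_filtered.astype(cfg.history_dtype))
        if idx < cfg.warmup:
            return FrameResult(index=idx, is_warmup=True, normalised=z,
                               pcs=self.pcs,
                               recon=Reconstruction(z.copy(), 0.0))
        update_ipca(self.pcs, z, amnesic=cfg.amnesic, copy=False)
        model = None
        recon = None
        if cfg.select_every and (idx % cfg.select_every == 0):
            model = self._select()
            if cfg.compute_recon:
                recon = reconstruct(z, model.S)
        return FrameResult(index=idx, is_warmup=False, normalised=z,
                           pcs=self.pcs, model=model, recon=recon)

    def current_model(self, with_T: bool = True) -> FactorModel:
        """Cone selection on the current V; optionally assemble T from history.

        T columns are the selected pixel series z-scored with the *final*
        running statistics, the best estimate available once the stream has
        been consumed (the per-frame online z-scores are scaled by immature
        statistics early in the stream).
        """
        if self._model is None or self._model_frames != self.frames_processed:
            self._select()
        model = self._model
        assert model is not None
        if with_T and self.history:
            H = np.asarray(self.history)[:, model.selected].astype(np.float64)
            mu = self.norm_state.mean[model.selected]
            sd = np.maximum(self.norm_state.sigma[model.selected],
                            self.config.sigma_floor)
            model.T = (H - mu) / sd
        return model

    def history_matrix(self, normalised: bool = True) -> np.ndarray:
        """The movie seen so far (m x n); by default z-scored with the
        final running statistics."""
        H = np.asarray(self.history)
        if not normalised:
            return H
        sd = np.maximum(self.norm_state.sigma, self.config.sigma_floor)
        return (H - self.norm_state.mean) / sd


def run_stream(movie, image_shape, config: StreamConfig | None = None,
               callback=None) -> tuple[StreamProcessor, FactorModel]:
    """Stream an (m, n) matrix (or frame iterable) through a StreamProcessor.

    ``callback(processor, frame_result)`` runs after every frame (snapshots,
    progress, ...).  Returns the processor and the final FactorModel.
    """
    proc = StreamProcessor(image_shape, config)
    for frame in movie:
        res = proc.process_frame(frame)
        if callback is not None:
            callback(proc, res)
    return proc, proc.current_model(with_T=proc.config.keep_history)
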