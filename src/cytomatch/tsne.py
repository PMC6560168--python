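"""t-SNE embedding: exact reference implementation, approximate backend, sweep.

The exact route implements the standard algorithm in full: per-point Gaussian
bandwidths calibrated by binary search so that the conditional distribution's
perplexity (2^H, H Shannon entropy in bits) hits the target; symmetrised joint
similarities P_ij = (P_{j|i} + P_{i|j}) / 2n; Student-t (df=1) low-dimensional
kernel; gradient descent on the KL divergence with momentum, adaptive gains and
early exaggeration.  It is O(n^2) and capped at desk scale.

The approximate backend delegates to scikit-learn's Barnes-Hut implementation
(the trade-off parameter theta maps to its ``angle``); theta = 0 selects
scikit-learn's exact method.  Both backends return the same result schema so
they are interchangeable downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE as _SkTSNE
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .matrix import CellMatrix

EXACT_CAP_DEFAULT = 5_000

MACHINE_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class EmbeddingParams:
    """t-SNE run parameters (defaults follow common practice for cytometry)."""

    perplexity: float = 30.0
    n_iter: int = 1000
    theta: float = 0.5
    seed: int = 0
    learning_rate: float = 200.0
    early_exaggeration: float = 12.0
    early_exaggeration_iters: int = 250

    def __post_init__(self) -> None:
        if not self.perplexity > 0:
            raise ValueError("perplexity must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.early_exaggeration < 1:
            raise ValueError("early_exaggeration must be >= 1")
        if self.early_exaggeration_iters < 0:
            raise ValueError("early_exaggeration_iters must be >= 0")


@dataclass(frozen=True)
class EmbeddingResult:
    coords: np.ndarray  # (n, 2)
    params: EmbeddingParams
    final_objective: float  # KL(P || Q) at the last iteration

    def __post_init__(self) -> None:
        c = np.asarray(self.coords)
        if c.ndim != 2 or c.shape[1] != 2 or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite (n, 2) matrix")


@dataclass(frozen=True)
class SweepGrid:
    perplexities: tuple[float, ...] = (5.0, 30.0, 100.0)
    n_iters: tuple[int, ...] = (1000, 10000)
    thetas: tuple[float, ...] = (0.2, 0.5, 0.8)
    repeats: int = 1

    def __post_init__(self) -> None:
        if not (self.perplexities and self.n_iters and self.thetas):
            raise ValueError("grid lists must be non-empty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


# ---------------------------------------------------------------------------
# Perplexity calibration


def calibrate_bandwidths(
    distances: np.ndarray,
    perplexity: float,
    tol: float = 1e-5,
    max_steps: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point Gaussian bandwidths matching the target perplexity.

    For each point i a binary search over the precision beta_i = 1/(2 sigma_i^2)
    finds the conditional distribution P_{j|i} ∝ exp(-beta_i d_ij^2) whose
    perplexity 2^H equals the target within ``tol``.  Returns (sigmas,
    conditional matrix); each conditional row sums to 1 and has zero diagonal.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distances must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distances must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distances must have a zero diagonal")
    if not 1 <= perplexity <= n - 1:
        raise ValueError(
            f"perplexity must be in [1, n-1] (got {perplexity} for n={n})"
        )

    d2 = d**2
    P = np.zeros((n, n))
    sigmas = np.empty(n)
    target_h = np.log2(perplexity)
    for i in range(n):
        di = np.delete(d2[i], i)
        beta, row = _search_beta(di, target_h, tol, max_steps, i)
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
        P[i, np.arange(n) != i] = row
    return sigmas, P


def _entropy_and_row(d2: np.ndarray, beta: float) -> tuple[float, np.ndarray]:
    """Shannon entropy (bits) and normalised row for precision beta."""
    logits = -beta * (d2 - d2.min())  # shift for numerical stability
    w = np.exp(logits)
    s = w.sum()
    p = w / s
    nz = p > 0
    h = -np.sum(p[nz] * np.log2(p[nz]))
    return h, p


def _search_beta(d2, target_h, tol, max_steps, index):
    beta, lo, hi = 1.0, 0.0, np.inf
    log2_tol_target = target_h  # entropy target in bits
    for _ in range(max_steps):
        h, row = _entropy_and_row(d2, beta)
        # compare on the perplexity scale, as specified
        if abs(2.0**h - 2.0**log2_tol_target) <= tol:
            return beta, row
        if h > target_h:  # too flat -> increase precision
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (lo + hi)
        else:
            hi = beta
            beta = beta / 2.0 if lo == 0.0 else 0.5 * (lo + hi)
    # A perfectly symmetric neighbourhood can make 2^H constant in beta (e.g.
    # equidistant points, where the conditional is uniform for any sigma); if
    # the achieved perplexity is the best attainable, accept it.
    h, row = _entropy_and_row(d2, beta)
    if abs(2.0**h - 2.0**target_h) <= tol or np.allclose(row, row[0]):
        return beta, row
    raise RuntimeError(
        f"perplexity calibration did not converge for point {index} "
        f"(achieved 2^H={2.0 ** h:.6f})"
    )


def joint_probabilities(conditional: np.ndarray) -> np.ndarray:
    """Symmetrised joint similarities P = (P_c + P_c^T) / (2n), floored."""
    n = conditional.shape[0]
    P = (conditional + conditional.T) / (2.0 * n)
    return np.maximum(P, MACHINE_EPS)


# ---------------------------------------------------------------------------
# Exact gradient descent


def kl_and_grad(Y: np.ndarray, P: np.ndarray) -> tuple[float, np.ndarray]:
    """KL(P || Q) and its analytic gradient for the Student-t kernel.

    grad_i = 4 * sum_j (p_ij - q_ij) * (1 + |y_i - y_j|^2)^-1 * (y_i - y_j)
    """
    n = Y.shape[0]
    dist2 = squareform(pdist(Y, "sqeuclidean"))
    num = 1.0 / (1.0 + dist2)
    np.fill_diagonal(num, 0.0)
    Z = num.sum()
    Q = np.maximum(num / Z, MACHINE_EPS)
    mask = ~np.eye(n, dtype=bool)
    kl = float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))
    PQd = (P - Q) * num
    grad = 4.0 * ((np.diag(PQd.sum(axis=1)) - PQd) @ Y)
    return kl, grad


def exact_tsne(
    x: CellMatrix | np.ndarray,
    params: EmbeddingParams = EmbeddingParams(),
    exact_cap: int = EXACT_CAP_DEFAULT,
) -> EmbeddingResult:
    """Reference exact t-SNE (theta is ignored; O(n^2), capped at desk scale)."""
    X = x.protein_values() if isinstance(x, CellMatrix) else np.asarray(x, float)
    n = X.shape[0]
    if n > exact_cap:
        raise ValueError(
            f"exact t-SNE capped at {exact_cap} events (got {n}); "
            "use the approximate backend"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains NaN or infinite values")
    if params.perplexity >= n:
        raise ValueError("perplexity must be < number of events")

    rng = np.random.default_rng(params.seed)
    d = squareform(pdist(X))
    off_diag = d[~np.eye(n, dtype=bool)]
    if off_diag.size and off_diag.min() == 0.0:
        # duplicate rows: jitter keeps conditional distributions well-defined
        X = X + rng.normal(0.0, 1e-10, size=X.shape)
        d = squareform(pdist(X))
    _, cond = calibrate_bandwidths(d, params.perplexity, tol=1e-5)
    P = joint_probabilities(cond)

    Y = rng.normal(0.0, 1e-4, size=(n, 2))
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    ee_iters = min(params.early_exaggeration_iters, params.n_iter)
    kl = np.inf
    for it in range(params.n_iter):
        Pe = P * params.early_exaggeration if it < ee_iters else P
        kl, grad = kl_and_grad(Y, Pe)
        momentum = 0.5 if it < 250 else 0.8
        gains = np.where(np.sign(grad) != np.sign(update), gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - params.learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    # report the objective of the un-exaggerated problem
    kl, _ = kl_and_grad(Y, P)
    return EmbeddingResult(coords=Y, params=params, final_objective=max(kl, 0.0))


# ---------------------------------------------------------------------------
# Backends


def run_embedding(
    x: CellMatrix | np.ndarray,
    params: EmbeddingParams = EmbeddingParams(),
    backend: str = "approximate",
    exact_cap: int = EXACT_CAP_DEFAULT,
) -> EmbeddingResult:
    """Embed protein channels in 2-D with the chosen backend.

    ``exact`` runs the in-package reference (theta ignored); ``approximate``
    delegates to scikit-learn with ``angle`` = theta (theta = 0 selects its
    exact method).
    """
    X = x.protein_values() if isinstance(x, CellMatrix) else np.asarray(x, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains NaN or infinite values")
    if backend == "exact":
        return exact_tsne(X, params, exact_cap=exact_cap)
    if backend != "approximate":
        raise ValueError(f"unknown backend {backend!r}")
    if params.perplexity >= X.shape[0]:
        raise ValueError("perplexity must be < number of events")
    if params.n_iter < 250:
        raise ValueError(
            "the approximate backend requires n_iter >= 250 "
            "(use the exact backend for shorter runs)"
        )
    kwargs = dict(
        n_components=2,
        perplexity=params.perplexity,
        max_iter=params.n_iter,
        learning_rate=params.learning_rate,
        early_exaggeration=params.early_exaggeration,
        init="random",
        random_state=params.seed % (2**31),
        verbose=0,
    )
    if params.theta == 0.0:
        model = _SkTSNE(method="exact", **kwargs)
    else:
        model = _SkTSNE(method="barnes_hut", angle=params.theta, **kwargs)
    coords = model.fit_transform(X)
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=float),
        params=params,
        final_objective=float(max(model.kl_divergence_, 0.0)),
    )


class TSNEEmbedder(BaseEstimator):
    """sklearn-style wrapper: ``fit_transform(X)`` -> (n, 2) coordinates.

    Fitted attributes: ``embedding_``, ``kl_divergence_``, ``result_``.
    """

    def __init__(
        self,
        perplexity: float = 30.0,
        n_iter: int = 1000,
        theta: float = 0.5,
        random_state: int = 0,
        learning_rate: float = 200.0,
        early_exaggeration: float = 12.0,
        backend: str = "approximate",
        exact_cap: int = EXACT_CAP_DEFAULT,
    ):
        self.perplexity = perplexity
        self.n_iter = n_iter
        self.theta = theta
        self.random_state = random_state
        self.learning_rate = learning_rate
        self.early_exaggeration = early_exaggeration
        self.backend = backend
        self.exact_cap = exact_cap

    def _params(self) -> EmbeddingParams:
        return EmbeddingParams(
            perplexity=self.perplexity,
            n_iter=self.n_iter,
            theta=self.theta,
            seed=self.random_state,
            learning_rate=self.learning_rate,
            early_exaggeration=self.early_exaggeration,
        )

    def fit(self, X, y=None):
        res = run_embedding(X, self._params(), backend=self.backend,
                            exact_cap=self.exact_cap)
        self.result_ = res
        self.embedding_ = res.coords
        self.kl_divergence_ = res.final_objective
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


# ---------------------------------------------------------------------------
# Embedding quality and the parameter sweep


def knn_purity(coords: np.ndarray, labels: np.ndarray, k: int = 1) -> float:
    """Fraction of points whose nearest neighbour(s) share their label."""
    labels = np.asarray(labels)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = labels[idx[:, 1:]]
    return float(np.mean(neigh == labels[:, None]))


def separability_scores(coords: np.ndarray, labels: np.ndarray) -> dict:
    labels = np.asarray(labels)
    out = {"knn_purity": knn_purity(coords, labels)}
    if len(np.unique(labels)) > 1:
        out["silhouette"] = float(silhouette_score(coords, labels))
    else:
        out["silhouette"] = float("nan")
    return out


def parameter_sweep(
    x: CellMatrix | np.ndarray,
    grid: SweepGrid,
    labels: np.ndarray,
    backend: str = "approximate",
    base_params: EmbeddingParams = EmbeddingParams(),
) -> pd.DataFrame:
    """One embedding per grid point per repeat, scored against ``labels``.

    Row seeds are distinct, derived deterministically from the base seed.
    """
    rows = []
    counter = 0
    for perp, n_iter, theta in itertools.product(
        grid.perplexities, grid.n_iters, grid.thetas
    ):
        for rep in range(grid.repeats):
            seed = (base_params.seed + 1_000_003 * counter) % (2**31)
            counter += 1
            params = replace(
                base_params, perplexity=perp, n_iter=n_iter, theta=theta, seed=seed
            )
            try:
                res = run_embedding(x, params, backend=backend)
            except Exception as err:
                raise RuntimeError(
                    f"embedding failed at grid point (perplexity={perp}, "
                    f"n_iter={n_iter}, theta={theta}, repeat={rep})"
                ) from err
            scores = separability_scores(res.coords, labels)
            rows.append(
                {
                    "perplexity": perp,
                    "n_iter": n_iter,
                    "theta": theta,
                    "repeat": rep,
                    "seed": seed,
                    "kl": res.final_objective,
                    "silhouette": scores["silhouette"],
                    "knn_purity": scores["knn_purity"],
                }
            )
    return pd.DataFrame(rows)
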