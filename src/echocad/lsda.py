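"""Locality Sensitive Discriminant Analysis (LSDA).

A supervised graph-embedding linear reduction: k-nearest-neighbour graphs are
split by label agreement into a within-class adjacency Ww and a between-class
adjacency Wb, and projection directions a maximize local between-class
separation while preserving local within-class geometry:

    X^T (alpha * Lb + (1 - alpha) * Ww) X a
        = lambda * (X^T Dw X + ridge * I) a

with Dw the diagonal degree matrix of Ww and Lb = Db - Wb the between-class
graph Laplacian.  The r eigenvectors with the largest eigenvalues form the
projection.  For wide data (d >> n) the problem is solved in the
n-dimensional span of the samples, which is exactly equivalent to the primal
problem restricted to that span.

The estimator follows the scikit-learn transformer API, standardizing
features internally (the stored mean/scale are applied at transform time, so
train/test separation is leakage-free).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted


@dataclass
class NeighborhoodGraphs:
    """Symmetric 0/1 within-class (Ww) and between-class (Wb) kNN adjacencies."""

    Ww: np.ndarray
    Wb: np.ndarray
    k: int


def build_neighborhood_graphs(X: np.ndarray, y, k: int) -> NeighborhoodGraphs:
    """Euclidean kNN per point, edges split by label agreement, OR-symmetrized.

    Ties in distance are broken by ascending sample index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    dist = pairwise_distances(X)
    np.fill_diagonal(dist, np.inf)
    # stable argsort breaks distance ties by index order
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
    same = y[:, None] == y[None, :]
    Ww = np.zeros((n, n), dtype=np.uint8)
    Wb = np.zeros((n, n), dtype=np.uint8)
    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    edge_same = same[rows, cols]
    Ww[rows[edge_same], cols[edge_same]] = 1
    Wb[rows[~edge_same], cols[~edge_same]] = 1
    Ww = np.maximum(Ww, Ww.T)
    Wb = np.maximum(Wb, Wb.T)
    return NeighborhoodGraphs(Ww=Ww, Wb=Wb, k=k)


class LSDA(TransformerMixin, BaseEstimator):
    """Locality sensitive discriminant analysis transformer.

    Parameters
    ----------
    n_components : target dimension r (30 by default).
    n_neighbors : kNN size for the locality graphs.
    alpha : between/within trade-off in [0, 1]; alpha = 1 uses only the
        between-class Laplacian.
    ridge : Tikhonov regularization added to the constraint matrix.
    solver : 'auto' picks the dual (sample-space) path when d > n.
    between : 'laplacian' uses Lb = Db - Wb in the objective; 'adjacency'
        uses Wb directly (a published variant).
    n_pca : dimension of the PCA pre-projection applied when the input is
        overcomplete (more features than samples); default:
        ``n_components``.  With many more
        features than samples the graph eigenproblem otherwise admits
        degenerate directions that collapse each training class to a point
        — perfectly separating the training folds but calibrating any
        downstream threshold on a zero-width class.  Restricting to a PCA
        subspace well below the sample count (standard practice for
        graph-embedding discriminants) removes them.  Set to None to
        disable.

    Attributes
    ----------
    projection_ : (d, r) matrix with orthonormal, sign-fixed columns.
    feature_mean_, feature_scale_ : standardization vectors.
    eigenvalues_ : the r retained generalized eigenvalues, descending.
    """

    def __init__(
        self,
        n_components: int = 30,
        n_neighbors: int = 5,
        alpha: float = 0.5,
        ridge: float = 1e-6,
        solver: str = "auto",
        between: str = "laplacian",
        graphs: NeighborhoodGraphs | None = None,
        n_pca: int | str | None = "n_components",
    ):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.alpha = alpha
        self.ridge = ridge
        self.solver = solver
        self.between = between
        self.graphs = graphs
        self.n_pca = n_pca

    # -- fitting -----------------------------------------------------------

    def _objective_matrices(self, y) -> tuple[np.ndarray, np.ndarray]:
        graphs = self.graphs
        if graphs is None:
            graphs = build_neighborhood_graphs(self._Xs, y, self.n_neighbors)
        Ww = graphs.Ww.astype(float)
        Wb = graphs.Wb.astype(float)
        Dw = np.diag(Ww.sum(axis=1))
        if self.between == "laplacian":
            B = np.diag(Wb.sum(axis=1)) - Wb
        elif self.between == "adjacency":
            B = Wb
        else:
            raise ValueError("between must be 'laplacian' or 'adjacency'")
        M = self.alpha * B + (1.0 - self.alpha) * Ww
        return M, Dw

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        n, d = X.shape
        if np.unique(y).size < 2:
            raise ValueError("at least two classes are required")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

        self.feature_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        self.feature_scale_ = scale
        Xs = (X - self.feature_mean_) / self.feature_scale_

        n_pca = self.n_components if self.n_pca == "n_components" else self.n_pca
        basis = None
        # only the overcomplete regime (d >= n) admits degenerate
        # class-collapse directions; well-posed inputs are left untouched
        if n_pca is not None and d >= n and d > n_pca:
            basis = PCA(
                n_components=min(n_pca, n - 1), svd_solver="full"
            ).fit(Xs).components_.T  # d x k, orthonormal columns
            Xs = Xs @ basis
            d = Xs.shape[1]
        self._Xs = Xs

        M, Dw = self._objective_matrices(y)

        r_max = min(d, n - 1)
        r = min(self.n_components, r_max)
        if r < self.n_components:
            warnings.warn(
                f"n_components={self.n_components} capped to {r} "
                f"(min(n_features, n_samples - 1))"
            )

        solver = self.solver
        if solver == "auto":
            solver = "dual" if d > n else "primal"
        if solver == "primal":
            A = Xs.T @ M @ Xs
            Bc = Xs.T @ Dw @ Xs + self.ridge * np.eye(d)
            try:
                vals, vecs = scipy.linalg.eigh(A, Bc)
            except scipy.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "singular constraint matrix; set ridge > 0"
                ) from err
            proj = vecs[:, ::-1][:, :r]
            vals = vals[::-1][:r]
        elif solver == "dual":
            # restrict to the span of the samples: a = Xs^T U S^{-1/2} v
            G = Xs @ Xs.T
            gvals, gvecs = scipy.linalg.eigh(G)
            keep = gvals > max(1e-10 * gvals.max(), 0.0)
            if self.ridge <= 0 and keep.sum() < n:
                raise np.linalg.LinAlgError(
                    "singular constraint matrix; set ridge > 0"
                )
            U = gvecs[:, keep]
            S = gvals[keep]
            P = U * (S**0.5)  # n x rank, columns scaled
            A = P.T @ M @ P
            Bc = P.T @ Dw @ P + self.ridge * np.eye(P.shape[1])
            vals, vecs = scipy.linalg.eigh(A, Bc)
            order = np.argsort(vals)[::-1][:r]
            vals = vals[order]
            back = U * (S**-0.5)
            proj = Xs.T @ (back @ vecs[:, order])
        else:
            raise ValueError("solver must be 'auto', 'primal' or 'dual'")

        if basis is not None:
            proj = basis @ proj  # back to the original feature space
        # orthonormalize (QR keeps the leading directions) and fix signs
        q, _ = np.linalg.qr(proj)
        signs = np.sign(q[np.argmax(np.abs(q), axis=0), np.arange(q.shape[1])])
        signs[signs == 0] = 1.0
        self.projection_ = q * signs
        self.eigenvalues_ = vals
        self.n_components_ = self.projection_.shape[1]
        self.n_features_in_ = X.shape[1]
        del self._Xs
        return self

    # -- transforming ------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "projection_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} features, "
                f"model expects {self.n_features_in_}"
            )
        Xs = (X - self.feature_mean_) / self.feature_scale_
        return Xs @ self.projection_

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """JSON manifest + binary matrix payload; round-trips bit-exactly."""
        check_is_fitted(self, "projection_")
        path = Path(path)
        manifest = {
            "params": {
                k: v for k, v in self.get_params().items() if k != "graphs"
            },
            "n_features_in": int(self.n_features_in_),
            "n_components_fitted": int(self.n_components_),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
        np.savez(
            path.with_suffix(".npz"),
            projection=self.projection_,
            feature_mean=self.feature_mean_,
            feature_scale=self.feature_scale_,
            eigenvalues=self.eigenvalues_,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSDA":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        model = cls(**manifest["params"])
        data = np.load(path.with_suffix(".npz"))
        model.projection_ = data["projection"]
        model.feature_mean_ = data["feature_mean"]
        model.feature_scale_ = data["feature_scale"]
        model.eigenvalues_ = data["eigenvalues"]
        model.n_features_in_ = manifest["n_features_in"]
        model.n_components_ = manifest["n_components_fitted"]
        return model


def lsda_fit(
    X,
    y,
    r: int = 30,
    k: int = 5,
    alpha: float = 0.5,
    ridge: float = 1e-6,
    **kwargs,
) -> LSDA:
    """Fit an LSDA model (thin wrapper over the estimator)."""
    return LSDA(
        n_components=r, n_neighbors=k, alpha=alpha, ridge=ridge, **kwargs
    ).fit(X, y)


def lsda_transform(model: LSDA, X) -> np.ndarray:
    """Project data with a fitted model."""
    return model.transform(X)
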