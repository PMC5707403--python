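"""Latent-variable models: NIPALS PCA, NIPALS PLS2, post-transformation, VIP.

The discriminant machinery of the pipeline. PLS2 regresses the spectral
block X on a multi-column design response Y (class contrast plus time).
The fitted latent space is then rotated ("post-transformed") into a
predictive part tp, which carries all the Y-related variation, and
orthogonal parts to1, to2, ... which carry none; the rotation leaves the
model's predictions unchanged, so interpretation improves at no cost in
fit. Variable importance is summarised by VIP scores, whose squares
average to one over variables.

Models follow the Model -> Results convention: construct with data, call
``fit()``, and read estimates off the results object.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PCA", "PCAResults", "PLS2", "PLS2Results", "PtPLS2Results", "build_design_matrix"]

_MAX_ITER = 10000
_CONV_TOL = 1e-10
# power iteration stalls when leading eigenvalues are close: the per-step
# score change then underestimates the remaining error, so PCA gets a much
# tighter stop and a larger iteration budget than PLS
_PCA_MAX_ITER = 20000
_PCA_CONV_TOL = 1e-14


def _sign_align(w: np.ndarray) -> float:
    """Sign convention: flip so the first nonzero loading element is positive."""
    nz = np.flatnonzero(np.abs(w) > 1e-14)
    if nz.size and w[nz[0]] < 0:
        return -1.0
    return 1.0


def build_design_matrix(
    groups: "pd.Series | np.ndarray | list",
    time: "pd.Series | np.ndarray | list | None" = None,
    positive_class: str | None = None,
) -> pd.DataFrame:
    """Encode a two-class contrast (+1/-1) with an optional centered time column.

    The class column is +1 for ``positive_class`` (default: first label in
    sorted order) and -1 otherwise. Time, when given, is appended centered.
    """
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 class labels, got {labels}")
    pos = positive_class if positive_class is not None else labels[0]
    if pos not in labels:
        raise ValueError(f"positive_class {pos!r} not among {labels}")
    cols = {"class": np.where(g == pos, 1.0, -1.0)}
    if time is not None:
        t = np.asarray(time, dtype=float)
        cols["time"] = t - t.mean()
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# PCA


class PCA:
    """NIPALS principal component analysis of a scaled matrix.

    Parameters
    ----------
    X : (n, p) matrix, already centered/scaled as desired.
    n_components : number of components to extract; reduced with a warning
        if it exceeds the matrix rank.
    """

    def __init__(self, X: np.ndarray, n_components: int):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        max_a = min(self.X.shape[0] - 1, self.X.shape[1])
        if n_components < 1 or n_components > max_a:
            raise ValueError(f"n_components must be in [1, {max_a}]")
        self.n_components = int(n_components)

    def fit(self) -> "PCAResults":
        E = self.X.copy()
        total_ss = float((self.X**2).sum())
        if total_ss == 0:
            raise ValueError("X is identically zero")
        scores, loadings, evr = [], [], []
        for a in range(self.n_components):
            col_ss = (E**2).sum(axis=0)
            if col_ss.max() <= total_ss * 1e-14:
                warnings.warn(
                    f"rank exhausted: returning {a} of {self.n_components} components",
                    stacklevel=2,
                )
                break
            t = E[:, int(np.argmax(col_ss))].copy()
            for _ in range(_PCA_MAX_ITER):
                p = E.T @ t / (t @ t)
                p /= np.linalg.norm(p)
                t_new = E @ p
                if np.linalg.norm(t_new - t) <= _PCA_CONV_TOL * max(np.linalg.norm(t_new), 1e-300):
                    t = t_new
                    break
                t = t_new
            s = _sign_align(p)
            p, t = s * p, s * t
            E = E - np.outer(t, p)
            scores.append(t)
            loadings.append(p)
            evr.append(float(t @ t) / total_ss)
        return PCAResults(
            model=self,
            scores=np.column_stack(scores),
            loadings=np.column_stack(loadings),
            explained_variance_ratio=np.array(evr),
        )


@dataclass
class PCAResults:
    model: PCA
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A), orthonormal columns
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def summary(self) -> str:
        lines = ["NIPALS PCA", f"  n = {self.model.X.shape[0]}, p = {self.model.X.shape[1]}"]
        cum = 0.0
        for a, f in enumerate(self.explained_variance_ratio, 1):
            cum += f
            lines.append(f"  PC{a}: explained variance {f:.3f} (cumulative {cum:.3f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PLS2


class PLS2:
    """NIPALS PLS2 regression of Y (design matrix) on X.

    Both blocks are taken as provided (scale beforehand; see
    :mod:`arrestomix.preprocessing`). X is deflated per component, Y is not
    (the standard PLS2 NIPALS variant); the coefficient matrix B satisfies
    Yhat = X @ B.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray, n_components: int):
        self.X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self.Y = Y.reshape(-1, 1) if Y.ndim == 1 else Y
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if np.any(self.Y.std(axis=0) == 0):
            raise ValueError("constant Y column: cannot drive PLS regression")
        self.n_components = int(n_components)

    def fit(self) -> "PLS2Results":
        X, Y = self.X, self.Y
        n, p = X.shape
        q = Y.shape[1]
        A = self.n_components
        E = X.copy()
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((q, A))
        T = np.zeros((n, A))
        for a in range(A):
            u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
            t = np.zeros(n)
            converged = False
            for _ in range(_MAX_ITER):
                w = E.T @ u / (u @ u)
                nw = np.linalg.norm(w)
                if nw <= 1e-300:
                    raise ValueError(f"NIPALS breakdown at component {a + 1} (zero weight)")
                w /= nw
                t_new = E @ w
                qv = Y.T @ t_new / (t_new @ t_new)
                u = Y @ qv / (qv @ qv)
                if np.linalg.norm(t_new - t) <= _CONV_TOL * max(np.linalg.norm(t_new), 1e-300):
                    t = t_new
                    converged = True
                    break
                t = t_new
            if not converged:
                raise ValueError(f"NIPALS did not converge for component {a + 1}")
            s = _sign_align(w)
            w, t, qv = s * w, s * t, s * qv
            pv = E.T @ t / (t @ t)
            E = E - np.outer(t, pv)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
        # rotated weights: T = X @ x_rotations for the original (undeflated) X
        x_rotations = W @ np.linalg.pinv(P.T @ W)
        coef = x_rotations @ Q.T
        fitted = X @ coef
        ss_tot = float((Y**2).sum())
        r2y = 1.0 - float(((Y - fitted) ** 2).sum()) / ss_tot
        return PLS2Results(
            model=self,
            x_weights=W,
            x_loadings=P,
            y_loadings=Q,
            scores=T,
            x_rotations=x_rotations,
            coef=coef,
            fitted_values=fitted,
            r2y=r2y,
        )


@dataclass
class PLS2Results:
    model: PLS2
    x_weights: np.ndarray  # W (p, A)
    x_loadings: np.ndarray  # P (p, A)
    y_loadings: np.ndarray  # Q (q, A)
    scores: np.ndarray  # T (n, A)
    x_rotations: np.ndarray  # W* (p, A)
    coef: np.ndarray  # B (p, q)
    fitted_values: np.ndarray
    r2y: float

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict Y for new (identically scaled) X, optionally truncating components."""
        X = np.asarray(X, dtype=float)
        a = self.n_components if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components:
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        if a == self.n_components:
            return X @ self.coef
        W, P, Q = self.x_weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:, :a]
        coef_a = W @ np.linalg.pinv(P.T @ W) @ Q.T
        return X @ coef_a

    def vip(self) -> np.ndarray:
        """Variable Influence on Projection.

        VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
        with SSY_a the Y sum of squares explained by component a. The mean
        of the squared entries is exactly 1.
        """
        W, Q, T = self.x_weights, self.y_loadings, self.scores
        p = W.shape[0]
        ssy = np.array([(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(self.n_components)])
        if ssy.sum() <= 0:
            raise ValueError("zero explained Y sum of squares: VIP undefined")
        wn = W / np.linalg.norm(W, axis=0, keepdims=True)
        return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())

    def post_transform(
        self, rank_tol: float = 1e-8, n_predictive: int | None = None
    ) -> "PtPLS2Results":
        """Rotate the latent space into predictive and orthogonal parts.

        The orthogonal rotation G comes from the SVD of T'Y: left singular
        vectors with nonzero singular value span the predictive subspace,
        the remainder the orthogonal one. Predictions are invariant; every
        orthogonal score column is uncorrelated with every fitted-Y column.
        ``n_predictive`` can be forced (e.g. to drop a response direction
        judged non-significant); by default it is the numerical rank of T'Y
        at ``rank_tol`` relative to the largest singular value.
        """
        T, Y = self.scores, self.model.Y
        M = T.T @ Y  # (A, q)
        G, sv, _ = np.linalg.svd(M, full_matrices=True)
        if sv.size == 0 or sv[0] <= 0:
            raise ValueError("degenerate Y: T'Y has no nonzero singular value")
        if n_predictive is None:
            n_pred = int(np.sum(sv > rank_tol * sv[0]))
        else:
            n_pred = int(n_predictive)
            if not 1 <= n_pred <= self.n_components:
                raise ValueError(f"n_predictive must be in [1, {self.n_components}]")
        rotated = T @ G
        return PtPLS2Results(
            parent=self,
            rotation=G,
            n_predictive=n_pred,
            predictive_scores=rotated[:, :n_pred],
            orthogonal_scores=rotated[:, n_pred:],
            singular_values=sv,
        )

    def summary(self) -> str:
        n, p = self.model.X.shape
        return "\n".join(
            [
                "NIPALS PLS2",
                f"  n = {n}, p = {p}, responses = {self.model.Y.shape[1]}",
                f"  components A = {self.n_components}",
                f"  R2Y = {self.r2y:.4f}",
            ]
        )


@dataclass
class PtPLS2Results:
    """Post-transformed PLS2: same predictions, interpretable score split.

    ``predictive_scores`` (tp axes) carry all response-related variation;
    ``orthogonal_scores`` (to1, to2, ...) are uncorrelated with the fitted
    response. The component structure is reported as "A = n_pred + n_orth".
    """

    parent: PLS2Results
    rotation: np.ndarray  # G (A, A), orthogonal
    n_predictive: int
    predictive_scores: np.ndarray
    orthogonal_scores: np.ndarray
    singular_values: np.ndarray = field(repr=False)

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_scores.shape[1]

    @property
    def components_label(self) -> str:
        return f"A = {self.n_predictive} + {self.n_orthogonal}"

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        return self.parent.predict(X, n_components=n_components)

    @property
    def fitted_values(self) -> np.ndarray:
        # reconstruct through the rotated representation: T Q' = (T G)(Q G)'
        Q_rot = self.parent.y_loadings @ self.rotation
        T_rot = np.column_stack([self.predictive_scores, self.orthogonal_scores])
        return T_rot @ Q_rot.T

    def score_table(self) -> pd.DataFrame:
        cols = {f"tp{i + 1}": self.predictive_scores[:, i] for i in range(self.n_predictive)}
        cols.update(
            {f"to{i + 1}": self.orthogonal_scores[:, i] for i in range(self.n_orthogonal)}
        )
        return pd.DataFrame(cols)

    def summary(self) -> str:
        return "\n".join(
            [
                "ptPLS2 (post-transformed PLS2)",
                f"  {self.components_label} components",
                f"  R2Y = {self.parent.r2y:.4f} (invariant under post-transformation)",
            ]
        )
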