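"""Resampling-based model validation and variable selection.

Everything a latent model's quoted statistic rests on: cross-validated Q2
(with scaling re-estimated on each training fold so no information leaks
into the held-out fold), response-permutation tests with the add-one
p-value, component-count selection, Q2-maximizing VIP variable selection,
and Monte-Carlo stability selection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .latent import PLS2
from .preprocessing import Scaler

__all__ = [
    "ValidationReport",
    "StabilitySelectionResult",
    "make_folds",
    "cross_validate_q2",
    "select_components",
    "permutation_test",
    "vip_select",
    "stability_selection",
    "validate",
]


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y.reshape(-1, 1) if Y.ndim == 1 else Y


def _scaled(X: np.ndarray, method: str | None) -> tuple[np.ndarray, Scaler | None]:
    if method is None:
        return np.asarray(X, dtype=float), None
    s = Scaler(method).fit(X)
    return s.transform(X), s


@dataclass
class ValidationReport:
    """Fit and resampling statistics for one latent model."""

    r2: float
    q2: float
    n_components: int
    fold_scheme: str
    n_folds: int
    permutation_p_r2: float | None = None
    permutation_p_q2: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    q2_per_component: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Model validation",
            f"  A = {self.n_components} components, {self.n_folds}-fold CV ({self.fold_scheme})",
            f"  R2 = {self.r2:.4f}",
            f"  Q2 = {self.q2:.4f}",
        ]
        if self.n_permutations:
            lines.append(
                f"  permutation test ({self.n_permutations} permutations, seed {self.seed}): "
                f"p(R2) = {self.permutation_p_r2:.4g}, p(Q2) = {self.permutation_p_q2:.4g}"
            )
        return "\n".join(lines)


@dataclass
class StabilitySelectionResult:
    selection_frequency: np.ndarray
    n_subsets: int
    inclusion_probability: float
    vip_threshold: float
    stability_threshold: float
    seed: int

    @property
    def stable_set(self) -> np.ndarray:
        return np.flatnonzero(self.selection_frequency >= self.stability_threshold)


def make_folds(
    n: int, n_folds: int, scheme: str = "interleaved", group_ids=None
) -> list[np.ndarray]:
    """Deterministic fold assignment.

    ``interleaved`` ("venetian blind"): sample i goes to fold i mod n_folds.
    ``grouped``: whole groups (animals) are assigned round-robin, in order
    of first appearance, so repeated measures never straddle folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if scheme == "interleaved":
        assign = np.arange(n) % n_folds
    elif scheme == "grouped":
        if group_ids is None:
            raise ValueError("grouped scheme requires group_ids")
        gids = np.asarray(group_ids)
        uniq = list(dict.fromkeys(gids.tolist()))  # first-appearance order
        fold_of = {g: i % n_folds for i, g in enumerate(uniq)}
        assign = np.array([fold_of[g] for g in gids])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    folds = [np.flatnonzero(assign == k) for k in range(n_folds)]
    folds = [f for f in folds if f.size]
    if any(f.size < 2 for f in folds):
        raise ValueError("a fold has fewer than 2 samples; reduce n_folds")
    return folds


def cross_validate_q2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_folds: int = 7,
    scheme: str = "interleaved",
    group_ids=None,
    x_scaling: str | None = "pareto",
    y_scaling: str | None = "mean_center",
) -> np.ndarray:
    """Cumulative Q2 per component from n-fold full cross-validation.

    Q2(a) = 1 - PRESS(a)/SS_tot. X and Y scaling is re-estimated on each
    training fold and applied to the held-out fold (no leakage); SS_tot is
    the held-out sum of squares about the training-fold mean.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    folds = make_folds(X.shape[0], n_folds, scheme, group_ids)
    press = np.zeros(n_components)
    ss_tot = 0.0
    for test_idx in folds:
        train = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        if train.size < 2:
            raise ValueError("training fold has fewer than 2 samples")
        Xtr, xs = _scaled(X[train], x_scaling)
        Ytr, ys = _scaled(Y[train], y_scaling)
        Xte = xs.transform(X[test_idx]) if xs else X[test_idx]
        Yte = ys.transform(Y[test_idx]) if ys else Y[test_idx]
        res = PLS2(Xtr, Ytr, n_components).fit()
        ss_tot += float((Yte**2).sum())
        for a in range(1, n_components + 1):
            press[a - 1] += float(((Yte - res.predict(Xte, n_components=a)) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("zero held-out sum of squares")
    return 1.0 - press / ss_tot


def select_components(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int,
    n_folds: int = 7,
    min_increment: float = 0.01,
    **cv_kwargs,
) -> tuple[int, np.ndarray]:
    """Pick the component count: add a component only while Q2 improves.

    Returns (A, Q2 trace). A component a+1 is accepted only if
    Q2(a+1) > Q2(a) + ``min_increment``; the floor is A = 1 (flagged by a
    warning when even the first component has Q2 <= 0).
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    q2 = cross_validate_q2(X, Y, max_components, n_folds=n_folds, **cv_kwargs)
    a = 1
    while a < max_components and q2[a] > q2[a - 1] + min_increment:
        a += 1
    if q2[0] <= 0 and a == 1:
        warnings.warn("no predictive ability: Q2 <= 0 at A = 1", stacklevel=2)
    return a, q2


def _r2_of_fit(X, Y, n_components, x_scaling, y_scaling) -> float:
    Xs, _ = _scaled(X, x_scaling)
    Ys, _ = _scaled(Y, y_scaling)
    return PLS2(Xs, Ys, n_components).fit().r2y


def _permute_rows(Y: np.ndarray, rng: np.random.Generator, group_ids) -> np.ndarray:
    if group_ids is None:
        return Y[rng.permutation(Y.shape[0])]
    # animal-level permutation: whole blocks of rows are exchanged between
    # animals, preserving the within-animal time structure
    gids = np.asarray(group_ids)
    uniq = list(dict.fromkeys(gids.tolist()))
    blocks = [np.flatnonzero(gids == g) for g in uniq]
    sizes = {b.size for b in blocks}
    if len(sizes) != 1:
        raise ValueError(
            "group-level permutation requires equal sample counts per group"
        )
    order = rng.permutation(len(blocks))
    out = np.empty_like(Y)
    for dest, src in zip(blocks, [blocks[i] for i in order]):
        out[dest] = Y[src]
    return out


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_permutations: int = 1000,
    seed: int = 0,
    statistics: tuple[str, ...] = ("R2", "Q2"),
    n_folds: int = 7,
    scheme: str = "interleaved",
    group_ids=None,
    x_scaling: str | None = "pareto",
    y_scaling: str | None = "mean_center",
) -> dict:
    """Response-permutation test of a PLS2 model.

    Rows of Y are permuted jointly (X untouched, preserving its covariance
    structure), the statistic recomputed per permutation, and
    p = (1 + #{null >= observed}) / (1 + n_permutations), so the smallest
    attainable p is 1/(n_permutations + 1). When ``group_ids`` is given,
    permutation exchanges whole animals' response blocks instead of
    individual samples.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    rng = np.random.default_rng(seed)
    want_q2 = "Q2" in statistics
    want_r2 = "R2" in statistics

    def stat(Yv):
        out = {}
        if want_r2:
            out["R2"] = _r2_of_fit(X, Yv, n_components, x_scaling, y_scaling)
        if want_q2:
            out["Q2"] = cross_validate_q2(
                X, Yv, n_components, n_folds=n_folds, scheme=scheme,
                x_scaling=x_scaling, y_scaling=y_scaling,
            )[-1]
        return out

    observed = stat(Y)
    null = {k: np.empty(n_permutations) for k in observed}
    for b in range(n_permutations):
        Yp = _permute_rows(Y, rng, group_ids)
        sb = stat(Yp)
        for k in observed:
            null[k][b] = sb[k]
    result = {"observed": observed, "null": null, "n_permutations": n_permutations, "seed": seed}
    for k in observed:
        result[f"p_{k}"] = (1.0 + np.sum(null[k] >= observed[k])) / (1.0 + n_permutations)
    return result


def vip_select(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_folds: int = 7,
    thresholds: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2),
    x_scaling: str | None = "pareto",
    y_scaling: str | None = "mean_center",
    **cv_kwargs,
) -> tuple[np.ndarray, list[dict]]:
    """Q2-maximizing VIP variable selection.

    Sweeps VIP thresholds: for each, variables with full-model VIP below
    the threshold are dropped, the model is refit and re-cross-validated.
    Returns (selected variable indices, trace). The full variable set is
    always a candidate, so the selected subset's Q2 never falls below the
    full model's.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    Xs, _ = _scaled(X, x_scaling)
    Ys, _ = _scaled(Y, y_scaling)
    vip = PLS2(Xs, Ys, n_components).fit().vip()

    def q2_of(idx):
        a = min(n_components, idx.size)
        return cross_validate_q2(
            X[:, idx], Y, a, n_folds=n_folds,
            x_scaling=x_scaling, y_scaling=y_scaling, **cv_kwargs,
        )[-1]

    all_idx = np.arange(X.shape[1])
    trace = [{"threshold": None, "kept": all_idx, "q2": q2_of(all_idx)}]
    for thr in thresholds:
        kept = np.flatnonzero(vip >= thr)
        if kept.size == 0:
            warnings.warn(f"threshold {thr} eliminates all variables; skipped", stacklevel=2)
            continue
        trace.append({"threshold": thr, "kept": kept, "q2": q2_of(kept)})
    best = max(trace, key=lambda r: r["q2"])
    return best["kept"], trace


def stability_selection(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_subsets: int = 50,
    inclusion_probability: float = 0.70,
    vip_threshold: float = 1.0,
    seed: int = 0,
    stability_threshold: float = 0.8,
    x_scaling: str | None = "pareto",
    y_scaling: str | None = "mean_center",
) -> StabilitySelectionResult:
    """Monte-Carlo stability selection with PLS-VIP scoring.

    Each of ``n_subsets`` subsets includes every sample independently with
    probability ``inclusion_probability``; a PLS model is fitted per subset
    and a variable counts as selected when its VIP exceeds
    ``vip_threshold``. The selection frequency over subsets measures how
    stably a variable matters.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if not 0 < inclusion_probability < 1:
        raise ValueError("inclusion_probability must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    rng = np.random.default_rng(seed)
    counts = np.zeros(X.shape[1])
    min_n = n_components + 2
    for _ in range(n_subsets):
        for attempt in range(11):
            mask = rng.random(X.shape[0]) < inclusion_probability
            if mask.sum() >= min_n and np.all(Y[mask].std(axis=0) > 0):
                break
            warnings.warn("degenerate subset redrawn", stacklevel=2)
        else:
            raise ValueError("could not draw a usable subset in 10 redraws")
        Xs, _ = _scaled(X[mask], x_scaling)
        Ys, _ = _scaled(Y[mask], y_scaling)
        vip = PLS2(Xs, Ys, n_components).fit().vip()
        counts += vip > vip_threshold
    return StabilitySelectionResult(
        selection_frequency=counts / n_subsets,
        n_subsets=n_subsets,
        inclusion_probability=inclusion_probability,
        vip_threshold=vip_threshold,
        stability_threshold=stability_threshold,
        seed=seed,
    )


def validate(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_folds: int = 7,
    scheme: str = "interleaved",
    n_permutations: int = 0,
    seed: int = 0,
    group_ids=None,
    x_scaling: str | None = "pareto",
    y_scaling: str | None = "mean_center",
) -> ValidationReport:
    """One-stop validation: R2, Q2, and (optionally) permutation p-values."""
    r2 = _r2_of_fit(X, Y, n_components, x_scaling, y_scaling)
    q2_trace = cross_validate_q2(
        X, Y, n_components, n_folds=n_folds, scheme=scheme, group_ids=group_ids,
        x_scaling=x_scaling, y_scaling=y_scaling,
    )
    report = ValidationReport(
        r2=r2,
        q2=float(q2_trace[-1]),
        n_components=n_components,
        fold_scheme=scheme,
        n_folds=n_folds,
        q2_per_component=q2_trace,
        seed=seed,
    )
    if n_permutations:
        perm = permutation_test(
            X, Y, n_components, n_permutations=n_permutations, seed=seed,
            n_folds=n_folds, scheme=scheme, group_ids=group_ids,
            x_scaling=x_scaling, y_scaling=y_scaling,
        )
        report.permutation_p_r2 = perm["p_R2"]
        report.permutation_p_q2 = perm["p_Q2"]
        report.n_permutations = n_permutations
    return report
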