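"""Spectral preprocessing: binning, normalization, and scaling.

Raw 1H NMR traces (intensity vs chemical shift in ppm) are reduced to
fixed-width bins by trapezoidal integration, rows are normalized to a
constant sum so that spectra with different overall concentration become
comparable, and columns are mean-centered / Pareto-scaled before latent
modelling.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RawSpectraSet",
    "SpectraMatrix",
    "Scaler",
    "bin_spectra",
    "remove_bins",
    "normalize_constant_sum",
    "scale",
]


@dataclass
class RawSpectraSet:
    """A set of raw intensity-vs-ppm traces on a common axis.

    Parameters
    ----------
    ppm : (n_points,) strictly monotone chemical-shift axis.
    intensities : (n_samples, n_points) intensity matrix, finite.
    sample_ids : sample identifiers, one per row.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        d = np.diff(self.ppm)
        if self.ppm.ndim != 1 or len(self.ppm) < 2 or not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be a strictly monotone 1-D vector")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.shape != (len(self.sample_ids), len(self.ppm)):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.ppm)} ppm points"
            )
        # store with ascending axis internally
        if d[0] < 0:
            self.ppm = self.ppm[::-1]
            self.intensities = self.intensities[:, ::-1]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]


@dataclass
class SpectraMatrix:
    """Binned spectra: the X block consumed by the multivariate models.

    ``data`` is a samples x bins DataFrame whose columns are labelled by the
    ppm bin center. ``bin_edges`` lists the (lo, hi) interval of each
    surviving bin; bins are half-open [lo, hi) except the last, which is
    closed.
    """

    data: pd.DataFrame
    bin_edges: list[tuple[float, float]]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    normalization: str = "none"
    scaling: str = "none"

    def __post_init__(self) -> None:
        if len(self.bin_edges) != self.data.shape[1]:
            raise ValueError("bin_edges must have one entry per column")
        widths = [hi - lo for lo, hi in self.bin_edges]
        if widths and (max(widths) - min(widths)) > 1e-9:
            raise ValueError("bin widths must be constant")
        for lo, hi in self.bin_edges:
            for a, b in self.excluded_regions:
                if lo < b - 1e-12 and hi > a + 1e-12:
                    raise ValueError(f"bin [{lo}, {hi}) intersects excluded region [{a}, {b}]")

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def bin_centers(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.bin_edges])


def bin_spectra(
    raw: RawSpectraSet,
    ppm_min: float,
    ppm_max: float,
    width: float,
    exclusions: list[tuple[float, float]] | None = None,
) -> SpectraMatrix:
    """Reduce raw spectra to fixed-width bins by trapezoidal integration.

    The bin value is the trapezoidal integral of the intensity over
    [lo, hi). Bins fully inside an exclusion interval are dropped, and a bin
    that straddles an exclusion boundary is dropped as well (conservative:
    partially contaminated bins never survive).
    """
    if ppm_min >= ppm_max:
        raise ValueError("ppm_min must be < ppm_max")
    if width <= 0:
        raise ValueError("bin width must be positive")
    exclusions = [tuple(sorted(e)) for e in (exclusions or [])]
    for a, b in exclusions:
        if a < ppm_min - 1e-12 or b > ppm_max + 1e-12:
            raise ValueError(f"exclusion [{a}, {b}] outside binning range")
    if raw.ppm[0] > ppm_min + 1e-9 or raw.ppm[-1] < ppm_max - 1e-9:
        raise ValueError(
            f"ppm axis [{raw.ppm[0]:.3f}, {raw.ppm[-1]:.3f}] does not cover "
            f"requested range [{ppm_min}, {ppm_max}]"
        )

    n_bins = int(round((ppm_max - ppm_min) / width))
    edges = ppm_min + width * np.arange(n_bins + 1)

    # cumulative trapezoid on a refined axis that contains every bin edge,
    # so bin integrals are exact differences of the cumulative integral
    axis = np.union1d(raw.ppm, edges)
    axis = axis[(axis >= raw.ppm[0]) & (axis <= raw.ppm[-1])]
    Y = np.empty((raw.n_samples, len(axis)))
    for i in range(raw.n_samples):
        Y[i] = np.interp(axis, raw.ppm, raw.intensities[i])
    from scipy.integrate import cumulative_trapezoid

    C = cumulative_trapezoid(Y, axis, axis=1, initial=0.0)
    edge_idx = np.searchsorted(axis, edges)
    vals = C[:, edge_idx[1:]] - C[:, edge_idx[:-1]]

    keep = np.ones(n_bins, dtype=bool)
    for a, b in exclusions:
        lo, hi = edges[:-1], edges[1:]
        overlaps = (lo < b - 1e-12) & (hi > a + 1e-12)
        keep &= ~overlaps
    if not keep.any():
        raise ValueError("no bins survive the exclusion regions")

    kept_edges = [(float(edges[j]), float(edges[j + 1])) for j in np.flatnonzero(keep)]
    centers = [f"{(lo + hi) / 2:.4f}" for lo, hi in kept_edges]
    df = pd.DataFrame(vals[:, keep], index=raw.sample_ids, columns=centers)
    return SpectraMatrix(df, kept_edges, excluded_regions=list(exclusions))


def remove_bins(matrix: SpectraMatrix, regions: list[tuple[float, float]]) -> SpectraMatrix:
    """Drop bins overlapping any of the given ppm regions (e.g. drug signals)."""
    if not regions:
        return matrix
    regions = [tuple(sorted(r)) for r in regions]
    keep = []
    removed = []
    for j, (lo, hi) in enumerate(matrix.bin_edges):
        hit = any(lo < b - 1e-12 and hi > a + 1e-12 for a, b in regions)
        (removed if hit else keep).append(j)
    if removed:
        warnings.warn(
            f"removed {len(removed)} bins overlapping {len(regions)} regions", stacklevel=2
        )
    return SpectraMatrix(
        matrix.data.iloc[:, keep],
        [matrix.bin_edges[j] for j in keep],
        excluded_regions=matrix.excluded_regions + regions,
        normalization=matrix.normalization,
        scaling=matrix.scaling,
    )


def normalize_constant_sum(matrix: SpectraMatrix, target: float = 100.0) -> SpectraMatrix:
    """Scale each spectrum so its bins sum to ``target`` (constant-sum normalization)."""
    X = matrix.X
    sums = X.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [matrix.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"non-positive row sum for sample(s) {names}")
    df = matrix.data.mul(target / sums, axis=0)
    return replace(matrix, data=df, normalization="constant_sum")


@dataclass
class Scaler:
    """Column scaling fitted on one matrix and applicable to another.

    Mean centering subtracts the column mean; Pareto scaling divides the
    centered column by the square root of its sample standard deviation
    (n-1), damping dominant peaks less aggressively than unit variance.
    Zero-variance columns are centered only and flagged.
    """

    method: str
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    constant_columns: np.ndarray | None = None

    _METHODS = ("mean_center", "pareto", "unit_variance")

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if self.method not in self._METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}")
        if X.shape[0] < 2 and self.method != "mean_center":
            raise ValueError(f"{self.method} scaling needs at least 2 rows")
        self.means = X.mean(axis=0)
        self.sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        self.constant_columns = self.sds <= 0
        return self

    def _divisor(self) -> np.ndarray:
        d = np.ones_like(self.sds)
        ok = ~self.constant_columns
        if self.method == "pareto":
            d[ok] = np.sqrt(self.sds[ok])
        elif self.method == "unit_variance":
            d[ok] = self.sds[ok]
        return d

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means is None:
            raise ValueError("Scaler is not fitted")
        return (np.asarray(X, dtype=float) - self.means) / self._divisor()

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self._divisor() + self.means

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale(X: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale columns; returns (scaled matrix, column means, column sample sds).

    Constant columns are centered only (a warning flags them).
    """
    s = Scaler(method).fit(np.asarray(X, dtype=float))
    if s.constant_columns.any():
        warnings.warn(
            f"{int(s.constant_columns.sum())} constant column(s) centered only", stacklevel=2
        )
    return s.transform(X), s.means, s.sds
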