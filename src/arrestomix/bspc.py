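"""Batch Statistical Process Control of per-animal metabolic trajectories.

Animals traverse the same physiological phase (e.g. asphyxia) at different
speeds, so each animal's sampling minutes are first linearly expanded onto
a common timescale. A PLS model is then fitted on reference animals only,
predicting expanded time from the spectral profile ("maturity" model); the
across-reference mean +/- k*SD of the predicted-time trajectory, evaluated
on a common grid, gives pointwise control limits. Animals whose predicted
trajectory leaves the limits are flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .latent import PLS2
from .preprocessing import Scaler
from .validation import cross_validate_q2, validate

__all__ = ["ExpandedTrajectorySet", "expand_timescale", "BSPC", "BSPCResults", "BSPCChart"]


@dataclass
class ExpandedTrajectorySet:
    """Per-animal samples with minutes mapped onto a common timescale.

    ``X`` holds one row per sample; ``animal_ids`` and ``expanded_time``
    align with its rows. ``original_duration`` records each animal's true
    phase duration (minutes).
    """

    X: np.ndarray
    animal_ids: np.ndarray
    expanded_time: np.ndarray
    target_duration: float
    original_duration: dict[str, float]

    def rows_of(self, animal) -> np.ndarray:
        return np.flatnonzero(self.animal_ids == animal)

    @property
    def animals(self) -> list:
        return list(dict.fromkeys(self.animal_ids.tolist()))


def expand_timescale(
    X: np.ndarray,
    animal_ids,
    minute_in_phase,
    durations: dict | None = None,
    target_duration: float = 10.0,
) -> ExpandedTrajectorySet:
    """Linearly expand each animal's phase minutes to a common duration.

    Minute m of an animal whose phase lasted d minutes maps to
    m * target_duration / d, so every animal's trajectory spans
    [0, target_duration] and d = target_duration is the identity. When
    ``durations`` is omitted, each animal's largest observed minute is
    taken as its phase duration.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    animal_ids = np.asarray(animal_ids)
    minutes = np.asarray(minute_in_phase, dtype=float)
    if not (len(animal_ids) == len(minutes) == X.shape[0]):
        raise ValueError("X rows, animal_ids and minute_in_phase must align")
    if target_duration <= 0:
        raise ValueError("target_duration must be positive")
    animals = list(dict.fromkeys(animal_ids.tolist()))
    dur = {}
    expanded = np.empty_like(minutes)
    for a in animals:
        rows = np.flatnonzero(animal_ids == a)
        if rows.size < 2:
            raise ValueError(f"animal {a!r} has fewer than 2 timepoints")
        d = float(durations[a]) if durations is not None else float(minutes[rows].max())
        if d <= 0:
            raise ValueError(f"non-positive phase duration for animal {a!r}")
        dur[a] = d
        expanded[rows] = minutes[rows] * target_duration / d
    return ExpandedTrajectorySet(X, animal_ids, expanded, float(target_duration), dur)


class BSPC:
    """Batch SPC model: PLS maturity prediction with pointwise control limits.

    Parameters
    ----------
    trajectories : expanded trajectories for every animal (reference and test).
    reference_ids : the animals (e.g. the no-damaged ones) used both to fit
        the PLS model and to estimate the control limits; test animals are
        only ever projected.
    n_components : PLS components for the time model.
    grid_step : spacing (expanded minutes) of the monitoring grid.
    x_scaling : column scaling estimated on the reference samples.
    """

    def __init__(
        self,
        trajectories: ExpandedTrajectorySet,
        reference_ids,
        n_components: int = 3,
        grid_step: float = 0.5,
        x_scaling: str | None = "pareto",
    ):
        self.trajectories = trajectories
        self.reference_ids = list(reference_ids)
        if len(self.reference_ids) < 2:
            raise ValueError("need at least 2 reference animals")
        missing = set(self.reference_ids) - set(trajectories.animals)
        if missing:
            raise ValueError(f"reference animals not in trajectory set: {sorted(missing)}")
        self.n_components = int(n_components)
        self.grid_step = float(grid_step)
        self.x_scaling = x_scaling

    def fit(self, n_folds: int = 7, cv_scheme: str = "grouped") -> "BSPCResults":
        tr = self.trajectories
        ref_rows = np.flatnonzero(np.isin(tr.animal_ids, self.reference_ids))
        Xr, tref = tr.X[ref_rows], tr.expanded_time[ref_rows]
        scaler = Scaler(self.x_scaling).fit(Xr) if self.x_scaling else None
        Xrs = scaler.transform(Xr) if scaler else Xr
        y = tref - tref.mean()
        pls = PLS2(Xrs, y.reshape(-1, 1), self.n_components).fit()
        y_offset = float(tref.mean())

        report = validate(
            Xr, tref.reshape(-1, 1), self.n_components, n_folds=min(n_folds, len(self.reference_ids)),
            scheme=cv_scheme, group_ids=tr.animal_ids[ref_rows],
            x_scaling=self.x_scaling, y_scaling="mean_center",
        )

        grid = np.arange(0.0, tr.target_duration + 1e-9, self.grid_step)

        def predict_minutes(rows):
            Xs = scaler.transform(tr.X[rows]) if scaler else tr.X[rows]
            return pls.predict(Xs)[:, 0] + y_offset

        # interpolate each reference animal's predicted-time trajectory on the grid
        curves = np.full((len(self.reference_ids), grid.size), np.nan)
        for i, a in enumerate(self.reference_ids):
            rows = tr.rows_of(a)
            order = np.argsort(tr.expanded_time[rows])
            t_a = tr.expanded_time[rows][order]
            p_a = predict_minutes(rows)[order]
            inside = (grid >= t_a.min() - 1e-9) & (grid <= t_a.max() + 1e-9)
            curves[i, inside] = np.interp(grid[inside], t_a, p_a)
        n_at = np.sum(~np.isnan(curves), axis=0)
        ok = n_at >= 2
        if not ok.all():
            warnings.warn(
                f"dropped {int((~ok).sum())} grid point(s) covered by < 2 reference animals",
                stacklevel=2,
            )
        if not ok.any():
            raise ValueError("no grid point covered by at least 2 reference animals")
        grid = grid[ok]
        curves = curves[:, ok]
        mean_t = np.nanmean(curves, axis=0)
        sd_t = np.nanstd(curves, axis=0, ddof=1)
        return BSPCResults(
            model=self,
            pls=pls,
            scaler=scaler,
            y_offset=y_offset,
            grid=grid,
            reference_mean=mean_t,
            reference_sd=sd_t,
            r2=report.r2,
            q2=report.q2,
            validation=report,
        )


@dataclass
class BSPCResults:
    model: BSPC
    pls: object
    scaler: Scaler | None
    y_offset: float
    grid: np.ndarray
    reference_mean: np.ndarray
    reference_sd: np.ndarray
    r2: float
    q2: float
    validation: object = field(repr=False, default=None)

    def predict_time(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X) if self.scaler else np.asarray(X, dtype=float)
        return self.pls.predict(Xs)[:, 0] + self.y_offset

    def chart(self, k: float = 2.0, flag_min_fraction: float = 0.2) -> "BSPCChart":
        """Project every animal through the model and flag excursions.

        A point is out of control when its predicted time leaves
        [mean(t) - k*sd(t), mean(t) + k*sd(t)]; an animal is flagged when
        at least ``flag_min_fraction`` of its grid points are out.
        """
        if k <= 0:
            raise ValueError("k must be positive")
        tr = self.model.trajectories
        lower = self.reference_mean - k * self.reference_sd
        upper = self.reference_mean + k * self.reference_sd
        rows_out = []
        summaries = []
        for a in tr.animals:
            rows = tr.rows_of(a)
            order = np.argsort(tr.expanded_time[rows])
            t_a = tr.expanded_time[rows][order]
            p_a = self.predict_time(tr.X[rows])[order]
            inside = (self.grid >= t_a.min() - 1e-9) & (self.grid <= t_a.max() + 1e-9)
            if not inside.any():
                warnings.warn(f"animal {a!r} has no samples in the grid range", stacklevel=2)
                continue
            g = self.grid[inside]
            pred = np.interp(g, t_a, p_a)
            lo, up = lower[inside], upper[inside]
            out = (pred < lo) | (pred > up)
            frac = float(out.mean())
            first = float(g[out][0]) if out.any() else np.nan
            summaries.append(
                {
                    "animal": a,
                    "is_reference": a in self.model.reference_ids,
                    "fraction_out": frac,
                    "first_excursion_time": first,
                    "out_of_control": frac >= flag_min_fraction,
                }
            )
            for gi, pi, li, ui, oi in zip(g, pred, lo, up, out):
                rows_out.append(
                    {"animal": a, "time": gi, "predicted": pi, "lower": li, "upper": ui, "flag": bool(oi)}
                )
        return BSPCChart(
            points=pd.DataFrame(rows_out),
            summary=pd.DataFrame(summaries).set_index("animal"),
            k=float(k),
            flag_min_fraction=float(flag_min_fraction),
        )


@dataclass
class BSPCChart:
    """Control chart: per-point trajectories with limits and per-animal flags."""

    points: pd.DataFrame
    summary: pd.DataFrame
    k: float
    flag_min_fraction: float

    @property
    def flagged_animals(self) -> list:
        return self.summary.index[self.summary["out_of_control"]].tolist()
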