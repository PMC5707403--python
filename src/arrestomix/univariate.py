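"""Longitudinal univariate statistics on quantified metabolites.

Mixed-effects models with a random intercept per animal capture the
dependence of repeated plasma measurements on the same subject; paired
Wilcoxon signed-rank and unpaired Mann-Whitney U tests handle the
phase-to-phase and between-group comparisons; fold changes summarise
effect sizes per animal; Benjamini-Hochberg q-values correct for testing
many metabolites at once.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MixedModelFit",
    "fit_mixed_model",
    "wilcoxon_paired",
    "mann_whitney",
    "fold_changes",
    "fdr_qvalues",
    "effect_table",
]


@dataclass
class MixedModelFit:
    """Fixed effects (Wald tests), variance components, and fit quality.

    ``coefficients`` maps term -> (estimate, p_value). The group term uses
    the coding recorded in ``group_coding``; R2 is the squared Pearson
    correlation between fitted and observed values (a descriptive fit
    statistic, not a marginal/conditional decomposition).
    """

    metabolite: str
    coefficients: dict[str, tuple[float, float]]
    includes_interaction: bool
    random_intercept_variance: float
    residual_variance: float
    r2: float
    n_animals: int
    n_obs: int
    group_coding: str
    standard_errors: dict[str, float]

    def summary(self) -> str:
        lines = [
            f"Mixed-effects model: {self.metabolite}",
            f"  n = {self.n_obs} observations, {self.n_animals} animals",
            f"  random intercept variance = {self.random_intercept_variance:.4g}, "
            f"residual variance = {self.residual_variance:.4g}",
            f"  R2 (corr(fitted, observed)^2) = {self.r2:.3f}",
            f"  group coding: {self.group_coding}",
        ]
        for term, (est, p) in self.coefficients.items():
            lines.append(f"  {term}: {est:.4g} (p = {p:.3g})")
        return "\n".join(lines)


def fit_mixed_model(
    data: pd.DataFrame,
    metabolite: str,
    include_interaction: bool = False,
    value_col: str = "value",
    time_col: str = "minute",
    group_col: str = "group",
    animal_col: str = "animal_id",
    metabolite_col: str = "metabolite",
) -> MixedModelFit:
    """Fit y ~ time + group (+ time:group) with a random intercept per animal.

    REML estimation through statsmodels MixedLM; Wald p-values use the
    normal approximation. ``data`` is tidy (one row per sample and
    metabolite); the reference group level is the first in sorted order,
    recorded in the output.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = data
    if metabolite_col in df.columns:
        df = df[df[metabolite_col] == metabolite]
    if df.empty:
        raise ValueError(f"no rows for metabolite {metabolite!r}")
    df = df[[value_col, time_col, group_col, animal_col]].dropna().copy()
    groups = sorted(df[group_col].unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    per_group = df.groupby(group_col)[animal_col].nunique()
    if (per_group < 2).any():
        raise ValueError("need at least 2 animals per group")
    if df[time_col].nunique() < 2:
        raise ValueError("singular design: time is constant")
    ref, other = groups
    df["_g"] = (df[group_col] == other).astype(float)
    exog = pd.DataFrame(
        {"Intercept": 1.0, "time": df[time_col].astype(float), "group": df["_g"]}
    )
    if include_interaction:
        exog["time:group"] = exog["time"] * exog["group"]
    model = MixedLM(df[value_col].astype(float).to_numpy(), exog.to_numpy(),
                    groups=df[animal_col].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    if not res.converged:
        raise ValueError(f"mixed model did not converge for {metabolite!r}")
    k = exog.shape[1]
    coefs = {
        name: (float(res.params[i]), float(res.pvalues[i]))
        for i, name in enumerate(exog.columns[:k])
    }
    ses = {name: float(res.bse[i]) for i, name in enumerate(exog.columns[:k])}
    fitted = res.fittedvalues
    r2 = float(np.corrcoef(fitted, df[value_col].astype(float))[0, 1] ** 2)
    return MixedModelFit(
        metabolite=metabolite,
        coefficients=coefs,
        includes_interaction=include_interaction,
        random_intercept_variance=float(np.asarray(res.cov_re)[0, 0]),
        residual_variance=float(res.scale),
        r2=r2,
        n_animals=int(df[animal_col].nunique()),
        n_obs=len(df),
        group_coding=f"group = 1 for {other!r}, 0 for {ref!r} (reference)",
        standard_errors=ses,
    )


def wilcoxon_paired(before, after) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-animal values.

    Zero differences are dropped (Wilcoxon's policy), ties are mid-ranked.
    The p-value is exact (enumeration over sign assignments) for n <= 25
    without ties; otherwise the normal approximation with continuity
    correction is used.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size < 2:
        raise ValueError("before/after must be equal-length vectors of length >= 2")
    d = after - before
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: no information")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent groups.

    Exact p by enumeration for n_a + n_b <= 20 without ties; tie-corrected
    normal approximation with continuity correction otherwise. Returns
    (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)


def fold_changes(
    data: pd.DataFrame,
    from_query: dict,
    to_query: dict,
    group: str | None = None,
    value_col: str = "value",
    animal_col: str = "animal_id",
    metabolite_col: str = "metabolite",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-metabolite fold changes between two timepoints.

    Fold change per animal is the relative increase
    (x_to - x_from) / x_from; the output reports its mean, min and max
    across animals (columns ``mean_fc``, ``min_fc``, ``max_fc``).
    ``from_query``/``to_query`` select the two timepoints by column
    equality, e.g. ``{"phase": "CPR", "minute": 1}``. Animals with
    non-positive baseline are excluded with a warning.
    """

    def _select(q):
        m = pd.Series(True, index=data.index)
        for k, v in q.items():
            m &= data[k] == v
        return data[m]

    df_from, df_to = _select(from_query), _select(to_query)
    if group is not None:
        df_from = df_from[df_from[group_col] == group]
        df_to = df_to[df_to[group_col] == group]
    if df_from.empty or df_to.empty:
        raise ValueError("no samples match the from/to selection")
    rows = []
    for met in sorted(df_to[metabolite_col].unique()):
        f = df_from[df_from[metabolite_col] == met].set_index(animal_col)[value_col]
        t = df_to[df_to[metabolite_col] == met].set_index(animal_col)[value_col]
        animals = f.index.intersection(t.index)
        if animals.empty:
            raise ValueError(f"no animal has both timepoints for {met!r}")
        x_from, x_to = f.loc[animals].astype(float), t.loc[animals].astype(float)
        ok = x_from > 0
        if not ok.all():
            warnings.warn(
                f"{met}: excluded {int((~ok).sum())} animal(s) with non-positive baseline",
                stacklevel=2,
            )
        fc = (x_to[ok] - x_from[ok]) / x_from[ok]
        rows.append(
            {
                "metabolite": met,
                "mean_fc": float(fc.mean()),
                "min_fc": float(fc.min()),
                "max_fc": float(fc.max()),
                "n_animals": int(ok.sum()),
                "definition": "(x_to - x_from) / x_from",
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")


def fdr_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def effect_table(
    data: pd.DataFrame,
    from_query: dict,
    to_query: dict,
    group: str | None = None,
    test: str = "wilcoxon",
    **cols,
) -> pd.DataFrame:
    """Per-metabolite test p/q-values plus fold-change summaries.

    ``test`` = "wilcoxon" pairs the two timepoints per animal (within-group
    change); "mann_whitney" compares the ``to`` values between the two
    levels of the group column (between-group difference at one timepoint).
    """
    value_col = cols.get("value_col", "value")
    animal_col = cols.get("animal_col", "animal_id")
    metabolite_col = cols.get("metabolite_col", "metabolite")
    group_col = cols.get("group_col", "group")
    fc = fold_changes(
        data, from_query, to_query, group=group, value_col=value_col,
        animal_col=animal_col, metabolite_col=metabolite_col, group_col=group_col,
    )

    def _select(q, g=None):
        m = pd.Series(True, index=data.index)
        for k, v in q.items():
            m &= data[k] == v
        d = data[m]
        return d[d[group_col] == g] if g is not None else d

    ps, direction = [], []
    for met in fc.index:
        if test == "wilcoxon":
            f = _select(from_query, group)
            t = _select(to_query, group)
            f = f[f[metabolite_col] == met].set_index(animal_col)[value_col]
            t = t[t[metabolite_col] == met].set_index(animal_col)[value_col]
            animals = f.index.intersection(t.index)
            _, p = wilcoxon_paired(f.loc[animals], t.loc[animals])
        elif test == "mann_whitney":
            d = _select(to_query)
            d = d[d[metabolite_col] == met]
            levels = sorted(d[group_col].unique())
            if len(levels) != 2:
                raise ValueError("mann_whitney needs exactly 2 group levels")
            _, p = mann_whitney(
                d[d[group_col] == levels[0]][value_col],
                d[d[group_col] == levels[1]][value_col],
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        ps.append(p)
        direction.append("up" if fc.loc[met, "mean_fc"] > 0 else "down")
    out = fc.copy()
    out["p_value"] = ps
    out["q_value"] = fdr_qvalues(np.array(ps))
    out["test"] = test
    out["direction"] = direction
    return out[["p_value", "q_value", "mean_fc", "min_fc", "max_fc",
                "n_animals", "test", "direction", "definition"]]
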