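"""Synthetic swine-cohort generator with known ground truth.

Emulates the statistical structure of a two-arm cardiac-arrest experiment:
two groups of animals (asphyxial, "ACA", and ventricular-fibrillation,
"VFCA"), sampled every minute through baseline, a variable asphyxial
pre-arrest period (ACA only), five minutes of untreated cardiac arrest,
a variable CPR period, and a post-ROSC follow-up. Metabolite
concentrations follow a piecewise log-linear trajectory per phase with
class-specific slopes and fold-change caps (e.g. succinate rising up to
40-fold in damaged versus up to 3-fold in no-damaged animals), animal
random intercepts, and multiplicative lognormal noise. NMR-like spectra
are rendered from the concentrations as sums of Lorentzian peaks.

Every drawn parameter is recorded in the ground truth, so downstream
estimators can be checked for recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import RawSpectraSet

__all__ = [
    "MetaboliteSpec",
    "CohortConfig",
    "SampleMetadata",
    "GroundTruth",
    "generate_cohort",
    "generate_spectra",
    "simulate_linear_mixed",
    "default_metabolite_panel",
    "default_cohort_config",
    "to_tidy",
]

PHASES = ("baseline", "asphyxia", "CA", "CPR", "post-ROSC", "24h")


@dataclass
class MetaboliteSpec:
    """One metabolite's baseline, dynamics, and NMR signature.

    ``slope_per_min`` maps (group, phase, damage_class) to the per-minute
    rate of the log fold-change during that phase; "*" is a wildcard in
    any position, and missing keys mean no drift. ``max_fold_change``
    caps the fold change by damage class ("*" wildcard again).
    ``ppm_peaks`` lists (center ppm, relative amplitude, half width at
    half maximum in ppm) Lorentzian components.
    """

    name: str
    baseline_mean: float
    baseline_cv: float = 0.0
    animal_intercept_sd: float = 0.0
    slope_per_min: dict = field(default_factory=dict)
    max_fold_change: dict = field(default_factory=dict)
    ppm_peaks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError(f"{self.name}: baseline_mean must be positive")
        for c, _a, _h in self.ppm_peaks:
            if not 0.80 <= c <= 9.00:
                raise ValueError(f"{self.name}: peak at {c} ppm outside [0.80, 9.00]")
        for cap in self.max_fold_change.values():
            if cap < 1:
                raise ValueError(f"{self.name}: fold-change cap must be >= 1")

    def slope(self, group: str, phase: str, damage_class: str) -> float:
        for key in (
            (group, phase, damage_class),
            (group, phase, "*"),
            ("*", phase, damage_class),
            ("*", phase, "*"),
        ):
            if key in self.slope_per_min:
                return float(self.slope_per_min[key])
        return 0.0

    def cap(self, damage_class: str) -> float:
        if damage_class in self.max_fold_change:
            return float(self.max_fold_change[damage_class])
        return float(self.max_fold_change.get("*", math.inf))


@dataclass
class CohortConfig:
    """Study design: group sizes, phase durations, and metabolite presets."""

    n_animals_per_group: int = 10
    groups: tuple[str, str] = ("ACA", "VFCA")
    damaged_fraction_aca: float = 0.4
    asphyxia_duration_range_min: tuple[int, int] = (4, 10)
    ca_duration_min: int = 5
    cpr_duration_range_min: tuple[int, int] = (2, 10)
    post_rosc_hours: tuple[int, ...] = (1, 2, 3, 4, 24)
    metabolite_specs: list = field(default_factory=list)
    random_seed: int = 0
    noise_sd_frac: float = 0.08
    post_rosc_decay_tau_min: float = 60.0
    # damaged animals tolerate asphyxia longer before arresting: their
    # pre-arrest period never falls below this floor
    damaged_min_asphyxia_min: int = 7

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be positive")
        if not 0 <= self.damaged_fraction_aca <= 1:
            raise ValueError("damaged_fraction_aca must be in [0, 1]")
        for lo, hi in (self.asphyxia_duration_range_min, self.cpr_duration_range_min):
            if lo <= 0 or hi < lo:
                raise ValueError("duration ranges must be positive and ordered")
        if self.ca_duration_min <= 0:
            raise ValueError("ca_duration_min must be positive")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")
        if not self.metabolite_specs:
            raise ValueError("metabolite_specs must not be empty")


@dataclass
class SampleMetadata:
    sample_id: str
    animal_id: str
    group: str
    damage_class: str  # "damaged" | "no-damaged" | "n/a"
    phase: str
    minute_in_phase: int


@dataclass
class GroundTruth:
    """Every drawn parameter, for recovery tests."""

    seed: int
    animals: pd.DataFrame  # animal_id, group, damage_class, asphyxia/cpr durations
    baselines: pd.DataFrame  # animal_id x metabolite true baseline
    noiseless: pd.DataFrame  # sample_id x metabolite noise-free concentration
    fold_change: pd.DataFrame  # sample_id x metabolite true g (fold vs baseline)


def _animal_timeline(group: str, d_asp: int, d_ca: int, d_cpr: int, hours) -> list[tuple[str, int, float]]:
    """(phase, minute_in_phase, minutes since asphyxia/CA onset) per sample."""
    out = [("baseline", 0, 0.0)]
    t = 0.0
    if group == "ACA":
        for m in range(1, d_asp + 1):
            out.append(("asphyxia", m, float(m)))
        t = float(d_asp)
    for m in range(1, d_ca + 1):
        out.append(("CA", m, t + m))
    t += d_ca
    for m in range(1, d_cpr + 1):
        out.append(("CPR", m, t + m))
    t += d_cpr
    for h in hours:
        phase = "24h" if h >= 24 else "post-ROSC"
        out.append((phase, int(h * 60), t + h * 60))
    return out


def _log_fold(spec: MetaboliteSpec, group: str, dclass: str, phase: str,
              minute: int, carried: float, tau: float) -> float:
    """Log fold-change at ``minute`` of ``phase``, given the log fold
    ``carried`` over from the previous phases; capped at the class cap."""
    cap = math.log(spec.cap(dclass)) if math.isfinite(spec.cap(dclass)) else math.inf
    if phase in ("post-ROSC", "24h"):
        lf = carried * math.exp(-minute / tau)
    else:
        lf = carried + spec.slope(group, phase, dclass) * minute
    return min(lf, cap)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one cohort.

    Returns (quant, metadata, ground_truth): ``quant`` is a samples x
    metabolites table of concentrations (µmol/L), ``metadata`` one row per
    sample. The concentration model is
    y = baseline_animal * g(phase, t; class) * exp(eps),
    eps ~ N(0, noise_sd_frac^2), with g piecewise log-linear per phase,
    capped at the class fold-change cap, and decaying exponentially toward
    baseline after ROSC. Identical seed => identical output.
    """
    rng = np.random.default_rng(config.random_seed)
    specs = config.metabolite_specs
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate metabolite names")

    # deterministic damage-class assignment: seeded shuffle, exact fraction
    n = config.n_animals_per_group
    n_damaged = int(round(config.damaged_fraction_aca * n))
    aca_order = rng.permutation(n)
    animal_rows = []
    for g in config.groups:
        for i in range(n):
            aid = f"{g}{i + 1:02d}"
            if g == "ACA":
                dclass = "damaged" if int(np.where(aca_order == i)[0][0]) < n_damaged else "no-damaged"
                lo, hi = config.asphyxia_duration_range_min
                if dclass == "damaged":
                    lo = min(max(lo, config.damaged_min_asphyxia_min), hi)
                d_asp = int(rng.integers(lo, hi + 1))
            else:
                dclass, d_asp = "n/a", 0
            d_cpr = int(rng.integers(config.cpr_duration_range_min[0],
                                     config.cpr_duration_range_min[1] + 1))
            animal_rows.append(
                {"animal_id": aid, "group": g, "damage_class": dclass,
                 "asphyxia_duration": d_asp, "cpr_duration": d_cpr}
            )
    animals = pd.DataFrame(animal_rows).set_index("animal_id")

    # animal baselines: lognormal around baseline_mean plus additive intercept
    baselines = {}
    for spec in specs:
        sigma = math.sqrt(math.log(1.0 + spec.baseline_cv**2))
        ln = spec.baseline_mean * np.exp(rng.normal(0.0, sigma, size=len(animals))
                                         - 0.5 * sigma**2)
        add = rng.normal(0.0, spec.animal_intercept_sd, size=len(animals))
        baselines[spec.name] = np.maximum(ln + add, 1e-9 * spec.baseline_mean)
    baselines = pd.DataFrame(baselines, index=animals.index)

    meta_rows, quant_rows, clean_rows, fold_rows, sample_ids = [], [], [], [], []
    for aid, arow in animals.iterrows():
        timeline = _animal_timeline(
            arow["group"], arow["asphyxia_duration"], config.ca_duration_min,
            arow["cpr_duration"], config.post_rosc_hours,
        )
        carried = {s.name: 0.0 for s in specs}
        prev_phase = "baseline"
        for phase, minute, _tmin in timeline:
            if phase != prev_phase and prev_phase not in ("post-ROSC", "24h"):
                # roll the completed phase's drift into the carried log fold
                if prev_phase != "baseline":
                    d_prev = {"asphyxia": arow["asphyxia_duration"],
                              "CA": config.ca_duration_min,
                              "CPR": arow["cpr_duration"]}[prev_phase]
                    for s in specs:
                        carried[s.name] = _log_fold(
                            s, arow["group"], arow["damage_class"], prev_phase,
                            d_prev, carried[s.name], config.post_rosc_decay_tau_min,
                        )
                prev_phase = phase
            sid = f"{aid}_{phase}_{minute}"
            sample_ids.append(sid)
            meta_rows.append(
                SampleMetadata(sid, aid, arow["group"], arow["damage_class"], phase, minute)
            )
            conc, clean, folds = {}, {}, {}
            for s in specs:
                lf = _log_fold(s, arow["group"], arow["damage_class"], phase,
                               minute, carried[s.name], config.post_rosc_decay_tau_min)
                gfold = math.exp(lf)
                mu = baselines.loc[aid, s.name] * gfold
                eps = rng.normal(0.0, config.noise_sd_frac) if config.noise_sd_frac > 0 else 0.0
                conc[s.name] = mu * math.exp(eps)
                clean[s.name] = mu
                folds[s.name] = gfold
            quant_rows.append(conc)
            clean_rows.append(clean)
            fold_rows.append(folds)

    quant = pd.DataFrame(quant_rows, index=pd.Index(sample_ids, name="sample_id"))
    metadata = pd.DataFrame([m.__dict__ for m in meta_rows]).set_index("sample_id")
    truth = GroundTruth(
        seed=config.random_seed,
        animals=animals,
        baselines=baselines,
        noiseless=pd.DataFrame(clean_rows, index=quant.index),
        fold_change=pd.DataFrame(fold_rows, index=quant.index),
    )
    return quant, metadata, truth


def generate_spectra(
    quant: pd.DataFrame,
    specs: list[MetaboliteSpec],
    ppm_min: float = 0.79,
    ppm_max: float = 9.01,
    ppm_grid_step: float = 0.002,
    baseline_amp: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RawSpectraSet:
    """Render NMR-like spectra from a concentration table.

    Each spectrum is the concentration-weighted sum of each metabolite's
    Lorentzian peaks, plus a smooth broad baseline and additive Gaussian
    noise; intensities are clipped at zero. With zero noise and baseline
    the integrated spectrum is linear in concentration.
    """
    ppm = np.arange(ppm_min, ppm_max + ppm_grid_step / 2, ppm_grid_step)
    by_name = {s.name: s for s in specs}
    unknown = [c for c in quant.columns if c not in by_name]
    if unknown:
        raise ValueError(f"no spectral signature for metabolites {unknown}")
    shapes = {}
    for name in quant.columns:
        sig = np.zeros_like(ppm)
        for c, amp, hwhm in by_name[name].ppm_peaks:
            if not ppm[0] <= c <= ppm[-1]:
                raise ValueError(f"{name}: peak at {c} ppm outside the grid")
            sig += amp * hwhm**2 / ((ppm - c) ** 2 + hwhm**2)
        shapes[name] = sig
    rng = np.random.default_rng(seed)
    base = baseline_amp * np.exp(-((ppm - 4.5) ** 2) / 18.0)
    intens = np.zeros((quant.shape[0], ppm.size))
    for j, name in enumerate(quant.columns):
        intens += np.outer(quant[name].to_numpy(dtype=float), shapes[name])
    intens += base
    if noise_sd > 0:
        intens += rng.normal(0.0, noise_sd, size=intens.shape)
    np.clip(intens, 0.0, None, out=intens)
    return RawSpectraSet(ppm, intens, list(quant.index))


def simulate_linear_mixed(
    beta: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0),
    sigma_b: float = 1.0,
    sigma: float = 0.5,
    n_animals_per_group: int = 10,
    n_timepoints: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact linear-mixed data with known coefficients, for recovery tests.

    y_it = b0 + b1 t + b2 g_i + b3 t g_i + u_i + eps_it with
    u_i ~ N(0, sigma_b^2), eps ~ N(0, sigma^2), g_i in {0 (ACA), 1 (VFCA)},
    t = 0..n_timepoints-1. Tidy output with a single metabolite "sim".
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = beta
    rows = []
    for gi, gname in enumerate(("ACA", "VFCA")):
        for i in range(n_animals_per_group):
            u = rng.normal(0.0, sigma_b)
            aid = f"{gname}{i + 1:02d}"
            for t in range(n_timepoints):
                y = b0 + b1 * t + b2 * gi + b3 * t * gi + u + rng.normal(0.0, sigma)
                rows.append({"animal_id": aid, "group": gname, "minute": t,
                             "metabolite": "sim", "value": y})
    return pd.DataFrame(rows)


def to_tidy(quant: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Melt a samples x metabolites table into the tidy layout the
    univariate layer consumes (sample_id, animal_id, group, damage_class,
    phase, minute, metabolite, value)."""
    long = quant.reset_index().melt(
        id_vars="sample_id", var_name="metabolite", value_name="value"
    )
    meta = metadata.reset_index().rename(columns={"minute_in_phase": "minute"})
    return long.merge(meta, on="sample_id", how="left")


# ---------------------------------------------------------------------------
# shipped presets
#
# Peak positions and half-widths below are generator conventions taken from
# common literature chemical shifts (lactate doublet ~1.33 ppm, succinate
# singlet ~2.41 ppm, ...), not claims about any particular dataset; baseline
# concentrations are order-of-magnitude plasma values.

_LN40_10 = math.log(40.0) / 10.0  # damaged: up to 40-fold over a 10-min asphyxia
_LN3_10 = math.log(3.0) / 10.0  # no-damaged: up to 3-fold


def _cpr_slope(mean_fold_change: float, mean_duration_min: float = 6.0) -> float:
    """Per-minute log rate so the expected end/begin ratio over a CPR phase
    of the mean duration equals 1 + mean_fold_change (fold change defined as
    the relative increase)."""
    return math.log(1.0 + mean_fold_change) / mean_duration_min


def default_metabolite_panel() -> list[MetaboliteSpec]:
    """Preset metabolite panel with asphyxia/CA/CPR dynamics.

    ACA animals accumulate anaerobic and TCA-cycle markers during asphyxia
    (damaged far more than no-damaged, succinate capped at 40x vs 3x);
    VFCA animals stay at baseline until CPR, when the same markers rise.
    """
    hw = 0.004

    def spec(name, mean, peaks, slopes=None, caps=None, cv=0.15, isd=0.0):
        return MetaboliteSpec(
            name=name, baseline_mean=mean, baseline_cv=cv, animal_intercept_sd=isd,
            slope_per_min=slopes or {}, max_fold_change=caps or {}, ppm_peaks=peaks,
        )

    return [
        spec(
            "succinate", 10.0, [(2.41, 1.0, hw)],
            slopes={
                ("ACA", "asphyxia", "damaged"): _LN40_10,
                ("ACA", "asphyxia", "no-damaged"): _LN3_10,
                ("ACA", "CA", "*"): 0.02,
                ("ACA", "CPR", "*"): 0.02,
                ("VFCA", "CPR", "*"): _cpr_slope(5.39),
            },
            caps={"damaged": 40.0, "no-damaged": 3.0, "n/a": 12.0},
        ),
        spec(
            "lactate", 1500.0, [(1.33, 1.0, hw), (4.11, 0.30, hw)],
            slopes={
                ("ACA", "asphyxia", "damaged"): 0.18,
                ("ACA", "asphyxia", "no-damaged"): 0.10,
                ("ACA", "CA", "*"): 0.04,
                ("VFCA", "CPR", "*"): _cpr_slope(0.53),
            },
            caps={"damaged": 8.0, "no-damaged": 4.0, "n/a": 4.0},
        ),
        spec(
            "malate", 8.0, [(2.37, 0.6, hw), (2.68, 0.6, hw)],
            slopes={
                ("ACA", "asphyxia", "damaged"): 0.16,
                ("ACA", "asphyxia", "no-damaged"): 0.06,
                ("VFCA", "CPR", "*"): _cpr_slope(2.11),
            },
            caps={"damaged": 6.0, "no-damaged": 2.0, "n/a": 3.5},
        ),
        spec(
            "fumarate", 2.0, [(6.52, 0.8, hw)],
            slopes={
                ("ACA", "asphyxia", "damaged"): 0.10,
                ("ACA", "asphyxia", "no-damaged"): 0.03,
            },
            caps={"damaged": 3.0, "no-damaged": 1.5, "n/a": 1.5},
        ),
        spec(
            "glutamate", 150.0, [(2.10, 0.5, hw), (2.35, 0.4, hw)],
            slopes={
                ("ACA", "asphyxia", "damaged"): 0.08,
                ("ACA", "asphyxia", "no-damaged"): -0.02,
                ("VFCA", "CPR", "*"): _cpr_slope(0.55),
            },
            caps={"damaged": 2.5, "no-damaged": 1.2, "n/a": 1.6},
        ),
        spec(
            "hypoxanthine", 20.0, [(8.19, 0.7, hw), (8.21, 0.7, hw)],
            slopes={
                ("ACA", "asphyxia", "*"): 0.09,
                ("ACA", "CA", "*"): 0.05,
                ("VFCA", "CPR", "*"): _cpr_slope(1.92),
            },
            caps={"damaged": 5.0, "no-damaged": 2.5, "n/a": 3.0},
        ),
        spec(
            "alanine", 300.0, [(1.48, 0.9, hw)],
            slopes={("VFCA", "CPR", "*"): _cpr_slope(0.32)},
            caps={"*": 1.4},
        ),
        spec(
            "glycine", 400.0, [(3.56, 1.0, hw)],
            slopes={("ACA", "asphyxia", "damaged"): 0.02},
            caps={"*": 1.3},
        ),
        spec("glucose", 4000.0, [(3.42, 0.4, hw), (3.72, 0.5, hw), (5.23, 0.25, hw)]),
        spec("creatinine", 60.0, [(3.04, 1.0, hw), (4.06, 0.8, hw)]),
    ]


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The shipped study-design preset: 10 + 10 animals, 40% damaged ACA,
    4-10 min asphyxia, 5 min CA, 2-10 min CPR, post-ROSC hours 1-4 and 24."""
    kwargs = dict(
        n_animals_per_group=10,
        damaged_fraction_aca=0.4,
        metabolite_specs=default_metabolite_panel(),
        random_seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
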