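"""Pipeline presets chaining the stages into the three headline analyses.

``ca-contrast``    ptPLS2-DA of the two arrest etiologies over the untreated
                   cardiac-arrest minutes, with permutation validation and
                   VIP/stability variable selection.
``asphyxia-bspc``  timescale expansion of the asphyxial period, BSPC control
                   chart referenced on no-damaged animals, plus an
                   unsupervised PCA of baseline vs last-asphyxia-minute
                   samples.
``cpr-contrast``   within-group begin-vs-end-of-CPR ptPLS2-DA plus the
                   paired Wilcoxon / fold-change effect table.

Every run directory gets a config snapshot (with hash and seed) and a log,
so outputs are bit-reproducible from the snapshot.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .bspc import BSPC, expand_timescale
from .latent import PCA, PLS2, build_design_matrix
from .preprocessing import Scaler, bin_spectra, normalize_constant_sum, remove_bins
from .simulate import default_cohort_config, generate_cohort, generate_spectra, to_tidy
from .univariate import effect_table
from .validation import select_components, stability_selection, validate

__all__ = ["PipelineConfig", "run_pipeline", "PRESETS"]

PRESETS = ("ca-contrast", "asphyxia-bspc", "cpr-contrast")
log = logging.getLogger("arrestomix")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either point ``spectra_path``/``quant_path``/``metadata_path`` at
    existing tables, or leave them unset to simulate the default synthetic
    cohort with ``seed``.
    """

    output_dir: str = "arrestomix_run"
    seed: int = 0
    spectra_path: str | None = None
    quant_path: str | None = None
    metadata_path: str | None = None
    # preprocessing
    ppm_min: float = 0.80
    ppm_max: float = 9.00
    bin_width: float = 0.01
    exclusions: list = dataclasses.field(default_factory=lambda: [(4.66, 5.18)])
    drug_regions: list = dataclasses.field(default_factory=list)
    normalize_target: float = 100.0
    scaling: str = "pareto"
    # modelling
    components: str | int = "auto"
    max_components: int = 5
    # validation
    n_folds: int = 7
    cv_scheme: str = "interleaved"
    n_permutations: int = 199
    # bspc
    bspc_phase: str = "asphyxia"
    bspc_target_duration: float = 10.0
    bspc_k: float = 2.0
    bspc_reference_class: str = "no-damaged"
    bspc_components: int = 3
    bspc_grid_step: float = 0.5
    # stats / cpr preset
    cpr_group: str = "VFCA"
    # spectra simulation
    spectra_noise_sd: float = 0.5
    spectra_baseline_amp: float = 0.0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)


def _load_inputs(cfg: PipelineConfig):
    """Return (quant, metadata, spectra_matrix) from files or simulation."""
    if cfg.quant_path or cfg.metadata_path or cfg.spectra_path:
        if not (cfg.quant_path and cfg.metadata_path):
            raise ValueError("quant_path and metadata_path must be given together")
        quant = aio.read_table(cfg.quant_path, index_col="sample_id")
        metadata = aio.read_table(
            cfg.metadata_path,
            required=("animal_id", "group", "damage_class", "phase", "minute_in_phase"),
            index_col="sample_id",
        )
        raw = aio.read_spectra(cfg.spectra_path) if cfg.spectra_path else None
    else:
        config = default_cohort_config(seed=cfg.seed)
        quant, metadata, _truth = generate_cohort(config)
        raw = generate_spectra(
            quant, config.metabolite_specs, seed=cfg.seed + 1,
            noise_sd=cfg.spectra_noise_sd, baseline_amp=cfg.spectra_baseline_amp,
        )
    matrix = None
    if raw is not None:
        matrix = bin_spectra(raw, cfg.ppm_min, cfg.ppm_max, cfg.bin_width, cfg.exclusions)
        if cfg.drug_regions:
            matrix = remove_bins(matrix, [tuple(r) for r in cfg.drug_regions])
        matrix = normalize_constant_sum(matrix, cfg.normalize_target)
    return quant, metadata, matrix


def _require_phase(metadata: pd.DataFrame, phase: str, preset: str) -> pd.DataFrame:
    sel = metadata[metadata["phase"] == phase]
    if sel.empty:
        raise ValueError(
            f"preset {preset!r} needs samples with phase == {phase!r}; metadata has "
            f"phases {sorted(metadata['phase'].unique())}"
        )
    return sel


def _pick_components(cfg: PipelineConfig, X, Y, group_ids=None) -> int:
    if cfg.components != "auto":
        return int(cfg.components)
    max_a = min(cfg.max_components, X.shape[0] - 2, X.shape[1])
    a, _ = select_components(
        X, Y, max_a, n_folds=cfg.n_folds, scheme=cfg.cv_scheme,
        group_ids=group_ids, x_scaling=cfg.scaling,
    )
    return a


def _snapshot(cfg: PipelineConfig, outdir: Path, preset: str) -> None:
    payload = dataclasses.asdict(cfg)
    payload["preset"] = preset
    text = json.dumps(payload, indent=1, default=str)
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    (outdir / "config.json").write_text(
        json.dumps({**json.loads(text), "config_hash": digest}, indent=1)
    )
    log.info("preset %s -> %s (config hash %s, seed %d)", preset, outdir, digest, cfg.seed)


def _contrast_analysis(cfg, X_df, meta, outdir, label, time_col=None, positive_class=None,
                       group_col="group"):
    """Shared ptPLS2-DA machinery for the CA and CPR contrasts."""
    X = X_df.to_numpy(dtype=float)
    Y = build_design_matrix(
        meta[group_col], time=meta[time_col] if time_col else None,
        positive_class=positive_class,
    ).to_numpy()
    a = _pick_components(cfg, X, Y)
    report = validate(
        X, Y, a, n_folds=cfg.n_folds, scheme=cfg.cv_scheme,
        n_permutations=cfg.n_permutations, seed=cfg.seed, x_scaling=cfg.scaling,
    )
    scaler = Scaler(cfg.scaling).fit(X)
    ys = Scaler("mean_center").fit(Y)
    res = PLS2(scaler.transform(X), ys.transform(Y), a).fit()
    pt = res.post_transform()
    scores = pt.score_table()
    scores.insert(0, "sample_id", X_df.index)
    scores.insert(1, group_col, meta[group_col].to_numpy())
    aio.write_table(scores.set_index("sample_id"), outdir / f"{label}_scores.csv")
    vip = pd.DataFrame({"variable": X_df.columns, "vip": res.vip()}).set_index("variable")
    aio.write_table(vip.sort_values("vip", ascending=False), outdir / f"{label}_vip.csv")
    stab = stability_selection(X, Y, a, seed=cfg.seed, x_scaling=cfg.scaling)
    stab_df = pd.DataFrame(
        {"variable": X_df.columns, "selection_frequency": stab.selection_frequency}
    ).set_index("variable")
    aio.write_table(
        stab_df.sort_values("selection_frequency", ascending=False),
        outdir / f"{label}_stability.csv",
    )
    summary = {
        "preset": label,
        "n_samples": int(X.shape[0]),
        "n_variables": int(X.shape[1]),
        "components": pt.components_label,
        "R2": report.r2,
        "Q2": report.q2,
        "p_R2": report.permutation_p_r2,
        "p_Q2": report.permutation_p_q2,
        "n_permutations": report.n_permutations,
        "seed": cfg.seed,
        "stable_set": stab_df.index[stab.selection_frequency >= stab.stability_threshold].tolist(),
    }
    (outdir / f"{label}_validation.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_pipeline(config: "PipelineConfig | dict", preset: str) -> Path:
    """Run one preset end to end; returns the run directory."""
    if isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    cfg = config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _snapshot(cfg, outdir, preset)
        quant, metadata, matrix = _load_inputs(cfg)

        if preset == "ca-contrast":
            meta = _require_phase(metadata, "CA", preset)
            X_df = (matrix.data if matrix is not None else quant).loc[meta.index]
            summary = _contrast_analysis(
                cfg, X_df, meta, outdir, "ca_contrast",
                time_col="minute_in_phase", positive_class="ACA",
            )
        elif preset == "asphyxia-bspc":
            meta = _require_phase(metadata, "asphyxia", preset)
            X_all = matrix.data if matrix is not None else quant
            X_df = X_all.loc[meta.index]
            traj = expand_timescale(
                X_df.to_numpy(dtype=float), meta["animal_id"].to_numpy(),
                meta["minute_in_phase"].to_numpy(dtype=float),
                target_duration=cfg.bspc_target_duration,
            )
            ref = (
                metadata.loc[meta.index]
                .query("damage_class == @cfg.bspc_reference_class")["animal_id"]
                .unique()
                .tolist()
            )
            model = BSPC(
                traj, ref, n_components=cfg.bspc_components,
                grid_step=cfg.bspc_grid_step, x_scaling=cfg.scaling,
            ).fit()
            chart = model.chart(k=cfg.bspc_k)
            aio.write_table(chart.points.set_index("animal"), outdir / "bspc_chart.csv")
            aio.write_table(chart.summary, outdir / "bspc_summary.csv")
            # endpoint PCA: baseline vs last asphyxial minute
            base = _require_phase(metadata, "baseline", preset)
            last_rows = meta.loc[
                meta.groupby("animal_id")["minute_in_phase"].idxmax()
            ]
            aca_base = base[base["group"] == "ACA"]
            pca_meta = pd.concat([aca_base, last_rows])
            Xp = X_all.loc[pca_meta.index].to_numpy(dtype=float)
            pca = PCA(Scaler(cfg.scaling).fit_transform(Xp), 2).fit()
            ptab = pd.DataFrame(
                {
                    "sample_id": pca_meta.index,
                    "animal_id": pca_meta["animal_id"].to_numpy(),
                    "phase": pca_meta["phase"].to_numpy(),
                    "damage_class": pca_meta["damage_class"].to_numpy(),
                    "pc1": pca.scores[:, 0],
                    "pc2": pca.scores[:, 1],
                }
            ).set_index("sample_id")
            aio.write_table(ptab, outdir / "endpoint_pca_scores.csv")
            summary = {
                "preset": "asphyxia_bspc",
                "reference_animals": ref,
                "R2": model.r2,
                "Q2": model.q2,
                "k": cfg.bspc_k,
                "flagged_animals": chart.flagged_animals,
                "endpoint_pca_explained_variance": pca.explained_variance_ratio.sum(),
                "seed": cfg.seed,
            }
            (outdir / "bspc_validation.json").write_text(json.dumps(summary, indent=1, default=str))
        else:  # cpr-contrast
            meta = _require_phase(metadata, "CPR", preset)
            meta = meta[meta["group"] == cfg.cpr_group]
            if meta.empty:
                raise ValueError(f"no CPR samples for group {cfg.cpr_group!r}")
            first = meta.loc[meta.groupby("animal_id")["minute_in_phase"].idxmin()].copy()
            last = meta.loc[meta.groupby("animal_id")["minute_in_phase"].idxmax()].copy()
            first["cpr_end"] = "begin"
            last["cpr_end"] = "end"
            both = pd.concat([first, last])
            X_df = (matrix.data if matrix is not None else quant).loc[both.index]
            summary = _contrast_analysis(
                cfg, X_df, both, outdir, "cpr_contrast",
                positive_class="end", group_col="cpr_end",
            )
            # quantified-metabolite effect table over the same endpoints
            tidy = to_tidy(quant, metadata)
            tidy["is_first"] = tidy["sample_id"].isin(first.index)
            tidy["is_last"] = tidy["sample_id"].isin(last.index)
            eff = effect_table(
                tidy, {"is_first": True}, {"is_last": True}, group=cfg.cpr_group,
            )
            aio.write_table(eff, outdir / "cpr_effect_table.csv")
            summary["effect_table"] = "cpr_effect_table.csv"
            (outdir / "cpr_contrast_validation.json").write_text(
                json.dumps(summary, indent=1, default=str)
            )
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
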