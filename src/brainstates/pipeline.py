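"""End-to-end orchestration: simulate -> LEiDA -> metrics -> energy -> PLS.

Each stage reads only persisted artifacts of the previous stage, so any
stage can be rerun in isolation and a full rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import control, io, leida, metrics, pls, synth

__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "stage_simulate", "stage_leida", "stage_metrics", "stage_energy", "stage_pls"]

log = logging.getLogger("brainstates")


@dataclass
class PipelineConfig:
    outdir: str = "brainstates_run"
    manifest: str | None = None          # if None, the simulate stage creates one
    seed: int = 0
    # simulate
    n_subjects: int = 20
    n_regions: int = 218
    n_timepoints: int = 261
    n_states: int = 3
    sampling_interval: float = 1.97
    noise_sd: float = 0.3
    stay_prob: float = synth.DEFAULT_STAY_PROB
    behavior_noise_sd: float = synth.DEFAULT_BEHAVIOR_NOISE_SD
    # leida
    low_hz: float = 0.01
    high_hz: float = 0.1
    k_min: int = 2
    k_max: int = 20
    n_restarts: int = 50
    keep_edges: bool = False
    # energy
    from_state: int = 2
    to_state: int = 1
    rho: float = 1.0
    horizon: float = 1.0
    binarize_states: bool = False
    consensus_fraction: float = 0.5
    n_grid: int = 1001
    # pls
    pls_mode: str = "behavioral"         # or "meancentered"
    behaviors: tuple[str, ...] = ("age", "behavior")
    features: str = "fo"                 # fo | tp | energy
    n_perm: int = 1000
    n_boot: int = 1000
    impute_uniform: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.behaviors = tuple(cfg.behaviors)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        payload = asdict(self)
        payload["behaviors"] = list(self.behaviors)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
        return Path(path)


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    chosen_k: int | None = None
    state_names: list[str] | None = None
    significant_lvs: list[int] | None = None

    def add_stage(self, name: str, **info) -> None:
        if any(s["stage"] == name for s in self.stages):
            raise ValueError(f"stage {name} already recorded")
        self.stages.append({"stage": name, **info})

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
        return Path(path)


def _rel(config: PipelineConfig, path) -> str:
    try:
        return str(Path(path).relative_to(config.outdir))
    except ValueError:
        return str(path)


def _seed_for(config: PipelineConfig, stage: str) -> int:
    # crc32 is stable across processes (str hash is salted per run)
    child = np.random.SeedSequence(config.seed,
                                   spawn_key=(zlib.crc32(stage.encode()) % (2 ** 16),))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def stage_simulate(config: PipelineConfig, report: RunReport) -> Path:
    outdir = Path(config.outdir) / "simulate"
    cohort = synth.generate_cohort(
        n_subjects=config.n_subjects, n_regions=config.n_regions,
        n_timepoints=config.n_timepoints, n_states=config.n_states,
        sampling_interval=config.sampling_interval, noise_sd=config.noise_sd,
        stay_prob=config.stay_prob, behavior_noise_sd=config.behavior_noise_sd,
        seed=config.seed,
    )
    manifest = synth.write_cohort(cohort, outdir)
    report.add_stage("simulate", manifest=_rel(config, manifest), seed=config.seed,
                     n_subjects=config.n_subjects, n_regions=config.n_regions,
                     n_timepoints=config.n_timepoints, n_states=config.n_states)
    log.info("simulate: wrote %d subjects to %s", config.n_subjects, outdir)
    return manifest


def stage_leida(config: PipelineConfig, report: RunReport, manifest_path: Path) -> None:
    outdir = Path(config.outdir) / "leida"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(manifest_path)
    eig: dict[str, np.ndarray] = {}
    for row in manifest.itertuples():
        ts = synth.BoldTimeSeries(row.subject_id, io.read_matrix_tsv(row.ts_path),
                                  config.sampling_interval)
        eig[row.subject_id] = leida.subject_eigenvectors(ts, config.low_hz, config.high_hz)
    pooled, index = leida.pool_eigenvectors(eig, keep_edges=config.keep_edges)
    model = leida.LeidaStates(
        k_range=(config.k_min, config.k_max), n_restarts=config.n_restarts,
        random_state=_seed_for(config, "leida"),
    ).fit(pooled)
    regions_path = manifest_path.parent / "regions.tsv"
    if regions_path.exists():
        model.name_states(io.read_region_table(regions_path)["network_label"])
    sequences = leida.unpool_labels(model.labels_, index)

    io.write_matrix_tsv(outdir / "pooled_eigenvectors.tsv", pooled)
    index.to_csv(outdir / "pooled_index.tsv", sep="\t", index=False)
    io.write_state_model(outdir / "state_model.json", model)
    io.write_sequences(outdir / "state_sequences.tsv", sequences)
    model.validity_.reset_index().to_csv(outdir / "validity.tsv", sep="\t",
                                         index=False, float_format="%.17g")
    report.chosen_k = int(model.chosen_k_)
    report.state_names = list(getattr(model, "state_names_", []))
    report.add_stage("leida", pooled_eigenvectors=int(pooled.shape[0]),
                     chosen_k=int(model.chosen_k_), keep_edges=config.keep_edges,
                     seed=_seed_for(config, "leida"),
                     state_names=report.state_names,
                     outputs=[_rel(config, outdir / f) for f in (
                         "pooled_eigenvectors.tsv", "pooled_index.tsv",
                         "state_model.json", "state_sequences.tsv", "validity.tsv")])
    log.info("leida: %d pooled frames, chosen k=%d", pooled.shape[0], model.chosen_k_)


def stage_metrics(config: PipelineConfig, report: RunReport) -> None:
    outdir = Path(config.outdir) / "metrics"
    outdir.mkdir(parents=True, exist_ok=True)
    model = io.read_state_model(Path(config.outdir) / "leida" / "state_model.json")
    sequences = io.read_sequences(Path(config.outdir) / "leida" / "state_sequences.tsv")
    k = model.chosen_k_
    fo = metrics.cohort_fo_table(sequences, k)
    tp, visited = metrics.cohort_tp_table(sequences, k)
    if config.impute_uniform:
        for sid in tp.index[~visited]:
            block = tp.loc[sid].to_numpy().reshape(k, k)
            block[block.sum(axis=1) == 0] = 1.0 / k
            tp.loc[sid] = block.ravel()
        visited[:] = True
    fo.rename_axis("subject_id").to_csv(outdir / "fo.tsv", sep="\t", float_format="%.17g")
    tp.join(visited).rename_axis("subject_id").to_csv(outdir / "tp.tsv", sep="\t",
                                                      float_format="%.17g")
    n_incomplete = int((~visited).sum())
    if n_incomplete:
        report.warnings.append(f"{n_incomplete} subject(s) with unvisited states")
    report.add_stage("metrics", n_states=int(k), n_incomplete=n_incomplete,
                     outputs=[_rel(config, outdir / "fo.tsv"), _rel(config, outdir / "tp.tsv")])


def stage_energy(config: PipelineConfig, report: RunReport, manifest_path: Path) -> None:
    outdir = Path(config.outdir) / "energy"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(manifest_path)
    model = io.read_state_model(Path(config.outdir) / "leida" / "state_model.json")
    ids = manifest["subject_id"].tolist()
    mats = [io.read_matrix_tsv(p, square=True, symmetric=True)
            for p in manifest["sc_path"]]
    masked, mask = control.consensus_threshold(mats, config.consensus_fraction)
    energies = {}
    for sid, a in zip(ids, masked):
        res = control.transition_energy(
            a, model.centroids_, config.from_state, config.to_state,
            T=config.horizon, rho=config.rho, binarize_states=config.binarize_states,
            n_grid=config.n_grid)
        energies[sid] = res.per_region_energy
        io.write_matrix_tsv(outdir / f"{sid}_region_energy.tsv",
                            res.per_region_energy[:, None])
    table = pd.DataFrame.from_dict(energies, orient="index")
    table.columns = [f"region_{j}" for j in range(table.shape[1])]
    table.rename_axis("subject_id").to_csv(outdir / "energy.tsv", sep="\t",
                                           float_format="%.17g")
    report.add_stage("energy", from_state=config.from_state, to_state=config.to_state,
                     rho=config.rho, horizon=config.horizon,
                     consensus_edges=int(mask.sum() // 2),
                     outputs=[_rel(config, outdir / "energy.tsv")])


def _load_features(config: PipelineConfig) -> tuple[pd.DataFrame, pd.Series]:
    base = Path(config.outdir)
    if config.features == "fo":
        table = pd.read_csv(base / "metrics" / "fo.tsv", sep="\t", index_col="subject_id")
        keep = pd.Series(True, index=table.index)
    elif config.features == "tp":
        raw = pd.read_csv(base / "metrics" / "tp.tsv", sep="\t", index_col="subject_id")
        keep = raw.pop("all_states_visited").astype(bool)
        table = raw
    elif config.features == "energy":
        table = pd.read_csv(base / "energy" / "energy.tsv", sep="\t", index_col="subject_id")
        keep = pd.Series(True, index=table.index)
    else:
        raise ValueError(f"unknown feature block '{config.features}'")
    return table, keep


def stage_pls(config: PipelineConfig, report: RunReport, manifest_path: Path) -> None:
    outdir = Path(config.outdir) / "pls"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(manifest_path, check_files=False).set_index("subject_id")
    table, keep = _load_features(config)
    if not keep.all() and not config.impute_uniform:
        report.warnings.append(
            f"excluding {int((~keep).sum())} subject(s) with unvisited states from PLS")
        table = table.loc[keep]
    manifest = manifest.loc[table.index]
    seed = _seed_for(config, "pls")
    X = table.to_numpy()
    if config.pls_mode == "behavioral":
        Y = manifest[list(config.behaviors)].to_numpy(dtype=float)
        fit = pls.BehavioralPLS(n_perm=config.n_perm, n_boot=config.n_boot,
                                random_state=seed).fit(X, Y)
        extra = {"behavior_saliences": fit.behavior_saliences_.tolist(),
                 "behaviors": list(config.behaviors)}
        scores = fit.brainscores_
    elif config.pls_mode == "meancentered":
        groups = manifest["group"].to_numpy()
        fit = pls.MeanCenteredPLS(n_perm=config.n_perm, n_boot=config.n_boot,
                                  random_state=seed).fit(X, groups)
        extra = {"group_saliences": fit.group_saliences_.tolist(),
                 "group_names": list(fit.group_names_),
                 "group_brainscores": fit.group_brainscores_.tolist(),
                 "group_brainscore_ci": fit.group_brainscore_ci_.tolist()}
        scores = fit.brainscores_
    else:
        raise ValueError(f"unknown pls mode '{config.pls_mode}'")
    payload = {
        "mode": config.pls_mode,
        "feature_block": config.features,
        "feature_names": table.columns.tolist(),
        "singular_values": fit.singular_values_.tolist(),
        "perm_pvalues": fit.perm_pvalues_.tolist(),
        "brain_saliences": fit.brain_saliences_.tolist(),
        "bootstrap_ratios": np.where(np.isfinite(fit.bootstrap_ratios_),
                                     fit.bootstrap_ratios_, None).tolist(),
        "seed": seed,
        **extra,
    }
    (outdir / "pls_result.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame(scores, index=table.index,
                 columns=[f"lv{i+1}" for i in range(scores.shape[1])]
                 ).rename_axis("subject_id").to_csv(outdir / "brainscores.tsv", sep="\t",
                                                    float_format="%.17g")
    sig = [i + 1 for i, p in enumerate(fit.perm_pvalues_) if p < 0.05]
    report.significant_lvs = sig
    report.add_stage("pls", mode=config.pls_mode, features=config.features,
                     n_perm=config.n_perm, n_boot=config.n_boot, seed=seed,
                     significant_lvs=sig,
                     outputs=[_rel(config, outdir / "pls_result.json"),
                              _rel(config, outdir / "brainscores.tsv")])


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order; returns the provenance report.

    Identical config + seed reproduce byte-identical artifacts.
    """
    report = RunReport()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    if config.manifest is None:
        manifest_path = stage_simulate(config, report)
    else:
        manifest_path = Path(config.manifest)
        report.add_stage("input", manifest=_rel(config, manifest_path))
    stage_leida(config, report, manifest_path)
    stage_metrics(config, report)
    stage_energy(config, report, manifest_path)
    stage_pls(config, report, manifest_path)
    report.save(outdir / "run_report.json")
    return report
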