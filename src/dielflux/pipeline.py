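"""End-to-end pipeline: generation → simulation → fitting → statistics.

A single YAML config drives every stage; all stochastic stages receive
seeds spawned deterministically from one master seed, so re-running the
same config reproduces byte-identical numeric outputs.  Every run writes
its intermediate tables, a JSON manifest (inputs, outputs, seeds, package
version) and a human-readable log into the run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import assign_members, replicate_variance_weights, vs_cluster
from .design import ExperimentDesign
from .fitting import ParamGrid, default_grid, grid_search, select_variant
from .light import IrradianceProfile
from .model import SimConfig
from .quantitation import (fold_change_analysis, noon_night_groups,
                           spike_info_from_table, transcripts_per_cell,
                           znormalize)
from .rhythm import rhythm_test
from .synthetic import (generate_metabolite_table, generate_transcript_reads)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("dielflux")

DEFAULT_CONFIG = {
    "seed": 0,
    "design": {},
    "light": {},
    "sim": {},
    "generate": {
        "n_peaks": 281,
        "n_genes": 4278,
        "noise_sd": 0.3,
        "depth": 19_200_000,
    },
    "fit": {
        "enabled": True,
        "variants": ["base", "o", "h", "b", "oh", "ob", "hb", "ohb"],
        "adjust": "standard",
        "alpha": 0.05,
        "pair": None,       # "met_feature:gene_feature"; default: first peak/gene
        "grids": None,      # optional {variant: {param: [values]}}
    },
    "analysis": {
        "alpha": 0.05,
        "membership_threshold": 0.5,
        "c_candidates": [2, 3, 4, 5, 6],
        "n_perm": 199,
        "rhythm_features": 64,  # rhythm-test the first K metabolite peaks
    },
    "stages": ["generate", "quantify", "cluster", "rhythm", "foldchange", "fit"],
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    design: ExperimentDesign
    light: IrradianceProfile
    sim: SimConfig
    generate: dict
    fit: dict
    analysis: dict
    stages: list

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = _merge(DEFAULT_CONFIG, raw or {})
        light = IrradianceProfile(**cfg["light"])
        design = ExperimentDesign(light=light, **cfg["design"])
        sim = SimConfig(**cfg["sim"])
        unknown = set(cfg["stages"]) - set(DEFAULT_CONFIG["stages"])
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        return cls(seed=int(cfg["seed"]), design=design, light=light, sim=sim,
                   generate=cfg["generate"], fit=cfg["fit"],
                   analysis=cfg["analysis"], stages=list(cfg["stages"]))


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key, val in base.items():
        if key in override and isinstance(val, dict) and isinstance(override[key], dict):
            out[key] = _merge(val, override[key])
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = val
    extra = set(override) - set(base)
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    return out


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured stages and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = {
        "metabolites": int(seeds[0].generate_state(1)[0] % 2**31),
        "reads": int(seeds[1].generate_state(1)[0] % 2**31),
        "cluster": int(seeds[2].generate_state(1)[0] % 2**31),
        "rhythm": int(seeds[3].generate_state(1)[0] % 2**31),
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": config.stages,
        "outputs": {},
        "status": "running",
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    state: dict = {}
    try:
        for stage in config.stages:
            log.info("stage %s: start", stage)
            _STAGES[stage](config, outdir, stage_seeds, state, manifest)
            log.info("stage %s: done", stage)
        manifest["status"] = "complete"
    except Exception as exc:  # manifest records partial completion
        manifest["status"] = f"failed in stage {stage}: {exc}"
        raise
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.removeHandler(handler)
        handler.close()
    return outdir


def _record(manifest, name, path):
    manifest["outputs"][name] = str(path)


def _stage_generate(config, outdir, seeds, state, manifest):
    mets, met_truth = generate_metabolite_table(
        config.design, n_peaks=config.generate["n_peaks"],
        noise_sd=config.generate["noise_sd"], seed=seeds["metabolites"])
    reads, read_truth = generate_transcript_reads(
        config.design, n_genes=config.generate["n_genes"],
        depth=config.generate["depth"], seed=seeds["reads"])
    mets.to_tsv(outdir / "metabolites.tsv")
    met_truth.to_files(outdir / "metabolites")
    reads.to_tsv(outdir / "reads.tsv")
    read_truth.to_files(outdir / "reads")
    state.update(mets=mets, met_truth=met_truth, reads=reads,
                 read_truth=read_truth)
    for name in ("metabolites.tsv", "reads.tsv", "metabolites.truth.json",
                 "reads.truth.json"):
        _record(manifest, name, outdir / name)


def _require_generated(config, outdir, seeds, state):
    if "mets" not in state:
        _stage_generate(config, outdir, seeds, state, {"outputs": {}})


def _stage_quantify(config, outdir, seeds, state, manifest):
    _require_generated(config, outdir, seeds, state)
    genes, spikes = spike_info_from_table(state["reads"],
                                          state["read_truth"].spike_copies)
    result = transcripts_per_cell(genes, spikes)
    result.tpc.to_csv(outdir / "transcripts_per_cell.tsv", sep="\t")
    state["tpc"] = result.tpc
    _record(manifest, "transcripts_per_cell.tsv", outdir / "transcripts_per_cell.tsv")


def _stage_cluster(config, outdir, seeds, state, manifest):
    _require_generated(config, outdir, seeds, state)
    profiles, weights = replicate_variance_weights(state["mets"])
    model = vs_cluster(profiles, c_candidates=config.analysis["c_candidates"],
                       weights=weights, seed=seeds["cluster"])
    labels = assign_members(model, config.analysis["membership_threshold"])
    out = model.membership.copy()
    out["assigned"] = labels
    out.to_csv(outdir / "clusters.tsv", sep="\t")
    model.candidates.to_csv(outdir / "cluster_selection.tsv", sep="\t", index=False)
    state["clusters"] = model
    _record(manifest, "clusters.tsv", outdir / "clusters.tsv")
    _record(manifest, "cluster_selection.tsv", outdir / "cluster_selection.tsv")


def _stage_rhythm(config, outdir, seeds, state, manifest):
    _require_generated(config, outdir, seeds, state)
    mets = state["mets"]
    z, _ = znormalize(mets.per_cell())
    k = config.analysis["rhythm_features"]
    result = rhythm_test(z.iloc[:k], mets.sample_times, mets.replicates,
                         n_perm=config.analysis["n_perm"],
                         alpha=config.analysis["alpha"], seed=seeds["rhythm"],
                         clock_offset=config.design.clock_offset)
    result.table.to_csv(outdir / "rhythm.tsv", sep="\t")
    state["rhythm"] = result
    _record(manifest, "rhythm.tsv", outdir / "rhythm.tsv")


def _stage_foldchange(config, outdir, seeds, state, manifest):
    if "tpc" not in state:
        _stage_quantify(config, outdir, seeds, state, {"outputs": {}})
    tpc = state["tpc"]
    noon, night = noon_night_groups(tpc.columns, config.design.clock_offset)
    table = fold_change_analysis(tpc, noon, night, alpha=config.analysis["alpha"])
    table.to_csv(outdir / "fold_change.tsv", sep="\t")
    state["fold_change"] = table
    _record(manifest, "fold_change.tsv", outdir / "fold_change.tsv")


def _stage_fit(config, outdir, seeds, state, manifest):
    _require_generated(config, outdir, seeds, state)
    mets, reads = state["mets"], state["reads"]
    pair = config.fit.get("pair")
    if pair:
        met_name, gene_name = pair.split(":")
    else:
        met_name = mets.values.index[0]
        gene_name = state["read_truth"].tpc_true.index[0]
    met_series = _per_timepoint(mets.per_cell().loc[met_name], mets)
    genes, spikes = spike_info_from_table(reads, state["read_truth"].spike_copies)
    tpc = state.get("tpc")
    if tpc is None:
        tpc = transcripts_per_cell(genes, spikes).tpc
        state["tpc"] = tpc
    gene_series = _per_timepoint(tpc.loc[gene_name], reads)

    results = {}
    lines = []
    for variant in config.fit["variants"]:
        grids = config.fit.get("grids") or {}
        if variant in grids:
            grid = ParamGrid(variant=variant, values=grids[variant])
        else:
            grid = default_grid(variant)
        res = grid_search(grid, config.design, met_series, gene_series,
                          config.sim, config.light, alpha=config.fit["alpha"])
        results[variant] = res
        lines.append(f"{variant}\t{res.n_combinations} combinations\t"
                     f"{res.n_saved} saved\t{res.n_unfittable} unfittable")
        log.info("fit %s: %d/%d saved", variant, res.n_saved, res.n_combinations)
    report = select_variant(results, n=config.design.n_timepoints,
                            mode=config.fit["adjust"])
    report.to_frame().to_csv(outdir / "fit_report.tsv", sep="\t", index=False)
    summary = (f"pair: {met_name}:{gene_name}\n"
               f"adjustment: {report.adjust_mode}\nwinner: {report.winner}\n"
               + "\n".join(lines) + "\n")
    (outdir / "fit_report.txt").write_text(summary)
    state["fit_report"] = report
    _record(manifest, "fit_report.tsv", outdir / "fit_report.tsv")
    _record(manifest, "fit_report.txt", outdir / "fit_report.txt")


def _per_timepoint(series, matrix) -> np.ndarray:
    """Reshape one feature's sample values to (timepoint, replicate)."""
    import pandas as pd

    times = np.array([float(c.split("_")[0][1:]) for c in series.index])
    frame = pd.DataFrame({"t": times, "v": series.to_numpy(dtype=float)})
    ordered = frame.sort_values("t", kind="stable")
    n_t = len(np.unique(times))
    return ordered["v"].to_numpy().reshape(n_t, -1)


_STAGES = {
    "generate": _stage_generate,
    "quantify": _stage_quantify,
    "cluster": _stage_cluster,
    "rhythm": _stage_rhythm,
    "foldchange": _stage_foldchange,
    "fit": _stage_fit,
}
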