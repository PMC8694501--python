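"""End-to-end pipeline: simulate -> cluster x M -> ensemble -> select-k ->
markers -> NTP on an external cohort -> signature scoring -> survival and
mutation statistics.

Every stage writes plain TSV/GMT/JSON artifacts into the run directory and
registers them in ``manifest.json``; a rerun with an existing run directory
skips stages whose outputs are already recorded (resumability) and yields
bit-identical final artifacts under the same seed.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ALGORITHMS, AlgorithmParams, run_algorithm
from .ensemble import adjusted_rand_index, build_consensus_matrix, ensemble_labels
from .io import GeneSetCollection, read_labels, write_gmt, write_labels, write_matrix
from .markers import build_templates, derive_markers, ntp_classify
from .model_selection import select_k
from .scoring import compare_by_subtype, ssgsea_scores
from .simulate import SimulationConfig, simulate_external_cohort, simulate_multiomics, write_dataset
from .survival import cox_multivariable, km_logrank, mutation_stats

logger = logging.getLogger("moclust")

STAGES = (
    "simulate", "select_k", "cluster", "ensemble", "markers",
    "ntp", "score", "survival", "mutation",
)


@dataclass
class PipelineConfig:
    """Run settings for the full analysis."""

    outdir: str = "run"
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHMS
    k_min: int = 2
    k_max: int = 6
    B_gap: int = 10
    B_cpi: int = 10
    prior_k: int | None = None
    n_top: int = 100
    n_perm: int = 1000
    fdr_cut: float = 0.05
    external_batch_shift: float = 0.5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("algorithm list must be non-empty")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        from .simulate import LayerSpec
        if "layer_specs" in sim_raw:
            sim_raw["layer_specs"] = tuple(LayerSpec(**d) for d in sim_raw["layer_specs"])
        for tup_key in ("proportions", "hazard_rates", "censor_window", "gleason_high_props"):
            if tup_key in sim_raw:
                sim_raw[tup_key] = tuple(sim_raw[tup_key])
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(simulation=SimulationConfig(**sim_raw), **raw)


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"version": __version__, "stages": {}, "timings": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def done(self, stage: str) -> bool:
        outputs = self.data["stages"].get(stage)
        return bool(outputs) and all((self.path.parent / p).exists() for p in outputs)

    def record(self, stage: str, outputs: list[str], elapsed: float) -> None:
        self.data["stages"][stage] = outputs
        self.data["timings"][stage] = round(elapsed, 3)
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, writing artifacts into ``config.outdir``.

    Returns the run directory. A stage failure aborts with the stage name
    in the exception message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json")
    manifest.data["seed"] = config.seed

    state: dict = {}

    def stage(name: str, fn) -> None:
        if manifest.done(name) and name in _LOADERS:
            logger.info("stage %s: outputs present, skipping", name)
            _LOADERS[name](outdir, config, state)
            return
        t0 = time.time()
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.record(name, outputs, time.time() - t0)
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    # --- simulate -----------------------------------------------------------
    def _simulate() -> list[str]:
        sim = config.simulation.with_(seed=config.seed)
        dataset, truth = simulate_multiomics(sim)
        write_dataset(dataset, truth, outdir)
        state["dataset"], state["truth"], state["sim"] = dataset, truth, sim
        return [f"layer_{l.name}.tsv" for l in dataset.layers] + ["clinical.tsv", "true_labels.tsv"]

    stage("simulate", _simulate)
    dataset, truth = state["dataset"], state["truth"]

    # --- select k -----------------------------------------------------------
    def _select() -> list[str]:
        curve = select_k(dataset, range(config.k_min, config.k_max + 1),
                         B_gap=config.B_gap, B_cpi=config.B_cpi,
                         seed=config.seed, prior_k=config.prior_k)
        pd.DataFrame({
            "k": curve.k_values, "cpi": curve.cpi_mean, "cpi_sd": curve.cpi_sd,
            "gap": curve.gap, "gap_sd": curve.gap_sd,
        }).to_csv(outdir / "selection_curves.tsv", sep="\t", index=False)
        (outdir / "chosen_k.json").write_text(json.dumps(
            {"chosen_k": curve.chosen_k, "gap_rule_k": curve.gap_rule_k}))
        state["k"] = curve.chosen_k
        return ["selection_curves.tsv", "chosen_k.json"]

    stage("select_k", _select)
    k = state["k"]

    # --- per-algorithm clustering -------------------------------------------
    def _cluster() -> list[str]:
        params = AlgorithmParams(seed=config.seed)
        results = []
        outs = []
        for name in config.algorithms:
            r = run_algorithm(name, dataset, k, params)
            write_labels(r.labels, outdir / f"labels_{name}.tsv", r.sample_ids)
            outs.append(f"labels_{name}.tsv")
            results.append(r)
        state["results"] = results
        return outs

    stage("cluster", _cluster)

    # --- consensus ensemble ---------------------------------------------------
    def _ensemble() -> list[str]:
        M = build_consensus_matrix(state["results"])
        ens = ensemble_labels(M, k)
        write_matrix(pd.DataFrame(M.values, index=M.sample_ids, columns=M.sample_ids),
                     outdir / "consensus_matrix.tsv")
        write_labels(ens.labels, outdir / "final_labels.tsv", ens.sample_ids)
        (outdir / "ensemble_summary.json").write_text(json.dumps({
            "k": ens.k, "pac": ens.pac, "mean_silhouette": ens.mean_silhouette,
            "ari_vs_truth": adjusted_rand_index(truth.true_labels, ens.labels),
        }))
        state["final_labels"] = ens.labels
        return ["consensus_matrix.tsv", "final_labels.tsv", "ensemble_summary.json"]

    stage("ensemble", _ensemble)
    final_labels = state["final_labels"]

    # --- markers --------------------------------------------------------------
    def _markers() -> list[str]:
        mrna = dataset.layers[0]
        ms = derive_markers(mrna, final_labels, n_top=config.n_top)
        write_gmt({f"subtype{s}_markers": genes for s, genes in ms.markers.items()},
                  outdir / "markers.gmt")
        state["markers"] = ms
        return ["markers.gmt"]

    stage("markers", _markers)

    # --- NTP on an external cohort ---------------------------------------------
    def _ntp() -> list[str]:
        templates = build_templates(state["markers"])
        sim = config.simulation.with_(seed=config.seed,
                                      batch_shift_sd=config.external_batch_shift)
        ext_layer, ext_truth = simulate_external_cohort(sim, seed2=config.seed + 1)
        res = ntp_classify(ext_layer, templates, n_perm=config.n_perm,
                           fdr_cut=config.fdr_cut, seed=config.seed)
        res.to_csv(outdir / "ntp_external.tsv", sep="\t")
        write_labels(ext_truth.true_labels, outdir / "external_true_labels.tsv",
                     ext_layer.sample_ids)
        return ["ntp_external.tsv", "external_true_labels.tsv"]

    stage("ntp", _ntp)

    # --- signature scoring ------------------------------------------------------
    def _score() -> list[str]:
        sets = GeneSetCollection({f"subtype{s}_markers": genes
                                  for s, genes in state["markers"].markers.items() if genes})
        scores = ssgsea_scores(dataset.layers[0], sets)
        scores.to_csv(outdir / "signature_scores.tsv", sep="\t")
        comp = compare_by_subtype(scores, final_labels)
        comp.table.to_csv(outdir / "signature_comparison.tsv", sep="\t")
        return ["signature_scores.tsv", "signature_comparison.tsv"]

    stage("score", _score)

    # --- survival ---------------------------------------------------------------
    def _survival() -> list[str]:
        clin = dataset.clinical
        km = km_logrank(clin["rfs_months"], clin["rfs_event"], final_labels)
        (outdir / "logrank.json").write_text(json.dumps(
            {"chi_square": km.chi_square, "p_value": km.p_value, "df": km.df}))
        # reference subtype = best prognosis (lowest event rate)
        tab = clin.copy()
        tab["subtype"] = final_labels
        rates = tab.groupby("subtype")["rfs_event"].mean()
        ref = int(rates.idxmin())
        fit = cox_multivariable(tab, ["subtype", "age", "psa", "t_stage", "gleason"],
                                references={"subtype": ref,
                                            "t_stage": int(tab["t_stage"].min()),
                                            "gleason": int(tab["gleason"].min())})
        fit.summary.to_csv(outdir / "cox_table.tsv", sep="\t")
        return ["logrank.json", "cox_table.tsv"]

    stage("survival", _survival)

    # --- mutation stats ------------------------------------------------------------
    def _mutation() -> list[str]:
        binary = [l for l in dataset.layers if l.kind == "binary"]
        if not binary:
            return []
        summary = mutation_stats(binary[0], final_labels)
        summary.per_gene.to_csv(outdir / "mutation_enrichment.tsv", sep="\t")
        summary.tmb.to_csv(outdir / "tmb.tsv", sep="\t")
        return ["mutation_enrichment.tsv", "tmb.tsv"]

    stage("mutation", _mutation)
    return outdir


# loaders used when a completed stage is skipped on resume
def _load_simulate(outdir: Path, config: PipelineConfig, state: dict) -> None:
    sim = config.simulation.with_(seed=config.seed)
    dataset, truth = simulate_multiomics(sim)  # deterministic regeneration
    state["dataset"], state["truth"], state["sim"] = dataset, truth, sim


def _load_select(outdir: Path, config: PipelineConfig, state: dict) -> None:
    state["k"] = int(json.loads((outdir / "chosen_k.json").read_text())["chosen_k"])


def _load_cluster(outdir: Path, config: PipelineConfig, state: dict) -> None:
    from .cluster import ClusteringResult
    results = []
    for name in config.algorithms:
        lab = read_labels(outdir / f"labels_{name}.tsv")
        results.append(ClusteringResult(algorithm=name, k=int(lab.max()),
                                        labels=lab.to_numpy(), sample_ids=list(lab.index)))
    state["results"] = results


def _load_ensemble(outdir: Path, config: PipelineConfig, state: dict) -> None:
    state["final_labels"] = read_labels(outdir / "final_labels.tsv").to_numpy()


def _load_markers(outdir: Path, config: PipelineConfig, state: dict) -> None:
    from .io import read_gmt
    from .markers import MarkerSet
    coll = read_gmt(outdir / "markers.gmt")
    markers = {int(name.replace("subtype", "").replace("_markers", "")): genes
               for name, genes in coll}
    state["markers"] = MarkerSet(markers=markers, n_top=config.n_top)


def _noop(outdir: Path, config: PipelineConfig, state: dict) -> None:
    pass


_LOADERS = {
    "simulate": _load_simulate,
    "select_k": _load_select,
    "cluster": _load_cluster,
    "ensemble": _load_ensemble,
    "markers": _load_markers,
    "ntp": _noop,
    "score": _noop,
    "survival": _noop,
    "mutation": _noop,
}
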