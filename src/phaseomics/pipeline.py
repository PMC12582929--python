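"""End-to-end orchestration: simulate -> differential -> PCA -> benchmark ->
GAT -> concordance, with a manifest recording inputs, seeds and outputs.

All numeric TSV output is written with ``repr`` float formatting, so a rerun
under the same seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import ModelSpec, build_supervised_table, rank_models, run_loocv
from .differential import analyze, significant_features
from .gat import (GATConfig, TrainingSchedule, build_graph, eligible_proteins,
                  gat_loocv)
from .io import write_abundance_table, write_pathway_annotations, write_sample_metadata
from .pca import feature_pca, project_biplot, sample_pca
from .report import (concordance_summary, cross_phase_summary, direction_table,
                     predicted_fold_changes)
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("phaseomics")

DEFAULT_CONFIG = {
    "simulate": {},                # SimulationConfig fields
    "differential": {"alpha": 0.05, "fc_threshold": 0.58, "min_detected": 3},
    "pca": {"n_components": 2},
    "models": {"families": ["Ridge", "Lasso", "PLS", "RandomForest", "GBT"]},
    "gnn": {"enabled": True, "hidden_dim": 128, "heads": 4, "dropout": 0.3,
            "epochs": 300},
    "report": {"minimal_band": 0.58},
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=lambda v: repr(v),
              index_label=index_label)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: str | Path | dict | None, outdir: str | Path,
                 seed: int | None = None) -> dict:
    """Run every stage on a simulated dataset; returns the manifest dict."""
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg["seed"],
                      "config": cfg, "outputs": {}}

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = str(path)

    # -- simulate ----------------------------------------------------------
    try:
        sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg.get("simulate", {}))
        truth, metab, prot = simulate_dataset(sim_cfg)
        phases = list(sim_cfg.phases)
        for ph in phases:
            for tag, m in (("metabolomics", metab[ph]), ("proteomics", prot[ph])):
                p = out / f"{tag}_{ph}.tsv"
                write_abundance_table(m, p)
                record("simulate", f"{tag}_{ph}", p)
        write_sample_metadata(
            [s for ph in phases for s in metab[ph].samples],
            out / "samples.tsv")
        record("simulate", "samples", out / "samples.tsv")
        write_pathway_annotations(truth.pathway_assignment, out / "pathways.tsv")
        record("simulate", "pathways", out / "pathways.tsv")
        truth.to_json(out / "truth.json")
        record("simulate", "truth", out / "truth.json")
    except Exception as e:                               # noqa: BLE001
        raise StageError("simulate", e) from e

    # -- normalize ---------------------------------------------------------
    # simulated abundances are emitted on the normalized scale already
    # (internal-standard / wet-weight division applies to real inputs only),
    # so this stage just records the matrices it passes through
    for ph in phases:
        record("normalize", f"metabolomics_{ph}",
               out / f"metabolomics_{ph}.tsv")
        record("normalize", f"proteomics_{ph}", out / f"proteomics_{ph}.tsv")

    # -- differential (per phase) -----------------------------------------
    diff: dict[str, pd.DataFrame] = {}
    try:
        d = cfg["differential"]
        for ph in phases:
            res = analyze(metab[ph], alpha=d["alpha"],
                          fc_threshold=d["fc_threshold"],
                          min_detected=d["min_detected"])
            diff[ph] = res
            p = out / f"differential_{ph}.tsv"
            _write_tsv(res, p)
            record("differential", ph, p)
    except Exception as e:
        raise StageError("differential", e) from e

    # -- pca ---------------------------------------------------------------
    try:
        for ph in phases:
            res = sample_pca(metab[ph], n_components=cfg["pca"]["n_components"])
            p = out / f"pca_scores_{ph}.tsv"
            _write_tsv(res.scores, p, index_label="sample_id")
            record("pca", f"scores_{ph}", p)
            sig = significant_features(diff[ph])
            if len(sig) >= 2:
                fres = feature_pca(metab[ph], sig)
                bip = project_biplot(fres, truth.pathway_assignment, sig)
                bp = out / f"biplot_{ph}.tsv"
                _write_tsv(bip.set_index("feature_id"), bp)
                record("pca", f"biplot_{ph}", bp)
    except Exception as e:
        raise StageError("pca", e) from e

    # -- supervised table --------------------------------------------------
    t0, t1 = phases[0], phases[1]
    try:
        table = build_supervised_table(metab[t0], metab[t1], prot[t0], prot[t1])
    except Exception as e:
        raise StageError("table", e) from e

    # -- classical benchmark ----------------------------------------------
    try:
        results = []
        for fam in cfg["models"]["families"]:
            r = run_loocv(table, ModelSpec(family=fam, seed=cfg["seed"]))
            results.append(r)
            p = out / f"loocv_{fam}.tsv"
            _write_tsv(r.predictions, p)
            record("benchmark", fam, p)
        ranking = rank_models(results)
        p = out / "model_ranking.tsv"
        _write_tsv(ranking.set_index("family"), p)
        record("benchmark", "ranking", p)
        best = {r.family: r for r in results}[ranking["family"].iloc[0]]
    except Exception as e:
        raise StageError("benchmark", e) from e

    # -- gnn ---------------------------------------------------------------
    gat_res = None
    if cfg["gnn"].get("enabled", True):
        try:
            g = build_graph(truth.pathway_assignment,
                            metab[t0].analysis_features,
                            prot[t0].analysis_features)
            gcfg = GATConfig(hidden_dim=cfg["gnn"]["hidden_dim"],
                             heads=cfg["gnn"]["heads"],
                             dropout=cfg["gnn"]["dropout"])
            sched = TrainingSchedule(epochs=cfg["gnn"]["epochs"],
                                     seed=cfg["seed"])
            gat_res = gat_loocv(g, table, gcfg, sched)
            edge_df = pd.DataFrame(
                [(g.node_ids[i], g.node_ids[j],
                  ";".join(sorted(g.provenance[(i, j)])))
                 for i, j in g.edges],
                columns=["node_a", "node_b", "pathways"])
            p = out / "graph_edges.tsv"
            edge_df.to_csv(p, sep="\t", index=False)
            record("gnn", "edges", p)
            (out / "eligible_proteins.txt").write_text(
                "\n".join(eligible_proteins(g)) + "\n")
            record("gnn", "eligible", out / "eligible_proteins.txt")
            p = out / "gat_predictions.tsv"
            _write_tsv(gat_res.predictions, p)
            record("gnn", "predictions", p)
        except Exception as e:
            raise StageError("gnn", e) from e

    # -- concordance -------------------------------------------------------
    try:
        sets, heat = cross_phase_summary(diff)
        p = out / "crossphase_heatmap.tsv"
        _write_tsv(heat, p)
        record("report", "heatmap", p)
        (out / "crossphase_sets.json").write_text(
            json.dumps(sets, indent=1, sort_keys=True))
        record("report", "sets", out / "crossphase_sets.json")

        meta = prot[t1].samples
        obs_all = np.log2(
            prot[t1].data.loc[:, prot[t1].strain_columns("MUT")].mean(axis=1)
            / prot[t1].data.loc[:, prot[t1].strain_columns("WT")].mean(axis=1))
        source = gat_res if gat_res is not None else best
        pred_abund = 2.0 ** source.predictions.dropna(axis=1, how="any")
        pred_fc = predicted_fold_changes(pred_abund, meta)
        obs_fc = obs_all.reindex(pred_fc.index)
        tab = direction_table(pred_fc, obs_fc,
                              minimal_band=cfg["report"]["minimal_band"])
        p = out / "concordance.tsv"
        _write_tsv(tab, p, index_label="protein_id")
        record("report", "concordance", p)
        summary = concordance_summary(pred_fc, obs_fc,
                                      minimal_band=cfg["report"]["minimal_band"])
        manifest["concordance"] = summary
    except Exception as e:
        raise StageError("report", e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
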