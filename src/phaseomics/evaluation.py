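"""Self-validation experiments on synthetic data with known ground truth.

These drive the parameter-recovery checks: differential-stage sensitivity /
FDR against planted effects, and predicted-vs-true fold-change concordance
for the Ridge and GAT regressors under leave-one-out cross-validation.
"""

from __future__ import annotations

import numpy as np

from .benchmark import ModelSpec, build_supervised_table, run_loocv
from .differential import analyze
from .gat import GATConfig, TrainingSchedule, build_graph, eligible_proteins, gat_loocv
from .report import pearson_concordance, predicted_fold_changes
from .simulate import SimulationConfig, simulate_dataset


def differential_recovery(n_seeds: int = 200, seed0: int = 0,
                          effect_log2fc: float = 1.0,
                          noise_sd_log2: float = 0.3,
                          n_metabolites: int = 60) -> tuple[float, float]:
    """Mean sensitivity and FDR of the significance gate over seeds."""
    sens, fdr = [], []
    for s in range(seed0, seed0 + n_seeds):
        cfg = SimulationConfig(
            n_metabolites=n_metabolites, n_proteins=2, n_pathways=4,
            frac_affected=0.3, effect_log2fc=effect_log2fc,
            noise_sd_log2=noise_sd_log2, seed=s, phases=("OD0.6",))
        truth, metab, _ = simulate_dataset(cfg, censor=False)
        res = analyze(metab["OD0.6"])
        called = set(res.index[res["significant"]])
        planted = set(truth.affected_metabolites)
        sens.append(len(called & planted) / len(planted))
        fdr.append(len(called - planted) / len(called) if called else 0.0)
    return float(np.mean(sens)), float(np.mean(fdr))


def _concordance_setup(noise_sd_log2: float, protein_noise_sd_log2: float,
                       seed: int):
    cfg = SimulationConfig(
        n_metabolites=12, n_proteins=6, n_pathways=3, frac_affected=0.5,
        effect_log2fc=1.0, noise_sd_log2=noise_sd_log2,
        protein_noise_sd_log2=protein_noise_sd_log2, seed=seed,
        phases=("OD0.6", "OD2.0"))
    truth, metab, prot = simulate_dataset(cfg, censor=False)
    table = build_supervised_table(metab["OD0.6"], metab["OD2.0"],
                                   prot["OD0.6"], prot["OD2.0"])
    g = build_graph(truth.pathway_assignment,
                    metab["OD0.6"].feature_ids, prot["OD0.6"].feature_ids)
    meta = prot["OD2.0"].samples
    return truth, table, g, meta


def _truth_vs_pred_r(truth, predictions, meta, phase="OD2.0") -> float:
    pred_fc = predicted_fold_changes(2.0 ** predictions, meta)
    true_fc = np.array([truth.protein_log2fc(p, phase) for p in pred_fc.index])
    return pearson_concordance(pred_fc.to_numpy(), true_fc)


def ridge_concordance(noise_sd_log2: float = 0.0,
                      protein_noise_sd_log2: float = 0.0,
                      seed: int = 0) -> float:
    """Pearson r between Ridge-LOOCV predicted and planted protein log2FC."""
    truth, table, g, meta = _concordance_setup(noise_sd_log2,
                                               protein_noise_sd_log2, seed)
    elig = [p for p in eligible_proteins(g) if p in table.Y.columns]
    res = run_loocv(table, ModelSpec("Ridge", seed=seed))
    return _truth_vs_pred_r(truth, res.predictions[elig], meta)


def gat_concordance(noise_sd_log2: float = 0.0,
                    protein_noise_sd_log2: float = 0.0,
                    seed: int = 0, epochs: int = 300) -> float:
    """Pearson r between GAT-LOOCV predicted and planted protein log2FC."""
    truth, table, g, meta = _concordance_setup(noise_sd_log2,
                                               protein_noise_sd_log2, seed)
    res = gat_loocv(g, table, GATConfig(),
                    TrainingSchedule(epochs=epochs, seed=seed))
    return _truth_vs_pred_r(truth, res.predictions, meta)


def gat_concordance_median(n_seeds: int, seed0: int = 0,
                           noise_sd_log2: float = 0.3,
                           protein_noise_sd_log2: float = 0.1,
                           epochs: int = 300) -> float:
    rs = [gat_concordance(noise_sd_log2, protein_noise_sd_log2,
                          seed=s, epochs=epochs)
          for s in range(seed0, seed0 + n_seeds)]
    return float(np.median(rs))
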