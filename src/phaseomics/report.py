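"""Predicted-vs-observed fold-change concordance and cross-phase summaries."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import SampleMeta
from .differential import FC_THRESHOLD_DEFAULT


def predicted_fold_changes(preds: pd.DataFrame, meta: list[SampleMeta]) -> pd.Series:
    """log2(mean_MUT / mean_WT) per protein over replicate-level predictions.

    ``preds`` holds abundance-scale predictions, rows indexed by sample id
    (or the benchmark row key ``STRAIN_r<k>``), one column per protein.
    """
    strain_of = {}
    for s in meta:
        strain_of[s.sample_id] = s.strain
        strain_of[f"{s.strain}_r{s.replicate}"] = s.strain
    strains = [strain_of.get(r) for r in preds.index]
    if any(s is None for s in strains):
        unknown = [r for r, s in zip(preds.index, strains) if s is None]
        raise ValueError(f"rows not in metadata: {unknown}")
    strains = np.asarray(strains)
    for strain in ("WT", "MUT"):
        if not (strains == strain).any():
            raise ValueError(f"no {strain} predictions present")
    mut = preds.loc[strains == "MUT"].mean(axis=0)
    wt = preds.loc[strains == "WT"].mean(axis=0)
    if (mut <= 0).any() or (wt <= 0).any():
        raise ValueError("non-positive strain mean; predictions must be on "
                         "the abundance scale")
    return pd.Series(np.log2(mut / wt), index=preds.columns, name="log2fc")


def pearson_concordance(pred_fc, obs_fc) -> float:
    """Pearson correlation between aligned fold-change vectors.

    Returns NaN (with a warning) when either vector has zero variance.
    Requires n >= 3.
    """
    a = np.asarray(pred_fc, dtype=float)
    b = np.asarray(obs_fc, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be aligned 1-d arrays")
    if len(a) < 3:
        raise ValueError("Pearson r needs at least 3 points")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance: Pearson r undefined", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def direction_table(pred_fc: pd.Series, obs_fc: pd.Series,
                    minimal_band: float = FC_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Directional call per protein: down / up / minimal, plus agreement.

    A fold change within ``(-minimal_band, +minimal_band)`` is "minimal".
    """
    if not pred_fc.index.equals(obs_fc.index):
        raise ValueError("prediction and observation indices differ")

    def call(v: pd.Series) -> pd.Series:
        return pd.Series(np.where(v <= -minimal_band, "down",
                                  np.where(v >= minimal_band, "up", "minimal")),
                         index=v.index)

    pc, oc = call(pred_fc), call(obs_fc)
    return pd.DataFrame({
        "predicted_log2fc": pred_fc,
        "observed_log2fc": obs_fc,
        "predicted_call": pc,
        "observed_call": oc,
        "agreement": pc == oc,
    })


def concordance_summary(pred_fc: pd.Series, obs_fc: pd.Series,
                        minimal_band: float = FC_THRESHOLD_DEFAULT) -> dict:
    table = direction_table(pred_fc, obs_fc, minimal_band)
    return {
        "pearson_r": pearson_concordance(pred_fc.to_numpy(), obs_fc.to_numpy()),
        "n_proteins": int(len(table)),
        "n_agreement": int(table["agreement"].sum()),
    }


def cross_phase_summary(results: dict[str, pd.DataFrame]) -> tuple[dict, pd.DataFrame]:
    """Shared/unique significant features across phases + heatmap table.

    Returns a dict with the per-phase significant sets, their intersection
    and per-phase unique sets, and a log2FC heatmap over the union with
    per-feature max-|value| normalization into [-1, 1].
    """
    if len(results) < 2:
        raise ValueError("need at least two phases")
    sig = {ph: set(df.index[df["significant"]]) for ph, df in results.items()}
    phases = list(results)
    inter = set.intersection(*sig.values())
    union = sorted(set.union(*sig.values()))
    unique = {ph: sig[ph] - set.union(*(sig[o] for o in phases if o != ph))
              for ph in phases}

    heat = pd.DataFrame(index=pd.Index(union, name="feature_id"),
                        columns=phases, dtype=float)
    for ph, df in results.items():
        heat[ph] = df["log2fc"].reindex(union)
    maxabs = heat.abs().max(axis=1)
    nonzero = maxabs > 0
    heat.loc[nonzero] = heat.loc[nonzero].div(maxabs[nonzero], axis=0)

    sets = {
        "significant": {ph: sorted(s) for ph, s in sig.items()},
        "intersection": sorted(inter),
        "unique": {ph: sorted(s) for ph, s in unique.items()},
    }
    return sets, heat
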