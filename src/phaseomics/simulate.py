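"""Seeded generator of two-strain multi-omics datasets with planted truth.

All effects live on the log2 scale, so planted fold changes are exact in
expectation.  Metabolite log2 abundance for sample ``s`` of strain ``g``::

    base_f + phase_shift_{f,t} + effect_f * 1[g == MUT] + N(0, noise_sd_log2)

Protein log2 abundance is a convex weighted sum of its linked metabolites'
log2 abundances in the same sample plus N(0, protein_noise_sd_log2): all
strain signal reaching the proteome flows through metabolites.

Determinism: two ``numpy`` Generator streams are used, seeded as
``default_rng([seed, 0])`` for the ground truth and ``default_rng([seed, 1])``
for abundances.  Draw order is documented inline and never depends on
configuration values other than the counts that size each draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, PathwayAnnotation, SampleMeta

#: probability that a protein link stays within the protein's home pathway
WITHIN_PATHWAY_LINK_PROB = 0.9


@dataclass
class SimulationConfig:
    n_metabolites: int = 60
    n_proteins: int = 20
    n_pathways: int = 5
    replicates_per_group: int = 4
    phases: tuple[str, ...] = ("OD0.6", "OD2.0", "OD4.0")
    frac_affected: float = 0.3
    effect_log2fc: float = 1.0
    noise_sd_log2: float = 0.3
    protein_link_density: float = 3.0
    protein_noise_sd_log2: float = 0.1
    censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_proteins", "n_pathways",
                     "replicates_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_affected", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_sd_log2", "protein_noise_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.phases:
            raise ValueError("at least one phase required")
        self.phases = tuple(self.phases)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset."""

    affected_metabolites: dict[str, dict[str, float]]  # fid -> phase -> log2fc
    pathway_assignment: PathwayAnnotation
    protein_weights: dict[str, dict[str, float]]  # pid -> {metabolite: weight}
    censored_features: dict[str, str]  # fid -> strain rendered undetectable

    def effect_of(self, fid: str, phase: str) -> float:
        return self.affected_metabolites.get(fid, {}).get(phase, 0.0)

    def protein_log2fc(self, pid: str, phase: str) -> float:
        """Planted protein effect implied by the linear metabolite map."""
        w = self.protein_weights[pid]
        return float(sum(wv * self.effect_of(m, phase) for m, wv in w.items()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "affected_metabolites": self.affected_metabolites,
            "pathway_assignment": sorted(self.pathway_assignment.entries),
            "protein_weights": self.protein_weights,
            "censored_features": self.censored_features,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            affected_metabolites=d["affected_metabolites"],
            pathway_assignment=PathwayAnnotation.from_pairs(
                tuple(p) for p in d["pathway_assignment"]),
            protein_weights=d["protein_weights"],
            censored_features=d["censored_features"],
        )


def metabolite_ids(cfg: SimulationConfig) -> list[str]:
    return [f"M{i:03d}" for i in range(1, cfg.n_metabolites + 1)]


def protein_ids(cfg: SimulationConfig) -> list[str]:
    return [f"P{i:03d}" for i in range(1, cfg.n_proteins + 1)]


def make_truth(cfg: SimulationConfig) -> SyntheticTruth:
    """Draw pathway structure, planted effects and censoring (stream 0).

    Draw order: metabolite pathway assignment, protein home pathways,
    per-protein link counts/choices/weights, affected set, effect signs,
    censored subset.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    mids, pids = metabolite_ids(cfg), protein_ids(cfg)
    pathways = [f"PW{i:02d}" for i in range(1, cfg.n_pathways + 1)]

    # partition metabolites into pathways (each pathway non-empty when possible)
    assign = np.asarray(
        [i % cfg.n_pathways for i in range(cfg.n_metabolites)], dtype=int)
    rng.shuffle(assign)
    pairs = [(m, pathways[a]) for m, a in zip(mids, assign)]

    by_pw: dict[str, list[str]] = {pw: [] for pw in pathways}
    for m, a in zip(mids, assign):
        by_pw[pathways[a]].append(m)

    protein_weights: dict[str, dict[str, float]] = {}
    home = rng.integers(0, cfg.n_pathways, size=cfg.n_proteins)
    for pid, h in zip(pids, home):
        hpw = pathways[int(h)]
        pairs.append((pid, hpw))
        k = max(1, int(rng.poisson(cfg.protein_link_density)))
        linked: list[str] = []
        for _ in range(k):
            pool = by_pw[hpw] if (rng.random() < WITHIN_PATHWAY_LINK_PROB
                                  and by_pw[hpw]) else mids
            cand = pool[int(rng.integers(0, len(pool)))]
            if cand not in linked:
                linked.append(cand)
        raw_w = rng.uniform(0.5, 1.5, size=len(linked))
        raw_w /= raw_w.sum()
        protein_weights[pid] = {m: float(w) for m, w in zip(linked, raw_w)}
        # cross-pathway links annotate the protein into those pathways too,
        # so the shared-pathway graph rule recovers every link
        for m in linked:
            pairs.append((pid, pathways[assign[mids.index(m)]]))

    n_aff = round(cfg.frac_affected * cfg.n_metabolites)
    aff_idx = rng.choice(cfg.n_metabolites, size=n_aff, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_aff)
    affected = {
        mids[int(i)]: {ph: float(s * cfg.effect_log2fc) for ph in cfg.phases}
        for i, s in zip(sorted(aff_idx), signs)
    }

    n_cens = round(cfg.censor_rate * n_aff)
    censored: dict[str, str] = {}
    if n_cens:
        order = rng.permutation(sorted(affected))
        for fid in order[:n_cens]:
            eff = affected[fid][cfg.phases[0]]
            # undetectable in the strain where the feature is lower
            censored[fid] = "MUT" if eff < 0 else "WT"

    return SyntheticTruth(
        affected_metabolites=affected,
        pathway_assignment=PathwayAnnotation.from_pairs(pairs),
        protein_weights=protein_weights,
        censored_features=censored,
    )


def _sample_meta(cfg: SimulationConfig, phase: str) -> list[SampleMeta]:
    metas = []
    for strain in ("WT", "MUT"):
        for rep in range(1, cfg.replicates_per_group + 1):
            metas.append(SampleMeta(f"{strain}_{phase}_r{rep}", strain, phase, rep))
    return metas


def simulate_timecourse(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[dict[str, AbundanceMatrix], dict[str, AbundanceMatrix]]:
    """Generate per-phase metabolomics and proteomics matrices (stream 1).

    Draw order: metabolite baselines, per-phase shifts, then per phase:
    metabolite noise grid, protein noise grid.  Noise grids are always drawn
    and multiplied by the configured sd, so setting sd=0 changes values but
    not the stream position.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    mids, pids = metabolite_ids(cfg), protein_ids(cfg)
    n_m, n_p = len(mids), len(pids)
    n_s = 2 * cfg.replicates_per_group

    base = rng.normal(10.0, 2.0, size=n_m)
    phase_shift = rng.normal(0.0, 1.0, size=(n_m, len(cfg.phases)))

    metab: dict[str, AbundanceMatrix] = {}
    prot: dict[str, AbundanceMatrix] = {}
    for t, phase in enumerate(cfg.phases):
        metas = _sample_meta(cfg, phase)
        is_mut = np.array([m.strain == "MUT" for m in metas], dtype=float)
        effect = np.array([truth.effect_of(f, phase) for f in mids])

        noise = rng.normal(0.0, 1.0, size=(n_m, n_s)) * cfg.noise_sd_log2
        log2_m = (base[:, None] + phase_shift[:, t][:, None]
                  + np.outer(effect, is_mut) + noise)

        pnoise = rng.normal(0.0, 1.0, size=(n_p, n_s)) * cfg.protein_noise_sd_log2
        W = np.zeros((n_p, n_m))
        for i, pid in enumerate(pids):
            for m, w in truth.protein_weights[pid].items():
                W[i, mids.index(m)] = w
        log2_p = W @ log2_m + pnoise

        cols = [m.sample_id for m in metas]
        metab[phase] = AbundanceMatrix(
            data=pd.DataFrame(2.0 ** log2_m, index=mids, columns=cols),
            samples=metas, modality="metabolomics", scale="normalized")
        prot[phase] = AbundanceMatrix(
            data=pd.DataFrame(2.0 ** log2_p, index=pids, columns=cols),
            samples=metas, modality="proteomics", scale="normalized")
    return metab, prot


def apply_detection_censoring(m: AbundanceMatrix, truth: SyntheticTruth) -> AbundanceMatrix:
    """Blank every sample of the designated strain for censored features."""
    df = m.data.copy()
    for fid, strain in truth.censored_features.items():
        if fid not in df.index:
            raise ValueError(f"censored feature {fid!r} not in matrix")
        df.loc[fid, m.strain_columns(strain)] = np.nan
    return m.with_data(df)


def simulate_dataset(cfg: SimulationConfig, censor: bool = True):
    """Convenience wrapper: truth + matrices (+ optional censoring)."""
    truth = make_truth(cfg)
    metab, prot = simulate_timecourse(truth, cfg)
    if censor:
        metab = {ph: apply_detection_censoring(m, truth) for ph, m in metab.items()}
    return truth, metab, prot
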