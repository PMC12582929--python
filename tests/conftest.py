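import numpy as np
import pandas as pd
import pytest

from phaseomics.datamodel import AbundanceMatrix, SampleMeta
from phaseomics.simulate import SimulationConfig, simulate_dataset


def make_matrix(values, feature_ids=None, phase="OD0.6", modality="metabolomics",
                scale="normalized", n_wt=None):
    """Build an AbundanceMatrix from a 2-d array; first half WT, rest MUT."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if n_wt is None:
        n_wt = n_samp // 2
    feature_ids = feature_ids or [f"F{i + 1}" for i in range(n_feat)]
    samples = []
    for i in range(n_samp):
        strain = "WT" if i < n_wt else "MUT"
        rep = i + 1 if i < n_wt else i - n_wt + 1
        samples.append(SampleMeta(f"{strain}_{phase}_r{rep}", strain, phase, rep))
    df = pd.DataFrame(values, index=feature_ids,
                      columns=[s.sample_id for s in samples])
    return AbundanceMatrix(data=df, samples=samples, modality=modality,
                           scale=scale)


@pytest.fixture
def two_phase_dataset():
    """Small deterministic two-phase simulation shared by several suites."""
    cfg = SimulationConfig(n_metabolites=12, n_proteins=5, n_pathways=3,
                           frac_affected=0.5, effect_log2fc=1.0,
                           noise_sd_log2=0.2, protein_noise_sd_log2=0.05,
                           seed=11, phases=("OD0.6", "OD2.0"))
    truth, metab, prot = simulate_dataset(cfg, censor=False)
    return cfg, truth, metab, prot


@pytest.fixture
def meta_file(tmp_path):
    p = tmp_path / "meta.tsv"
    p.write_text(
        "sample_id\tstrain\tphase\treplicate\n"
        "S1\tWT\tOD0.6\t1\nS2\tWT\tOD0.6\t2\n"
        "S3\tMUT\tOD0.6\t1\nS4\tMUT\tOD0.6\t2\n")
    return p
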