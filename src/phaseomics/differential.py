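"""Two-group differential abundance: fold changes, t-tests, q-values.

A feature is *significant* iff p < alpha AND |log2FC| >= fc_threshold
(defaults 0.05 and 0.58, i.e. a 1.5-fold change).  q-values are reported
alongside but do not gate significance.  Features detected in only one
strain are excluded from testing and reported via the ``detection`` column.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .datamodel import AbundanceMatrix

ALPHA_DEFAULT = 0.05
FC_THRESHOLD_DEFAULT = 0.58  # round(log2(1.5), 2)
MIN_DETECTED_DEFAULT = 3

_TINY_P = np.nextafter(0.0, 1.0)


def _strain_values(m: AbundanceMatrix, strain: str) -> pd.DataFrame:
    return m.data.loc[m.analysis_features, m.strain_columns(strain)]


def presence_absence_screen(m: AbundanceMatrix, min_detected: int = MIN_DETECTED_DEFAULT
                            ) -> pd.Series:
    """Classify each feature as detected in both / WT_only / MUT_only / neither.

    "Detected" in a strain means >= ``min_detected`` non-missing replicate
    values in that strain.
    """
    wt, mut = _strain_values(m, "WT"), _strain_values(m, "MUT")
    if wt.shape[1] == 0 or mut.shape[1] == 0:
        raise ValueError("need at least one sample per strain")
    if min_detected > min(wt.shape[1], mut.shape[1]):
        raise ValueError(
            f"min_detected={min_detected} exceeds group size "
            f"{min(wt.shape[1], mut.shape[1])}")
    in_wt = wt.notna().sum(axis=1) >= min_detected
    in_mut = mut.notna().sum(axis=1) >= min_detected
    out = pd.Series("neither", index=wt.index, name="detection")
    out[in_wt & in_mut] = "both"
    out[in_wt & ~in_mut] = "WT_only"
    out[~in_wt & in_mut] = "MUT_only"
    return out


def log2_fold_change(m: AbundanceMatrix) -> pd.Series:
    """Per-feature log2(mean_MUT / mean_WT) over non-missing replicates."""
    wt = _strain_values(m, "WT").mean(axis=1)
    mut = _strain_values(m, "MUT").mean(axis=1)
    both = wt.notna() & mut.notna()
    bad = both & ((wt <= 0) | (mut <= 0))
    if bad.any():
        raise ValueError(
            f"non-positive group mean for feature(s) {list(wt.index[bad])}")
    return pd.Series(np.log2(mut / wt), index=wt.index, name="log2fc")


def ttest_two_sample(m: AbundanceMatrix, min_per_group: int = 2) -> pd.Series:
    """Two-sided pooled-variance Student t-test per feature, on log2 values.

    Degenerate cases: zero pooled variance with equal means gives p = 1;
    with unequal means the smallest positive float is reported with a
    warning.  Features with < ``min_per_group`` values in either group get
    NaN.
    """
    wt = np.log2(_strain_values(m, "WT"))
    mut = np.log2(_strain_values(m, "MUT"))
    p = pd.Series(np.nan, index=wt.index, name="p_value")
    for fid in wt.index:
        a = wt.loc[fid].dropna().to_numpy()
        b = mut.loc[fid].dropna().to_numpy()
        if len(a) < min_per_group or len(b) < min_per_group:
            continue
        n1, n2 = len(a), len(b)
        sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
               / (n1 + n2 - 2))
        if sp2 == 0.0:
            if a.mean() == b.mean():
                p[fid] = 1.0
            else:
                warnings.warn(
                    f"zero pooled variance with unequal means for {fid}; "
                    "reporting smallest positive p", RuntimeWarning)
                p[fid] = _TINY_P
            continue
        t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p[fid] = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return p


def estimate_pi0(p: np.ndarray, lambda_grid) -> float:
    """Estimate the null proportion pi0 from the p-value tail.

    A single lambda gives the direct Storey estimator; a grid fits a natural
    cubic spline to pi0(lambda) and evaluates it at the largest lambda.
    """
    lam = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("lambda values must lie in [0, 1)")
    m = len(p)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if len(lam) == 1:
        pi0 = pi0_lam[0]
    else:
        order = np.argsort(lam)
        spline = CubicSpline(lam[order], pi0_lam[order], bc_type="natural")
        pi0 = float(spline(lam.max()))
    return float(min(max(pi0, _TINY_P), 1.0))


def storey_qvalues(p_values, lambda_grid=(0.5,)) -> np.ndarray:
    """Storey q-values; with pi0 = 1 this reduces to Benjamini-Hochberg.

    q for the i-th smallest p is ``min_{j >= i} pi0 * m * p_(j) / j``,
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    pi0 = estimate_pi0(p, lambda_grid)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_features(
    log2fc, p_value, q_value,
    alpha: float = ALPHA_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p_value, dtype=float)
    q = np.asarray(q_value, dtype=float)
    if not (len(fc) == len(p) == len(q)):
        raise ValueError("log2fc, p_value and q_value must be aligned")
    significant = (p < alpha) & (np.abs(fc) >= fc_threshold)
    direction = np.where(significant & (fc > 0), "up",
                         np.where(significant & (fc < 0), "down", "none"))
    return pd.DataFrame({
        "log2fc": fc, "p_value": p, "q_value": q,
        "significant": significant, "direction": direction,
    })


def analyze(
    m: AbundanceMatrix,
    alpha: float = ALPHA_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    min_detected: int = MIN_DETECTED_DEFAULT,
    lambda_grid=(0.5,),
) -> pd.DataFrame:
    """Full differential table for one matrix (MUT vs WT).

    Features not detected in both strains carry NaN statistics and are
    never significant; they are reported through the ``detection`` column
    (the presence/absence screen).
    """
    detection = presence_absence_screen(m, min_detected=min_detected)
    keep = detection.index[detection == "both"]
    tested = m.with_data(m.data.loc[keep], standard_id=None)

    fc = log2_fold_change(tested)
    p = ttest_two_sample(tested)
    valid = p.notna()
    q = pd.Series(np.nan, index=p.index)
    if valid.any():
        q[valid] = storey_qvalues(p[valid].to_numpy(), lambda_grid)

    cls = classify_features(fc, p.fillna(1.0), q.fillna(1.0),
                            alpha=alpha, fc_threshold=fc_threshold)
    cls.index = fc.index
    cls.loc[~valid, ["p_value", "q_value"]] = np.nan
    cls.loc[~valid, "significant"] = False
    cls.loc[~valid, "direction"] = "none"

    n_wt = _strain_values(m, "WT").notna().sum(axis=1)
    n_mut = _strain_values(m, "MUT").notna().sum(axis=1)
    out = pd.DataFrame(index=pd.Index(m.analysis_features, name="feature_id"))
    out = out.join(cls).join(detection).join(n_wt.rename("n_WT")).join(
        n_mut.rename("n_MUT"))
    absent = out["detection"] != "both"
    out.loc[absent, ["log2fc", "p_value", "q_value"]] = np.nan
    out.loc[absent, "significant"] = False
    out.loc[absent, "direction"] = "none"
    out["significant"] = out["significant"].astype(bool)
    return out


def significant_features(result: pd.DataFrame) -> list[str]:
    return list(result.index[result["significant"]])
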