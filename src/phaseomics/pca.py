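"""PCA on scaled abundance data: sample-separation plots and pathway biplots.

``fit_pca`` works on any observations x variables frame via SVD of the
centered matrix; loadings columns are sign-fixed so the largest-magnitude
entry of each component is positive, making outputs bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, PathwayAnnotation


@dataclass
class PCAResult:
    scores: pd.DataFrame          # observations x components
    loadings: pd.DataFrame        # variables x components (orthonormal cols)
    explained_variance_pct: np.ndarray  # over ALL components, sums to 100
    centering: pd.Series
    scaling_method: str

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def scale_matrix(m: AbundanceMatrix, method: str = "standardize") -> AbundanceMatrix:
    """Per-feature scaling across samples.

    standardize: mean 0, sd 1 (sample sd, n-1); zero-variance features are
    dropped with a warning.  minmax: min 0, max 1; constant features map to
    all 0.  Features that are entirely missing are dropped with a warning.
    """
    if method not in ("standardize", "minmax", "none"):
        raise ValueError(f"unknown scaling method {method!r}")
    df = m.data.loc[m.analysis_features].copy()
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping all-missing feature(s): "
                      f"{list(df.index[all_missing])}", RuntimeWarning)
        df = df.loc[~all_missing]
    if method == "none":
        return m.with_data(df, scale="scaled", standard_id=None)
    if method == "standardize":
        sd = df.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"dropping zero-variance feature(s): "
                          f"{list(df.index[zero])}", RuntimeWarning)
            df, sd = df.loc[~zero], sd[~zero]
        out = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        rng_ = df.max(axis=1) - df.min(axis=1)
        out = df.sub(df.min(axis=1), axis=0)
        nonconst = rng_ != 0
        out.loc[nonconst] = out.loc[nonconst].div(rng_[nonconst], axis=0)
        out.loc[~nonconst] = 0.0
    return m.with_data(out, scale="scaled", standard_id=None)


def fit_pca(X: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """SVD-based PCA of an observations x variables frame (no missing cells).

    explained_variance_pct_k = 100 * sigma_k^2 / sum(sigma^2).  If
    ``n_components`` exceeds the matrix rank the returned components are
    truncated to the rank with a warning.
    """
    if X.isna().any().any():
        raise ValueError("PCA input must not contain missing values")
    center = X.mean(axis=0)
    Xc = (X - center).to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; "
                      "truncating", RuntimeWarning)
        n_components = rank

    # deterministic sign: largest-|.| loading entry of each component positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0

    total = (s ** 2).sum()
    pct = 100.0 * (s ** 2) / total if total > 0 else np.zeros_like(s)
    comp = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame((U[:, :n_components] * s[:n_components]),
                          index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt[:n_components].T, index=X.columns, columns=comp)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_pct=pct, centering=center,
                     scaling_method="pre-scaled input")


def sample_pca(m: AbundanceMatrix, n_components: int = 2,
               scale: str = "standardize") -> PCAResult:
    """Samples-as-observations PCA; features with any missing cell excluded."""
    scaled = scale_matrix(m, method=scale)
    df = scaled.data.dropna(axis=0, how="any")
    res = fit_pca(df.T, n_components=n_components)
    res.scaling_method = scale
    return res


def feature_pca(m: AbundanceMatrix, feature_ids, n_components: int = 2,
                scale: str = "standardize") -> PCAResult:
    """Features-as-observations PCA over a feature subset (biplot substrate)."""
    sub = m.with_data(m.data.loc[list(feature_ids)], standard_id=None)
    scaled = scale_matrix(sub, method=scale)
    df = scaled.data.dropna(axis=0, how="any")
    res = fit_pca(df, n_components=n_components)
    res.scaling_method = scale
    return res


def project_biplot(pca: PCAResult, ann: PathwayAnnotation,
                   significant_features) -> pd.DataFrame:
    """Biplot table: (feature, PC1, PC2, pathway); one row per pathway.

    Features without any annotation are labeled "unannotated" rather than
    dropped.
    """
    feats = [f for f in significant_features if f in pca.scores.index]
    if not feats:
        raise ValueError("no significant features present in the PCA scores")
    rows = []
    for fid in feats:
        pws = sorted(ann.pathways_of(fid)) or ["unannotated"]
        pc1 = pca.scores.at[fid, "PC1"]
        pc2 = pca.scores.at[fid, "PC2"] if "PC2" in pca.scores.columns else 0.0
        for pw in pws:
            rows.append((fid, pc1, pc2, pw))
    return pd.DataFrame(rows, columns=["feature_id", "PC1", "PC2", "pathway"])
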