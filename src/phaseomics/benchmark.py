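"""Cross-phase supervised benchmark under leave-one-out cross-validation.

The prediction problem: rows are aligned (strain, replicate) samples; the
predictors are metabolite log2 abundances at two phases plus protein log2
abundances at the earlier phase; the targets are protein log2 abundances at
the later phase.  Five regressor families are compared by LOOCV mean squared
error, with all scaling re-estimated inside each training fold so no
information leaks from the held-out row.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge

from .datamodel import AbundanceMatrix

FAMILIES = ("PLS", "Ridge", "Lasso", "RandomForest", "GBT", "Mean")
ALPHA_GRID = np.logspace(-3, 3, 7)

# column-block prefixes
METAB_T0, METAB_T1, PROT_T0 = "metab_t0|", "metab_t1|", "prot_t0|"


@dataclass
class FeatureTable:
    """Assembled supervised table (log2 scale, no missing cells)."""

    X: pd.DataFrame                  # rows: "STRAIN_r<k>", cols: tagged blocks
    Y: pd.DataFrame                  # targets: later-phase protein log2
    row_meta: pd.DataFrame           # strain, replicate per row
    col_modality: dict[str, str]     # column -> scaling modality
    dropped: dict[str, list[str]]    # block -> features dropped for missing

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(self.X, index=True).to_numpy().tobytes())
        h.update(pd.util.hash_pandas_object(self.Y, index=True).to_numpy().tobytes())
        return h.hexdigest()


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class CVResult:
    family: str
    mse: float                      # mean over (fold, target) pairs
    per_target_mse: pd.Series
    predictions: pd.DataFrame       # held-out predictions, original (log2) scale
    fold_assignment: list[str]      # held-out row id per fold, in order
    fold_scalers: list[dict]        # per fold: column -> (kind, p1, p2)
    skipped_targets: list[str]
    table_fingerprint: str


def _complete_log2_block(m: AbundanceMatrix, prefix: str, rows: list[tuple[str, int]]
                         ) -> tuple[pd.DataFrame, list[str]]:
    cols = {}
    for strain, rep in rows:
        match = [s.sample_id for s in m.samples
                 if s.strain == strain and s.replicate == rep]
        if len(match) != 1:
            raise ValueError(f"unpairable replicate ({strain}, r{rep}) "
                             f"in {prefix.rstrip('|')} block")
        cols[(strain, rep)] = match[0]
    df = m.data.loc[m.analysis_features, [cols[r] for r in rows]]
    dropped = list(df.index[df.isna().any(axis=1)])
    df = df.drop(index=dropped)
    block = pd.DataFrame(np.log2(df.to_numpy().T),
                         index=[f"{s}_r{r}" for s, r in rows],
                         columns=[f"{prefix}{f}" for f in df.index])
    return block, dropped


def build_supervised_table(
    metab_t0: AbundanceMatrix, metab_t1: AbundanceMatrix,
    prot_t0: AbundanceMatrix, prot_t1: AbundanceMatrix,
) -> FeatureTable:
    """Align the four matrices by (strain, replicate) into one table.

    Features/targets with any missing value are dropped and logged.
    """
    rows = sorted({(s.strain, s.replicate) for s in metab_t0.samples},
                  key=lambda t: (t[0] != "WT", t[1]))
    for m, name in ((metab_t1, "metab_t1"), (prot_t0, "prot_t0"),
                    (prot_t1, "prot_t1")):
        design = {(s.strain, s.replicate) for s in m.samples}
        if design != set(rows):
            raise ValueError(f"replicate design of {name} does not match metab_t0")

    b0, d0 = _complete_log2_block(metab_t0, METAB_T0, rows)
    b1, d1 = _complete_log2_block(metab_t1, METAB_T1, rows)
    bp, dp = _complete_log2_block(prot_t0, PROT_T0, rows)
    y, dy = _complete_log2_block(prot_t1, "", rows)

    X = pd.concat([b0, b1, bp], axis=1)
    col_modality = {c: "metabolomics" for c in list(b0.columns) + list(b1.columns)}
    col_modality.update({c: "proteomics" for c in bp.columns})
    col_modality.update({c: "proteomics" for c in y.columns})
    row_meta = pd.DataFrame(rows, columns=["strain", "replicate"],
                            index=X.index)
    return FeatureTable(X=X, Y=y, row_meta=row_meta, col_modality=col_modality,
                        dropped={"metab_t0": d0, "metab_t1": d1,
                                 "prot_t0": dp, "prot_t1": dy})


# -- fold-local scaling ----------------------------------------------------

def fit_scaler(train: pd.DataFrame, col_modality: dict[str, str]) -> dict:
    """Per-column scaling parameters estimated on training rows only.

    proteomics -> standardize (sample sd; sd 0 or n<2 falls back to 1);
    metabolomics -> minmax (zero range falls back to 1).
    """
    params = {}
    for c in train.columns:
        v = train[c].to_numpy(dtype=float)
        if col_modality.get(c, "proteomics") == "proteomics":
            mu = v.mean()
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            params[c] = ("standardize", mu, sd if sd > 0 else 1.0)
        else:
            lo, rng_ = v.min(), v.max() - v.min()
            params[c] = ("minmax", lo, rng_ if rng_ > 0 else 1.0)
    return params


def apply_scaler(df: pd.DataFrame, params: dict) -> pd.DataFrame:
    out = df.copy()
    for c in df.columns:
        _, p1, p2 = params[c]
        out[c] = (df[c] - p1) / p2
    return out


def invert_scaler(df: pd.DataFrame, params: dict) -> pd.DataFrame:
    out = df.copy()
    for c in df.columns:
        _, p1, p2 = params[c]
        out[c] = df[c] * p2 + p1
    return out


# -- estimators ------------------------------------------------------------

def _make_estimator(spec: ModelSpec, alpha: float | None = None,
                    n_train: int = 0, n_feat: int = 0):
    hp = spec.hyperparameters
    if spec.family == "Ridge":
        return Ridge(alpha=alpha if alpha is not None else 1.0)
    if spec.family == "Lasso":
        return Lasso(alpha=alpha if alpha is not None else 1.0, max_iter=50000)
    if spec.family == "PLS":
        k = hp.get("n_components", min(3, max(1, n_train - 1), max(1, n_feat)))
        return PLSRegression(n_components=k, scale=False)
    if spec.family == "RandomForest":
        return RandomForestRegressor(
            n_estimators=hp.get("n_estimators", 100),
            criterion="squared_error", max_depth=None,
            random_state=spec.seed)
    if spec.family == "GBT":
        return GradientBoostingRegressor(
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=hp.get("max_depth", 6),
            n_estimators=hp.get("n_estimators", 200),
            random_state=spec.seed)
    if spec.family == "Mean":
        return DummyRegressor(strategy="mean")
    raise AssertionError(spec.family)


def _tune_alpha(spec: ModelSpec, Xtr: np.ndarray, ytr: np.ndarray,
                grid=ALPHA_GRID) -> float:
    """Inner-LOOCV grid search for Ridge/Lasso within a training fold."""
    grid = list(spec.hyperparameters.get("alpha_grid", grid))
    best, best_err = grid[0], np.inf
    n = len(ytr)
    for a in grid:
        errs = []
        for i in range(n):
            tr = np.arange(n) != i
            est = _make_estimator(spec, alpha=a)
            est.fit(Xtr[tr], ytr[tr])
            errs.append((est.predict(Xtr[~tr])[0] - ytr[i]) ** 2)
        err = float(np.mean(errs))
        if err < best_err - 1e-15:
            best, best_err = a, err
    return best


def run_loocv(table: FeatureTable, spec: ModelSpec,
              scale_within_fold: bool = True) -> CVResult:
    """Leave-one-out CV: fit on all rows but one, predict the held-out row.

    Scaling (and Ridge/Lasso regularization strength) is re-estimated inside
    each training fold.  MSE is the mean over all (fold, target) squared
    errors in the model's fit space (the scaled space when
    ``scale_within_fold``); predictions are returned inverse-transformed to
    the original log2 scale.
    """
    n = table.X.shape[0]
    if n < 3 and spec.family != "Mean":
        raise ValueError("LOOCV needs at least 3 rows")
    preds = pd.DataFrame(np.nan, index=table.X.index, columns=table.Y.columns)
    sq_err: dict[str, list[float]] = {t: [] for t in table.Y.columns}
    fold_scalers, fold_rows = [], []
    skipped: set[str] = set()

    for i, row in enumerate(table.X.index):
        tr_idx = table.X.index != row
        Xtr_raw, Xte_raw = table.X.loc[tr_idx], table.X.loc[[row]]
        Ytr_raw, Yte_raw = table.Y.loc[tr_idx], table.Y.loc[[row]]

        if scale_within_fold:
            xs = fit_scaler(Xtr_raw, table.col_modality)
            ys = fit_scaler(Ytr_raw, table.col_modality)
            Xtr, Xte = apply_scaler(Xtr_raw, xs), apply_scaler(Xte_raw, xs)
            Ytr, Yte = apply_scaler(Ytr_raw, ys), apply_scaler(Yte_raw, ys)
            fold_scalers.append({"X": xs, "Y": ys})
        else:
            Xtr, Xte, Ytr, Yte = Xtr_raw, Xte_raw, Ytr_raw, Yte_raw
            fold_scalers.append({})
        fold_rows.append(row)

        yhat_scaled = {}
        for t in table.Y.columns:
            ytr = Ytr[t].to_numpy()
            if np.all(ytr == ytr[0]) and spec.family not in ("Mean",):
                if t not in skipped:
                    warnings.warn(f"target {t} constant within a training fold; "
                                  "skipped", RuntimeWarning)
                skipped.add(t)
                continue
            alpha = None
            if spec.family in ("Ridge", "Lasso"):
                alpha = _tune_alpha(spec, Xtr.to_numpy(), ytr)
            est = _make_estimator(spec, alpha=alpha, n_train=len(ytr),
                                  n_feat=Xtr.shape[1])
            est.fit(Xtr.to_numpy(), ytr)
            yh = float(np.asarray(est.predict(Xte.to_numpy())).ravel()[0])
            yhat_scaled[t] = yh
            sq_err[t].append((yh - float(Yte[t].iloc[0])) ** 2)

        row_pred = pd.DataFrame(yhat_scaled, index=[row])
        if scale_within_fold and not row_pred.empty:
            row_pred = invert_scaler(row_pred, {c: fold_scalers[-1]["Y"][c]
                                                for c in row_pred.columns})
        for t, v in row_pred.items():
            preds.loc[row, t] = v.iloc[0]

    per_target = pd.Series({t: np.mean(e) for t, e in sq_err.items() if e},
                           dtype=float)
    all_errs = [e for errs in sq_err.values() for e in errs]
    return CVResult(
        family=spec.family,
        mse=float(np.mean(all_errs)) if all_errs else np.nan,
        per_target_mse=per_target,
        predictions=preds,
        fold_assignment=fold_rows,
        fold_scalers=fold_scalers,
        skipped_targets=sorted(skipped),
        table_fingerprint=table.fingerprint(),
    )


def rank_models(results: list[CVResult]) -> pd.DataFrame:
    """Ascending by MSE; ties broken alphabetically by family name."""
    if len(results) < 2:
        raise ValueError("need at least 2 results to rank")
    fps = {r.table_fingerprint for r in results}
    if len(fps) != 1:
        raise ValueError("results come from different tables")
    order = sorted(results, key=lambda r: (r.mse, r.family))
    return pd.DataFrame({
        "family": [r.family for r in order],
        "mse": [r.mse for r in order],
        "n_targets": [len(r.per_target_mse) for r in order],
    })
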