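"""Pathway-linked metabolite-protein graph and a NumPy graph attention net.

The graph joins a metabolite and a protein whenever they share a pathway
label.  The regressor is a two-layer graph attention network (4 heads,
128 hidden channels total, concatenated after layer 1 and averaged into a
scalar output head after layer 2) trained full-batch with Adam under a step
learning-rate decay.  Forward and backward passes are written explicitly in
NumPy (verified against central finite differences), so the model is fully
deterministic under a fixed seed and needs no deep-learning runtime.

Per-head attention for receiver i and sender j in N(i) u {i}::

    z = W x;  e_ij = LeakyReLU(a_recv . z_i + a_send . z_j)
    alpha_ij = softmax_j(e_ij);  h_i = sum_j alpha_ij z_j

Layer 1 is followed by batch normalization over nodes, ELU and dropout;
layer 2 is the linear regression head (heads averaged, no activation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .benchmark import (FeatureTable, METAB_T0, METAB_T1, PROT_T0, CVResult,
                        apply_scaler, fit_scaler, invert_scaler)
from .datamodel import PathwayAnnotation

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class OmicsGraph:
    """Simple undirected bipartite-ish graph with pathway provenance."""

    node_ids: list[str]
    kinds: list[str]                      # "metabolite" | "protein"
    edges: list[tuple[int, int]]          # i < j, node indices
    provenance: dict[tuple[int, int], frozenset[str]]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def degree(self, idx: int) -> int:
        return sum(1 for i, j in self.edges if i == idx or j == idx)

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed (sender, receiver) arrays including uniform self-loops."""
        src, dst = [], []
        for i, j in self.edges:
            src += [i, j]
            dst += [j, i]
        for i in range(self.n_nodes):
            src.append(i)
            dst.append(i)
        return np.asarray(src, dtype=int), np.asarray(dst, dtype=int)


def build_graph(ann: PathwayAnnotation, metabolite_ids, protein_ids,
                metabolite_edges: bool = False) -> OmicsGraph:
    """Edge (metabolite, protein) iff they share >= 1 pathway label.

    Node order is deterministic: metabolites then proteins, each sorted.
    Metabolite-metabolite within-pathway edges are off by default.
    """
    mids = sorted(metabolite_ids)
    pids = sorted(protein_ids)
    overlap = set(mids) & set(pids)
    if overlap:
        raise ValueError(f"id(s) present in both lists: {sorted(overlap)}")
    node_ids = mids + pids
    kinds = ["metabolite"] * len(mids) + ["protein"] * len(pids)
    idx = {n: i for i, n in enumerate(node_ids)}
    pws = {n: ann.pathways_of(n) for n in node_ids}

    edges: dict[tuple[int, int], set[str]] = {}
    for m in mids:
        for p in pids:
            shared = pws[m] & pws[p]
            if shared:
                key = tuple(sorted((idx[m], idx[p])))
                edges.setdefault(key, set()).update(shared)
    if metabolite_edges:
        for a in range(len(mids)):
            for b in range(a + 1, len(mids)):
                shared = pws[mids[a]] & pws[mids[b]]
                if shared:
                    edges.setdefault((a, b), set()).update(shared)
    return OmicsGraph(
        node_ids=node_ids, kinds=kinds, edges=sorted(edges),
        provenance={k: frozenset(v) for k, v in edges.items()})


def eligible_proteins(g: OmicsGraph) -> list[str]:
    """Proteins with at least one edge; only these are trained/predicted."""
    deg = np.zeros(g.n_nodes, dtype=int)
    for i, j in g.edges:
        deg[i] += 1
        deg[j] += 1
    return [n for n, k, d in zip(g.node_ids, g.kinds, deg)
            if k == "protein" and d >= 1]


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

@dataclass
class GATConfig:
    hidden_dim: int = 128          # total over heads when hidden_is_total
    heads: int = 4
    dropout: float = 0.3
    neg_slope: float = 0.2         # LeakyReLU slope inside attention
    hidden_is_total: bool = True   # False -> hidden_dim per head

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.hidden_is_total and self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")

    @property
    def per_head(self) -> int:
        return (self.hidden_dim // self.heads if self.hidden_is_total
                else self.hidden_dim)


@dataclass
class TrainingSchedule:
    learning_rate: float = 1e-3
    step_size: int = 100
    gamma: float = 0.5
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")

    def lr_at(self, epoch: int) -> float:
        return self.learning_rate * self.gamma ** (epoch // self.step_size)


# ---------------------------------------------------------------------------
# attention head forward / backward
# ---------------------------------------------------------------------------

def _head_forward(X, W, a_recv, a_send, src, dst, slope):
    S, N, _ = X.shape
    Z = X @ W                                   # (S, N, d)
    s_recv = Z @ a_recv                         # (S, N)
    s_send = Z @ a_send
    epre = s_recv[:, dst] + s_send[:, src]      # (S, E)
    e = np.where(epre > 0, epre, slope * epre)
    rows = np.arange(S)[:, None]
    mx = np.full((S, N), -np.inf)
    np.maximum.at(mx, (rows, dst), e)
    ex = np.exp(e - mx[:, dst])
    denom = np.zeros((S, N))
    np.add.at(denom, (rows, dst), ex)
    alpha = ex / denom[:, dst]                  # (S, E)
    H = np.zeros_like(Z)
    np.add.at(H, (rows, dst), alpha[..., None] * Z[:, src])
    cache = (X, W, a_recv, a_send, src, dst, slope, Z, epre, alpha)
    return H, cache


def _head_backward(dH, cache):
    X, W, a_recv, a_send, src, dst, slope, Z, epre, alpha = cache
    S, N, _ = Z.shape
    rows = np.arange(S)[:, None]

    dZ = np.zeros_like(Z)
    np.add.at(dZ, (rows, src), alpha[..., None] * dH[:, dst])
    dalpha = np.sum(dH[:, dst] * Z[:, src], axis=-1)          # (S, E)

    t = alpha * dalpha
    tsum = np.zeros((S, N))
    np.add.at(tsum, (rows, dst), t)
    de = alpha * (dalpha - tsum[:, dst])
    depre = de * np.where(epre > 0, 1.0, slope)

    ds_recv = np.zeros((S, N))
    np.add.at(ds_recv, (rows, dst), depre)
    ds_send = np.zeros((S, N))
    np.add.at(ds_send, (rows, src), depre)

    da_recv = np.einsum("sn,snd->d", ds_recv, Z)
    da_send = np.einsum("sn,snd->d", ds_send, Z)
    dZ += ds_recv[..., None] * a_recv + ds_send[..., None] * a_send

    dW = np.einsum("snf,snd->fd", X, dZ)
    dX = dZ @ W.T
    return dX, dW, da_recv, da_send


def attention_coefficients(X, W, a_recv, a_send, src, dst, slope):
    """(alpha, src, dst) for inspection/tests; rows per receiver sum to 1."""
    _, cache = _head_forward(X, W, a_recv, a_send, src, dst, slope)
    return cache[9], src, dst


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class GATModel:
    """Two-layer GAT regressor over one fixed graph.

    Parameters are Glorot-uniform initialised from ``default_rng([seed, 0])``;
    dropout masks come from ``default_rng([seed, 1])``.
    """

    def __init__(self, g: OmicsGraph, in_dim: int, cfg: GATConfig, seed: int = 0):
        self.graph = g
        self.cfg = cfg
        self.in_dim = in_dim
        self.src, self.dst = g.edge_index()
        rng = np.random.default_rng([seed, 0])
        self._dropout_rng = np.random.default_rng([seed, 1])
        d = cfg.per_head
        htot = d * cfg.heads
        self.params: dict[str, np.ndarray] = {}

        def glorot(*shape):
            fan_in, fan_out = shape[0], shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        for h in range(cfg.heads):
            self.params[f"W1_{h}"] = glorot(in_dim, d)
            self.params[f"ar1_{h}"] = glorot(d, 1).ravel()
            self.params[f"as1_{h}"] = glorot(d, 1).ravel()
            self.params[f"W2_{h}"] = glorot(htot, 1)
            self.params[f"ar2_{h}"] = glorot(1, 1).ravel()
            self.params[f"as2_{h}"] = glorot(1, 1).ravel()
        self.params["bn_gamma"] = np.ones(htot)
        self.params["bn_beta"] = np.zeros(htot)
        self.bn_mean = np.zeros(htot)
        self.bn_var = np.ones(htot)

    # -- forward -----------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False):
        """X: (samples, nodes, in_dim) -> (samples, nodes) output."""
        cfg = self.cfg
        if X.ndim != 3 or X.shape[1] != self.graph.n_nodes \
                or X.shape[2] != self.in_dim:
            raise ValueError(
                f"feature layout mismatch: expected (*, {self.graph.n_nodes}, "
                f"{self.in_dim}), got {X.shape}")
        caches1, Hs = [], []
        for h in range(cfg.heads):
            H, c = _head_forward(X, self.params[f"W1_{h}"],
                                 self.params[f"ar1_{h}"], self.params[f"as1_{h}"],
                                 self.src, self.dst, cfg.neg_slope)
            caches1.append(c)
            Hs.append(H)
        H1 = np.concatenate(Hs, axis=-1)                      # (S, N, htot)

        # batch normalization over all nodes in the batch
        if train:
            mu = H1.mean(axis=(0, 1))
            var = H1.var(axis=(0, 1))
            self.bn_mean = (1 - _BN_MOMENTUM) * self.bn_mean + _BN_MOMENTUM * mu
            self.bn_var = (1 - _BN_MOMENTUM) * self.bn_var + _BN_MOMENTUM * var
        else:
            mu, var = self.bn_mean, self.bn_var
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (H1 - mu) * inv_sd
        B = self.params["bn_gamma"] * xhat + self.params["bn_beta"]

        A = np.where(B > 0, B, np.expm1(B))                   # ELU
        if train and cfg.dropout > 0:
            mask = (self._dropout_rng.random(A.shape) >= cfg.dropout)
            D = A * mask / (1.0 - cfg.dropout)
        else:
            mask = None
            D = A

        caches2, outs = [], []
        for h in range(cfg.heads):
            Hh, c = _head_forward(D, self.params[f"W2_{h}"],
                                  self.params[f"ar2_{h}"], self.params[f"as2_{h}"],
                                  self.src, self.dst, cfg.neg_slope)
            caches2.append(c)
            outs.append(Hh[..., 0])
        out = np.mean(outs, axis=0)                           # (S, N)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite activations in forward pass")
        cache = (caches1, H1, mu, inv_sd, xhat, B, A, mask, D, caches2, train)
        return out, cache

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dOut: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.cfg
        caches1, H1, mu, inv_sd, xhat, B, A, mask, D, caches2, train = cache
        grads: dict[str, np.ndarray] = {}
        dD = np.zeros_like(D)
        for h in range(cfg.heads):
            dHh = (dOut / cfg.heads)[..., None]
            dXh, dW, dar, das = _head_backward(dHh, caches2[h])
            grads[f"W2_{h}"] = dW
            grads[f"ar2_{h}"] = dar
            grads[f"as2_{h}"] = das
            dD += dXh

        if mask is not None:
            dA = dD * mask / (1.0 - cfg.dropout)
        else:
            dA = dD
        dB = dA * np.where(B > 0, 1.0, A + 1.0)               # ELU'

        grads["bn_gamma"] = np.sum(dB * xhat, axis=(0, 1))
        grads["bn_beta"] = np.sum(dB, axis=(0, 1))
        dxhat = dB * self.params["bn_gamma"]
        if train:
            M = H1.shape[0] * H1.shape[1]
            dvar = np.sum(dxhat * (H1 - mu), axis=(0, 1)) * (-0.5) * inv_sd ** 3
            dmu = (np.sum(dxhat, axis=(0, 1)) * (-inv_sd)
                   + dvar * np.sum(-2.0 * (H1 - mu), axis=(0, 1)) / M)
            dH1 = dxhat * inv_sd + dvar * 2.0 * (H1 - mu) / M + dmu / M
        else:
            dH1 = dxhat * inv_sd

        d = cfg.per_head
        dX = None
        for h in range(cfg.heads):
            dXh, dW, dar, das = _head_backward(
                dH1[..., h * d:(h + 1) * d], caches1[h])
            grads[f"W1_{h}"] = dW
            grads[f"ar1_{h}"] = dar
            grads[f"as1_{h}"] = das
            dX = dXh if dX is None else dX + dXh
        grads["_dX"] = dX
        return grads

    # -- loss --------------------------------------------------------------
    def loss_and_grads(self, X, Y, target_nodes, train: bool = True):
        """MSE at the target (protein) nodes, mean over samples x targets."""
        out, cache = self.forward(X, train=train)
        pred = out[:, target_nodes]
        resid = pred - Y
        loss = float(np.mean(resid ** 2))
        dOut = np.zeros_like(out)
        dOut[:, target_nodes] = 2.0 * resid / resid.size
        grads = self.backward(cache, dOut)
        grads.pop("_dX")
        return loss, grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inference mode: dropout off, batch-norm running statistics."""
        out, _ = self.forward(X, train=False)
        return out


@dataclass
class TrainedGAT:
    model: GATModel
    loss_trajectory: list[float]
    schedule: TrainingSchedule
    eligible: list[str]
    target_nodes: np.ndarray


def train_gat(model: GATModel, X: np.ndarray, Y: np.ndarray,
              target_nodes: np.ndarray, sched: TrainingSchedule) -> TrainedGAT:
    """Full-batch Adam training with step learning-rate decay."""
    if X.shape[0] < 1:
        raise ValueError("need at least one training sample")
    m_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_t = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses: list[float] = []
    for epoch in range(sched.epochs):
        loss, grads = model.loss_and_grads(X, Y, target_nodes, train=True)
        if not np.isfinite(loss):
            last = epoch - 1
            raise FloatingPointError(
                f"training diverged at epoch {epoch}; last finite epoch {last}")
        losses.append(loss)
        lr = sched.lr_at(epoch)
        t = epoch + 1
        for k, gp in grads.items():
            m_t[k] = b1 * m_t[k] + (1 - b1) * gp
            v_t[k] = b2 * v_t[k] + (1 - b2) * gp ** 2
            mhat = m_t[k] / (1 - b1 ** t)
            vhat = v_t[k] / (1 - b2 ** t)
            model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
    elig = eligible_proteins(model.graph)
    return TrainedGAT(model=model, loss_trajectory=losses, schedule=sched,
                      eligible=elig, target_nodes=target_nodes)


def predict_protein_abundance(trained: TrainedGAT, X: np.ndarray,
                              proteins: list[str] | None = None) -> pd.DataFrame:
    """Per-sample predictions for eligible proteins (scaled target space)."""
    g = trained.model.graph
    if proteins is None:
        proteins = trained.eligible
    bad = [p for p in proteins if p not in trained.eligible]
    if bad:
        raise ValueError(f"protein not eligible: {bad}")
    out = trained.model.predict(X)
    cols = {p: out[:, g.index_of(p)] for p in proteins}
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# coupling to the supervised table
# ---------------------------------------------------------------------------

def assemble_node_features(g: OmicsGraph, X_scaled: pd.DataFrame) -> np.ndarray:
    """Map tagged table columns onto per-node 3-vectors.

    metabolite node: [metab_t0, metab_t1, 0]; protein node: [prot_t0, 0, 1].
    Features absent from the table (dropped for missingness) are zero-padded.
    """
    S = X_scaled.shape[0]
    feat = np.zeros((S, g.n_nodes, 3))
    for i, (nid, kind) in enumerate(zip(g.node_ids, g.kinds)):
        if kind == "metabolite":
            for k, pref in enumerate((METAB_T0, METAB_T1)):
                col = f"{pref}{nid}"
                if col in X_scaled.columns:
                    feat[:, i, k] = X_scaled[col].to_numpy()
        else:
            col = f"{PROT_T0}{nid}"
            if col in X_scaled.columns:
                feat[:, i, 0] = X_scaled[col].to_numpy()
            feat[:, i, 2] = 1.0
    return feat


def gat_loocv(g: OmicsGraph, table: FeatureTable, cfg: GATConfig,
              sched: TrainingSchedule) -> CVResult:
    """LOOCV for the GAT with fold-local scaling, mirroring ``run_loocv``."""
    elig = [p for p in eligible_proteins(g) if p in table.Y.columns]
    if not elig:
        raise ValueError("no eligible protein has a target column")
    tnodes = np.array([g.index_of(p) for p in elig])
    n = table.X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 rows")

    preds = pd.DataFrame(np.nan, index=table.X.index, columns=elig)
    sq_err: dict[str, list[float]] = {p: [] for p in elig}
    fold_scalers, fold_rows = [], []
    for row in table.X.index:
        tr = table.X.index != row
        xs = fit_scaler(table.X.loc[tr], table.col_modality)
        ys = fit_scaler(table.Y.loc[tr, elig], table.col_modality)
        Xtr = apply_scaler(table.X.loc[tr], xs)
        Xte = apply_scaler(table.X.loc[[row]], xs)
        Ytr = apply_scaler(table.Y.loc[tr, elig], ys)
        Yte = apply_scaler(table.Y.loc[[row], elig], ys)
        fold_scalers.append({"X": xs, "Y": ys})
        fold_rows.append(row)

        model = GATModel(g, in_dim=3, cfg=cfg, seed=sched.seed)
        trained = train_gat(model, assemble_node_features(g, Xtr),
                            Ytr.to_numpy(), tnodes, sched)
        yh = predict_protein_abundance(trained, assemble_node_features(g, Xte),
                                       elig)
        for p in elig:
            sq_err[p].append((yh[p].iloc[0] - float(Yte[p].iloc[0])) ** 2)
        yh.index = [row]
        preds.loc[[row], elig] = invert_scaler(yh, ys).to_numpy()

    all_errs = [e for errs in sq_err.values() for e in errs]
    return CVResult(
        family="GAT",
        mse=float(np.mean(all_errs)),
        per_target_mse=pd.Series({p: float(np.mean(e))
                                  for p, e in sq_err.items()}),
        predictions=preds,
        fold_assignment=fold_rows,
        fold_scalers=fold_scalers,
        skipped_targets=[],
        table_fingerprint=table.fingerprint(),
    )
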