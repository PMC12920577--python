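"""The hybrid lead-graph / transformer arrhythmia classifier.

Input is the extracted feature tensor (segments x T sub-windows x leads x
features).  Per sub-window, a stack of graph-convolution layers mixes
information across the ECG leads over a lead graph

    h_v' = sigma( sum_{u in N(v)} (1 / c_vu) W h_u + b ),

with symmetric normalization ``c_vu = sqrt(deg(v) deg(u))`` and self-loops,
a single weight matrix shared by all nodes (GCN convention).  Lead features
are then mean-pooled, linearly embedded to ``d_model``, tagged with
sinusoidal positional codes, and passed through transformer encoder blocks
(multi-head scaled dot-product self-attention + add&norm + feed-forward +
add&norm).  Mean-pooling over time yields ``h_final``, a fully connected
hidden layer with ReLU feeds the softmax output layer, and training
minimizes (optionally class-weighted) cross-entropy.

Defaults mirror the tuned configuration (Adam, learning rate 1e-4, batch 32,
3 GNN layers, 4 transformer layers, d_model 128, 8 heads, dropout 0.3,
ReLU); all of it is overridable for scaled-down runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, mean, softmax as softmax_t
from .errors import NumericError, ValidationError
from .io import CLASS_SYMBOLS
from .nn import Dropout, Linear, Module, TransformerEncoderBlock, positional_encoding

__all__ = [
    "LeadGraph", "ModelConfig", "LeadGraphTransformer", "build_lead_graph", "graph_conv",
    "scaled_dot_attention", "model_forward", "cross_entropy_loss", "decision_map",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class LeadGraph:
    """Undirected lead graph with self-loops and normalized adjacency.

    ``adjacency`` is the dense symmetric 0/1 edge matrix (self-loops on the
    diagonal); ``norm_adjacency[v, u] = adjacency[v, u] / sqrt(deg v * deg u)``.
    """

    n_nodes: int
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValidationError("adjacency shape must be n_nodes x n_nodes")
        if not np.array_equal(a, a.T):
            raise ValidationError("edge set must be symmetric")
        if not np.all(np.diag(a) == 1):
            raise ValidationError("every node needs a self-loop")

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def norm_adjacency(self) -> np.ndarray:
        d = self.degrees.astype(np.float64)
        c = np.sqrt(np.outer(d, d))
        return self.adjacency / c

    def edge_norms(self) -> dict[tuple[int, int], float]:
        """Per-edge normalization constants c_vu = sqrt(deg v * deg u)."""
        d = self.degrees
        out = {}
        for v in range(self.n_nodes):
            for u in range(self.n_nodes):
                if self.adjacency[v, u]:
                    out[(v, u)] = float(np.sqrt(d[v] * d[u]))
        return out


def build_lead_graph(n_leads: int, strategy: str = "full",
                     signals: np.ndarray | None = None,
                     corr_threshold: float = 0.3) -> LeadGraph:
    """Construct the lead graph.

    ``full``: complete graph plus self-loops; ``identity``: self-loops only;
    ``correlation``: connect leads whose absolute Pearson correlation over
    ``signals`` (samples x leads) reaches ``corr_threshold``.
    """
    if n_leads < 1:
        raise ValidationError("n_leads must be >= 1")
    if strategy == "full":
        adj = np.ones((n_leads, n_leads), dtype=np.int64)
    elif strategy == "identity":
        adj = np.eye(n_leads, dtype=np.int64)
    elif strategy == "correlation":
        if signals is None:
            raise ValidationError("correlation strategy requires signals")
        sig = np.asarray(signals, dtype=np.float64)
        if sig.shape[1] != n_leads:
            raise ValidationError("signals must have one column per lead")
        if n_leads == 1:
            adj = np.eye(1, dtype=np.int64)
        else:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(sig.T)
            r = np.nan_to_num(r, nan=0.0)
            adj = (np.abs(r) >= corr_threshold).astype(np.int64)
            np.fill_diagonal(adj, 1)
            adj = np.maximum(adj, adj.T)
    else:
        raise ValidationError(f"unknown graph strategy {strategy!r}")
    return LeadGraph(n_nodes=n_leads, adjacency=adj)


def graph_conv(node_feats: np.ndarray, graph: LeadGraph, weight: np.ndarray,
               bias: np.ndarray, activation: str = "relu") -> np.ndarray:
    """Single graph-convolution step on plain arrays (reference entry point).

    ``node_feats`` is nodes x d_in; returns nodes x d_out.
    """
    h = np.asarray(node_feats, dtype=np.float64)
    w = np.asarray(weight, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] != graph.n_nodes or w.shape[0] != h.shape[1]:
        raise ValidationError("graph_conv shape mismatch")
    out = graph.norm_adjacency @ h @ w + np.asarray(bias)
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation in (None, "identity", "linear"):
        return out
    raise ValidationError(f"unknown activation {activation!r}")


def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention on plain arrays.

    Returns ``(outputs, weights)``: ``weights = softmax(q k^T / sqrt(d_k))``
    row-wise and ``outputs = weights @ v``.
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    d_k = q.shape[-1]
    if d_k == 0:
        raise ValidationError("d_k must be positive")
    if k.shape[-1] != d_k or k.shape[-2] != v.shape[-2]:
        raise ValidationError("attention shape mismatch")
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    scores = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ v, w


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults are the tuned full-scale configuration."""

    n_gnn_layers: int = 3
    n_transformer_layers: int = 4
    d_model: int = 128
    heads: int = 8
    dropout: float = 0.3
    activation: str = "relu"
    n_classes: int = 4
    learning_rate: float = 1e-4
    batch_size: int = 32
    optimizer: str = "adam"
    d_gnn: int = 32          # GNN hidden width
    head_hidden: int = 64    # FC hidden width before the softmax layer
    ff_mult: int = 4
    uniform_attention: bool = False

    def __post_init__(self) -> None:
        if self.n_gnn_layers < 0 or self.n_transformer_layers < 0:
            raise ValidationError("layer counts must be >= 0")
        for name in ("d_model", "heads", "n_classes", "batch_size", "d_gnn", "head_hidden"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        if self.d_model % self.heads != 0:
            raise ValidationError("d_model must be divisible by heads")


class _GNNLayer(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.lin = Linear(d_in, d_out, rng)

    def __call__(self, h: Tensor, norm_adj: Tensor) -> Tensor:
        return (norm_adj @ self.lin(h)).relu()


class LeadGraphTransformer(Module):
    """The assembled classifier; see the module docstring for the data flow."""

    def __init__(self, d_feat: int, T: int, graph: LeadGraph,
                 config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.graph = graph
        self.d_feat = d_feat
        self.T = T
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._norm_adj = Tensor(graph.norm_adjacency)
        dims = [d_feat] + [cfg.d_gnn] * cfg.n_gnn_layers
        self.gnn_layers = [_GNNLayer(dims[i], dims[i + 1], rng)
                           for i in range(cfg.n_gnn_layers)]
        self.embed = Linear(dims[-1], cfg.d_model, rng)
        self._pe = Tensor(positional_encoding(T, cfg.d_model))
        self.blocks = [TransformerEncoderBlock(cfg.d_model, cfg.heads, cfg.dropout, rng,
                                               uniform_attention=cfg.uniform_attention,
                                               ff_mult=cfg.ff_mult)
                       for _ in range(cfg.n_transformer_layers)]
        self.drop = Dropout(cfg.dropout)
        self.head_hidden = Linear(cfg.d_model, cfg.head_hidden, rng)
        self.head_out = Linear(cfg.head_hidden, cfg.n_classes, rng)
        # feature standardization fitted during training (identity before fit)
        self.feat_mean = np.zeros(d_feat)
        self.feat_scale = np.ones(d_feat)

    def fit_standardizer(self, x: np.ndarray) -> None:
        flat = x.reshape(-1, x.shape[-1])
        self.feat_mean = flat.mean(axis=0)
        scale = flat.std(axis=0)
        scale[scale < 1e-12] = 1.0
        self.feat_scale = scale

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Class probabilities for a batch (B, T, leads, d_feat)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.T or x.shape[2] != self.graph.n_nodes \
                or x.shape[3] != self.d_feat:
            raise ValidationError(
                f"batch shape {x.shape} does not match model "
                f"(*, {self.T}, {self.graph.n_nodes}, {self.d_feat})")
        drop_rng = rng if train else None
        h = Tensor((x - self.feat_mean) / self.feat_scale)
        for layer in self.gnn_layers:
            h = layer(h, self._norm_adj)          # (B, T, L, d)
        h = mean(h, axis=2)                       # lead mean-pool -> (B, T, d)
        h = self.embed(h) + self._pe              # (B, T, d_model)
        h = self.drop(h, drop_rng)
        for block in self.blocks:
            h = block(h, drop_rng)
        h_final = mean(h, axis=1)                 # time mean-pool -> (B, d_model)
        hidden = self.head_hidden(h_final).relu()
        probs = softmax_t(self.head_out(hidden), axis=-1)
        if np.isnan(probs.data).any():
            raise NumericError("NaN in output probabilities (softmax head)")
        return probs

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size]).data
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)


def model_forward(model: LeadGraphTransformer, batch: np.ndarray, mode: str = "eval",
                  seed: int = 0) -> np.ndarray:
    """Functional forward pass: probabilities with dropout active in train mode."""
    if mode not in ("train", "eval"):
        raise ValidationError("mode must be 'train' or 'eval'")
    rng = np.random.default_rng(seed) if mode == "train" else None
    return model.forward(batch, train=(mode == "train"), rng=rng).data


def cross_entropy_loss(probs: Tensor | np.ndarray, labels: np.ndarray,
                       class_weights: np.ndarray | None = None) -> Tensor:
    """Mean over the batch of ``-w_y log p_y`` (clamped at 1e-12)."""
    t = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    B, K = t.shape
    if labels.shape != (B,) or labels.min(initial=0) < 0 or labels.max(initial=0) >= K:
        raise ValidationError("labels must be codes in [0, n_classes)")
    onehot = np.zeros((B, K))
    onehot[np.arange(B), labels] = 1.0
    if (t.data[np.arange(B), labels] <= 0).any():
        import warnings
        warnings.warn("zero predicted probability clamped at 1e-12")
    w = np.ones(K) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    clamped = t * Tensor(onehot) + Tensor(1e-12)
    per_class = clamped.log() * Tensor(onehot * w[None, :])
    return -(per_class.sum() / float(B))


def decision_map(probs: np.ndarray, thresholds: np.ndarray | dict[str, float] | None = None,
                 label_map=None) -> tuple[str, bool, float]:
    """Map a probability vector to (label symbol, detected flag, confidence).

    Default is argmax (ties break to the lowest class index).  Per-class
    thresholds act as vetoes: if the argmax is an abnormal class whose
    probability falls short of its threshold, the decision falls back to N
    (not detected).  Raising an abnormal threshold therefore only ever turns
    that class's positives into N calls.
    """
    p = np.asarray(probs, dtype=np.float64)
    symbols = [label_map.decode(i) for i in range(p.size)] if label_map is not None \
        else list(CLASS_SYMBOLS[:p.size])
    symbols = sorted(symbols)  # contiguous codes are alphabetical
    winner = int(np.argmax(p))
    if thresholds is not None:
        thr = np.zeros(p.size)
        if isinstance(thresholds, dict):
            for sym, v in thresholds.items():
                thr[symbols.index(sym)] = v
        else:
            thr = np.asarray(thresholds, dtype=np.float64)
        if (thr < 0).any() or (thr > 1).any():
            raise ValidationError("thresholds must lie in [0, 1]")
        if symbols[winner] != "N" and p[winner] < thr[winner] and "N" in symbols:
            winner = symbols.index("N")
    label = symbols[winner]
    detected = label != "N"
    return label, detected, float(p[winner])


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: LeadGraphTransformer, path: str | Path) -> Path:
    """Single-file checkpoint: config manifest (JSON) + parameter arrays."""
    path = Path(path)
    manifest = {
        "config": asdict(model.config),
        "d_feat": model.d_feat,
        "T": model.T,
        "adjacency": model.graph.adjacency.tolist(),
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["feat_mean"] = model.feat_mean
    arrays["feat_scale"] = model.feat_scale
    np.savez(path, manifest=json.dumps(manifest), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> LeadGraphTransformer:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        cfg = ModelConfig(**manifest["config"])
        adj = np.asarray(manifest["adjacency"], dtype=np.int64)
        graph = LeadGraph(n_nodes=adj.shape[0], adjacency=adj)
        model = LeadGraphTransformer(d_feat=manifest["d_feat"], T=manifest["T"],
                              graph=graph, config=cfg)
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"param_{i}"]
        model.feat_mean = data["feat_mean"]
        model.feat_scale = data["feat_scale"]
    return model
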