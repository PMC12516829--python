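"""Multi-task graph transformer for physicochemical property regression.

Architecture: per-node inputs are the featurized atoms concatenated with a
random-walk structural encoding, linearly projected to the hidden width.
Each of ``n_layers`` blocks runs two parallel branches over the batch graph —

* an edge-conditioned GINE-style message-passing branch over bonds, and
* multi-head global self-attention whose post-softmax row weights are
  multiplied elementwise by an exponential decay mask ``gamma**d(i, j)``
  (``d`` = shortest-path hop distance, 0 across disconnected fragments) and
  renormalized to sum to one —

whose outputs are summed with a residual connection, layer-normalized, then
passed through a feed-forward stage with its own residual and normalization.
Mean pooling over each molecule's nodes feeds eight independent linear heads
(intrinsic solubility S0, solubility at pH 2 / pH 7 / FaSSIF, logP, and logD
at pH 2.6 / 7.4 / 10.5).

Training minimizes a homoscedastic-uncertainty-weighted sum of per-task
masked MSE terms, ``sum_t exp(-s_t) * L_t + r(s_t)`` with learnable ``s_t``,
using Adam and early stopping on validation loss.  Everything runs on the
package's internal NumPy autodiff; a fixed seed makes runs bit-reproducible
on one thread configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from ._autodiff import Tensor, gather, segment_sum
from .curation import TaskTable, TASK_NAMES
from .molgraph import FeatureConfig, MolecularGraph

__all__ = [
    "ModelConfig",
    "GraphTransformer",
    "decay_mask",
    "multitask_loss",
    "train",
    "TrainingHistory",
]

N_TASKS = len(TASK_NAMES)


@dataclass(frozen=True)
class ModelConfig:
    learning_rate: float = 0.005
    rw_steps: int = 20
    max_epochs: int = 200
    early_stop_patience: int = 30
    decay_gamma: float = 0.6
    n_layers: int = 2
    hidden_dim: int = 96
    n_heads: int = 4
    batch_size: int = 16
    seed: int = 0
    uncertainty_reg: str = "kendall"   # 'kendall' (r = s/2) or 'softplus'
    # linear warmup then cosine decay of the learning rate, as in the graph
    # transformer training recipes this model follows
    warmup_epochs: int = 5
    lr_schedule: str = "cosine"        # 'cosine' or 'constant'

    def __post_init__(self):
        if not (0.0 <= self.decay_gamma <= 1.0):
            raise ValueError("decay_gamma must be in [0, 1]")
        for name in ("rw_steps", "max_epochs", "early_stop_patience",
                     "n_layers", "hidden_dim", "n_heads", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.uncertainty_reg not in ("kendall", "softplus"):
            raise ValueError("uncertainty_reg must be 'kendall' or 'softplus'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch under the configured schedule."""
        if epoch <= self.warmup_epochs:
            return self.learning_rate * epoch / max(self.warmup_epochs, 1)
        if self.lr_schedule == "constant":
            return self.learning_rate
        span = max(self.max_epochs - self.warmup_epochs, 1)
        t = (epoch - self.warmup_epochs) / span
        return self.learning_rate * 0.5 * (1.0 + np.cos(np.pi * min(t, 1.0)))


def decay_mask(hop_dist: np.ndarray, gamma: float) -> np.ndarray:
    """Attention decay mask gamma**hop; 0 across components, 1 on the diagonal."""
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    hop = np.asarray(hop_dist, float)
    finite = np.isfinite(hop)
    mask = np.zeros_like(hop)
    # 0**0 == 1 handles the gamma = 0 diagonal
    mask[finite] = gamma ** hop[finite]
    return mask


# ---------------------------------------------------------------------------
# batching


@dataclass
class GraphBatch:
    """Dense batch of graphs: stacked nodes plus a block-diagonal decay mask."""

    node_x: np.ndarray        # (N, d_node + K)
    edge_src: np.ndarray      # (2m,) directed
    edge_dst: np.ndarray      # (2m,)
    edge_attr: np.ndarray     # (2m, d_edge)
    graph_idx: np.ndarray     # (N,)
    mask: np.ndarray          # (N, N) block-diagonal decay mask
    n_graphs: int


def collate(graphs: list[MolecularGraph], gamma: float) -> GraphBatch:
    xs, srcs, dsts, attrs, gidx, offset = [], [], [], [], [], 0
    n_total = sum(g.n_atoms for g in graphs)
    mask = np.zeros((n_total, n_total))
    for b, g in enumerate(graphs):
        n = g.n_atoms
        xs.append(np.hstack([g.node_features, g.rw_encoding]))
        if g.n_edges:
            i, j = g.edge_list[:, 0] + offset, g.edge_list[:, 1] + offset
            srcs.append(np.r_[i, j])
            dsts.append(np.r_[j, i])
            attrs.append(np.vstack([g.edge_features, g.edge_features]))
        gidx.append(np.full(n, b))
        mask[offset:offset + n, offset:offset + n] = decay_mask(g.hop_dist, gamma)
        offset += n
    d_edge = graphs[0].edge_features.shape[1]
    return GraphBatch(
        node_x=np.vstack(xs),
        edge_src=np.concatenate(srcs) if srcs else np.zeros(0, int),
        edge_dst=np.concatenate(dsts) if dsts else np.zeros(0, int),
        edge_attr=np.vstack(attrs) if attrs else np.zeros((0, d_edge)),
        graph_idx=np.concatenate(gidx),
        mask=mask,
        n_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# model


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _layernorm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * g + b


class GraphTransformer:
    """Decay-masked graph transformer with eight regression heads."""

    def __init__(self, config: ModelConfig,
                 feature_config: FeatureConfig | None = None):
        self.config = config
        self.feature_config = feature_config or FeatureConfig(
            rw_steps=config.rw_steps
        )
        if self.feature_config.rw_steps != config.rw_steps:
            raise ValueError("feature_config.rw_steps must match config.rw_steps")
        # per-task target standardization (fit during training)
        self.target_mean = np.zeros(N_TASKS)
        self.target_std = np.ones(N_TASKS)
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- parameters -----------------------------------------------------------
    def _add(self, name, data):
        self.params[name] = Tensor(data, requires_grad=True)

    def _init_params(self, rng):
        cfg = self.config
        h = cfg.hidden_dim
        d_in = self.feature_config.node_dim + cfg.rw_steps
        d_edge = self.feature_config.edge_dim
        self._add("in.W", _glorot(rng, d_in, h))
        self._add("in.b", np.zeros(h))
        for l in range(cfg.n_layers):
            p = f"l{l}."
            self._add(p + "gine.We", _glorot(rng, d_edge, h))
            self._add(p + "gine.be", np.zeros(h))
            self._add(p + "gine.W1", _glorot(rng, h, h))
            self._add(p + "gine.b1", np.zeros(h))
            self._add(p + "gine.W2", _glorot(rng, h, h))
            self._add(p + "gine.b2", np.zeros(h))
            for w in ("Wq", "Wk", "Wv", "Wo"):
                self._add(p + "attn." + w, _glorot(rng, h, h))
            for b in ("bq", "bk", "bv", "bo"):
                self._add(p + "attn." + b, np.zeros(h))
            self._add(p + "ln1.g", np.ones(h))
            self._add(p + "ln1.b", np.zeros(h))
            self._add(p + "ffn.W1", _glorot(rng, h, 2 * h))
            self._add(p + "ffn.b1", np.zeros(2 * h))
            self._add(p + "ffn.W2", _glorot(rng, 2 * h, h))
            self._add(p + "ffn.b2", np.zeros(h))
            self._add(p + "ln2.g", np.ones(h))
            self._add(p + "ln2.b", np.zeros(h))
        self._add("head.W", _glorot(rng, h, N_TASKS))
        self._add("head.b", np.zeros(N_TASKS))
        # uncertainty-weighting log-variance parameters s_t
        self._add("loss.s", np.zeros(N_TASKS))

    # -- forward --------------------------------------------------------------
    def _gps_block(self, x: Tensor, batch: GraphBatch, layer: int) -> Tensor:
        # pre-norm layout: both branches read the normalized state and add
        # their output back onto the raw residual stream
        P = self.params
        p = f"l{layer}."
        n = batch.node_x.shape[0]
        cfg = self.config
        h, H = cfg.hidden_dim, cfg.n_heads
        dh = h // H
        xn = _layernorm(x, P[p + "ln1.g"], P[p + "ln1.b"])

        # GINE branch: ReLU(x_src + edge embedding) summed into destinations
        if len(batch.edge_src):
            e = (Tensor(batch.edge_attr) @ P[p + "gine.We"] + P[p + "gine.be"]).relu()
            msg = (gather(xn, batch.edge_src) + e).relu()
            agg = segment_sum(msg, batch.edge_dst, n)
            pre = xn + agg
        else:
            pre = xn
        local = ((pre @ P[p + "gine.W1"] + P[p + "gine.b1"]).relu()
                 @ P[p + "gine.W2"] + P[p + "gine.b2"])

        # decay-masked global attention: softmax rows, elementwise mask,
        # renormalize so each row stays a convex combination
        def split(t):
            return t.reshape(n, H, dh).transpose(1, 0, 2)

        q = split(xn @ P[p + "attn.Wq"] + P[p + "attn.bq"])
        k = split(xn @ P[p + "attn.Wk"] + P[p + "attn.bk"])
        v = split(xn @ P[p + "attn.Wv"] + P[p + "attn.bv"])
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
        w = scores.softmax(axis=-1) * Tensor(batch.mask[None, :, :])
        w = w * (w.sum(axis=-1, keepdims=True) ** -1.0)
        attn = (w @ v).transpose(1, 0, 2).reshape(n, h)
        attn = attn @ P[p + "attn.Wo"] + P[p + "attn.bo"]

        s = x + local + attn
        sn = _layernorm(s, P[p + "ln2.g"], P[p + "ln2.b"])
        f = ((sn @ P[p + "ffn.W1"] + P[p + "ffn.b1"]).relu()
             @ P[p + "ffn.W2"] + P[p + "ffn.b2"])
        return s + f

    def forward(self, batch: GraphBatch) -> Tensor:
        """Standardized-scale predictions, shape (n_graphs, 8)."""
        P = self.params
        x = Tensor(batch.node_x) @ P["in.W"] + P["in.b"]
        for l in range(self.config.n_layers):
            x = self._gps_block(x, batch, l)
        pooled = segment_sum(x, batch.graph_idx, batch.n_graphs)
        counts = np.bincount(batch.graph_idx, minlength=batch.n_graphs)
        pooled = pooled * Tensor(1.0 / counts[:, None])
        return pooled @ P["head.W"] + P["head.b"]

    def predict(self, graphs: list[MolecularGraph],
                batch_size: int | None = None) -> np.ndarray:
        """Task-native-unit predictions, shape (n_graphs, 8)."""
        bs = batch_size or self.config.batch_size
        outs = []
        for i in range(0, len(graphs), bs):
            batch = collate(graphs[i:i + bs], self.config.decay_gamma)
            outs.append(self.forward(batch).data)
        z = np.vstack(outs)
        return z * self.target_std + self.target_mean

    # -- persistence ----------------------------------------------------------
    def save(self, path: str):
        meta = json.dumps({
            "config": asdict(self.config),
            "feature_config": asdict(self.feature_config),
        })
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        np.savez(path, _meta=np.array(meta), _tmean=self.target_mean,
                 _tstd=self.target_std, **arrays)

    @classmethod
    def load(cls, path: str) -> "GraphTransformer":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            fc = meta["feature_config"]
            fc["elements"] = tuple(fc["elements"])
            fc["hybridizations"] = tuple(fc["hybridizations"])
            model = cls(ModelConfig(**meta["config"]), FeatureConfig(**fc))
            model.target_mean = z["_tmean"]
            model.target_std = z["_tstd"]
            for k in model.params:
                model.params[k].data = z[k.replace(".", "__")]
        return model


# ---------------------------------------------------------------------------
# loss


def multitask_loss(
    preds: Tensor,
    targets: np.ndarray,
    observed: np.ndarray,
    log_vars: Tensor,
    reg: str = "kendall",
) -> Tensor:
    """Uncertainty-weighted masked multi-task loss.

    ``sum_t exp(-s_t) * MSE_t + r(s_t)`` over tasks with at least one observed
    entry in the batch; unobserved cells contribute exactly zero gradient.
    ``reg``: 'kendall' -> r(s) = s/2; 'softplus' -> r(s) = log(1 + exp(s)).
    """
    observed = np.asarray(observed, bool)
    counts = observed.sum(axis=0)
    if counts.sum() == 0:
        warnings.warn("multitask_loss: no observed targets in batch")
        return Tensor(0.0)
    mask = observed.astype(float)
    safe_targets = np.where(observed, targets, 0.0)
    err = (preds - Tensor(safe_targets)) * Tensor(mask)
    mse_per_task = (err * err).sum(axis=0) * Tensor(
        np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    )
    active = Tensor((counts > 0).astype(float))
    if reg == "kendall":
        r = log_vars * 0.5
    elif reg == "softplus":
        r = log_vars.softplus()
    else:
        raise ValueError(f"unknown uncertainty regularizer {reg!r}")
    return (((-log_vars).exp() * mse_per_task + r) * active).sum()


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.t = 0
        self.m = {k: np.zeros(p.shape) for k, p in params.items()}
        self.v = {k: np.zeros(p.shape) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based
    stopped_epoch: int = 0       # 1-based


def _loss_on(model: GraphTransformer, graphs, z_targets, observed) -> Tensor:
    batch = collate(graphs, model.config.decay_gamma)
    preds = model.forward(batch)
    return multitask_loss(preds, z_targets, observed,
                          model.params["loss.s"],
                          reg=model.config.uncertainty_reg)


def train(
    task_table: TaskTable,
    graphs: list[MolecularGraph],
    split,
    config: ModelConfig | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[GraphTransformer, TrainingHistory]:
    """Fit a :class:`GraphTransformer` on a task table.

    ``split`` provides disjoint ``train`` and ``val`` index sequences (an
    evalsplit SplitResult or any object with those attributes / keys).
    Targets are standardized per task on the training observations; the best
    validation-epoch weights are restored on return.  Fully reproducible for
    a fixed ``config.seed``.
    """
    config = config or ModelConfig()
    if isinstance(split, dict):
        train_idx = np.asarray(split["train"], int)
        val_idx = np.asarray(split["val"], int)
    else:
        train_idx = np.asarray(split.train, int)
        val_idx = np.asarray(split.val, int)
    if len(train_idx) == 0:
        raise ValueError("empty training split")
    if set(train_idx) & set(val_idx):
        raise ValueError("train/val splits overlap")
    if len(graphs) != task_table.n_compounds:
        raise ValueError("graphs and task table must align")

    model = GraphTransformer(config, feature_config)
    obs = task_table.observed
    vals = task_table.values
    # per-task standardization on training observations
    for t in range(N_TASKS):
        o = obs[train_idx, t]
        if o.any():
            tv = vals[train_idx, t][o]
            model.target_mean[t] = tv.mean()
            sd = tv.std()
            model.target_std[t] = sd if sd > 1e-9 else 1.0
    z = np.where(obs, (vals - model.target_mean) / model.target_std, 0.0)

    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1CE]))
    hist = TrainingHistory()
    best_val = np.inf
    best_state = {k: p.data.copy() for k, p in model.params.items()}

    train_graphs = [graphs[i] for i in train_idx]
    val_graphs = [graphs[i] for i in val_idx]

    for epoch in range(1, config.max_epochs + 1):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(len(train_idx))
        ep_losses = []
        for s in range(0, len(order), config.batch_size):
            sel = order[s:s + config.batch_size]
            rows = train_idx[sel]
            loss = _loss_on(model, [train_graphs[i] for i in sel],
                            z[rows], obs[rows])
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(loss.item())
        hist.train_loss.append(float(np.mean(ep_losses)))

        if len(val_idx):
            vloss = _loss_on(model, val_graphs, z[val_idx], obs[val_idx]).item()
        else:
            vloss = hist.train_loss[-1]
        hist.val_loss.append(vloss)
        if vloss < best_val:
            best_val = vloss
            hist.best_epoch = epoch
            best_state = {k: p.data.copy() for k, p in model.params.items()}
        hist.stopped_epoch = epoch
        if epoch - hist.best_epoch >= config.early_stop_patience:
            break

    for k, p in model.params.items():
        p.data = best_state[k]
    return model, hist
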