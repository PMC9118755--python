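"""Multi-view representation learning for lncRNAs and diseases.

Each similarity view (three for lncRNAs, two for diseases) is treated as a
weighted graph.  A per-view graph convolutional network (GCN) propagates
randomly initialized node embeddings through the symmetrically normalized
adjacency D^{-1/2}(I+S)D^{-1/2}; the per-view, per-layer outputs form the
channels of a feature stack.  A squeeze-excitation attention block rescales
the channels by learned gates, and a bank of feature-dimension convolution
filters (one F x 1 filter per output channel, shared across input channels
and summed) collapses the stack into a C_out x n representation per entity
class.  All parameters — initial embeddings, GCN weights, attention weights,
filters — are trained jointly by Adam on the squared Frobenius norm of
(X'^T Y' - LD), i.e. on reconstructing the association matrix from inner
products of the two representations.

The trainer is plain numpy with analytic gradients: the graphs involved are
dense and small (hundreds of nodes), so a tensor framework would add nothing
but overhead.  Training runs in float32; similarity math elsewhere stays in
float64.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AssociationMatrix
from .similarity import DISEASE_VIEW_ORDER, LNCRNA_VIEW_ORDER, SimilarityView

__all__ = [
    "GcnConfig",
    "NormalizedGraph",
    "LayerEmbeddingStack",
    "AttentionParams",
    "ConvFuser",
    "EntityRepresentation",
    "LossTrace",
    "normalize_graph",
    "gcn_forward",
    "channel_attention",
    "cnn_fuse",
    "reconstruction_loss",
    "train_representations",
]


@dataclass
class GcnConfig:
    """Hyperparameters of the representation learner.

    Defaults follow the reference configuration: embedding size 128, two GCN
    layers, 128 convolution filters, attention expansion factor mu = 5,
    Adam at learning rate 0.001 for 250 epochs.  The three ablation flags
    reproduce the model variants: ``first_layer_only`` keeps only the first
    GCN layer's channels, ``use_attention=False`` gives every channel the
    same weight, and ``use_cnn=False`` replaces the convolutional fusion by
    a channel-wise mean.
    """

    embedding_size: int = 128
    num_layers: int = 2
    n_filters: int = 128
    attention_expansion: int = 5
    learning_rate: float = 0.001
    epochs: int = 250
    seed: int = 0
    use_attention: bool = True
    use_cnn: bool = True
    first_layer_only: bool = False
    leakage_safe: bool = True

    def __post_init__(self) -> None:
        for name in ("embedding_size", "num_layers", "n_filters", "attention_expansion", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def effective_layers(self) -> int:
        return 1 if self.first_layer_only else self.num_layers


@dataclass
class NormalizedGraph:
    """Symmetrically normalized similarity graph D^{-1/2}(I+S)D^{-1/2}."""

    values: np.ndarray
    view_name: str
    entity_ids: list[str]


@dataclass
class LayerEmbeddingStack:
    """Ordered per-view, per-layer feature matrices, each F x n."""

    channels: list[np.ndarray]
    channel_index: list[tuple[str, int]]  # (view_name, layer >= 1)
    entity_ids: list[str]

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels}
        if len(shapes) > 1:
            raise ValueError(f"channels have inconsistent shapes: {shapes}")
        if len(self.channels) != len(self.channel_index):
            raise ValueError("channel_index length does not match channel count")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class AttentionParams:
    """Squeeze-excitation weights; no bias terms on either linear map."""

    W1: np.ndarray  # (C * mu, C)
    W2: np.ndarray  # (C, C * mu)
    mu: int = 5


@dataclass
class ConvFuser:
    """C_out feature-dimension filters (each length F) shared across channels."""

    filters: np.ndarray  # (C_out, F)
    biases: np.ndarray  # (C_out,)


@dataclass
class EntityRepresentation:
    """Final C_out x n embedding; one column per entity."""

    values: np.ndarray
    entity_ids: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("entity representation contains non-finite entries")
        if self.values.shape[1] != len(self.entity_ids):
            raise ValueError("one column per entity required")

    def column(self, entity_id: str) -> np.ndarray:
        return self.values[:, self.entity_ids.index(entity_id)]


@dataclass
class LossTrace:
    """Per-epoch training loss values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("loss trace contains non-finite values")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def normalize_graph(view: SimilarityView) -> NormalizedGraph:
    """D^{-1/2}(I + S)D^{-1/2} with D(i,i) the row sum of I + S."""
    a = np.eye(view.n) + view.values
    inv_sqrt_deg = 1.0 / np.sqrt(a.sum(axis=1))
    values = inv_sqrt_deg[:, None] * a * inv_sqrt_deg[None, :]
    return NormalizedGraph(values, view.view_name, list(view.entity_ids))


def gcn_forward(
    graphs: Sequence[NormalizedGraph],
    weights: Sequence[Sequence[np.ndarray]],
    init: Sequence[np.ndarray],
    first_layer_only: bool = False,
) -> LayerEmbeddingStack:
    """Propagate X^{(l+1)} = ReLU(N X^{(l)} W^{(l)}) per view; stack layers.

    The returned channels are the per-layer outputs transposed to F x n, in
    view order, inner order layer 1..l.
    """
    if not graphs:
        raise ValueError("at least one view required")
    if len(weights) != len(graphs) or len(init) != len(graphs):
        raise ValueError("one weight list and one init matrix per view required")
    channels: list[np.ndarray] = []
    index: list[tuple[str, int]] = []
    for graph, view_weights, x0 in zip(graphs, weights, init):
        x = np.asarray(x0)
        n_layers = 1 if first_layer_only else len(view_weights)
        for layer in range(n_layers):
            x = _relu(graph.values @ x @ view_weights[layer])
            if not np.isfinite(x).all():
                raise FloatingPointError(
                    f"non-finite GCN activation in view {graph.view_name} layer {layer + 1}"
                )
            channels.append(x.T.copy())
            index.append((graph.view_name, layer + 1))
    return LayerEmbeddingStack(channels, index, list(graphs[0].entity_ids))


def channel_attention(
    stack: LayerEmbeddingStack, params: AttentionParams
) -> tuple[LayerEmbeddingStack, np.ndarray]:
    """Scale each channel by a squeeze-excitation gate in (0, 1).

    The gate vector is sigmoid(W2 ReLU(W1 z)) where z holds the global
    average pool (mean) of each channel.  Returns the rescaled stack and the
    gate vector for inspection.
    """
    c = stack.n_channels
    if params.W1.shape != (c * params.mu, c) or params.W2.shape != (c, c * params.mu):
        raise ValueError("attention weight shapes do not match the channel count")
    z = np.array([ch.mean() for ch in stack.channels])
    gates = _sigmoid(params.W2 @ _relu(params.W1 @ z))
    scaled = [g * ch for g, ch in zip(gates, stack.channels)]
    return (
        LayerEmbeddingStack(scaled, list(stack.channel_index), list(stack.entity_ids)),
        gates,
    )


def cnn_fuse(stack: LayerEmbeddingStack, fuser: ConvFuser) -> EntityRepresentation:
    """Collapse the channel stack into a C_out x n representation.

    Output channel q at entity j is the inner product of filter w_q with
    column j of every input channel, summed over channels, plus b_q — an
    F x 1 valid convolution down the feature axis.
    """
    f = stack.channels[0].shape[0]
    if fuser.filters.shape[1] != f:
        raise ValueError("filter length must equal the feature dimension F")
    summed = np.add.reduce(stack.channels)  # filters are channel-shared
    values = fuser.filters @ summed + fuser.biases[:, None]
    return EntityRepresentation(values, list(stack.entity_ids))


def mean_fuse(stack: LayerEmbeddingStack) -> EntityRepresentation:
    """Channel-wise mean fusion (the no-CNN ablation): an F x n embedding."""
    values = np.add.reduce(stack.channels) / stack.n_channels
    return EntityRepresentation(values, list(stack.entity_ids))


def reconstruction_loss(
    x: EntityRepresentation,
    y: EntityRepresentation,
    ld: AssociationMatrix,
    mask: np.ndarray | None = None,
) -> float:
    """Sum of squared errors between X'^T Y' and LD over unmasked cells."""
    if x.values.shape[0] != y.values.shape[0]:
        raise ValueError("lncRNA and disease representations must share C_out")
    diff = x.values.T @ y.values - ld.values
    if mask is not None:
        diff = diff * np.asarray(mask)
    return float((diff**2).sum())


# ---------------------------------------------------------------------------
# Joint training
# ---------------------------------------------------------------------------

_CANONICAL = {"lncrna": LNCRNA_VIEW_ORDER, "disease": DISEASE_VIEW_ORDER}


def sort_views(views: Sequence[SimilarityView], side: str) -> list[SimilarityView]:
    """Order views canonically (lncRNA: LFS, LSS, LGS; disease: DSS, DGS)."""
    order = _CANONICAL[side]
    by_name = {v.view_name: v for v in views}
    if len(by_name) != len(views):
        raise ValueError("duplicate view names")
    unknown = set(by_name) - set(order)
    if unknown:
        raise ValueError(f"views {sorted(unknown)} do not belong to the {side} side")
    return [by_name[name] for name in order if name in by_name]


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class _Side:
    """Forward/backward state for one entity class (lncRNAs or diseases)."""

    def __init__(
        self,
        views: Sequence[SimilarityView],
        cfg: GcnConfig,
        rng: np.random.Generator,
    ) -> None:
        self.cfg = cfg
        self.entity_ids = list(views[0].entity_ids)
        self.n = len(self.entity_ids)
        self.view_names = [v.view_name for v in views]
        self.graphs = [
            normalize_graph(v).values.astype(np.float32) for v in views
        ]
        f = cfg.embedding_size
        self.x0 = [_glorot(rng, (self.n, f)) for _ in views]
        self.w = [
            [_glorot(rng, (f, f)) for _ in range(cfg.effective_layers)] for _ in views
        ]
        c = len(views) * cfg.effective_layers
        self.n_channels = c
        if cfg.use_attention:
            mu = cfg.attention_expansion
            self.w1 = _glorot(rng, (c * mu, c))
            self.w2 = _glorot(rng, (c, c * mu))
        if cfg.use_cnn:
            self.wf = _glorot(rng, (cfg.n_filters, f))
            self.bf = np.zeros(cfg.n_filters, dtype=np.float32)

    def parameters(self) -> list[np.ndarray]:
        params = [*self.x0]
        for view_w in self.w:
            params.extend(view_w)
        if self.cfg.use_attention:
            params.extend([self.w1, self.w2])
        if self.cfg.use_cnn:
            params.extend([self.wf, self.bf])
        return params

    # -- forward ----------------------------------------------------------
    def forward(self) -> np.ndarray:
        cfg = self.cfg
        self._layer_out: list[list[np.ndarray]] = []  # per view, per layer (n, F)
        self._ax: list[list[np.ndarray]] = []  # cached A @ X^{(l)} per layer
        channels: list[np.ndarray] = []
        for graph, x0, view_w in zip(self.graphs, self.x0, self.w):
            outs, axs = [], []
            x = x0
            for w in view_w:
                ax = graph @ x
                x = _relu(ax @ w)
                axs.append(ax)
                outs.append(x)
                channels.append(x.T)
            self._layer_out.append(outs)
            self._ax.append(axs)
        self._channels = channels
        c = self.n_channels
        if cfg.use_attention:
            self._z = np.array([ch.mean() for ch in channels], dtype=channels[0].dtype)
            self._h_pre = self.w1 @ self._z
            self._h = _relu(self._h_pre)
            self._gates = _sigmoid(self.w2 @ self._h)
        else:
            self._gates = np.ones(c, dtype=channels[0].dtype)
        m = np.zeros_like(channels[0])
        for g, ch in zip(self._gates, channels):
            m += g * ch
        self._m = m
        if cfg.use_cnn:
            out = self.wf @ m + self.bf[:, None]
        else:
            out = m / c
        self._out = out
        return out

    # -- backward ---------------------------------------------------------
    def backward(self, d_out: np.ndarray) -> list[np.ndarray]:
        cfg = self.cfg
        if cfg.use_cnn:
            g_wf = d_out @ self._m.T
            g_bf = d_out.sum(axis=1)
            d_m = self.wf.T @ d_out
        else:
            d_m = d_out / self.n_channels
        d_gates = np.array(
            [(d_m * ch).sum() for ch in self._channels], dtype=d_m.dtype
        )
        d_channels = [g * d_m for g in self._gates]
        if cfg.use_attention:
            s = self._gates * (1.0 - self._gates)
            g_pre2 = d_gates * s
            g_w2 = np.outer(g_pre2, self._h)
            d_h = self.w2.T @ g_pre2
            g_pre1 = d_h * (self._h_pre > 0)
            g_w1 = np.outer(g_pre1, self._z)
            d_z = self.w1.T @ g_pre1
            size = float(self._channels[0].size)
            for k in range(self.n_channels):
                d_channels[k] = d_channels[k] + d_z[k] / size
        g_x0: list[np.ndarray] = []
        g_w: list[list[np.ndarray]] = []
        n_layers = cfg.effective_layers
        for vi, (graph, view_w) in enumerate(zip(self.graphs, self.w)):
            outs = self._layer_out[vi]
            axs = self._ax[vi]
            base = vi * n_layers
            carried = np.zeros_like(outs[-1])
            g_view_w = [None] * n_layers
            for layer in range(n_layers - 1, -1, -1):
                g_layer = d_channels[base + layer].T + carried
                d_pre = g_layer * (outs[layer] > 0)
                g_view_w[layer] = axs[layer].T @ d_pre
                carried = graph @ (d_pre @ view_w[layer].T)
            g_w.append(g_view_w)
            g_x0.append(carried)
        flat = [*g_x0]
        for view_g in g_w:
            flat.extend(view_g)
        if cfg.use_attention:
            flat.extend([g_w1, g_w2])
        if cfg.use_cnn:
            flat.extend([g_wf, g_bf])
        return flat


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train_representations(
    views_l: Sequence[SimilarityView],
    views_d: Sequence[SimilarityView],
    ld: AssociationMatrix,
    cfg: GcnConfig,
    loss_mask: np.ndarray | None = None,
) -> tuple[EntityRepresentation, EntityRepresentation, LossTrace]:
    """Jointly train both sides' GCN/attention/CNN parameters with Adam.

    ``loss_mask`` (binary L x T, 1 = cell participates in the loss) supports
    leakage-safe cross-validation: held-out association cells are excluded
    from the reconstruction objective.  Deterministic for a fixed seed.
    """
    views_l = sort_views(views_l, "lncrna")
    views_d = sort_views(views_d, "disease")
    for v in views_l:
        if v.entity_ids != ld.lncrna_ids:
            raise ValueError(f"view {v.view_name} entity order differs from LD rows")
    for v in views_d:
        if v.entity_ids != ld.disease_ids:
            raise ValueError(f"view {v.view_name} entity order differs from LD columns")

    rng = np.random.default_rng(cfg.seed)
    side_l = _Side(views_l, cfg, rng)
    side_d = _Side(views_d, cfg, rng)
    target = ld.values.astype(np.float32)
    mask = None
    if loss_mask is not None:
        mask = np.asarray(loss_mask, dtype=np.float32)
        if mask.shape != target.shape:
            raise ValueError("loss mask shape must match the association matrix")

    opt = _Adam(side_l.parameters() + side_d.parameters(), cfg.learning_rate)
    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        xp = side_l.forward()
        yp = side_d.forward()
        diff = xp.T @ yp - target
        if mask is not None:
            diff = diff * mask
        loss = float((diff**2).sum())
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        trace[epoch] = loss
        err = 2.0 * diff
        d_xp = yp @ err.T
        d_yp = xp @ err
        grads = side_l.backward(d_xp) + side_d.backward(d_yp)
        opt.step(grads)

    x_final = side_l.forward().astype(np.float64)
    y_final = side_d.forward().astype(np.float64)
    return (
        EntityRepresentation(x_final, side_l.entity_ids),
        EntityRepresentation(y_final, side_d.entity_ids),
        LossTrace(trace),
    )
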