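"""Graph-convolutional network for pocket-graph affinity regression.

The convolution is the symmetric-normalized propagation rule

    F' = sigma( D^{-1/2} (A + I) D^{-1/2} . F . W )

applied independently per distance-binned adjacency matrix. The network is a
shared node-wise input layer followed by one graph-convolution block per bin
(GC 128 -> FC 128 -> dropout -> GC 128 -> FC 128 -> dropout -> GC 32 ->
FC 16*n_bins -> sum-gather), concatenation of the gathered vectors, a final
fully-connected layer with dropout, and a linear scalar output. Hidden
activations are ReLU; graph-convolution layers carry no bias, node-wise
fully-connected layers do, and padded node rows are re-zeroed after every
node-wise layer so padding never reaches the gather sum.

Implemented directly on numpy arrays with an explicit backward pass; see
``training_eval`` for the optimizer and loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .featurizer import N_FEATURES, VALID_N_BINS, PocketGraph

_EPS_DROPOUT = 1e-12


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``block_variant`` selects the internal block layout: ``"three_fc"`` (the
    default) places a fully-connected layer after every graph convolution,
    with widths (128, 128, 16*n_bins); ``"two_fc"`` omits the third
    fully-connected layer so the gathered width is the last GC width (32).
    """

    n_bins: int = 2
    n_features: int = N_FEATURES
    input_fc_width: int = 128
    gc_widths: tuple[int, int, int] = (128, 128, 32)
    block_fc_widths: tuple[int, int] = (128, 128)
    final_fc_width: int = 128
    dropout_rate: float = 0.5
    seed: int = 0
    block_variant: str = "three_fc"

    def __post_init__(self):
        if self.n_bins not in VALID_N_BINS:
            raise ValueError(f"n_bins must be one of {VALID_N_BINS}, got {self.n_bins}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.block_variant not in ("three_fc", "two_fc"):
            raise ValueError(f"unknown block_variant {self.block_variant!r}")
        for w in (self.input_fc_width, *self.gc_widths, *self.block_fc_widths, self.final_fc_width):
            if int(w) <= 0:
                raise ValueError("layer widths must be positive")

    @property
    def block_out_width(self) -> int:
        """Width of one block's gathered vector."""
        return 16 * self.n_bins if self.block_variant == "three_fc" else self.gc_widths[2]

    @property
    def concat_width(self) -> int:
        return self.n_bins * self.block_out_width


@dataclass
class Network:
    """A realized network: config plus all trainable parameter arrays."""

    config: NetworkConfig
    params: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def copy(self) -> "Network":
        return Network(self.config, {k: v.copy() for k, v in self.params.items()})


# ---------------------------------------------------------------------------
# Primitive operations


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization with self-loops:
    D^{-1/2} (A + I) D^{-1/2}, D the degree matrix of A + I.

    Isolated nodes (including zero-padded ones) get a lone diagonal entry 1,
    so they propagate only their own (zero) features.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def graph_conv(F: np.ndarray, A_hat: np.ndarray, W: np.ndarray, activation: bool = True) -> np.ndarray:
    """One graph convolution: sigma(A_hat @ F @ W), no bias."""
    F, A_hat, W = np.asarray(F), np.asarray(A_hat), np.asarray(W)
    if A_hat.shape[1] != F.shape[0] or F.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A_hat {A_hat.shape}, F {F.shape}, W {W.shape}"
        )
    out = A_hat @ F @ W
    return np.maximum(out, 0.0) if activation else out


def graph_gather(F: np.ndarray, n_nodes: int) -> np.ndarray:
    """Column-wise sum over the first ``n_nodes`` rows (the real nodes)."""
    F = np.asarray(F)
    if n_nodes > F.shape[0]:
        raise ValueError(f"n_nodes {n_nodes} exceeds {F.shape[0]} rows")
    return F[:n_nodes].sum(axis=0)


# ---------------------------------------------------------------------------
# Parameter initialization


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_network(config: NetworkConfig) -> Network:
    """Instantiate all weights, Glorot-uniform, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    p: dict[str, np.ndarray] = {}
    p["input_fc_W"] = _glorot(rng, config.n_features, config.input_fc_width)
    p["input_fc_b"] = np.zeros(config.input_fc_width)
    g1, g2, g3 = config.gc_widths
    f1, f2 = config.block_fc_widths
    for b in range(config.n_bins):
        pre = f"block{b}_"
        p[pre + "gc1_W"] = _glorot(rng, config.input_fc_width, g1)
        p[pre + "fc1_W"] = _glorot(rng, g1, f1)
        p[pre + "fc1_b"] = np.zeros(f1)
        p[pre + "gc2_W"] = _glorot(rng, f1, g2)
        p[pre + "fc2_W"] = _glorot(rng, g2, f2)
        p[pre + "fc2_b"] = np.zeros(f2)
        p[pre + "gc3_W"] = _glorot(rng, f2, g3)
        if config.block_variant == "three_fc":
            p[pre + "fc3_W"] = _glorot(rng, g3, config.block_out_width)
            p[pre + "fc3_b"] = np.zeros(config.block_out_width)
    p["final_fc_W"] = _glorot(rng, config.concat_width, config.final_fc_width)
    p["final_fc_b"] = np.zeros(config.final_fc_width)
    p["out_W"] = _glorot(rng, config.final_fc_width, 1)
    p["out_b"] = np.zeros(1)
    return Network(config=config, params=p)


# ---------------------------------------------------------------------------
# Batched forward / backward
#
# Shapes: X (B, N, F_in); A_hat (B, n_bins, N, N) pre-normalized; mask (B, N)
# with 1 on real nodes. All node-wise layers multiply by the mask so biases
# never leak into padded rows.


def _dropout_mask(rng: np.random.Generator | None, shape, rate: float):
    if rng is None or rate <= 0.0:
        return None
    keep = 1.0 - rate
    return (rng.random(shape) < keep) / max(keep, _EPS_DROPOUT)


def forward_batch(
    net: Network,
    X: np.ndarray,
    A_hat: np.ndarray,
    mask: np.ndarray,
    drop_rng: np.random.Generator | None = None,
):
    """Batched forward pass. ``drop_rng`` enables (inverted) dropout; pass
    None for eval mode. Returns (predictions (B,), cache for backward)."""
    cfg = net.config
    p = net.params
    if A_hat.shape[1] != cfg.n_bins:
        raise ValueError(f"graph has {A_hat.shape[1]} adjacency bins, network expects {cfg.n_bins}")
    m = mask[:, :, None]
    cache: dict = {"X": X, "mask": mask, "A_hat": A_hat}

    # shared node-wise input layer
    z0 = X @ p["input_fc_W"] + p["input_fc_b"]
    h0 = np.maximum(z0, 0.0) * m
    d0 = _dropout_mask(drop_rng, h0.shape, cfg.dropout_rate)
    h0d = h0 * d0 if d0 is not None else h0
    cache.update(z0=z0, h0=h0, d0=d0, h0d=h0d)

    gathered = []
    for b in range(cfg.n_bins):
        pre = f"block{b}_"
        A = A_hat[:, b]
        c: dict = {}
        # GC1 -> FC1 -> dropout
        c["gc1_in"] = h0d
        c["gc1_M"] = A @ h0d
        c["gc1_z"] = c["gc1_M"] @ p[pre + "gc1_W"]
        c["gc1_h"] = np.maximum(c["gc1_z"], 0.0)
        c["fc1_z"] = (c["gc1_h"] @ p[pre + "fc1_W"] + p[pre + "fc1_b"])
        c["fc1_h"] = np.maximum(c["fc1_z"], 0.0) * m
        c["d1"] = _dropout_mask(drop_rng, c["fc1_h"].shape, cfg.dropout_rate)
        c["h1"] = c["fc1_h"] * c["d1"] if c["d1"] is not None else c["fc1_h"]
        # GC2 -> FC2 -> dropout
        c["gc2_M"] = A @ c["h1"]
        c["gc2_z"] = c["gc2_M"] @ p[pre + "gc2_W"]
        c["gc2_h"] = np.maximum(c["gc2_z"], 0.0)
        c["fc2_z"] = (c["gc2_h"] @ p[pre + "fc2_W"] + p[pre + "fc2_b"])
        c["fc2_h"] = np.maximum(c["fc2_z"], 0.0) * m
        c["d2"] = _dropout_mask(drop_rng, c["fc2_h"].shape, cfg.dropout_rate)
        c["h2"] = c["fc2_h"] * c["d2"] if c["d2"] is not None else c["fc2_h"]
        # GC3 (-> FC3) -> gather
        c["gc3_M"] = A @ c["h2"]
        c["gc3_z"] = c["gc3_M"] @ p[pre + "gc3_W"]
        c["gc3_h"] = np.maximum(c["gc3_z"], 0.0)
        if cfg.block_variant == "three_fc":
            c["fc3_z"] = (c["gc3_h"] @ p[pre + "fc3_W"] + p[pre + "fc3_b"])
            c["fc3_h"] = np.maximum(c["fc3_z"], 0.0) * m
            block_nodes = c["fc3_h"]
        else:
            block_nodes = c["gc3_h"] * m
        c["block_nodes"] = block_nodes
        gathered.append(block_nodes.sum(axis=1))  # (B, block_out_width)
        cache[f"block{b}"] = c

    G = np.concatenate(gathered, axis=1)
    zf = G @ p["final_fc_W"] + p["final_fc_b"]
    hf = np.maximum(zf, 0.0)
    df = _dropout_mask(drop_rng, hf.shape, cfg.dropout_rate)
    hfd = hf * df if df is not None else hf
    pred = (hfd @ p["out_W"] + p["out_b"]).ravel()
    cache.update(G=G, zf=zf, hf=hf, df=df, hfd=hfd)
    return pred, cache


def _weight_grad(H: np.ndarray, dZ: np.ndarray) -> np.ndarray:
    """Sum over batch and nodes of H_i^T dZ_i, as one flat matmul."""
    f, g = H.shape[-1], dZ.shape[-1]
    return H.reshape(-1, f).T @ dZ.reshape(-1, g)


def backward_batch(net: Network, cache: dict, dpred: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all parameters, given d(loss)/d(pred)."""
    cfg = net.config
    p = net.params
    mask = cache["mask"]
    m = mask[:, :, None]
    A_hat = cache["A_hat"]
    grads: dict[str, np.ndarray] = {}

    dpred = dpred.reshape(-1, 1)
    grads["out_W"] = cache["hfd"].T @ dpred
    grads["out_b"] = dpred.sum(axis=0)
    dhfd = dpred @ p["out_W"].T
    if cache["df"] is not None:
        dhfd = dhfd * cache["df"]
    dzf = dhfd * (cache["zf"] > 0)
    grads["final_fc_W"] = cache["G"].T @ dzf
    grads["final_fc_b"] = dzf.sum(axis=0)
    dG = dzf @ p["final_fc_W"].T

    w = cfg.block_out_width
    dh0d_total = np.zeros_like(cache["h0d"])
    for b in range(cfg.n_bins):
        pre = f"block{b}_"
        c = cache[f"block{b}"]
        A = A_hat[:, b]
        dgather = dG[:, b * w : (b + 1) * w]  # (B, w)
        dnodes = np.repeat(dgather[:, None, :], cache["X"].shape[1], axis=1)

        if cfg.block_variant == "three_fc":
            dfc3h = dnodes * m
            dfc3z = dfc3h * (c["fc3_z"] > 0)
            grads[pre + "fc3_W"] = _weight_grad(c["gc3_h"], dfc3z)
            grads[pre + "fc3_b"] = dfc3z.sum(axis=(0, 1))
            dgc3h = dfc3z @ p[pre + "fc3_W"].T
        else:
            dgc3h = dnodes * m
        dgc3z = dgc3h * (c["gc3_z"] > 0)
        grads[pre + "gc3_W"] = _weight_grad(c["gc3_M"], dgc3z)
        dh2 = A @ (dgc3z @ p[pre + "gc3_W"].T)  # A symmetric

        dfc2h = dh2 * c["d2"] if c["d2"] is not None else dh2
        dfc2h = dfc2h * m
        dfc2z = dfc2h * (c["fc2_z"] > 0)
        grads[pre + "fc2_W"] = _weight_grad(c["gc2_h"], dfc2z)
        grads[pre + "fc2_b"] = dfc2z.sum(axis=(0, 1))
        dgc2h = dfc2z @ p[pre + "fc2_W"].T
        dgc2z = dgc2h * (c["gc2_z"] > 0)
        grads[pre + "gc2_W"] = _weight_grad(c["gc2_M"], dgc2z)
        dh1 = A @ (dgc2z @ p[pre + "gc2_W"].T)

        dfc1h = dh1 * c["d1"] if c["d1"] is not None else dh1
        dfc1h = dfc1h * m
        dfc1z = dfc1h * (c["fc1_z"] > 0)
        grads[pre + "fc1_W"] = _weight_grad(c["gc1_h"], dfc1z)
        grads[pre + "fc1_b"] = dfc1z.sum(axis=(0, 1))
        dgc1h = dfc1z @ p[pre + "fc1_W"].T
        dgc1z = dgc1h * (c["gc1_z"] > 0)
        grads[pre + "gc1_W"] = _weight_grad(c["gc1_M"], dgc1z)
        dh0d_total += A @ (dgc1z @ p[pre + "gc1_W"].T)

    dh0 = dh0d_total * cache["d0"] if cache["d0"] is not None else dh0d_total
    dh0 = dh0 * m
    dz0 = dh0 * (cache["z0"] > 0)
    grads["input_fc_W"] = _weight_grad(cache["X"], dz0)
    grads["input_fc_b"] = dz0.sum(axis=(0, 1))
    return grads


# ---------------------------------------------------------------------------
# Graph stacking and the single-graph interface


def normalize_graph_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Normalize each bin's matrix of one graph; cached by callers since it
    is weight-independent."""
    return np.stack([normalize_adjacency(adjacency[k]) for k in range(adjacency.shape[0])])


def stack_graphs(graphs: list[PocketGraph], crop: bool = True):
    """Stack graphs into batched tensors (X, A_hat, mask, y, ids).

    With ``crop``, trailing all-zero padding beyond the largest true node
    count is removed; predictions are unchanged (padding invariance) and the
    dense matrix products shrink accordingly.
    """
    if not graphs:
        raise ValueError("no graphs to stack")
    n_max = max(g.n_nodes for g in graphs) if crop else graphs[0].features.shape[0]
    X = np.stack([g.features[:n_max] for g in graphs])
    A_hat = np.stack([normalize_graph_adjacency(g.adjacency[:, :n_max, :n_max]) for g in graphs])
    mask = np.zeros((len(graphs), n_max))
    for i, g in enumerate(graphs):
        mask[i, : g.n_nodes] = 1.0
    y = np.array([g.label for g in graphs])
    ids = [g.id for g in graphs]
    return X, A_hat, mask, y, ids


def forward(net: Network, graph: PocketGraph, train_mode: bool = False,
            rng: np.random.Generator | None = None) -> float:
    """Predict the affinity of one pocket graph. Dropout is active only in
    train mode (supply ``rng``); eval mode is deterministic."""
    X, A_hat, mask, _, _ = stack_graphs([graph], crop=False)
    drop_rng = rng if train_mode else None
    if train_mode and rng is None:
        drop_rng = np.random.default_rng(net.config.seed)
    pred, _ = forward_batch(net, X, A_hat, mask, drop_rng=drop_rng)
    return float(pred[0])


# ---------------------------------------------------------------------------
# Checkpointing


def save_network(path: str, net: Network) -> None:
    """Single-file checkpoint: config as JSON plus all weight arrays."""
    meta = json.dumps(asdict(net.config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **net.params)


def load_network(path: str) -> Network:
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    meta = json.loads(bytes(data["__config__"]).decode())
    meta["gc_widths"] = tuple(meta["gc_widths"])
    meta["block_fc_widths"] = tuple(meta["block_fc_widths"])
    cfg = NetworkConfig(**meta)
    params = {k: data[k] for k in data.files if k != "__config__"}
    return Network(config=cfg, params=params)
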