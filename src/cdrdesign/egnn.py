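"""E(n)-equivariant graph network stack with per-layer coordinate masking.

Each layer passes messages over the k-nearest-neighbour residue graph.
Feature updates are invariant and coordinate updates equivariant under
rigid motions: messages depend on node features and squared pairwise
distance only, and coordinate updates are sums of relative displacement
vectors scaled by learned scalars. After every layer the coordinates of
non-CDR rows are reset to the input coordinates by the masking vector,
so only the loop being designed moves.

The final layer's features feed a two-layer feedforward head producing
20-way amino-acid logits for every node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concatenate, segment_sum, tensor
from .graph_prep import GraphSample, MASK_TOKEN

__all__ = ["ModelConfig", "ForwardTrace", "Model", "init_params", "apply_coord_mask"]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults mirror the full-scale design: 16 layers, 64-nearest-node
    graph, 256-wide amino-acid embedding plus a 2-wide chain-type
    embedding. The structural-plausibility losses attach after layer 4,
    hence at least 5 layers are required.
    """

    n_layers: int = 16
    aa_embed_dim: int = 256
    chain_embed_dim: int = 2
    hidden_dim: int = 256
    k_neighbors: int = 64
    n_aa_types: int = 20
    mask_token_id: int = MASK_TOKEN
    coord_scale: float = 0.1  # init scale of the coordinate-update head
    dtype: type = np.float64

    def __post_init__(self):
        if self.n_layers < 5:
            raise ValueError("need at least 5 layers (violation losses start after layer 4)")

    @property
    def input_dim(self) -> int:
        return self.aa_embed_dim + self.chain_embed_dim


@dataclass
class ForwardTrace:
    """Per-layer outputs retained for the layer-wise (local) losses."""

    per_layer_coords: list  # n_layers × (L,3), post-masking
    per_layer_feats: list   # n_layers × (L,hidden)
    final_logits: object    # (L,20)

    def numpy(self) -> "ForwardTrace":
        """Detach to plain ndarrays (for metrics and inference)."""
        as_np = lambda t: t.data if isinstance(t, Tensor) else np.asarray(t)
        return ForwardTrace(
            [as_np(c) for c in self.per_layer_coords],
            [as_np(f) for f in self.per_layer_feats],
            as_np(self.final_logits),
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, scale: float = 1.0):
    lim = scale * np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(fan_out: int):
    return Tensor(np.zeros(fan_out), requires_grad=True)


def _linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return x @ W + b


def init_params(config: ModelConfig, seed: int = 0) -> dict:
    """Initialise all learnable parameters, keyed by component name."""
    rng = np.random.default_rng(seed)
    h, d_in = config.hidden_dim, config.input_dim
    p: dict[str, Tensor] = {
        "aa_embed": Tensor(
            rng.normal(0, 0.1, size=(config.n_aa_types + 1, config.aa_embed_dim)),
            requires_grad=True,
        ),
        "chain_embed": Tensor(
            rng.normal(0, 0.1, size=(2, config.chain_embed_dim)), requires_grad=True
        ),
        "proj_W": _glorot(rng, d_in, h),
        "proj_b": _zeros(h),
    }
    for k in range(config.n_layers):
        # edge message MLP: (h_i, h_j, d²) -> h
        p[f"l{k}.msg_W1"] = _glorot(rng, 2 * h + 1, h)
        p[f"l{k}.msg_b1"] = _zeros(h)
        p[f"l{k}.msg_W2"] = _glorot(rng, h, h)
        p[f"l{k}.msg_b2"] = _zeros(h)
        # coordinate scalar: message -> 1
        p[f"l{k}.coord_W1"] = _glorot(rng, h, h)
        p[f"l{k}.coord_b1"] = _zeros(h)
        p[f"l{k}.coord_W2"] = _glorot(rng, h, 1, scale=config.coord_scale)
        p[f"l{k}.coord_b2"] = _zeros(1)
        # node update MLP: (h_i, m_i) -> h, applied with a residual
        p[f"l{k}.node_W1"] = _glorot(rng, 2 * h, h)
        p[f"l{k}.node_b1"] = _zeros(h)
        p[f"l{k}.node_W2"] = _glorot(rng, h, h)
        p[f"l{k}.node_b2"] = _zeros(h)
    # feedforward head: two fully connected layers, nonlinearity between
    p["head_W1"] = _glorot(rng, h, h)
    p["head_b1"] = _zeros(h)
    p["head_W2"] = _glorot(rng, h, config.n_aa_types)
    p["head_b2"] = _zeros(config.n_aa_types)
    return p


def embed_inputs(
    seq_tokens: np.ndarray, chain_type: np.ndarray, params: dict
) -> Tensor:
    """Concatenate the amino-acid and chain-type embeddings rowwise."""
    if seq_tokens.min() < 0 or seq_tokens.max() > MASK_TOKEN:
        raise ValueError("sequence token out of range [0, 20]")
    if not np.all((chain_type == 0) | (chain_type == 1)):
        raise ValueError("chain_type must be 0 (antibody) or 1 (antigen)")
    return concatenate(
        [params["aa_embed"][seq_tokens], params["chain_embed"][chain_type]], axis=1
    )


def egnn_layer(
    feats: Tensor,
    coords: Tensor,
    edges: np.ndarray,
    params: dict,
    layer: int,
) -> tuple[Tensor, Tensor]:
    """One equivariant message-passing layer.

    Messages m_ij = φ_e(f_i, f_j, ‖x_i − x_j‖²); coordinates move by the
    mean of (x_i − x_j)·φ_x(m_ij) over in-neighbours; features update
    through φ_h(f_i, Σ m_ij) with a residual connection.
    """
    pre = f"l{layer}."
    src, dst = edges[:, 0], edges[:, 1]
    L = feats.shape[0]

    x_dst, x_src = coords[dst], coords[src]
    rel = x_dst - x_src
    d2 = (rel * rel).sum(axis=1, keepdims=True)

    # log-compressed distance feature keeps far pairs O(1); relative
    # vectors normalised by (d + 1) bound coordinate steps — both are
    # invariant functions of the squared pair distance
    msg_in = concatenate([feats[dst], feats[src], (d2 * 0.01 + 1.0).log()], axis=1)
    m = _linear(msg_in, params[pre + "msg_W1"], params[pre + "msg_b1"]).silu()
    m = _linear(m, params[pre + "msg_W2"], params[pre + "msg_b2"]).silu()

    coef = _linear(
        _linear(m, params[pre + "coord_W1"], params[pre + "coord_b1"]).silu(),
        params[pre + "coord_W2"],
        params[pre + "coord_b2"],
    )
    n_in = np.bincount(dst, minlength=L).reshape(-1, 1).astype(float)
    rel_unit = rel / (d2.sqrt() + 1.0)
    coords_out = coords + segment_sum(rel_unit * coef, dst, L) / np.maximum(n_in, 1.0)

    agg = segment_sum(m, dst, L) / np.maximum(n_in, 1.0)  # mean over in-edges
    upd_in = concatenate([feats, agg], axis=1)
    upd = _linear(upd_in, params[pre + "node_W1"], params[pre + "node_b1"]).silu()
    upd = _linear(upd, params[pre + "node_W2"], params[pre + "node_b2"])
    return feats + upd, coords_out


def apply_coord_mask(x_k, x_input, mask: np.ndarray):
    """Rowwise select x̃ = x_k·M + x_input·(1−M); pins non-CDR rows.

    Works on Tensors (differentiable path) and plain arrays alike.
    """
    m = np.asarray(mask, dtype=float).reshape(-1, 1)
    if isinstance(x_k, Tensor) or isinstance(x_input, Tensor):
        return tensor(x_k) * m + tensor(x_input) * (1.0 - m)
    return x_k * m + x_input * (1.0 - m)


class Model:
    """The layer stack plus amino-acid head, bound to a parameter set."""

    def __init__(self, config: ModelConfig, params: dict | None = None, seed: int = 0):
        self.config = config
        self.params = params if params is not None else init_params(config, seed)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(self, sample: GraphSample) -> ForwardTrace:
        cfg = self.config
        x_input = np.asarray(sample.coords, dtype=cfg.dtype)
        feats = embed_inputs(sample.seq_tokens, sample.chain_type, self.params)
        feats = _linear(feats, self.params["proj_W"], self.params["proj_b"])
        coords = tensor(x_input)

        per_coords, per_feats = [], []
        for k in range(cfg.n_layers):
            feats, coords = egnn_layer(feats, coords, sample.edges, self.params, k)
            coords = apply_coord_mask(coords, x_input, sample.mask)
            per_coords.append(coords)
            per_feats.append(feats)

        logits = self.head(feats)
        return ForwardTrace(per_coords, per_feats, logits)

    def head(self, feats) -> Tensor:
        """Two fully connected layers with a nonlinearity in between → 20 logits."""
        h = _linear(tensor(feats), self.params["head_W1"], self.params["head_b1"]).silu()
        return _linear(h, self.params["head_W2"], self.params["head_b2"])

    # -- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=self.config.dtype)

    def save(self, path) -> None:
        import json as _json

        cfg = {
            k: (v if not isinstance(v, type) else v.__name__)
            for k, v in vars(self.config).items()
        }
        np.savez(path, __config__=np.frombuffer(
            _json.dumps(cfg).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path) -> "Model":
        import json as _json

        with np.load(path) as z:
            cfg = _json.loads(bytes(z["__config__"].tobytes()).decode())
            cfg["dtype"] = getattr(np, cfg.get("dtype", "float64"))
            config = ModelConfig(**cfg)
            model = cls(config)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model
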