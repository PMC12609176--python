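"""The multimodal forward pass.

Three per-residue information streams are combined:

* an E(3)-equivariant graph network over the residue graph turns the 62-dim
  node features into structural embeddings F_struct (feature updates are
  invariant, coordinate updates equivariant under rigid motions);
* a pretrained-encoder sequence embedding F_seq;
* a pooled function-text embedding F_text.

Structure and sequence attend to each other in two symmetric cross-attention
branches, each conditioned on the text vector through a projected broadcast
concatenated into the branch FFN.  A sigmoid gate then blends the fused
features with the original concatenated features per residue, and a small
feed-forward head emits K-class probabilities per residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, concat, layer_norm, softmax
from .errors import ConsistencyError, EmptyInputError
from .structure import N_FEATURES, ResidueGraph

MAX_LEN = 1024


@dataclass
class NetworkConfig:
    d_s: int = 32
    d_h: int = 32
    d_t: int = 32
    n_classes: int = 7
    egnn_layers: int = 2
    attn_scale: str = "as_printed"  # or "key_dim"
    n_heads: int = 1
    per_dim_gate: bool = False
    seed: int = 0

    @property
    def d_final(self) -> int:
        return self.d_s + self.d_h

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls(**json.loads(s))


@dataclass
class ForwardOutput:
    """All intermediate and final activations of one protein's forward pass.

    Tensors retain the autodiff graph so losses can backpropagate; the
    numpy views are for inspection and prediction.
    """

    f_struct: Tensor  # (L, d_h)
    f_seq: Tensor  # (L, d_s)
    o_struct: Tensor  # (L, d_h)
    o_seq: Tensor  # (L, d_s)
    coords_out: Tensor  # (L, 3) final EGNN coordinates (computed, unused downstream)
    gate: Tensor  # (L, 1) or (L, d_final)
    f_final: Tensor  # (L, d_s + d_h)
    logits: Tensor  # (L, K)

    @property
    def probs(self) -> np.ndarray:
        z = self.logits.data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    @property
    def predicted(self) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return np.argmax(self.probs, axis=1)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

class ModelParams:
    """Flat registry of named parameter Tensors with fan-in init."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        d_s, d_h, d_t, K = config.d_s, config.d_h, config.d_t, config.n_classes

        def lin(name: str, fan_in: int, fan_out: int) -> None:
            bound = 1.0 / np.sqrt(fan_in)
            self.params[f"{name}.W"] = Tensor(
                rng.uniform(-bound, bound, (fan_in, fan_out)), requires_grad=True)
            self.params[f"{name}.b"] = Tensor(
                rng.uniform(-bound, bound, fan_out), requires_grad=True)

        def norm(name: str, dim: int) -> None:
            self.params[f"{name}.g"] = Tensor(np.ones(dim), requires_grad=True)
            self.params[f"{name}.b"] = Tensor(np.zeros(dim), requires_grad=True)

        # EGNN layers: first embeds the 62-dim node features into d_h
        in_dim = N_FEATURES
        for layer in range(config.egnn_layers):
            lin(f"egnn{layer}.phi_e.0", 2 * in_dim + 2, d_h)
            lin(f"egnn{layer}.phi_e.1", d_h, d_h)
            lin(f"egnn{layer}.phi_x.0", d_h, d_h)
            lin(f"egnn{layer}.phi_x.1", d_h, 1)
            lin(f"egnn{layer}.phi_h.0", in_dim + d_h, d_h)
            lin(f"egnn{layer}.phi_h.1", d_h, d_h)
            in_dim = d_h

        # cross-attention branches: 1 = structure query, 2 = sequence query
        lin("br1.WK", d_s, d_h)
        lin("br1.WV", d_s, d_h)
        lin("br1.text", d_t, d_h)
        lin("br1.ffn.0", 2 * d_h, 2 * d_h)
        lin("br1.ffn.1", 2 * d_h, d_h)
        norm("br1.norm1", d_h)
        norm("br1.norm2", d_h)
        lin("br2.WK", d_h, d_s)
        lin("br2.WV", d_h, d_s)
        lin("br2.text", d_t, d_s)
        lin("br2.ffn.0", 2 * d_s, 2 * d_s)
        lin("br2.ffn.1", 2 * d_s, d_s)
        norm("br2.norm1", d_s)
        norm("br2.norm2", d_s)

        d_f = config.d_final
        gate_out = d_f if config.per_dim_gate else 1
        lin("gate.0", 2 * d_f, d_f)
        lin("gate.1", d_f, gate_out)
        lin("head.0", d_f, d_h)
        lin("head.1", d_h, K)

    def __getitem__(self, name: str) -> Tensor:
        return self.params[name]

    def linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in arrays:
                raise ConsistencyError(f"checkpoint missing parameter {k}")
            if arrays[k].shape != v.data.shape:
                raise ConsistencyError(f"shape mismatch for {k}")
            v.data = np.array(arrays[k], dtype=np.float64)


# ---------------------------------------------------------------------------
# EGNN
# ---------------------------------------------------------------------------

def egnn_forward(graph: ResidueGraph, h0: np.ndarray, params: ModelParams,
                 phi_x_zero: bool = False) -> tuple[Tensor, Tensor]:
    """T-layer equivariant message passing.

    Per layer, over both directions of each undirected edge (recv i, send j):
    m_ij = phi_e(h_i, h_j, |x_i - x_j|^2, a_ij); coordinates move by
    (M - 1)^-1 * sum_j (x_i - x_j) * phi_x(m_ij) with M the node count;
    m_i = sum_j m_ij; h_i = phi_h(h_i, m_i).  Nodes without edges receive a
    zero message.  For M = 1 the coordinate update is skipped.

    ``phi_x_zero`` stubs the coordinate map to 0 (diagnostics only).
    """
    L = graph.n_nodes
    if h0.shape[0] != L:
        raise ConsistencyError(f"h0 rows {h0.shape[0]} != graph nodes {L}")
    h = h0 if isinstance(h0, Tensor) else Tensor(np.asarray(h0, dtype=float))
    x = Tensor(graph.coords.copy())

    if len(graph.edges):
        recv = np.concatenate([graph.edges[:, 0], graph.edges[:, 1]])
        send = np.concatenate([graph.edges[:, 1], graph.edges[:, 0]])
        a_ij = Tensor(np.tile(graph.edge_distance, 2)[:, None])
        scatter = np.zeros((L, len(recv)))
        scatter[recv, np.arange(len(recv))] = 1.0
        scatter_t = Tensor(scatter)
    else:
        recv = send = None

    for layer in range(params.config.egnn_layers):
        pre = f"egnn{layer}"
        if recv is None:
            m_i = Tensor(np.zeros((L, params.config.d_h)))
        else:
            hi = h.take_rows(recv)
            hj = h.take_rows(send)
            diff = x.take_rows(recv) - x.take_rows(send)
            dist2 = (diff**2).sum(axis=1, keepdims=True)
            e_in = concat([hi, hj, dist2, a_ij], axis=1)
            m_ij = params.linear(f"{pre}.phi_e.1",
                                 params.linear(f"{pre}.phi_e.0", e_in).silu()).silu()
            if L > 1:
                if phi_x_zero:
                    coef = Tensor(np.zeros((len(recv), 1)))
                else:
                    coef = params.linear(
                        f"{pre}.phi_x.1",
                        params.linear(f"{pre}.phi_x.0", m_ij).silu())
                x = x + (scatter_t @ (diff * coef)) * (1.0 / (L - 1))
            m_i = scatter_t @ m_ij
        h = params.linear(f"{pre}.phi_h.1",
                          params.linear(f"{pre}.phi_h.0",
                                        concat([h, m_i], axis=1)).silu())
    return h, x


# ---------------------------------------------------------------------------
# cross-attention
# ---------------------------------------------------------------------------

def _attention(q: Tensor, k: Tensor, v: Tensor, scale_dim: float,
               n_heads: int) -> Tensor:
    d = q.shape[1]
    if d % n_heads:
        raise ConsistencyError(f"branch dim {d} not divisible by {n_heads} heads")
    w = d // n_heads
    outs = []
    for head in range(n_heads):
        qh, kh, vh = (t.cols(head * w, (head + 1) * w) for t in (q, k, v))
        attn = softmax(qh @ kh.T * (1.0 / np.sqrt(scale_dim)), axis=-1)
        outs.append(attn @ vh)
    return outs[0] if n_heads == 1 else concat(outs, axis=1)


def cross_attention_branch(q_feat: Tensor, kv_feat: Tensor, f_text: Tensor,
                     params: ModelParams, branch: str, scale_dim: float) -> Tensor:
    """One cross-attention branch with text conditioning.

    Z = Norm(Q + softmax(Q K^T / sqrt(scale_dim)) V) with K, V projected
    from the key/value stream; O = Norm(Z + FFN(Concat(Z, text))) where the
    text vector is linearly projected to the branch width and broadcast to
    every residue.
    """
    L = q_feat.shape[0]
    if L == 0:
        raise EmptyInputError("zero-length input to cross-attention")
    if kv_feat.shape[0] != L:
        raise ConsistencyError("query and key/value streams differ in length")
    k = params.linear(f"{branch}.WK", kv_feat)
    v = params.linear(f"{branch}.WV", kv_feat)
    att = _attention(q_feat, k, v, scale_dim, params.config.n_heads)
    z = layer_norm(q_feat + att, params[f"{branch}.norm1.g"],
                   params[f"{branch}.norm1.b"])
    text_row = params.linear(f"{branch}.text", f_text.reshape(1, -1))
    text_rows = text_row.take_rows(np.zeros(L, dtype=int))
    ffn_in = concat([z, text_rows], axis=1)
    ffn = params.linear(f"{branch}.ffn.1",
                        params.linear(f"{branch}.ffn.0", ffn_in).gelu())
    return layer_norm(z + ffn, params[f"{branch}.norm2.g"],
                      params[f"{branch}.norm2.b"])


def cross_modal_attention(f_struct: Tensor, f_seq: Tensor, f_text: Tensor,
              params: ModelParams) -> tuple[Tensor, Tensor]:
    """Two symmetric branches: structure queries sequence, and vice versa."""
    cfg = params.config
    if cfg.attn_scale == "as_printed":
        s1, s2 = cfg.d_s, cfg.d_h
    elif cfg.attn_scale == "key_dim":
        s1, s2 = cfg.d_h, cfg.d_s
    else:
        raise ConsistencyError(f"unknown attn_scale {cfg.attn_scale!r}")
    o_struct = cross_attention_branch(f_struct, f_seq, f_text, params, "br1", s1)
    o_seq = cross_attention_branch(f_seq, f_struct, f_text, params, "br2", s2)
    return o_struct, o_seq


def adaptive_fuse(o_struct: Tensor, o_seq: Tensor, f_struct: Tensor, f_seq: Tensor,
             params: ModelParams,
             gate_preactivation: float | None = None) -> tuple[Tensor, Tensor]:
    """Adaptive gated fusion of cross-modal and original features.

    F_fused = Concat(O_seq, O_struct), F_orig = Concat(F_seq, F_struct);
    the gate omega* = sigmoid(MLP(Concat(F_fused, F_orig))) lies in (0, 1)
    and blends them elementwise.  ``gate_preactivation`` forces the
    pre-sigmoid score to a constant (diagnostics only).
    """
    f_fused = concat([o_seq, o_struct], axis=1)
    f_orig = concat([f_seq, f_struct], axis=1)
    if gate_preactivation is None:
        score = params.linear(
            "gate.1", params.linear("gate.0", concat([f_fused, f_orig], axis=1)).gelu())
    else:
        shape = (f_fused.shape[0],
                 params.config.d_final if params.config.per_dim_gate else 1)
        score = Tensor(np.full(shape, float(gate_preactivation)))
    omega = score.sigmoid()
    f_final = f_fused * omega + f_orig * (1.0 - omega)
    return omega, f_final


# ---------------------------------------------------------------------------
# full forward
# ---------------------------------------------------------------------------

def forward(graph: ResidueGraph, h0: np.ndarray, seq_emb: np.ndarray,
            text_emb: np.ndarray, params: ModelParams) -> ForwardOutput:
    """Full forward pass for one protein; probability rows sum to 1."""
    for name, val in (("graph", graph), ("node features", h0),
                      ("sequence embedding", seq_emb), ("text embedding", text_emb)):
        if val is None:
            raise EmptyInputError(f"missing modality: {name}")
    L = graph.n_nodes
    if L > MAX_LEN:
        raise ConsistencyError(f"protein length {L} exceeds maximum {MAX_LEN}")
    seq_emb = np.asarray(seq_emb, dtype=float)
    if seq_emb.shape != (L, params.config.d_s):
        raise ConsistencyError(
            f"sequence embedding shape {seq_emb.shape} != ({L}, {params.config.d_s})")
    text_emb = np.asarray(text_emb, dtype=float).reshape(-1)
    if text_emb.shape[0] != params.config.d_t:
        raise ConsistencyError(
            f"text embedding dim {text_emb.shape[0]} != {params.config.d_t}")

    f_struct, coords_out = egnn_forward(graph, h0, params)
    f_seq = Tensor(seq_emb)
    f_text = Tensor(text_emb)
    o_struct, o_seq = cross_modal_attention(f_struct, f_seq, f_text, params)
    omega, f_final = adaptive_fuse(o_struct, o_seq, f_struct, f_seq, params)
    logits = params.linear("head.1", params.linear("head.0", f_final).gelu())
    return ForwardOutput(f_struct=f_struct, f_seq=f_seq, o_struct=o_struct,
                         o_seq=o_seq, coords_out=coords_out, gate=omega,
                         f_final=f_final, logits=logits)
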