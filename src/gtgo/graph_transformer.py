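"""The PPI branch: node embedding, linear-attention encoder, and an
edge-weighted residual GCN, concatenated into a PPI-based embedding.

Two branches read the same embedded node features H0:

* a single-layer softmax-free global attention (SGA) followed by layer
  norm and an MLP, which propagates information between *any* pair of
  proteins in O(N d^2) time by associating the attention product as
  Q (K^T V) — the N x N attention matrix is never materialized;
* a two-layer GCN over the symmetric-normalized, self-looped, confidence
  weighted adjacency, with the residual added outside the nonlinearity,
  which captures direct-interaction neighborhoods.

Splitting global from local propagation avoids the over-smoothing that
comes from stacking message-passing layers to widen the receptive field.

Each matrix-form operation has a brute-force twin (``sga_dense_oracle``,
``gcn_nodewise_oracle``) that computes the same quantity from first
principles; tests assert their agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

from . import _autodiff as ad
from ._autodiff import Tensor
from .core_data import FeatureMatrix, PPINetwork, ValidationError

__all__ = [
    "EmbeddingMatrix",
    "GraphBranchParameters",
    "NormalizedAdjacency",
    "init_graph_branch_params",
    "embed_nodes",
    "frobenius_normalize",
    "sga_linear",
    "sga_dense_oracle",
    "transformer_encoder",
    "normalize_adjacency",
    "gcn_layer",
    "gcn_nodewise_oracle",
    "gcn_forward",
    "ppi_embedding",
]

EPS_D = 1e-6      # magnitude floor on the attention normalizer diagonal
LN_EPS = 1e-5     # layer-norm variance epsilon


@dataclass
class EmbeddingMatrix:
    """Dense N x k node embedding with a role tag naming its stage."""

    values: np.ndarray
    role: str  # H0 | SGA_out | H_Trans | H_GCN_l | H_PPI

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all():
            raise ValidationError(f"{self.role}: embedding contains non-finite entries")


@dataclass
class GraphBranchParameters:
    """Learnable parameters of the PPI branch (numpy arrays)."""

    W0: np.ndarray            # m x d node-embedding weights
    b0: np.ndarray            # d
    Wq: np.ndarray            # d x d
    bq: np.ndarray
    Wk: np.ndarray
    bk: np.ndarray
    Wv: np.ndarray
    bv: np.ndarray
    ln_scale: np.ndarray      # d
    ln_shift: np.ndarray      # d
    mlp_W1: np.ndarray        # d x d
    mlp_b1: np.ndarray
    mlp_W2: np.ndarray        # d x d
    mlp_b2: np.ndarray
    gcn_weights: list[np.ndarray] = field(default_factory=list)  # L matrices d x d
    activation: str = "relu"  # "relu" | "identity" (test hook)
    encoder_outer_residual: bool = False

    @property
    def d(self) -> int:
        return self.W0.shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_graph_branch_params(
    m: int,
    d: int,
    rng: np.random.Generator,
    n_gcn_layers: int = 2,
    activation: str = "relu",
    encoder_outer_residual: bool = False,
) -> GraphBranchParameters:
    """Seeded uniform Glorot initialization of every branch parameter."""
    zeros = lambda k: np.zeros(k)
    return GraphBranchParameters(
        W0=_glorot(rng, m, d),
        b0=zeros(d),
        Wq=_glorot(rng, d, d),
        bq=zeros(d),
        Wk=_glorot(rng, d, d),
        bk=zeros(d),
        Wv=_glorot(rng, d, d),
        bv=zeros(d),
        ln_scale=np.ones(d),
        ln_shift=zeros(d),
        mlp_W1=_glorot(rng, d, d),
        mlp_b1=zeros(d),
        mlp_W2=_glorot(rng, d, d),
        mlp_b2=zeros(d),
        gcn_weights=[_glorot(rng, d, d) for _ in range(n_gcn_layers)],
        activation=activation,
        encoder_outer_residual=encoder_outer_residual,
    )


def _act(name: str):
    if name == "relu":
        return ad.relu
    if name == "identity":
        return lambda t: t
    raise ValidationError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# tensor-level stages (shared by the public numpy API and the trainer)
# ---------------------------------------------------------------------------


def _embed_nodes_t(X, W0: Tensor, b0: Tensor, act) -> Tensor:
    if sp.issparse(X):
        lin = ad.spmm(X, W0)
    else:
        lin = ad.as_tensor(X) @ W0
    return act(lin + b0)


def _frobenius_normalize_t(M: Tensor) -> Tensor:
    sq = (M * M).sum()
    if sq.value <= 0:
        raise ValidationError("cannot Frobenius-normalize a zero matrix")
    return M / sq.sqrt()


def _sga_t(H0: Tensor, p: dict[str, Tensor]) -> Tensor:
    n = H0.shape[0]
    Q = H0 @ p["Wq"] + p["bq"]
    K = H0 @ p["Wk"] + p["bk"]
    V = H0 @ p["Wv"] + p["bv"]
    Qn = _frobenius_normalize_t(Q)
    Kn = _frobenius_normalize_t(K)
    ksum = Kn.sum(axis=0, keepdims=True)          # K~^T 1_N as a 1 x d row
    dvec = 1.0 + (1.0 / n) * (Qn @ ksum.t())      # N x 1 normalizer diagonal
    if np.abs(dvec.value).min() < EPS_D:
        raise ValidationError("degenerate SGA normalizer: |D_ii| below 1e-6")
    num = V + (1.0 / n) * (Qn @ (Kn.t() @ V))
    return num / dvec + H0


def _layer_norm_t(X: Tensor, scale: Tensor, shift: Tensor) -> Tensor:
    mu = X.mean(axis=1, keepdims=True)
    xc = X - mu
    var = (xc * xc).mean(axis=1, keepdims=True)
    return xc / (var + LN_EPS).sqrt() * scale + shift


def _mlp_t(X: Tensor, p: dict[str, Tensor], act, dropout_mask=None) -> Tensor:
    h = act(X @ p["mlp_W1"] + p["mlp_b1"])
    if dropout_mask is not None:
        h = h * ad.constant(dropout_mask)
    return h @ p["mlp_W2"] + p["mlp_b2"]


def _transformer_encoder_t(
    H0: Tensor, p: dict[str, Tensor], act, outer_residual: bool, dropout_mask=None
) -> Tensor:
    sga = _sga_t(H0, p)
    if outer_residual:
        sga = sga + H0
    return _mlp_t(_layer_norm_t(sga, p["ln_scale"], p["ln_shift"]), p, act, dropout_mask)


def _gcn_layer_t(H: Tensor, A_hat: sp.spmatrix, W: Tensor, act) -> Tensor:
    return H + act(ad.spmm(A_hat, H @ W))


def _gcn_forward_t(H0: Tensor, A_hat: sp.spmatrix, weights: list[Tensor], act) -> Tensor:
    H = H0
    for W in weights:
        H = _gcn_layer_t(H, A_hat, W, act)
    return H


def params_to_tensors(p: GraphBranchParameters, requires_grad: bool = False) -> dict[str, Tensor]:
    names = [
        "W0", "b0", "Wq", "bq", "Wk", "bk", "Wv", "bv",
        "ln_scale", "ln_shift", "mlp_W1", "mlp_b1", "mlp_W2", "mlp_b2",
    ]
    out = {k: Tensor(getattr(p, k), requires_grad=requires_grad) for k in names}
    out["gcn_weights"] = [Tensor(W, requires_grad=requires_grad) for W in p.gcn_weights]
    return out


# ---------------------------------------------------------------------------
# public numpy-facing operations
# ---------------------------------------------------------------------------


def embed_nodes(X: FeatureMatrix | np.ndarray, params: GraphBranchParameters) -> EmbeddingMatrix:
    """Map initial node features to the shared hidden matrix
    H0 = sigma(X W0 + b0)."""
    mat = X.X if isinstance(X, FeatureMatrix) else X
    if mat.shape[1] != params.W0.shape[0]:
        raise ValidationError(
            f"feature dimension {mat.shape[1]} != W0 rows {params.W0.shape[0]}"
        )
    t = params_to_tensors(params)
    out = _embed_nodes_t(mat, t["W0"], t["b0"], _act(params.activation))
    return EmbeddingMatrix(out.value, role="H0")


def frobenius_normalize(M: np.ndarray) -> np.ndarray:
    """Divide a matrix by its Frobenius norm; errors on a zero matrix."""
    M = np.asarray(M, dtype=np.float64)
    norm = np.sqrt((M * M).sum())
    if norm <= 0:
        raise ValidationError("cannot Frobenius-normalize a zero matrix")
    return M / norm


def sga_linear(H0: EmbeddingMatrix | np.ndarray, params: GraphBranchParameters) -> EmbeddingMatrix:
    """Softmax-free global attention in linear time.

    Computes D^{-1} [V + (1/N) Q~ (K~^T V)] + H0 with Frobenius-normalized
    Q~, K~, evaluated strictly as chained N x d / d x d products.
    """
    H = H0.values if isinstance(H0, EmbeddingMatrix) else np.asarray(H0)
    out = _sga_t(Tensor(H), params_to_tensors(params))
    return EmbeddingMatrix(out.value, role="SGA_out")


def sga_dense_oracle(
    H0: EmbeddingMatrix | np.ndarray, params: GraphBranchParameters
) -> EmbeddingMatrix:
    """Reference SGA that materializes the dense N x N score matrix.

    Algebraically identical to :func:`sga_linear`; kept independent as a
    cross-check and guarded to small N.
    """
    H = np.asarray(H0.values if isinstance(H0, EmbeddingMatrix) else H0, dtype=np.float64)
    n = H.shape[0]
    if n > 2048:
        raise ValidationError("dense SGA oracle is guarded to N <= 2048")
    Q = H @ params.Wq + params.bq
    K = H @ params.Wk + params.bk
    V = H @ params.Wv + params.bv
    Qn = frobenius_normalize(Q)
    Kn = frobenius_normalize(K)
    P = (Qn @ Kn.T) / n                      # the full N x N score matrix
    dvec = 1.0 + P.sum(axis=1)
    if np.abs(dvec).min() < EPS_D:
        raise ValidationError("degenerate SGA normalizer: |D_ii| below 1e-6")
    out = (V + P @ V) / dvec[:, None] + H
    return EmbeddingMatrix(out, role="SGA_out")


def transformer_encoder(
    H0: EmbeddingMatrix | np.ndarray, params: GraphBranchParameters
) -> EmbeddingMatrix:
    """Single-layer linear-attention encoder: MLP(LN(SGA(H0))).

    The residual connection lives inside SGA; setting
    ``params.encoder_outer_residual`` adds a second residual before the
    layer norm (an alternative reading of the encoder equation).
    """
    H = H0.values if isinstance(H0, EmbeddingMatrix) else np.asarray(H0)
    out = _transformer_encoder_t(
        Tensor(H),
        params_to_tensors(params),
        _act(params.activation),
        params.encoder_outer_residual,
    )
    return EmbeddingMatrix(out.value, role="H_Trans")


@dataclass
class NormalizedAdjacency:
    """A_hat = D~^{-1/2} (A + I) D~^{-1/2}; every diagonal entry positive."""

    values: sp.csr_matrix


def normalize_adjacency(network: PPINetwork) -> NormalizedAdjacency:
    """Symmetric normalization of the self-looped weighted adjacency."""
    a_tilde = (network.adjacency + sp.identity(network.n, format="csr")).tocsr()
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(inv_sqrt)
    return NormalizedAdjacency(values=(D @ a_tilde @ D).tocsr())


def gcn_layer(
    H: np.ndarray, A_hat: NormalizedAdjacency, W: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One residual GCN layer: H + sigma(A_hat H W)."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[1] != W.shape[0]:
        raise ValidationError(f"hidden dim {H.shape[1]} != W rows {W.shape[0]}")
    out = _gcn_layer_t(Tensor(H), A_hat.values, Tensor(W), _act(activation))
    return out.value


def gcn_nodewise_oracle(
    H: np.ndarray, network: PPINetwork, W: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """Reference GCN layer computed per node from the raw network.

    Explicit loop over N(i) u {i} with confidence weights and weighted
    degrees (self-loop included); must equal
    ``gcn_layer(H, normalize_adjacency(network), W)``.
    """
    if network.n > 512:
        raise ValidationError("nodewise GCN oracle is guarded to N <= 512")
    H = np.asarray(H, dtype=np.float64)
    act = np.vectorize(lambda v: max(v, 0.0)) if activation == "relu" else (lambda v: v)
    A = network.adjacency.toarray()
    deg = A.sum(axis=1) + 1.0  # weighted degree including unit self-loop
    out = np.empty_like(H)
    for i in range(network.n):
        msg = np.zeros(H.shape[1])
        for j in range(network.n):
            w_ij = 1.0 if i == j else A[i, j]
            if w_ij == 0.0:
                continue
            msg += (w_ij / np.sqrt(deg[i] * deg[j])) * (H[j] @ W)
        out[i] = H[i] + np.asarray(act(msg), dtype=np.float64)
    return out


def gcn_forward(
    H0: EmbeddingMatrix | np.ndarray, A_hat: NormalizedAdjacency, params: GraphBranchParameters
) -> EmbeddingMatrix:
    """Stack the configured GCN layers (two by default) over H0."""
    H = H0.values if isinstance(H0, EmbeddingMatrix) else np.asarray(H0)
    t = params_to_tensors(params)
    out = _gcn_forward_t(Tensor(H), A_hat.values, t["gcn_weights"], _act(params.activation))
    return EmbeddingMatrix(out.value, role=f"H_GCN_{len(params.gcn_weights)}")


def ppi_embedding(H_gcn: EmbeddingMatrix, H_trans: EmbeddingMatrix) -> EmbeddingMatrix:
    """Concatenate the local (GCN) and global (encoder) embeddings,
    GCN block first."""
    a, b = H_gcn.values, H_trans.values
    if a.shape[0] != b.shape[0]:
        raise ValidationError("branch outputs disagree on protein count")
    return EmbeddingMatrix(np.concatenate([a, b], axis=1), role="H_PPI")
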