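"""Sequence branch: turn precomputed protein-language-model output into
a d-dimensional sequence-based embedding.

The package never runs a language model.  Its input contract starts at
either per-protein 1024-d vectors or per-protein 1024 x n residue-level
matrices, which are mean-pooled over the residue axis before the
single-layer MLP projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .core_data import ValidationError

__all__ = [
    "SequenceBranchParameters",
    "init_sequence_branch_params",
    "pool_residue_embeddings",
    "sequence_embedding",
]


@dataclass
class SequenceBranchParameters:
    seq_W: np.ndarray  # d x k projection (k = language-model dimension)
    seq_b: np.ndarray  # d
    activation: str = "relu"

    @property
    def d(self) -> int:
        return self.seq_W.shape[0]


def init_sequence_branch_params(
    d: int, in_dim: int, rng: np.random.Generator, activation: str = "relu"
) -> SequenceBranchParameters:
    limit = np.sqrt(6.0 / (d + in_dim))
    return SequenceBranchParameters(
        seq_W=rng.uniform(-limit, limit, size=(d, in_dim)),
        seq_b=np.zeros(d),
        activation=activation,
    )


def pool_residue_embeddings(residue_matrix: np.ndarray) -> np.ndarray:
    """Mean over the residue axis of a k x n residue-level matrix."""
    residue_matrix = np.asarray(residue_matrix, dtype=np.float64)
    if residue_matrix.ndim != 2 or residue_matrix.shape[1] < 1:
        raise ValidationError("residue matrix must be k x n with n >= 1")
    return residue_matrix.mean(axis=1)


def _sequence_embedding_t(E: Tensor, W: Tensor, b: Tensor, act) -> Tensor:
    return act(E @ W.t() + b)


def sequence_embedding(h_seq: np.ndarray, params: SequenceBranchParameters) -> np.ndarray:
    """Project pooled language-model vectors: f(seq_W h + seq_b).

    Accepts a single k-vector or a batch of shape (B, k); the batch form
    applies the map row-wise.
    """
    h = np.asarray(h_seq, dtype=np.float64)
    single = h.ndim == 1
    if single:
        h = h[None, :]
    if h.shape[1] != params.seq_W.shape[1]:
        raise ValidationError(
            f"embedding dimension {h.shape[1]} != seq_W columns {params.seq_W.shape[1]}"
        )
    act = ad.relu if params.activation == "relu" else (lambda t: t)
    out = _sequence_embedding_t(Tensor(h), Tensor(params.seq_W), Tensor(params.seq_b), act).value
    return out[0] if single else out
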