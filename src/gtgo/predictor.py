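"""Fusion, GO-term classifier, BCE loss, and the training protocol.

The final protein embedding concatenates the PPI-based embedding (2d,
from the dual-branch graph transformer) with the sequence-based
embedding (d, from the language-model projection); a single fully
connected layer with logistic squashing scores every GO term.  Training
minimizes mean binary cross-entropy with Adam, shuffled mini-batches of
labeled proteins, and early stopping on validation loss.

Batching semantics: the graph branches always run over the full network
(their receptive field is the whole graph); a batch selects which
labeled proteins contribute to the loss, with gradients flowing through
the shared graph computation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .core_data import (
    AnnotationMatrix,
    DatasetSplit,
    FeatureMatrix,
    PPINetwork,
    PredictionMatrix,
    ProteinCatalog,
    ValidationError,
)
from .graph_transformer import (
    NormalizedAdjacency,
    _act,
    _embed_nodes_t,
    _gcn_forward_t,
    _glorot,
    _transformer_encoder_t,
    normalize_adjacency,
)

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "DataBundle",
    "Model",
    "build_bundle",
    "init_model",
    "fuse",
    "classify",
    "bce_loss",
    "forward",
    "train",
    "save_model",
    "load_model",
    "label_prior_baseline",
    "grid_search",
]

BCE_EPS = 1e-7

# hyperparameter search grids
LR_GRID = (1e-5, 2e-5, 5e-5, 1e-4, 5e-4)
WD_GRID = (1e-5, 1e-6, 0.0)
DROPOUT_GRID = (0.2, 0.3, 0.4, 0.5)


@dataclass
class TrainingConfig:
    batch_size: int = 1024
    hidden_d: int = 1024
    learning_rate: float = 5e-4
    weight_decay: float = 0.0
    dropout: float = 0.2
    max_epochs: int = 1000
    patience: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size, patience and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_losses: list[float] = field(default_factory=list)
    valid_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stop_reason: str = ""  # patience_exhausted | max_epochs

    @property
    def best_valid_loss(self) -> float:
        return self.valid_losses[self.best_epoch - 1]


@dataclass
class DataBundle:
    """All model inputs aligned on one shared catalog."""

    network: PPINetwork
    features: FeatureMatrix
    annotations: AnnotationMatrix
    seq_emb: np.ndarray  # N x k, zero rows for proteins without embeddings
    A_hat: NormalizedAdjacency

    @property
    def catalog(self) -> ProteinCatalog:
        return self.network.catalog


def build_bundle(
    network: PPINetwork,
    features: FeatureMatrix,
    annotations: AnnotationMatrix,
    seq_catalog: ProteinCatalog,
    seq_E: np.ndarray,
):
    """Align all four views on a shared catalog (see core_data.align);
    proteins without a sequence embedding get a zero vector."""
    from .core_data import align

    net, feats, ann, report = align(network, features, annotations)
    E = np.zeros((len(net.catalog), seq_E.shape[1]))
    for pid, row in zip(seq_catalog.ids, seq_E):
        if pid in net.catalog:
            E[net.catalog.index[pid]] = row
    bundle = DataBundle(
        network=net,
        features=feats,
        annotations=ann,
        seq_emb=E,
        A_hat=normalize_adjacency(net),
    )
    return bundle, report


class Model:
    """Trainable parameter set plus architecture configuration.

    ``branches`` selects the classifier input: "both" (3d), "ppi" (2d)
    or "seq" (d) — the single-branch forms are the ablation variants.
    """

    PARAM_NAMES = [
        "W0", "b0", "Wq", "bq", "Wk", "bk", "Wv", "bv",
        "ln_scale", "ln_shift", "mlp_W1", "mlp_b1", "mlp_W2", "mlp_b2",
        "seq_W", "seq_b", "W_out", "b_out",
    ]

    def __init__(self, params: dict[str, Tensor], config: dict):
        self.params = params
        self.config = config

    def parameters(self) -> list[Tensor]:
        out = [self.params[k] for k in self.PARAM_NAMES]
        return out + list(self.params["gcn"])

    def clone_values(self) -> dict:
        state = {k: self.params[k].value.copy() for k in self.PARAM_NAMES}
        state["gcn"] = [w.value.copy() for w in self.params["gcn"]]
        return state

    def load_values(self, state: dict) -> None:
        for k in self.PARAM_NAMES:
            self.params[k].value = state[k].copy()
        for w, v in zip(self.params["gcn"], state["gcn"]):
            w.value = v.copy()


def init_model(
    m: int,
    d: int,
    n_terms: int,
    seq_dim: int = 1024,
    seed: int = 0,
    n_gcn_layers: int = 2,
    activation: str = "relu",
    branches: str = "both",
    encoder_outer_residual: bool = False,
) -> Model:
    if branches not in ("both", "ppi", "seq"):
        raise ValidationError("branches must be both|ppi|seq")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    emb_dim = {"both": 3 * d, "ppi": 2 * d, "seq": d}[branches]
    t = lambda a: Tensor(a, requires_grad=True)
    params = {
        "W0": t(_glorot(rng, m, d)),
        "b0": t(np.zeros(d)),
        "Wq": t(_glorot(rng, d, d)),
        "bq": t(np.zeros(d)),
        "Wk": t(_glorot(rng, d, d)),
        "bk": t(np.zeros(d)),
        "Wv": t(_glorot(rng, d, d)),
        "bv": t(np.zeros(d)),
        "ln_scale": t(np.ones(d)),
        "ln_shift": t(np.zeros(d)),
        "mlp_W1": t(_glorot(rng, d, d)),
        "mlp_b1": t(np.zeros(d)),
        "mlp_W2": t(_glorot(rng, d, d)),
        "mlp_b2": t(np.zeros(d)),
        "seq_W": t(np.ascontiguousarray(_glorot(rng, seq_dim, d).T)),  # d x seq_dim
        "seq_b": t(np.zeros(d)),
        "W_out": t(np.ascontiguousarray(_glorot(rng, emb_dim, n_terms).T)),  # M x emb_dim
        "b_out": t(np.zeros(n_terms)),
        "gcn": [t(_glorot(rng, d, d)) for _ in range(n_gcn_layers)],
    }
    config = {
        "m": m,
        "d": d,
        "n_terms": n_terms,
        "seq_dim": seq_dim,
        "n_gcn_layers": n_gcn_layers,
        "activation": activation,
        "branches": branches,
        "encoder_outer_residual": encoder_outer_residual,
        "seed": int(seed),
    }
    return Model(params, config)


# ---------------------------------------------------------------------------
# functional pieces
# ---------------------------------------------------------------------------


def fuse(emb_ppi: np.ndarray, emb_seq: np.ndarray) -> np.ndarray:
    """Concatenate PPI-based and sequence-based embeddings, PPI first."""
    a = np.atleast_2d(np.asarray(emb_ppi, dtype=np.float64))
    b = np.atleast_2d(np.asarray(emb_seq, dtype=np.float64))
    if a.shape[0] != b.shape[0]:
        raise ValidationError("row count mismatch between PPI and sequence embeddings")
    out = np.concatenate([a, b], axis=1)
    return out[0] if np.asarray(emb_ppi).ndim == 1 else out


def classify(emb: np.ndarray, W_out: np.ndarray, b_out: np.ndarray) -> np.ndarray:
    """Fully connected GO-term classifier with logistic squashing."""
    emb = np.atleast_2d(np.asarray(emb, dtype=np.float64))
    if emb.shape[1] != W_out.shape[1]:
        raise ValidationError(f"embedding dim {emb.shape[1]} != classifier {W_out.shape[1]}")
    logits = emb @ W_out.T + b_out
    scores = 1.0 / (1.0 + np.exp(-logits))
    return scores[0] if np.asarray(emb).ndim == 1 else scores


def bce_loss(Y: np.ndarray, S: np.ndarray) -> float:
    """Mean binary cross-entropy over all B x M cells; scores are
    clipped to [1e-7, 1 - 1e-7] before the logs."""
    Y = np.asarray(Y, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if Y.shape != S.shape:
        raise ValidationError("label/score shape mismatch")
    if not (np.isfinite(Y).all() and np.isfinite(S).all()):
        raise ValidationError("non-finite input to bce_loss")
    S = np.clip(S, BCE_EPS, 1.0 - BCE_EPS)
    return float(-(Y * np.log(S) + (1 - Y) * np.log(1 - S)).mean())


def _bce_loss_t(Y: np.ndarray, S: Tensor) -> Tensor:
    Sc = S.clip(BCE_EPS, 1.0 - BCE_EPS)
    Yt = ad.constant(np.asarray(Y, dtype=np.float64))
    return -(Yt * Sc.log() + (1.0 - Yt) * (1.0 - Sc).log()).mean()


def _forward_scores_t(
    model: Model,
    bundle: DataBundle,
    rows: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full-graph branch computation, scores for the requested rows."""
    p = model.params
    cfg = model.config
    act = _act(cfg["activation"])
    branches = cfg["branches"]
    training = dropout > 0.0 and rng is not None

    def mask(shape):
        return (rng.random(shape) >= dropout) / (1.0 - dropout)

    blocks: list[Tensor] = []
    if branches in ("both", "ppi"):
        H0 = _embed_nodes_t(bundle.features.X, p["W0"], p["b0"], act)
        if training:
            H0 = H0 * ad.constant(mask(H0.shape))
        H_gcn = _gcn_forward_t(H0, bundle.A_hat.values, p["gcn"], act)
        mlp_mask = mask((H0.shape[0], cfg["d"])) if training else None
        H_trans = _transformer_encoder_t(
            H0, p, act, cfg["encoder_outer_residual"], dropout_mask=mlp_mask
        )
        blocks += [H_gcn.take_rows(rows), H_trans.take_rows(rows)]
    if branches in ("both", "seq"):
        E = ad.constant(bundle.seq_emb[rows])
        blocks.append(act(E @ p["seq_W"].t() + p["seq_b"]))
    emb = ad.concat(blocks, axis=1) if len(blocks) > 1 else blocks[0]
    logits = emb @ p["W_out"].t() + p["b_out"]
    return logits.sigmoid()


def forward(model: Model, bundle: DataBundle, ids) -> PredictionMatrix:
    """Predict GO-term scores for the requested proteins (dropout off)."""
    rows = bundle.catalog.rows(ids)
    scores = _forward_scores_t(model, bundle, rows).value
    pred = PredictionMatrix(
        catalog=ProteinCatalog.from_ids(ids),
        terms=bundle.annotations.terms,
        S=scores,
    )
    pred.validate()
    return pred


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            if self.wd:
                g = g + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train(
    bundle: DataBundle,
    split: DatasetSplit,
    cfg: TrainingConfig,
    model: Model | None = None,
) -> tuple[Model, TrainingHistory]:
    """Adam training with early stopping on validation loss.

    The split should already have passed
    :func:`core_data.restrict_training_to_network`.  Each epoch shuffles
    the training proteins into batches of ``cfg.batch_size``; validation
    loss is computed once per epoch with dropout off.  Training stops
    when validation loss has not strictly improved for ``cfg.patience``
    consecutive epochs (equal loss counts as no improvement) or at
    ``cfg.max_epochs``; the best-epoch parameters are restored.

    When the valid list is empty the training loss is monitored instead
    (useful for deliberate-overfit fixtures).
    """
    cfg.validate()
    if not split.train:
        raise ValidationError("empty training split")
    catalog = bundle.catalog
    train_idx = catalog.rows(split.train)
    valid_idx = catalog.rows(split.valid) if split.valid else np.array([], dtype=np.intp)
    Y = bundle.annotations.Y.astype(np.float64)

    if model is None:
        model = init_model(
            m=bundle.features.m,
            d=cfg.hidden_d,
            n_terms=len(bundle.annotations.terms),
            seq_dim=bundle.seq_emb.shape[1],
            seed=cfg.seed,
        )
    params = model.parameters()
    opt = _Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 21]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 22]))

    history = TrainingHistory()
    best_loss = np.inf
    best_state = model.clone_values()
    best_epoch = 0
    bad_epochs = 0
    stop_reason = "max_epochs"

    for epoch in range(1, cfg.max_epochs + 1):
        perm = shuffle_rng.permutation(len(train_idx))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            batch = train_idx[perm[start : start + cfg.batch_size]]
            opt.zero_grad()
            scores = _forward_scores_t(model, bundle, batch, cfg.dropout, dropout_rng)
            loss = _bce_loss_t(Y[batch], scores)
            if not np.isfinite(loss.value):
                raise ValidationError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value) * len(batch)
            n_seen += len(batch)
        history.train_losses.append(epoch_loss / n_seen)

        if len(valid_idx):
            vscores = _forward_scores_t(model, bundle, valid_idx)
            monitored = float(_bce_loss_t(Y[valid_idx], vscores).value)
        else:
            monitored = history.train_losses[-1]
        history.valid_losses.append(monitored)

        if monitored < best_loss:
            best_loss = monitored
            best_state = model.clone_values()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                stop_reason = "patience_exhausted"
                break

    model.load_values(best_state)
    history.best_epoch = best_epoch
    history.stop_reason = stop_reason
    return model, history


# ---------------------------------------------------------------------------
# persistence, baseline, search
# ---------------------------------------------------------------------------


def save_model(model: Model, path) -> None:
    """Serialize all parameters plus config; round-trip is bitwise."""
    arrays = {k: model.params[k].value for k in Model.PARAM_NAMES}
    for i, w in enumerate(model.params["gcn"]):
        arrays[f"gcn_{i}"] = w.value
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> Model:
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"].tobytes()).decode())
        t = lambda a: Tensor(a.copy(), requires_grad=True)
        params = {k: t(data[k]) for k in Model.PARAM_NAMES}
        params["gcn"] = [t(data[f"gcn_{i}"]) for i in range(config["n_gcn_layers"])]
    return Model(params, config)


def label_prior_baseline(Y_train: np.ndarray, n_proteins: int) -> np.ndarray:
    """Frequency baseline: score every protein with each term's training
    prevalence.  The margin over this baseline measures how much signal
    the model actually extracts."""
    prior = np.asarray(Y_train, dtype=np.float64).mean(axis=0)
    return np.tile(prior, (n_proteins, 1))


def grid_search(
    bundle: DataBundle,
    split: DatasetSplit,
    base: TrainingConfig,
    lr_grid=LR_GRID,
    wd_grid=WD_GRID,
):
    """Deterministic local sweep over the learning-rate / weight-decay
    grids, selecting the configuration with the lowest validation loss."""
    results = []
    best = None
    for lr in lr_grid:
        for wd in wd_grid:
            cfg = dataclasses.replace(base, learning_rate=lr, weight_decay=wd)
            model, hist = train(bundle, split, cfg)
            results.append((lr, wd, hist.best_valid_loss))
            if best is None or hist.best_valid_loss < best[2]:
                best = (lr, wd, hist.best_valid_loss, model, cfg)
    return best, results
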