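"""Seeded generator of desk-scale benchmark datasets.

Real PPI benchmarks couple four data views through shared functional
modules: proteins in the same module interact more often, share domain
signatures, carry overlapping GO annotations, and have similar
sequences.  The generator reproduces exactly that coupling with a
planted-partition network, module-owned sparse binary features,
module-driven multi-label annotations, and module-separated Gaussian
sequence embeddings — one knob per view controls how much signal that
view carries.

All generators are pure functions of ``(cfg, seed)``: each draws from
its own independent substream fanned out from the global seed, so
repeated calls are bitwise identical and changing one view's draw does
not perturb the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse as sp

from .core_data import (
    AnnotationMatrix,
    DatasetSplit,
    FeatureMatrix,
    PPINetwork,
    ProteinCatalog,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "simulate_network",
    "simulate_features",
    "simulate_annotations",
    "simulate_sequence_embeddings",
    "simulate_dataset",
    "make_split",
]

# fixed substream tags so each generator owns an independent RNG stream
_STREAM_NETWORK = 1
_STREAM_FEATURES = 2
_STREAM_LABELS = 3
_STREAM_EMBEDDINGS = 4
_STREAM_SPLIT = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give four well-separated functional modules of 25 proteins
    each — large enough that both graph branches and the sequence branch
    are informative, small enough for second-scale training.
    """

    n_modules: int = 4
    proteins_per_module: int = 25
    p_in: float = 0.5
    p_out: float = 0.05
    weight_low: float = 0.4
    weight_high: float = 0.95
    m_features: int = 40
    features_per_module: int = 10
    feature_on_prob: float = 0.8
    feature_noise_prob: float = 0.02
    n_terms: int = 20
    terms_per_module: int = 5
    label_flip_prob: float = 0.0
    emb_dim: int = 1024
    emb_separation: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1 or self.proteins_per_module < 2:
            raise ValidationError("need >= 1 module of >= 2 proteins")
        if not (0 < self.weight_low <= self.weight_high <= 1):
            raise ValidationError("weight range must satisfy 0 < low <= high <= 1")
        if self.p_in < self.p_out:
            warnings.warn("p_in < p_out: modules will be anti-assortative")
        if self.n_modules * self.terms_per_module > self.n_terms:
            raise ValidationError("n_terms too small for terms_per_module per module")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _protein_ids(cfg: SimulationConfig) -> list[str]:
    n = cfg.n_modules * cfg.proteins_per_module
    return [f"P{i:04d}" for i in range(n)]


def _module_vector(cfg: SimulationConfig) -> np.ndarray:
    return np.repeat(np.arange(cfg.n_modules), cfg.proteins_per_module)


def simulate_network(cfg: SimulationConfig) -> tuple[PPINetwork, dict[str, int]]:
    """Planted-partition weighted network.

    Each unordered pair gets an edge with probability ``p_in`` (same
    module) or ``p_out`` (different modules); confidences are uniform on
    ``[weight_low, weight_high]``.  Isolated proteins are permitted, as
    in real STRING subgraphs.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_NETWORK)
    ids = _protein_ids(cfg)
    mods = _module_vector(cfg)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    p_edge = np.where(mods[iu] == mods[ju], cfg.p_in, cfg.p_out)
    present = rng.random(len(iu)) < p_edge
    weights = rng.uniform(cfg.weight_low, cfg.weight_high, size=len(iu))
    ii, jj, ww = iu[present], ju[present], weights[present]
    adj = sp.coo_matrix(
        (np.concatenate([ww, ww]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n, n),
    ).tocsr()
    net = PPINetwork(catalog=ProteinCatalog.from_ids(ids), adjacency=adj)
    net.validate()
    return net, {pid: int(m) for pid, m in zip(ids, mods)}


def simulate_features(assignment: dict[str, int], cfg: SimulationConfig) -> FeatureMatrix:
    """Module-owned sparse binary features.

    Module k owns the feature block ``[k*fpm, (k+1)*fpm)``; members turn
    each owned feature on with ``feature_on_prob`` and every feature
    also flips on with ``feature_noise_prob`` for non-members.
    """
    cfg.validate()
    if cfg.m_features < cfg.n_modules * cfg.features_per_module:
        raise ValidationError("m_features < n_modules * features_per_module")
    rng = _rng(cfg, _STREAM_FEATURES)
    ids = list(assignment)
    mods = np.array([assignment[p] for p in ids])
    n, m, fpm = len(ids), cfg.m_features, cfg.features_per_module
    owned = np.zeros((n, m), dtype=bool)
    for k in range(cfg.n_modules):
        owned[np.ix_(mods == k, range(k * fpm, (k + 1) * fpm))] = True
    on = np.where(owned, rng.random((n, m)) < cfg.feature_on_prob, False)
    noise = ~owned & (rng.random((n, m)) < cfg.feature_noise_prob)
    X = sp.csr_matrix((on | noise).astype(np.float64))
    fm = FeatureMatrix(catalog=ProteinCatalog.from_ids(ids), X=X)
    fm.validate()
    return fm


def simulate_annotations(assignment: dict[str, int], cfg: SimulationConfig) -> AnnotationMatrix:
    """Module-driven multi-label annotations with label noise.

    Module k's members are positive for its ``terms_per_module`` owned
    terms; every cell then flips independently with ``label_flip_prob``.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_LABELS)
    ids = list(assignment)
    mods = np.array([assignment[p] for p in ids])
    tpm = cfg.terms_per_module
    Y = np.zeros((len(ids), cfg.n_terms), dtype=np.uint8)
    for k in range(cfg.n_modules):
        Y[np.ix_(mods == k, range(k * tpm, (k + 1) * tpm))] = 1
    flips = rng.random(Y.shape) < cfg.label_flip_prob
    Y = np.where(flips, 1 - Y, Y).astype(np.uint8)
    terms = tuple(f"GO:{j:07d}" for j in range(cfg.n_terms))
    ann = AnnotationMatrix(
        catalog=ProteinCatalog.from_ids(ids), terms=terms, Y=Y, domain_tag="MFO"
    )
    ann.validate()
    return ann


def simulate_sequence_embeddings(
    assignment: dict[str, int], cfg: SimulationConfig
) -> tuple[ProteinCatalog, np.ndarray]:
    """Module-separated Gaussian sequence embeddings.

    A protein in module k is drawn from Normal(mu_k, I) with
    ``mu_k = emb_separation * e_k`` on the first ``n_modules`` axes, so
    centroid distances are ``emb_separation * sqrt(2)`` for all pairs.
    """
    cfg.validate()
    if cfg.emb_dim < cfg.n_modules:
        raise ValidationError("emb_dim must be >= n_modules for orthogonal means")
    rng = _rng(cfg, _STREAM_EMBEDDINGS)
    ids = list(assignment)
    mods = np.array([assignment[p] for p in ids])
    E = rng.standard_normal((len(ids), cfg.emb_dim))
    E[np.arange(len(ids)), mods] += cfg.emb_separation
    return ProteinCatalog.from_ids(ids), E


def make_split(
    catalog: ProteinCatalog,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    assignment: dict[str, int] | None = None,
) -> DatasetSplit:
    """Random train/valid/test partition, stratified by module when an
    assignment is given; fractions honored to +-1 protein per stratum."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_SPLIT]))
    if assignment is None:
        strata = [list(catalog.ids)]
    else:
        mods = sorted(set(assignment.values()))
        strata = [[p for p in catalog.ids if assignment[p] == k] for k in mods]
    train: list[str] = []
    valid: list[str] = []
    test: list[str] = []
    for stratum in strata:
        ids = list(stratum)
        rng.shuffle(ids)
        n = len(ids)
        n_train = int(round(fractions[0] * n))
        n_valid = int(round(fractions[1] * n))
        n_valid = min(n_valid, n - n_train)
        train += ids[:n_train]
        valid += ids[n_train : n_train + n_valid]
        test += ids[n_train + n_valid :]
    split = DatasetSplit(train=train, valid=valid, test=test)
    split.validate()
    return split


def simulate_dataset(cfg: SimulationConfig):
    """Generate the full coupled fixture set.

    Returns ``(network, features, annotations, (emb_catalog, E), split,
    assignment)`` — every view aligned on the same protein catalog.
    """
    net, assignment = simulate_network(cfg)
    feats = simulate_features(assignment, cfg)
    ann = simulate_annotations(assignment, cfg)
    emb = simulate_sequence_embeddings(assignment, cfg)
    split = make_split(net.catalog, seed=cfg.seed, assignment=assignment)
    return net, feats, ann, emb, split, assignment
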