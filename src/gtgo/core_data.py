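"""Data model and IO for PPI networks, node features, GO annotations,
splits and prediction matrices.

The on-disk formats are deliberately plain: whitespace-delimited edge
lists in the STRING detailed-links dialect, two-column GAF-like
annotation tables, triplet or dense TSV feature matrices, TSV or HDF5
sequence-embedding containers, and one-id-per-line split files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse as sp

__all__ = [
    "ProteinCatalog",
    "PPINetwork",
    "FeatureMatrix",
    "AnnotationMatrix",
    "DatasetSplit",
    "PredictionMatrix",
    "AlignmentReport",
    "load_network",
    "load_annotations",
    "load_features",
    "load_split",
    "load_embeddings_tsv",
    "save_embeddings_tsv",
    "load_embeddings_h5",
    "save_embeddings_h5",
    "align",
    "restrict_training_to_network",
    "write_predictions",
    "read_predictions",
]


class ValidationError(ValueError):
    """Input violates a documented contract."""


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinCatalog:
    """Ordered set of unique protein accessions with 0-based row lookup."""

    ids: tuple[str, ...]
    index: dict[str, int] = field(compare=False)

    @classmethod
    def from_ids(cls, ids) -> "ProteinCatalog":
        ids = tuple(ids)
        if len(ids) == 0:
            raise ValidationError("catalog must contain at least one protein")
        index = {p: i for i, p in enumerate(ids)}
        if len(index) != len(ids):
            raise ValidationError("duplicate protein ids in catalog")
        return cls(ids=ids, index=index)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self.index

    def rows(self, ids) -> np.ndarray:
        missing = [p for p in ids if p not in self.index]
        if missing:
            raise KeyError(f"proteins not in catalog: {missing[:10]}")
        return np.array([self.index[p] for p in ids], dtype=np.intp)


@dataclass
class PPINetwork:
    """Sparse symmetric weighted adjacency; a_ij is interaction confidence."""

    catalog: ProteinCatalog
    adjacency: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.catalog)

    def validate(self) -> None:
        a = self.adjacency
        if a.shape != (self.n, self.n):
            raise ValidationError("adjacency shape does not match catalog")
        if abs(a - a.T).max() > 0:
            raise ValidationError("adjacency is not symmetric")
        if a.diagonal().any():
            raise ValidationError("adjacency has self-loops")
        if a.nnz and (a.data <= 0).any() or a.nnz and (a.data > 1).any():
            raise ValidationError("stored confidences must lie in (0, 1]")


@dataclass
class FeatureMatrix:
    """N x m sparse nonnegative initial node features (InterPro-style)."""

    catalog: ProteinCatalog
    X: sp.csr_matrix

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        if self.X.shape[0] != len(self.catalog):
            raise ValidationError("feature row count does not match catalog")
        if self.X.nnz and ((self.X.data < 0).any() or not np.isfinite(self.X.data).all()):
            raise ValidationError("features must be finite and nonnegative")


@dataclass
class AnnotationMatrix:
    """Binary protein x GO-term labels for one ontology domain."""

    catalog: ProteinCatalog
    terms: tuple[str, ...]
    Y: np.ndarray  # uint8, N x M
    domain_tag: str = "MFO"

    def validate(self) -> None:
        if self.Y.shape != (len(self.catalog), len(self.terms)):
            raise ValidationError("annotation matrix shape mismatch")
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("duplicate GO terms")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValidationError("annotations must be binary")


@dataclass
class DatasetSplit:
    train: list[str]
    valid: list[str]
    test: list[str]
    test_subset_tags: dict[str, str] | None = None

    def validate(self) -> None:
        tr, va, te = set(self.train), set(self.valid), set(self.test)
        if tr & va or tr & te or va & te:
            raise ValidationError("split lists must be pairwise disjoint")


@dataclass
class PredictionMatrix:
    """Scores in [0, 1] for (protein, GO term) pairs."""

    catalog: ProteinCatalog
    terms: tuple[str, ...]
    S: np.ndarray  # float64, N x M

    def validate(self) -> None:
        if self.S.shape != (len(self.catalog), len(self.terms)):
            raise ValidationError("prediction matrix shape mismatch")
        if not np.isfinite(self.S).all():
            raise ValidationError("scores must be finite")
        if (self.S < 0).any() or (self.S > 1).any():
            raise ValidationError("scores must lie in [0, 1]")


@dataclass
class AlignmentReport:
    n_union: int
    n_isolated: int          # proteins absent from the network
    n_zero_feature_rows: int  # proteins absent from the feature table
    n_unannotated: int       # proteins absent from the annotation table


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def load_network(path, min_confidence: float = 0.0) -> PPINetwork:
    """Read a STRING-style edge list into a symmetric weighted network.

    Columns are (id_a, id_b, weight), whitespace-delimited; extra middle
    columns are tolerated (first, second and last fields are used).  Any
    weight above 1 switches interpretation of the whole file to the
    0-1000 STRING integer scale.  Duplicate and reversed edges collapse
    to the maximum confidence; self-edges and edges below
    ``min_confidence`` are dropped.
    """
    ids: list[str] = []
    seen: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}
    weights_raw: list[float] = []
    rows = []
    header_skipped = False
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
        a, b, w_str = parts[0], parts[1], parts[-1]
        try:
            w = float(w_str)
        except ValueError:
            if not header_skipped and lineno == 1:
                header_skipped = True
                continue
            raise ParseError(f"{path}: line {lineno}: non-numeric weight {w_str!r}")
        if w < 0 or w > 1000:
            raise ValidationError(f"{path}: line {lineno}: weight {w} outside [0, 1000]")
        for p in (a, b):
            if p not in seen:
                seen[p] = len(ids)
                ids.append(p)
        rows.append((seen[a], seen[b], w))
        weights_raw.append(w)
    if not ids:
        raise ValidationError(f"{path}: no edges found")
    scale = 1000.0 if any(w > 1 for w in weights_raw) else 1.0
    for ia, ib, w in rows:
        if ia == ib:
            continue
        w /= scale
        if w < min_confidence or w == 0:
            continue
        key = (min(ia, ib), max(ia, ib))
        edges[key] = max(edges.get(key, 0.0), w)
    catalog = ProteinCatalog.from_ids(ids)
    n = len(catalog)
    if edges:
        ii, jj = zip(*edges.keys())
        ww = list(edges.values())
        adj = sp.coo_matrix((ww + ww, (ii + jj, jj + ii)), shape=(n, n)).tocsr()
    else:
        adj = sp.csr_matrix((n, n))
    net = PPINetwork(catalog=catalog, adjacency=adj)
    net.validate()
    return net


def load_annotations(path, domain_tag: str = "MFO") -> AnnotationMatrix:
    """Read a two-column (protein, GO term) table into a binary matrix.

    Proteins and terms are ordered by first appearance; repeated pairs
    are idempotent.
    """
    prot_ids: list[str] = []
    prot_seen: dict[str, int] = {}
    terms: list[str] = []
    term_seen: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        p, t = parts[0], parts[1]
        if p not in prot_seen:
            prot_seen[p] = len(prot_ids)
            prot_ids.append(p)
        if t not in term_seen:
            term_seen[t] = len(terms)
            terms.append(t)
        pairs.add((prot_seen[p], term_seen[t]))
    if not pairs:
        raise ValidationError(f"{path}: empty annotation table")
    Y = np.zeros((len(prot_ids), len(terms)), dtype=np.uint8)
    for i, j in pairs:
        Y[i, j] = 1
    ann = AnnotationMatrix(
        catalog=ProteinCatalog.from_ids(prot_ids),
        terms=tuple(terms),
        Y=Y,
        domain_tag=domain_tag,
    )
    ann.validate()
    return ann


def load_features(path) -> FeatureMatrix:
    """Read node features from triplet TSV (protein, index, value) or a
    dense TSV whose header row names the feature columns."""
    with open(path) as fh:
        first = fh.readline().strip()
    dense = False
    parts = first.split()
    if parts and parts[0].lower() in ("protein", "id"):
        dense = True
    if dense:
        ids, rows = [], []
        with open(path) as fh:
            header = fh.readline().split()
            m = len(header) - 1
            for lineno, raw in enumerate(fh, start=2):
                line = raw.strip()
                if not line:
                    continue
                p = line.split()
                if len(p) != m + 1:
                    raise ParseError(f"{path}: line {lineno}: expected {m + 1} columns")
                ids.append(p[0])
                rows.append([float(v) for v in p[1:]])
        X = sp.csr_matrix(np.asarray(rows))
    else:
        ids, seen = [], {}
        triples = []
        m = 0
        for lineno, line in _data_lines(path):
            p = line.split()
            if len(p) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            pid, j, v = p[0], int(p[1]), float(p[2])
            if pid not in seen:
                seen[pid] = len(ids)
                ids.append(pid)
            m = max(m, j + 1)
            triples.append((seen[pid], j, v))
        ii, jj, vv = zip(*triples)
        X = sp.coo_matrix((vv, (ii, jj)), shape=(len(ids), m)).tocsr()
    fm = FeatureMatrix(catalog=ProteinCatalog.from_ids(ids), X=X)
    fm.validate()
    return fm


def load_split(train_path, valid_path, test_path) -> DatasetSplit:
    """Read one-id-per-line split files; the test file may carry a second
    column with a STRING/HOMO/NONE subset tag."""

    def read_ids(path):
        return [line.split()[0] for _, line in _data_lines(path)]

    tags: dict[str, str] = {}
    test_ids = []
    for _, line in _data_lines(test_path):
        parts = line.split()
        test_ids.append(parts[0])
        if len(parts) > 1:
            tags[parts[0]] = parts[1]
    split = DatasetSplit(
        train=read_ids(train_path),
        valid=read_ids(valid_path),
        test=test_ids,
        test_subset_tags=tags or None,
    )
    split.validate()
    return split


def save_embeddings_tsv(path, catalog: ProteinCatalog, E: np.ndarray) -> None:
    with open(path, "w") as fh:
        for pid, row in zip(catalog.ids, E):
            fh.write(pid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def load_embeddings_tsv(path) -> tuple[ProteinCatalog, np.ndarray]:
    ids, rows = [], []
    dim = None
    for lineno, line in _data_lines(path):
        parts = line.split()
        ids.append(parts[0])
        vec = [float(v) for v in parts[1:]]
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise ParseError(f"{path}: line {lineno}: inconsistent embedding dimension")
        rows.append(vec)
    if not ids:
        raise ValidationError(f"{path}: empty embedding table")
    return ProteinCatalog.from_ids(ids), np.asarray(rows, dtype=np.float64)


def save_embeddings_h5(path, catalog: ProteinCatalog, E: np.ndarray) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for pid, row in zip(catalog.ids, E):
            fh[pid] = np.asarray(row, dtype=np.float64)


def load_embeddings_h5(path) -> tuple[ProteinCatalog, np.ndarray]:
    import h5py

    with h5py.File(path, "r") as fh:
        ids = list(fh.keys())
        E = np.stack([fh[pid][()] for pid in ids])
    return ProteinCatalog.from_ids(ids), E


# ---------------------------------------------------------------------------
# catalog alignment and the training-set restriction rule
# ---------------------------------------------------------------------------


def align(
    network: PPINetwork,
    features: FeatureMatrix,
    annotations: AnnotationMatrix,
) -> tuple[PPINetwork, FeatureMatrix, AnnotationMatrix, AlignmentReport]:
    """Re-index network, features and annotations onto one shared catalog.

    The shared catalog is the union of all ids, network first-appearance
    order first.  Proteins missing from the feature table get all-zero
    feature rows; proteins missing from the network become isolated
    nodes; proteins missing annotations get all-zero label rows.
    """
    ids = list(network.catalog.ids)
    seen = set(ids)
    for extra in (features.catalog.ids, annotations.catalog.ids):
        for p in extra:
            if p not in seen:
                seen.add(p)
                ids.append(p)
    catalog = ProteinCatalog.from_ids(ids)
    n = len(catalog)

    adj = sp.lil_matrix((n, n))
    adj[: network.n, : network.n] = network.adjacency
    net_out = PPINetwork(catalog=catalog, adjacency=adj.tocsr())

    X = sp.lil_matrix((n, features.m))
    feat_rows = [catalog.index[p] for p in features.catalog.ids]
    X[feat_rows, :] = features.X
    feat_out = FeatureMatrix(catalog=catalog, X=X.tocsr())

    Y = np.zeros((n, len(annotations.terms)), dtype=np.uint8)
    ann_rows = [catalog.index[p] for p in annotations.catalog.ids]
    Y[ann_rows, :] = annotations.Y
    ann_out = AnnotationMatrix(
        catalog=catalog, terms=annotations.terms, Y=Y, domain_tag=annotations.domain_tag
    )

    report = AlignmentReport(
        n_union=n,
        n_isolated=n - network.n,
        n_zero_feature_rows=n - len(features.catalog),
        n_unannotated=n - len(annotations.catalog),
    )
    return net_out, feat_out, ann_out, report


def restrict_training_to_network(split: DatasetSplit, network: PPINetwork) -> DatasetSplit:
    """Keep only training proteins resident in the PPI network.

    The model is network-based: proteins outside the network contribute
    no graph signal, so they are excluded from the training loss.  Valid
    and test lists are left untouched.
    """
    train = [p for p in split.train if p in network.catalog]
    if not train:
        raise ValidationError("no training proteins remain after network restriction")
    return dataclasses.replace(split, train=train)


# ---------------------------------------------------------------------------
# prediction round-trip
# ---------------------------------------------------------------------------


def write_predictions(pred: PredictionMatrix, path) -> None:
    """Write a prediction matrix as a sparse three-column TSV.

    Catalog and term order are preserved in commented header lines so
    that all-zero rows/columns survive the round trip; zero scores are
    omitted from the body.
    """
    pred.validate()
    with open(path, "w") as fh:
        fh.write("## proteins\t" + "\t".join(pred.catalog.ids) + "\n")
        fh.write("## terms\t" + "\t".join(pred.terms) + "\n")
        for i, pid in enumerate(pred.catalog.ids):
            for j, term in enumerate(pred.terms):
                s = pred.S[i, j]
                if s != 0.0:
                    fh.write(f"{pid}\t{term}\t{s:.6g}\n")


def read_predictions(path) -> PredictionMatrix:
    ids: list[str] | None = None
    terms: list[str] | None = None
    entries = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("## proteins\t"):
                ids = line.split("\t")[1:]
                continue
            if line.startswith("## terms\t"):
                terms = line.split("\t")[1:]
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            entries.append((parts[0], parts[1], float(parts[2])))
    if ids is None or terms is None:
        raise ParseError(f"{path}: missing catalog/term header lines")
    catalog = ProteinCatalog.from_ids(ids)
    tindex = {t: j for j, t in enumerate(terms)}
    S = np.zeros((len(ids), len(terms)))
    for pid, term, s in entries:
        S[catalog.index[pid], tindex[term]] = s
    pred = PredictionMatrix(catalog=catalog, terms=tuple(terms), S=S)
    pred.validate()
    return pred
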