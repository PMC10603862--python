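"""Concrete microservice callables that initialize the environment.

Each function here backs a registered descriptor (see :mod:`semflow.builtin`)
and follows one calling convention::

    svc(payload, *, seed=0, params=None) -> payload'

Payloads are small typed containers; the classifier/optimizer artifacts
carry their train/test split along so downstream stages can re-run
cross-validation without re-reading data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


class ServiceError(ValueError):
    pass


class ServiceUnavailable(ServiceError):
    """Raised by descriptor-only services whose model is not shipped."""


def _params(params: Optional[Mapping]) -> dict:
    return dict(params) if params else {}


# ---------------------------------------------------------------------------
# Payload containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledTable:
    frame: pd.DataFrame
    label: str = "target"

    def __post_init__(self) -> None:
        if self.label not in self.frame.columns:
            raise ServiceError(f"label column {self.label!r} missing")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != self.label)

    @property
    def n_classes(self) -> int:
        return self.frame[self.label].nunique()


@dataclass
class SplitData:
    train: pd.DataFrame
    test: pd.DataFrame
    label: str
    ratio: float
    seed: int

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.train.columns if c != self.label)


@dataclass
class ClassificationModel:
    pipeline: Pipeline
    feature_names: tuple[str, ...]
    split: SplitData
    accuracy: float

    @property
    def metrics(self) -> dict:
        return {"accuracy": float(self.accuracy)}

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(frame[list(self.feature_names)])

    def importances(self) -> np.ndarray:
        """Absolute standardized coefficients (scaler inside the pipeline)."""
        return np.abs(self.pipeline.named_steps["clf"].coef_.ravel())


@dataclass
class OptimizedModel:
    pipeline: Pipeline
    selected_features: tuple[str, ...]
    cv_curve: tuple[tuple[int, float], ...]  # (n_features, mean CV accuracy)
    accuracy: float
    split: SplitData
    via_feature_reuse: bool = False

    @property
    def metrics(self) -> dict:
        return {
            "accuracy": float(self.accuracy),
            "n_selected": len(self.selected_features),
        }

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(frame[list(self.selected_features)])


@dataclass
class CountMatrix:
    counts: np.ndarray  # cells x genes, non-negative integers
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ServiceError("count matrix must be 2-D (cells x genes)")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ServiceError("count matrix dimensions do not match identifier lists")
        if self.counts.size and self.counts.min() < 0:
            raise ServiceError("count matrix entries must be non-negative")


@dataclass
class NormalizedMatrix:
    values: np.ndarray
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x dims
    cell_ids: tuple[str, ...]
    method: str


@dataclass
class ClusterLabels:
    labels: np.ndarray
    cell_ids: tuple[str, ...]
    method: str

    @property
    def metrics(self) -> dict:
        return {"n_clusters": int(len(np.unique(self.labels)))}


# ---------------------------------------------------------------------------
# Data processing services
# ---------------------------------------------------------------------------

def svc_csv_load(path: str, *, seed: int = 0, params: Optional[Mapping] = None) -> LabeledTable:
    """csv_path -> labeled_table. The label column (default ``target``)
    must be present; feature cells must be numeric."""
    p = _params(params)
    label = p.get("label", "target")
    frame = pd.read_csv(path)
    if frame.empty:
        raise ServiceError("empty dataset")
    if label not in frame.columns:
        raise ServiceError(f"label column {label!r} not found in {list(frame.columns)}")
    features = frame.drop(columns=[label])
    non_numeric = [c for c in features.columns if not pd.api.types.is_numeric_dtype(features[c])]
    if non_numeric:
        raise ServiceError(f"non-numeric feature columns: {non_numeric}")
    return LabeledTable(frame, label=label)


def svc_load_counts(path: str, *, seed: int = 0, params: Optional[Mapping] = None) -> CountMatrix:
    """counts_csv_path -> count_matrix. CSV with cell ids in the first
    column and gene ids as header; Matrix Market (.mtx) also accepted."""
    if str(path).endswith(".mtx"):
        from scipy.io import mmread

        raw = mmread(path)
        m = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        cells = tuple(f"cell{i}" for i in range(m.shape[0]))
        genes = tuple(f"gene{j}" for j in range(m.shape[1]))
        return CountMatrix(m.astype(np.int64), cells, genes)
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise ServiceError("empty dataset")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values < 0) or np.any(np.mod(values, 1) != 0):
        raise ServiceError("count matrix cells must be non-negative integers")
    return CountMatrix(
        values.astype(np.int64),
        tuple(str(i) for i in frame.index),
        tuple(str(c) for c in frame.columns),
    )


def svc_split(table: LabeledTable, *, seed: int = 0, params: Optional[Mapping] = None) -> SplitData:
    """labeled_table -> split_data. Stratified train/test split."""
    p = _params(params)
    ratio = float(p.get("ratio", 0.8))
    if not 0 < ratio < 1:
        raise ServiceError(f"split ratio must be in (0, 1), got {ratio}")
    y = table.frame[table.label]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ServiceError("single-class input cannot be split for classification")
    if counts.min() < 2:
        raise ServiceError("need at least 2 rows per class to stratify")
    train, test = train_test_split(
        table.frame, train_size=ratio, stratify=y, random_state=seed
    )
    return SplitData(train=train, test=test, label=table.label, ratio=ratio, seed=seed)


def svc_quality_control(
    payload: Union[LabeledTable, CountMatrix],
    *,
    seed: int = 0,
    params: Optional[Mapping] = None,
):
    """Tabular: drop rows with missing values and zero-variance feature
    columns. Counts: drop cells whose total count falls below the q-th
    percentile (default 5) and genes detected in fewer than ``min_cells``
    (default 3) cells."""
    p = _params(params)
    if isinstance(payload, LabeledTable):
        frame = payload.frame.dropna(axis=0)
        if frame.empty:
            raise ServiceError("no data survives QC")
        keep = [payload.label] + [
            c
            for c in frame.columns
            if c != payload.label and frame[c].nunique() > 1
        ]
        frame = frame[[c for c in frame.columns if c in keep]]
        if frame.shape[1] < 2:
            raise ServiceError("no data survives QC")
        return LabeledTable(frame, label=payload.label)

    if isinstance(payload, CountMatrix):
        q = float(p.get("qc_percentile", 5.0))
        min_cells = int(p.get("min_cells", 3))
        totals = payload.counts.sum(axis=1)
        threshold = np.percentile(totals, q)
        cell_mask = totals >= threshold
        if not cell_mask.any():
            raise ServiceError("no data survives QC")
        counts = payload.counts[cell_mask]
        detected = (counts > 0).sum(axis=0)
        gene_mask = detected >= min_cells
        if not gene_mask.any():
            raise ServiceError("no data survives QC")
        return CountMatrix(
            counts[:, gene_mask],
            tuple(c for c, k in zip(payload.cell_ids, cell_mask) if k),
            tuple(g for g, k in zip(payload.gene_ids, gene_mask) if k),
        )
    raise ServiceError(f"quality control cannot handle {type(payload).__name__}")


def svc_normalize(
    payload: Union[LabeledTable, CountMatrix],
    *,
    seed: int = 0,
    params: Optional[Mapping] = None,
):
    """Tabular: per-feature z-score. Counts: scale each cell to the median
    total count, then log(1 + x)."""
    if isinstance(payload, LabeledTable):
        frame = payload.frame.copy()
        for c in payload.feature_names:
            sd = frame[c].std(ddof=0)
            if sd == 0 or not np.isfinite(sd):
                raise ServiceError(f"zero-variance feature {c!r} reached normalization (QC contract violation)")
            frame[c] = (frame[c] - frame[c].mean()) / sd
        return LabeledTable(frame, label=payload.label)
    if isinstance(payload, CountMatrix):
        totals = payload.counts.sum(axis=1).astype(float)
        if np.any(totals == 0):
            raise ServiceError("cell with zero total count reached normalization")
        median = float(np.median(totals))
        scaled = payload.counts / totals[:, None] * median
        return NormalizedMatrix(np.log1p(scaled), payload.cell_ids, payload.gene_ids)
    raise ServiceError(f"normalization cannot handle {type(payload).__name__}")


# ---------------------------------------------------------------------------
# ML services
# ---------------------------------------------------------------------------

def _make_pipeline(seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
        ]
    )


def svc_classify(split: SplitData, *, seed: int = 0, params: Optional[Mapping] = None) -> ClassificationModel:
    """split_data -> classification_model. Regularized linear classifier
    with in-pipeline standardization; absolute coefficients double as
    feature importances for the downstream optimizer."""
    features = list(split.feature_names)
    if not features:
        raise ServiceError("no feature columns to train on")
    y_train = split.train[split.label]
    if y_train.nunique() < 2:
        raise ServiceError("degenerate train partition (single class)")
    pipe = _make_pipeline(seed)
    pipe.fit(split.train[features], y_train)
    accuracy = float(pipe.score(split.test[features], split.test[split.label]))
    return ClassificationModel(pipe, tuple(features), split, accuracy)


def rfe_cv_path(
    split: SplitData,
    *,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[list[tuple[int, float]], dict[int, tuple[str, ...]]]:
    """Backward feature-elimination path with cross-validated scoring.

    Starting from all p features, repeatedly drop the feature with the
    smallest absolute standardized coefficient, recording the k-fold mean
    CV accuracy at every subset size p, p-1, ..., 1. Returns the CV curve
    and the feature set evaluated at each size.
    """
    features = list(split.feature_names)
    y = split.train[split.label]
    class_min = int(y.value_counts().min())
    if cv_folds > class_min:
        raise ServiceError(
            f"cv_folds={cv_folds} exceeds the smallest class count ({class_min})"
        )
    curve: list[tuple[int, float]] = []
    sets: dict[int, tuple[str, ...]] = {}
    current = features
    while current:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(_make_pipeline(seed), split.train[current], y, cv=cv)
        curve.append((len(current), float(scores.mean())))
        sets[len(current)] = tuple(current)
        if len(current) == 1:
            break
        pipe = _make_pipeline(seed)
        pipe.fit(split.train[current], y)
        weakest = int(np.argmin(np.abs(pipe.named_steps["clf"].coef_.ravel())))
        current = current[:weakest] + current[weakest + 1:]
    return curve, sets


def svc_optimize(
    payload: Union[ClassificationModel, SplitData],
    *,
    seed: int = 0,
    params: Optional[Mapping] = None,
) -> OptimizedModel:
    """classification_model -> optimized_model. Recursive feature
    elimination scored by cross-validated accuracy; the subset size with
    the best mean CV accuracy wins (ties -> fewer features), then the model
    is refit on the full train partition with the selected subset."""
    p = _params(params)
    split = payload.split if isinstance(payload, ClassificationModel) else payload
    if len(split.feature_names) < 2:
        raise ServiceError("optimization needs at least 2 features")
    curve, sets = rfe_cv_path(split, seed=seed, cv_folds=int(p.get("cv_folds", 5)))
    best_size = min(curve, key=lambda item: (-item[1], item[0]))[0]
    selected = sets[best_size]
    pipe = _make_pipeline(seed)
    pipe.fit(split.train[list(selected)], split.train[split.label])
    accuracy = float(pipe.score(split.test[list(selected)], split.test[split.label]))
    return OptimizedModel(pipe, selected, tuple(curve), accuracy, split)


def svc_feature_projection(
    payload: Union[ClassificationModel, SplitData],
    *,
    seed: int = 0,
    params: Optional[Mapping] = None,
) -> OptimizedModel:
    """Replacement for the optimizer stage when world knowledge already
    names the informative subset for this schema: project onto the stored
    features and refit (no elimination loop)."""
    p = _params(params)
    features = tuple(p.get("features", ()))
    if not features:
        raise ServiceError("feature projection requires stored features")
    split = payload.split if isinstance(payload, ClassificationModel) else payload
    missing = [f for f in features if f not in split.feature_names]
    if missing:
        raise ServiceError(f"stored features missing from data: {missing}")
    pipe = _make_pipeline(seed)
    pipe.fit(split.train[list(features)], split.train[split.label])
    accuracy = float(pipe.score(split.test[list(features)], split.test[split.label]))
    return OptimizedModel(pipe, features, (), accuracy, split, via_feature_reuse=True)


# ---------------------------------------------------------------------------
# Embedding and clustering services
# ---------------------------------------------------------------------------

def _embed(matrix: NormalizedMatrix, method: str, dims: int, seed: int, params: Mapping) -> Embedding:
    values = np.asarray(matrix.values, dtype=float)
    if dims >= values.shape[1]:
        raise ServiceError(f"dims={dims} must be smaller than feature count {values.shape[1]}")
    if method == "pca":
        model = PCA(n_components=dims, svd_solver="full", random_state=seed)
        coords = model.fit_transform(values)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=dims,
            random_state=seed,
            init="pca",
            perplexity=float(params.get("perplexity", min(30.0, max(5.0, values.shape[0] / 10)))),
        ).fit_transform(values)
    elif method == "umap":
        try:
            import umap
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ServiceUnavailable("umap-learn is not installed") from exc
        coords = umap.UMAP(n_components=dims, random_state=seed).fit_transform(values)
    else:
        raise ServiceError(f"unknown embedding method {method!r}")
    return Embedding(np.asarray(coords, dtype=float), matrix.cell_ids, method)


def svc_embed(matrix: NormalizedMatrix, *, seed: int = 0, params: Optional[Mapping] = None) -> Embedding:
    p = _params(params)
    return _embed(matrix, p.get("method", "pca"), int(p.get("dims", 2)), seed, p)


def svc_embed_pca(matrix: NormalizedMatrix, *, seed: int = 0, params: Optional[Mapping] = None) -> Embedding:
    p = _params(params)
    return _embed(matrix, "pca", int(p.get("dims", 2)), seed, p)


def svc_embed_tsne(matrix: NormalizedMatrix, *, seed: int = 0, params: Optional[Mapping] = None) -> Embedding:
    p = _params(params)
    return _embed(matrix, "tsne", int(p.get("dims", 2)), seed, p)


def svc_embed_umap(matrix: NormalizedMatrix, *, seed: int = 0, params: Optional[Mapping] = None) -> Embedding:
    p = _params(params)
    return _embed(matrix, "umap", int(p.get("dims", 2)), seed, p)


def _knn_graph_communities(coords: np.ndarray, n_neighbors: int) -> np.ndarray:
    import networkx as nx

    n = coords.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            g.add_edge(i, int(j))
    communities = nx.algorithms.community.greedy_modularity_communities(g)
    # deterministic labelling: communities ordered by their lowest node index
    ordered = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(ordered):
        for m in members:
            labels[m] = lab
    return labels


def svc_cluster(emb: Embedding, *, seed: int = 0, params: Optional[Mapping] = None) -> ClusterLabels:
    """embedding -> cluster_labels. ``kmeans`` (Lloyd, seeded init, k given)
    or ``graph`` (k-nearest-neighbour graph + greedy modularity
    maximization, communities labelled by lowest member index)."""
    p = _params(params)
    method = p.get("method", "kmeans")
    coords = np.asarray(emb.coords, dtype=float)
    if coords.shape[0] < 2:
        raise ServiceError("clustering needs at least 2 points")
    if method == "kmeans":
        k = int(p.get("k", 3))
        if k > coords.shape[0]:
            raise ServiceError(f"k={k} exceeds number of points {coords.shape[0]}")
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(coords)
    elif method == "graph":
        labels = _knn_graph_communities(coords, int(p.get("n_neighbors", 15)))
    else:
        raise ServiceError(f"unknown clustering method {method!r}")
    return ClusterLabels(np.asarray(labels, dtype=int), emb.cell_ids, method)


def svc_cluster_kmeans(emb: Embedding, *, seed: int = 0, params: Optional[Mapping] = None) -> ClusterLabels:
    p = _params(params)
    p["method"] = "kmeans"
    return svc_cluster(emb, seed=seed, params=p)


def svc_cluster_graph(emb: Embedding, *, seed: int = 0, params: Optional[Mapping] = None) -> ClusterLabels:
    p = _params(params)
    p["method"] = "graph"
    return svc_cluster(emb, seed=seed, params=p)


# ---------------------------------------------------------------------------
# Descriptor-only services (models not shipped)
# ---------------------------------------------------------------------------

def svc_text_generate(prompt, *, seed: int = 0, params: Optional[Mapping] = None):
    raise ServiceUnavailable("text generation model is not shipped in this environment")


def svc_image_classify(image, *, seed: int = 0, params: Optional[Mapping] = None):
    raise ServiceUnavailable("image classification model is not shipped in this environment")
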