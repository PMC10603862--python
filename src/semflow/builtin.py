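"""Default environment initialization: descriptor records for the built-in
microservices, grouped as (1) data processing, (2) ML, (3) optimization,
plus the single-cell extension set used by the clustering scenario."""

from __future__ import annotations

from .kg import KnowledgeSpace
from .registry import Registry, register

_MIT = "MIT"
_SKLEARN_DEP = {"id": "scikit-learn", "install_uri": "https://pypi.org/project/scikit-learn/", "version": ">=1.0"}
_PANDAS_DEP = {"id": "pandas", "install_uri": "https://pypi.org/project/pandas/", "version": ">=2.0"}
_NUMPY_DEP = {"id": "numpy", "install_uri": "https://pypi.org/project/numpy/", "version": ">=1.24"}


def _svc(name, description, inputs, outputs, category, func, framework="scikit-learn", deps=None):
    return {
        "name": name,
        "description": description,
        "framework": framework,
        "dependencies": deps if deps is not None else [_SKLEARN_DEP],
        "inputs": inputs,
        "outputs": outputs,
        "category": category,
        "license": _MIT,
        "invoke_path": f"local:semflow.services:{func}",
    }


#: Group 1 — data processing; Group 2 — ML models; Group 3 — optimization.
DEFAULT_SERVICES: tuple[dict, ...] = (
    _svc(
        "csv_loader",
        "Load a labeled CSV table into a typed dataframe payload",
        [{"name": "path", "data_kind": "csv_path"}],
        [{"name": "table", "data_kind": "labeled_table"}],
        "data processing",
        "svc_csv_load",
        framework="pandas",
        deps=[_PANDAS_DEP],
    ),
    _svc(
        "table_quality_control",
        "Drop rows with missing values and zero-variance feature columns",
        [{"name": "table", "data_kind": "labeled_table"}],
        [{"name": "table", "data_kind": "labeled_table"}],
        "data processing",
        "svc_quality_control",
        framework="pandas",
        deps=[_PANDAS_DEP],
    ),
    _svc(
        "table_normalize",
        "Per-feature z-score scaling of a labeled table",
        [{"name": "table", "data_kind": "labeled_table"}],
        [{"name": "table", "data_kind": "labeled_table"}],
        "data processing",
        "svc_normalize",
        framework="pandas",
        deps=[_PANDAS_DEP],
    ),
    _svc(
        "data_split",
        "Stratified train/test partitioning of a labeled table",
        [{"name": "table", "data_kind": "labeled_table"}],
        [{"name": "split", "data_kind": "split_data"}],
        "data processing",
        "svc_split",
    ),
    _svc(
        "classification_pipeline",
        "Regularized linear classifier with in-pipeline standardization",
        [{"name": "split", "data_kind": "split_data"}],
        [{"name": "model", "data_kind": "classification_model"}],
        "supervised classification",
        "svc_classify",
    ),
    _svc(
        "kmeans_clustering",
        "Lloyd k-means clustering of embedded points",
        [{"name": "embedding", "data_kind": "embedding"}],
        [{"name": "labels", "data_kind": "cluster_labels"}],
        "unsupervised clustering",
        "svc_cluster_kmeans",
    ),
    _svc(
        "text_generation",
        "Causal language model answering a text prompt (descriptor only; model not shipped)",
        [{"name": "prompt", "data_kind": "text_prompt"}],
        [{"name": "answer", "data_kind": "text_answer"}],
        "text generation base model",
        "svc_text_generate",
        framework="transformers",
        deps=[{"id": "transformers", "install_uri": "https://pypi.org/project/transformers/", "version": ">=4.0"}],
    ),
    _svc(
        "image_classifier",
        "Vision transformer image classifier (descriptor only; model not shipped)",
        [{"name": "image", "data_kind": "image"}],
        [{"name": "label", "data_kind": "image_label"}],
        "image classification base model",
        "svc_image_classify",
        framework="transformers",
        deps=[{"id": "transformers", "install_uri": "https://pypi.org/project/transformers/", "version": ">=4.0"}],
    ),
    _svc(
        "rfecv_optimize",
        "Recursive feature elimination scored by cross-validated accuracy",
        [{"name": "model", "data_kind": "classification_model"}],
        [{"name": "model", "data_kind": "optimized_model"}],
        "optimization",
        "svc_optimize",
    ),
)

#: Extension set for the single-cell clustering scenario: loading, QC,
#: normalization, three embedding alternatives, and graph clustering.
SINGLE_CELL_SERVICES: tuple[dict, ...] = (
    _svc(
        "counts_loader",
        "Load a cells-by-genes count matrix from CSV or Matrix Market",
        [{"name": "path", "data_kind": "counts_csv_path"}],
        [{"name": "counts", "data_kind": "count_matrix"}],
        "data processing",
        "svc_load_counts",
        framework="pandas",
        deps=[_PANDAS_DEP],
    ),
    _svc(
        "counts_quality_control",
        "Remove low-depth cells (below the depth percentile) and rarely detected genes",
        [{"name": "counts", "data_kind": "count_matrix"}],
        [{"name": "counts", "data_kind": "qc_count_matrix"}],
        "data processing",
        "svc_quality_control",
        framework="numpy",
        deps=[_NUMPY_DEP],
    ),
    _svc(
        "counts_normalize",
        "Median-depth scaling followed by log1p transform",
        [{"name": "counts", "data_kind": "qc_count_matrix"}],
        [{"name": "matrix", "data_kind": "normalized_matrix"}],
        "data processing",
        "svc_normalize",
        framework="numpy",
        deps=[_NUMPY_DEP],
    ),
    _svc(
        "pca_embedding",
        "Principal-component embedding of a normalized matrix",
        [{"name": "matrix", "data_kind": "normalized_matrix"}],
        [{"name": "embedding", "data_kind": "embedding"}],
        "feature embedding",
        "svc_embed_pca",
    ),
    _svc(
        "tsne_embedding",
        "t-SNE embedding of a normalized matrix",
        [{"name": "matrix", "data_kind": "normalized_matrix"}],
        [{"name": "embedding", "data_kind": "embedding"}],
        "feature embedding",
        "svc_embed_tsne",
    ),
    _svc(
        "umap_embedding",
        "UMAP embedding of a normalized matrix (delegates to umap-learn)",
        [{"name": "matrix", "data_kind": "normalized_matrix"}],
        [{"name": "embedding", "data_kind": "embedding"}],
        "feature embedding",
        "svc_embed_umap",
        framework="umap-learn",
        deps=[{"id": "umap-learn", "install_uri": "https://pypi.org/project/umap-learn/", "version": ">=0.5"}],
    ),
    _svc(
        "louvain_clustering",
        "k-nearest-neighbour graph plus greedy modularity maximization",
        [{"name": "embedding", "data_kind": "embedding"}],
        [{"name": "labels", "data_kind": "cluster_labels"}],
        "unsupervised clustering",
        "svc_cluster_graph",
        framework="networkx",
        deps=[{"id": "networkx", "install_uri": "https://pypi.org/project/networkx/", "version": ">=3.0"}],
    ),
)


def bootstrap(space: KnowledgeSpace | None = None, single_cell: bool = False) -> tuple[KnowledgeSpace, Registry]:
    """Register the default service set (optionally plus the single-cell
    extension) into a knowledge space and return it with its registry."""
    space = space if space is not None else KnowledgeSpace()
    records = DEFAULT_SERVICES + (SINGLE_CELL_SERVICES if single_cell else ())
    for record in records:
        register(space, record)
    return space, Registry(space)
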