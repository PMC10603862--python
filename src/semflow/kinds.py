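"""Controlled vocabulary of data kinds flowing between microservices.

Every service port declares one of these kinds; the planner composes chains
by matching an output kind to the next input kind. The vocabulary is frozen
here on purpose: adding a kind is a reviewed code change, not runtime data,
which keeps planning sound.
"""

from __future__ import annotations

DATA_KINDS: frozenset[str] = frozenset(
    {
        "csv_path",
        "labeled_table",
        "split_data",
        "classification_model",
        "optimized_model",
        "counts_csv_path",
        "count_matrix",
        "qc_count_matrix",
        "normalized_matrix",
        "embedding",
        "cluster_labels",
        "text_prompt",
        "text_answer",
        "image",
        "image_label",
    }
)

MODALITIES: frozenset[str] = frozenset({"tabular", "counts", "text", "image"})


def check_data_kind(kind: str) -> str:
    if kind not in DATA_KINDS:
        raise ValueError(
            f"unknown data kind {kind!r}; expected one of {sorted(DATA_KINDS)}"
        )
    return kind
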