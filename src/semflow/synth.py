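"""Synthetic study fixtures: everything the framework needs to run
end-to-end without any download.

Two families of generators are provided, each a pure function of its spec
(seed included) that returns the data together with its ground truth:

* labeled clinical-style tables whose binary label follows a logistic
  model on a planted informative feature subset (noise features are
  independent of the label), including a heart-disease-style schema with
  its conventional 14 column names, and a Parkinson-voice-style schema
  for transfer experiments;
* cells-by-genes count matrices with planted clusters (block-elevated
  expression profiles, multinomial sampling at lognormal depths) and a
  planted set of low-depth cells that the quality-control stage removes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .services import CountMatrix, LabeledTable


@dataclass(frozen=True)
class TabularSpec:
    n_rows: int
    informative_features: tuple[tuple[str, float], ...]  # (name, log-odds effect)
    noise_features: tuple[str, ...]
    class_balance: float = 0.5
    noise_sd: float = 0.5  # sd of latent logit noise
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.informative_features] + list(self.noise_features)
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not all(np.isfinite(e) for _, e in self.informative_features):
            raise ValueError("effect sizes must be finite")
        if not 0 < self.class_balance < 1:
            raise ValueError("class balance must lie in (0, 1)")


def default_tabular_spec(
    n_rows: int = 500,
    n_informative: int = 5,
    n_noise: int = 10,
    effect: float = 1.5,
    seed: int = 0,
) -> TabularSpec:
    """Planted-signal benchmark conditions: standardized-normal features,
    log-odds effect of 1.5 per informative feature, balanced classes."""
    return TabularSpec(
        n_rows=n_rows,
        informative_features=tuple((f"signal_{i}", effect) for i in range(n_informative)),
        noise_features=tuple(f"noise_{i}" for i in range(n_noise)),
        seed=seed,
    )


def make_classification_table(spec: TabularSpec) -> tuple[LabeledTable, dict]:
    """Labels are drawn from a logistic model on the informative features
    only; noise features are independent of the label. Ground truth names
    the informative set."""
    rng = np.random.default_rng(spec.seed)
    inf_names = [n for n, _ in spec.informative_features]
    betas = np.array([e for _, e in spec.informative_features])
    names = inf_names + list(spec.noise_features)
    X = rng.standard_normal((spec.n_rows, len(names)))
    logit = X[:, : len(inf_names)] @ betas if len(inf_names) else np.zeros(spec.n_rows)
    logit = logit + rng.normal(0.0, spec.noise_sd, spec.n_rows)
    logit = logit + np.log(spec.class_balance / (1 - spec.class_balance))
    prob = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random(spec.n_rows) < prob).astype(int)
    frame = pd.DataFrame(X, columns=names)
    frame["target"] = y
    truth = {
        "informative": tuple(inf_names),
        "effects": dict(spec.informative_features),
        "class_balance": spec.class_balance,
    }
    return LabeledTable(frame), truth


HEART_COLUMNS: tuple[str, ...] = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal", "target",
)

#: The eight designated informative features of the heart-style schema,
#: with their planted standardized log-odds effects.
HEART_INFORMATIVE: Mapping[str, float] = {
    "sex": 1.0,
    "cp": 1.0,
    "thalach": -1.0,
    "exang": 1.0,
    "oldpeak": 1.0,
    "slope": -1.0,
    "ca": 1.0,
    "thal": 1.0,
}


def make_heartlike_table(n_rows: int = 335, seed: int = 0) -> tuple[LabeledTable, dict]:
    """A clinical-style table with exactly the conventional 14 heart-disease
    column names and value encodings (sex in {0,1}, slope in {0,1,2},
    ca in 0-3, ...). Signal is planted only in the eight designated
    informative features so feature-selection runs have a known answer."""
    if n_rows < 20:
        raise ValueError("need at least 20 rows")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    cols["age"] = rng.integers(29, 78, n_rows)
    cols["sex"] = rng.binomial(1, 0.68, n_rows)
    cols["cp"] = rng.integers(0, 4, n_rows)
    cols["trestbps"] = np.clip(rng.normal(131, 17, n_rows), 94, 200).round().astype(int)
    cols["chol"] = np.clip(rng.normal(246, 51, n_rows), 126, 564).round().astype(int)
    cols["fbs"] = rng.binomial(1, 0.15, n_rows)
    cols["restecg"] = rng.choice([0, 1, 2], n_rows, p=[0.50, 0.48, 0.02])
    cols["thalach"] = np.clip(rng.normal(149, 22, n_rows), 71, 202).round().astype(int)
    cols["exang"] = rng.binomial(1, 0.33, n_rows)
    cols["oldpeak"] = np.clip(rng.exponential(1.0, n_rows), 0, 6.2).round(1)
    cols["slope"] = rng.choice([0, 1, 2], n_rows, p=[0.21, 0.46, 0.33])
    cols["ca"] = rng.choice([0, 1, 2, 3], n_rows, p=[0.58, 0.21, 0.12, 0.09])
    cols["thal"] = rng.choice([0, 1, 2, 3], n_rows, p=[0.02, 0.06, 0.55, 0.37])

    logit = np.zeros(n_rows)
    for name, beta in HEART_INFORMATIVE.items():
        x = cols[name].astype(float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n_rows)
        logit += beta * z
    logit += rng.normal(0.0, 0.5, n_rows)
    prob = 1.0 / (1.0 + np.exp(-logit))
    cols["target"] = (rng.random(n_rows) < prob).astype(int)

    frame = pd.DataFrame({name: cols[name] for name in HEART_COLUMNS})
    truth = {"informative": tuple(HEART_INFORMATIVE), "effects": dict(HEART_INFORMATIVE)}
    return LabeledTable(frame), truth


PARKINSON_COLUMNS: tuple[str, ...] = (
    "mdvp_fo", "mdvp_fhi", "mdvp_flo", "jitter_percent", "jitter_abs",
    "rap", "ppq", "ddp", "shimmer", "shimmer_db", "apq3", "apq5", "apq",
    "dda", "nhr", "hnr", "rpde", "dfa", "spread1", "spread2", "d2", "ppe",
    "target",
)

_PARKINSON_INFORMATIVE: tuple[tuple[str, float], ...] = (
    ("spread1", 1.2),
    ("ppe", 1.2),
    ("mdvp_fo", -1.0),
    ("hnr", -1.0),
    ("dfa", 0.8),
)


def make_parkinsonlike_table(n_rows: int = 195, seed: int = 0) -> tuple[LabeledTable, dict]:
    """A voice-measurement-style table (different schema, same task shape as
    the heart-style table) for transfer experiments."""
    noise = tuple(c for c in PARKINSON_COLUMNS if c != "target" and c not in dict(_PARKINSON_INFORMATIVE))
    spec = TabularSpec(
        n_rows=n_rows,
        informative_features=_PARKINSON_INFORMATIVE,
        noise_features=noise,
        seed=seed,
    )
    table, truth = make_classification_table(spec)
    frame = table.frame[[c for c in PARKINSON_COLUMNS]]
    return LabeledTable(frame), truth


@dataclass(frozen=True)
class CountsSpec:
    n_cells: int = 300
    n_genes: int = 400
    k_clusters: int = 3
    proportions: Optional[tuple[float, ...]] = None
    profile_fold: float = 6.0  # expression elevation of a cluster's own gene block
    depth_mean: float = 2000.0
    depth_sigma: float = 0.25  # lognormal sd of healthy cell depths
    n_lowdepth_cells: Optional[int] = None  # default: 5% of cells
    lowdepth_range: tuple[int, int] = (50, 150)
    seed: int = 0

    def resolved_proportions(self) -> np.ndarray:
        if self.proportions is None:
            return np.full(self.k_clusters, 1.0 / self.k_clusters)
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != self.k_clusters or not np.isclose(p.sum(), 1.0):
            raise ValueError("cluster proportions must have length k and sum to 1")
        return p

    def resolved_lowdepth(self) -> int:
        if self.n_lowdepth_cells is not None:
            return self.n_lowdepth_cells
        return int(np.floor(0.05 * self.n_cells))


def make_count_matrix(spec: CountsSpec) -> tuple[CountMatrix, dict]:
    """Cells-by-genes counts with planted clusters and low-depth cells.

    Each cluster elevates its own contiguous gene block by ``profile_fold``;
    per-cell totals are lognormal around ``depth_mean`` except for the
    planted low-depth cells, whose totals fall far below the 5th depth
    percentile so the QC stage removes exactly that set.
    """
    rng = np.random.default_rng(spec.seed)
    props = spec.resolved_proportions()

    # deterministic cluster sizes (largest-remainder), then shuffled order
    sizes = np.floor(props * spec.n_cells).astype(int)
    while sizes.sum() < spec.n_cells:
        sizes[int(np.argmax(props * spec.n_cells - sizes))] += 1
    labels = np.repeat(np.arange(spec.k_clusters), sizes)
    rng.shuffle(labels)

    block = spec.n_genes // spec.k_clusters
    profiles = np.ones((spec.k_clusters, spec.n_genes))
    for c in range(spec.k_clusters):
        profiles[c, c * block: (c + 1) * block] *= spec.profile_fold
    profiles /= profiles.sum(axis=1, keepdims=True)

    depths = rng.lognormal(np.log(spec.depth_mean), spec.depth_sigma, spec.n_cells)
    depths = np.maximum(depths, spec.depth_mean * 0.4).astype(int)
    n_low = spec.resolved_lowdepth()
    low_idx = rng.choice(spec.n_cells, size=n_low, replace=False) if n_low else np.array([], dtype=int)
    depths[low_idx] = rng.integers(spec.lowdepth_range[0], spec.lowdepth_range[1] + 1, n_low)

    counts = np.vstack(
        [rng.multinomial(depths[i], profiles[labels[i]]) for i in range(spec.n_cells)]
    )
    cells = tuple(f"cell{i:05d}" for i in range(spec.n_cells))
    genes = tuple(f"g{j:04d}" for j in range(spec.n_genes))
    truth = {
        "labels": labels.copy(),
        "lowdepth_cells": tuple(cells[i] for i in sorted(low_idx.tolist())),
        "k_clusters": spec.k_clusters,
    }
    return CountMatrix(counts, cells, genes), truth


# ---------------------------------------------------------------------------
# File output helpers (CLI `fixtures` subcommands)
# ---------------------------------------------------------------------------

def table_to_csv(table: LabeledTable) -> str:
    buf = io.StringIO()
    table.frame.to_csv(buf, index=False)
    return buf.getvalue()


def counts_to_csv(matrix: CountMatrix) -> str:
    frame = pd.DataFrame(matrix.counts, index=list(matrix.cell_ids), columns=list(matrix.gene_ids))
    buf = io.StringIO()
    frame.to_csv(buf)
    return buf.getvalue()
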