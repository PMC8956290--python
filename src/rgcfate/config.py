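"""Run configuration: the numeric defaults used throughout the pipeline.

Every stage reads its parameters from :class:`RunConfig`; all values can be
overridden from YAML or keyword arguments, and the configuration is serialized
into each output directory so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Mapping from developmental age label to time in days used for transport
#: gaps and logistic fits (E13 is day 0).
AGE_DAYS: dict[str, float] = {
    "E13": 0.0,
    "E14": 1.0,
    "E16": 3.0,
    "P0": 6.0,
    "P5": 11.0,
    "P56": 20.0,
}


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Defaults follow the published analysis protocol for the retinal
    ganglion cell time course; each one is overridable.
    """

    # preprocessing
    min_genes_per_cell: int = 700
    min_cells_per_gene: int = 10
    normalize_target: float | None = None  # None -> median of column sums
    hvg_z_factor: float = 0.8

    # clustering
    n_neighbors: int = 30
    louvain_resolution: float = 0.5
    de_logfc_threshold: float = 0.5
    de_alpha: float = 1e-5
    merge_min_de_genes: int = 10

    # cross-age mapping
    train_frac: float = 0.6
    max_train_cells_per_cluster: int = 300
    max_cluster_error: float = 0.10
    n_top_features: int = 500
    classifier_split_frac: float = 0.5

    # optimal transport
    epsilon: float = 0.005
    lambda1: float = 1.0
    lambda2: float = 50.0
    growth_iters: int = 3

    # fate couplings / specification
    coupling_threshold: float = 0.2
    decay_terminal_t: float = 36.0
    localization_factor: float = 0.95

    # laterality
    laterality_k_sd: float = 1.5
    laterality_fc: float = 1.5
    laterality_alpha: float = 5e-5

    # bookkeeping
    age_days: dict[str, float] = field(default_factory=lambda: dict(AGE_DAYS))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)
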