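"""Framework configuration.

All thresholds and stochastic settings used across the pipeline live in a
single :class:`FrameworkConfig` so that a YAML file (or CLI flags) can
reproduce a full analysis.  The defaults are the study settings:
``|log2FC| >= 1`` with adjusted ``p <= 0.05`` for differential expression,
and 1000 random forests of 500 trees with 10 candidate variables per split
on a stratified 70/30 train/test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RFConfig:
    """Settings for the repeated random-forest classification."""

    n_models: int = 1000
    n_trees: int = 500
    mtry: int = 10
    train_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_models < 1 or self.n_trees < 1 or self.mtry < 1:
            raise ValueError("n_models, n_trees and mtry must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class FrameworkConfig:
    """Tunable parameters of the whole analysis framework.

    Parameters
    ----------
    lfc_threshold
        Minimum absolute log2 fold-change for a gene to be called
        differentially expressed (log2 units, default 1.0).
    p_threshold
        Maximum family-wise adjusted p-value for a DE call (default 0.05).
    k_min, k_max
        Inclusive search range for the silhouette-based choice of the
        number of gene clusters.
    efficiency_mode
        ``mean_of_abs`` (mean of |log2FC|, the default) or ``abs_of_mean``
        (|mean log2FC|) when forming the efficiency-score ratio.
    min_category_size
        Minimum number of qualifying genes for a functional category to be
        scored or used as a classifier feature.
    epsilon
        Division guard for the efficiency ratio.
    bh_across_genes
        If true, apply an additional Benjamini-Hochberg correction across
        genes on top of the per-gene Dunnett adjustment (off by default).
    """

    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    k_min: int = 2
    k_max: int = 15
    efficiency_mode: str = "mean_of_abs"
    min_category_size: int = 3
    epsilon: float = 1e-8
    bh_across_genes: bool = False
    rf: RFConfig = field(default_factory=RFConfig)

    def validate(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("cluster search range must satisfy 2 <= k_min <= k_max")
        if self.efficiency_mode not in ("mean_of_abs", "abs_of_mean"):
            raise ValueError(f"unknown efficiency_mode {self.efficiency_mode!r}")
        if self.min_category_size < 1:
            raise ValueError("min_category_size must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.rf.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FrameworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rf = RFConfig(**raw.pop("rf", {}))
        cfg = cls(rf=rf, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
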