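"""Profile distances and two-dimensional treatment-efficiency scores.

Two scalar summaries drive the quantitative drug comparison:

* the *profile distance* between two per-gene log2FC vectors, the mean
  absolute difference

      d(P1, P2) = (1/N) sum_i |log2FC(P1)_i - log2FC(P2)_i| ;

  against an all-zero profile it is the *distance from the healthy state*
  and serves as a proxy for treatment efficiency (smaller = closer to
  healthy expression);

* the per-category *efficiency score*

      E(P, f) = log10( m(lfc vs disease) / m(lfc vs healthy) ),

  where m is the mean absolute log2FC over the category's DE genes
  (``mean_of_abs``, the default) or the absolute mean (``abs_of_mean``).
  E > 0 marks categories a treatment moved far from the diseased state
  while staying near the healthy one.

Each functional category also yields a 2-D coordinate (mean log2FC versus
healthy, mean log2FC versus disease): vertical displacement is desirable
(distance from disease), horizontal displacement undesirable (distance
from health).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FrameworkConfig
from .errors import ConsistencyError
from .study import AnnotationSet
from .diffexpr import ContrastResult

log = logging.getLogger(__name__)

_DEFAULT_CONFIG = FrameworkConfig()

SCORE_CAP = 12.0


@dataclass
class TreatmentProfile:
    """Dual-baseline log2FC vectors of one treatment over a gene subset."""

    treatment: str
    lfc_vs_wt: pd.Series
    lfc_vs_tg: pd.Series

    def __post_init__(self) -> None:
        if not self.lfc_vs_wt.index.equals(self.lfc_vs_tg.index):
            raise ConsistencyError("profile vectors are not aligned on genes")
        if len(self.lfc_vs_wt) < 1:
            raise ValueError("profile requires at least one gene")

    @property
    def gene_subset(self) -> pd.Index:
        return self.lfc_vs_wt.index

    def restrict(self, genes) -> "TreatmentProfile":
        keep = self.gene_subset.intersection(pd.Index(sorted(genes)))
        return TreatmentProfile(
            treatment=self.treatment,
            lfc_vs_wt=self.lfc_vs_wt.loc[keep],
            lfc_vs_tg=self.lfc_vs_tg.loc[keep],
        )


def treatment_profile(
    vs_wt: ContrastResult,
    vs_tg: ContrastResult,
    treatment: str,
    genes=None,
) -> TreatmentProfile:
    """Build a treatment's dual-baseline profile from contrast tables."""
    lfc_wt = vs_wt.lfc[treatment]
    lfc_tg = vs_tg.lfc[treatment]
    if genes is not None:
        idx = vs_wt.genes.intersection(pd.Index(sorted(genes)))
        lfc_wt, lfc_tg = lfc_wt.loc[idx], lfc_tg.loc[idx]
    return TreatmentProfile(treatment=treatment, lfc_vs_wt=lfc_wt, lfc_vs_tg=lfc_tg)


def profile_distance(p1: pd.Series, p2: pd.Series) -> float:
    """Mean absolute difference of two aligned log2FC vectors."""
    if len(p1) == 0:
        raise ValueError("profile distance over an empty gene subset")
    if len(p1) != len(p2) or not p1.index.equals(p2.index):
        raise ConsistencyError("profiles are not aligned on the same gene subset")
    return float(np.abs(p1.to_numpy() - p2.to_numpy()).mean())


def distance_from_wt(profile: TreatmentProfile, subset=None) -> float:
    """Distance of the versus-healthy profile from the all-zero profile."""
    vec = profile.lfc_vs_wt
    if subset is not None:
        keep = vec.index.intersection(pd.Index(sorted(subset)))
        if len(keep) == 0:
            raise ValueError("empty gene subset for distance from healthy state")
        vec = vec.loc[keep]
    return profile_distance(vec, pd.Series(0.0, index=vec.index))


def _magnitude(values: np.ndarray, mode: str) -> float:
    if mode == "mean_of_abs":
        return float(np.abs(values).mean())
    if mode == "abs_of_mean":
        return float(np.abs(values.mean()))
    raise ValueError(f"unknown efficiency mode {mode!r}")


def efficiency_score(
    profile: TreatmentProfile,
    category_genes,
    mode: str = "mean_of_abs",
    config: FrameworkConfig = _DEFAULT_CONFIG,
) -> float | None:
    """log10 ratio of disease-baseline over healthy-baseline magnitude.

    Evaluated over the category's genes within the profile's gene subset
    (callers restrict the profile to DE genes first).  Returns ``None`` if
    fewer than ``min_category_size`` genes qualify.  The denominator is
    guarded by ``epsilon`` and the score capped at +/-12 for reporting.
    """
    keep = profile.gene_subset.intersection(pd.Index(sorted(category_genes)))
    if len(keep) < config.min_category_size:
        log.warning(
            "category skipped for %s: %d genes < min_category_size=%d",
            profile.treatment, len(keep), config.min_category_size,
        )
        return None
    num = _magnitude(profile.lfc_vs_tg.loc[keep].to_numpy(), mode)
    den = _magnitude(profile.lfc_vs_wt.loc[keep].to_numpy(), mode)
    score = np.log10(max(num, config.epsilon) / max(den, config.epsilon))
    return float(np.clip(score, -SCORE_CAP, SCORE_CAP))


def category_2d_coordinates(
    profile: TreatmentProfile,
    annotation: AnnotationSet,
    de_genes,
    config: FrameworkConfig = _DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-category 2-D coordinates and efficiency scores for one treatment.

    For every category with at least ``min_category_size`` DE genes:
    x = mean log2FC versus healthy, y = mean log2FC versus disease over
    the category's DE genes, plus the efficiency score in the configured
    mode.  Small categories are skipped (logged), not an error.
    """
    de = frozenset(de_genes)
    rows = []
    for cid in annotation.ids():
        genes = annotation.members(cid) & de
        keep = profile.gene_subset.intersection(pd.Index(sorted(genes)))
        if len(keep) < config.min_category_size:
            continue
        sub = profile.restrict(keep)
        rows.append(
            {
                "category": cid,
                "name": annotation.name(cid),
                "treatment": profile.treatment,
                "n_genes": len(keep),
                "x_mean_lfc_vs_wt": float(sub.lfc_vs_wt.mean()),
                "y_mean_lfc_vs_tg": float(sub.lfc_vs_tg.mean()),
                "score": efficiency_score(sub, keep, config.efficiency_mode, config),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category", "name", "treatment", "n_genes",
            "x_mean_lfc_vs_wt", "y_mean_lfc_vs_tg", "score",
        ],
    )
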