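"""DE gene-set algebra: nested set collections, the per-treatment
restored / not-restored / altered trichotomy, and exclusive multi-set
intersections (UpSet semantics).

Three nested gene sets summarise a dual-baseline analysis:

* the *disease set* — genes DE between the disease control and the healthy
  control (the disease-associated profile);
* the *extended set* — genes DE versus the healthy control in the disease
  or in at least one treatment arm;
* the *full union* — genes DE versus either baseline in any comparison.

For each treatment arm the disease set splits into genes *restored* by the
arm (no longer DE versus healthy) and *not restored* (still DE), while
genes DE versus healthy only under that arm are *altered* — secondary,
non-disease effects of the intervention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .errors import ConsistencyError
from .study import DISEASE, TREATMENT
from .diffexpr import ContrastResult


@dataclass(frozen=True)
class DESetCollection:
    disease_set: frozenset[str]
    extended_wt_set: frozenset[str]
    full_union_set: frozenset[str]

    def __post_init__(self) -> None:
        if not (self.disease_set <= self.extended_wt_set <= self.full_union_set):
            raise ConsistencyError("DE set collection is not nested")


@dataclass(frozen=True)
class TrichotomyEntry:
    """Partition of DE genes for one treatment arm."""

    treatment: str
    restored: frozenset[str]
    not_restored: frozenset[str]
    altered: frozenset[str]


def _condition_with_role(result: ContrastResult, role: str) -> str:
    hits = [c for c in result.conditions if result.roles.get(c) == role]
    if len(hits) != 1:
        raise ConsistencyError(f"expected one {role} condition, found {hits}")
    return hits[0]


def build_de_sets(vs_wt: ContrastResult, vs_tg: ContrastResult) -> DESetCollection:
    """Assemble the three nested DE gene sets from the two contrast tables."""
    if not vs_wt.genes.equals(vs_tg.genes):
        raise ConsistencyError("contrast results do not share a gene universe")
    disease_cond = _condition_with_role(vs_wt, DISEASE)
    treatments = [c for c in vs_wt.conditions if vs_wt.roles.get(c) == TREATMENT]

    disease = vs_wt.de_genes(disease_cond)
    extended = set(disease)
    for t in treatments:
        extended |= vs_wt.de_genes(t)
    full = set(extended)
    for c in vs_tg.conditions:
        full |= vs_tg.de_genes(c)
    return DESetCollection(
        disease_set=disease,
        extended_wt_set=frozenset(extended),
        full_union_set=frozenset(full),
    )


def trichotomize(
    disease_set: frozenset[str] | set[str],
    treatment_de_vs_wt: frozenset[str] | set[str],
    treatment: str,
    treatment_de_vs_tg: frozenset[str] | set[str] | None = None,
) -> TrichotomyEntry:
    """Split genes into restored / not-restored / altered for one arm.

    restored = disease genes no longer DE vs healthy under the arm;
    not_restored = disease genes still DE vs healthy; altered = arm's
    DE-vs-healthy genes outside the disease set.  If ``treatment_de_vs_tg``
    is given, genes DE only versus the disease control are additionally
    counted as altered (the more inclusive reading).
    """
    disease = frozenset(disease_set)
    de_wt = frozenset(treatment_de_vs_wt)
    altered = de_wt - disease
    if treatment_de_vs_tg is not None:
        altered |= frozenset(treatment_de_vs_tg) - disease
    return TrichotomyEntry(
        treatment=treatment,
        restored=disease - de_wt,
        not_restored=disease & de_wt,
        altered=frozenset(altered),
    )


def trichotomy_all(
    vs_wt: ContrastResult,
    disease_set: frozenset[str] | set[str] | None = None,
    vs_tg: ContrastResult | None = None,
) -> dict[str, TrichotomyEntry]:
    """Per-treatment trichotomy from a versus-healthy contrast table.

    ``disease_set`` defaults to the disease-control column's DE genes.
    Passing ``vs_tg`` switches on the inclusive "altered" mode.
    """
    if disease_set is None:
        disease_set = vs_wt.de_genes(_condition_with_role(vs_wt, DISEASE))
    treatments = [c for c in vs_wt.conditions if vs_wt.roles.get(c) == TREATMENT]
    out: dict[str, TrichotomyEntry] = {}
    for t in treatments:
        de_tg = vs_tg.de_genes(t) if vs_tg is not None else None
        out[t] = trichotomize(disease_set, vs_wt.de_genes(t), t, de_tg)
    return out


def exclusive_intersections(
    named_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], int]:
    """Exclusive (UpSet) intersection counts for a family of named sets.

    Returns, for every non-empty combination of set labels (as a sorted
    tuple), the number of elements belonging to exactly those sets and no
    other.  Counts over all combinations sum to the size of the union.
    """
    if not named_sets:
        raise ValueError("need at least one named set")
    labels = sorted(named_sets)
    sets = {lab: frozenset(named_sets[lab]) for lab in labels}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            counts[combo] = 0
    for element in frozenset().union(*sets.values()):
        signature = tuple(lab for lab in labels if element in sets[lab])
        counts[signature] += 1
    return counts


def pairwise_overlaps(
    named_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, str], int]:
    """Total (non-exclusive) pairwise overlap sizes |A ∩ B|."""
    labels = sorted(named_sets)
    sets = {lab: frozenset(named_sets[lab]) for lab in labels}
    return {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(labels, 2)
    }
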