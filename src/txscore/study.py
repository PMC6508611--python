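"""Central data model and I/O for expression studies and gene-set annotations.

An :class:`ExpressionStudy` couples a log2-scale gene-by-sample expression
matrix with the sample design: every sample belongs to one condition, and
exactly one condition plays the role of healthy control (e.g. wild-type
littermates) and exactly one the role of disease control (e.g. untreated
transgenic animals).  All remaining conditions are treatment arms.  The
dual-baseline analyses downstream rely on those two anchor conditions.

Functional categories (GO terms, KEGG pathways, transcription-factor target
sets, ...) are held in an :class:`AnnotationSet` loaded from standard GMT
files and pre-intersected with the study's measured gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

log = logging.getLogger(__name__)

HEALTHY = "healthy_control"
DISEASE = "disease_control"
TREATMENT = "treatment"

_ROLES = {HEALTHY, DISEASE, TREATMENT}
_TIMINGS = {"prophylactic", "therapeutic", "none"}


@dataclass
class ExpressionStudy:
    """A validated log2 expression matrix plus its sample design.

    Attributes
    ----------
    matrix
        Genes (rows) by samples (columns), log2 scale, no missing values.
    design
        Series mapping sample identifier to condition label.
    roles
        Mapping condition -> role (``healthy_control`` / ``disease_control``
        / ``treatment``).
    timing
        Optional mapping condition -> intervention timing
        (``prophylactic`` / ``therapeutic`` / ``none``).
    """

    matrix: pd.DataFrame
    design: pd.Series
    roles: dict[str, str]
    timing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if self.matrix.columns.duplicated().any():
            dup = self.matrix.columns[self.matrix.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        mat_samples = set(self.matrix.columns)
        design_samples = set(self.design.index)
        if mat_samples != design_samples:
            missing = sorted(mat_samples ^ design_samples)
            raise FormatError(
                f"samples present in only one of matrix/design: {missing}"
            )
        if self.matrix.isna().any().any():
            raise FormatError("matrix contains missing values after load")
        conditions = set(self.design)
        unknown = conditions - set(self.roles)
        if unknown:
            raise DesignError(f"conditions without a role: {sorted(unknown)}")
        bad = {r for r in self.roles.values() if r not in _ROLES}
        if bad:
            raise DesignError(f"unknown roles {sorted(bad)}; expected {sorted(_ROLES)}")
        for want in (HEALTHY, DISEASE):
            found = [c for c in conditions if self.roles[c] == want]
            if len(found) != 1:
                raise DesignError(
                    f"need exactly one {want} condition, found {len(found)}"
                )

    # -- accessors ------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def healthy_control(self) -> str:
        return next(c for c in self.conditions if self.roles[c] == HEALTHY)

    @property
    def disease_control(self) -> str:
        return next(c for c in self.conditions if self.roles[c] == DISEASE)

    @property
    def treatments(self) -> list[str]:
        return [c for c in self.conditions if self.roles[c] == TREATMENT]

    def samples_of(self, condition: str) -> list[str]:
        if condition not in self.roles:
            raise DesignError(f"unknown condition {condition!r}")
        return [s for s, c in self.design.items() if c == condition]

    def values_of(self, condition: str) -> np.ndarray:
        """Expression submatrix (genes x replicates) of one condition."""
        return self.matrix[self.samples_of(condition)].to_numpy()

    def subset_conditions(self, conditions: Iterable[str]) -> "ExpressionStudy":
        keep = list(conditions)
        samples = [s for s, c in self.design.items() if c in keep]
        return ExpressionStudy(
            matrix=self.matrix[samples],
            design=self.design.loc[samples],
            roles={c: r for c, r in self.roles.items() if c in keep},
            timing={c: t for c, t in self.timing.items() if c in keep},
        )


@dataclass
class AnnotationSet:
    """Functional categories over a gene universe.

    ``categories`` maps category id -> (display name, member gene set);
    members are expected to be pre-intersected with the study universe.
    """

    categories: dict[str, tuple[str, frozenset[str]]]
    namespace: str = ""

    def __len__(self) -> int:
        return len(self.categories)

    def __contains__(self, cid: str) -> bool:
        return cid in self.categories

    def members(self, cid: str) -> frozenset[str]:
        return self.categories[cid][1]

    def name(self, cid: str) -> str:
        return self.categories[cid][0]

    def ids(self) -> list[str]:
        return list(self.categories)

    def restrict(self, universe: set[str], min_size: int = 1) -> "AnnotationSet":
        """Intersect every category with ``universe``; drop small ones."""
        out: dict[str, tuple[str, frozenset[str]]] = {}
        dropped = 0
        for cid, (name, members) in self.categories.items():
            kept = frozenset(members & universe)
            if len(kept) >= min_size:
                out[cid] = (name, kept)
            else:
                dropped += 1
        if dropped:
            log.warning(
                "dropped %d/%d categories below %d genes after universe intersection",
                dropped, len(self.categories), min_size,
            )
        return AnnotationSet(categories=out, namespace=self.namespace)


# ---------------------------------------------------------------------------
# loaders


def load_expression_study(
    matrix_path: str | Path,
    design_path: str | Path,
    transpose: bool = False,
) -> ExpressionStudy:
    """Load a TSV expression matrix and a sample sheet into a study.

    The matrix is tab-separated with gene identifiers in the first column
    and a header row of sample identifiers (use ``transpose=True`` for the
    samples-in-rows dialect).  The sample sheet has columns ``sample``,
    ``condition``, ``role`` and optionally ``timing``.  Gene rows with any
    missing value are dropped and counted in the log, so downstream code
    always sees a complete matrix.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if transpose:
        matrix = matrix.T
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    sheet = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample", "condition", "role"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet needs columns {sorted(required)}, got {list(sheet.columns)}"
        )
    if sheet["sample"].duplicated().any():
        dup = sheet.loc[sheet["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"duplicate sample {dup!r} in sample sheet")

    design = pd.Series(
        sheet["condition"].to_numpy(), index=pd.Index(sheet["sample"], name="sample")
    )
    roles: dict[str, str] = {}
    for cond, sub in sheet.groupby("condition"):
        uniq = set(sub["role"])
        if len(uniq) != 1:
            raise DesignError(f"condition {cond!r} has conflicting roles {sorted(uniq)}")
        roles[str(cond)] = uniq.pop()
    timing: dict[str, str] = {}
    if "timing" in sheet.columns:
        for cond, sub in sheet.groupby("condition"):
            uniq = {t for t in sub["timing"] if isinstance(t, str) and t}
            if len(uniq) > 1:
                raise DesignError(
                    f"condition {cond!r} has conflicting timings {sorted(uniq)}"
                )
            timing[str(cond)] = uniq.pop() if uniq else "none"

    complete = matrix.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d gene rows with missing values", n_dropped)
        matrix = matrix.loc[complete]
    matrix = matrix.astype(float)

    return ExpressionStudy(matrix=matrix, design=design, roles=roles, timing=timing)


def load_gmt(
    path: str | Path,
    universe: set[str] | None = None,
    min_category_size: int = 1,
    namespace: str = "",
) -> AnnotationSet:
    """Parse a GMT file (id, description, member genes per tab-separated line).

    Members are intersected with ``universe`` when given; categories with
    fewer than ``min_category_size`` surviving members are dropped with a
    warning.
    """
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            cid, desc, members = fields[0], fields[1], fields[2:]
            if cid in categories:
                raise FormatError(f"{path}:{lineno}: duplicate category id {cid!r}")
            categories[cid] = (desc, frozenset(m for m in members if m))
            n_lines += 1
    annot = AnnotationSet(categories=categories, namespace=namespace)
    if not n_lines:
        log.warning("GMT file %s is empty", path)
    if universe is not None:
        annot = annot.restrict(set(universe), min_size=min_category_size)
    log.info("loaded %d categories from %s (%d kept)", n_lines, path, len(annot))
    return annot


def write_gmt(annot: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(annot.categories):
            name, members = annot.categories[cid]
            fh.write("\t".join([cid, name, *sorted(members)]) + "\n")


def write_table(records: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a result table as TSV: sorted rows, 6 significant digits.

    Sorting by the primary key (defaults to all non-float columns, falling
    back to the first column) makes output byte-deterministic regardless of
    insertion order.
    """
    df = records.copy()
    if sort_by is None:
        sort_by = [c for c in df.columns if not pd.api.types.is_float_dtype(df[c])]
        if not sort_by:
            sort_by = [df.columns[0]]
    if len(df):
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
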