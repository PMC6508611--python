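"""Synthetic studies with the statistical structure the framework assumes.

The generator emulates a two-control drug-intervention transcriptome
study: a healthy control arm, a diseased control arm carrying planted
over- and under-expressed gene blocks, and several treatment arms that
each restore a fraction of the disease blocks to healthy levels, reverse a
(usually small) fraction past the healthy level to the opposite sign, and
displace a treatment-specific "altered" block that is untouched in
disease.  Expression is independent Gaussian on the log2 scale around
gene-specific baselines drawn Uniform(4, 12).

Which disease genes an arm fails to restore is governed by a shared
per-gene *difficulty* score with small arm-specific jitter: every arm
restores its easiest genes first, so hard genes are left unrestored by
several arms at once — matching the heavily overlapping not-restored sets
seen in real multi-arm studies — while the jitter keeps the sets from
being strictly nested.

:func:`reference_truth` encodes the reference study design: 404 planted
over- and 463 under-expressed disease genes, five anti-TNF arms (one
prophylactic with 3 replicates, four therapeutic with 10), 10 healthy and
13 diseased replicates (66 samples), arm-specific not-restored counts
(3 / 25 / 92 / 106 / 175) and altered blocks (170 / 0 / 30 / 217 / 175,
with a 40-gene overlap between the two largest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study import AnnotationSet, ExpressionStudy, HEALTHY, DISEASE, TREATMENT


@dataclass(frozen=True)
class ArmTruth:
    """Planted behaviour of one treatment arm.

    ``restoration`` and ``reversal`` map direction (``up``/``down``) to
    the fraction of that disease block restored to healthy mean or flipped
    to the opposite sign; the remainder stays at the diseased level.
    ``altered`` is the arm-specific block displaced only under this arm.
    """

    restoration: dict[str, float]
    reversal: dict[str, float]
    altered: frozenset[str]
    timing: str = "therapeutic"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic study."""

    disease_up: frozenset[str]
    disease_down: frozenset[str]
    arms: dict[str, ArmTruth]
    group_sizes: dict[str, int]
    healthy_condition: str = "wild_type"
    disease_condition: str = "transgenic"
    effect_size: float = 2.5
    noise_sd: float = 0.25
    difficulty_jitter: float = 0.15
    n_decoy_categories: int = 50
    decoy_size_range: tuple[int, int] = (10, 200)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.disease_up & self.disease_down:
            raise ValueError("disease_up and disease_down overlap")
        disease = self.disease_up | self.disease_down
        for name, arm in self.arms.items():
            if arm.altered & disease:
                raise ValueError(f"altered block of {name!r} overlaps disease genes")
            for d in ("up", "down"):
                r, v = arm.restoration[d], arm.reversal[d]
                if not (0.0 <= r <= 1.0 and 0.0 <= v <= 1.0 and r + v <= 1.0 + 1e-12):
                    raise ValueError(
                        f"{name!r}/{d}: restoration {r} + reversal {v} invalid"
                    )
        for cond in (self.healthy_condition, self.disease_condition, *self.arms):
            if self.group_sizes.get(cond, 0) < 1:
                raise ValueError(f"missing replicate count for condition {cond!r}")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")

    @property
    def planted_genes(self) -> frozenset[str]:
        out = self.disease_up | self.disease_down
        for arm in self.arms.values():
            out |= arm.altered
        return frozenset(out)

    def category_map(self) -> dict[str, frozenset[str]]:
        """Planted alignment of functional categories to gene blocks.

        The disease blocks are additionally split into 3 over- and 5
        under-expressed sub-blocks, mirroring a typical cluster structure.
        """
        out: dict[str, frozenset[str]] = {
            "DISEASE_UP": self.disease_up,
            "DISEASE_DOWN": self.disease_down,
        }
        for prefix, block, parts in (
            ("UP", sorted(self.disease_up), 3),
            ("DOWN", sorted(self.disease_down), 5),
        ):
            for i, chunk in enumerate(np.array_split(np.array(block), parts), start=1):
                out[f"{prefix}_{i}"] = frozenset(chunk.tolist())
        for name, arm in self.arms.items():
            if arm.altered:
                out[f"ALTERED_{name}"] = arm.altered
        return out


@dataclass(frozen=True)
class ArmRealization:
    restored: frozenset[str]
    not_restored: frozenset[str]      # remain-at-disease plus reversed
    reversed_: frozenset[str]         # subset of not_restored
    altered: frozenset[str]


def realize_truth(truth: SyntheticTruth, seed: int) -> dict[str, ArmRealization]:
    """Deterministically assign per-arm restored / reversed gene sets.

    Each disease gene receives a difficulty score per direction; an arm's
    not-restored genes are the hardest ones under its jittered copy of the
    scores, and the reversed genes are the hardest of those.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    blocks = {"up": sorted(truth.disease_up), "down": sorted(truth.disease_down)}
    difficulty = {d: rng.random(len(blocks[d])) for d in blocks}
    out: dict[str, ArmRealization] = {}
    for name, arm in truth.arms.items():
        restored: set[str] = set()
        not_restored: set[str] = set()
        reversed_: set[str] = set()
        for d, genes in blocks.items():
            n = len(genes)
            scores = difficulty[d] + truth.difficulty_jitter * rng.standard_normal(n)
            order = np.argsort(scores, kind="stable")
            n_restored = int(round(arm.restoration[d] * n))
            n_reversed = int(round(arm.reversal[d] * n))
            easy = [genes[i] for i in order[:n_restored]]
            hard = [genes[i] for i in order[n_restored:]]
            restored.update(easy)
            not_restored.update(hard)
            reversed_.update(hard[len(hard) - n_reversed:])
        out[name] = ArmRealization(
            restored=frozenset(restored),
            not_restored=frozenset(not_restored),
            reversed_=frozenset(reversed_),
            altered=arm.altered,
        )
    return out


def _background_ids(truth: SyntheticTruth, n_genes: int) -> list[str]:
    planted = sorted(truth.planted_genes)
    if n_genes < len(planted):
        raise ValueError(
            f"n_genes={n_genes} smaller than the {len(planted)} planted genes"
        )
    background = [f"BG{i:05d}" for i in range(n_genes - len(planted))]
    clash = set(background) & set(planted)
    if clash:
        raise ValueError(f"background ids collide with planted genes: {sorted(clash)[:5]}")
    return planted + background


def generate_study(
    truth: SyntheticTruth, n_genes: int, seed: int
) -> tuple[ExpressionStudy, AnnotationSet]:
    """Simulate a complete study plus block-aligned functional categories.

    Identical ``(truth, n_genes, seed)`` yield byte-identical output.  The
    annotation contains the planted category map plus decoy categories of
    random genes so that enrichment specificity is testable.
    """
    genes = _background_ids(truth, n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    realization = realize_truth(truth, seed)

    root = np.random.SeedSequence([seed, 202])
    rng_mu, rng_noise, rng_sign, rng_decoy = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    mu = rng_mu.uniform(4.0, 12.0, size=n_genes)
    sign = np.zeros(n_genes)
    for g in truth.disease_up:
        sign[gene_pos[g]] = 1.0
    for g in truth.disease_down:
        sign[gene_pos[g]] = -1.0

    conditions = [truth.healthy_condition, truth.disease_condition, *truth.arms]
    cond_mean: dict[str, np.ndarray] = {
        truth.healthy_condition: mu,
        truth.disease_condition: mu + sign * truth.effect_size,
    }
    for name, arm in truth.arms.items():
        real = realization[name]
        mean = mu + sign * truth.effect_size        # start at diseased level
        for g in real.restored:
            mean[gene_pos[g]] = mu[gene_pos[g]]
        for g in real.reversed_:
            i = gene_pos[g]
            mean[i] = mu[i] - sign[i] * truth.effect_size
        alt_sign = rng_sign.choice([-1.0, 1.0], size=len(arm.altered))
        for s, g in zip(alt_sign, sorted(arm.altered)):
            i = gene_pos[g]
            mean[i] = mu[i] + s * truth.effect_size
        cond_mean[name] = mean

    columns: list[str] = []
    data: list[np.ndarray] = []
    design_rows: list[tuple[str, str]] = []
    for cond in conditions:
        for rep in range(truth.group_sizes[cond]):
            sample = f"{cond}_{rep + 1:02d}"
            columns.append(sample)
            design_rows.append((sample, cond))
            data.append(
                cond_mean[cond] + truth.noise_sd * rng_noise.standard_normal(n_genes)
            )
    matrix = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene"), columns=columns
    )
    design = pd.Series(
        {s: c for s, c in design_rows}, name="condition"
    ).loc[columns]
    design.index.name = "sample"
    roles = {truth.healthy_condition: HEALTHY, truth.disease_condition: DISEASE}
    timing = {truth.healthy_condition: "none", truth.disease_condition: "none"}
    for name, arm in truth.arms.items():
        roles[name] = TREATMENT
        timing[name] = arm.timing
    study = ExpressionStudy(matrix=matrix, design=design, roles=roles, timing=timing)

    categories: dict[str, tuple[str, frozenset[str]]] = {
        cid: (cid.replace("_", " ").lower(), members)
        for cid, members in truth.category_map().items()
    }
    lo, hi = truth.decoy_size_range
    for i in range(truth.n_decoy_categories):
        size = int(rng_decoy.integers(lo, hi + 1))
        members = rng_decoy.choice(n_genes, size=size, replace=False)
        cid = f"DECOY_{i + 1:03d}"
        categories[cid] = (cid.lower(), frozenset(genes[j] for j in members))
    annotation = AnnotationSet(categories=categories, namespace="SYNTH")
    return study, annotation


def expected_trichotomy(
    realization: dict[str, ArmRealization],
) -> dict[str, dict[str, frozenset[str]]]:
    """Planted restored / not-restored / altered sets per arm.

    Reversed genes sit at the mirror image of the diseased level, hence
    remain differentially expressed versus healthy and count as not
    restored.
    """
    return {
        name: {
            "restored": real.restored,
            "not_restored": real.not_restored,
            "altered": real.altered,
        }
        for name, real in realization.items()
    }


# ---------------------------------------------------------------------------
# reference designs


def _ids(prefix: str, start: int, count: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(start, start + count)]


def reference_truth(
    effect_size: float = 2.5, noise_sd: float = 0.25
) -> SyntheticTruth:
    """The reference anti-TNF study design as a ready-made ground truth.

    Five arms over 404 over- / 463 under-expressed disease genes; the
    prophylactic-like arm restores nearly everything but reverses its few
    failures, while the therapeutic arms leave progressively larger
    fractions unrestored.  Arm altered-block sizes are 170 / 0 / 30 /
    217 / 175, the two largest sharing 40 genes.
    """
    up = _ids("G", 1, 404)
    down = _ids("G", 405, 463)
    alt_ip = _ids("G", 868, 170)
    alt_ada = _ids("G", 1038, 30)
    alt_eta = _ids("G", 1068, 217)
    alt_cert = alt_eta[-40:] + _ids("G", 1285, 135)

    def frac(nr_up: int, nr_down: int) -> dict[str, float]:
        return {"up": 1.0 - nr_up / 404.0, "down": 1.0 - nr_down / 463.0}

    arms = {
        "infliximab_prophylactic": ArmTruth(
            restoration=frac(1, 2),
            reversal={"up": 1.0 / 404.0, "down": 2.0 / 463.0},
            altered=frozenset(alt_ip),
            timing="prophylactic",
        ),
        "infliximab_therapeutic": ArmTruth(
            restoration=frac(12, 13),
            reversal={"up": 0.0, "down": 0.0},
            altered=frozenset(),
        ),
        "adalimumab": ArmTruth(
            restoration=frac(43, 49),
            reversal={"up": 0.0, "down": 0.0},
            altered=frozenset(alt_ada),
        ),
        "etanercept": ArmTruth(
            restoration=frac(49, 57),
            reversal={"up": 0.0, "down": 0.0},
            altered=frozenset(alt_eta),
        ),
        "certolizumab": ArmTruth(
            restoration=frac(82, 93),
            reversal={"up": 0.0, "down": 0.0},
            altered=frozenset(alt_cert),
        ),
    }
    group_sizes = {
        "wild_type": 10,
        "transgenic": 13,
        "infliximab_prophylactic": 3,
        "infliximab_therapeutic": 10,
        "adalimumab": 10,
        "etanercept": 10,
        "certolizumab": 10,
    }
    return SyntheticTruth(
        disease_up=frozenset(up),
        disease_down=frozenset(down),
        arms=arms,
        group_sizes=group_sizes,
        effect_size=effect_size,
        noise_sd=noise_sd,
    )


def null_truth(noise_sd: float = 0.25) -> SyntheticTruth:
    """The reference design with every planted effect switched off."""
    return reference_truth(effect_size=0.0, noise_sd=noise_sd)
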