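import numpy as np
import pandas as pd
import pytest

from txscore import ArmTruth, ExpressionStudy, SyntheticTruth
from txscore.diffexpr import ContrastResult


def make_study(matrix, design, roles, timing=None):
    return ExpressionStudy(
        matrix=matrix, design=pd.Series(design), roles=roles, timing=timing or {}
    )


@pytest.fixture
def toy_study():
    """Deterministic 6-gene study: healthy + disease controls + 2 arms.

    Gene g1 is planted up in disease and restored by arm_a only; g2 is a
    flat (zero-variance) gene.
    """
    rng = np.random.default_rng(7)
    conditions = {"wt": 4, "tg": 4, "arm_a": 4, "arm_b": 4}
    samples, design = [], {}
    for cond, n in conditions.items():
        for i in range(n):
            s = f"{cond}{i}"
            samples.append(s)
            design[s] = cond
    genes = [f"g{i}" for i in range(1, 7)]
    base = rng.uniform(5, 9, size=len(genes))
    data = {}
    for s in samples:
        cond = design[s]
        mu = base.copy()
        if cond in ("tg", "arm_b"):
            mu[0] += 3.0  # g1 up in disease, not restored by arm_b
        data[s] = mu + rng.normal(0, 0.15, size=len(genes))
    matrix = pd.DataFrame(data, index=genes)
    matrix.loc["g2"] = 5.0  # zero variance everywhere
    roles = {"wt": "healthy_control", "tg": "disease_control",
             "arm_a": "treatment", "arm_b": "treatment"}
    return make_study(matrix, design, roles)


def contrast_from_sets(baseline, universe, de_sets, roles):
    """Build a ContrastResult whose DE calls equal the given per-condition sets."""
    genes = pd.Index(sorted(universe))
    conditions = list(de_sets)
    lfc = pd.DataFrame(0.0, index=genes, columns=conditions)
    adj = pd.DataFrame(1.0, index=genes, columns=conditions)
    for cond, de in de_sets.items():
        for g in de:
            lfc.loc[g, cond] = 2.0
            adj.loc[g, cond] = 0.01
    return ContrastResult(
        baseline=baseline, lfc=lfc, raw_p=adj.copy(), adj_p=adj, roles=roles
    )


def small_truth(effect_size=2.5, noise_sd=0.25):
    """Scaled-down two-control design: 3 arms over 20 up / 24 down genes."""
    up = [f"U{i:03d}" for i in range(20)]
    down = [f"D{i:03d}" for i in range(24)]
    alt_a = frozenset(f"A{i:03d}" for i in range(8))
    alt_c = frozenset(f"C{i:03d}" for i in range(12))
    arms = {
        "arm_early": ArmTruth(
            restoration={"up": 0.95, "down": 0.95},
            reversal={"up": 0.05, "down": 0.05},
            altered=alt_a, timing="prophylactic",
        ),
        "arm_mid": ArmTruth(
            restoration={"up": 0.8, "down": 0.8},
            reversal={"up": 0.0, "down": 0.0},
            altered=frozenset(),
        ),
        "arm_late": ArmTruth(
            restoration={"up": 0.5, "down": 0.5},
            reversal={"up": 0.0, "down": 0.0},
            altered=alt_c,
        ),
    }
    group_sizes = {"wild_type": 6, "transgenic": 6,
                   "arm_early": 4, "arm_mid": 6, "arm_late": 6}
    return SyntheticTruth(
        disease_up=frozenset(up), disease_down=frozenset(down),
        arms=arms, group_sizes=group_sizes,
        effect_size=effect_size, noise_sd=noise_sd,
        n_decoy_categories=10, decoy_size_range=(5, 30),
    )
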