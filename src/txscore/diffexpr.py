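"""Dual-baseline differential expression: one-way ANOVA with Dunnett's test.

For every gene, expression is modelled as a one-way layout across all study
conditions with a common (pooled) residual variance.  Each non-baseline
condition is compared against the chosen baseline with Dunnett's
many-to-one procedure: the per-comparison statistic is the usual pooled
two-sample t

    t_j = (mean_j - mean_0) / sqrt(MSE * (1/n_j + 1/n_0)),

and the family-wise adjusted p-value is P(max_j |T_j| >= |t|) under the
global null, where (T_1 .. T_m) follow the correlated multivariate-t law
induced by the shared control mean and pooled variance estimate.  Because
the design (group sizes, residual degrees of freedom) is identical for all
genes, that null distribution is computed once per contrast by numerical
quadrature and applied to every gene, which makes a ~19k-gene analysis
essentially free.

Fold-changes are differences of group means, since the matrix is already on
log2 scale.  The study is analysed against both anchors — the healthy
control and the disease control — giving the two contrast tables that all
downstream set, distance and efficiency analyses consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .config import FrameworkConfig
from .errors import DesignError
from .study import ExpressionStudy

log = logging.getLogger(__name__)

_DEFAULT_CONFIG = FrameworkConfig()

_NULL_CACHE: dict[tuple, "DunnettNull"] = {}


def _get_null(n_groups: tuple[int, ...], n_control: int, df: int) -> "DunnettNull":
    """Memoised null distribution; identical designs share one table."""
    key = (tuple(sorted(n_groups)), n_control, df)
    if key not in _NULL_CACHE:
        _NULL_CACHE[key] = DunnettNull(np.array(key[0]), n_control, df)
    return _NULL_CACHE[key]


# ---------------------------------------------------------------------------
# Dunnett max-|T| null distribution


class DunnettNull:
    """Null distribution of max_j |T_j| for many-to-one comparisons.

    Conditioning on the control-group z-score and on the pooled scale
    estimate makes the m comparison statistics independent, so the CDF is a
    double integral of a product of normal-CDF differences:

        F(q) = E_{Z0, U} prod_j [ Phi(b_j) - Phi(a_j) ],

    with Z0 ~ N(0,1), U = S/sigma (sqrt of a scaled chi-square with the
    residual df) and integration limits determined by q and the group
    sizes.  The integral is evaluated with Gauss-Hermite (control mean) and
    Gauss-Legendre in probability space (scale) nodes; the survival
    function used for p-values is a monotone interpolant of 1 - F on a
    fine grid.  With a single comparison the exact two-sided t survival
    function is used instead.
    """

    def __init__(
        self,
        n_groups: np.ndarray,
        n_control: int,
        df: int,
        n_z: int = 48,
        n_u: int = 48,
        q_max: float = 40.0,
        n_grid: int = 1500,
    ) -> None:
        self.n_groups = np.asarray(n_groups, dtype=float)
        self.n_control = float(n_control)
        self.df = int(df)
        self.m = len(self.n_groups)
        if self.m == 1:
            self._interp = None
            return

        # Gauss-Hermite for the standard-normal control mean
        xh, wh = hermgauss(n_z)
        z_nodes = np.sqrt(2.0) * xh           # (n_z,)
        z_weights = wh / np.sqrt(np.pi)
        # Gauss-Legendre in probability space for U = S/sigma
        xl, wl = leggauss(n_u)
        p_nodes = 0.5 * (xl + 1.0)
        p_weights = 0.5 * wl
        u_nodes = np.sqrt(stats.chi2.ppf(p_nodes, self.df) / self.df)  # (n_u,)

        grid = np.concatenate([[0.0], np.geomspace(1e-3, q_max, n_grid - 1)])
        a = np.sqrt(1.0 / self.n_groups + 1.0 / self.n_control)  # (m,)
        q = grid[:, None, None]                                   # (nq,1,1)
        z = z_nodes[None, :, None]
        u = u_nodes[None, None, :]
        prod = np.ones((len(grid), n_z, n_u))
        shift = z / np.sqrt(self.n_control)
        for j in range(self.m):
            half = q * u * a[j]
            sj = np.sqrt(self.n_groups[j])
            prod *= ndtr(sj * (shift + half)) - ndtr(sj * (shift - half))
        cdf = np.tensordot(
            np.tensordot(prod, z_weights, axes=([1], [0])), p_weights, axes=([1], [0])
        )
        cdf = np.clip(np.maximum.accumulate(cdf), 0.0, 1.0)
        self._grid = grid
        self._interp = PchipInterpolator(grid, cdf, extrapolate=False)

    def sf(self, q: np.ndarray) -> np.ndarray:
        """Family-wise p-value P(max_j |T_j| >= q)."""
        q = np.abs(np.asarray(q, dtype=float))
        if self.m == 1:
            return np.clip(2.0 * stats.t.sf(q, self.df), 0.0, 1.0)
        out = np.empty_like(q, dtype=float)
        inside = q <= self._grid[-1]
        out[inside] = 1.0 - self._interp(q[inside])
        out[~inside] = 0.0
        out[np.isinf(q)] = 0.0
        return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# contrast result container


@dataclass
class ContrastResult:
    """Per-gene statistics for every condition versus one baseline.

    ``lfc``, ``raw_p`` and ``adj_p`` are genes x conditions frames sharing
    an identical index (the gene universe) and columns (all non-baseline
    conditions).  ``adj_p`` carries the Dunnett family-wise adjustment
    within each gene; an optional Benjamini-Hochberg pass across genes can
    be layered on top via the configuration.
    """

    baseline: str
    lfc: pd.DataFrame
    raw_p: pd.DataFrame
    adj_p: pd.DataFrame
    roles: dict[str, str]
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    timing: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.lfc.index

    @property
    def conditions(self) -> list[str]:
        return list(self.lfc.columns)

    def de_mask(self) -> pd.DataFrame:
        """Boolean frame: DE iff |log2FC| >= threshold and adj_p <= threshold."""
        return (self.lfc.abs() >= self.lfc_threshold) & (self.adj_p <= self.p_threshold)

    def de_genes(self, condition: str) -> frozenset[str]:
        if condition not in self.lfc.columns:
            raise DesignError(f"no contrast for condition {condition!r}")
        mask = self.de_mask()[condition]
        return frozenset(mask.index[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, condition, log2FC, raw_p, adj_p, de."""
        de = self.de_mask()
        rows = []
        for cond in self.lfc.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.lfc.index,
                        "condition": cond,
                        "baseline": self.baseline,
                        "log2FC": self.lfc[cond].to_numpy(),
                        "raw_p": self.raw_p[cond].to_numpy(),
                        "adj_p": self.adj_p[cond].to_numpy(),
                        "de": de[cond].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# operations


def log2fc_profile(study: ExpressionStudy, condition: str, baseline: str) -> pd.Series:
    """Per-gene log2 fold-change: mean(condition) - mean(baseline).

    Values are already log2 scale, so the fold-change is a difference of
    group means; a condition against itself is exactly zero.
    """
    for label in (condition, baseline):
        if label not in study.roles:
            raise DesignError(f"unknown condition {label!r}")
    cond_mean = study.values_of(condition).mean(axis=1)
    base_mean = study.values_of(baseline).mean(axis=1)
    return pd.Series(cond_mean - base_mean, index=study.genes, name=condition)


def anova_dunnett(
    study: ExpressionStudy,
    baseline: str,
    config: FrameworkConfig = _DEFAULT_CONFIG,
) -> ContrastResult:
    """One-way ANOVA + Dunnett many-to-one comparisons against ``baseline``.

    Returns per-gene log2FC, raw two-sided pooled-t p-values and Dunnett
    family-wise adjusted p-values for every non-baseline condition.  Genes
    with zero total variance are defined non-significant (p = 1, lfc = 0).
    """
    if baseline not in study.roles:
        raise DesignError(f"unknown baseline condition {baseline!r}")
    conditions = [c for c in study.conditions if c != baseline]
    groups = [baseline] + conditions
    for c in groups:
        if len(study.samples_of(c)) < 2:
            raise DesignError(f"condition {c!r} has fewer than 2 samples")

    values = {c: study.values_of(c) for c in groups}
    n = {c: values[c].shape[1] for c in groups}
    means = {c: values[c].mean(axis=1) for c in groups}
    n_total = sum(n.values())
    df = n_total - len(groups)

    sse = np.zeros(len(study.genes))
    for c in groups:
        sse += ((values[c] - means[c][:, None]) ** 2).sum(axis=1)
    mse = sse / df

    total = np.concatenate([values[c] for c in groups], axis=1)
    zero_var = total.var(axis=1) == 0.0

    null = _get_null(tuple(n[c] for c in conditions), n[baseline], df)

    lfc = pd.DataFrame(index=study.genes, columns=conditions, dtype=float)
    raw = pd.DataFrame(index=study.genes, columns=conditions, dtype=float)
    adj = pd.DataFrame(index=study.genes, columns=conditions, dtype=float)
    for c in conditions:
        diff = means[c] - means[baseline]
        se = np.sqrt(mse * (1.0 / n[c] + 1.0 / n[baseline]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        # zero residual variance with a real mean difference: infinitely
        # significant; with no difference: t = 0
        degenerate = se == 0.0
        if degenerate.any():
            d = diff[degenerate]
            t[degenerate] = np.where(d > 0, np.inf, np.where(d < 0, -np.inf, 0.0))
        raw_p = np.clip(2.0 * stats.t.sf(np.abs(t), df), 0.0, 1.0)
        adj_p = null.sf(t)
        lfc[c] = np.where(zero_var, 0.0, diff)
        raw[c] = np.where(zero_var, 1.0, raw_p)
        adj[c] = np.where(zero_var, 1.0, np.maximum(adj_p, raw_p))

    if config.bh_across_genes:
        for c in conditions:
            adj[c] = multipletests(adj[c].to_numpy(), method="fdr_bh")[1]

    return ContrastResult(
        baseline=baseline,
        lfc=lfc,
        raw_p=raw,
        adj_p=adj,
        roles=dict(study.roles),
        lfc_threshold=config.lfc_threshold,
        p_threshold=config.p_threshold,
        timing=dict(study.timing),
    )


def dual_baseline(
    study: ExpressionStudy,
    config: FrameworkConfig = _DEFAULT_CONFIG,
) -> tuple[ContrastResult, ContrastResult]:
    """Contrast every condition against both the healthy and disease controls.

    Returns ``(vs_healthy, vs_disease)``; the disease-vs-healthy comparison
    is a column of the first result.
    """
    vs_wt = anova_dunnett(study, study.healthy_control, config)
    vs_tg = anova_dunnett(study, study.disease_control, config)
    return vs_wt, vs_tg


def dunnett_mc_sf(
    q: float,
    n_groups: np.ndarray,
    n_control: int,
    df: int,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the many-to-one max-|T| tail probability.

    Independent check of :class:`DunnettNull`: simulate the group means and
    the pooled variance directly and tally max_j |T_j| >= q.
    """
    rng = np.random.default_rng(seed)
    n_groups = np.asarray(n_groups, dtype=float)
    z0 = rng.standard_normal(n_draws) / np.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    max_t = np.zeros(n_draws)
    for nj in n_groups:
        zj = rng.standard_normal(n_draws) / np.sqrt(nj)
        tj = np.abs(zj - z0) / (s * np.sqrt(1.0 / nj + 1.0 / n_control))
        np.maximum(max_t, tj, out=max_t)
    return float((max_t >= q).mean())
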