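"""Spatio-temporal differential-expression screen with a moderated t-statistic.

Comparisons are two-group contrasts drawn from the sample design: the same
brain region at adjacent developmental stages (hemisphere-stratified) and any
two regions at the same stage (hemispheres pooled). Per gene, the pooled
two-group variance s_g^2 (d_g df) is shrunk toward a prior s0^2 (d0 df)
estimated across genes by moment matching on log variances:

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
    t_g    = log2FC_g / (s~_g * sqrt(1/n1 + 1/n2)),  df = d_g + d0

A gene passes the screen when adj.P < alpha and |log2FC| >= log2(fc).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .enrichment import bh_adjust
from .preprocess import ExpressionBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Comparison:
    label: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    kind: str  # "adjacent-stage" or "region-pair"

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError(f"comparison {self.label}: empty group")
        if set(self.group1) & set(self.group2):
            raise ValueError(f"comparison {self.label}: groups overlap")


@dataclass
class VariancePrior:
    """Scaled-inverse-chi-square prior on gene variances: d0 df, scale s0^2."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive (may be inf)")
        if not self.s0sq > 0:
            raise ValueError("s0sq must be positive")


def make_comparison_plan(meta: pd.DataFrame, mode: str = "both") -> list[Comparison]:
    """Enumerate two-group comparisons from the sample design.

    adjacent-stage: per (region, hemisphere), stages s vs s+1 where both are
    present. region-pair: per stage, each unordered region pair, hemispheres
    pooled. Comparisons with an empty group are dropped and logged.
    """
    if mode not in {"adjacent-stage", "region-pair", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    plan: list[Comparison] = []

    if mode in {"adjacent-stage", "both"}:
        for (region, hemi), grp in meta.groupby(["region", "hemisphere"], sort=True):
            stages = sorted(grp["stage"].unique())
            for s in stages:
                if s + 1 not in stages:
                    continue
                g1 = tuple(grp.index[grp["stage"] == s])
                g2 = tuple(grp.index[grp["stage"] == s + 1])
                plan.append(
                    Comparison(
                        label=f"{region}_{hemi}_stg{s}-stg{s + 1}",
                        group1=g1, group2=g2, kind="adjacent-stage",
                    )
                )
    if mode in {"region-pair", "both"}:
        for stage, grp in meta.groupby("stage", sort=True):
            regions = sorted(grp["region"].unique())
            for r1, r2 in itertools.combinations(regions, 2):
                g1 = tuple(grp.index[grp["region"] == r1])
                g2 = tuple(grp.index[grp["region"] == r2])
                if not g1 or not g2:
                    logger.info("skipping empty comparison %s vs %s at stage %d", r1, r2, stage)
                    continue
                plan.append(
                    Comparison(
                        label=f"stg{stage}_{r1}-vs-{r2}",
                        group1=g1, group2=g2, kind="region-pair",
                    )
                )
    if not plan:
        raise ValueError("no valid comparison can be formed from the metadata")
    return plan


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 (psi' is strictly decreasing)."""
    if y <= 0:
        return np.inf
    # bracket: psi'(x) ~ 1/x + 1/(2x^2) for large x, ~ 1/x^2 for small x
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - y
    if f(lo) < 0:  # y larger than psi'(1e-8): x below lo
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_variance_prior(s2: np.ndarray, df) -> VariancePrior:
    """Moment-matching estimate of (d0, s0^2) from per-gene sample variances.

    Under s_g^2 ~ s0^2 * chi^2_{d_g}-scaled sampling with a scaled-inverse-
    chi-square prior, e_g = log s_g^2 - psi(d_g/2) + log(d_g/2) has mean
    log s0^2 + psi(d0/2) - log(d0/2) and excess variance psi'(d0/2) beyond the
    sampling term psi'(d_g/2); d0 solves the latter (infinite when the excess
    is non-positive) and s0^2 follows from the mean.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (df >= 1) & (s2 > 0) & np.isfinite(s2)
    if not (s2 > 0).any():
        raise ValueError("all variances are zero")
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 genes with df >= 1 and positive variance, got {ok.sum()}")
    s2, df = s2[ok], df[ok]
    g = s2.size
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).mean() * g / (g - 1))
    excess = e_var - float(special.polygamma(1, df / 2).mean())
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0sq=float(np.exp(e_mean)))
    x = _trigamma_inverse(excess)
    d0 = 2 * x
    s0sq = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return VariancePrior(d0=d0, s0sq=s0sq)


class ModeratedTTest(BaseEstimator):
    """Two-group moderated t-test, one test per feature (gene).

    sklearn-style estimator: ``fit(X, y)`` with X of shape
    (n_samples, n_genes) and binary labels y; group 1 is the smaller label,
    the effect is mean(group2) - mean(group1). With ``prior_df=None`` the
    variance prior is estimated across genes by moment matching; setting
    ``prior_df`` (0, finite, or ``np.inf``) with ``prior_s2`` injects it.

    Fitted attributes: ``log2fc_``, ``s2_pooled_``, ``df_residual_``,
    ``df_prior_``, ``s2_prior_``, ``s2_post_``, ``t_``, ``pvalue_``,
    ``adj_pvalue_``.
    """

    def __init__(self, prior_df: float | None = None, prior_s2: float | None = None,
                 alpha: float = 0.05, fc: float = 2.0):
        self.prior_df = prior_df
        self.prior_s2 = prior_s2
        self.alpha = alpha
        self.fc = fc

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 groups, got {classes.size}")
        self.classes_ = classes
        m1, m2 = (y == classes[0]), (y == classes[1])
        n1, n2 = int(m1.sum()), int(m2.sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(f"each group needs >= 2 samples (got {n1}, {n2})")
        x1, x2 = X[m1], X[m2]
        self.log2fc_ = x2.mean(axis=0) - x1.mean(axis=0)
        d_g = n1 + n2 - 2
        ss = ((x1 - x1.mean(axis=0)) ** 2).sum(axis=0) + ((x2 - x2.mean(axis=0)) ** 2).sum(axis=0)
        self.s2_pooled_ = ss / d_g
        self.df_residual_ = float(d_g)

        if self.prior_df is None:
            prior = estimate_variance_prior(self.s2_pooled_, d_g)
            d0, s0sq = prior.d0, prior.s0sq
        else:
            d0 = float(self.prior_df)
            if d0 > 0 and self.prior_s2 is None:
                raise ValueError("prior_s2 must be given with a positive prior_df")
            s0sq = float(self.prior_s2) if self.prior_s2 is not None else 0.0
        self.df_prior_, self.s2_prior_ = d0, s0sq

        if np.isinf(d0):
            s2_post = np.full_like(self.s2_pooled_, s0sq)
        else:
            s2_post = (d0 * s0sq + d_g * self.s2_pooled_) / (d0 + d_g)
        self.s2_post_ = s2_post

        se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.log2fc_ / se
        undefined = se == 0
        t[undefined] = np.nan
        self.t_ = t
        if np.isinf(d0):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), d_g + d0)
        p[undefined] = np.nan
        self.pvalue_ = p

        adj = np.full_like(p, np.nan)
        defined = ~np.isnan(p)
        if defined.any():
            adj[defined] = bh_adjust(p[defined])
        self.adj_pvalue_ = adj
        if undefined.any():
            logger.warning("%d genes with zero posterior variance excluded from adjustment",
                           int(undefined.sum()))
        return self

    def decision(self, alpha: float | None = None, fc: float | None = None) -> np.ndarray:
        """Boolean pass flags: adj.P < alpha and |log2FC| >= log2(fc)."""
        check_is_fitted(self, "adj_pvalue_")
        alpha = self.alpha if alpha is None else alpha
        fc = self.fc if fc is None else fc
        with np.errstate(invalid="ignore"):
            return (self.adj_pvalue_ < alpha) & (np.abs(self.log2fc_) >= np.log2(fc))


def moderated_t_fit(
    bundle: ExpressionBundle,
    plan: list[Comparison],
    prior_df: float | None = None,
    prior_s2: float | None = None,
    alpha: float = 0.05,
    fc: float = 2.0,
) -> dict[str, pd.DataFrame]:
    """Run the moderated t-test for every comparison in the plan.

    Returns one DE table per comparison label: gene, log2fc, s2, df, t,
    pvalue, adj_pvalue, pass (BH adjustment within each comparison).
    """
    expr = bundle.expression
    tables: dict[str, pd.DataFrame] = {}
    for comp in plan:
        cols = list(comp.group1) + list(comp.group2)
        missing = [c for c in cols if c not in expr.columns]
        if missing:
            raise KeyError(f"comparison {comp.label}: samples not in expression: {missing[:5]}")
        X = expr[cols].to_numpy(dtype=float).T
        y = np.array([0] * len(comp.group1) + [1] * len(comp.group2))
        est = ModeratedTTest(prior_df=prior_df, prior_s2=prior_s2, alpha=alpha, fc=fc).fit(X, y)
        tables[comp.label] = pd.DataFrame(
            {
                "gene_id": expr.index,
                "log2fc": est.log2fc_,
                "s2": est.s2_pooled_,
                "df": est.df_residual_,
                "t": est.t_,
                "pvalue": est.pvalue_,
                "adj_pvalue": est.adj_pvalue_,
                "pass": est.decision(),
            }
        )
    return tables


def de_screen(table: pd.DataFrame, alpha: float = 0.05, fc: float = 2.0) -> tuple[pd.DataFrame, int]:
    """Flag genes with adj.P < alpha and |FC| >= fc; return table and count."""
    if "adj_pvalue" not in table:
        raise ValueError("DE table lacks adjusted p-values")
    out = table.copy()
    with np.errstate(invalid="ignore"):
        out["pass"] = (out["adj_pvalue"] < alpha) & (out["log2fc"].abs() >= np.log2(fc))
    out["pass"] = out["pass"].fillna(False)
    return out, int(out["pass"].sum())


def de_gene_union(tables: dict[str, pd.DataFrame], kinds: list[Comparison] | None = None) -> set[str]:
    """Union of passing gene ids over all comparisons (optionally restricted)."""
    labels = None if kinds is None else {c.label for c in kinds}
    out: set[str] = set()
    for label, t in tables.items():
        if labels is not None and label not in labels:
            continue
        out |= set(t.loc[t["pass"], "gene_id"].astype(str))
    return out


def de_count_matrix(
    tables: dict[str, pd.DataFrame], plan: list[Comparison]
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Counts of screen-passing genes per comparison, arranged by design.

    Returns (region_pair_matrices, adjacent_counts): a symmetric
    region x region count matrix per stage, and a long table
    (stage_pair, hemisphere, region, n_pass) for adjacent-stage comparisons.
    """
    region_mats: dict[int, pd.DataFrame] = {}
    adj_rows = []
    for comp in plan:
        if comp.label not in tables:
            raise KeyError(f"missing DE table for comparison {comp.label}")
        n_pass = int(tables[comp.label]["pass"].sum())
        if comp.kind == "region-pair":
            stage_s, pair = comp.label.split("_", 1)
            stage = int(stage_s.removeprefix("stg"))
            r1, r2 = pair.split("-vs-")
            mat = region_mats.get(stage)
            if mat is None:
                regions = sorted(
                    {c.label.split("_", 1)[1].split("-vs-")[i]
                     for c in plan if c.kind == "region-pair"
                     and c.label.startswith(f"stg{stage}_") for i in (0, 1)}
                )
                mat = pd.DataFrame(0, index=regions, columns=regions)
                region_mats[stage] = mat
            mat.loc[r1, r2] = n_pass
            mat.loc[r2, r1] = n_pass
        else:
            region, hemi, pair = comp.label.split("_", 2)
            adj_rows.append((pair, hemi, region, n_pass))
    adjacent = pd.DataFrame(adj_rows, columns=["stage_pair", "hemisphere", "region", "n_pass"])
    return region_mats, adjacent


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
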