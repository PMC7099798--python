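"""Microarray-style probe preprocessing: background correction, quantile
normalization and median-polish summarization.

The three steps are sklearn-compatible transformers operating on arrays of
shape (n_chips, n_probes), so they compose in an ``sklearn.pipeline.Pipeline``;
the module-level functions wrap them in the probes x samples orientation used
by the file formats. The fixed order of the pipeline is background correction
-> quantile normalization -> log2 -> median polish.

Background model (normexp): observed intensity o = s + n with signal
s ~ Exp(alpha) and background n ~ N(mu, sigma^2). The corrected value is the
posterior mean E[s | o], a normal with mean a = o - mu - sigma^2*alpha and
sd sigma truncated to (0, o) — always strictly positive and monotone in o.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)


@dataclass
class ExpressionBundle:
    """Gene-level log2 expression (genes x samples) with sample metadata.

    ``meta`` is indexed by sample id with columns region, stage, hemisphere,
    donor; its rows match the expression columns 1:1.
    """

    expression: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.meta.index):
            raise ValueError("expression columns and metadata rows do not match 1:1")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValueError("expression contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.expression)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


# ---------------------------------------------------------------------------
# normexp background correction


def _estimate_normexp_params(x: np.ndarray) -> tuple[float, float, float]:
    """Estimate (mu, sigma, alpha) for one chip.

    mu is the histogram mode of the intensities, sigma the RMS deviation of
    values below mu, and alpha the reciprocal mean excess of values above mu.
    """
    n = x.size
    bins = max(10, int(round(np.sqrt(n))))
    hist, edges = np.histogram(x, bins=bins)
    k = int(np.argmax(hist))
    mu = float(0.5 * (edges[k] + edges[k + 1]))
    below = x[x < mu]
    if below.size:
        sigma = float(np.sqrt(np.mean((below - mu) ** 2)))
    else:
        sigma = float(np.std(x) * 0.1)
    sigma = max(sigma, 1e-6 * max(np.std(x), 1.0))
    above = x[x > mu]
    mean_excess = float(np.mean(above - mu)) if above.size else float(np.std(x))
    alpha = 1.0 / max(mean_excess, 1e-12)
    return mu, sigma, alpha


def _normexp_signal(o: np.ndarray, mu: float, sigma: float, alpha: float) -> np.ndarray:
    """Posterior mean of the signal given observed intensities for one chip.

    E[s | o] for the normal truncated to (0, o):
    a + sigma * (phi(lo) - phi(hi)) / (Phi(hi) - Phi(lo)) with lo = -a/sigma,
    hi = (o - a)/sigma. hi > 0 always (a < o by construction); the only
    degenerate regime is a << 0, where the exact tail limit sigma^2 / (-a)
    is used instead.
    """
    o = np.asarray(o, dtype=float)
    a = o - mu - sigma**2 * alpha
    lo = -a / sigma
    hi = (o - a) / sigma
    phi = lambda z: np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
    denom = special.ndtr(hi) - special.ndtr(lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = a + sigma * (phi(lo) - phi(hi)) / denom
        tail = sigma**2 / np.maximum(-a, sigma * 1e-6)
    out = np.where(denom > 1e-12, exact, tail)
    bad = ~np.isfinite(out) | (out <= 0)
    if bad.any():
        out[bad] = tail[bad]
    eps = 1e-10 * (sigma + np.abs(mu))
    return np.clip(out, eps, o)


class NormExpBackgroundCorrector(TransformerMixin, BaseEstimator):
    """Normal + exponential convolution background correction, one chip per row.

    Parameters left at ``None`` are estimated per chip from the intensity
    distribution; supplying ``mu``, ``sigma`` and ``alpha`` injects known
    values (useful on simulated data). Output is strictly positive.
    """

    def __init__(self, mu: float | None = None, sigma: float | None = None,
                 alpha: float | None = None):
        self.mu = mu
        self.sigma = sigma
        self.alpha = alpha

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[1] < 10:
            raise ValueError(
                f"normexp parameters are unidentifiable with {X.shape[1]} probes (< 10)"
            )
        if (X <= 0).any():
            raise ValueError("intensities must be positive")
        params = []
        for row in X:
            if self.mu is None or self.sigma is None or self.alpha is None:
                mu, sigma, alpha = _estimate_normexp_params(row)
            else:
                mu, sigma, alpha = self.mu, self.sigma, self.alpha
            params.append((self.mu if self.mu is not None else mu,
                           self.sigma if self.sigma is not None else sigma,
                           self.alpha if self.alpha is not None else alpha))
        self.params_ = np.asarray(params, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        out = np.empty_like(X)
        for i, (row, (mu, sigma, alpha)) in enumerate(zip(X, self.params_)):
            out[i] = _normexp_signal(row, mu, sigma, alpha)
        return out


# ---------------------------------------------------------------------------
# quantile normalization


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every chip (row) to share the mean empirical distribution.

    The reference distribution is the across-chip mean of each order
    statistic; each chip's values are replaced by the reference value at
    their rank, ties receiving the mean of the tied reference values.
    Fitting and transforming the same matrix is idempotent.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[0] == 1:
            warnings.warn("single chip: quantile normalization is the identity", stacklevel=2)
            return X.copy()
        n = X.shape[1]
        out = np.empty_like(X)
        grid = np.arange(n, dtype=float)
        for i, row in enumerate(X):
            ranks = stats.rankdata(row, method="average") - 1.0
            out[i] = np.interp(ranks, grid, self.reference_)
        return out


# ---------------------------------------------------------------------------
# median polish


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Tukey median polish of a 2-D table: overall + row + column effects.

    Alternately sweeps row and column medians until a full sweep no longer
    moves any median by more than ``tol`` (which leaves every residual row
    and column median below ``tol``) or ``max_iter`` sweeps have run. On
    even-sized tables the sum of absolute residuals stalls while medians
    still oscillate, so the stop rule watches the sweep magnitude instead.
    Returns (overall, row_effects, col_effects, residuals).
    """
    r = np.array(matrix, dtype=float)
    if r.ndim != 2:
        raise ValueError("median_polish expects a 2-D matrix")
    overall = 0.0
    row_eff = np.zeros(r.shape[0])
    col_eff = np.zeros(r.shape[1])
    for _ in range(max_iter):
        rm = np.median(r, axis=1)
        row_eff += rm
        r -= rm[:, None]
        delta = np.median(row_eff)
        overall += delta
        row_eff -= delta
        cm = np.median(r, axis=0)
        col_eff += cm
        r -= cm[None, :]
        delta = np.median(col_eff)
        overall += delta
        col_eff -= delta
        if max(np.abs(rm).max(), np.abs(cm).max()) < tol:
            break
    return overall, row_eff, col_eff, r


def _median_polish_3d(stack: np.ndarray, max_iter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Vectorized median polish over a (genes, probes, samples) stack.

    All genes in the stack share a probe count, so the row/column sweeps run
    simultaneously; each gene stops contributing once converged. Returns the
    per-gene summarized sample values overall + column effect.
    """
    r = stack.astype(float).copy()
    g = r.shape[0]
    overall = np.zeros(g)
    col_eff = np.zeros((g, r.shape[2]))
    row_eff = np.zeros((g, r.shape[1]))
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        a = active
        rm = np.median(r[a], axis=2)
        row_eff[a] += rm
        r[a] -= rm[:, :, None]
        delta = np.median(row_eff[a], axis=1)
        overall[a] += delta
        row_eff[a] -= delta[:, None]
        cm = np.median(r[a], axis=1)
        col_eff[a] += cm
        r[a] -= cm[:, None, :]
        delta = np.median(col_eff[a], axis=1)
        overall[a] += delta
        col_eff[a] -= delta[:, None]
        done = np.maximum(
            np.abs(rm).max(axis=1), np.abs(cm).max(axis=1)
        ) < tol
        idx = np.flatnonzero(a)
        active[idx[done]] = False
    return overall[:, None] + col_eff


class MedianPolishSummarizer(TransformerMixin, BaseEstimator):
    """Summarize probe intensities into one log2 value per gene and chip.

    ``probe_gene`` assigns each probe (feature) to a gene; intensities are
    log2-transformed first unless ``log2=False`` (input already on log scale).
    ``transform`` maps (n_chips, n_probes) to (n_chips, n_genes); the fitted
    ``genes_`` attribute gives the output column order.
    """

    def __init__(self, probe_gene=None, log2: bool = True,
                 max_iter: int = 10, tol: float = 1e-6):
        self.probe_gene = probe_gene
        self.log2 = log2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.probe_gene is None:
            raise ValueError("probe_gene (gene id per probe column) is required")
        probe_gene = np.asarray(self.probe_gene)
        if probe_gene.shape[0] != X.shape[1]:
            raise ValueError("probe_gene length must equal the number of probe columns")
        self.genes_ = pd.unique(probe_gene)
        self._groups_ = {
            g: np.flatnonzero(probe_gene == g) for g in self.genes_
        }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "genes_")
        X = check_array(X, dtype=float)
        if self.log2:
            if (X <= 0).any():
                raise ValueError("non-positive intensity: log2 undefined")
            X = np.log2(X)
        out = np.empty((X.shape[0], len(self.genes_)))
        # genes with equal probe counts are polished together as a 3-D stack
        by_count: dict[int, list[int]] = {}
        for j, g in enumerate(self.genes_):
            by_count.setdefault(len(self._groups_[g]), []).append(j)
        for count, gene_idx in by_count.items():
            stack = np.stack(
                [X[:, self._groups_[self.genes_[j]]].T for j in gene_idx]
            )  # (n_genes_in_group, probes, chips)
            summarized = _median_polish_3d(stack, self.max_iter, self.tol)
            for row, j in enumerate(gene_idx):
                out[:, j] = summarized[row]
        return out


# ---------------------------------------------------------------------------
# functional wrappers (probes x samples orientation) and expression I/O


def normexp_background_correct(
    probe_df: pd.DataFrame,
    mu: float | None = None,
    sigma: float | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Background-correct a probes x samples intensity matrix per chip."""
    est = NormExpBackgroundCorrector(mu=mu, sigma=sigma, alpha=alpha)
    corrected = est.fit_transform(probe_df.to_numpy(dtype=float).T).T
    return pd.DataFrame(corrected, index=probe_df.index, columns=probe_df.columns)


def quantile_normalize(probe_df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a probes x samples matrix across samples."""
    qn = QuantileNormalizer()
    out = qn.fit_transform(probe_df.to_numpy(dtype=float).T).T
    return pd.DataFrame(out, index=probe_df.index, columns=probe_df.columns)


def median_polish_summarize(
    probe_df: pd.DataFrame,
    probe_map: pd.Series | pd.DataFrame,
    meta: pd.DataFrame | None = None,
    log2: bool = True,
) -> pd.DataFrame | ExpressionBundle:
    """Summarize probes x samples intensities into gene x sample log2 expression.

    ``probe_map`` maps probe_id to gene_id (Series, or DataFrame with those
    columns). With ``meta`` supplied, returns an :class:`ExpressionBundle`.
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = probe_map.set_index("probe_id")["gene_id"]
    genes = probe_map.reindex(probe_df.index)
    if genes.isna().any():
        missing = probe_df.index[genes.isna()][:5].tolist()
        raise ValueError(f"probes without a gene mapping: {missing}")
    mp = MedianPolishSummarizer(probe_gene=genes.to_numpy(), log2=log2)
    summarized = mp.fit_transform(probe_df.to_numpy(dtype=float).T).T
    expr = pd.DataFrame(summarized, index=pd.Index(mp.genes_, name="gene_id"),
                        columns=probe_df.columns)
    if meta is None:
        return expr
    return ExpressionBundle(expression=expr, meta=meta)


def rma_preprocess(
    probe_df: pd.DataFrame,
    probe_map: pd.Series | pd.DataFrame,
    meta: pd.DataFrame,
    background: bool = True,
) -> ExpressionBundle:
    """The fixed preprocessing chain: background -> quantile -> log2 + median polish."""
    x = normexp_background_correct(probe_df) if background else probe_df
    x = quantile_normalize(x)
    return median_polish_summarize(x, probe_map, meta=meta, log2=True)


def read_probe_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if (df.to_numpy(dtype=float) <= 0).any():
        raise ValueError(f"{path}: probe intensities must be positive")
    return df


def write_probe_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_probe_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: probe map needs columns probe_id, gene_id")
    return df.set_index("probe_id")["gene_id"]


REGION_VOCABULARY = (
    "OFC", "DFC", "VFC", "MFC", "M1C", "S1C", "IPC", "A1C",
    "STC", "ITC", "V1C", "HIP", "AMY", "STR", "MD", "CBC",
)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample, region, stage, hemisphere, donor."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "donor": str})
    required = {"sample", "region", "stage", "hemisphere"}
    if not required <= set(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    meta = meta.set_index("sample")
    meta["stage"] = meta["stage"].astype(int)
    if not meta["stage"].between(1, 15).all():
        raise ValueError("stages must lie in 1..15")
    bad = set(meta["region"]) - set(REGION_VOCABULARY)
    if bad:
        raise ValueError(f"unknown region label(s): {sorted(bad)}")
    if not meta["hemisphere"].isin(["L", "R"]).all():
        raise ValueError("hemisphere must be 'L' or 'R'")
    return meta


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


def write_expression(bundle: ExpressionBundle, path: str | Path) -> None:
    bundle.expression.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
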