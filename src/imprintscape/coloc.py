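"""Sliding-window chromosomal co-distribution of two gene sets.

Windows of width ``w`` advance by stride ``s`` along each chromosome; genes
are tallied per window (by start coordinate), per-window ratios against the
reference annotation are formed, and the co-distribution of two sets is
summarized by a correlation on (optionally log10) ratios, with a
membership-permutation null for significance. Chromosome/arm-level
over-representation uses the hypergeometric distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CytoBandMap, GeneSet, GenomeAnnotation, normalize_chrom, resolve_symbols

logger = logging.getLogger(__name__)


@dataclass
class WindowGrid:
    """Tiling of the genome into windows of width ``window`` at stride ``step``."""

    window: int
    step: int
    windows: pd.DataFrame  # columns: chrom, start, end, index

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class WindowCounts:
    """Per-window reference / set-A / set-B gene tallies and ratios.

    ``table`` columns: chrom, start, end, n_ref, n_a, n_b, r_a, r_b (ratios
    NaN where n_ref = 0). ``n_unresolved`` counts query symbols that could not
    be matched to the annotation.
    """

    table: pd.DataFrame
    grid: WindowGrid
    n_unresolved: int = 0


@dataclass
class CoDistributionResult:
    r: float
    n_windows_used: int
    method: str
    transform: str
    n_windows_excluded: int
    permutation_pvalue: float | None = None
    n_permutations: int | None = None


def build_windows(genome: GenomeAnnotation, window: int, step: int) -> WindowGrid:
    """Tile every chromosome with windows [k*step, min(k*step + window, L)).

    Starts run 0, step, 2*step, ... while start < L, so the last window is
    truncated at the chromosome end and always has >= 1 bp.
    """
    if window <= 0 or step <= 0:
        raise ValueError(f"window and step must be positive (got {window}, {step})")
    rows = []
    idx = 0
    for chrom, length in genome.chromosomes:
        for start in range(0, int(length), step):
            rows.append((chrom, start, min(start + window, int(length)), idx))
            idx += 1
    grid = pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])
    return WindowGrid(window=window, step=step, windows=grid)


def _gene_window_assignment(
    grid: WindowGrid, genome: GenomeAnnotation, by: str = "start"
) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (gene_row, window_index) pairs: which windows each gene falls in.

    A gene is assigned by its start coordinate (or midpoint with
    ``by='midpoint'``): with step = window each gene hits exactly one window;
    with step < window it hits every window containing the coordinate.
    """
    w, s = grid.window, grid.step
    win = grid.windows
    first_idx = win.groupby("chrom", sort=False)["index"].min()
    n_win = win.groupby("chrom", sort=False)["index"].count()

    genes = genome.genes
    if by == "start":
        pos = genes["start"].to_numpy(dtype=np.int64)
    elif by == "midpoint":
        pos = ((genes["start"] + genes["end"]) // 2).to_numpy(dtype=np.int64)
    else:
        raise ValueError(f"unknown assignment rule {by!r}")

    chrom_key = genes["chrom"].map(normalize_chrom)
    first_by_chrom = {normalize_chrom(c): int(first_idx[c]) for c in first_idx.index}
    count_by_chrom = {normalize_chrom(c): int(n_win[c]) for c in n_win.index}

    gene_rows: list[np.ndarray] = []
    win_rows: list[np.ndarray] = []
    for chrom, idx in chrom_key.groupby(chrom_key).groups.items():
        if chrom not in first_by_chrom:
            continue
        base, nwin = first_by_chrom[chrom], count_by_chrom[chrom]
        x = pos[np.asarray(idx)]
        jmax = np.minimum(x // s, nwin - 1)
        jmin = np.maximum((x - w) // s + 1, 0)
        counts = (jmax - jmin + 1).astype(np.int64)
        counts = np.maximum(counts, 0)
        g = np.repeat(np.asarray(idx), counts)
        offs = np.concatenate([np.arange(n) for n in counts]) if len(counts) else np.array([], int)
        j = np.repeat(jmin, counts) + offs
        gene_rows.append(g)
        win_rows.append(base + j)
    if gene_rows:
        return np.concatenate(gene_rows), np.concatenate(win_rows)
    return np.array([], dtype=np.int64), np.array([], dtype=np.int64)


def count_in_windows(
    grid: WindowGrid,
    genome: GenomeAnnotation,
    set_a: GeneSet | None = None,
    set_b: GeneSet | None = None,
    by: str = "start",
) -> WindowCounts:
    """Tally reference and query-set genes per window; form ratios r = n_set/n_ref."""
    if len(grid) == 0:
        raise ValueError("empty window grid")
    gene_rows, win_rows = _gene_window_assignment(grid, genome, by=by)
    n_win = len(grid)
    n_ref = np.bincount(win_rows, minlength=n_win)

    n_unresolved = 0
    out = grid.windows[["chrom", "start", "end"]].copy()
    out["n_ref"] = n_ref
    for label, gene_set in (("a", set_a), ("b", set_b)):
        if gene_set is None:
            continue
        mask = resolve_symbols(genome, gene_set)
        n_unresolved += len(gene_set) - len(set(genome.symbols()[mask]))
        hits = mask[gene_rows]
        out[f"n_{label}"] = np.bincount(win_rows[hits], minlength=n_win)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"r_{label}"] = np.where(n_ref > 0, out[f"n_{label}"] / n_ref, np.nan)
    return WindowCounts(table=out, grid=grid, n_unresolved=n_unresolved)


def ratio_profile(counts: WindowCounts, which: str = "a", threshold: float = 0.5) -> pd.DataFrame:
    """Per-window ratio track with an above-threshold flag (ratio >= threshold).

    Windows with no reference gene keep a missing ratio and no flag.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    col = f"r_{which}"
    if col not in counts.table:
        raise KeyError(f"counts have no ratio column {col!r}")
    out = counts.table[["chrom", "start", "end", "n_ref", col]].copy()
    out = out.rename(columns={col: "ratio"})
    flag = out["ratio"] >= threshold
    out["above_threshold"] = flag.astype("boolean").mask(out["n_ref"] == 0)
    return out


def _correlate(r_a: np.ndarray, r_b: np.ndarray, method: str, transform: str) -> float:
    if transform == "log10":
        r_a, r_b = np.log10(r_a), np.log10(r_b)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(r_a) == 0 or np.ptp(r_b) == 0:
        warnings.warn("zero variance in a ratio track; correlation reported as 0", stacklevel=2)
        return 0.0
    if method == "pearson":
        return float(stats.pearsonr(r_a, r_b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(r_a, r_b).statistic)
    raise ValueError(f"unknown method {method!r}")


def _usable_mask(table: pd.DataFrame, transform: str) -> np.ndarray:
    if transform == "log10":
        return (
            (table["n_ref"] > 0) & (table["n_a"] > 0) & (table["n_b"] > 0)
        ).to_numpy()
    return (table["n_ref"] > 0).to_numpy()


def codistribution_correlation(
    counts: WindowCounts, method: str = "pearson", transform: str = "log10"
) -> CoDistributionResult:
    """Correlation of the two sets' per-window ratios across the genome.

    With ``transform='log10'`` only windows with n_ref, n_a and n_b all
    positive enter (the log of a zero ratio is undefined); the number of
    excluded windows is reported. Fewer than 3 usable windows is an error.
    """
    t = counts.table
    if "r_a" not in t or "r_b" not in t:
        raise ValueError("counts must carry both set-A and set-B tallies")
    usable = _usable_mask(t, transform)
    n_used = int(usable.sum())
    if n_used < 3:
        raise ValueError(
            f"only {n_used} windows usable after requiring "
            + ("n_ref>0, n_a>0 and n_b>0" if transform == "log10" else "n_ref>0")
            + "; need >= 3"
        )
    r = _correlate(
        t.loc[usable, "r_a"].to_numpy(), t.loc[usable, "r_b"].to_numpy(), method, transform
    )
    return CoDistributionResult(
        r=r,
        n_windows_used=n_used,
        method=method,
        transform=transform,
        n_windows_excluded=len(t) - n_used,
    )


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table of non-negative counts.

    Two-sided p sums the probabilities of all tables (margins fixed) whose
    point probability does not exceed the observed one.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative entry in contingency table")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table entries must be integers")
    arr = arr.astype(int)
    if arr.sum(axis=0).min() <= 0 or arr.sum(axis=1).min() <= 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    return float(stats.fisher_exact(arr, alternative=alternative).pvalue)


def chromosome_enrichment(
    genome: GenomeAnnotation,
    query: GeneSet,
    bands: CytoBandMap | None = None,
    level: str = "chromosome",
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of a gene set per chromosome or arm.

    For each category: N = annotated genes, K = genes in the category,
    n = resolvable query genes, x = query genes in the category,
    expected = n*K/N. p doubles the relevant hypergeometric tail (upper when
    x >= expected, lower otherwise), capped at 1; the tie x = expected is
    reported as "up" with the upper-tail p.
    """
    if level not in {"chromosome", "arm"}:
        raise ValueError(f"level must be 'chromosome' or 'arm', got {level!r}")
    if level == "arm" and bands is None:
        raise ValueError("level='arm' requires a CytoBandMap")

    genes = genome.genes
    if level == "chromosome":
        category = genes["chrom"].map(normalize_chrom)
    else:
        category = pd.Series(
            [
                normalize_chrom(c) + bands.arm_of(c, int(s))
                for c, s in zip(genes["chrom"], genes["start"])
            ],
            index=genes.index,
        )
    mask = resolve_symbols(genome, query)
    n_total = len(genes)
    n_query = int(mask.sum())
    dropped = len(query) - len(set(genome.symbols()[mask]))
    if dropped:
        logger.warning("chromosome_enrichment: %d query symbols dropped (unannotated)", dropped)

    rows = []
    for cat in category.unique():
        in_cat = (category == cat).to_numpy()
        K = int(in_cat.sum())
        x = int((in_cat & mask).sum())
        expected = n_query * K / n_total
        hg = stats.hypergeom(n_total, K, n_query)
        if x >= expected:
            p = min(1.0, 2.0 * float(hg.sf(x - 1)))
            direction = "up"
        else:
            p = min(1.0, 2.0 * float(hg.cdf(x)))
            direction = "down"
        rows.append((cat, n_total, K, n_query, x, expected, p, direction))
    out = pd.DataFrame(
        rows, columns=["category", "N", "K", "n", "x", "expected", "pvalue", "direction"]
    )
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def codistribution_permutation_pvalue(
    genome: GenomeAnnotation,
    set_a: GeneSet,
    set_b: GeneSet,
    grid: WindowGrid,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
    transform: str = "log10",
) -> CoDistributionResult:
    """Permutation significance for the co-distribution correlation.

    The null redraws set B's membership uniformly from the annotated genes
    (size preserved) and recomputes the correlation each time;
    p = (1 + #{r_null >= r_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)

    gene_rows, win_rows = _gene_window_assignment(grid, genome)
    n_win = len(grid)
    n_ref = np.bincount(win_rows, minlength=n_win)
    mask_a = resolve_symbols(genome, set_a)
    mask_b = resolve_symbols(genome, set_b)
    n_a = np.bincount(win_rows[mask_a[gene_rows]], minlength=n_win)
    n_b = np.bincount(win_rows[mask_b[gene_rows]], minlength=n_win)

    def corr_for(nb: np.ndarray) -> float:
        if transform == "log10":
            usable = (n_ref > 0) & (n_a > 0) & (nb > 0)
        else:
            usable = n_ref > 0
        if usable.sum() < 3:
            return np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = n_a[usable] / n_ref[usable]
            rb = nb[usable] / n_ref[usable]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _correlate(ra, rb, method, transform)

    r_obs = corr_for(n_b)
    if np.isnan(r_obs):
        raise ValueError("too few usable windows for the observed correlation")

    size_b = int(mask_b.sum())
    n_genes = len(genome.genes)
    exceed = 0
    for _ in range(n_perm):
        perm = np.zeros(n_genes, dtype=bool)
        perm[rng.choice(n_genes, size=size_b, replace=False)] = True
        r_null = corr_for(np.bincount(win_rows[perm[gene_rows]], minlength=n_win))
        if not np.isnan(r_null) and r_null >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    usable_obs = int((_usable_mask_arrays(n_ref, n_a, n_b, transform)).sum())
    return CoDistributionResult(
        r=r_obs,
        n_windows_used=usable_obs,
        method=method,
        transform=transform,
        n_windows_excluded=n_win - usable_obs,
        permutation_pvalue=p,
        n_permutations=n_perm,
    )


def _usable_mask_arrays(n_ref, n_a, n_b, transform):
    if transform == "log10":
        return (n_ref > 0) & (n_a > 0) & (n_b > 0)
    return n_ref > 0


def write_window_counts(counts: WindowCounts, path) -> None:
    """bedGraph-like TSV export of per-window tallies and ratios."""
    counts.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
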