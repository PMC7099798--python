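"""Over-representation analysis of a gene set against GMT term collections.

The test is the hypergeometric upper tail: draw n study genes from a
background of N, of which K belong to the term; the p-value is
P(X >= x) for the observed overlap x. Adjustment across terms is
Benjamini–Hochberg by default (Bonferroni available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import GeneSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TermCollection:
    """Mapping term_id -> (description, member symbols), symbols upper-cased."""

    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())


def read_gmt(path: str | Path) -> TermCollection:
    """Read a GMT file: term_id <TAB> description <TAB> member symbols..."""
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{i}: GMT needs >= 3 columns, got {len(parts)}")
        term_id, desc = parts[0], parts[1]
        members = frozenset(p.strip().upper() for p in parts[2:] if p.strip())
        if term_id in terms:
            raise ValidationError(f"{path}:{i}: duplicate term id {term_id!r}")
        if members:
            terms[term_id] = (desc, members)
    if not terms:
        raise ValidationError(f"{path}: no terms")
    return TermCollection(terms=terms)


def write_gmt(terms: TermCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, members) in terms:
            fh.write("\t".join([term_id, desc, *sorted(members)]) + "\n")


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n).

    N: background size, K: category size, n: draws, x: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N (got N={N}, K={K}, n={n})")
    if not 0 <= x <= min(K, n):
        raise ValueError(f"need 0 <= x <= min(K, n) (got x={x}, K={K}, n={n})")
    if x == 0:
        return 1.0
    # survival function is evaluated in log space internally for stability
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment, returned in the input order.

    'bh' is the Benjamini–Hochberg step-up (adjusted p monotone non-decreasing
    along the sorted p-values, capped at 1); 'bonferroni' multiplies by m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def ora_test(
    study: GeneSet,
    terms: TermCollection,
    background: GeneSet,
    alpha: float = 0.05,
    min_term_size: int = 2,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set across a term collection.

    Study genes outside the background are dropped (count logged); terms with
    fewer than ``min_term_size`` background members are skipped. Rows carry
    GeneRatio x/n and BgRatio K/N and are sorted by p-value; adjusted p-values
    span all tested terms.
    """
    bg = background.members
    if not bg:
        raise ValueError("empty background")
    study_in = study.members & bg
    dropped = len(study.members) - len(study_in)
    if dropped:
        logger.warning("ora_test: %d study genes outside the background dropped", dropped)
    if not study_in:
        raise ValueError("no study genes remain after background intersection")

    N, n = len(bg), len(study_in)
    rows = []
    for term_id, (desc, members) in sorted(terms, key=lambda kv: kv[0]):
        term_bg = members & bg
        K = len(term_bg)
        if K < min_term_size:
            logger.info("ora_test: skipping term %s (K=%d < %d)", term_id, K, min_term_size)
            continue
        overlap = sorted(study_in & term_bg)
        x = len(overlap)
        p = hypergeom_upper_tail(N, K, n, x)
        rows.append(
            {
                "term_id": term_id,
                "description": desc,
                "N": N,
                "K": K,
                "n": n,
                "x": x,
                "expected": n * K / N,
                "gene_ratio": f"{x}/{n}",
                "bg_ratio": f"{K}/{N}",
                "pvalue": p,
                "genes": ";".join(overlap),
            }
        )
    if not rows:
        raise ValueError("no testable terms after background intersection")
    out = pd.DataFrame(rows)
    out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy(), method=adjust)
    out["significant"] = out["adj_pvalue"] < alpha
    out = out.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    return out


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
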