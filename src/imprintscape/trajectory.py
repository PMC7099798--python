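"""Multi-way gene-set intersection and spatio-temporal expression trajectories."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import GeneSet
from .preprocess import ExpressionBundle

logger = logging.getLogger(__name__)


@dataclass
class IntersectionReport:
    """Sizes and member lists for all pairwise and the full intersection."""

    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], frozenset[str]]
    common: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", name, size, "") for name, size in self.set_sizes.items()]
        for (a, b), members in self.pairwise.items():
            rows.append(("pairwise", f"{a} & {b}", len(members), ";".join(sorted(members))))
        rows.append(("common", " & ".join(self.set_sizes), len(self.common),
                     ";".join(sorted(self.common))))
        return pd.DataFrame(rows, columns=["level", "sets", "size", "members"])


def intersect_sets(sets: list[GeneSet]) -> IntersectionReport:
    """Exact set algebra over >= 2 named gene sets (case-insensitive symbols)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets to intersect")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("gene sets must have distinct names")
    members = {s.name: frozenset(m.upper() for m in s.members) for s in sets}
    pairwise = {
        (a, b): members[a] & members[b] for a, b in itertools.combinations(names, 2)
    }
    common = frozenset.intersection(*members.values())
    return IntersectionReport(
        set_sizes={n: len(members[n]) for n in names},
        pairwise=pairwise,
        common=common,
    )


def trajectory_means(bundle: ExpressionBundle, genes: GeneSet | list[str]) -> pd.DataFrame:
    """Mean log2 expression per (gene, region, stage), hemispheres and donors pooled.

    Long-format output (gene_id, region, stage, mean_log2, n_samples), one row
    per populated cell — ready for one-line-per-region trajectory plots.
    Requested genes absent from the bundle are listed in a warning; an
    entirely absent set is an error.
    """
    wanted = list(genes.members) if isinstance(genes, GeneSet) else [str(g) for g in genes]
    idx_upper = bundle.expression.index.astype(str).str.upper()
    mask = idx_upper.isin({g.upper() for g in wanted})
    if not mask.any():
        raise ValueError("none of the requested genes are present in the expression bundle")
    missing = {g.upper() for g in wanted} - set(idx_upper[mask])
    if missing:
        logger.warning("trajectory_means: %d requested genes absent: %s",
                       len(missing), sorted(missing)[:5])
    expr = bundle.expression.loc[mask]
    long = (
        expr.reset_index(names="gene_id")
        .melt(id_vars="gene_id", var_name="sample", value_name="log2_expression")
        .merge(bundle.meta[["region", "stage"]], left_on="sample", right_index=True)
    )
    out = (
        long.groupby(["gene_id", "region", "stage"], sort=True)["log2_expression"]
        .agg(mean_log2="mean", n_samples="size")
        .reset_index()
    )
    return out


def write_trajectories(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
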