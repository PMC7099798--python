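"""Readers, writers and containers for genome annotations, cytogenetic bands and gene lists.

All coordinates are 0-based half-open throughout the package; BED and refFlat
already use this convention, so no conversion happens at these boundaries.
Chromosome names are matched with the ``chr`` prefix stripped but written back
as they were read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


class ParseError(ValueError):
    """A line of an input file could not be parsed; the message names the line."""


class ValidationError(ValueError):
    """A parsed object violates a structural invariant."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix for matching purposes."""
    return name[3:] if name.lower().startswith("chr") else name


def _chrom_sort_key(name: str):
    n = normalize_chrom(name)
    return (0, int(n)) if n.isdigit() else (1, n)


@dataclass
class GenomeAnnotation:
    """A set of chromosomes with lengths plus gene records located on them.

    ``genes`` is a DataFrame with columns gene_id, symbol, chrom, start, end,
    strand; 0-based half-open coordinates. Invariants (checked by
    :meth:`validate`): 0 <= start < end <= chromosome length, every gene's
    chromosome is declared, gene_ids are unique.
    """

    chromosomes: Sequence[tuple[str, int]]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.validate()

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {normalize_chrom(c): int(l) for c, l in self.chromosomes}

    def validate(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValidationError(f"gene table is missing columns {missing}")
        lengths = self.chrom_lengths
        g = self.genes
        unknown = set(g["chrom"].map(normalize_chrom)) - set(lengths)
        if unknown:
            raise ValidationError(f"genes on undeclared chromosomes: {sorted(unknown)}")
        if (g["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        bad = g[g["start"] >= g["end"]]
        if len(bad):
            raise ValidationError(
                f"start >= end for gene(s) {bad['gene_id'].head().tolist()}"
            )
        limit = g["chrom"].map(lambda c: lengths[normalize_chrom(c)])
        over = g[g["end"] > limit]
        if len(over):
            raise ValidationError(
                f"gene(s) extend past chromosome end: {over['gene_id'].head().tolist()}"
            )
        if g["gene_id"].duplicated().any():
            dups = g.loc[g["gene_id"].duplicated(), "gene_id"].unique()[:5]
            raise ValidationError(f"duplicate gene_id(s): {list(dups)}")

    def symbols(self) -> pd.Series:
        """Upper-cased symbols, aligned with the gene table rows."""
        return self.genes["symbol"].str.upper()

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CytoBandMap:
    """Cytogenetic bands per chromosome with derived p/q arm boundaries.

    ``arm_boundaries`` maps the normalized chromosome name to the start of the
    lexicographically first q-band; ``None`` marks a chromosome with no q-band
    (treated as a single "p" arm).
    """

    bands: pd.DataFrame
    arm_boundaries: dict[str, int | None] = field(default_factory=dict)

    def arm_of(self, chrom: str, pos: int) -> str:
        boundary = self.arm_boundaries.get(normalize_chrom(chrom))
        if boundary is None:
            return "p"
        return "p" if pos < boundary else "q"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with optional per-member provenance tags."""

    name: str
    members: frozenset[str]
    provenance: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members

    def __iter__(self):
        return iter(sorted(self.members))


# ---------------------------------------------------------------------------
# readers


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Read a 2-column (chrom, length) TSV."""
    out: list[tuple[str, int]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        try:
            out.append((parts[0], int(parts[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: bad length {parts[1]!r}") from exc
    return out


def _parse_bed6(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{i}: BED6 needs 6 columns, got {len(parts)}")
        chrom, start, end, name, _score, strand = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer coordinate") from exc
        if start_i >= end_i:
            raise ValidationError(f"{path}:{i}: start {start_i} >= end {end_i}")
        if strand not in {"+", "-", "."}:
            raise ParseError(f"{path}:{i}: bad strand {strand!r}")
        rows.append((name, name, chrom, start_i, end_i, strand))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _parse_refflat(path: Path) -> pd.DataFrame:
    # refFlat: geneName, name, chrom, strand, txStart, txEnd, ... (>= 6 used)
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ParseError(f"{path}:{i}: refFlat needs >= 6 columns, got {len(parts)}")
        symbol, gene_id, chrom, strand, tx_start, tx_end = parts[:6]
        try:
            start_i, end_i = int(tx_start), int(tx_end)
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer txStart/txEnd") from exc
        if start_i >= end_i:
            raise ValidationError(f"{path}:{i}: txStart {start_i} >= txEnd {end_i}")
        if strand not in {"+", "-", "."}:
            raise ParseError(f"{path}:{i}: bad strand {strand!r}")
        rows.append((gene_id, symbol, chrom, start_i, end_i, strand))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def read_gene_annotation(
    path: str | Path,
    dialect: str = "bed6",
    chrom_sizes: str | Path | Sequence[tuple[str, int]] | None = None,
) -> GenomeAnnotation:
    """Read a BED6 or refFlat gene annotation into a validated :class:`GenomeAnnotation`.

    Chromosome lengths come from ``chrom_sizes`` (a path to a 2-column TSV or
    a sequence of pairs); when absent they are inferred as the maximum gene
    end per chromosome. Rows sharing a gene_id are collapsed to the widest
    span (min start, max end) with a logged warning.
    """
    path = Path(path)
    if dialect == "bed6":
        genes = _parse_bed6(path)
    elif dialect == "refflat":
        genes = _parse_refflat(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'bed6' or 'refflat'")
    if genes.empty:
        raise ValidationError(f"{path}: no gene records")

    if genes["gene_id"].duplicated().any():
        n_dup = int(genes["gene_id"].duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene_id rows to widest spans", path, n_dup)
        genes = (
            genes.groupby("gene_id", as_index=False, sort=False)
            .agg(
                symbol=("symbol", "first"),
                chrom=("chrom", "first"),
                start=("start", "min"),
                end=("end", "max"),
                strand=("strand", "first"),
            )
        )[GENE_COLUMNS]

    if chrom_sizes is None:
        sizes = (
            genes.groupby("chrom", sort=False)["end"].max().astype(int).items()
        )
        chromosomes = sorted(((c, l) for c, l in sizes), key=lambda cl: _chrom_sort_key(cl[0]))
    elif isinstance(chrom_sizes, (str, Path)):
        chromosomes = read_chrom_sizes(chrom_sizes)
    else:
        chromosomes = [(c, int(l)) for c, l in chrom_sizes]

    order = {normalize_chrom(c): i for i, (c, _) in enumerate(chromosomes)}
    genes = genes.sort_values(
        by=["chrom", "start"],
        key=lambda s: s.map(lambda v: order.get(normalize_chrom(v), v)) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def write_bed6(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes as BED6 (score column fixed to 0)."""
    g = annotation.genes
    out = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": g["start"],
            "end": g["end"],
            "name": g["gene_id"],
            "score": 0,
            "strand": g["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_chrom_sizes(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in annotation.chromosomes:
            fh.write(f"{chrom}\t{length}\n")


def read_cytoband(path: str | Path) -> CytoBandMap:
    """Read a UCSC cytoBand file (chrom, start, end, band name, gieStain).

    The p/q arm boundary per chromosome is the start of the lexicographically
    first band whose name begins with ``q``; a chromosome with no q-band is a
    single "p" arm (warning logged).
    """
    path = Path(path)
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ParseError(f"{path}:{i}: cytoBand needs 5 columns, got {len(parts)}")
        chrom, start, end, name, stain = parts[:5]
        try:
            rows.append((chrom, int(start), int(end), name, stain))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer coordinate") from exc
    if not rows:
        raise ValidationError(f"{path}: no bands")
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    bands = bands.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    for chrom, grp in bands.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(f"overlapping bands on {chrom}")

    boundaries: dict[str, int | None] = {}
    for chrom, grp in bands.groupby("chrom"):
        q = grp[grp["name"].str.startswith("q")]
        if q.empty:
            logger.warning("chromosome %s has no q-band; treated as single arm 'p'", chrom)
            boundaries[normalize_chrom(chrom)] = None
        else:
            boundaries[normalize_chrom(chrom)] = int(
                q.loc[q["name"].sort_values().index[0], "start"]
            )
    return CytoBandMap(bands=bands, arm_boundaries=boundaries)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene list: one symbol per line, or 2-column TSV (symbol, source).

    Symbols are whitespace-trimmed and upper-cased; duplicates collapse with
    provenance tags concatenated. Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    members: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"\t", line)
        symbol = parts[0].strip().upper()
        if not symbol:
            continue
        source = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        tags = members.setdefault(symbol, [])
        if source and source not in tags:
            tags.append(source)
    if not members:
        raise ValidationError(f"{path}: no gene symbols after filtering")
    return GeneSet(
        name=name or path.stem,
        members=frozenset(members),
        provenance={s: tuple(t) for s, t in members.items() if t},
    )


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(gene_set.members):
            tags = gene_set.provenance.get(symbol)
            fh.write(f"{symbol}\t{';'.join(tags)}\n" if tags else f"{symbol}\n")


def merge_gene_sets(sets: Iterable[GeneSet], name: str) -> GeneSet:
    """Union of gene sets; per-member provenance tags are concatenated.

    Per-source and union sizes are logged so gene attrition across catalogue
    sources stays auditable.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("merge_gene_sets needs at least one input set")
    members: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for s in sets:
        logger.info("merge source %s: %d symbols", s.name, len(s))
        members |= s.members
        for sym in s.members:
            tags = provenance.setdefault(sym, [])
            for t in s.provenance.get(sym, (s.name,)):
                if t not in tags:
                    tags.append(t)
    logger.info("merged set %s: %d symbols from %d sources", name, len(members), len(sets))
    return GeneSet(
        name=name,
        members=frozenset(members),
        provenance={s: tuple(t) for s, t in provenance.items()},
    )


def resolve_symbols(annotation: GenomeAnnotation, gene_set: GeneSet) -> np.ndarray:
    """Boolean mask over annotation rows marking genes whose symbol is in the set.

    Unresolved symbols (present in the set, absent from the annotation) are
    logged with a count.
    """
    upper = annotation.symbols()
    mask = upper.isin(gene_set.members).to_numpy()
    resolved = set(upper[mask])
    unresolved = gene_set.members - resolved
    if unresolved:
        logger.warning(
            "gene set %s: %d of %d symbols not found in annotation",
            gene_set.name, len(unresolved), len(gene_set),
        )
    return mask
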