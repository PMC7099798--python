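"""End-to-end orchestration: genome -> co-distribution -> enrichment ->
expression preprocessing -> differential expression -> intersection ->
trajectories, from a single config with fixed seeds.

Every stage writes its tables under the configured output directory and the
run finishes with a manifest (stage, artifact, rows, sha256) plus a
human-readable summary. Rerunning the same config and seed reproduces all
deterministic outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coloc, de, enrichment, genome_io, preprocess, simulate, trajectory

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    genome: dict[str, Any] = field(default_factory=dict)
    coloc: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    expression: dict[str, Any] = field(default_factory=dict)
    de: dict[str, Any] = field(default_factory=dict)
    trajectory: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "seed" not in raw:
            raise PipelineError("config: missing required key 'seed'")
        if "outdir" not in raw:
            raise PipelineError("config: missing required key 'outdir'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _count_rows(path: Path) -> int:
    return sum(1 for _ in path.open())


def _child_seed(seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig | dict[str, Any]) -> pd.DataFrame:
    """Execute all stages in order; returns the manifest table."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[tuple[str, Path]] = []
    summary: list[str] = []

    def record(stage: str, path: Path) -> None:
        artifacts.append((stage, path))

    # ----- stage 1: genome ---------------------------------------------------
    stage = "genome"
    gcfg = dict(config.genome)
    try:
        if gcfg.get("simulate", True) and "annotation" not in gcfg:
            sim_kwargs = {k: v for k, v in gcfg.items() if k != "simulate"}
            sim_kwargs.setdefault("seed", _child_seed(config.seed, "genome"))
            genome_cfg = simulate.SyntheticGenomeConfig(**sim_kwargs)
            annotation, set_a, set_b, _truth = simulate.simulate_genome(
                genome_cfg, outdir=outdir
            )
        else:
            if "annotation" not in gcfg:
                raise PipelineError(
                    "genome stage: missing key 'annotation' and simulation disabled"
                )
            annotation = genome_io.read_gene_annotation(
                gcfg["annotation"],
                dialect=gcfg.get("dialect", "bed6"),
                chrom_sizes=gcfg.get("chrom_sizes"),
            )
            for key in ("set_a", "set_b"):
                if key not in gcfg:
                    raise PipelineError(f"genome stage: missing key {key!r}")
            set_a = genome_io.read_gene_list(gcfg["set_a"], name="set_a")
            set_b = genome_io.read_gene_list(gcfg["set_b"], name="set_b")
            genome_io.write_bed6(annotation, outdir / "genes.bed")
            genome_io.write_chrom_sizes(annotation, outdir / "chrom.sizes")
            genome_io.write_gene_list(set_a, outdir / "set_a.txt")
            genome_io.write_gene_list(set_b, outdir / "set_b.txt")
        for name in ("genes.bed", "chrom.sizes", "set_a.txt", "set_b.txt"):
            record(stage, outdir / name)
        summary.append(
            f"genome: {len(annotation)} genes on {len(annotation.chromosomes)} chromosomes; "
            f"|A|={len(set_a)}, |B|={len(set_b)}"
        )
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ----- stage 2: co-distribution ------------------------------------------
    stage = "coloc"
    ccfg = dict(config.coloc)
    try:
        window = int(ccfg.get("window", 1_000_000))
        step = int(ccfg.get("step", window))
        method = ccfg.get("method", "pearson")
        transform = ccfg.get("transform", "log10")
        grid = coloc.build_windows(annotation, window, step)
        counts = coloc.count_in_windows(grid, annotation, set_a, set_b)
        coloc.write_window_counts(counts, outdir / "window_counts.tsv")
        threshold = float(ccfg.get("threshold", 0.5))
        for which in ("a", "b"):
            coloc.ratio_profile(counts, which=which, threshold=threshold).to_csv(
                outdir / f"ratio_{which}.tsv", sep="\t", index=False, float_format="%.6g"
            )
        n_perm = int(ccfg.get("permutations", 199))
        result = coloc.codistribution_permutation_pvalue(
            annotation, set_a, set_b, grid,
            n_perm=n_perm, seed=_child_seed(config.seed, "coloc"),
            method=method, transform=transform,
        )
        pd.DataFrame(
            [{
                "r": result.r, "method": result.method, "transform": result.transform,
                "n_windows_used": result.n_windows_used,
                "n_windows_excluded": result.n_windows_excluded,
                "permutation_pvalue": result.permutation_pvalue,
                "n_permutations": result.n_permutations,
            }]
        ).to_csv(outdir / "codistribution.tsv", sep="\t", index=False, float_format="%.6g")
        for name in ("window_counts.tsv", "ratio_a.tsv", "ratio_b.tsv", "codistribution.tsv"):
            record(stage, outdir / name)
        summary.append(
            f"coloc: r={result.r:.3f} over {result.n_windows_used} windows "
            f"(perm p={result.permutation_pvalue:.4g}, {n_perm} permutations)"
        )
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ----- stage 3: enrichment -----------------------------------------------
    stage = "enrichment"
    ecfg = dict(config.enrichment)
    try:
        bands = (
            genome_io.read_cytoband(ecfg["cytoband"]) if "cytoband" in ecfg else None
        )
        level = ecfg.get("level", "chromosome")
        for label, gene_set in (("a", set_a), ("b", set_b)):
            table = coloc.chromosome_enrichment(annotation, gene_set, bands=bands, level=level)
            enrichment.write_enrichment_table(table, outdir / f"chrom_enrichment_{label}.tsv")
            record(stage, outdir / f"chrom_enrichment_{label}.tsv")
        if ecfg.get("gmt") == "simulate":
            terms = simulate.simulate_term_collection(
                annotation.symbols().tolist(),
                seed=_child_seed(config.seed, "gmt"),
                enriched_in=set_a,
                outpath=outdir / "terms.gmt",
            )
            record(stage, outdir / "terms.gmt")
        elif "gmt" in ecfg:
            terms = enrichment.read_gmt(ecfg["gmt"])
        else:
            terms = None
        if terms is not None:
            background = genome_io.GeneSet(
                name="annotation", members=frozenset(annotation.symbols())
            )
            ora = enrichment.ora_test(
                set_a, terms, background, alpha=float(ecfg.get("alpha", 0.05))
            )
            enrichment.write_enrichment_table(ora, outdir / "ora.tsv")
            record(stage, outdir / "ora.tsv")
            summary.append(
                f"enrichment: {int(ora['significant'].sum())} of {len(ora)} terms "
                f"significant for set A"
            )
        else:
            summary.append("enrichment: chromosome-level only (no GMT supplied)")
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ----- stage 4: expression preprocessing ---------------------------------
    stage = "expression"
    xcfg = dict(config.expression)
    try:
        if xcfg.get("simulate", True) and "probes" not in xcfg:
            sim_kwargs = {k: v for k, v in xcfg.items()
                          if k not in {"simulate", "n_planted", "planted_log2fc"}}
            sim_kwargs.setdefault("seed", _child_seed(config.seed, "expression"))
            n_genes = int(sim_kwargs.get("n_genes", 2000))
            rng = np.random.default_rng(_child_seed(config.seed, "panel"))
            # expression panel drawn from the annotation so the namespaces of
            # the genome sets and the DE genes line up; genes in A∩B enter
            # the panel first so a three-way intersection is reachable
            common_ab = np.array(sorted(set_a.members & set_b.members), dtype=object)
            symbols = annotation.symbols().to_numpy()
            head = common_ab[: min(len(common_ab), max(n_genes // 20, 10))]
            rest = rng.choice(
                np.setdiff1d(symbols, head), size=n_genes - len(head), replace=False
            )
            panel = np.concatenate([head, rest])
            if "effects" not in sim_kwargs:
                n_planted = int(xcfg.get("n_planted", 40))
                shift = float(xcfg.get("planted_log2fc", 2.0))
                planted = list(head[: min(len(head), n_planted // 2)])
                others = rng.choice(
                    np.setdiff1d(panel, planted),
                    size=n_planted - len(planted), replace=False,
                )
                planted += list(others)
                xsim_regions = tuple(sim_kwargs.get("regions", ("OFC", "HIP", "CBC")))
                xsim_stages = tuple(sim_kwargs.get("stages", (1, 2, 3, 4)))
                sim_kwargs["effects"] = tuple(
                    simulate.PlantedEffect(gene=g, log2fc=shift, region=xsim_regions[-1])
                    if i % 2 == 0
                    else simulate.PlantedEffect(gene=g, log2fc=shift, stage=xsim_stages[-1])
                    for i, g in enumerate(planted)
                )
            sim_kwargs["gene_ids"] = list(panel)
            sim_kwargs["n_genes"] = n_genes
            xp_cfg = simulate.SyntheticExpressionConfig(**sim_kwargs)
            sim = simulate.simulate_probe_expression(xp_cfg, outdir=outdir)
            probe_df, probe_map, meta = sim.probe_matrix, sim.probe_map, sim.meta
        else:
            for key in ("probes", "probe_map", "samples"):
                if key not in xcfg:
                    raise PipelineError(
                        f"expression stage: missing key {key!r} and simulation disabled"
                    )
            probe_df = preprocess.read_probe_matrix(xcfg["probes"])
            probe_map = pd.read_csv(xcfg["probe_map"], sep="\t")
            meta = preprocess.read_sample_meta(xcfg["samples"])
            preprocess.write_probe_matrix(probe_df, outdir / "probes.tsv")
            probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
            preprocess.write_sample_meta(meta, outdir / "samples.tsv")
        bundle = preprocess.rma_preprocess(probe_df, probe_map, meta)
        preprocess.write_expression(bundle, outdir / "expression.tsv")
        for name in ("probes.tsv", "probe_map.tsv", "samples.tsv", "expression.tsv"):
            record(stage, outdir / name)
        summary.append(
            f"expression: {bundle.n_genes} genes x {bundle.n_samples} samples after "
            "background correction, quantile normalization and median polish"
        )
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ----- stage 5: differential expression ----------------------------------
    stage = "de"
    dcfg = dict(config.de)
    try:
        alpha = float(dcfg.get("alpha", 0.05))
        fc = float(dcfg.get("fc", 2.0))
        mode = dcfg.get("mode", "both")
        plan = de.make_comparison_plan(bundle.meta, mode=mode)
        tables = de.moderated_t_fit(bundle, plan, alpha=alpha, fc=fc)
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        rows = []
        for comp in plan:
            path = de_dir / f"{comp.label}.tsv"
            de.write_de_table(tables[comp.label], path)
            record(stage, path)
            rows.append((comp.label, comp.kind, int(tables[comp.label]["pass"].sum())))
        pd.DataFrame(rows, columns=["comparison", "kind", "n_pass"]).to_csv(
            outdir / "de_summary.tsv", sep="\t", index=False
        )
        record(stage, outdir / "de_summary.tsv")
        region_mats, adjacent = de.de_count_matrix(tables, plan)
        for stg, mat in region_mats.items():
            path = outdir / f"de_counts_region_pair_stg{stg}.tsv"
            mat.to_csv(path, sep="\t", index_label="region")
            record(stage, path)
        adjacent.to_csv(outdir / "de_counts_adjacent.tsv", sep="\t", index=False)
        record(stage, outdir / "de_counts_adjacent.tsv")
        de_genes = sorted(de.de_gene_union(tables))
        (outdir / "de_genes.txt").write_text("".join(g + "\n" for g in de_genes))
        record(stage, outdir / "de_genes.txt")
        summary.append(f"de: {len(plan)} comparisons, {len(de_genes)} genes pass "
                       f"adj.P<{alpha} and |FC|>={fc}")
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ----- stage 6: intersection ----------------------------------------------
    stage = "intersect"
    try:
        if de_genes:
            de_set = genome_io.GeneSet(name="de_genes", members=frozenset(
                g.upper() for g in de_genes
            ))
            report = trajectory.intersect_sets([set_a, set_b, de_set])
            report.to_frame().to_csv(outdir / "intersection.tsv", sep="\t", index=False)
            common = sorted(report.common)
        else:
            pd.DataFrame(
                [("common", "set_a & set_b & de_genes", 0, "")],
                columns=["level", "sets", "size", "members"],
            ).to_csv(outdir / "intersection.tsv", sep="\t", index=False)
            common = []
        record(stage, outdir / "intersection.tsv")
        summary.append(f"intersect: {len(common)} genes common to A, B and the DE screen")
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ----- stage 7: trajectories ----------------------------------------------
    stage = "trajectory"
    try:
        expr_genes = set(bundle.expression.index.astype(str).str.upper())
        candidates = [g for g in common if g in expr_genes]
        if not candidates:
            candidates = sorted((set_a.members | set_b.members) & expr_genes)[:20]
        if not candidates:
            candidates = list(bundle.expression.index[:5].astype(str))
        traj = trajectory.trajectory_means(bundle, candidates)
        trajectory.write_trajectories(traj, outdir / "trajectories.tsv")
        record(stage, outdir / "trajectories.tsv")
        summary.append(f"trajectory: {traj['gene_id'].nunique()} genes x "
                       f"{traj[['region', 'stage']].drop_duplicates().shape[0]} cells")
        logger.info(summary[-1])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    manifest = pd.DataFrame(
        [
            (stage_name, p.relative_to(outdir).as_posix(), _count_rows(p), _sha256(p))
            for stage_name, p in artifacts
        ],
        columns=["stage", "artifact", "n_rows", "sha256"],
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    (outdir / "summary.txt").write_text("".join(line + "\n" for line in summary))
    logger.info("pipeline complete: %d stages, %d artifacts",
                manifest["stage"].nunique(), len(manifest))
    return manifest
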