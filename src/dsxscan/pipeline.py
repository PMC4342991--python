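"""End-to-end orchestration of the sexual-dimorphism analysis stages.

``run_all`` wires the stages together on a synthetic study in which a
subset of genes contain planted binding sites and a subset carry planted
sex effects, so the final DET / motif-gene overlap has a known ground
truth. Each stage is also runnable on its own against user-supplied files
(see :mod:`dsxscan.cli`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import annotation, expression, integrate, motif, simulate


def _echo(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return dataclasses.asdict(cfg)
    return dict(cfg)


def simulate_study(
    outdir: Union[str, Path],
    seed: int = 0,
    genome_cfg: Optional[simulate.GenomeSimConfig] = None,
    expr_cfg: Optional[simulate.ExprSimConfig] = None,
    motif_spec: motif.MotifSpec = motif.MotifSpec(),
    n_genes: Optional[int] = None,
    gene_min_len: int = 200,
    gene_max_len: int = 300,
) -> dict:
    """Write a complete synthetic study (genome, genes, expression, truth).

    Planted motif sites are made intragenic: the first genes are placed so
    that each contains one planted site, and the planted sex effects are
    assigned to a deterministic subset of those motif-bearing genes plus
    others, giving the downstream overlap stage a non-trivial truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_cfg = genome_cfg or simulate.GenomeSimConfig(
        n_scaffolds=4,
        scaffold_length=500_000,
        planted_sites=(
            simulate.PlantedSiteSpec(0, 20, "+"),
            simulate.PlantedSiteSpec(1, 20, "+"),
            simulate.PlantedSiteSpec(0, 4, "-"),
        ),
        seed=seed,
        # sparse sites: room for a containing gene and for genes outside
        # the proximity window, so the motif-proximate set is non-trivial
        site_min_gap=25_000,
    )
    expr_cfg = expr_cfg or simulate.ExprSimConfig(seed=seed)
    n_genes = n_genes if n_genes is not None else expr_cfg.n_genes
    if n_genes != expr_cfg.n_genes:
        raise ValueError("n_genes must match expr_cfg.n_genes")

    genome, genome_truth = simulate.simulate_genome(genome_cfg, motif_spec)
    site_intervals = [
        (s.scaffold, s.start, s.end) for s in genome_truth.planted_sites
    ]
    genes = simulate.simulate_annotation(
        genome,
        n_genes,
        seed,
        min_len=gene_min_len,
        max_len=gene_max_len,
        contain_intervals=site_intervals,
    )
    gene_ids = sorted(g.gene_id for g in genes)
    n_de = simulate._round_half_up(expr_cfg.n_genes * expr_cfg.de_fraction)
    # put as many planted effects as possible on motif-bearing genes so the
    # overlap stage has planted signal; the rest go to the remaining genes
    motif_bearing = [f"g{i + 1:04d}" for i in range(len(site_intervals))]
    n_on_motif = min(n_de, len(motif_bearing))
    de_gene_ids = motif_bearing[:n_on_motif] + [
        g for g in gene_ids if g not in motif_bearing
    ][: n_de - n_on_motif]
    study, expr_truth = simulate.simulate_expression(
        expr_cfg, gene_ids=gene_ids, de_gene_ids=de_gene_ids
    )

    simulate.write_genome_fasta(genome, outdir / "genome.fa")
    annotation.write_gff_genes(genes, outdir / "genes.gff3")
    study.to_files(
        outdir / "expression.tsv", outdir / "samples.tsv", outdir / "probe_map.tsv"
    )
    genome_truth.sites_table().to_csv(
        outdir / "truth_sites.tsv", sep="\t", index=False
    )
    expr_truth.de_table().to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    return {
        "genome_fasta": str(outdir / "genome.fa"),
        "gff3": str(outdir / "genes.gff3"),
        "expression_tsv": str(outdir / "expression.tsv"),
        "samples_tsv": str(outdir / "samples.tsv"),
        "probe_map_tsv": str(outdir / "probe_map.tsv"),
        "n_planted_sites": len(genome_truth.planted_sites),
        "n_planted_de": len(expr_truth.de_genes),
        "genome_cfg": _echo(genome_cfg),
        "expr_cfg": _echo(expr_cfg),
    }


def run_scan(
    genome_fasta: Union[str, Path],
    motif_spec: motif.MotifSpec,
    out_bed: Union[str, Path],
) -> list[motif.MotifHit]:
    hits = motif.scan_genome(genome_fasta, motif_spec)
    motif.write_hits_bed(hits, out_bed)
    return hits


def run_annotate(
    hits_bed: Union[str, Path],
    gff3: Union[str, Path],
    proximity: annotation.ProximityConfig,
    out_tsv: Union[str, Path],
) -> list[annotation.GeneSiteAssociation]:
    hits = motif.read_hits_bed(hits_bed)
    genes = annotation.read_gff_genes(gff3)
    associations = annotation.associate_genes(hits, genes, proximity)
    annotation.write_associations_tsv(associations, out_tsv)
    return associations


def run_de_stage(
    expression_tsv: Union[str, Path],
    samples_tsv: Union[str, Path],
    probe_map_tsv: Union[str, Path],
    de_cfg: expression.DEConfig,
    out_tsv: Union[str, Path],
) -> tuple[pd.DataFrame, dict]:
    study = expression.ExpressionStudy.from_files(
        expression_tsv, samples_tsv, probe_map_tsv
    )
    results, summary = expression.run_de(study, de_cfg)
    results.to_csv(out_tsv, sep="\t", index_label="gene_id", float_format="%.6g")
    return results, summary


def run_all(
    outdir: Union[str, Path],
    seed: int = 0,
    motif_spec: motif.MotifSpec = motif.MotifSpec(),
    proximity: annotation.ProximityConfig = annotation.ProximityConfig(),
    de_cfg: expression.DEConfig = expression.DEConfig(),
    genome_cfg: Optional[simulate.GenomeSimConfig] = None,
    expr_cfg: Optional[simulate.ExprSimConfig] = None,
) -> dict:
    """Simulate -> scan -> annotate -> DE -> integrate, all artifacts on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_study(
        outdir, seed=seed, genome_cfg=genome_cfg, expr_cfg=expr_cfg,
        motif_spec=motif_spec,
    )
    hits = run_scan(sim["genome_fasta"], motif_spec, outdir / "hits.bed")
    associations = run_annotate(
        outdir / "hits.bed", sim["gff3"], proximity, outdir / "associations.tsv"
    )
    de_results, de_summary = run_de_stage(
        sim["expression_tsv"],
        sim["samples_tsv"],
        sim["probe_map_tsv"],
        de_cfg,
        outdir / "de_results.tsv",
    )
    expression.volcano_table(de_results, outdir / "volcano.tsv")

    det_genes = set(de_results.index[de_results["is_det"]])
    motif_genes = annotation.motif_gene_list(associations)
    overlap = integrate.overlap_det_motif(det_genes, motif_genes)
    # generic over-representation demo: is the motif-proximate set enriched
    # among DETs relative to the expression universe?
    universe = set(de_results.index)
    categories = {"motif_proximate": set(motif_genes) & universe}
    enrichment = integrate.enrichment_test(det_genes, categories, universe)
    summary = integrate.final_report(
        de_results,
        associations,
        overlap,
        enrichment,
        outdir,
        config_echo={
            "seed": seed,
            "motif": _echo(motif_spec),
            "proximity": _echo(proximity),
            "de": _echo(de_cfg),
            "simulate": sim,
        },
    )
    summary["n_hits"] = len(hits)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
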