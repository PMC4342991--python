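"""Intersect DE gene lists with motif-proximate genes; over-representation.

The over-representation statistic is the plain upper-tail hypergeometric
probability P(X >= overlap) with Benjamini-Hochberg adjustment across
categories. This is a generic gene-set test, not a replica of any
annotation service's modified statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneSiteAssociation, write_associations_tsv


@dataclass(frozen=True)
class OverlapReport:
    n_det: int
    n_motif_genes: int
    overlap_ids: tuple[str, ...]
    n_overlap: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_overlap", len(self.overlap_ids))

    def to_dict(self) -> dict:
        return {
            "n_det": self.n_det,
            "n_motif_genes": self.n_motif_genes,
            "n_overlap": self.n_overlap,
            "overlap_ids": list(self.overlap_ids),
        }


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    universe_size: int
    category_size: int
    selected_size: int
    overlap: int
    p_value: float
    p_adj: float


def overlap_det_motif(
    det_genes: Iterable[str], motif_genes: Iterable[str]
) -> OverlapReport:
    """Exact intersection of the DE gene list with motif-proximate genes."""
    det = set(det_genes)
    motif = set(motif_genes)
    return OverlapReport(
        n_det=len(det),
        n_motif_genes=len(motif),
        overlap_ids=tuple(sorted(det & motif)),
    )


def enrichment_test(
    selected: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per category.

    p = P(X >= overlap) with X ~ Hypergeometric(universe, category,
    selected); BH-adjusted across all tested categories. ``selected`` and
    every category must lie within the universe.
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError(
            f"selected genes outside the universe: "
            f"{sorted(selected - universe)[:5]}"
        )
    n_univ = len(universe)
    n_sel = len(selected)
    names = sorted(categories)
    raw = []
    rows = []
    for name in names:
        members = set(categories[name])
        if not members <= universe:
            raise ValueError(
                f"category {name!r} has genes outside the universe: "
                f"{sorted(members - universe)[:5]}"
            )
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_sel))
        p = min(1.0, p)
        raw.append(p)
        rows.append((name, len(members), k, p))
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    return [
        EnrichmentResult(name, n_univ, size, n_sel, k, p, float(p_adj))
        for (name, size, k, p), p_adj in zip(rows, adjusted)
    ]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "category_id",
        "universe_size",
        "category_size",
        "selected_size",
        "overlap",
        "p_value",
        "p_adj",
    ]
    return pd.DataFrame([vars(r) for r in results], columns=cols)


def read_category_map(path: Union[str, PathLike]) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, category_id) -> category -> gene set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("category map needs two columns: gene_id, category_id")
    gene_col, cat_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, cat in zip(df[gene_col], df[cat_col]):
        out.setdefault(cat, set()).add(gene)
    return out


def final_report(
    de_results: pd.DataFrame,
    associations: Sequence[GeneSiteAssociation],
    overlap: OverlapReport,
    enrichment: Sequence[EnrichmentResult],
    outdir: Union[str, PathLike],
    config_echo: Optional[dict] = None,
) -> dict:
    """Write the per-gene master table, overlap, enrichment and run summary.

    Returns the machine-readable run summary (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    assoc_by_gene: dict[str, list[GeneSiteAssociation]] = {}
    for a in associations:
        assoc_by_gene.setdefault(a.gene_id, []).append(a)
    master_rows = []
    for gene_id, row in de_results.iterrows():
        gene_assoc = assoc_by_gene.get(gene_id, [])
        master_rows.append(
            {
                "gene_id": gene_id,
                "log2_fc": row["log2_fc"],
                "p_raw": row["p_raw"],
                "p_adj": row["p_adj"],
                "is_det": bool(row["is_det"]),
                "bias_class": row["bias_class"],
                "n_motif_sites": len(gene_assoc),
                "site_relations": ",".join(a.relation for a in gene_assoc),
                "site_distances": ",".join(str(a.distance) for a in gene_assoc),
            }
        )
    master_cols = [
        "gene_id",
        "log2_fc",
        "p_raw",
        "p_adj",
        "is_det",
        "bias_class",
        "n_motif_sites",
        "site_relations",
        "site_distances",
    ]
    master = pd.DataFrame(master_rows, columns=master_cols)
    master.to_csv(outdir / "genes_master.tsv", sep="\t", index=False, float_format="%.6g")
    write_associations_tsv(associations, outdir / "associations.tsv")
    enrichment_table(enrichment).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )

    summary = {
        "n_genes_tested": int(len(de_results)),
        "n_det": int(de_results["is_det"].sum()) if len(de_results) else 0,
        "n_male_strong": int((de_results.get("bias_class", pd.Series(dtype=str)) == "male_strong").sum()),
        "n_female_strong": int((de_results.get("bias_class", pd.Series(dtype=str)) == "female_strong").sum()),
        "n_associations": len(associations),
        "n_motif_genes": len(assoc_by_gene),
        "overlap": overlap.to_dict(),
        "n_enrichment_categories": len(enrichment),
        "config": config_echo or {},
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
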