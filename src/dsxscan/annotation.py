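"""Assign motif hits to genes by containment or flanking-window proximity.

A hit is *intragenic* when its interval overlaps a gene's interval, and
otherwise associates with every gene whose closest end lies within a fixed
window (default 10 kb, boundary inclusive). Upstream/downstream labels are
relative to the gene's strand (5' side = upstream); the hit's own strand
plays no role in labeling. All coordinates are 0-based half-open
internally; GFF3 1-based inclusive coordinates are converted at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .motif import MotifHit


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class ProximityConfig:
    """Flanking window for gene-site association, in bp, boundary inclusive."""

    window_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


@dataclass(frozen=True)
class GeneSiteAssociation:
    gene_id: str
    hit: MotifHit
    relation: str  # intragenic | upstream | downstream
    distance: int  # closest-end gap; 0 if intragenic


def read_gff_genes(path: Union[str, PathLike]) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file into 0-based half-open models.

    Non-gene features are ignored. Raises ``ValueError`` with the line
    number on a malformed feature line.
    """
    import gffutils

    path = Path(path)
    # Pre-validate line by line so parse errors carry a line number;
    # gffutils then handles attribute parsing and ID resolution.
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid coordinates {start}..{end}")
            n_features += 1
    if n_features == 0:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        if feat.id in seen:
            raise ValueError(f"duplicate gene ID {feat.id!r} in {path}")
        seen.add(feat.id)
        genes.append(
            GeneModel(
                gene_id=feat.id,
                scaffold=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
            )
        )
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: Union[str, PathLike]) -> None:
    """Write gene models as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tdsxscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def associate_genes(
    hits: Sequence[MotifHit],
    genes: Sequence[GeneModel],
    cfg: ProximityConfig = ProximityConfig(),
) -> list[GeneSiteAssociation]:
    """All (gene, hit) pairs with overlap or closest-end gap <= window_bp.

    A hit may associate with several genes and a gene with several hits;
    every qualifying pair is reported (no nearest-only reduction). Output
    is sorted by (gene_id, hit.start).
    """
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)

    out: list[GeneSiteAssociation] = []
    for scaf, scaf_genes in by_scaffold.items():
        scaf_hits = [h for h in hits if h.scaffold == scaf]
        if not scaf_hits:
            continue
        g_start = np.array([g.start for g in scaf_genes])
        g_end = np.array([g.end for g in scaf_genes])
        g_minus = np.array([g.strand == "-" for g in scaf_genes])
        for h in scaf_hits:
            overlap = (h.start < g_end) & (g_start < h.end)
            # signed gaps: positive only on the respective side
            gap_left = g_start - h.end  # hit left of gene
            gap_right = h.start - g_end  # hit right of gene
            gap = np.where(gap_left >= 0, gap_left, gap_right)
            near = ~overlap & (gap >= 0) & (gap <= cfg.window_bp)
            for j in np.nonzero(overlap | near)[0]:
                if overlap[j]:
                    relation, dist = "intragenic", 0
                else:
                    hit_is_left = gap_left[j] >= 0
                    # 5' flank of a + gene is its left side
                    if hit_is_left != g_minus[j]:
                        relation = "upstream"
                    else:
                        relation = "downstream"
                    dist = int(gap[j])
                out.append(
                    GeneSiteAssociation(scaf_genes[j].gene_id, h, relation, dist)
                )
    out.sort(key=lambda a: (a.gene_id, a.hit.start, a.hit.strand))
    return out


def motif_gene_list(associations: Iterable[GeneSiteAssociation]) -> list[str]:
    """Deduplicated, sorted gene ids with at least one associated site."""
    return sorted({a.gene_id for a in associations})


def write_associations_tsv(
    associations: Sequence[GeneSiteAssociation], path: Union[str, PathLike]
) -> None:
    import pandas as pd

    rows = [
        {
            "gene_id": a.gene_id,
            "scaffold": a.hit.scaffold,
            "hit_start": a.hit.start,
            "hit_end": a.hit.end,
            "hit_strand": a.hit.strand,
            "mismatches": a.hit.mismatches,
            "relation": a.relation,
            "distance": a.distance,
        }
        for a in associations
    ]
    cols = [
        "gene_id",
        "scaffold",
        "hit_start",
        "hit_end",
        "hit_strand",
        "mismatches",
        "relation",
        "distance",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
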