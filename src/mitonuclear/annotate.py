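"""SNP-to-gene annotation and QTL interval grouping.

A SNP is assigned to a gene when it falls inside any CDS interval or
within a configurable window (default 250 bp) upstream of the CDS start on
the gene's strand. Significant SNPs are grouped into QTL intervals by
single-linkage merging within a bp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "read_gff3",
    "assign_snp_to_genes",
    "collapse_qtls",
]


@dataclass
class GeneModel:
    """A gene with its CDS intervals (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        for s, e in self.cds:
            if s > e:
                raise ValueError(f"{self.name}: malformed CDS interval ({s}, {e})")

    @property
    def cds_start(self) -> int:
        """Translation-start side of the CDS span (strand-aware)."""
        if not self.cds:
            raise ValueError(f"{self.name}: no CDS intervals")
        return min(s for s, _ in self.cds) if self.strand == "+" else max(e for _, e in self.cds)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene features + their CDS intervals) from GFF3.

    Parsed with :mod:`gffutils` (in-memory database); CDS features are
    attached to genes directly or through transcript features. The gene
    label prefers the ``Name`` attribute, falling back to ``ID``. Genes
    without CDS children are skipped.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for g in db.features_of_type("gene"):
        cds = sorted(
            (c.start, c.end)
            for c in db.children(g, featuretype="CDS", order_by="start")
        )
        if not cds:
            continue
        models.append(
            GeneModel(
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                name=g.attributes.get("Name", [g.id])[0],
                cds=cds,
            )
        )
    return models


def assign_snp_to_genes(
    snps: pd.DataFrame,
    gene_models: list[GeneModel],
    upstream_window: int = 250,
    strict_chroms: bool = True,
) -> pd.DataFrame:
    """Map SNPs to genes: inside a CDS, or within the upstream window.

    "Upstream" is measured from the CDS start (translation start) on the
    gene's strand, end-inclusive: a plus-strand SNP at ``cds_start - d``
    is an upstream hit for ``1 <= d <= upstream_window``. A SNP may hit
    multiple genes. Returns columns ``snp_id``, ``chrom``, ``pos``,
    ``gene``, ``relation`` (``cds`` | ``upstream``), ``distance`` (bp to
    the CDS start; 0 for CDS hits).
    """
    gene_chroms = {g.chrom for g in gene_models}
    if strict_chroms:
        unknown = set(snps["chrom"]) - gene_chroms
        if unknown:
            raise ValueError(
                f"SNP chromosomes absent from gene models: {sorted(unknown)}"
            )
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits = []
    for _, row in snps.iterrows():
        pos = int(row["pos"])
        snp_id = row.get("snp_id", f"{row['chrom']}:{pos}")
        for g in by_chrom.get(row["chrom"], []):
            if any(s <= pos <= e for s, e in g.cds):
                hits.append(
                    {"snp_id": snp_id, "chrom": g.chrom, "pos": pos,
                     "gene": g.name, "relation": "cds", "distance": 0}
                )
                continue
            cstart = g.cds_start
            dist = cstart - pos if g.strand == "+" else pos - cstart
            if 1 <= dist <= upstream_window:
                hits.append(
                    {"snp_id": snp_id, "chrom": g.chrom, "pos": pos,
                     "gene": g.name, "relation": "upstream", "distance": int(dist)}
                )
    return pd.DataFrame(
        hits, columns=["snp_id", "chrom", "pos", "gene", "relation", "distance"]
    )


def collapse_qtls(
    significant_snps: pd.DataFrame,
    merge_window_bp: int = 25_000,
    p_col: str = "p_int",
) -> pd.DataFrame:
    """Group significant SNPs into QTL intervals by single-linkage merging.

    SNPs on the same chromosome within ``merge_window_bp`` of each other
    join the same QTL; the peak SNP is the member with the smallest
    p-value. Returns one row per QTL: ``chrom``, ``start``, ``end``,
    ``n_snps``, ``peak_pos``, ``peak_p``. Every input SNP belongs to
    exactly one QTL and intervals on a chromosome are disjoint.
    """
    cols = ["chrom", "start", "end", "n_snps", "peak_pos", "peak_p"]
    if len(significant_snps) == 0:
        return pd.DataFrame(columns=cols)
    df = significant_snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
    qtls = []
    cur: dict | None = None
    for _, row in df.iterrows():
        pos = int(row["pos"])
        p = float(row[p_col]) if p_col in df.columns else np.nan
        if (
            cur is None
            or row["chrom"] != cur["chrom"]
            or pos - cur["end"] > merge_window_bp
        ):
            if cur is not None:
                qtls.append(cur)
            cur = {"chrom": row["chrom"], "start": pos, "end": pos,
                   "n_snps": 1, "peak_pos": pos, "peak_p": p}
        else:
            cur["end"] = pos
            cur["n_snps"] += 1
            if np.isnan(cur["peak_p"]) or (not np.isnan(p) and p < cur["peak_p"]):
                cur["peak_pos"], cur["peak_p"] = pos, p
    qtls.append(cur)
    return pd.DataFrame(qtls, columns=cols)
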