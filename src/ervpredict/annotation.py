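"""Derive raw insertion factors from genomic coordinates and gene models.

All coordinates here are 0-based half-open. The distance to the nearest exon
is measured from the nearer *edge* of the insertion to the nearer intron/exon
boundary; ties break toward the upstream (lower-coordinate) boundary. On the
+ strand the upstream intron boundary is a splice donor and the downstream an
acceptor; on the - strand the two are swapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from ervpredict.io_tables import ErvInsertion, GeneModel


@dataclass(frozen=True)
class IntronContext:
    gene_id: str
    intron_index: int  # 1-based ordinal in genomic coordinate order
    intron_start: int
    intron_end: int
    gene_strand: str

    @property
    def intron_size_bp(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def upstream_boundary_type(self) -> str:
        return "donor" if self.gene_strand == "+" else "acceptor"

    @property
    def downstream_boundary_type(self) -> str:
        return "acceptor" if self.gene_strand == "+" else "donor"


def relative_orientation(erv_strand: str, gene_strand: str) -> str:
    """'sense' iff the ERV and its enclosing gene are on the same strand."""
    for name, strand in (("erv_strand", erv_strand), ("gene_strand", gene_strand)):
        if strand not in ("+", "-"):
            raise ValueError(f"{name} must be '+' or '-', got {strand!r}")
    return "sense" if erv_strand == gene_strand else "antisense"


def find_enclosing_intron(
    coords: tuple, genes
) -> Union[None, IntronContext, list]:
    """Locate the intron fully containing an insertion interval.

    ``coords`` is (chrom, start, end) or (chrom, start, end, strand).
    Returns None when the insertion overlaps any exon or lies outside all
    genes, a single IntronContext when exactly one gene's intron contains it,
    and a list of contexts when introns of several overlapping genes do —
    the caller must then disambiguate.
    """
    chrom, start, end = coords[0], int(coords[1]), int(coords[2])
    if end <= start:
        raise ValueError(f"empty insertion interval {coords}")
    gene_iter = genes.values() if isinstance(genes, dict) else genes
    hits = []
    for gene in gene_iter:
        if gene.chrom != chrom:
            continue
        for idx, (istart, iend) in enumerate(gene.introns, start=1):
            if istart <= start and end <= iend:
                hits.append(
                    IntronContext(
                        gene_id=gene.gene_id,
                        intron_index=idx,
                        intron_start=istart,
                        intron_end=iend,
                        gene_strand=gene.strand,
                    )
                )
    if not hits:
        return None
    return hits[0] if len(hits) == 1 else hits


def exon_distance(coords: tuple, ctx: IntronContext) -> tuple[int, str]:
    """Distance in bp from the insertion's nearer edge to the nearer exon.

    Returns (distance_bp, nearest_site) with nearest_site the splice-site
    type (donor/acceptor) of the nearer boundary; ties break upstream.
    """
    start, end = int(coords[1]), int(coords[2])
    d_up = start - ctx.intron_start
    d_down = ctx.intron_end - end
    if d_up < 0 or d_down < 0:
        raise ValueError(f"insertion [{start}, {end}) extends outside intron [{ctx.intron_start}, {ctx.intron_end})")
    if d_up <= d_down:
        return d_up, ctx.upstream_boundary_type
    return d_down, ctx.downstream_boundary_type


def derive_factors(
    insertions: Sequence[dict],
    genes,
    families: Optional[dict] = None,
) -> list[ErvInsertion]:
    """Build factor records from BED-style insertions and gene models.

    Each insertion dict needs chrom/start/end/name/strand (as returned by
    :func:`ervpredict.io_tables.read_bed_insertions`). The ERV family comes
    from ``families[name]``, or from a ``name|family`` suffix in the BED name.
    Insertions outside any intron are skipped; an insertion falling in introns
    of several overlapping genes raises, naming the candidates.
    """
    records = []
    for ins in insertions:
        name = ins["name"]
        if families and name in families:
            family = families[name]
            rec_id = name
        elif "|" in name:
            rec_id, family = name.rsplit("|", 1)
        else:
            raise ValueError(f"insertion {name!r}: no family given (use a families mapping or a 'name|family' BED name)")
        coords = (ins["chrom"], ins["start"], ins["end"], ins["strand"])
        ctx = find_enclosing_intron(coords, genes)
        if ctx is None:
            continue
        if isinstance(ctx, list):
            candidates = [c.gene_id for c in ctx]
            raise ValueError(f"insertion {name!r} lies in introns of several genes {candidates}; disambiguate the gene")
        dist, _site = exon_distance(coords, ctx)
        records.append(
            ErvInsertion(
                id=rec_id,
                family=family,
                orientation=relative_orientation(ins["strand"], ctx.gene_strand),
                intron_size_bp=ctx.intron_size_bp,
                exon_distance_bp=dist,
                label="unknown",
                gene_id=ctx.gene_id,
                coords=coords,
            )
        )
    return records
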