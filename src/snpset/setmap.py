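"""Position-based SNP-to-gene assignment with configurable boundaries.

Two boundary conventions are used by the pipeline: a promoter-logic window of
2 kb upstream / 500 bp downstream (strand-aware) for the genotyped
self-contained set test, and a symmetric +/-50 kb flank (strand ignored) for
the gene-based stage, which is meant to capture regulatory elements.  Window
endpoints are inclusive on both sides and clamped at position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sim import AnnotationTable, SnpSpec

__all__ = ["GeneWindow", "SnpGeneMap", "gene_window", "map_snps_to_genes",
           "build_set_snplist"]


@dataclass(frozen=True)
class GeneWindow:
    gene: str
    chrom: str
    win_start: int
    win_stop: int

    def __post_init__(self) -> None:
        if self.win_start > self.win_stop:
            raise ValueError(f"{self.gene}: window start exceeds stop")
        if self.win_start < 1:
            raise ValueError(f"{self.gene}: window start below 1 (clamp upstream)")


@dataclass
class SnpGeneMap:
    """Bidirectional SNP/gene assignment."""

    snp_to_genes: dict[str, list[str]]
    gene_to_snps: dict[str, list[str]]
    snp_pos: dict[str, tuple[str, int]] = field(default_factory=dict)


def gene_window(
    gene: str,
    chrom: str,
    start: int,
    stop: int,
    strand: str = "+",
    boundary_up: int = 2000,
    boundary_down: int = 500,
    strand_aware: bool = True,
    symmetric_flank: int | None = None,
) -> GeneWindow:
    """Test window for one gene.

    With ``symmetric_flank`` set, the window is [start - flank, stop + flank]
    regardless of strand.  Otherwise the upstream boundary extends past the
    transcription start: [start - up, stop + down] on the + strand and, when
    ``strand_aware``, the mirror [start - down, stop + up] on the - strand.
    """
    if boundary_up < 0 or boundary_down < 0:
        raise ValueError("boundaries must be non-negative")
    if symmetric_flank is not None:
        if symmetric_flank < 0:
            raise ValueError("symmetric_flank must be non-negative")
        lo, hi = start - symmetric_flank, stop + symmetric_flank
    elif strand == "-" and strand_aware:
        lo, hi = start - boundary_down, stop + boundary_up
    else:
        lo, hi = start - boundary_up, stop + boundary_down
    return GeneWindow(gene, chrom, max(lo, 1), hi)


def map_snps_to_genes(
    snps: list[SnpSpec],
    annotation: AnnotationTable,
    boundary_up: int = 2000,
    boundary_down: int = 500,
    strand_aware: bool = True,
    symmetric_flank: int | None = None,
) -> SnpGeneMap:
    """Assign each SNP to every gene whose window contains it (inclusive).

    Multi-gene membership is allowed; genes and SNP lists come back sorted so
    the mapping is deterministic.
    """
    windows = [
        gene_window(r.gene, str(r.chrom), int(r.start), int(r.stop), r.strand,
                    boundary_up, boundary_down, strand_aware, symmetric_flank)
        for r in annotation.records.itertuples()
    ]
    by_chrom: dict[str, list[GeneWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    snp_to_genes: dict[str, list[str]] = {}
    gene_to_snps: dict[str, list[str]] = {w.gene: [] for w in windows}
    snp_pos: dict[str, tuple[str, int]] = {}
    for s in snps:
        snp_pos[s.snp_id] = (s.chrom, s.pos)
        hits = [
            w.gene for w in by_chrom.get(s.chrom, ())
            if w.win_start <= s.pos <= w.win_stop
        ]
        snp_to_genes[s.snp_id] = sorted(hits)
        for g in hits:
            gene_to_snps[g].append(s.snp_id)
    for g in gene_to_snps:
        gene_to_snps[g].sort(key=lambda sid: (snp_pos[sid][0], snp_pos[sid][1], sid))
    return SnpGeneMap(snp_to_genes, gene_to_snps, snp_pos)


def build_set_snplist(
    gene_set: list[str], snp_map: SnpGeneMap
) -> tuple[list[str], dict]:
    """Deduplicated, position-sorted SNP list for a gene set.

    Unknown gene names and genes contributing zero SNPs are reported, not
    fatal — genes can drop out of a panel for lack of coverage.  An empty
    union is an error: there is nothing to test.
    """
    unknown = [g for g in gene_set if g not in snp_map.gene_to_snps]
    empty = [
        g for g in gene_set
        if g in snp_map.gene_to_snps and not snp_map.gene_to_snps[g]
    ]
    union: set[str] = set()
    for g in gene_set:
        union.update(snp_map.gene_to_snps.get(g, ()))
    if not union:
        raise ValueError("gene set maps to zero SNPs")
    ordered = sorted(union, key=lambda sid: (*snp_map.snp_pos[sid], sid))
    report = {"unknown_genes": unknown, "empty_genes": empty,
              "n_genes": len(gene_set), "n_snps": len(ordered)}
    return ordered, report

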