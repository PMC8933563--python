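"""CRE candidate detection, peak-to-gene assignment, and Th0-novel peaks.

A developmental CRE candidate is an ATAC peak (accessibility is the
positional anchor) that carries concomitant H3K27Ac in the same cell
state. Peaks are assigned to genes by the gene-body-or-near-TSS rule: a
peak overlapping a gene body links to that gene; otherwise it links to the
gene with the nearest TSS provided the distance is strictly under
``max_tss_dist`` (default 10 kb). A "novel" Th0 peak is one with no
qualifying overlap against any developmental (DP or CD4SP) ATAC peak —
accessibility gained only upon stimulation, like the E4a element at Cd4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .intervals import IntervalIndex, distance_to_point, overlap_length
from .io_formats import GeneModel, GenomicInterval, PeakSet

Category = Literal["gene_body", "upstream", "downstream"]


@dataclass(frozen=True)
class PeakGeneLink:
    peak: GenomicInterval
    gene_id: str
    category: Category
    tss_distance: int


def gene_index(genes: Iterable[GeneModel]) -> IntervalIndex:
    """Index gene models by their body interval."""
    return IntervalIndex(genes, interval_of=lambda g: g.body)


def cre_candidates(atac: PeakSet, k27ac: PeakSet, min_bp: int = 1) -> PeakSet:
    """ATAC peaks with >= min_bp overlap against >= 1 H3K27Ac peak.

    The ATAC coordinates are retained; H3K27Ac serves only as evidence of
    enhancer activity.
    """
    if atac.assay != "ATAC":
        raise ValueError(f"first argument must be ATAC peaks, got assay {atac.assay!r}")
    if k27ac.assay != "H3K27Ac":
        raise ValueError(f"second argument must be H3K27Ac peaks, got assay {k27ac.assay!r}")
    if atac.state != k27ac.state:
        raise ValueError(f"cell states differ: {atac.state!r} vs {k27ac.state!r}")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    idx = IntervalIndex(k27ac.intervals)
    kept = [
        p
        for p in atac
        if any(overlap_length(p, k) >= min_bp for k in idx.query(p))
    ]
    return PeakSet(assay="ATAC", state=atac.state, intervals=kept)


def _tie_key(gene: GeneModel) -> str:
    return gene.gene_id


def assign_peak(
    peak: GenomicInterval,
    genes: IntervalIndex,
    max_tss_dist: int = 10_000,
    anchor: str = "edge",
) -> PeakGeneLink | None:
    """Assign one peak to a gene under the gene-body-or-near-TSS rule.

    Overlap with >= 1 gene body wins (among overlapped genes, the one whose
    TSS is nearest; ties broken by lexicographic gene_id). Otherwise the
    globally nearest TSS on the peak's chromosome is taken, and the link is
    made only if that distance is strictly below ``max_tss_dist``.
    ``anchor`` selects the distance convention: nearest peak edge
    (``'edge'``, default) or peak midpoint (``'midpoint'``).
    """
    if len(genes) == 0:
        raise ValueError("empty gene index")
    if anchor not in ("edge", "midpoint"):
        raise ValueError(f"anchor must be 'edge' or 'midpoint', got {anchor!r}")

    def dist(g: GeneModel) -> int:
        if anchor == "midpoint":
            mid = int(peak.midpoint)
            return abs(mid - g.tss)
        return distance_to_point(peak, g.tss)

    overlapped = [g for g in genes.query(peak) if overlap_length(peak, g.body) >= 1]
    if overlapped:
        best = min(overlapped, key=lambda g: (dist(g), _tie_key(g)))
        return PeakGeneLink(
            peak=peak, gene_id=best.gene_id, category="gene_body", tss_distance=dist(best)
        )

    candidates = genes.items_on(peak.chrom)
    if not candidates:
        return None
    best = min(candidates, key=lambda g: (dist(g), _tie_key(g)))
    d = dist(best)
    if d >= max_tss_dist:
        return None
    # strand-aware side: upstream is 5' of the TSS on the gene's strand
    left_of_tss = peak.midpoint < best.tss
    if best.body.strand == "+":
        category: Category = "upstream" if left_of_tss else "downstream"
    else:
        category = "downstream" if left_of_tss else "upstream"
    return PeakGeneLink(peak=peak, gene_id=best.gene_id, category=category, tss_distance=d)


def assign_peaks(
    peaks: Iterable[GenomicInterval],
    genes: IntervalIndex,
    max_tss_dist: int = 10_000,
    anchor: str = "edge",
) -> list[PeakGeneLink]:
    """Assign every peak; peaks linking to no gene are dropped."""
    links = []
    for p in peaks:
        link = assign_peak(p, genes, max_tss_dist=max_tss_dist, anchor=anchor)
        if link is not None:
            links.append(link)
    return links


def genes_with_dev_cre(
    cre_dp: PeakSet,
    cre_cd4sp: PeakSet,
    genes: IntervalIndex,
    max_tss_dist: int = 10_000,
    anchor: str = "edge",
) -> set[str]:
    """Genes linked to >= 1 CRE candidate in either developmental state."""
    linked: set[str] = set()
    for peakset in (cre_dp, cre_cd4sp):
        for link in assign_peaks(peakset, genes, max_tss_dist=max_tss_dist, anchor=anchor):
            linked.add(link.gene_id)
    return linked


def novel_th0_peaks(
    th0_atac: PeakSet,
    dp_atac: PeakSet,
    cd4sp_atac: PeakSet,
    min_bp: int = 1,
    min_overlap_fraction: float = 0.0,
) -> PeakSet:
    """Th0 ATAC peaks with no qualifying overlap against developmental ATAC peaks.

    A developmental peak disqualifies a Th0 peak when they share >= min_bp
    bases and (optionally) the overlap covers >= ``min_overlap_fraction`` of
    the Th0 peak. With the defaults any 1-bp overlap disqualifies.
    """
    for ps in (th0_atac, dp_atac, cd4sp_atac):
        if ps.assay != "ATAC":
            raise ValueError(f"all inputs must be ATAC peak sets, got {ps.assay!r}")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    dev = IntervalIndex(list(dp_atac.intervals) + list(cd4sp_atac.intervals))

    def disqualified(p: GenomicInterval) -> bool:
        for d in dev.query(p):
            ov = overlap_length(p, d)
            if ov >= min_bp and ov >= min_overlap_fraction * p.length:
                return True
        return False

    novel = [p for p in th0_atac if not disqualified(p)]
    return PeakSet(assay="ATAC", state=th0_atac.state, intervals=novel)


def genes_with_novel_peaks(
    novel: PeakSet,
    genes: IntervalIndex,
    max_tss_dist: int = 10_000,
    anchor: str = "edge",
) -> set[str]:
    """Genes receiving >= 1 link from the Th0-novel peaks."""
    return {
        link.gene_id
        for link in assign_peaks(novel, genes, max_tss_dist=max_tss_dist, anchor=anchor)
    }
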