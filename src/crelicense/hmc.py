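"""Gene-body 5hmC (CMS-IP) enrichment scoring.

5hmC marks loci undergoing TET-mediated active DNA demethylation. The
score for a gene is the log2 ratio of immunoprecipitated (CMS-IP) to input
signal summed over the gene body only — "intragenic" — because 5hmC is
depleted at transcription start sites and no promoter flank is added.
Signal is aggregated as a coverage-weighted sum (value x overlapped bp);
the ratio of sums is invariant to gene length and to the segmentation of
the underlying bedGraph. A pseudocount on both sums keeps every score
finite. A gene is 5hmC-positive in a state when its score strictly exceeds
the threshold (default log2 ratio > 2, i.e. >4-fold enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModel, SignalTrack


@dataclass(frozen=True)
class HmcGeneScore:
    gene_id: str
    state: str
    log2_ratio: float


def gene_hmc_score(
    ip: SignalTrack,
    input_track: SignalTrack,
    gene: GeneModel,
    state: str = "unknown",
    pseudocount: float = 1.0,
    mode: str = "sum",
) -> HmcGeneScore:
    """Score one gene: log2((S_ip + pc) / (S_input + pc)) over the gene body.

    ``mode='sum'`` uses coverage-weighted sums (default); ``mode='mean'``
    divides both sums by the gene-body length first, which changes the
    pseudocount's weight but not the pc=0 ratio.
    """
    body = gene.body
    if body.length <= 0:
        raise ValueError(f"gene {gene.gene_id}: zero-length body")
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    s_ip = ip.weighted_sum(body.chrom, body.start, body.end)
    s_input = input_track.weighted_sum(body.chrom, body.start, body.end)
    if mode == "mean":
        s_ip /= body.length
        s_input /= body.length
    num = s_ip + pseudocount
    den = s_input + pseudocount
    if den <= 0 or num <= 0:
        raise ValueError(
            f"gene {gene.gene_id}: non-positive signal with pseudocount {pseudocount}"
        )
    return HmcGeneScore(gene_id=gene.gene_id, state=state, log2_ratio=math.log2(num / den))


def score_genes(
    ip: SignalTrack,
    input_track: SignalTrack,
    genes: Sequence[GeneModel],
    state: str,
    pseudocount: float = 1.0,
    mode: str = "sum",
) -> list[HmcGeneScore]:
    """Score every gene in one cell state."""
    return [
        gene_hmc_score(ip, input_track, g, state=state, pseudocount=pseudocount, mode=mode)
        for g in genes
    ]


def hmc_positive_genes(
    scores: Iterable[HmcGeneScore], threshold: float = 2.0
) -> tuple[dict[str, set[str]], set[str]]:
    """Split scores into per-state positive sets and their union.

    A gene is positive when its log2 ratio strictly exceeds ``threshold``;
    the union set is "5hmC in either state" (e.g. DP or CD4SP).
    """
    per_state: dict[str, set[str]] = {}
    for s in scores:
        per_state.setdefault(s.state, set())
        if s.log2_ratio > threshold:
            per_state[s.state].add(s.gene_id)
    union: set[str] = set()
    for genes in per_state.values():
        union |= genes
    return per_state, union


def _as_score_map(scores: Iterable[HmcGeneScore] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(scores, Mapping):
        return dict(scores)
    return {s.gene_id: s.log2_ratio for s in scores}


def hmc_higher_in_dp(
    scores_dp: Iterable[HmcGeneScore] | Mapping[str, float],
    scores_cd4sp: Iterable[HmcGeneScore] | Mapping[str, float],
    threshold: float = 2.0,
) -> set[str]:
    """Among 5hmC-positive genes, those with strictly more 5hmC in DP than CD4SP.

    These are genes whose demethylation is already underway in the DP
    precursor rather than acquired at the CD4 SP stage.
    """
    dp = _as_score_map(scores_dp)
    cd4sp = _as_score_map(scores_cd4sp)
    if set(dp) != set(cd4sp):
        only = set(dp).symmetric_difference(cd4sp)
        raise ValueError(f"genes scored in one state only: {sorted(only)[:5]}...")
    positive = {g for g, v in dp.items() if v > threshold} | {
        g for g, v in cd4sp.items() if v > threshold
    }
    return {g for g in positive if dp[g] > cd4sp[g]}
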