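"""Per-gene signatures, cascade (Venn) summaries, and gene-set enrichment.

The cascade mirrors the genome-wide integration: among genes changing
expression from DN3 to CD4 SP, how many carry intragenic 5hmC; among
upregulated 5hmC-positive genes, how many have a developmental CRE
(ATAC + H3K27Ac); and of those, how many gain a novel accessible peak upon
activation (Th0). The final "licensed" flag is the four-way conjunction
upregulated AND 5hmC-any AND developmental-CRE AND Th0-novel.

Enrichment of a gene list against user-supplied term annotations uses the
upper-tail hypergeometric test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GeneSignature:
    """Boolean criteria for one gene plus the final licensed flag."""

    gene_id: str
    changed: bool
    upregulated: bool
    hmc_dp: bool
    hmc_cd4sp: bool
    dev_cre: bool
    novel_th0: bool

    @property
    def hmc_any(self) -> bool:
        return self.hmc_dp or self.hmc_cd4sp

    @property
    def licensed(self) -> bool:
        return self.upregulated and self.hmc_any and self.dev_cre and self.novel_th0


def build_signatures(
    changed: set[str],
    upregulated: set[str],
    hmc_dp: set[str],
    hmc_cd4sp: set[str],
    dev_cre: set[str],
    novel_th0: set[str],
    universe: Sequence[str],
) -> list[GeneSignature]:
    """One signature per universe gene; every criterion set must be within the universe."""
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValueError("universe contains duplicate gene ids")
    for label, s in (
        ("changed", changed),
        ("upregulated", upregulated),
        ("hmc_dp", hmc_dp),
        ("hmc_cd4sp", hmc_cd4sp),
        ("dev_cre", dev_cre),
        ("novel_th0", novel_th0),
    ):
        extra = s - uni
        if extra:
            raise ValueError(f"{label} set contains genes outside universe: {sorted(extra)[:5]}")
    if not upregulated <= changed:
        raise ValueError("upregulated genes must be a subset of changed genes")
    return [
        GeneSignature(
            gene_id=g,
            changed=g in changed,
            upregulated=g in upregulated,
            hmc_dp=g in hmc_dp,
            hmc_cd4sp=g in hmc_cd4sp,
            dev_cre=g in dev_cre,
            novel_th0=g in novel_th0,
        )
        for g in universe
    ]


def percentage(child: int, parent: int) -> float | None:
    """100 x child/parent rounded to 1 decimal; None (NA) when parent is 0."""
    if parent == 0:
        return None
    return round(100.0 * child / parent, 1)


@dataclass(frozen=True)
class VennSummary:
    """Nested cascade counts and their percentages (1-decimal, NA when undefined)."""

    n_universe: int
    n_changed: int
    n_hmc_among_changed: int
    n_positive_correlation: int  # upregulated AND 5hmC-any
    n_upregulated_hmc: int  # the intersection universe of the final Venn
    n_with_dev_cre: int
    n_with_novel_th0: int
    n_licensed: int

    @property
    def pct_hmc_among_changed(self) -> float | None:
        return percentage(self.n_hmc_among_changed, self.n_changed)

    @property
    def pct_positive_correlation(self) -> float | None:
        return percentage(self.n_positive_correlation, self.n_hmc_among_changed)

    @property
    def pct_dev_cre(self) -> float | None:
        return percentage(self.n_with_dev_cre, self.n_upregulated_hmc)

    @property
    def pct_novel_th0(self) -> float | None:
        return percentage(self.n_with_novel_th0, self.n_with_dev_cre)

    def to_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_changed": self.n_changed,
            "n_hmc_among_changed": self.n_hmc_among_changed,
            "n_positive_correlation": self.n_positive_correlation,
            "n_upregulated_hmc": self.n_upregulated_hmc,
            "n_with_dev_cre": self.n_with_dev_cre,
            "n_with_novel_th0": self.n_with_novel_th0,
            "n_licensed": self.n_licensed,
            "pct_hmc_among_changed": self.pct_hmc_among_changed,
            "pct_positive_correlation": self.pct_positive_correlation,
            "pct_dev_cre": self.pct_dev_cre,
            "pct_novel_th0": self.pct_novel_th0,
        }


def venn_summary(signatures: Iterable[GeneSignature]) -> VennSummary:
    """Count the nested cascade over a collection of gene signatures."""
    sigs = list(signatures)
    changed = [s for s in sigs if s.changed]
    hmc_changed = [s for s in changed if s.hmc_any]
    upreg_hmc = [s for s in sigs if s.upregulated and s.hmc_any]
    with_cre = [s for s in upreg_hmc if s.dev_cre]
    with_novel = [s for s in with_cre if s.novel_th0]
    licensed = [s for s in sigs if s.licensed]
    return VennSummary(
        n_universe=len(sigs),
        n_changed=len(changed),
        n_hmc_among_changed=len(hmc_changed),
        n_positive_correlation=len(upreg_hmc),
        n_upregulated_hmc=len(upreg_hmc),
        n_with_dev_cre=len(with_cre),
        n_with_novel_th0=len(with_novel),
        n_licensed=len(licensed),
    )


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"need K, n <= N with all non-negative; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in stats.false_discovery_control(p, method="bh")]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # query genes annotated to the term
    K: int  # term size within the universe
    n: int  # query size
    N: int  # universe size
    p: float
    q: float


def enrich(
    query: set[str],
    terms: Mapping[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query gene set.

    Term gene sets are intersected with the universe before testing; terms
    with zero query overlap are dropped before BH adjustment. Results are
    sorted by (p, term_id) and independent of the mapping's iteration order.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(query)
    rows: list[tuple[str, int, int]] = []
    for term_id in sorted(terms):
        term_genes = terms[term_id] & universe
        k = len(term_genes & query)
        if k == 0:
            continue
        rows.append((term_id, k, len(term_genes)))
    pvals = [hypergeom_p(k, K, n, N) for _, k, K in rows]
    qvals = bh_adjust(pvals)
    results = [
        EnrichmentResult(term_id=t, k=k, K=K, n=n, N=N, p=p, q=q)
        for (t, k, K), p, q in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
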