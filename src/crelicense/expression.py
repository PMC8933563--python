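"""Count filtering, median-of-ratios normalization and stage fold-change gating.

The expression gate of the cascade asks which genes more-than-double their
expression from the DN3 precursor stage to CD4 single-positive thymocytes.
Raw counts are filtered (a gene is dropped only when *every* sample is
below ``min_count``), normalized by DESeq2-style median-of-ratios size
factors, and compared between stages as
``log2((mean_target + pc) / (mean_base + pc))`` over each stage's samples.
Gating is strict: "fold change > 2" means ``log2FC > 1`` for upregulation
and ``|log2FC| > 1`` for any change.

No dispersion estimation or Wald testing is performed; the gate is the
fold change itself. :func:`stage_ttest` offers an optional Welch t-test on
log-normalized values for users who want an accompanying p-value column —
it is not equivalent to a negative-binomial Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import parse_sample_label


@dataclass
class CountsMatrix:
    """Genes x samples matrix; columns are '<stage>_<replicate>' labels."""

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        # every column must parse to a stage; raises FormatError otherwise
        self._stage_of = {col: parse_sample_label(col)[0] for col in self.values.columns}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for col in self.values.columns:
            seen.setdefault(self._stage_of[col], None)
        return list(seen)

    def stage_of(self, sample: str) -> str:
        return self._stage_of[sample]

    def samples_for(self, stage: str) -> list[str]:
        cols = [c for c in self.values.columns if self._stage_of[c] == stage]
        if not cols:
            raise ValueError(f"unknown stage label {stage!r}; have {self.stages}")
        return cols


@dataclass
class StageComparison:
    """Per-gene log2 fold change between two stages of a normalized matrix."""

    base_stage: str
    target_stage: str
    pseudocount: float
    base_mean: pd.Series
    target_mean: pd.Series
    log2fc: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "base_mean": self.base_mean,
                "target_mean": self.target_mean,
                "log2fc": self.log2fc,
            }
        )
        df.index.name = "gene_id"
        return df


def filter_low_counts(m: CountsMatrix, min_count: int = 10) -> CountsMatrix:
    """Drop genes whose counts are below ``min_count`` in *all* samples."""
    if min_count < 0:
        raise ValueError(f"min_count must be >= 0, got {min_count}")
    if m.normalized:
        raise ValueError("filter_low_counts expects raw counts")
    keep = (m.values >= min_count).any(axis=1)
    return CountsMatrix(values=m.values.loc[keep].copy(), normalized=False)


def size_factors(m: CountsMatrix) -> pd.Series:
    """DESeq2 median-of-ratios size factors.

    For each gene with strictly positive counts in every sample, compute its
    geometric mean across samples; a sample's factor is the median over those
    genes of count / geometric-mean.
    """
    if m.normalized:
        raise ValueError("size_factors expects raw counts")
    counts = m.values.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has nonzero counts in every sample; cannot normalize")
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.values.columns, name="size_factor")


def normalize(m: CountsMatrix, factors: pd.Series) -> CountsMatrix:
    """Divide each sample's column by its size factor."""
    if (np.asarray(factors) <= 0).any():
        raise ValueError("size factors must be positive")
    if list(factors.index) != list(m.values.columns):
        factors = factors.reindex(m.values.columns)
        if factors.isna().any():
            raise ValueError("size factors do not cover all samples")
    values = m.values.astype(float) / factors
    return CountsMatrix(values=values, normalized=True)


def stage_log2fc(
    m: CountsMatrix, base: str, target: str, pseudocount: float = 1.0
) -> StageComparison:
    """Per-gene log2((target mean + pc) / (base mean + pc)) on normalized counts."""
    if not m.normalized:
        raise ValueError("stage_log2fc expects a normalized matrix")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    base_cols = m.samples_for(base)
    target_cols = m.samples_for(target)
    base_mean = m.values[base_cols].mean(axis=1)
    target_mean = m.values[target_cols].mean(axis=1)
    lfc = np.log2((target_mean + pseudocount) / (base_mean + pseudocount))
    return StageComparison(
        base_stage=base,
        target_stage=target,
        pseudocount=pseudocount,
        base_mean=base_mean,
        target_mean=target_mean,
        log2fc=pd.Series(lfc, index=m.values.index, name="log2fc"),
    )


def changed_genes(c: StageComparison, lfc_threshold: float = 1.0) -> set[str]:
    """Genes with |log2FC| strictly above the threshold (fold change > 2^t)."""
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0")
    return set(c.log2fc.index[c.log2fc.abs() > lfc_threshold])


def upregulated_genes(c: StageComparison, lfc_threshold: float = 1.0) -> set[str]:
    """Genes with log2FC strictly above the threshold."""
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0")
    return set(c.log2fc.index[c.log2fc > lfc_threshold])


def stage_ttest(
    m: CountsMatrix, base: str, target: str, pseudocount: float = 1.0
) -> pd.Series:
    """Welch t-test p-values on log2(normalized + pc), per gene.

    Provided for convenience only; not equivalent to a count-model Wald test.
    """
    if not m.normalized:
        raise ValueError("stage_ttest expects a normalized matrix")
    base_vals = np.log2(m.values[m.samples_for(base)] + pseudocount)
    target_vals = np.log2(m.values[m.samples_for(target)] + pseudocount)
    result = stats.ttest_ind(target_vals, base_vals, axis=1, equal_var=False)
    return pd.Series(result.pvalue, index=m.values.index, name="pvalue")
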