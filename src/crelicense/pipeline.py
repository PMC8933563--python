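"""End-to-end orchestration: config, stage sequencing, and output writing.

A single :class:`PipelineConfig` (usually loaded from YAML) names every
input file and houses every numeric threshold of the cascade:

- ``min_count`` (10): a gene is dropped when below this in all samples
- ``lfc_threshold`` (1.0, log2): "fold change > 2" gate, applied strictly
- ``hmc_threshold`` (2.0): intragenic log2 CMS-IP/input must strictly exceed
- ``max_tss_dist`` (10000 bp): peak-to-gene linking, strict "< 10 kb"
- ``min_overlap_bp`` (1): ATAC/H3K27Ac co-occurrence and Th0-novelty overlap

Identical config and inputs give byte-identical outputs: the run log
records the config hash and the stage-wise gene counts, never timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import expression, hmc
from .cre_annotation import (
    cre_candidates,
    gene_index,
    genes_with_dev_cre,
    genes_with_novel_peaks,
    novel_th0_peaks,
)
from .io_formats import (
    PeakSet,
    read_bed,
    read_bedgraph,
    read_counts,
    read_gene_table,
    write_bed,
)
from .prioritization import (
    EnrichmentResult,
    GeneSignature,
    VennSummary,
    build_signatures,
    enrich,
    venn_summary,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    gene_table: Path
    counts: Path
    hmc_tracks: dict[str, dict[str, Path]]  # state -> {'ip': path, 'input': path}
    atac: dict[str, Path]  # state -> BED (needs base/dev states and the activated state)
    k27ac: dict[str, Path]  # developmental states -> BED
    terms: Path | None = None
    output_dir: Path = Path("crelicense_out")
    min_count: int = 10
    lfc_threshold: float = 1.0
    hmc_threshold: float = 2.0
    max_tss_dist: int = 10_000
    min_overlap_bp: int = 1
    count_pseudocount: float = 1.0
    hmc_pseudocount: float = 1.0
    base_stage: str = "DN3"
    target_stage: str = "CD4SP"
    dev_states: tuple[str, str] = ("DP", "CD4SP")
    activated_state: str = "Th0"
    tss_anchor: str = "edge"
    min_peak_score: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_count", "max_tss_dist", "min_overlap_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def p(value: str) -> Path:
            candidate = Path(value)
            return candidate if candidate.is_absolute() else base / candidate

        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        hmc_tracks = {
            state: {kind: p(v) for kind, v in kinds.items()}
            for state, kinds in inputs.get("hmc", {}).items()
        }
        out = raw.get("output_dir", "crelicense_out")
        return cls(
            gene_table=p(inputs["gene_table"]),
            counts=p(inputs["counts"]),
            hmc_tracks=hmc_tracks,
            atac={state: p(v) for state, v in inputs.get("atac", {}).items()},
            k27ac={state: p(v) for state, v in inputs.get("k27ac", {}).items()},
            terms=p(inputs["terms"]) if inputs.get("terms") else None,
            output_dir=Path(out) if Path(out).is_absolute() else base / out,
            **params,
        )

    def config_hash(self) -> str:
        # output_dir is excluded: it does not affect the analysis
        payload = {
            k: str(v) if isinstance(v, Path) else v
            for k, v in self.__dict__.items()
            if k != "output_dir"
        }
        payload["hmc_tracks"] = {
            s: {k: str(v) for k, v in kinds.items()} for s, kinds in self.hmc_tracks.items()
        }
        payload["atac"] = {s: str(v) for s, v in self.atac.items()}
        payload["k27ac"] = {s: str(v) for s, v in self.k27ac.items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    signatures: list[GeneSignature]
    venn: VennSummary
    novel_peaks: PeakSet
    comparison: expression.StageComparison
    hmc_scores: pd.DataFrame
    enrichment: list[EnrichmentResult] | None
    outputs: dict[str, Path]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _read_terms(path: Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["term_id", "gene_id"]:
        raise ValueError(f"{path}: expected columns term_id, gene_id")
    terms: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        terms.setdefault(row.term_id, set()).add(row.gene_id)
    return terms


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full cascade and write the output bundle."""
    load = _stage("load_inputs")(_load_inputs)
    genes, counts = load(config)

    comp, changed, upregulated, universe = _stage("expression_gate")(_expression_gate)(
        config, counts
    )
    scores_df, hmc_sets, hmc_union = _stage("hmc_scoring")(_hmc_scoring)(config, genes)
    dev_cre_genes = _stage("cre_detection")(_cre_detection)(config, genes)
    novel, novel_genes = _stage("novel_peaks")(_novel_peaks)(config, genes)

    @_stage("signatures")
    def _signatures() -> tuple[list[GeneSignature], VennSummary]:
        uni = set(universe)
        sigs = build_signatures(
            changed=changed & uni,
            upregulated=upregulated & uni,
            hmc_dp=hmc_sets.get(config.dev_states[0], set()) & uni,
            hmc_cd4sp=hmc_sets.get(config.dev_states[1], set()) & uni,
            dev_cre=dev_cre_genes & uni,
            novel_th0=novel_genes & uni,
            universe=universe,
        )
        return sigs, venn_summary(sigs)

    signatures, venn = _signatures()

    enrichment: list[EnrichmentResult] | None = None
    if config.terms is not None:
        @_stage("enrichment")
        def _enrichment() -> list[EnrichmentResult]:
            terms = _read_terms(config.terms)
            licensed = {s.gene_id for s in signatures if s.licensed}
            return enrich(licensed, terms, set(universe))

        enrichment = _enrichment()

    outputs = _stage("write_outputs")(_write_outputs)(
        config, signatures, venn, novel, comp, scores_df, enrichment
    )
    return PipelineResult(
        signatures=signatures,
        venn=venn,
        novel_peaks=novel,
        comparison=comp,
        hmc_scores=scores_df,
        enrichment=enrichment,
        outputs=outputs,
    )


def _load_inputs(config: PipelineConfig):
    genes = read_gene_table(config.gene_table)
    counts = read_counts(config.counts)
    return genes, counts


def _expression_gate(config: PipelineConfig, counts):
    filtered = expression.filter_low_counts(counts, min_count=config.min_count)
    factors = expression.size_factors(filtered)
    normalized = expression.normalize(filtered, factors)
    comp = expression.stage_log2fc(
        normalized,
        base=config.base_stage,
        target=config.target_stage,
        pseudocount=config.count_pseudocount,
    )
    changed = expression.changed_genes(comp, lfc_threshold=config.lfc_threshold)
    upregulated = expression.upregulated_genes(comp, lfc_threshold=config.lfc_threshold)
    universe = filtered.gene_ids
    return comp, changed, upregulated, universe


def _hmc_scoring(config: PipelineConfig, genes):
    all_scores: list[hmc.HmcGeneScore] = []
    rows = []
    for state, kinds in config.hmc_tracks.items():
        ip = read_bedgraph(kinds["ip"])
        input_track = read_bedgraph(kinds["input"])
        state_scores = hmc.score_genes(
            ip, input_track, genes, state=state, pseudocount=config.hmc_pseudocount
        )
        all_scores.extend(state_scores)
        rows += [
            {
                "gene_id": s.gene_id,
                "state": s.state,
                "log2_ratio": s.log2_ratio,
                "positive": s.log2_ratio > config.hmc_threshold,
            }
            for s in state_scores
        ]
    per_state, _union = hmc.hmc_positive_genes(all_scores, threshold=config.hmc_threshold)
    df = pd.DataFrame(rows, columns=["gene_id", "state", "log2_ratio", "positive"])
    return df, per_state, _union


def _cre_detection(config: PipelineConfig, genes):
    idx = gene_index(genes)
    cres = []
    for state in config.dev_states:
        atac = read_bed(config.atac[state], assay="ATAC", state=state,
                        min_score=config.min_peak_score)
        k27 = read_bed(config.k27ac[state], assay="H3K27Ac", state=state,
                       min_score=config.min_peak_score)
        cres.append(cre_candidates(atac, k27, min_bp=config.min_overlap_bp))
    return genes_with_dev_cre(
        cres[0], cres[1], idx, max_tss_dist=config.max_tss_dist, anchor=config.tss_anchor
    )


def _novel_peaks(config: PipelineConfig, genes):
    idx = gene_index(genes)
    th0 = read_bed(
        config.atac[config.activated_state], assay="ATAC", state=config.activated_state,
        min_score=config.min_peak_score,
    )
    dev = [
        read_bed(config.atac[state], assay="ATAC", state=state, min_score=config.min_peak_score)
        for state in config.dev_states
    ]
    novel = novel_th0_peaks(th0, dev[0], dev[1], min_bp=config.min_overlap_bp)
    novel_genes = genes_with_novel_peaks(
        novel, idx, max_tss_dist=config.max_tss_dist, anchor=config.tss_anchor
    )
    return novel, novel_genes


def _write_outputs(
    config: PipelineConfig,
    signatures: list[GeneSignature],
    venn: VennSummary,
    novel: PeakSet,
    comp: expression.StageComparison,
    scores_df: pd.DataFrame,
    enrichment: list[EnrichmentResult] | None,
) -> dict[str, Path]:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    sig_df = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "changed": s.changed,
                "upregulated": s.upregulated,
                "hmc_dp": s.hmc_dp,
                "hmc_cd4sp": s.hmc_cd4sp,
                "hmc_any": s.hmc_any,
                "dev_cre": s.dev_cre,
                "novel_th0": s.novel_th0,
                "licensed": s.licensed,
            }
            for s in signatures
        ]
    )
    outputs["signatures"] = outdir / "signatures.tsv"
    sig_df.to_csv(outputs["signatures"], sep="\t", index=False)

    outputs["venn"] = outdir / "venn.json"
    with open(outputs["venn"], "w", encoding="utf-8") as fh:
        json.dump(venn.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    outputs["novel_peaks"] = outdir / "novel_peaks.bed"
    write_bed(novel, outputs["novel_peaks"])

    outputs["comparison"] = outdir / "stage_comparison.tsv"
    comp.to_frame().to_csv(outputs["comparison"], sep="\t")

    outputs["hmc_scores"] = outdir / "hmc_scores.tsv"
    scores_df.to_csv(outputs["hmc_scores"], sep="\t", index=False)

    if enrichment is not None:
        enr_df = pd.DataFrame(
            [
                {"term_id": r.term_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                 "p": r.p, "q": r.q}
                for r in enrichment
            ],
            columns=["term_id", "k", "K", "n", "N", "p", "q"],
        )
        outputs["enrichment"] = outdir / "enrichment.tsv"
        enr_df.to_csv(outputs["enrichment"], sep="\t", index=False)

    outputs["run_log"] = outdir / "run_log.txt"
    with open(outputs["run_log"], "w", encoding="utf-8") as fh:
        fh.write(f"config_sha256\t{config.config_hash()}\n")
        for key, value in sorted(venn.to_dict().items()):
            fh.write(f"{key}\t{value}\n")
    return outputs
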