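"""Synthetic toy genome with planted gene classes for end-to-end validation.

The generator emits exactly the files the pipeline reads — a gene table,
a stage-labelled count matrix (DN3/DP/CD4SP), CMS-IP and input bedGraph
tracks per state, ATAC and H3K27Ac BED files per state (DP, CD4SP, Th0) —
plus a truth table labelling every gene with the criterion profile that
was planted for it:

- ``licensed``        all four criteria (upregulated, intragenic 5hmC,
                      developmental CRE, Th0-novel peak)
- ``no_novel_peak``   everything except the Th0-only peak
- ``no_dev_cre``      everything except the ATAC+H3K27Ac CRE
- ``no_hmc``          everything except 5hmC enrichment
- ``not_upregulated`` everything except the expression change
- ``null``            flat expression, background signal, no peaks

Geometry is chosen so that every planted feature clears its detection
threshold with margin: the expression change is 8-fold against a 2-fold
gate, 5hmC enrichment is 16-fold against a 4-fold gate, and the planted
Th0 peak sits at most ~4 kb from the TSS against a 10 kb rule. Planted
peaks sit at least 3 kb inside the gene body (developmental CRE) and 8 kb
inside or ~4 kb upstream (Th0), so position jitter bounded by 2 kb can
neither push a peak out of its body nor bring distinct peaks into overlap
— no truth label can flip. With
``dispersion == 0`` counts are the exact class means and the whole bundle
is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CountsMatrix
from .io_formats import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_counts,
    write_gene_table,
)
from .prioritization import GeneSignature

TRUTH_CLASSES = ("licensed", "no_novel_peak", "no_dev_cre", "no_hmc", "not_upregulated", "null")

_DEFAULT_FRACTIONS = {
    "licensed": 0.10,
    "no_novel_peak": 0.05,
    "no_dev_cre": 0.05,
    "no_hmc": 0.05,
    "not_upregulated": 0.05,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-truth bundle.

    ``dispersion`` is the negative-binomial dispersion alpha
    (variance = mu + alpha * mu^2); 0 switches count sampling off and
    emits the exact class means. ``peak_jitter_bp`` shifts every peak by a
    uniform offset in [-jitter, +jitter].
    """

    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (12_000, 20_000)
    intergenic_gap_range: tuple[int, int] = (30_000, 60_000)
    stages: tuple[str, ...] = ("DN3", "DP", "CD4SP")
    replicates: int = 2
    base_mean: float = 200.0
    dispersion: float = 0.0
    lfc: float = 3.0  # log2 units, planted DN3 -> CD4SP change
    hmc_log2_enrichment: float = 4.0
    frac_hmc_higher_dp: float = 0.25
    peak_width_range: tuple[int, int] = (300, 500)
    bin_size: int = 100
    class_fractions: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    peak_jitter_bp: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.replicates < 1:
            raise ValueError("n_genes, n_chromosomes and replicates must be >= 1")
        for name in ("gene_length_range", "intergenic_gap_range", "peak_width_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        unknown = set(self.class_fractions) - set(TRUTH_CLASSES)
        if unknown:
            raise ValueError(f"unknown truth classes {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if sum(self.class_fractions.values()) > 1 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        if self.dispersion < 0 or self.peak_jitter_bp < 0:
            raise ValueError("dispersion and peak_jitter_bp must be >= 0")
        if len(self.stages) < 2:
            raise ValueError("need at least a base and a target stage")


# class -> which of the four criteria are planted
_PLANT = {
    "licensed": dict(upregulated=True, hmc=True, dev_cre=True, novel=True),
    "no_novel_peak": dict(upregulated=True, hmc=True, dev_cre=True, novel=False),
    "no_dev_cre": dict(upregulated=True, hmc=True, dev_cre=False, novel=True),
    "no_hmc": dict(upregulated=True, hmc=False, dev_cre=True, novel=True),
    "not_upregulated": dict(upregulated=False, hmc=True, dev_cre=True, novel=True),
    "null": dict(upregulated=False, hmc=False, dev_cre=False, novel=False),
}

_DEV_CRE_BODY_OFFSET = 3_000
_NOVEL_BODY_OFFSET = 8_000
_NOVEL_UPSTREAM_DIST = 4_000


@dataclass
class SyntheticBundle:
    """In-memory bundle plus the file paths the generator wrote."""

    config: SyntheticConfig
    genes: list[GeneModel]
    counts: CountsMatrix
    truth: dict[str, str]
    peaks: dict[tuple[str, str], PeakSet]  # (assay, state) -> PeakSet
    tracks: dict[tuple[str, str], SignalTrack]  # (state, 'ip'|'input') -> track
    paths: dict[str, Path]


def _assign_classes(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    counts = {cls: int(round(frac * config.n_genes)) for cls, frac in config.class_fractions.items()}
    total = sum(counts.values())
    if total > config.n_genes:
        raise ValueError("class fractions allocate more genes than n_genes")
    labels = [cls for cls in TRUTH_CLASSES if cls != "null" for _ in range(counts.get(cls, 0))]
    labels += ["null"] * (config.n_genes - total)
    order = rng.permutation(config.n_genes)
    return [labels[i] for i in order]


def _lay_out_genes(config: SyntheticConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    width = len(str(config.n_genes))
    idx = 0
    for c, n_on_chrom in enumerate(per_chrom, start=1):
        cursor = int(rng.integers(*config.intergenic_gap_range))
        for _ in range(n_on_chrom):
            length = int(rng.integers(*config.gene_length_range))
            strand = "+" if rng.integers(2) == 0 else "-"
            body = GenomicInterval(f"chr{c}", cursor, cursor + length, strand=strand)
            genes.append(GeneModel(gene_id=f"g{idx + 1:0{width}d}", body=body))
            cursor = body.end + int(rng.integers(*config.intergenic_gap_range))
            idx += 1
    return genes


def _sample_counts(
    config: SyntheticConfig, truth: Sequence[str], genes: Sequence[GeneModel], rng: np.random.Generator
) -> CountsMatrix:
    columns = [f"{stage}_{r + 1}" for stage in config.stages for r in range(config.replicates)]
    n_stages = len(config.stages)
    data = np.zeros((len(genes), len(columns)), dtype="int64")
    for i, (gene, cls) in enumerate(zip(genes, truth)):
        upregulated = _PLANT[cls]["upregulated"]
        for s, stage in enumerate(config.stages):
            if upregulated:
                # ramp the planted log2 change linearly across the stage order
                mu = config.base_mean * 2 ** (config.lfc * s / (n_stages - 1))
            else:
                mu = config.base_mean
            for r in range(config.replicates):
                j = s * config.replicates + r
                if config.dispersion > 0:
                    size = 1.0 / config.dispersion
                    p = size / (size + mu)
                    data[i, j] = rng.negative_binomial(size, p)
                else:
                    data[i, j] = int(round(mu))
    df = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=columns)
    df.index.name = "gene_id"
    return CountsMatrix(values=df)


def _hmc_tracks(
    config: SyntheticConfig, truth: Sequence[str], genes: Sequence[GeneModel], dp_high: set[str]
) -> dict[tuple[str, str], SignalTrack]:
    """Fixed-width bins over gene bodies; IP = input x 2^factor for 5hmC+ genes."""
    segs: dict[tuple[str, str], list[tuple[str, int, int, float]]] = {
        (state, kind): [] for state in ("DP", "CD4SP") for kind in ("ip", "input")
    }
    f = config.hmc_log2_enrichment
    for gene, cls in zip(genes, truth):
        has_hmc = _PLANT[cls]["hmc"]
        if has_hmc and gene.gene_id in dp_high:
            factors = {"DP": f + 1.0, "CD4SP": max(f - 1.0, 0.0)}
        elif has_hmc:
            factors = {"DP": 0.0, "CD4SP": f}
        else:
            factors = {"DP": 0.0, "CD4SP": 0.0}
        body = gene.body
        for start in range(body.start, body.end, config.bin_size):
            end = min(start + config.bin_size, body.end)
            for state in ("DP", "CD4SP"):
                segs[(state, "input")].append((body.chrom, start, end, 1.0))
                segs[(state, "ip")].append((body.chrom, start, end, 2.0 ** factors[state]))
    return {key: SignalTrack(seg_list) for key, seg_list in segs.items()}


def _jitter(rng: np.random.Generator, jitter: int) -> int:
    return int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0


def _plant_peaks(
    config: SyntheticConfig, truth: Sequence[str], genes: Sequence[GeneModel], rng: np.random.Generator
) -> dict[tuple[str, str], list[GenomicInterval]]:
    peaks: dict[tuple[str, str], list[GenomicInterval]] = {
        ("ATAC", "DP"): [],
        ("ATAC", "CD4SP"): [],
        ("ATAC", "Th0"): [],
        ("H3K27Ac", "DP"): [],
        ("H3K27Ac", "CD4SP"): [],
    }
    for i, (gene, cls) in enumerate(zip(genes, truth)):
        body = gene.body
        w = int(rng.integers(*config.peak_width_range))
        dev_state = "DP" if rng.integers(2) == 0 else "CD4SP"
        if _PLANT[cls]["dev_cre"]:
            shift = _jitter(rng, config.peak_jitter_bp)
            start = body.start + _DEV_CRE_BODY_OFFSET + shift
            peaks[("ATAC", dev_state)].append(GenomicInterval(body.chrom, start, start + w))
            # concomitant acetylation: wider mark centred on the same site
            peaks[("H3K27Ac", dev_state)].append(
                GenomicInterval(body.chrom, start - 100, start + w + 100)
            )
        if _PLANT[cls]["novel"]:
            shift = _jitter(rng, config.peak_jitter_bp)
            if i % 2 == 0:  # inside the gene body, far from the planted CRE
                start = body.start + _NOVEL_BODY_OFFSET + shift
            elif body.strand == "+":  # upstream of the TSS
                start = gene.tss - _NOVEL_UPSTREAM_DIST - w + shift
            else:
                start = gene.tss + _NOVEL_UPSTREAM_DIST + shift
            peaks[("ATAC", "Th0")].append(GenomicInterval(body.chrom, start, start + w))
    # background Th0 peaks in gene deserts: novel but assignable to no gene
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    desert = 0
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: g.body.start)
        for left, right in zip(ordered, ordered[1:]):
            desert += 1
            if desert % 3 != 0:
                continue
            mid = (left.body.end + right.body.start) // 2
            w = int(rng.integers(*config.peak_width_range))
            shift = _jitter(rng, config.peak_jitter_bp)
            peaks[("ATAC", "Th0")].append(
                GenomicInterval(chrom, mid - w // 2 + shift, mid - w // 2 + w + shift)
            )
    return peaks


def generate(config: SyntheticConfig, outdir: str | Path) -> SyntheticBundle:
    """Generate and write the full bundle; deterministic for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    truth_labels = _assign_classes(config, rng)
    genes = _lay_out_genes(config, rng)
    counts = _sample_counts(config, truth_labels, genes, rng)

    hmc_gene_ids = [g.gene_id for g, cls in zip(genes, truth_labels) if _PLANT[cls]["hmc"]]
    n_dp_high = int(round(config.frac_hmc_higher_dp * len(hmc_gene_ids)))
    dp_high = set(
        rng.choice(hmc_gene_ids, size=n_dp_high, replace=False) if n_dp_high else []
    )
    tracks = _hmc_tracks(config, truth_labels, genes, dp_high)
    peak_lists = _plant_peaks(config, truth_labels, genes, rng)

    truth = {g.gene_id: cls for g, cls in zip(genes, truth_labels)}
    peaks = {
        (assay, state): PeakSet(assay=assay, state=state, intervals=ivs)
        for (assay, state), ivs in peak_lists.items()
    }

    paths: dict[str, Path] = {}
    paths["gene_table"] = outdir / "genes.tsv"
    write_gene_table(genes, paths["gene_table"])
    paths["counts"] = outdir / "counts.tsv"
    write_counts(counts, paths["counts"])
    for (state, kind), track in tracks.items():
        key = f"hmc_{state}_{kind}"
        paths[key] = outdir / f"{key}.bedgraph"
        write_bedgraph(track, paths[key])
    for (assay, state), ps in peaks.items():
        key = f"{'atac' if assay == 'ATAC' else 'k27ac'}_{state}"
        paths[key] = outdir / f"{key}.bed"
        write_bed(ps, paths[key])
    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tclass\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{truth[g.gene_id]}\n")

    return SyntheticBundle(
        config=config,
        genes=genes,
        counts=counts,
        truth=truth,
        peaks=peaks,
        tracks=tracks,
        paths=paths,
    )


def read_truth(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return dict(zip(df["gene_id"], df["class"]))


@dataclass(frozen=True)
class RecoveryReport:
    """Planted-truth recovery: sensitivity on licensed genes, leakage elsewhere."""

    n_per_class: dict[str, int]
    flagged_per_class: dict[str, int]
    sensitivity: float | None  # licensed genes flagged licensed; None when class empty
    leakage: dict[str, float]  # per non-licensed class: fraction wrongly flagged


def recovery_report(
    truth: Mapping[str, str], signatures: Iterable[GeneSignature]
) -> RecoveryReport:
    """Compare pipeline signatures against the planted truth labels."""
    sigs = {s.gene_id: s for s in signatures}
    if set(sigs) != set(truth):
        raise ValueError("signature universe does not match truth universe")
    n_per_class: dict[str, int] = {cls: 0 for cls in TRUTH_CLASSES}
    flagged: dict[str, int] = {cls: 0 for cls in TRUTH_CLASSES}
    for gene_id, cls in truth.items():
        if cls not in n_per_class:
            raise ValueError(f"unknown truth class {cls!r} for gene {gene_id}")
        n_per_class[cls] += 1
        if sigs[gene_id].licensed:
            flagged[cls] += 1
    sensitivity = (
        flagged["licensed"] / n_per_class["licensed"] if n_per_class["licensed"] else None
    )
    leakage = {
        cls: (flagged[cls] / n_per_class[cls]) if n_per_class[cls] else 0.0
        for cls in TRUTH_CLASSES
        if cls != "licensed"
    }
    return RecoveryReport(
        n_per_class=n_per_class,
        flagged_per_class=flagged,
        sensitivity=sensitivity,
        leakage=leakage,
    )
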