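# Methods

## The integration model

The pipeline formalizes a manual multi-omic curation into four per-gene
boolean criteria and their conjunction. All genomic arithmetic is 0-based
half-open (BED convention); adjacency is never overlap.

**Expression gate.** Raw counts (genes × samples, stages parsed from
`<stage>_<replicate>` column names) are filtered: a gene is removed only
when its count is below `min_count` (default 10) in *every* sample.
Normalization is median-of-ratios: for genes with positive counts in all
samples, factorⱼ = medianᵍ(countᵍⱼ / geomeanᵍ). The stage statistic is
log₂((x̄_target + pc)/(x̄_base + pc)) with pseudocount pc = 1 on the stage
means; "changed" means |log₂FC| > 1 and "upregulated" log₂FC > 1, both
strict. No dispersion estimation or Wald test is performed — the gate is
the fold change itself. A Welch t-test on log-normalized values is
available (`stage_ttest`) but is explicitly not a count-model test.
Scaling one of m columns by c multiplies the scaled column's size factor
by exactly c^((m−1)/m) and every other factor by c^(−1/m) (each gene's
geometric mean absorbs c^(1/m)); the test suite asserts this closed form.

**5hmC gate.** The intragenic score is log₂((S_IP + pc)/(S_input + pc)),
where S is the coverage-weighted sum (segment value × overlapped bp) of a
bedGraph track over the gene body only. No promoter flank is added: 5hmC
is depleted at TSSs, and the criterion is deliberately intragenic. The
ratio-of-sums is invariant to gene length and to how the track is binned;
a mean-based mode exists for users who prefer per-bp averages (identical
at pc = 0). Positivity is score > 2 (strict), and "5hmC-any" is the union
over the DP and CD4 SP states. The exact enrichment statistic used by the
original CMS-IP processing is not restated in the source material;
ratio-of-sums with pseudocount 1 is this package's explicit, documented
choice.

**Developmental CRE gate.** A CRE candidate is an ATAC peak overlapping
(≥ `min_overlap_bp`, default 1) at least one H3K27Ac peak of the same cell
state; the ATAC coordinates are retained because accessibility is the
positional readout. Peak→gene assignment: a peak overlapping ≥ 1 gene body
links to the overlapped gene with the nearest TSS (tie → lexicographically
smallest gene_id, for determinism); otherwise to the gene with minimum TSS
distance, only if that distance is strictly < `max_tss_dist` (10 kb).
Distance is measured from the nearest peak edge — the published "< 10 kb"
rule names no anchor, and edge distance is the conservative reading; a
midpoint anchor is available via config. Upstream/downstream is
strand-aware (upstream = 5′ of the TSS). Each peak links to at most one
gene so cascade counts are well-defined.

**Th0-novelty gate.** A Th0 (activated-cell) ATAC peak is novel when it
has no qualifying overlap (≥ `min_overlap_bp`; optionally also ≥ a
reciprocal fraction of the peak) against any DP or CD4 SP ATAC peak. The
original analysis curated novelty manually; the binary overlap rule is the
algorithmization adopted here. H3K27Ac is *not* required at novel peaks
(ATAC-only novelty), since activation-state acetylation evidence is not
part of the novelty notion used; requiring it would only shrink the set.

**Conjunction and cascade.** `licensed = upregulated ∧ 5hmC-any ∧ dev-CRE
∧ Th0-novel`. The Venn summary reports the nested counts (changed →
5hmC-among-changed → upregulated∧5hmC → +dev-CRE → +novel) with
percentages rounded to one decimal (NA when the parent is empty). Two
caveats from the source arithmetic are reproduced as-is rather than
patched: the printed "10.8%" alongside 409/6719 is inconsistent (the raw
ratio is 6.1%; the package reports the raw ratio), and the printed 333
("positive correlation") vs 350 ("upregulated and 5hmC") are, under the
set definitions used here, the same intersection — `VennSummary` carries
both fields but computes them identically.

**Enrichment.** Upper-tail hypergeometric p = P(X ≥ k) for k query genes
in a K-gene term, query size n, universe N (scipy), with BH step-up
adjustment (scipy's `false_discovery_control`). Terms are user-supplied
two-column TSV (term_id, gene_id), intersected with the universe; terms
with k = 0 are dropped before BH so m counts only testable terms. No
ontology is bundled and no term-redundancy clustering is attempted.

## Synthetic data: what it emulates and what it does not

The generator lays out non-overlapping genes (default 100 genes on 2
chromosomes, bodies 12–20 kb, gaps 30–60 kb, random strands) and plants
six classes: `licensed` (10%), four ablation classes that each omit
exactly one criterion (5% each), and `null` genes (flat counts, IP =
input, no peaks). Defaults:

- counts: base mean 200; upregulated genes ramp log-linearly across the
  stage order to 2³ = 8-fold at CD4 SP (an 8-fold planted change against a
  2-fold gate). `dispersion` is the NB α (variance = μ + αμ²); 0 (the
  default) emits exact means, making the bundle fully deterministic and
  the noise-free recovery exact. Replicates: 2 per stage (DN3, DP, CD4SP).
- 5hmC: 100-bp bins over gene bodies, input 1.0; 5hmC⁺ genes get IP =
  input × 2⁴ in CD4 SP (16-fold against a 4-fold gate); a 25% subset is
  instead planted DP-high (2⁵ in DP, 2³ in CD4 SP) to exercise the
  DP-versus-CD4SP comparison.
- peaks: widths 300–500 bp. The developmental CRE sits 3 kb into the gene
  body with an H3K27Ac mark extending 100 bp beyond it on each side; the
  Th0-novel peak sits 8 kb into the body (even-indexed genes) or ~4 kb
  upstream of the TSS (odd-indexed), against the 10 kb rule. Every third
  intergenic desert also gets a background Th0 peak that is novel but
  assignable to no gene. These offsets leave ≥ 2 kb of slack on every
  rule, so the bounded position jitter (`peak_jitter_bp`, default 0,
  tested at 2 kb) can neither push a peak out of its body, bring planted
  peaks into overlap, nor cross the TSS-distance threshold — planted truth
  is invariant under default noise settings by construction.

What passing recovery shows: each detection stage responds to exactly the
feature it targets (the ablation classes flip exactly one signature bit),
and the thresholds are applied with the intended strictness. What it does
not show: performance on real data — the generator has no overlapping
genes, no mappability or GC structure, no replicate-level batch effects,
no partially-enriched 5hmC domains, and its planted effects clear every
threshold with margin, so recovery says nothing about sensitivity near
the thresholds on noisy signal.

## Numerical and design choices

- Strict inequalities everywhere the published thresholds are strict
  (">2", ">2", "<10 kb"); boundary values are excluded and tested.
- Pseudocount 1 on stage means and on both 5hmC sums; configurable.
- Percentages: `round(·, 1)`; parent 0 → NA (JSON null).
- Peak files may carry scores; an optional `min_peak_score` filter exists
  but defaults to off (all peaks imported).
- Determinism: a single integer seed drives the generator
  (`numpy.random.default_rng`); identical config + inputs give
  byte-identical pipeline outputs, and the run log records a SHA-256 of
  the analytic config (output directory excluded) plus the cascade counts
  — no timestamps.
- Problem sizes in the test suite (100-gene bundles, 1000×50 interval
  oracle instances, exhaustive hypergeometric enumeration to N = 12) were
  chosen to make the oracles exact and the suite fast on a laptop.

## Known limitations

- The expression gate is a fold-change filter, not a significance test;
  genes with large but noisy changes pass.
- Single-assignment peak→gene linking cannot represent enhancers shared
  by two genes; the nearest-TSS choice is a heuristic.
- The 5hmC score treats the gene body as one unit; focal 5hmC at a single
  intragenic CRE is diluted over long genes.
- The Th0-novelty rule is binary on overlap; a developmental peak shifted
  by more than its width yields "novel" even if biologically the same
  element.
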