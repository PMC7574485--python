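# Methods

`divergc` implements a comparative pipeline for detecting proteins that have
become aberrantly divergent in one rodent lineage (the gerbils: sand rat and
Mongolian jird) relative to a reference lineage (the murids: mouse and rat),
and for attributing that divergence to GC-biased gene conversion (gBGC)
rather than positive selection. This note documents the models, parameter
choices, numerical conventions and known limitations.

## 1. Conserved-position dissimilarity scoring

**Curation.** Each per-gene codon alignment passes three filters, applied in
this order: (i) any sequence whose gap count exceeds 70% of the non-gap
length of the longest sequence is removed (strict `>`, reference length
computed once before any removal); (ii) every amino-acid column containing a
stop codon, unknown residue (anything other than an unambiguous sense codon,
including `N` and other ambiguity codes) or missing residue in any species
is removed as a whole codon; (iii) an outgroup triple is chosen by a fixed
fallback table — {human, guinea pig, squirrel} → {human, degu, chinchilla} →
{human, guinea pig, jerboa} → {human, squirrel, degu} — taking the first
tier fully present. Columns at which all three outgroups share one residue
are **conserved positions**; the shared residue is taken as the ancestral
rodent state. Genes with fewer than 50 conserved positions are excluded.
The ordering gap-filter → site-filter → mask is this package's choice; the
filters commute in the common case but the order is fixed for
reproducibility. Column coordinates always refer to pre-site-filter
amino-acid positions so scores can be mapped back to input alignments.

**Scoring.** For a species *s* and gene *g* with conserved set *C* and
consensus residues *a\*(c)*,

    raw(g, s) = Σ_{c ∈ C} D(a*(c), a_s(c)),
    adjusted(g, s) = raw(g, s) / parsed_length(g),

where `parsed_length` is the number of columns surviving the site filter
(not the conserved-column count — "length of the parsed alignment" read
literally), and *D* is one of two bundled 20×20 dissimilarity tables:

* **Sneath-style index** — percentage of binary side-chain attributes in
  which two residues differ, over a curated 16-attribute table (aliphatic,
  aromatic, polar, charged, positive, negative, small, tiny, hydrophobic,
  hydroxyl, sulfur, amide, branched, ring, guanidinium, nitrogenous).
  Symmetric, 0 on the diagonal, strictly positive off it.
* **Epstein-style coefficient of difference** — built from side-chain
  polarity (charged 1.0 / polar 0.5 / nonpolar 0.0) and normalised
  side-chain volume: `100/√2 · √(Δp² + (c·Δs)²)` with `c = 1` when the
  replacement *grows* the side chain and `c = 0.5` when it shrinks it, so
  the coefficient is direction-dependent and is always evaluated
  consensus → focal (ancestral → derived). A floor of 1.0 keeps true
  substitutions strictly positive (polarity and size alone cannot separate
  e.g. Leu/Ile).

The original 1966/1967 publications print neither index in machine-readable
form; the bundled tables are generated by `scripts/derive_matrices.py` from
the constructions above, which follow the published principles
(attribute-set dissimilarity; polarity/size coefficient). Every downstream
result is a function of relative, not absolute, dissimilarities; the two
metrics rank genes near-identically (Spearman ρ > 0.97 on simulated data),
mirroring the concordance expected between them. Non-canonical focal
residues at conserved columns are skipped and counted, never scored as
maximal — the alternative would invent a penalty with no defined scale.

**Ranking.** The dissimilarity difference of a gene is
`adjusted(focal) − mean(adjusted over the reference set)`; the reference
mean is the mean of adjusted values (not the adjusted value of pooled raw
sums). Genes are ranked by descending difference with ties broken by
gene identifier. Classes use strict thresholds: "divergent" above 1.80 and
"extreme" above 3.0 — configuration values whose defaults correspond to the
discontinuities such rankings show over ~10⁴ rodent orthologues; a
largest-gap suggestion utility (`suggest_gap_cut`) is provided but never
auto-applied.

## 2. Category-partitioned substitution spectra

Single-nucleotide changes are partitioned by base class: WS (A/T → C/G),
SW (C/G → A/T), WW (A ↔ T), SS (C ↔ G). Because gBGC fixes weak→strong
alleles preferentially, `dS_ws/dS_sw ≫ 1` at synonymous sites is the
signature of conversion-driven evolution, independent of selection on the
protein.

**Counting.** The reference approach to this measurement fits a codon model
by maximum likelihood and counts by stochastic substitution mapping. This
package substitutes a deliberately simpler, fully testable approximation: marginal maximum-likelihood ancestral
reconstruction per nucleotide site under JC69 on the fixed input tree
(Felsenstein pruning, outside algorithm, argmax state with deterministic
ties), followed by per-branch codon comparison. Codon changes touching more
than one position are decomposed over all minimal single-step paths avoiding
intermediate stop codons, each path weighted `1/n_paths` (all paths,
unweighted-equivalently, when no stop-free path exists — logged). Counts are
summed over the branches from the murid–gerbil ancestor (the MRCA of mouse,
rat, sand rat and Mongolian jird) down to the chosen tip; the "Muridae" and
"murid–gerbil" node are the same node since Gerbillinae is nested within
Muridae. Validation against the simulator's event-level truth tables shows
per-category totals within ±10% at the default study conditions (the stated
acceptance bound is ±15%); the residual bias is the usual multiple-hit
undercount of reconstruction-based counting.

**Rates and outliers.** Synonymous opportunities use Nei–Gojobori
fractional site counting on the tip sequence, with stop-producing changes
counted as nonsynonymous; all four categories share the same denominator,
so category rates sum exactly to the total dS (respectively dN). Absolute
rate scales therefore differ from stochastic-mapping output by a constant;
ratios and outlier calls are scale-free. A gene is a category outlier when
its rate strictly exceeds 2.5× the dataset mean for that category. The
ratio `dS_ws/dS_sw` is flagged undefined when `dS_sw = 0`. Note that the
mean of per-gene ratios is upward-biased at small counts (E[X/Y] >
E[X]/E[Y]); where a calibration against 1 is needed (no-gBGC control) the
package's checks use the pooled ratio Σ WS / Σ SW with a delta-method
standard error instead.

## 3. Region enrichment and location null

Genes map to high-GC regions by locus midpoint, with half-open 0-based
intervals internally; BED input is taken as-is and gene-locus TSVs are
declared 1-based inclusive and converted on read. Enrichment of divergent
genes inside regions uses the two-sided Fisher exact test under the
point-probability rule (verified against exhaustive hypergeometric
enumeration for all tables with row margins ≤ 12); at the effect sizes of
interest sidedness is numerically negligible. Divergence clusters are
maximal runs of ≥ 3 divergent genes with consecutive midpoints < 1 Mb
apart. The location null draws 10,000 random gene sets of size *k* without
replacement and counts members inside regions; the empirical *p* uses
add-one smoothing, `(1 + #{samples ≥ observed})/(n + 1)`, so finite
sampling never reports *p* = 0. The statistic compared between the observed
set and the samplings is the in-region count; the choice is fixed here and
documented because other statistics (e.g. nearest-neighbour distances)
would also be defensible.

## 4. The simulator

`simulate_dataset` generates the study conditions end to end: per-gene
codon alignments along a 13-taxon rodent-like tree (12 rodents + human;
branch lengths in neutral substitutions/site proportioned to published
divergence times, with the murid–gerbil span ≈ 0.125 to each of the four
focal tips and the gerbil stem longer than the gerbil terminal branches),
gene coordinates on a synthetic genome, a high-GC region BED, and a truth
table of every substitution event that replays exactly to the tip
sequences.

Evolution is a Gillespie process at nucleotide resolution. The rate of a
single-nucleotide change is

    rate = μ/3 · f_sel            (+ μ/3 · (λ − 1) if the change is W→S on a
                                   gerbil-lineage branch of an island gene)

with `f_sel = 1` for synonymous changes, `ω` for nonsynonymous changes,
`ω·φ` at constrained codons, and 0 for changes creating stop codons.
Constrained codons (a per-gene fraction, default 0.6) model deep purifying
selection: nonsynonymous change there is forbidden on branches outside the
murid–gerbil clade — which guarantees the ≥ 50 outgroup-conserved positions
the scoring stage needs — and strongly suppressed (φ = 0.05) inside it.

gBGC is modelled as an *additive fixation route*, not a multiplier on the
selection-filtered rate: conversion fixes weak→strong variants regardless
of whether selection would have purged them, which is exactly the regime
that produces radically divergent proteins inside GC islands while the
orthologous murid copies stay conserved. The additive form reduces the
model to the plain purifying process at λ = 1, making the no-gBGC control
exact. It is a phenomenological stand-in for the underlying
population-genetic conversion dynamics (no recombination map, demography,
indels or assembly error are modelled).

Defaults (the study conditions of all built-in checks): 300 genes, 10%
island genes, λ = 5, mean gene length 200 codons (gamma-distributed,
minimum 60), μ = 1 (branch lengths are then neutral substitutions/site),
ω = 0.2, φ = 0.05, constrained fraction 0.6. Under these conditions planted
island genes score adjusted-dissimilarity differences of roughly 4–10
against a background within ±1.5 — the same order as the published 1.80/3.0
cuts — show gerbil dS_ws/dS_sw ≈ 4.5 versus ≈ 1.2 in the background, and
elevated gerbil GC3, reproducing the "chimney" pattern. Randomness flows
from a single seed through named per-gene substreams
(`numpy.random.SeedSequence.spawn`), so outputs are bitwise reproducible.

**What passing the simulated checks does and does not show.** The
simulator emulates the statistical structure the analysis assumes
(outgroup-conserved columns, lineage-restricted W→S excess, island
clustering of affected genes). It does not emulate alignment error,
orthology mistakes, assembly gaps, rate variation among genes beyond
length, isochore structure, or selection heterogeneity along proteins;
recovery rates on simulated data are therefore an upper bound on what the
pipeline would achieve on real alignments.

## 5. Problem sizes of the built-in checks

The test-suite and acceptance computations use 300-gene datasets at the
default conditions for recovery/accuracy checks, 150-gene datasets per λ ∈
{1, 2} for the calibration/monotonicity checks, 10,000 draws for the
sampling null, and exhaustive enumeration (margins ≤ 12) for the Fisher
oracle — sizes chosen so every quantity is estimated with comfortable
statistical margin while a full run completes in about a minute on one
core.

## 6. Known limitations

* JC69 marginal reconstruction ignores codon structure and base-composition
  bias; with strong GC skew the ancestral GC content can be slightly
  over-pulled toward the tips, part of the ±10% category-count error.
* The Sneath/Epstein tables are principled reconstructions, not the
  original printed constants; analyses depending on absolute score values
  (rather than differences and ranks) should treat the scale as arbitrary.
* Per-gene branch-length re-optimisation is not performed; rates inherit
  the fixed input tree's scale.
* Stored rates are never capped or winsorised; capping extreme dS values
  for display (a common plotting device for the "chimney" figure) is left
  to plotting code.
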