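# Methods

This note documents the models and procedures behind `knockoutkit`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behavior on real data.

## Knockout compendium

Large population-sequencing studies each publish a list of genes observed
with biallelic predicted loss-of-function (pLOF) — homozygous or compound
heterozygous — in apparently healthy adults. The compendium is the union of
those per-study lists with full provenance: a gene is one entry no matter
how many studies report it ("non-redundant" = distinct canonical symbols),
and its membership records every reporting study.

Gene identity is the canonical symbol string: stripped, uppercased, and
optionally remapped through a user-supplied two-column alias table (e.g.
`NEMO → IKBKG`). No identifier service is queried; the alias table is the
only harmonization mechanism, which makes every downstream count
deterministic and auditable. Published compilations rarely state their
harmonization procedure, so any shipped alias table is a convenience, not a
reconstruction of one.

Overlap statistics count genes by the number of studies reporting them
(with the conventional 1 / 2 / ≥3 binning), plus per-study exclusives.
Venn region counts are limited to 2–5 studies; larger designs should use
the overlap summary or an UpSet-style export of `count_by_n_studies`.

### Over-representation analysis

ORA uses the hypergeometric upper tail: with universe size N, gene-set size
K (after restriction to the universe), query size n and overlap k,

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n)

with Benjamini–Hochberg q-values across all sets tested in one call. The
universe is always user-supplied, never inferred: published analyses are
ambiguous between "all annotated genes" (~16,710 in the S_het annotation)
and "all protein-coding genes" (~20,000), and the choice changes every
p-value. Sets with zero overlap are reported with p = 1.

## S_het gene-set constraint

S_het is the selection coefficient against heterozygous loss of function;
larger values mean stronger purifying selection. The package consumes it as
a per-gene annotation table and never recomputes it. A group summary
reports median and interquartile range of the mapped members against a
stated background universe, with unmapped members counted but excluded
from statistics (no imputation). A two-sided Mann–Whitney rank-sum test
against the background is opt-in (`rank_sum=True` / `--rank-sum`):
the figure-style output this emulates is descriptive, and the package does
not attach an inferential claim unless asked.

## Human–mouse essentiality concordance

Mouse knockout programs classify genes as viable / subviable / lethal.
The concordance operation fixes the filter order:

1. keep mouse genes whose knockout call is `viable` (subviable is treated
   as non-viable and excluded);
2. keep one-to-one ortholog pairs only — a gene appearing in more than one
   one-to-one pair is a conflict and those pairs are excluded with a log
   entry;
3. translate the mouse set into human gene symbols;
4. restrict the human non-essential set to genes covered by one-to-one
   pairs, then intersect.

Because "fraction shared" has three defensible denominators (human-side
set, mouse-side set, or their union), `ConcordanceResult` exposes
`fraction_of_a`, `fraction_of_b` and `jaccard` explicitly rather than
privileging one.

## Hardy–Weinberg homozygosity

For a heterozygote frequency h ∈ (0, 0.5], the minor allele frequency is
the smaller root of 2(1−q)q = h:

    q = (1 − sqrt(1 − 2h)) / 2

giving homozygote frequency q² and an expected one homozygote per 1/q²
individuals. At h = 1‰ this is ≈ 3.996 × 10⁶ — the "one in four million"
intuition for why population missense variants at functional sites are
almost always seen in heterozygous state. h > 0.5 is rejected as
impossible (2pq peaks at 0.5); the small-h approximation q ≈ h/2 has
relative error < h for h ≤ 0.01, which the tests check numerically.

## PTM-site constraint and conservation

For one protein isoform, protein-level variant records are aggregated into
a per-residue track: missense count, cumulative allele frequency (sum of
the AFs of all missense variants mapping to the residue — a mutation-rate
proxy), and an any-homozygote flag. Only missense consequences count;
synonymous and nonsense records are validated but ignored. Records whose
reference residue disagrees with the sequence, or whose position falls
outside it, are rejected and counted; rejection above 5% triggers a hard
warning because it usually means the variant table was annotated on a
different isoform. One canonical sequence per protein is assumed
throughout.

A site is **constrained** iff its missense count is zero — a deliberately
literal criterion with no allele-frequency threshold. Constrained sites
are then tested for conservation in a single ortholog via global
Needleman–Wunsch alignment with affine gaps (Gotoh), BLOSUM62, gap open
−10, gap extend −1, terminal gaps charged normally. These defaults are the
package's own choice; published descriptions of this kind of analysis
typically name no parameters. Tie-breaking in the traceback is fixed
(diagonal, then up, then left) so alignments are reproducible. Conservation
means residue **identity** at the aligned position — the strictest
defensible reading of "conserved" — with `allow_similar` optionally
accepting positive BLOSUM62 scores. Sites aligned to a gap, or classified
without an ortholog, are `CONSTRAINED_UNALIGNED` rather than silently
dropped. The four statuses partition the sites; a site with any missense
variant is `MUTATED` regardless of conservation. Homozygote counts are
carried through to output but never influence the call.

The aligner is implemented in-package so that tie-breaking is under
contract; its scores are verified in the tests against an independent
affine-gap global aligner and against hand-computed DP tables on short
pairs.

Track export writes one TSV row per residue (`%.17g` float formatting so
re-reading is bit-exact) and, optionally, an SVG with allele-frequency
bars above, PTM tick marks below (constrained-and-conserved sites in red)
and domain bands (ankyrin-repeat region blue, PEST yellow). Every number
in the figure exists in the TSV.

## Synthetic data

Every generator takes one explicit seed and uses a private
`numpy.random.default_rng`; identical spec + seed gives byte-identical
output files. Hard guarantees — protected positions carry zero variants,
conserved positions are never substituted or deleted, explicit membership
matrices are reproduced verbatim — are asserted on every run.

* **Study lists** — either an explicit gene × study membership matrix
  (ground-truth overlap equals the column sums exactly) or per-study
  Bernoulli inclusion probabilities (ground truth computed from the
  realized draws). `gen_compendium_demo` builds a nine-study design whose
  marginals are planted at the published compilation's scale: 6689 genes,
  3895 single-study (2736 exclusive to the largest, million-exome-scale
  study), 2794 multi-study, with multi-study genes assigned to 2–9 studies
  (smaller overlaps more common, studies weighted by list size), plus a
  pathway gene set with 28 members inside the compendium.
* **Variant tables** — per-residue Poisson missense counts (default rate
  0.3/residue, roughly the density seen for well-covered exome genes),
  log-uniform allele frequencies on [1e-6, 1e-3] (rare-variant regime; no
  attempt to match a real site-frequency spectrum), AN = 10⁶ alleles,
  a 20% admixture of synonymous records to exercise consequence filtering,
  and occasional homozygotes (2%).
* **Orthologs** — per-position substitution probability (default 8%,
  roughly primate-scale protein divergence), optional short indels, and a
  returned base→ortholog position map that serves as the alignment oracle.
* **S_het groups** — log-normal scores per named group; the planted
  contrast used in tests is μ = −3 vs −2 at σ = 1, n = 200, i.e. groups
  one σ apart.
* **Concordance** — 1000 one-to-one viable ortholog pairs with a planted
  38% shared fraction, plus non-viable and non-one-to-one decoy pairs whose
  human genes are deliberately placed in the non-essential set so that any
  filter leak changes the counts.
* **`ikba_demo`** — the flagship fixture: a synthetic 317-residue sequence
  (the residue numbering, domain layout and site positions mirror the
  classic IκBα story — phospho-degron Ser32/Ser36, Tyr42, ubiquitin
  acceptor Lys67, ankyrin repeats 73–280, PEST 281–317 — but the sequence
  itself is random). Planted fates: 32/36/42/67 variant-free and conserved;
  100/150 deliberately hit by missense; 200 variant-free but substituted in
  the ortholog; 250 variant-free but inside a deleted loop (246–255).

What passing these tests shows — and does not. The generators prove the
machinery: exact union/overlap accounting, correct filter order, exact
planted-site recovery, correct tail probabilities. They do not emulate
real-data pathologies: symbol harmonization across heterogeneous sources,
isoform mismatches between a variant table and the chosen sequence,
multi-transcript coordinate lifting, or realistic site-frequency spectra.
Results on real inputs depend on those upstream choices, which the package
surfaces (rejection statistics, load logs) but cannot resolve.

## Numerical and degenerate-input choices

* Quartiles via `numpy.percentile` (linear interpolation).
* Hypergeometric tail via `hypergeom.sf(k−1, …)`; k = 0 short-circuits to
  p = 1 to avoid floating overshoot.
* HWE consistency is validated to 1e-12; heterozygote frequencies outside
  (0, 0.5] are fatal with an explanation.
* Empty study lists are retained (warning); an empty compendium, an empty
  ORA universe, or a query empty after universe restriction are fatal.
* Alignment of an empty sequence is fatal; ambiguous residues U/B/Z/J map
  to X on FASTA input (BLOSUM62 defines X scores).
* Problem sizes in the test and acceptance runs — 6689-gene compendium,
  1000 ortholog pairs, 317-residue protein, n = 200 score groups — are the
  study-scale conditions above; both complete in seconds.

## Known limitations

* One ortholog pair only; no multi-species phylogenetic conservation score.
* No transcript/protein coordinate lifting and no VCF parsing: variants
  arrive as protein-level records.
* The compendium treats a gene symbol as the unit of identity; paralog
  collapses or symbol clashes in the input propagate.
* ORA p-values are as interpretable as the supplied universe.
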