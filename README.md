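# knockoutkit

Tools for analyzing naturally occurring human gene knockouts and the
genetic constraint of post-translational-modification (PTM) sites, built
around the NF-κB signaling system but usable for any pathway.

Large population-sequencing efforts (hundreds of thousands to a million
exomes) report genes observed with biallelic predicted loss-of-function in
apparently healthy adults — natural "knockouts" that delineate the
non-essential part of the genome. `knockoutkit` provides, as a tested
library plus a `ko` command line:

* **Compendium** — union of per-study knockout gene lists with provenance,
  overlap statistics (genes in exactly 1 / 2 / ≥3 studies, per-study
  exclusives, Venn regions for up to five studies), and over-representation
  analysis of the compendium against GMT gene sets: hypergeometric upper
  tail P(X ≥ k) with Benjamini–Hochberg correction.
* **Gene-set constraint** — median/IQR of S_het (the selection coefficient
  against heterozygous loss of function) for named gene groups against a
  background universe, with an opt-in two-sided rank-sum test.
* **Cross-species concordance** — overlap of human non-essential genes with
  viable mouse knockouts, restricted to one-to-one orthologs, with all
  three candidate denominators (human-side, mouse-side, Jaccard) reported.
* **Hardy–Weinberg calculator** — individuals per homozygote implied by a
  heterozygote frequency h, via the exact minor root q = (1 − √(1 − 2h))/2.
* **PTM-site constraint** — per-residue missense counts and cumulative
  allele frequency from protein-level variant tables, global affine-gap
  alignment (BLOSUM62, −10/−1) against an ortholog, and a dual-criterion
  site call: `MUTATED`, `CONSTRAINED_CONSERVED`,
  `CONSTRAINED_NOT_CONSERVED`, or `CONSTRAINED_UNALIGNED`.
* **Synthetic data** — seeded generators for every input format with
  planted ground truth, so the whole pipeline is testable offline.

All reference data (gene lists, S_het tables, viability calls, ortholog
maps, variant tables, PTM tables, sequences) are user-supplied text files;
nothing is fetched from a database. See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

How often is a heterozygous variant seen homozygous? For h = 1‰ under
Hardy–Weinberg equilibrium:

```python
from knockoutkit import hwe_individuals_per_homozygote

res = hwe_individuals_per_homozygote(0.001)
print(f"q = {res.allele_freq:.6g}, q^2 = {res.homozygote_freq:.6g}, "
      f"1/q^2 = {res.individuals_per_homozygote:,.0f}")
```

```
q = 0.00050025, q^2 = 2.5025e-07, 1/q^2 = 3,995,999
```

— about one homozygote in four million individuals, which is why
population missense variants at functional sites are essentially always
monoallelic.

Classifying PTM sites on the bundled demonstration protein (a synthetic
317-residue IκBα-style sequence whose site numbering mirrors the real
protein — phospho-degron Ser32/Ser36, Tyr42, ubiquitin acceptor Lys67):

```python
from knockoutkit import build_residue_track, classify_sites
from knockoutkit.synthetic_data import ikba_demo

demo = ikba_demo(seed=3)
track = build_residue_track(demo.protein, demo.variants)
calls = classify_sites(demo.sites, track, demo.alignment())
for c in calls:
    print(f"{c.site.label:>5} {c.site.mod_type:<9} {c.status:<26} "
          f"missense={c.missense_count} cum_AF={c.cumulative_af:.2e}")
```

```
  S32 phospho   CONSTRAINED_CONSERVED      missense=0 cum_AF=0.00e+00
  S36 phospho   CONSTRAINED_CONSERVED      missense=0 cum_AF=0.00e+00
  Y42 phospho   CONSTRAINED_CONSERVED      missense=0 cum_AF=0.00e+00
  K67 ubiquitin CONSTRAINED_CONSERVED      missense=0 cum_AF=0.00e+00
 S100 phospho   MUTATED                    missense=1 cum_AF=5.00e-06
 T150 phospho   MUTATED                    missense=1 cum_AF=5.00e-06
 K200 ubiquitin CONSTRAINED_NOT_CONSERVED  missense=0 cum_AF=0.00e+00
 S250 phospho   CONSTRAINED_UNALIGNED      missense=0 cum_AF=0.00e+00
```

The four degradation- and activation-critical sites come out variant-free
in the population *and* conserved in the ortholog — the dual criterion for
candidate functional relevance — while the deliberately mutated decoy
sites are flagged `MUTATED` regardless of conservation.

The same pipeline from the shell, with a TSV track, per-site calls and an
SVG rendering:

```sh
ko ptm track --fasta protein.fa --ptm sites.tsv --variants variants.tsv \
   --ortholog lemur.fa --domains domains.tsv --out track.tsv --svg track.svg
```

Other subcommands: `ko compendium {build,overlaps,venn,ora}`,
`ko shet summarize`, `ko concordance`, `ko hwe --het-freq 0.001`, and
`ko simulate {studies,variants,ortholog,shet}` (synthetic inputs plus a
`truth.json` ground-truth file). Every run writes a `run_summary.json`;
outputs carry no timestamps, so seeded runs are byte-identical on re-run.

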