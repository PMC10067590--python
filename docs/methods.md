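# Methods

This note documents the models and procedures implemented in `mtintrons`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
affect results.

## In-silico PCR

**Primer-site model.** A primer binds wherever the ungapped Hamming distance
between the primer and the template window is within a mismatch budget
(default maximum 5).  Matching is IUPAC-aware and asymmetric: a primer base
matches a template ambiguity code iff the base belongs to the code's set, so
a template `N` matches every primer base and is counted as a match.  This is
the right bias for ambiguous assemblies: an `N` usually hides a real base
that the primer may well match.  Indels within the primer footprint are not
modelled — per-primer mismatch counts are only meaningful for ungapped
binding, which is also how practitioners read primer-specificity reports.
Both strands are scanned; circular templates are scanned across the origin
(a rotation of a circular template never changes the hit set).

**3′ ends.** Mismatches within the five 3′-terminal primer bases are counted
and reported but do **not** veto a hit by default: polymerase extension
sensitivity to 3′ mismatches varies by enzyme and cycling conditions, so the
decision is left to the user as a filter on the reported counts.

**Products.** Every convergent (forward plus-strand, reverse minus-strand)
hit pair whose end-to-end span falls within the product-size window becomes
a predicted amplicon.  Lengths are primers-inclusive (end-to-end), the
convention used by in-silico PCR tools and by the published product-size
tables this package is designed to reproduce.  The default window is
100–6,000 nt: wide enough to admit both the shortest intron products
(~550 nt) and >4-kb split-intron alleles, and narrow enough to exclude
products a 3-minute extension would not amplify.  All qualifying hit pairs
are reported; no greedy suppression — multiplicity is expressed by the
classification, not by hit pruning.

**Classification.** Per combination of one primer pair and one genome set
(multi-contig sets pool hits before classification):

| summary           | condition                                             |
|-------------------|-------------------------------------------------------|
| `single_perfect`  | exactly one product, both primers 0 mismatches        |
| `single_strong`   | exactly one product, worse primer 1–2 mismatches      |
| `single_weak`     | exactly one product, worse primer 3–5 mismatches      |
| `multiple_targets`| more than one product (class mix kept per amplicon)   |
| `no_match`        | no product                                            |

The field convention distinguishes "0–2 mismatches per primer" from "weak"
(4–5 mismatch) targets and leaves 3 unassigned; here 3 mismatches joins the
weak class so the partition is total.  This is a labelling choice only — the
per-primer mismatch counts are always carried on the amplicon.

## Pairwise alignment

Global alignment with affine gap costs (Needleman–Wunsch/Gotoh), via
Biopython's `PairwiseAligner`.  A gap of length L costs
`gap_open + (L−1)·gap_extend`.  Defaults: match +2, mismatch −3, gap open 8,
gap extend 1.  The high open-to-extend ratio keeps an isolated 1–10-nt indel
— the dominant indel class in plant mitochondrial introns — reported as one
contiguous gap run rather than fragmented, while the mismatch penalty keeps
SNPs aligned as substitutions rather than paired indels.  `N` scores 0
against everything.  Ties between equally optimal tracebacks are broken by
the aligner's deterministic traceback order (first alignment of the sorted
iterator), so coordinates are reproducible run-to-run; with these scores a
mismatch (−3) never ties a fresh gap pair (−16), so the tie set is
essentially gap-placement freedom inside equal-scoring runs.

Multiple sequence alignment is deliberately absent: the divergence
statistics below are defined on pairwise alignments, and multi-taxon
coordinate systems are tool-specific and not reproducible across aligners.

## Polymorphism typing and divergence statistics

* **SNP site** — a gap-free column with two differing unambiguous bases.
  C/T-like pairs (C/T or G/A) are flagged because plant mitochondrial C-to-U
  RNA editing can erase such differences at the RNA level; the flag is
  reported, never interpreted.
* **Indel event** — one maximal run of gap columns in one sequence,
  regardless of length; a 3,353-nt insertion is one event, as is a 1-nt gap.
  Complex regions where gap runs in the two sequences abut are resolved by
  the alignment's deterministic traceback; no post-hoc merging.
* **K₀** — substitutions per site on the gap-stripped alignment.  Columns
  containing `N` are excluded from both numerator and denominator.  The
  default correction is Jukes–Cantor, K₀ = −¾ ln(1 − 4p/3); Kimura's
  2-parameter correction is selectable (`correction="k2p"`), and at the
  divergence scales relevant here (p ≤ 0.05) the two differ by < 0.002,
  below the reporting precision.  p ≥ 0.75 raises an undefined-distance
  error rather than returning a complex number.
* **I** — indel events divided by the number of gap-stripped, N-free sites
  (the same denominator as p; the two definitions coincide whenever no `N`
  is present, which is always the case for Sanger-derived amplicons).
* **Group summaries** — arithmetic mean and *sample* (n−1) standard
  deviation over pairs; SD is defined as 0 for a single pair.

**Allele tables.** Entries with byte-identical amplicon sequences share an
allele; alleles are numbered by decreasing length (longest = allele 1, ties
broken lexicographically for determinism).  A configurable gel-resolvability
threshold (default 8 nt — roughly what acrylamide gels resolve for ~1-kb
products; smaller indels require sequencing) marks which allele pairs are
distinguishable by electrophoresis alone.  Entries are compared within a
locus only.

## CAPS marker diagnosis

Amplicons are linear PCR products, so only linear digestion is modelled.
Recognition sites are matched on the plus strand, and non-palindromic sites
additionally as their reverse complement with cut positions mapped back to
plus-strand coordinates; overlapping sites all count.  Ambiguity handling is
conservative in the opposite direction from primer matching: a site matches
only where the template code is *contained* in the site code, so every
reported cut is guaranteed.  An enzyme is diagnostic for an allele pair iff
its two fragment-length multisets differ; diagnostic enzymes are ranked by a
gel-practicality metric (the smallest distance from any fragment unique to
one pattern to the nearest fragment of the other — larger is easier to see),
largest first.

The bundled enzyme table lists 70+ common Type IIP enzymes with their
recognition sites and cut offsets.  It is a convenience set, not any
vendor's catalogue; every report carries `n_enzymes_tested`, so counts of
diagnostic enzymes are comparable only between runs using the same table.
Note that an indel is diagnostic for almost every cutting enzyme (some
fragment shifts by the indel length), whereas a lone SNP is diagnostic only
if it creates or destroys a site present in the table — single-SNP CAPS
counts are therefore strongly enzyme-set-dependent.

## Synthetic data generator

The generator builds miniature genomes with the structure the pipeline
cares about: per marker locus, an exon anchor, an exact forward-primer
site, a random intron, the reverse-complemented reverse-primer site, and a
second exon anchor, embedded in random intergenic filler.  Relatives are
derived by planting SNPs and indels *inside introns only* (exon flanks of
these markers are conserved in practice; an exon-mutation mode exists for
robustness testing but defaults off), with every event logged in a truth
record whose replay reproduces the derived sequence byte-for-byte.

Key parameters (per-site rates unless noted):

| parameter | default | rationale |
|---|---|---|
| `snp_rate` | preset | `congener` preset 0.001, `inter_genus` 0.04 — the two divergence scales observed for these introns (within-genus K₀ ≈ 0–0.001; between dicot genera ≈ 0.03–0.05) |
| `indel_rate` | preset | 0.0002 / 0.003 — indels occur at roughly 0.1–0.2× the substitution frequency at both scales |
| `n_snps`, `n_indels` | unset | exact per-locus counts, overriding the rates; used to plant precise contrasts |
| `indel_length_weights` | uniform 1–10 nt | short indels dominate real intron variation (slipped-strand mispairing); a rare large insertion (split-intron mimic) is available via `large_insertion_length/_prob` |
| `min_event_spacing` | 25 nt | keeps planted events from coalescing into one alignment gap run, so truth comparison is exact |
| `edge_buffer` | 30 nt | keeps events away from primer-adjacent intron ends |
| `exon_anchor_length` | 60 nt | typical conserved exon stretch available around these introns |

**Sanitization.** Random filler can contain chance windows within 5
mismatches of a 18–20-nt primer (expected a handful per 100 kb), which
would corrupt planted truth tables.  After assembly, every spurious window
within the scan budget of any amplification primer is re-randomized until a
scan finds exactly the planted sites.  Planted sites themselves (including
deliberately mismatched ones) are protected intervals.

**What the generator does not emulate:** real base composition and
repeat structure of plant mitochondrial genomes, genome rearrangement and
recombination, substitution-rate heterogeneity along the intron,
codon/structure constraints, heteroplasmy, and sequencing error.  Passing
tests on synthetic panels therefore demonstrate the *algorithmic*
correctness of scanning, pairing, classification, alignment, typing and
statistics under realistic event densities — not performance on noisy
assemblies.

### Evaluation panels

`mtintrons.panels` builds deterministic synthetic stand-ins for the
published survey conditions (the real inputs are GenBank records that this
package deliberately does not fetch):

* an 11 × 11 genome-set × locus panel planted with a fixed class mixture —
  79 perfect single products, 18 singles at 1–2 mismatches, 1 weak single,
  19 multi-target cells, 2 no-match cells — and with each clean single
  cell's product length set to the published prediction for that cell
  (e.g. 1067 nt for the Silene-latifolia-like ccmFci1 cell, 596 nt for the
  Allium-normal-like nad1i2 cell).  The published survey reports only the
  mixture totals, not which plain cells carried 1–2 mismatches; the 18 are
  planted in the two seagrass-like rows as a fixed, documented choice.
* congener amplicon panels for the three sequenced introns, with the
  published within-genus contrasts planted exactly (Cynodon-like nad5i4:
  3 SNPs + one 4-nt indel; Cenchrus-like ccmFci1: one 4-nt indel, no SNPs;
  one Vaccinium-like nad5i4 SNP; 1–2 SNPs in the citrus-like trio; a
  monomorphic solanum-like pair; ccmFci1 free of within-genus SNPs
  everywhere) and between-genus divergence planted at the published K₀
  scale by inverting the Jukes–Cantor correction into per-branch
  substitution counts.
* a split-intron pair sharing 632 5′ and 133 3′ nucleotides around a
  3,353-nt insertion.

Problem sizes throughout (intron lengths ~0.9–1 kb, genome sets of tens of
kilobases, 100-seed recovery sweeps over 3-locus genomes with ~400-nt
introns) match the real amplicons while keeping the full evaluation in the
seconds-to-a-minute range.

## Pipeline and reproducibility

`run_pipeline` executes scan → type → divergence → caps from one config and
writes five TSV reports plus a JSON manifest.  Every stage is a pure
function of (inputs, config); all randomness in the package flows from a
single seeded `numpy` generator, so identical seeds and configs give
byte-identical outputs.  Each report carries the config checksum in a
header comment line; the checksum covers analysis-relevant parameters only
(not the output directory or log level).  Divergence comparisons default to
all within-locus entry pairs in one group per locus; explicit
(entry, entry, group) triples in the config reproduce grouped layouts such
as within-genus vs between-genera tables.

## Known limitations

* Primer thermodynamics (melting temperature, 3′ ΔG) are out of scope; the
  mismatch-count model is a structural approximation of specificity.
* The mismatch model is substitutions-only; a template with an indel inside
  a primer footprint scores as multiple mismatches rather than a bulge.
* Circular digestion is not implemented (amplicons are linear).
* Alignment-parameter freedom means indel *coordinates* (not counts) near
  repeats can differ from other aligners' output; divergence statistics are
  insensitive to this at the tolerances used.
* The bundled enzyme table is not a complete commercial catalogue;
  single-SNP CAPS counts depend on the table supplied.
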