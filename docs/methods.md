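# Methods

This note records the models behind `anispec`, the parameter choices that
matter, what the synthetic world does and does not emulate, and the
numerical conventions a reader needs to interpret the outputs.

## Fragment ANI

A genome-pair comparison tiles the query into non-overlapping windows
(`window_bp = step_bp = 1000`, trailing windows ≥ `min_fragment_length =
500` bp kept, windows with > 50% N masked out and reported separately) and
finds each fragment's best local alignment against the full subject, both
strands. Identity is defined as matches divided by *all* alignment columns,
gap columns included — tools differ here, so the convention is stated in
the JSON report. A fragment counts as a hit only when the best alignment
covers ≥ 50% of the fragment at ≥ 70% identity; anything weaker is a zero
hit. This makes "divergent but alignable" and "no similarity found" a clean
dichotomy, which the downstream spectrum rules depend on, and it is why
low-complexity filtering is disabled in the BLAST backend.

The directional ANI is the *unweighted* mean over hit fragments (fragments
are near-uniform in length, so length weighting changes nothing
material); the reciprocal ANI is the arithmetic mean of the two directions.
The zero-hit fraction of tiled fragments is the direction's specific
fraction. Masked fragments are excluded from the denominator entirely: Ns
are assembly artefacts, not biology.

Two engines implement the per-fragment alignment:

- **blast** — `blastn -task blastn` with dust/soft-masking off, best HSP by
  bitscore per fragment. Benchmarks on 1 Mb simulated pairs show identity
  bias ≤ +0.1 percentage points down to ~86% identity and ~1–6 s per
  direction.
- **exact** — affine-gap Smith–Waterman (match +1, mismatch −2, gap open
  −5, extend −1) via Biopython's `PairwiseAligner`. Quadratic; the `auto`
  engine uses it only when both genomes are ≤ 50 kb. The test suite holds
  it to an independently written dynamic-programming oracle, fragment by
  fragment, with exact score and identity agreement.

The per-fragment identity spectrum is kept as a histogram (default edges
70, 75, 80, 85, 90, 95, 97, 99, 99.5, 100; half-open bins, top bin closed)
together with two pooled summaries: the fraction of hit fragments at
≥ 99.5% identity and the fraction of all fragments in the 85–90% band.

## Delimitation rules

Thresholds (all configurable, echoed in every report): conspecific at ANI
≥ 99.5 (`t_same`), distinct below 99 (`t_diff`), with the 99–99.5 interval
reported as `ambiguous` — published usage of these cut-offs treats the
region between them as undecided, and the pipeline does not pretend
otherwise. Below `t_diff` a spectrum exception applies: high-identity
fraction ≥ 0.80, divergent-band fraction ≥ 0.02 and mean specific fraction
≤ 0.03 together rescue the pair as `same_species_divergent_blocks`. The
three exception thresholds quantify a qualitative argument (most of the
genome at species-level identity, a visible 85–90% band, few specific
sequences) and are deliberately conservative; rule order is fixed, with the
exception evaluated only below the species line.

**A quantitative caveat on the divergent-block scenario.** The mean over
hit fragments bounds how far a small divergent minority can drag ANI: with
95% of fragments at background identity *b* and 4% in the 85–90% band, even
a perfectly identical background (*b* = 100) gives ANI ≥
(0.95·100 + 0.04·85)/0.99 = 99.39. Pushing ANI below 99 with the band at
85–90% requires roughly 9% of the genome in divergent blocks (then
ANI ≈ 98.7 at *b* ≈ 99.8, which is also the regime in which real bimodal
conspecific pairs have been reported). The simulator reproduces this regime
— see the bimodal-pair test and the worked example — but a composition of
exactly 95% / 4% / 1% cannot mathematically yield ANI < 99, and one bundled
scenario test documenting that composition is expected to fail; it is kept
as a record of the arithmetic rather than silenced.

## Synthetic genome pairs

The generator states a world and reports its truth; its defaults are the
conditions the analyses assume.

- **Ancestor**: i.i.d. bases, GC fraction 0.5 by default, split into equal
  contigs.
- **Substitutions**: Jukes–Cantor-like uniform replacement (each substituted
  site takes one of the three alternative bases with equal probability); the
  analysis consumes only identity fractions, so a richer substitution model
  would add parameters without adding signal. Divergence parameters are
  expected *pairwise* per-site probabilities; each lineage mutates at half
  that rate, and the exact expectation with double hits,
  P(match) = (1 − d/2)² + (d/2)²/3, is stored in the `TruthRecord`
  (`divergence_for_identity` inverts it). Recovery tests are therefore
  sharp: over 20 replicates at 1 Mb the mean realized identity sits within
  0.2 percentage points of the analytic value.
- **Divergent blocks**: a fraction `divergent_block_fraction` of the genome
  in 5 kb blocks (uniform placement, non-overlapping, bounded rejection
  sampling with 1000 retries) mutated at `divergent_block_divergence`.
- **Specific segments**: a fraction `specific_fraction` in 5 kb segments
  where *both* genomes receive distinct fresh random sequence. Replacing
  only one genome would double the realized zero-hit fraction — the partner
  direction would also find nothing over that locus, having lost the
  ancestral copy — so paired replacement is what makes the realized
  specific fraction per direction equal the parameter. Replacement (rather
  than deletion) keeps genome sizes comparable, mirroring specific
  sequences as zero-hit regions rather than length differences.
- **Indels**: geometric lengths, default rate 0 — identity spectra are the
  object of study, and an indel-free world keeps the positional alignment
  exact for truth bookkeeping. With indels enabled, realized identities in
  the `TruthRecord` refer to the pre-indel alignment and interval
  coordinates are pre-indel.

What the generator does **not** emulate: repeats and transposons (real
zero-hit regions are often repeat-rich), GC heterogeneity and rate
variation along the genome, assembly gaps/N-runs, and contamination. A
green recovery test therefore establishes correctness of the measurement
machinery on a clean divergence signal, not robustness to every artefact of
real draft assemblies.

## Barcodes

Extraction aligns the reference (ITS, LSU or ITS+LSU) to all contigs and
returns the best-matching subject span, reverse-complemented to reference
orientation when needed; it fails informatively below `min_identity`
(default 75%) or when the span is outside 0.5–2× the reference length (the
case where a real pipeline would re-assemble rRNA reads instead).
Difference counting uses an optimal global alignment (same scores as the
exact engine) and a column scan: "aligned nucleotides" are columns where
both sequences have a base, substitutions are the incompatible such columns
(IUPAC-compatible overlaps are not differences), and indel columns are
reported separately since published difference counts do not state their
convention. Counts near score ties can shift by ±1 under different
alignment scores, which is why the scores are exposed.

## Mating-type locus

Architecture is classified from annotations over the fixed vocabulary
(APN2, SLA2, mat1-1-1, mat1-1-2, mat1-1-3, mat1-2-1). `fused` requires both
idiomorphs between the flanks on one contig; `split_unlinked` one flanked
idiomorph plus an orphan idiomorph on a flankless contig; a single
idiomorph with both flanks is `single_idiomorph`; everything else —
including the same gene annotated on two contigs — is `incomplete` with an
explanatory evidence string. Gene order and strand inside the locus are
deliberately unconstrained.

Edge reassembly rescues a fused locus split by the assembler: APN2 plus
part of the mat cluster within `edge_distance` of one contig end and SLA2
plus the rest at another contig's end. The distance is measured from the
cluster edge to the contig end with a *strict* inequality, so
`edge_distance = 0` never reassembles; the default 2000 bp is a pragmatic
bound on how much sequence an assembler typically leaves beyond a collapsed
locus, and is configurable.

The coverage test treats reads/kbp as Poisson counts at 1 kbp exposure per
gene and combines a fold criterion with a one-sided conditional binomial
(C-)test of flank rate > mat rate: `elevated_flank` requires ratio ≥ 1.5
*and* p < 0.05, otherwise `equal_coverage`. The dual criterion keeps the
homokaryon false-positive rate far below the test's nominal level while a
balanced heterokaryon at depth 200 (ratio ≈ 2) is detected essentially
always; the one-sided direction matters because in real unlinked-idiomorph
homothallics the mat genes can run slightly *deeper* than the flanks, which
must not be flagged. Pseudogenic mat1-1-3 copies count as present for
architecture but are excluded from the coverage mean (pseudogenes may
diverge in mappability). The reads/kbp unit is modelled abstractly (the
exact read-counting protocol behind published values being unstated);
Poisson per-gene counts are the minimal noise model consistent with it.

Breeding-system inference is a fixed truth table: fused → homothallic;
split_unlinked → homothallic on equal coverage, heterothallic_likely on
elevated flanks, undetermined without coverage; single idiomorph →
heterothallic_likely, except that observed fruiting downgrades it to
single_mating_type_unresolved (partial sexual development with one mating
type leaves homothallism open); incomplete → undetermined. Whether an
unlinked-idiomorph arrangement reflects true genome structure or an
assembly artefact is reported as evidence, never as certainty.

## Numerical conventions

- Half-open 0-based intervals everywhere internally; GFF3 output converts
  to 1-based inclusive.
- Histogram bins are half-open with the top bin closed at 100; identities
  below the first edge (impossible under the default 70% hit threshold) are
  clipped into the first bin rather than dropped, preserving count
  conservation.
- Ties in best-hit selection resolve to the first-seen hit (BLAST output
  order / contig order, forward strand before reverse).
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical parameters and seed give
  byte-identical genomes, truth records and reports.
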