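# Methods

## Model and assumptions

The package models an isolate as a haploid genome carried by a population of
nuclei of at most two genotypes, genotype 1 at proportion *p*. Reads are
assumed to sample nuclei independently, so at a genomic position where the
two genotypes differ, the allele-1 read count at depth *d* is
X ~ Binomial(*d*, *p*); transcription is assumed proportional to genotype
frequency, so the same law governs RNA reads at transcribed variants. A
balanced heterokaryon therefore shows an allele-frequency peak at 0.5, a
homokaryon shows none, and departures (U-shaped distributions, peaks near
0.1/0.9) are interpreted as artefacts of collapsed repeats, assembly gaps or
coverage filtering rather than nuclear composition.

Analysis is deliberately restricted to territory where ddRAD and WG data are
comparable: uniquely re-anchored in-silico EcoRI–MseI fragments ("predicted
ddRAD regions"), intersected with coding intervals and depleted of repeats.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| min depth | 10 | reads | below this a position is NA |
| min allele frequency | 0.1 | fraction of depth | an allele is "recorded" at ≥ 0.1; no further allelic-ratio filter, since any ratio may reflect nuclear composition |
| min site quality | 30 | phred | binomial-tail score of the minor allele (see below) |
| classifier error rate ε | 0.01 | per base | substitution model for the quality score |
| fragment length | ≥ 50 | bp | double-digest size floor |
| repeat identity | 0.80 | fraction | M03 global / M07 per-locus match threshold |
| M12 score band | 30 | score units (match +1, edit −2) | secondary hits within the band count as extra placements |
| graph k | 41 | bases | bubble k-mer size; tests and the acceptance script use k = 21 on short synthetic transcripts (recorded per run) |
| k-mer solidity s | 2 | count | k-mers seen once are discarded |
| bubble support | total ≥ 6, each allele ≥ 2 | reads | retention floor |
| mapping identity | 0.80 transcriptome / 0.90 genome | fraction | bubble placement thresholds |
| mask k / multiplicity | 15 / 4 | — | k-mer interspersed-repeat mask |

Site quality is q = −10·log₁₀ P(X ≥ minor_count) with
X ~ Binomial(depth, ε/3): the probability that sequencing error alone
produces the observed minor-allele support, capped at 999. It plays the
filtering role of a variant caller's QUAL without attempting bit-exact
reproduction of any particular caller. When two alleles pass the frequency
floor but quality fails, the site is classified mono (the minor allele is
treated as unsupported), which keeps the position in coverage denominators.

## Synthetic data generator

`synth` emulates the statistical structure the analysis assumes: a random
genome (default 200 kb, GC 0.30 — AT-rich like the target fungi, which also
yields realistic MseI site densities), non-overlapping gene models with
ATG…stop ORF bodies, exact duplications and multi-copy interspersed
elements, two haplotypes differing at exactly `n_snps` planted positions
(default 300 on 200 kb = 1.5/kb, inside the 0.7–2.8/kb range reported for
real isolates), and WG/ddRAD/RNA reads drawn from the two haplotypes at
ratio *p* with independent per-base substitution errors (default 0.005).
Depth defaults are 30× (WG and ddRAD; real studies report 13–47× and
22–33×) and 50× RNA.

Deliberate simplifications, hence what passing tests do *not* show about
real data:

- Reads are emitted with truth alignments; mapping error, soft-clipping and
  mapping-quality effects are absent.
- Quality strings are constant Q37, including error positions; base-quality
  recalibration and quality-aware calling are not exercised.
- No indels/MNPs, PCR duplicates, coverage biases (GC, fragment-size
  selection windows) or partial digestion.
- Transcript models are single-isoform, unspliced copies of gene intervals;
  expression levels are log-normal (σ = 1) by default — the real
  transcriptome-wide distribution is unknown — or uniform where a stated
  per-transcript coverage is required.
- SNPs are planted ≥ 6 bp away from any EcoRI/MseI motif and never create
  one, so both haplotypes share a single digest map; fragment
  presence/absence polymorphism is therefore out of scope by construction.

## Numerical and design choices

- **Digest.** Cut offsets follow standard chemistry (EcoRI G^AATTC, MseI
  T^TAA), reported 0-based on the top strand; both motifs are palindromic so
  one-strand scanning is complete. "Delimited by an EcoRI and an MseI site"
  is read as two *consecutive* cuts of different enzymes (no internal cut),
  matching double-digest size selection; no upper size bound by default.
  Re-anchoring is exact both-strand occurrence counting at desk scale; an
  identity-threshold search is the natural real-data substitute.
- **Repeat labelling.** A fragment's own locus counts as its first match,
  so "more than one match" means at least one additional locus. M03 uses
  global alignment (match +1 / mismatch −1 / gap −2) with identity =
  matches/columns, with an edit-distance prescreen that cannot change the
  outcome; M07/M12 use seed(13-mer)-and-extend over edlib infix alignment —
  divergence concentrated so that no exact seed survives (> ~8% evenly
  spread substitutions) is invisible to them, as it is to any seeded mapper.
- **Sites.** Allele count ties are broken by count descending then base
  lexicographic; this affects reporting only, never classification.
  Frequencies are raw count/depth fractions, never renormalised. For
  frequency distributions, one of the two allele frequencies per bi-allelic
  site is chosen by a seeded uniform draw (seed 1 by default); histograms
  use 0.01 bins and density curves a Gaussian KDE. Positions are 0-based
  half-open internally; VCF is 1-based at the boundary. Pileup counts use
  base quality ≥ 13 and exclude indel-adjacent bases.
- **Bubbles.** The graph is stranded (stranded RNA libraries), node-centric
  (edges follow from k−1 overlap of solid k-mers), with odd k ≥ 15. Path
  support is the minimum node count along the path — conservative. Only
  simple two-path (Type0a) bubbles are enumerated; placement ambiguity
  means more than one qualifying hit. The bubble centre base decides coding
  status when a bubble straddles an ORF boundary; ORFs are longest ATG-to-
  stop on the transcript strand, 5′-most on ties; translation uses the
  standard nuclear code.
- **Concordance.** The hypergeometric test universe is the set of positions
  with depth ≥ 10 in *both* compared samples inside the analysis territory —
  a conservative eligible-site universe (configurable); results should be
  reported together with this definition. Partition counts are permutation-
  invariant up to pattern relabelling.
- **Determinism.** Every stochastic step derives its generator from the
  study seed plus a fixed stage tag, so stage outputs are reproducible
  independently of execution order; identical configuration and seed give
  byte-identical outputs.

## Residual error rates under the default conditions

Two coincidence effects survive the stated filters and are worth knowing:

- *Genome side*: a false bi-allelic call requires ≥ 3 reads carrying the
  same substituted base at one ~30× position (frequency floor 0.1); at
  0.5% per-base error this occurs at ≈ 5·10⁻⁵ per site, and its
  binomial-tail quality (≈ 38) exceeds the threshold of 30, so expect
  ~0.05 false bi-alleles per kb of 30× territory. Replication removes them:
  the probability that the same coincidence recurs at the same position in
  another replicate is negligible, which is why concordance across
  replicates, not any single-sample filter, is the package's evidence
  standard.
- *RNA side*: two reads sharing a central same-base error form an error
  bubble whose k-mers reach solidity 2 and whose allele counts pass the
  ≥ 2 / ≥ 6 floors. At 0.5% error, 50× and k = 41 this yields a few
  retained bubbles per hundred transcripts. These bubbles are almost never
  *consistent* with the genome call at their coordinate, so they inflate
  only the divergent count — mirroring the behaviour of real homokaryon
  samples.

## Problem sizes

The test suite and acceptance script run on 40–200 kb genomes, 10–80 genes,
80–300 planted SNPs, 30× WG/ddRAD and 50× RNA coverage, three replicates
per data type, and k = 21 graphs; these sizes keep every distributional
check well-powered (hundreds of planted events per assertion) on a single
CPU.

## Known limitations

Reference-free bubble calling cannot see variants within k bp of transcript
ends or pairs of variants closer than k (they break the single-SNP bubble
shape); seeded mapping misses homology without exact seed-length runs; the
site classifier has no genotype-likelihood model and no indel support; and
the hypergeometric test treats positions as exchangeable, ignoring linkage
within fragments.
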