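# Methods

This note documents the models, statistics, and design choices behind
`viromimic`: what each stage computes, why the defaults are what they are,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## The prediction principle

Persistent viruses encode proteins with sequence similarity to the host
proteins they subvert.  Given (i) a virome — sequenced viral nucleic acid
associated with a host — and (ii) the host's predicted proteome, a
translated homology search (protein queries against all six reading frames
of the viral sequences) scores each host protein by how much independent
viral evidence points at it.  Host proteins accumulating many distinct viral
matches are candidate immune components.  The pipeline then strips away
candidates whose function is already knowable (homology to a well-annotated
reference proteome, or a recognised protein domain) to leave a small set of
predicted immune proteins with unknown function.

## Search engine

### Translation and masking

Subjects are translated in all six frames under the standard genetic code;
codons containing N become X, stop codons become `*`, and trailing partial
codons are dropped.  Queries are hard-masked for low complexity before
seeding: any residue inside a sliding window (default 12 aa) whose Shannon
entropy over observed residue frequencies falls below 2.0 bits is replaced
by X.  This entropy window is a deliberate, simple stand-in for SEG-style
masking: it removes homopolymeric and two-letter repeats, which is what
matters for keeping seed statistics honest.

### Seeding and extension

The search is the classical seed-and-extend design: for every query
position, all 3-mers scoring at least `neighbor_thresh` (default 11) against
the query word are enumerated, their database occurrences looked up in a
precomputed word index, and each seed extended ungapped in both directions
with x-drop termination (default 20).  A seed landing inside a region
already extended on the same diagonal is skipped.  Ungapped HSPs whose
E-value is below `gap_trigger_evalue` (default 50, five times the reporting
cutoff) are refined by a full affine-gap Smith–Waterman restricted to a
window of 64 residues around the HSP; the window always contains the
ungapped HSP, so the gapped score can never fall below the ungapped one, and
because a windowed local alignment is also a local alignment of the full
pair, it can never exceed the exact Smith–Waterman score either — both
bounds are enforced by tests against an independently written oracle.
Within each (query, subject, frame), HSPs are kept greedily by descending
score, discarding any HSP that overlaps a kept one by more than half of its
own query span; this stops one mimic region from inflating unique-fragment
counts through stacked, near-duplicate HSPs.

Gap costs follow the BLAST convention: opening a gap costs
`gap_open + gap_extend` (11 + 1 by default) for its first residue and
`gap_extend` per further residue.  Stop codons score −4 against everything
and X scores −1, so translated alignments may run through stops at a penalty
— there is no ORF requirement.  The search contains no randomness; ordering
is fully specified, so results are reproducible byte for byte.

### Score statistics

Raw scores are converted to E-values with ungapped Karlin–Altschul
parameters computed directly from the scoring matrix and its background
frequencies (Robinson & Robinson amino-acid frequencies for BLOSUM62):
λ is the unique positive root of Σᵢⱼ pᵢpⱼ e^(λ·sᵢⱼ) = 1 (root-bracketed to
near machine precision), H = λ·Σᵢⱼ pᵢpⱼ sᵢⱼ e^(λ·sᵢⱼ), and K comes from the
classical lattice-case series K = δλe^(−2σ) / (H(1 − e^(−λδ))) with
σ = Σₖ (1/k)·E[min(1, e^(λSₖ))] over k-step sums of the pair-score walk,
truncated when a term drops below 1e-12.  For BLOSUM62 this yields
λ = 0.31761, K = 0.13374, H = 0.40121, matching the published ungapped
values to four digits.

The E-value of raw score S for a length-m query against a database of n
residues in c sequences is E = K·m′·n′·e^(−λS) with the standard edge
correction ℓ = round(ln(K·m·n)/H), m′ = max(1, m−ℓ), n′ = max(c, n−c·ℓ).
In translated mode, n counts residues over **all six frames** of every
fragment and c counts the translated frame sequences: a 200 bp fragment
contributes six ~66-aa sequences, and since ℓ is ~45 under typical search
sizes, correcting per frame sequence (rather than per fragment) is what
makes the E-values count themselves on null data.  Calibration is tested
empirically: for random queries against a random virome, the number of HSPs
reported at E ≤ 1 must be within a factor of three of the number of queries.

Two deliberate approximations, both conservative for the pipeline's
decisions: ungapped (λ, K) are applied to (mildly) gapped scores, as early
gapped BLAST did — user-supplied gapped parameters are accepted wherever a
`KAParams` is taken — and composition-based score adjustment is not
implemented.  The pipeline consumes E-values only through thresholds
(E < 1e-4, E < 1e-5), and the null-calibration and planted-recovery tests
validate those decisions directly.

## Candidate aggregation and triage

A host protein qualifies when at least `min_fragments` (default 5)
**distinct** virome fragments align to it at E strictly below 1e-4;
fragments are counted once per protein no matter how many HSPs they
produce.  Qualifying proteins pass through a strictly ordered cascade:

1. best reference-proteome hit at E < 1e-5 → `reference_homolog`;
2. otherwise any significant non-viral domain → `domain_annotated`;
3. otherwise a significant viral-tagged domain only → `viral_like`;
4. otherwise → `novel`.

The cascade short-circuits (a protein with both reference homology and
domain hits is classified by homology alone), and the four classes partition
the qualifying set.

Domain models are integer position-specific scoring matrices tagged with a
category (PAMP, apoptosis, viral, other).  Significance of the best sliding
window score uses an empirical null: the protein is residue-shuffled
`n_shuffles` times (default 1000), p = (1 + #{shuffled maxima ≥ observed}) /
(n_shuffles + 1), Bonferroni-corrected by the number of models, and hits are
reported below E < 0.01 — preserving the conventional conserved-domain
cutoff while replacing database-specific statistics with a null that is
exact for any model collection.  At the defaults, a hit therefore requires
that *no* shuffle reaches the observed score, which allows an early-exit
optimisation (a model is abandoned once its exceedance count makes the
cutoff unreachable) that changes neither the hit set nor any reported
p-value.  The shuffle seed is derived per protein, so scan order is
irrelevant.

## Enrichment

For each immune-domain category, the per-domain frequency — the proportion
of proteins carrying at least one hit to that domain (presence/absence, not
hit counts) — is computed in the candidate set and in the whole proteome;
the proteome baseline includes the candidates, which are a subset of it.
The two vectors are compared with a paired two-tailed t-test across the
domains of the category (one pair per domain, df = n_domains − 1), the only
pairing consistent with reporting per-domain frequency bars and a single p
per category.  Degenerate variance (all paired differences identical) is an
explicit error, never a silent p-value; its type-I behaviour is verified by
simulation (rejection rate at α = 0.05 within [0.02, 0.10] on label-shuffled
candidates).

## Transmembrane prediction

Novel-class candidates (by default; a flag widens this to all candidates)
are scanned with a 19-residue Kyte–Doolittle hydropathy window at threshold
1.6 — the scale authors' recommended setting for membrane-spanning
detection.  Maximal runs of above-threshold window centers are expanded to
their full window extents and merged when the expansions overlap.  This is a
simple hydropathy caller, not a topology model: no inside/outside
orientation, no signal-peptide discrimination.  One subtlety follows from
the run-merging semantics: when two hydrophobic blocks are joined by a
linker whose hydropathy lies between two thresholds and whose length exceeds
the window, raising the threshold can split one called segment into two, so
segment counts are not globally monotone in the threshold.  What is
guaranteed — and tested — is nesting: every segment called at a stricter
threshold lies inside a segment called at a looser one.

## The simulator and what passing tests mean

`mimicry_sim` generates the full study design with ground truth.  The
standard scenario (the `SimParams` defaults) is: 500 host proteins of
150–600 aa drawn i.i.d. from the scoring background; 50 immune targets; 10
domain models of 30 positions (+4 consensus / −2 otherwise; 4 PAMP, 4
apoptosis, 1 viral, 1 other — ten models keep the Bonferroni-corrected
minimum E-value, 10/1001, below the 0.01 cutoff at 1000 shuffles); mimics of
100 aa at 70% amino-acid identity, four copies per target (one 100-aa mimic
spans only two 200 bp fragments, so multiple copies are required to clear
the ≥5-fragment rule — mirroring the assumption that genuine immune targets
attract many independent viral segments); ten 50 kb viral genomes; a
reference proteome covering 60% of host proteins at 50% identity.

Construction details that make the ground truth exact:

* Mimics are planted at the nucleotide level — uniform-codon reverse
  translation followed by amino-acid-changing codon substitutions to an
  exact identity — with alternate copies on the minus strand, so both
  strands and all frames are exercised; indels are excluded to keep identity
  bookkeeping exact.
* Each immune protein's domain consensus sits near its N-terminus and mimic
  windows are drawn strictly downstream, so a planted mimic never contains
  the shared consensus; otherwise fragments of one protein's mimic would
  deposit evidence on every same-domain protein and blur precision.
* Domain assignments guarantee one target per assignable domain, one
  viral-only target, and one target with no domain, then draw the remainder
  at random — so all four triage classes are always populated, while
  per-domain counts retain honest sampling variance (an exactly balanced
  assignment would make the paired t-test degenerate by construction).
* Reference coverage is stratified within assignment groups, so the
  viral-only and no-domain strata always retain uncovered members.

What the simulator does **not** emulate: real viral genome architecture
(genes, ORFs, codon bias — uniform synonymous codons are the default, with a
codon-table hook), sequencing error or quality-score models (QC is tested on
hand-written FASTQ), indel divergence, paired-end structure, and
contaminating cellular sequence.  Passing the planted-recovery tests
therefore demonstrates that the statistics and bookkeeping of the pipeline
are correct under the stated divergence model; it does not certify recall on
real viromes, where divergence includes indels, composition bias, and
shorter effective alignments.

## Numerical and engineering choices

* All heavy kernels (seed scan, Smith–Waterman, ungapped extension) are
  compiled single-threaded numba; sequences are packed into one
  sentinel-separated int8 array.  Problem sizes in the tests and the
  acceptance script (the standard scenario: 500 proteins × 2,500 fragments)
  were chosen so a full pipeline run takes under two minutes on one CPU.
* Smith–Waterman traceback ties prefer diagonal, then up (gap in subject),
  then left; the best cell is the first maximum in row-major order.  These
  rules make alignments, not just scores, deterministic.
* Tabular output is BLAST outfmt-6 compatible: subject coordinates are
  1-based inclusive on the original nucleotide fragment with start > end on
  the minus strand; internal coordinates are uniformly 0-based half-open on
  the forward strand.
* E-values are printed with three significant digits (`1e-20`, `0.017`);
  round-tripping a hit table preserves every printed field exactly.
* `PipelineConfig` is a flat YAML-compatible mapping; values are coerced to
  their declared types on load (YAML parsers disagree about bare scientific
  notation), unknown keys are an error naming the key, and every run writes
  its resolved config plus a SHA-256 config digest into the manifest.  No
  output contains timestamps, so identical runs are byte-identical.

## Limitations

* Ungapped statistics on gapped scores under-report significance slightly;
  decisions use fixed thresholds validated by calibration tests, but
  absolute E-values near a cutoff should not be over-interpreted.
* The scoring background is the standard amino-acid background, not the
  codon-usage composition of translated DNA; on translated random sequence
  the true λ is ~9% higher than assumed, i.e. reported E-values are mildly
  conservative at fixed thresholds.  Composition-based adjustment is out of
  scope.
* Short mimicry elements (a few residues, e.g. linear motifs) cannot reach
  significant E-values by construction of local alignment statistics; the
  method is blind to them.
* The domain scan's empirical null is exchangeability of residues within the
  protein; it does not model positional composition bias.
* The hydropathy TM caller trades the accuracy of HMM topology models for
  transparency; its counts are indicative, not a reproduction of HMM-based
  predictions.
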