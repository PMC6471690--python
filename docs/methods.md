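# Methods

## Model and procedure

`editorf` treats c→u RNA editing (c→t at the DNA level) as a generative
hypothesis during ORF extraction rather than as something to predict from
sequence context. Only start and stop codons are edited *in silico*:

* start codons: `atg` (main) and `acg` (edited — one c→t at position 2 gives
  `atg`);
* stop codons: `taa`, `tag`, `tga` (main) and `caa`, `cag`, `cga` (edited —
  the complete set of codons one c→t substitution away from a main stop; no
  other codon becomes a stop under any combination of c→t edits).

Internal codons are never modified: an internal `acg` translates to T.
Translation uses the standard genetic code (plant mitochondria do not use a
deviant code), with the first codon forced to M and `n`-containing codons
rendered X. Codons containing `n` never match a start or stop.

Extraction scans each of the six strand×frame combinations once, left to
right, with the maximal-ORF rule: the earliest unconsumed start codon is
tracked; every stop codon terminates the current segment (whether or not an
ORF is emitted) and scanning resumes after it; an ORF is emitted when its
sense length reaches θ_len. Anchoring at the earliest start — even when an
edited `acg` precedes a main `atg` — is deliberate: a start codon is also a
sense codon, so the earliest anchor yields the maximal ORF per stop, at most
one candidate per (strand, frame, stop).

A consequence worth noting: the editing-aware scan is **not** a superset of
the standard scan. When an `acg` precedes the first `atg` of a segment, the
editing-aware ORF starts earlier and the standard cut is not produced at all
(the two scans cut the sequence differently). The invariant that does hold,
and that the test suite asserts, is the converse: every main/main candidate
of the editing-aware scan has an identical standard counterpart.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `theta_len` | 300 nt | minimum ORF length; the conventional cut-off for a potential protein-coding segment (~100 aa) |
| `use_edited_starts` | on | recognize `acg` as a start |
| `use_edited_stops` | off | recognize `caa`/`cag`/`cga` as stops; enlarging the stop set can only shorten ORFs |
| `length_includes_stop` | off | whether the stop codon's 3 nt count toward the θ_len comparison; reported lengths always exclude the stop |
| `strand_mode` | same | whether sub/int overlap requires the standard ORF on the same strand |
| similarity threshold | bitscore 200 | blastp score at/above which a candidate "encodes a known protein" (inclusive) |
| report bin edge | bitscore 80 | lower edge of the secondary evidence bin, [80, 200) half-open so 200 is never double-reported |

## Coordinate and naming conventions

Coordinates are 1-based inclusive on the scanned strand; reverse-strand ORFs
use positions within the reverse-complemented sequence. Every candidate also
carries its footprint (start codon through stop codon) projected onto the
forward reference, which is the axis used for overlap classification and for
deciding whether a standard tool would have produced the identical
extraction ("novel" = no standard ORF with the same strand and footprint).
Genomes are always scanned as linear molecules, even when a GenBank record
declares a circular topology; origin-spanning ORFs are out of scope, which
can cost a few candidates on a circular mitochondrial genome.

## Triage

Similarity search uses local NCBI BLAST+ executables via subprocess with
tabular output (`qseqid sseqid bitscore staxids stitle`), default aligner
parameters, best bitscore per query. Only the 200 threshold and the 80 bin
edge are method semantics. "Same organism" is decided by taxon id when the
database provides one and a `self_taxid` is configured, otherwise by
case-insensitive scientific-name prefix against `self_name` — deliberately
operator-controlled, because "the input organism" may be meant at species,
subspecies or cultivar-group level. Candidates similar to a protein of the
input organism are dropped; the remainder are catalogued with their best
evidence, and the no-known-protein set is additionally screened against an
EST database with tblastn (queried with the translated, i.e. edited, protein
sequence).

## Synthetic data

`make_genome` plants ORFs with chosen strand and start/stop codon types in a
background engineered so the scanner's expected output equals the planted
truth exactly:

* the background contains no `atg`/`acg` on either strand anywhere — the
  generator forbids the substrings {atg, acg, cat, cgt} (the starts and
  their reverse complements), which at once prevents spurious ORFs and
  prevents a background start from extending a planted ORF upstream;
* planted interiors draw codons from a 20-codon set that is free of main and
  edited stops in frame and closed under concatenation against the same
  forbidden substrings, so a planted segment cannot seed an ORF in any other
  frame or strand. The greedy construction of that set is seeded with an
  order chosen to maximize amino-acid diversity (14 distinct residues), so
  planted proteins are not flagged as low-complexity by aligners;
* a repair pass resamples background bases at segment junctions until no
  forbidden substring survives outside planted start codons.

Generation is deterministic given the seed. What this emulates is the
*logical* structure of an editing-hidden ORF, not real mitochondrial DNA: the
background is not compositionally realistic, carries no editing-site sequence
context, no genes, introns or repeats. Passing the recovery tests therefore
demonstrates correctness of the scanning/classification logic, not
performance on real genomes. Plain uniform-random genomes (`random_genome`)
are used separately to exercise incidental ORF handling against an
independent brute-force enumeration; on such genomes roughly 40% of
editing-aware candidates have no identical standard extraction — higher than
on real mtDNA, where base composition and gene density differ.

Toy BLAST databases (`make_toy_blast_dbs`) realize a chosen ground-truth
partition: self-organism proteins (taxid-mapped), other-organism proteins,
EST transcripts of selected candidates (with the edited start written as
`atg`, as the cell would transcribe it), plus unrelated decoys.

## Numerical and design choices

* Reported ORF length excludes the stop codon (`stop_pos − start_pos`); the
  alternative reading is available via `length_includes_stop` because it
  shifts which ORFs sit at the θ_len boundary.
* Intervals are closed; a single shared base counts as an `int` overlap.
* When several standard ORFs overlap a candidate, the recorded match is the
  one with the largest overlap, ties to the smallest start coordinate;
  containment takes precedence over larger partial overlaps (a container's
  overlap is always maximal anyway).
* Candidate ordering is deterministic everywhere: (strand, frame, start) for
  scans, (bitscore desc, start asc) for catalogues.
* An absent BLAST hit is represented by the absence of a summary, never a
  fabricated score of 0; sub-threshold records go to an `unsupported.tsv`
  rather than being dropped silently.
* Genome-scale summaries (`paper_scale_counts`) report candidate and novel
  counts under the 2×2 grid of the two genuinely open conventions
  (`length_includes_stop` × `strand_mode`), since neither is fixed by the
  method's description.

## Problem sizes

The test suite and acceptance script run on synthetic genomes of 2–100 kb:
100 random genomes of 5–50 kb for oracle equivalence, 50 planted genomes
(1–10 ORFs each) for recovery, 8-candidate toy databases for triage. These
sizes exercise every code path at full fidelity; scanning is linear in genome
length (a 490 kb mitochondrial genome takes well under a second).

## Known limitations

* No wrap-around ORFs on circular genomes.
* No editing of internal codons, no alternative (non-`atg`/`acg`) starts, no
  trans-splicing awareness, no editing-site context modelling.
* Homology triage quality is entirely a function of the databases supplied;
  the package ships only toy databases for testing.
* The brute-force oracle and the scanner agree exactly, but both implement
  the same stated rules; neither validates the biological premise that
  edited starts are used in vivo — that is what the EST/protein evidence
  stages are for.
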