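# editorf

Editing-aware discovery of candidate open reading frames (ORFs) in plant
mitochondrial genomes.

## The problem

In the mitochondria (and chloroplasts) of flowering plants, messenger RNAs are
post-transcriptionally edited, almost always by cytidine→uridine (c→u)
conversion — c→t relative to the DNA. Editing at the second position of a
genomic `acg` triplet creates the initiation codon `aug`; editing at the first
position of `caa`/`cag`/`cga` creates a stop codon. A conventional ORF finder,
which only recognizes `atg` starts, is blind to any protein whose start codon
exists only after editing, so part of the coding content of plant mtDNA stays
invisible to standard annotation.

`editorf` simulates this editing while scanning: it enumerates candidate ORFs
across all six reading frames, recognizing both `atg` and edited `acg` starts
(and optionally edited stops), labels each candidate against what a standard
scanner would return, and triages candidates by sequence homology into result
catalogues for expert review.

## The method

For each of the 6 strand×frame combinations, codons are scanned left to right
under the **maximal-ORF rule**: track the earliest unconsumed start codon
(`atg` or, with editing, `acg`); on reaching a stop codon, emit the ORF from
that start iff its length ≥ θ_len (default 300 nt), then resume after the
stop. Intermediate start codons are ignored — a start codon is also a sense
codon, so the earliest start yields the largest ORF ending at a given stop.
Stops are never read through. Enabling edited stops (`caa`/`cag`/`cga`, off by
default) only enlarges the stop set and therefore only shortens ORFs.

Downstream stages:

* **classify** — each candidate is labeled `sub` (contained in), `int`
  (intersects) or `new` (disjoint from) the ORFs of a standard, non-editing
  scan of the same genome, on forward-reference coordinates, same strand by
  default.
* **triage** — `blastp` against a known-protein database partitions candidates
  at bitscore ≥ 200 into *already known in the input organism* (dropped),
  *known in another organism* (retained), and *no known protein*; the last set
  is screened for transcript evidence against an EST database with `tblastn`.
* **report** — retained candidates are written as TSV catalogues binned by
  best bitscore, [200, ∞) and [80, 200), ordered by descending bitscore.

## Worked example

Build a synthetic genome with three planted ORFs — two of them findable only
through editing — and scan it:

```python
from editorf import *

specs = [
    PlantedOrfSpec("fwd", "edited", "main", aa_length=120),
    PlantedOrfSpec("rev", "main", "main", aa_length=115),
    PlantedOrfSpec("fwd", "edited", "edited", aa_length=110),
]
genome, truth = make_genome(specs, background_length=5000, seed=42)
write_fasta([(genome.id, genome.residues)], "demo.fasta")

cands = extract_orfs(genome, CodonModel(use_edited_stops=True), theta_len=300)
for c in cands:
    print(c.id, c.strand, f"frame={c.frame}", f"start={c.start_pos}",
          f"{c.start_type}/{c.stop_type}", f"len={c.orf_length}")
```

prints

```
orf0001 fwd frame=1 start=7 edited/main len=360
orf0002 fwd frame=2 start=734 edited/edited len=330
orf0003 rev frame=3 start=4278 main/main len=345
```

— the two `edited`-start ORFs and the ordinary one, with 1-based start
positions on their own strand and lengths excluding the stop codon. Comparing
with a standard scan labels them:

```python
std = standard_orfs(genome, theta_len=300)
print([l.value for l in classify_all(cands, std)])  # ['new', 'new', 'sub']
print(count_novel(cands, std))                      # (3, 2)
```

Two of three candidates are not extractable by a standard tool. The same flow
is available from the shell:

```
$ editorf summary --in demo.fasta
genome            : synthetic (5000 nt)
candidate ORFs    : 3
standard ORFs     : 1
novel (not std)   : 2 (66.7%)
labels            : {'new': 2, 'sub': 1}
```

(`editorf summary` scans with the default model — edited starts on, edited
stops off.) `editorf scan | classify | run` expose the full pipeline,
including BLAST triage driven by a `data.properties`-style config file naming
`blastp_path`, `tblastn_path`, `protein_db`, `est_db`, `self_taxid` and
`self_name`.

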