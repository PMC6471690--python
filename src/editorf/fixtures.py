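"""Synthetic genomes with planted ORFs, and toy BLAST databases.

The generator plants ORFs whose start and/or stop codons require c->t
editing to be recognized, inside a background engineered so that the
scanner's expected output is *exactly* the planted truth table:

* the background contains no start codon (``atg``/``acg``) on either strand
  anywhere — a trigram-exclusion model forbids the substrings
  {atg, acg, cat, cgt} (the two starts and their reverse complements) — so
  no spurious ORF can begin outside a planted segment, and no background
  start can extend a planted ORF leftward;
* planted ORF interiors are built from a codon set that is free of in-frame
  stops (main and edited) and closed under concatenation against the same
  trigram exclusions, so a planted segment cannot seed an ORF in any other
  frame or on the other strand.

Truth is therefore unambiguous by construction, under any edited-start /
edited-stop flag combination that recognizes the planted codon types.  This
deliberately does not emulate real compositional features of mitochondrial
DNA (base composition, editing-site context, gene density); it isolates the
scanning logic.  Plain random backgrounds (``random_genome``) are provided
separately so incidental-ORF handling can be exercised against a brute-force
oracle instead of a truth table.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .scanner import (
    EDITED_STARTS,
    EDITED_STOPS,
    MAIN_STOPS,
    CodonType,
    OrfCandidate,
    Strand,
    translate,
)
from .sequence_io import GenomeSequence, reverse_complement, write_fasta

# Substrings that could create a start codon in any frame on either strand:
# atg/acg forward, cat/cgt are their reverse complements.
_FORBIDDEN = ("atg", "acg", "cat", "cgt")
_BASES = "acgt"


class BlastToolsMissing(RuntimeError):
    """makeblastdb (or another BLAST+ tool) is not on PATH; tests should skip."""


# ---------------------------------------------------------------------------
# Safe interior codons
# ---------------------------------------------------------------------------

def _trigram_free(s: str) -> bool:
    return not any(s[i : i + 3] in _FORBIDDEN for i in range(len(s) - 2))


def _pair_safe(c1: str, c2: str) -> bool:
    """No forbidden trigram spans the junction c1|c2."""
    return _trigram_free(c1[1:] + c2[:2])


# Greedy seed order chosen to maximize amino-acid diversity of the resulting
# set (14 distinct residues), so planted proteins look protein-like enough
# for aligners not to mask them as low-complexity.
_CODON_PREFERENCE = (
    "aag", "act", "agg", "agt", "att", "cct", "cgg", "ctg", "ctt", "gag",
    "gct", "ggg", "ggt", "gtg", "gtt", "tct", "tgg", "tgt", "ttg", "ttt",
)


def _build_safe_codons() -> Tuple[str, ...]:
    """Codons usable in planted-ORF interiors: not stops (main or edited),
    internally trigram-free, and pairwise junction-safe in either order."""
    forbidden_codons = MAIN_STOPS | EDITED_STOPS | {"atg", "acg"}
    pool = [c for c in _CODON_PREFERENCE] + [
        "".join(c)
        for c in product(_BASES, repeat=3)
        if "".join(c) not in _CODON_PREFERENCE
    ]
    pool = [c for c in pool if c not in forbidden_codons and _trigram_free(c)]
    safe: List[str] = []
    for cand in pool:
        if _pair_safe(cand, cand) and all(
            _pair_safe(cand, s) and _pair_safe(s, cand) for s in safe
        ):
            safe.append(cand)
    return tuple(safe)


SAFE_CODONS = _build_safe_codons()


# ---------------------------------------------------------------------------
# Planted ORFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedOrfSpec:
    """One ORF to embed: where, on which strand, with which codon types.

    ``aa_length`` counts translated residues (initiator M included); the
    genomic footprint is ``3 * aa_length + 3`` nt including the stop codon.
    ``position`` is the 1-based forward coordinate of the footprint's first
    base, or None for automatic layout.
    """

    strand: Strand = "fwd"
    start_type: CodonType = "main"
    stop_type: CodonType = "main"
    aa_length: int = 110
    position: Optional[int] = None

    @property
    def footprint(self) -> int:
        return 3 * self.aa_length + 3


_START_OF = {"main": "atg", "edited": "acg"}
_STOPS_OF = {"main": sorted(MAIN_STOPS), "edited": sorted(EDITED_STOPS)}


def _orf_block(spec: PlantedOrfSpec, rng: np.random.Generator) -> str:
    """Start codon + interior + stop codon, on the ORF's own (scanned) strand."""
    start = _START_OF[spec.start_type]
    stop = rng.permutation(_STOPS_OF[spec.stop_type])[0]
    n_interior = spec.aa_length - 1
    firsts = [c for c in SAFE_CODONS if _pair_safe(start, c)]
    lasts = [c for c in SAFE_CODONS if _pair_safe(c, stop)]
    if n_interior < 1:
        raise ValueError("aa_length must be >= 2")
    interior = [str(rng.choice(SAFE_CODONS)) for _ in range(n_interior)]
    interior[0] = str(rng.choice([c for c in firsts if n_interior > 1 or c in lasts]))
    if n_interior > 1:
        interior[-1] = str(rng.choice(lasts))
    return start + "".join(interior) + stop


def _background(n: int, rng: np.random.Generator, context: str = "") -> str:
    """n random bases avoiding forbidden trigrams, given 2 bases of left context."""
    out: List[str] = []
    tail = context[-2:]
    for _ in range(n):
        choices = [b for b in _BASES if (tail + b)[-3:] not in _FORBIDDEN]
        b = str(rng.choice(choices))
        out.append(b)
        tail = (tail + b)[-2:]
    return "".join(out)


def _truth_candidate(
    spec: PlantedOrfSpec, pos: int, block: str, genome_len: int
) -> OrfCandidate:
    L = spec.footprint
    if spec.strand == "fwd":
        start_pos = pos
    else:
        start_pos = genome_len - (pos + L - 1) + 1
    stop_pos = start_pos + 3 * spec.aa_length
    nt = block[:-3]
    fwd_lo = pos
    fwd_hi = pos + L - 1
    return OrfCandidate(
        strand=spec.strand,
        frame=(start_pos - 1) % 3 + 1,
        start_pos=start_pos,
        stop_pos=stop_pos,
        start_type=spec.start_type,
        stop_type=spec.stop_type,
        nt_seq=nt,
        aa_seq=translate(nt, spec.start_type),
        fwd_interval=(fwd_lo, fwd_hi),
    )


def _layout(specs: Sequence[PlantedOrfSpec], total: int, rng: np.random.Generator) -> List[int]:
    """Assign 1-based forward positions; keeps >= 6 nt of background between
    segments and at both ends."""
    gap = 6
    placed = [s for s in specs if s.position is not None]
    auto = [s for s in specs if s.position is None]
    intervals: List[Tuple[int, int]] = []
    for s in placed:
        intervals.append((s.position, s.position + s.footprint - 1))
    need = sum(s.footprint for s in auto) + gap * (len(specs) + 1)
    if need + sum(s.footprint for s in placed) > total:
        raise ValueError(f"specs do not fit in background_length={total}")
    positions: Dict[int, int] = {}
    cursor = 1 + gap
    for idx, s in enumerate(specs):
        if s.position is not None:
            positions[idx] = s.position
            continue
        # slide cursor past any explicitly placed interval
        while True:
            lo, hi = cursor, cursor + s.footprint - 1
            clash = next(
                (iv for iv in intervals if not (hi + gap < iv[0] or lo > iv[1] + gap)), None
            )
            if clash is None:
                break
            cursor = clash[1] + gap + 1
        if cursor + s.footprint - 1 + gap > total:
            raise ValueError(f"specs do not fit in background_length={total}")
        positions[idx] = cursor
        intervals.append((cursor, cursor + s.footprint - 1))
        cursor += s.footprint + gap + int(rng.integers(0, gap))
    ordered = sorted(intervals)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(ordered, ordered[1:]):
        if b_lo <= a_hi + 2:
            raise ValueError("planted segments overlap or touch (need >= 3 nt gap)")
    return [positions[i] for i in range(len(specs))]


def make_genome(
    specs: Sequence[PlantedOrfSpec],
    background_length: int,
    seed: int,
    id: str = "synthetic",
) -> Tuple[GenomeSequence, List[OrfCandidate]]:
    """Build a genome of ``background_length`` nt containing exactly the
    planted ORFs, plus the expected candidate list (the truth table).

    Deterministic given ``seed``.  The truth list is sorted the way the
    scanner sorts its output, (strand, frame, start_pos).
    """
    rng = np.random.default_rng(seed)
    positions = _layout(specs, background_length, rng)
    blocks: List[Tuple[int, str, PlantedOrfSpec]] = []
    for spec, pos in zip(specs, positions):
        block = _orf_block(spec, rng)
        fwd_block = block if spec.strand == "fwd" else reverse_complement(block)
        blocks.append((pos, fwd_block, spec))
    blocks.sort(key=lambda t: t[0])

    chars = np.full(background_length, "", dtype=object)
    for pos, fwd_block, _ in blocks:
        chars[pos - 1 : pos - 1 + len(fwd_block)] = list(fwd_block)
    planted_mask = np.array([c != "" for c in chars])
    seq = "".join(c if c else "x" for c in chars)
    # fill gaps left to right with context-aware background
    out = list(seq)
    i = 0
    while i < background_length:
        if out[i] == "x":
            j = i
            while j < background_length and out[j] == "x":
                j += 1
            ctx = "".join(out[max(0, i - 2) : i])
            out[i:j] = list(_background(j - i, rng, context=ctx))
            i = j
        else:
            i += 1
    residues = _repair("".join(out), planted_mask, blocks, rng)
    genome = GenomeSequence(id=id, residues=residues)
    # truth is read back from the repaired genome (repairs never touch
    # planted bases, but reading back keeps truth and genome trivially in sync)
    truth: List[OrfCandidate] = []
    for spec, pos in zip(specs, positions):
        block_fwd = residues[pos - 1 : pos - 1 + spec.footprint]
        block_scanned = block_fwd if spec.strand == "fwd" else reverse_complement(block_fwd)
        truth.append(_truth_candidate(spec, pos, block_scanned, background_length))
    truth.sort(key=lambda c: (c.strand, c.frame, c.start_pos))
    return genome, truth


def _repair(
    seq: str,
    planted_mask: np.ndarray,
    blocks: Sequence[Tuple[int, str, PlantedOrfSpec]],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> str:
    """Resample background bases until no forbidden trigram survives outside
    planted start codons (junction trigrams can straddle segment edges)."""
    allowed: set = set()
    for pos, fwd_block, spec in blocks:
        # forward-axis location of the start codon trigram within the block
        if spec.strand == "fwd":
            allowed.add(pos - 1)
        else:
            allowed.add(pos - 1 + len(fwd_block) - 3)
    out = list(seq)
    n = len(out)
    for _ in range(max_rounds):
        dirty = False
        for i in range(n - 2):
            if "".join(out[i : i + 3]) in _FORBIDDEN and i not in allowed:
                bg = [j for j in range(i, i + 3) if not planted_mask[j]]
                if not bg:
                    raise AssertionError("forbidden trigram inside planted segment")
                j = bg[-1]
                old = out[j]
                out[j] = str(rng.choice([b for b in _BASES if b != old]))
                dirty = True
        if not dirty:
            return "".join(out)
    raise AssertionError("could not repair background trigrams")


def random_genome(length: int, seed: int, id: str = "random") -> GenomeSequence:
    """Plain uniform random genome (no suppression) for oracle-based tests."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(_BASES), size=length))
    return GenomeSequence(id=id, residues=residues)


# ---------------------------------------------------------------------------
# Toy BLAST databases
# ---------------------------------------------------------------------------

_OTHER_ORGANISMS = [("Zea mays", "4577"), ("Triticum aestivum", "4565"), ("Vicia faba", "3906")]

ExpectedPartition = Dict[str, str]


def blast_tools_available() -> bool:
    return all(shutil.which(t) for t in ("makeblastdb", "blastp", "tblastn"))


def _edited_transcript(cand: OrfCandidate) -> str:
    """The candidate's coding sequence as the cell would transcribe it:
    the (possibly edited) start codon reads atg."""
    return "atg" + cand.nt_seq[3:]


def make_toy_blast_dbs(
    candidates: Sequence[OrfCandidate],
    out_dir: Union[str, Path],
    self_name: str = "Oryza sativa",
    self_taxid: str = "4530",
    assignments: Optional[ExpectedPartition] = None,
    seed: int = 0,
) -> Tuple[str, str, ExpectedPartition]:
    """Build toy protein and EST databases realizing a chosen partition.

    ``assignments`` maps candidate id -> one of ``to_drop``,
    ``known_other_organism``, ``no_known_protein_est`` (absent from the
    protein db but present in the EST db) or ``no_known_protein`` (absent
    everywhere); unlisted candidates cycle through the four in order.
    Returns (protein_db, est_db, expected_partition).  Raises
    :class:`BlastToolsMissing` when makeblastdb is unavailable.
    """
    if not blast_tools_available():
        raise BlastToolsMissing("NCBI BLAST+ executables not found on PATH")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cycle = ["to_drop", "known_other_organism", "no_known_protein_est", "no_known_protein"]
    expected: ExpectedPartition = {}
    for i, cand in enumerate(candidates):
        expected[cand.id] = (assignments or {}).get(cand.id, cycle[i % 4])

    prot_records: List[Tuple[str, str]] = []
    est_records: List[Tuple[str, str]] = []
    taxid_map: List[str] = []
    for i, cand in enumerate(candidates):
        role = expected[cand.id]
        if role == "to_drop":
            sid = f"self{i:03d}"
            prot_records.append((f"{sid} hypothetical protein [{self_name}]", cand.aa_seq))
            taxid_map.append(f"{sid} {self_taxid}")
        elif role == "known_other_organism":
            org, taxid = _OTHER_ORGANISMS[i % len(_OTHER_ORGANISMS)]
            sid = f"other{i:03d}"
            prot_records.append((f"{sid} hypothetical protein [{org}]", cand.aa_seq))
            taxid_map.append(f"{sid} {taxid}")
        elif role == "no_known_protein_est":
            sid = f"est{i:03d}"
            est_records.append((f"{sid} cDNA clone", _edited_transcript(cand)))
    # decoys so neither database is empty and searches see unrelated subjects
    decoy_aa = "".join(rng.choice(list("LIVFWYHQDEKRSP"), size=120))
    prot_records.append((f"decoy000 unrelated protein [Arabidopsis thaliana]", decoy_aa))
    taxid_map.append("decoy000 3702")
    est_records.append(("estdecoy000 unrelated cDNA", random_genome(400, seed + 1).residues))

    prot_fa = out_dir / "proteins.faa"
    est_fa = out_dir / "ests.fna"
    write_fasta(prot_records, prot_fa)
    write_fasta(est_records, est_fa)
    (out_dir / "taxid_map.txt").write_text("\n".join(taxid_map) + "\n")

    prot_db = str(out_dir / "protdb")
    est_db = str(out_dir / "estdb")
    _makeblastdb(prot_fa, prot_db, "prot", out_dir / "taxid_map.txt")
    _makeblastdb(est_fa, est_db, "nucl", None)
    return prot_db, est_db, expected


def _makeblastdb(fasta: Path, out: str, dbtype: str, taxid_map: Optional[Path]) -> None:
    cmd = [
        "makeblastdb", "-in", str(fasta), "-dbtype", dbtype, "-out", out, "-parse_seqids",
    ]
    if taxid_map is not None:
        cmd += ["-taxid_map", str(taxid_map)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"makeblastdb failed:\n{proc.stderr}")
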