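"""Editing-aware ORF extraction across six reading frames.

In plant mitochondria, post-transcriptional c->u RNA editing (c->t relative to
the DNA) can create translation start codons — a genomic ``acg`` becomes the
initiator ``aug`` after editing of its second position — and, more rarely,
stop codons (``caa``/``cag``/``cga`` -> ``taa``/``tag``/``tga``).  A scanner
that only recognizes ``atg`` misses any protein whose start exists only after
editing.  This module simulates the editing of start (and optionally stop)
codons while scanning, so that such hidden ORFs are enumerated alongside
standard ones.

The extraction rule per frame is the *maximal-ORF* rule: track the earliest
unconsumed start codon (main ``atg`` or edited ``acg``); on reaching a stop
codon, emit the ORF from that earliest start iff its length reaches the
minimum ``theta_len`` (default 300 nt), then resume scanning after the stop.
Intermediate start codons are ignored — a start codon is also a sense codon,
so anchoring at the earliest start simply yields the largest ORF ending at
that stop.  Stops can never be read through: a stop codon admits no other
interpretation.  Enabling edited stops only enlarges the stop set, hence can
only shorten ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Literal, Optional, Tuple

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .sequence_io import GenomeSequence, reverse_complement

# ---------------------------------------------------------------------------
# Codon model
# ---------------------------------------------------------------------------

MAIN_STARTS = frozenset({"atg"})
EDITED_STARTS = frozenset({"acg"})
MAIN_STOPS = frozenset({"tag", "tga", "taa"})
# Codons one c->t edit away from a main stop (all edits at codon position 1);
# no other codon becomes a stop under any combination of c->t substitutions.
EDITED_STOPS = frozenset({"caa", "cag", "cga"})

DEFAULT_THETA_LEN = 300

Strand = Literal["fwd", "rev"]
CodonType = Literal["main", "edited"]


@dataclass(frozen=True)
class CodonModel:
    """Active start/stop codon sets, split into main and edited members.

    Defaults follow the method's study conditions: edited starts on,
    edited stops off.
    """

    use_edited_starts: bool = True
    use_edited_stops: bool = False
    main_starts: FrozenSet[str] = MAIN_STARTS
    edited_starts: FrozenSet[str] = EDITED_STARTS
    main_stops: FrozenSet[str] = MAIN_STOPS
    edited_stops: FrozenSet[str] = EDITED_STOPS

    def __post_init__(self) -> None:
        if self.main_starts & self.edited_starts or self.main_stops & self.edited_stops:
            raise ValueError("main and edited codon sets must be disjoint")

    @property
    def active_starts(self) -> FrozenSet[str]:
        return self.main_starts | self.edited_starts if self.use_edited_starts else self.main_starts

    @property
    def active_stops(self) -> FrozenSet[str]:
        return self.main_stops | self.edited_stops if self.use_edited_stops else self.main_stops

    def start_type(self, codon: str) -> CodonType:
        return "main" if codon in self.main_starts else "edited"

    def stop_type(self, codon: str) -> CodonType:
        return "main" if codon in self.main_stops else "edited"


STANDARD_MODEL = CodonModel(use_edited_starts=False, use_edited_stops=False)


# ---------------------------------------------------------------------------
# Candidate container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfCandidate:
    """One extracted ORF.

    ``start_pos``/``stop_pos`` are 1-based positions of the first base of the
    start / terminating stop codon on the *scanned* strand.  ``orf_length``
    excludes the stop codon (``stop_pos - start_pos``).  ``fwd_interval`` is
    the ORF's full genomic footprint (start codon through stop codon, both
    inclusive) projected onto the forward reference, used for overlap
    classification.
    """

    strand: Strand
    frame: int  # 1..3 on the scanned strand
    start_pos: int
    stop_pos: int
    start_type: CodonType
    stop_type: CodonType
    nt_seq: str
    aa_seq: str
    fwd_interval: Tuple[int, int]
    id: str = field(default="", compare=False)

    @property
    def orf_length(self) -> int:
        return self.stop_pos - self.start_pos

    def identity_key(self) -> Tuple[str, int, int]:
        """(strand, fwd start, fwd end): what 'the same extraction' means."""
        return (self.strand, *self.fwd_interval)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

_TABLE = unambiguous_dna_by_id[1]  # plant mitochondria use the standard code
_CODON_TO_AA = {codon.lower(): aa for codon, aa in _TABLE.forward_table.items()}
_CODON_TO_AA.update({codon.lower(): "*" for codon in _TABLE.stop_codons})


def translate(nt_seq: str, start_type: CodonType = "main") -> str:
    """Translate an ORF nucleotide sequence under the standard genetic code.

    The first codon translates to M whether it is ``atg`` or the edited
    ``acg`` (post-editing it is ``aug``).  Internal codons are translated
    literally: no internal editing is simulated, so internal ``acg`` is T.
    Codons containing ``n`` translate to X.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} is not a multiple of 3")
    aas = [_CODON_TO_AA.get(nt_seq[i : i + 3], "X") for i in range(0, len(nt_seq), 3)]
    if aas:
        aas[0] = "M"
    return "".join(aas)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _fwd_interval(strand: Strand, start_pos: int, stop_pos: int, genome_len: int) -> Tuple[int, int]:
    """Project the ORF footprint [start_pos, stop_pos+2] onto the forward axis."""
    lo, hi = start_pos, stop_pos + 2
    if strand == "fwd":
        return (lo, hi)
    return (genome_len - hi + 1, genome_len - lo + 1)


def _scan_strand(
    residues: str,
    strand: Strand,
    model: CodonModel,
    theta_len: int,
    genome_len: int,
    length_includes_stop: bool,
) -> List[OrfCandidate]:
    starts = model.active_starts
    stops = model.active_stops
    min_sense = theta_len - 3 if length_includes_stop else theta_len
    out: List[OrfCandidate] = []
    n = len(residues)
    for frame in (1, 2, 3):
        tracked: Optional[int] = None  # 0-based index of earliest unconsumed start
        for i in range(frame - 1, n - 2, 3):
            codon = residues[i : i + 3]
            if codon in stops:
                if tracked is not None:
                    length = i - tracked
                    if length >= min_sense and length >= 3:
                        nt = residues[tracked:i]
                        stype = model.start_type(residues[tracked : tracked + 3])
                        out.append(
                            OrfCandidate(
                                strand=strand,
                                frame=frame,
                                start_pos=tracked + 1,
                                stop_pos=i + 1,
                                start_type=stype,
                                stop_type=model.stop_type(codon),
                                nt_seq=nt,
                                aa_seq=translate(nt, stype),
                                fwd_interval=_fwd_interval(strand, tracked + 1, i + 1, genome_len),
                            )
                        )
                    tracked = None
            elif tracked is None and codon in starts:
                tracked = i
    return out


def extract_orfs(
    genome: GenomeSequence,
    codon_model: Optional[CodonModel] = None,
    theta_len: int = DEFAULT_THETA_LEN,
    length_includes_stop: bool = False,
) -> List[OrfCandidate]:
    """Enumerate editing-aware candidate ORFs over all six strand×frame combinations.

    Parameters
    ----------
    genome : GenomeSequence
        Normalized input sequence; scanned as linear.
    codon_model : CodonModel, optional
        Active codon sets; defaults to edited starts on, edited stops off.
    theta_len : int
        Minimum ORF length in nucleotides (default 300).
    length_includes_stop : bool
        If True, the stop codon's 3 nt count toward the ``theta_len``
        comparison (the reported ``orf_length`` always excludes the stop).
        Exposed because either reading of "ORF length" is defensible; it only
        shifts the threshold boundary.

    Returns
    -------
    list of OrfCandidate, sorted by (strand, frame, start_pos), with ids
    assigned ``orf0001``, ``orf0002``, ...
    """
    model = codon_model or CodonModel()
    if theta_len < 3:
        raise ValueError(f"theta_len must be >= 3, got {theta_len}")
    if genome.length == 0:
        return []
    fwd = _scan_strand(genome.residues, "fwd", model, theta_len, genome.length, length_includes_stop)
    rev = _scan_strand(
        reverse_complement(genome.residues), "rev", model, theta_len, genome.length, length_includes_stop
    )
    candidates = sorted(fwd + rev, key=lambda c: (c.strand, c.frame, c.start_pos))
    return [replace(c, id=f"orf{i:04d}") for i, c in enumerate(candidates, start=1)]


def standard_orfs(
    genome: GenomeSequence,
    theta_len: int = DEFAULT_THETA_LEN,
    length_includes_stop: bool = False,
) -> List[OrfCandidate]:
    """Extraction with editing disabled: atg starts, {tag,tga,taa} stops only.

    This is the reference output of a standard six-frame ORF extractor with
    the same maximal-ORF rule and length threshold.
    """
    orfs = extract_orfs(
        genome, STANDARD_MODEL, theta_len=theta_len, length_includes_stop=length_includes_stop
    )
    return [replace(c, id=f"std{i:04d}") for i, c in enumerate(orfs, start=1)]
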